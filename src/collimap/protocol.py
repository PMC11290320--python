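"""Periodic visual-stimulation protocol constants.

Two session types are used to map the superior colliculus (SC) with
intrinsic optical imaging:

* **Sweeps** — a bar drifts across the screen once per stimulus cycle
  (1/8 Hz), repeated 30 times (4 min per session).  Opposite-direction
  sessions (e.g. rightward/leftward) are paired so the hemodynamic delay
  cancels.
* **Rotations** — an oriented drifting grating rotates at 2 rpm for
  20 full turns (10 min).  Because a grating is 180°-periodic, the
  orientation signal repeats twice per rotation, so the analysis
  frequency is 2 × (2/60) Hz = 1/15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

SWEEP_DIRECTIONS = ("rightward", "leftward", "downward", "upward")
ROTATION_DIRECTIONS = ("ccw", "cw")


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and geometry of one periodic-stimulation imaging session.

    Parameters
    ----------
    frame_rate_hz
        Camera acquisition rate.  The acquisition hardware rate is not a
        protocol constant; a desk-scale default of 5 Hz is used.
    f_stim_hz
        Sweep repetition frequency (one bar passage per cycle).
    f_rot_rpm
        Grating rotation speed in rotations per minute.
    n_repeats
        Number of sweep cycles per session.
    n_cycles
        Number of full grating rotations per session.
    span_azimuth_deg, span_elevation_deg
        Extent of the visual field covered by the display.
    direction
        Stimulus drift/rotation direction for this session.
    """

    frame_rate_hz: float = 5.0
    f_stim_hz: float = 1.0 / 8.0
    f_rot_rpm: float = 2.0
    n_repeats: int = 30
    n_cycles: int = 20
    span_azimuth_deg: float = 110.0
    span_elevation_deg: float = 60.0
    direction: str = "rightward"

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "f_stim_hz", "f_rot_rpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_repeats < 1 or self.n_cycles < 1:
            raise ValueError("n_repeats and n_cycles must be >= 1")
        if self.direction not in SWEEP_DIRECTIONS + ROTATION_DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def f_rotation_hz(self) -> float:
        """Rotation frequency of the grating (full 360° turns per second)."""
        return self.f_rot_rpm / 60.0

    @property
    def f_orientation_hz(self) -> float:
        """Analysis frequency for orientation sessions.

        Gratings are 180°-periodic, so the orientation stimulus repeats
        twice per rotation: 2 rpm -> 1/15 Hz.
        """
        return 2.0 * self.f_rotation_hz

    @property
    def sweep_duration_s(self) -> float:
        """Duration of a sweep session (n_repeats cycles of f_stim)."""
        return self.n_repeats / self.f_stim_hz

    @property
    def rotation_duration_s(self) -> float:
        """Duration of a rotation session (n_cycles full turns)."""
        return self.n_cycles * 60.0 / self.f_rot_rpm

    def span_deg(self, axis: str) -> float:
        if axis == "azimuth":
            return self.span_azimuth_deg
        if axis == "elevation":
            return self.span_elevation_deg
        raise ValueError(f"axis must be 'azimuth' or 'elevation', got {axis!r}")
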