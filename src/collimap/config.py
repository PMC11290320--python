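"""Pipeline configuration: protocol constants, thresholds, windows."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .protocol import StimulusProtocol


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Protocol constants reflect the standard periodic-stimulation
    protocol (1/8 Hz sweeps repeated 30x, 2 rpm rotations for 20
    cycles, 110°x60° display); the grating drift rate (1.5 Hz) and
    spatial frequency (0.015 cpd) are recorded as stimulus metadata
    only — they do not enter the analysis.
    """

    # stimulation protocol
    frame_rate_hz: float = 5.0
    f_stim_hz: float = 1.0 / 8.0
    f_rot_rpm: float = 2.0
    n_repeats: int = 30
    n_cycles: int = 20
    span_azimuth_deg: float = 110.0
    span_elevation_deg: float = 60.0
    grating_drift_hz: float = 1.5     # metadata
    grating_spatial_cpd: float = 0.015  # metadata

    # imaging analysis
    alpha: float = 0.05
    pixel_pitch_um: float = 10.5
    n_mc_null: int = 100_000
    coverage_cell_deg: float = 5.0
    border_threshold: float = 0.5

    # behavior analysis
    likelihood_threshold: float = 0.9
    smooth_window_frames: int = 5
    sg_window_frames: int = 7
    sg_order: int = 2
    pose_frame_rate_hz: float = 25.0
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    arrest_window_s: tuple[float, float] = (1.0, 4.0)
    min_baseline_speed_cm_s: float = 2.0
    arena_diameter_cm: float = 30.0

    seed: int = 0

    def __post_init__(self) -> None:
        positives = ("frame_rate_hz", "f_stim_hz", "f_rot_rpm", "span_azimuth_deg",
                     "span_elevation_deg", "pixel_pitch_um", "pose_frame_rate_hz",
                     "grating_drift_hz", "grating_spatial_cpd", "arena_diameter_cm")
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.likelihood_threshold <= 1:
            raise ValueError("likelihood_threshold must be in (0, 1]")
        self.baseline_window_s = tuple(self.baseline_window_s)  # type: ignore[assignment]
        self.arrest_window_s = tuple(self.arrest_window_s)  # type: ignore[assignment]

    def protocol(self, direction: str = "rightward") -> StimulusProtocol:
        return StimulusProtocol(
            frame_rate_hz=self.frame_rate_hz, f_stim_hz=self.f_stim_hz,
            f_rot_rpm=self.f_rot_rpm, n_repeats=self.n_repeats, n_cycles=self.n_cycles,
            span_azimuth_deg=self.span_azimuth_deg,
            span_elevation_deg=self.span_elevation_deg, direction=direction,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
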