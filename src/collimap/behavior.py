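"""Flash-aligned running speed and the speed-modulation index.

A mouse running in a closed arena is startled by three brief flashes of
light and temporarily arrests locomotion.  Pose-tracking software
provides per-frame (x, y, likelihood) for the snout, the barycenter and
the base of the tail at 25 frames/s; the barycenter is the body part
used for quantification.

The pipeline is: drop low-confidence frames, smooth the positions,
differentiate with a Savitzky-Golay filter to get speed, and summarise
each trial as the modulation index

    index = (V_baseline - V_arrest) / V_baseline

with ``V_baseline`` the mean speed in the 1-s window before the first
flash and ``V_arrest`` the mean speed in the 3-s window starting 1 s
after it.  An index of 1 means a complete stop; negative values mean
the animal sped up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

BODY_PARTS = ("snout", "barycenter", "tail_base")


class TrialRejectedError(Exception):
    """Trial excluded because the animal was not running at baseline."""


@dataclass
class PoseTrack:
    """Tracked body-part positions over time.

    ``parts`` maps body-part name to an (n, 3) array of columns
    (x_px, y_px, likelihood).
    """

    time_s: np.ndarray
    parts: dict[str, np.ndarray]
    frame_rate_hz: float = 25.0
    flash_onsets_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        parts = {}
        for name, arr in self.parts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.time_s.size, 3):
                raise ValueError(f"part {name!r} must be (n_frames, 3)")
            lik = arr[:, 2]
            finite = np.isfinite(lik)
            if np.any((lik[finite] < 0) | (lik[finite] > 1)):
                raise ValueError(f"part {name!r} has likelihood outside [0, 1]")
            parts[name] = arr
        self.parts = parts

    @property
    def n_frames(self) -> int:
        return self.time_s.size


@dataclass
class SpeedTrace:
    """Speed versus time plus trial-level arrest summaries."""

    time_s: np.ndarray
    speed: np.ndarray
    frame_rate_hz: float
    units: str = "px/s"
    v_baseline: float | None = None
    v_arrest: float | None = None
    modulation_index: float | None = None


@dataclass(frozen=True)
class ArrestMetrics:
    v_baseline: float
    v_arrest: float
    modulation_index: float


def _fill_short_gaps(vals: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap;
    longer runs (and edge runs) stay masked entirely."""
    vals = vals.copy()
    isnan = np.isnan(vals)
    if not isnan.any():
        return vals
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in edges.reshape(-1, 2):
        if stop - start > max_gap or start == 0 or stop == len(vals):
            continue
        span = stop - start + 1
        vals[start:stop] = vals[start - 1] + (vals[stop] - vals[start - 1]) * (
            np.arange(1, span) / span)
    return vals


def clean_track(track: PoseTrack, likelihood_threshold: float = 0.9,
                smooth_window: int = 5, max_gap_s: float = 0.5) -> PoseTrack:
    """Mask low-confidence frames and smooth the positions.

    Frames with likelihood below ``likelihood_threshold`` are set to NaN
    per body part.  Gaps no longer than ``max_gap_s`` are linearly
    interpolated; longer gaps stay masked.  Positions are then smoothed
    with a centered moving average over ``smooth_window`` valid frames.
    """
    if not 0 < likelihood_threshold <= 1:
        raise ValueError("likelihood_threshold must be in (0, 1]")
    max_gap = int(round(max_gap_s * track.frame_rate_hz))
    out = {}
    for name, arr in track.parts.items():
        arr = arr.copy()
        bad = arr[:, 2] < likelihood_threshold
        arr[bad, 0:2] = np.nan
        if np.all(bad):
            raise ValueError(f"all frames of part {name!r} fall below the likelihood threshold")
        for col in (0, 1):
            vals = arr[:, col]
            if max_gap > 0:
                vals = _fill_short_gaps(vals, max_gap)
            s = pd.Series(vals).rolling(smooth_window, center=True, min_periods=1).mean()
            arr[:, col] = s.to_numpy()
        out[name] = arr
    return PoseTrack(track.time_s, out, track.frame_rate_hz, track.flash_onsets_s)


def compute_speed(track: PoseTrack, part: str = "barycenter", sg_window: int = 7,
                  sg_order: int = 2, px_per_cm: float | None = None) -> SpeedTrace:
    """Savitzky-Golay speed of one body part.

    The filter's first derivative is applied to x and y independently on
    every contiguous run of valid frames at least ``sg_window`` long;
    the speed is the Euclidean norm of the two derivatives.  Shorter
    runs (and masked frames) yield NaN.  With ``px_per_cm`` given the
    trace is returned in cm/s, otherwise px/s.
    """
    if part not in track.parts:
        raise KeyError(f"no body part {part!r} in track")
    if sg_window > track.n_frames:
        raise ValueError("Savitzky-Golay window larger than track")
    if sg_order >= sg_window:
        raise ValueError("sg_order must be < sg_window")
    xy = track.parts[part][:, 0:2]
    valid = np.all(np.isfinite(xy), axis=1)
    dt = 1.0 / track.frame_rate_hz
    speed = np.full(track.n_frames, np.nan)
    # contiguous valid runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for start, stop in edges.reshape(-1, 2):
        if stop - start < sg_window:
            continue
        vx = savgol_filter(xy[start:stop, 0], sg_window, sg_order, deriv=1, delta=dt)
        vy = savgol_filter(xy[start:stop, 1], sg_window, sg_order, deriv=1, delta=dt)
        speed[start:stop] = np.hypot(vx, vy)
    if np.all(np.isnan(speed)):
        raise ValueError("no valid run at least sg_window frames long")
    units = "px/s"
    if px_per_cm is not None:
        if px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        speed = speed / px_per_cm
        units = "cm/s"
    return SpeedTrace(track.time_s.copy(), speed, track.frame_rate_hz, units=units)


def arrest_metrics(trace: SpeedTrace, first_flash_s: float,
                   baseline_window_s: tuple[float, float] = (-1.0, 0.0),
                   arrest_window_s: tuple[float, float] = (1.0, 4.0),
                   min_baseline_speed: float = 0.0) -> ArrestMetrics:
    """Baseline and arrest speeds around the first flash, and the index.

    ``V_baseline`` averages the speed over ``first_flash + baseline_window``
    (default the 1 s before the flash) and ``V_arrest`` over
    ``first_flash + arrest_window`` (default 3 s starting 1 s after).
    The index is ``(V_baseline - V_arrest) / V_baseline``; no clipping,
    so speeding up gives a negative index.

    Raises
    ------
    ValueError
        If a window extends outside the recording or contains no valid
        speed samples.
    TrialRejectedError
        If ``V_baseline`` is below ``min_baseline_speed`` (the animal
        was not in motion); distinct from computation errors so callers
        can drop the trial.
    """
    t = trace.time_s
    windows = []
    for lo, hi in (baseline_window_s, arrest_window_s):
        a, b = first_flash_s + lo, first_flash_s + hi
        if a < t[0] - 1e-9 or b > t[-1] + 1.0 / trace.frame_rate_hz + 1e-9:
            raise ValueError(f"window [{a:.2f}, {b:.2f}) s outside recording")
        sel = (t >= a - 1e-9) & (t < b - 1e-9)
        vals = trace.speed[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no valid speed samples in window [{a:.2f}, {b:.2f}) s")
        windows.append(float(vals.mean()))
    v_baseline, v_arrest = windows
    if v_baseline < min_baseline_speed:
        raise TrialRejectedError(
            f"baseline speed {v_baseline:.3g} below minimum {min_baseline_speed:.3g}"
        )
    if v_baseline <= 0:
        raise TrialRejectedError("baseline speed is zero; index undefined")
    index = (v_baseline - v_arrest) / v_baseline
    trace.v_baseline, trace.v_arrest, trace.modulation_index = v_baseline, v_arrest, index
    return ArrestMetrics(v_baseline, v_arrest, index)


def group_summary(indices) -> tuple[float, float]:
    """Mean and SEM of a list of per-animal modulation indices."""
    x = np.asarray(indices, dtype=float)
    if x.size == 0:
        raise ValueError("empty index list")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, sem
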