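"""Synthetic inputs with known ground truth for every pipeline stage.

No raw data accompany the study this pipeline emulates, so each input
modality is generated with the statistical structure the analyses
assume, and the planted parameters are returned for parameter-recovery
testing:

* periodic-stimulation imaging movies whose per-pixel response phase
  encodes a planted retinotopic or orientation map, on top of a
  hemodynamic delay, slow drift and white noise;
* dye-coupling cell clouds drawn from a truncated bivariate Gaussian
  around an injection site below a surface polyline;
* pose-tracking tables with a planted flash-evoked locomotor arrest.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .behavior import BODY_PARTS, PoseTrack
from .coupling import CouplingNetwork
from .phasemap import Movie
from .protocol import ROTATION_DIRECTIONS, SWEEP_DIRECTIONS, StimulusProtocol

TWO_PI = 2.0 * np.pi

DEFAULT_SHAPE = (64, 64)


@dataclass
class ImagingGroundTruth:
    """Planted parameters of a synthetic imaging session pair.

    Either ``position_map_deg`` (retinotopy, values in [0, span]) or
    ``orientation_map_deg`` (values in [0, 180)) is set depending on the
    session type.  ``delay_s`` is the shared hemodynamic delay; it must
    stay below half the analysis period so the phase-sum convention
    downstream resolves it unambiguously.
    """

    position_map_deg: np.ndarray | None = None
    orientation_map_deg: np.ndarray | None = None
    span_deg: float = 110.0
    delay_s: float = 1.5
    magnitude_map: np.ndarray | float = 1.0
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.position_map_deg is not None:
            self.position_map_deg = np.asarray(self.position_map_deg, dtype=float)
            if np.any(self.position_map_deg < 0) or np.any(self.position_map_deg > self.span_deg):
                raise ValueError("position_map_deg must lie within [0, span_deg]")
        if self.orientation_map_deg is not None:
            self.orientation_map_deg = np.asarray(self.orientation_map_deg, dtype=float)
            if np.any(self.orientation_map_deg < 0) or np.any(self.orientation_map_deg >= 180):
                raise ValueError("orientation_map_deg must lie within [0, 180)")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ValueError("noise_sd and drift_amp must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        m = self.position_map_deg if self.position_map_deg is not None else self.orientation_map_deg
        if m is None:
            raise ValueError("ground truth holds no map")
        return m.shape

    def magnitude_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.magnitude_map, dtype=float), self.shape)


def linear_retinotopy_truth(shape: tuple[int, int] = DEFAULT_SHAPE, axis: str = "azimuth",
                            span_deg: float | None = None, margin_frac: float = 0.05,
                            delay_s: float = 1.5, magnitude: float = 1.0,
                            noise_sd: float = 0.0, drift_amp: float = 0.0,
                            seed: int = 0) -> ImagingGroundTruth:
    """Smooth position gradient across the frame (azimuth along columns,
    elevation along rows), kept ``margin_frac`` of the span away from
    the 0/span wrap point."""
    if span_deg is None:
        span_deg = 110.0 if axis == "azimuth" else 60.0
    h, w = shape
    lo, hi = margin_frac * span_deg, (1.0 - margin_frac) * span_deg
    if axis == "azimuth":
        grad = np.linspace(lo, hi, w)[None, :].repeat(h, axis=0)
    elif axis == "elevation":
        grad = np.linspace(lo, hi, h)[:, None].repeat(w, axis=1)
    else:
        raise ValueError("axis must be 'azimuth' or 'elevation'")
    return ImagingGroundTruth(position_map_deg=grad.copy(), span_deg=span_deg,
                              delay_s=delay_s, magnitude_map=magnitude,
                              noise_sd=noise_sd, drift_amp=drift_amp, seed=seed)


def patchy_orientation_truth(shape: tuple[int, int] = DEFAULT_SHAPE, delay_s: float = 1.5,
                             magnitude: float = 1.0, noise_sd: float = 0.0,
                             drift_amp: float = 0.0, seed: int = 0,
                             smooth: bool = True) -> ImagingGroundTruth:
    """Orientation map: either a smooth 180°-periodic field or cardinal
    patches (alternating near-horizontal / near-vertical blocks)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if smooth:
        ori = 90.0 + 80.0 * np.sin(TWO_PI * xx / w) * np.cos(TWO_PI * yy / h)
    else:
        ori = np.where(((xx // (w // 4)) + (yy // (h // 4))) % 2 == 0, 2.0, 92.0)
    return ImagingGroundTruth(orientation_map_deg=ori.astype(float), delay_s=delay_s,
                              magnitude_map=magnitude, noise_sd=noise_sd,
                              drift_amp=drift_amp, seed=seed)


def _drift(rng: np.random.Generator, t: np.ndarray, shape: tuple[int, int],
           drift_amp: float) -> np.ndarray:
    """Slow drift: per-pixel linear trend plus a 0.005-Hz sinusoid."""
    n_pix = shape[0] * shape[1]
    slopes = rng.uniform(-1.0, 1.0, n_pix)
    phases = rng.uniform(0.0, TWO_PI, n_pix)
    t_norm = (t / t[-1] - 0.5) * 2.0 if t[-1] > 0 else t
    d = slopes[None, :] * t_norm[:, None] + np.sin(TWO_PI * 0.005 * t[:, None] + phases[None, :])
    return drift_amp * d.reshape(len(t), *shape)


def _gamma_kernel(frame_rate_hz: float, shape_k: float = 4.0, scale_s: float = 0.6) -> np.ndarray:
    """Unit-area hemodynamic impulse response sampled at the frame rate."""
    t = np.arange(0, shape_k * scale_s * 4, 1.0 / frame_rate_hz)
    k = gamma_dist.pdf(t, a=shape_k, scale=scale_s)
    return k / k.sum()


def _session_movie(rng: np.random.Generator, phase_map: np.ndarray, truth: ImagingGroundTruth,
                   protocol: StimulusProtocol, f_hz: float, duration_s: float,
                   use_gamma_kernel: bool) -> Movie:
    fs = protocol.frame_rate_hz
    n = int(round(duration_s * fs))
    if abs(n / fs - duration_s) > 1e-9:
        raise ValueError("session duration is not an integer number of frames")
    cycles = duration_s * f_hz
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError("protocol duration must be an integer number of stimulus cycles")
    t = np.arange(n) / fs
    mag = truth.magnitude_array()
    signal = mag[None] * np.cos(TWO_PI * f_hz * t[:, None, None] - phase_map[None])
    if use_gamma_kernel:
        k = _gamma_kernel(fs)
        flat = signal.reshape(n, -1)
        # circular convolution keeps the record an integer number of cycles
        spec = np.fft.rfft(flat, axis=0) * np.fft.rfft(k, n=n)[:, None]
        signal = np.fft.irfft(spec, n=n, axis=0).reshape(signal.shape)
    if truth.drift_amp > 0:
        signal = signal + _drift(rng, t, truth.shape, truth.drift_amp)
    if truth.noise_sd > 0:
        signal = signal + rng.normal(0.0, truth.noise_sd, signal.shape)
    return Movie(signal, fs, protocol)


def make_retinotopy_sessions(truth: ImagingGroundTruth, protocol: StimulusProtocol,
                             use_gamma_kernel: bool = False
                             ) -> tuple[Movie, Movie, ImagingGroundTruth]:
    """Forward/reverse sweep-session pair encoding the planted position map.

    The forward session carries per-pixel phase
    ``2*pi*position/span + 2*pi*f_stim*delay`` and the reverse session
    the negated position phase plus the same delay term, matching the
    convention that opposite sweep directions share the hemodynamic
    delay and carry opposite position phases.
    """
    if truth.position_map_deg is None:
        raise ValueError("ground truth has no position map")
    f = protocol.f_stim_hz
    if truth.delay_s >= 0.5 / f:
        raise ValueError("delay_s must be below half the stimulus period")
    rng = np.random.default_rng(truth.seed)
    pos_phase = TWO_PI * truth.position_map_deg / truth.span_deg
    delay_phase = TWO_PI * f * truth.delay_s
    movies = []
    for sign in (+1.0, -1.0):
        phase = (sign * pos_phase + delay_phase) % TWO_PI
        movies.append(_session_movie(rng, phase, truth, protocol, f,
                                     protocol.sweep_duration_s, use_gamma_kernel))
    return movies[0], movies[1], truth


def make_orientation_sessions(truth: ImagingGroundTruth, protocol: StimulusProtocol,
                              use_gamma_kernel: bool = False
                              ) -> tuple[Movie, Movie, ImagingGroundTruth]:
    """Anticlockwise/clockwise rotation-session pair for the planted
    orientation map.

    At the orientation analysis frequency (1/15 Hz for 2 rpm) the ccw
    session carries phase ``2*pi*f*delay + 2*theta`` and the cw session
    ``2*pi*f*delay - 2*theta`` with ``theta`` the orientation in radians
    (the factor 2 reflects the 180°-periodic code).
    """
    if truth.orientation_map_deg is None:
        raise ValueError("ground truth has no orientation map")
    f = protocol.f_orientation_hz
    if truth.delay_s >= 0.5 / f:
        raise ValueError("delay_s must be below half the analysis period")
    rng = np.random.default_rng(truth.seed)
    theta = np.deg2rad(truth.orientation_map_deg)
    delay_phase = TWO_PI * f * truth.delay_s
    movies = []
    for sign in (+1.0, -1.0):
        phase = (delay_phase + sign * 2.0 * theta) % TWO_PI
        movies.append(_session_movie(rng, phase, truth, protocol, f,
                                     protocol.rotation_duration_s, use_gamma_kernel))
    return movies[0], movies[1], truth


def make_coupling_network(n_cells: int = 300, sigma_ml_um: float = 150.0,
                          sigma_dv_um: float = 150.0, injection_depth_um: float = 200.0,
                          surface_polyline: np.ndarray | None = None,
                          hemisphere: str = "left", seed: int = 0,
                          ) -> tuple[CouplingNetwork, dict]:
    """Truncated-Gaussian dye-coupling cloud around an injection site.

    Cell coordinates are drawn from a bivariate Gaussian centered at the
    injection site with axis standard deviations ``sigma_ml_um`` (x,
    medio-lateral) and ``sigma_dv_um`` (y, dorso-ventral; y increases
    ventrally), rejection-truncated at the surface polyline (no cell
    above the surface).  The patched cell itself sits exactly at the
    injection site as the first row.  Returns the network and the
    planted truth (sigmas, depth, requested cell count).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sigma_ml_um <= 0 or sigma_dv_um <= 0:
        raise ValueError("sigmas must be positive")
    if surface_polyline is None:
        surface_polyline = np.array([[-5000.0, 0.0], [5000.0, 0.0]])
    surface_polyline = np.asarray(surface_polyline, dtype=float)
    surf_y = lambda x: np.interp(x, surface_polyline[:, 0], surface_polyline[:, 1])
    injection = np.array([0.0, injection_depth_um + float(surf_y(0.0))])
    if injection[1] <= surf_y(injection[0]):
        raise ValueError("injection site lies outside the tissue (above the surface)")

    rng = np.random.default_rng(seed)
    cells = [injection]
    need = n_cells - 1
    while need > 0:
        draw = rng.normal(loc=injection, scale=(sigma_ml_um, sigma_dv_um),
                          size=(max(need * 2, 16), 2))
        keep = draw[draw[:, 1] > surf_y(draw[:, 0])]
        take = keep[:need]
        cells.append(take)
        need -= len(take)
    cells_xy = np.vstack([np.atleast_2d(c) for c in cells])[:n_cells]
    network = CouplingNetwork(injection_xy=injection, cells_xy=cells_xy,
                              surface_polyline=surface_polyline, hemisphere=hemisphere)
    truth = {"sigma_ml_um": sigma_ml_um, "sigma_dv_um": sigma_dv_um,
             "injection_depth_um": injection_depth_um, "n_cells": n_cells, "seed": seed}
    return network, truth


def make_arrest_trajectory(v_baseline_cm_s: float = 15.0, arrest_fraction: float = 0.75,
                           flash_time_s: float = 10.0, duration_s: float = 30.0,
                           frame_rate_hz: float = 25.0, noise_sd_px: float = 0.0,
                           dropout_rate: float = 0.0, seed: int = 0,
                           px_per_cm: float = 20.0, arrest_onset_s: float = 0.2,
                           arrest_duration_s: float = 5.0, turn_amplitude_rad: float = 0.5,
                           ) -> tuple[PoseTrack, tuple[float, ...], dict]:
    """Pose table with a planted flash-evoked locomotor arrest.

    The barycenter follows a gently curving path at ``v_baseline_cm_s``
    (``turn_amplitude_rad = 0`` gives a straight line);
    from ``flash + arrest_onset_s`` the speed drops by
    ``arrest_fraction`` for ``arrest_duration_s`` (covering the whole
    standard 1–4 s arrest analysis window) before recovering, so the
    planted modulation index equals ``arrest_fraction`` exactly.  Snout
    and tail-base ride at fixed offsets along the heading.  Likelihoods
    are drawn uniform on [0.95, 1] for valid frames and on [0, 0.9) for
    dropout frames (rate ``dropout_rate``).

    Returns the track, the three flash-onset times (first at
    ``flash_time_s``) and the planted truth.
    """
    if not 0.0 <= arrest_fraction <= 1.0:
        raise ValueError("arrest_fraction must be in [0, 1]")
    if v_baseline_cm_s < 0:
        raise ValueError("baseline speed must be >= 0")
    if not 0.0 < flash_time_s < duration_s:
        raise ValueError("flash must fall inside the recording")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    dt = 1.0 / frame_rate_hz

    speed = np.full(n, float(v_baseline_cm_s))
    in_arrest = (t >= flash_time_s + arrest_onset_s) & (
        t < flash_time_s + arrest_onset_s + arrest_duration_s)
    speed[in_arrest] *= 1.0 - arrest_fraction

    heading = 0.3 + turn_amplitude_rad * np.sin(TWO_PI * 0.03 * t)
    step = speed * dt
    x_cm = 15.0 + np.concatenate(([0.0], np.cumsum(step * np.cos(heading))[:-1]))
    y_cm = 15.0 + np.concatenate(([0.0], np.cumsum(step * np.sin(heading))[:-1]))

    offsets_cm = {"snout": 1.5, "barycenter": 0.0, "tail_base": -2.0}
    parts = {}
    for name in BODY_PARTS:
        off = offsets_cm[name]
        px = (x_cm + off * np.cos(heading)) * px_per_cm
        py = (y_cm + off * np.sin(heading)) * px_per_cm
        if noise_sd_px > 0:
            px = px + rng.normal(0.0, noise_sd_px, n)
            py = py + rng.normal(0.0, noise_sd_px, n)
        lik = rng.uniform(0.95, 1.0, n)
        if dropout_rate > 0:
            drop = rng.random(n) < dropout_rate
            lik[drop] = rng.uniform(0.0, 0.9, drop.sum())
        parts[name] = np.column_stack([px, py, lik])

    flash_onsets = (flash_time_s, flash_time_s + 0.35, flash_time_s + 0.7)
    track = PoseTrack(time_s=t, parts=parts, frame_rate_hz=frame_rate_hz,
                      flash_onsets_s=flash_onsets)
    truth = {"modulation_index": arrest_fraction, "v_baseline_cm_s": v_baseline_cm_s,
             "dropout_mask": {name: parts[name][:, 2] < 0.9 for name in parts},
             "px_per_cm": px_per_cm, "seed": seed}
    return track, flash_onsets, truth
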