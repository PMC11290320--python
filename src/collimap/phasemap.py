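"""Per-pixel preprocessing and single-frequency Fourier demodulation.

Periodic-stimulation intrinsic imaging encodes the stimulus variable
(visual-field position or grating orientation) in the *phase* of the
hemodynamic response at the stimulation frequency.  This module turns a
raw movie into a per-pixel phase/magnitude pair:

1. :func:`remove_slow_components` strips the stimulus-independent slow
   signal (baseline, drift) from every pixel's time course.
2. :func:`extract_fourier_component` demodulates each pixel at a single
   analysis frequency over an integer number of stimulus cycles.

Phase convention used throughout the package: a pixel trace
``x(t) = M * cos(2*pi*f*t - phi)`` yields magnitude ``M`` and phase
``phi`` in ``[0, 2*pi)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimulusProtocol

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class Movie:
    """A time x height x width stack of pixel intensities."""

    data: np.ndarray
    frame_rate_hz: float
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (t, h, w), got shape {self.data.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PhaseMap:
    """Per-pixel phase and magnitude at one analysis frequency.

    ``phase`` is wrapped to ``[0, 2*pi)``; ``magnitude`` is non-negative.
    Pixels outside ``valid_mask`` carry phase 0 and magnitude 0.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    f_analysis_hz: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float) % TWO_PI
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude shapes differ")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.phase.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.phase.shape:
                raise ValueError("valid_mask shape differs from phase")
        self.phase = np.where(self.valid_mask, self.phase, 0.0)
        self.magnitude = np.where(self.valid_mask, self.magnitude, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


def remove_slow_components(movie: Movie, f_stim_hz: float | None = None) -> Movie:
    """Remove slow, stimulus-independent signal from every pixel.

    Each pixel's time course has its temporal mean and least-squares
    linear trend subtracted, after which all spectral components strictly
    below half the stimulation frequency are projected out (rFFT-bin
    zeroing).  For a record covering an integer number of stimulus
    cycles the component at ``f_stim_hz`` falls exactly on a retained
    bin and is untouched.

    Raises
    ------
    ValueError
        If the movie is shorter than two stimulus cycles.
    """
    if f_stim_hz is None:
        if movie.protocol is None:
            raise ValueError("f_stim_hz not given and movie has no protocol")
        f_stim_hz = movie.protocol.f_stim_hz
    if f_stim_hz <= 0:
        raise ValueError("f_stim_hz must be positive")
    n = movie.n_frames
    if movie.duration_s < 2.0 / f_stim_hz - 1e-9:
        raise ValueError(
            f"movie duration {movie.duration_s:.2f}s covers fewer than two "
            f"cycles of {f_stim_hz:.4f} Hz"
        )

    x = movie.data.reshape(n, -1)
    t = np.arange(n) / movie.frame_rate_hz
    tc = t - t.mean()
    x = x - x.mean(axis=0)
    # fit the linear trend on the residual after removing a provisional
    # estimate of the stimulus-locked component, so a strong response at
    # f_stim cannot leak into the fitted slope
    basis = np.exp(-1j * TWO_PI * f_stim_hz * t)
    c = (2.0 / n) * (basis @ x)
    residual = x - np.real(np.conj(basis)[:, None] * c[None, :])
    slope = (tc @ residual) / (tc @ tc)
    x = x - tc[:, None] * slope

    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / movie.frame_rate_hz)
    spec[freqs < f_stim_hz / 2.0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=0)
    return Movie(x.reshape(movie.data.shape), movie.frame_rate_hz, movie.protocol)


def extract_fourier_component(movie: Movie, f_analysis_hz: float) -> PhaseMap:
    """Demodulate every pixel at a single frequency.

    Computes the complex demodulate ``C = (2/N) * sum x_n exp(-i 2 pi f t_n)``
    over the largest prefix of the movie covering an integer number of
    analysis cycles, and returns ``M = |C|`` and ``phi = (-arg C) mod 2 pi``
    so that ``x(t) = M cos(2 pi f t - phi)`` maps to ``(M, phi)``.

    The demodulation is carried out at the exact analysis frequency (not
    the nearest FFT bin), which avoids leakage for frequencies such as
    1/15 Hz that need not align with the FFT grid.

    Raises
    ------
    ValueError
        If ``f_analysis_hz`` exceeds the Nyquist frequency or the movie
        does not cover one full analysis cycle.
    """
    fs = movie.frame_rate_hz
    if f_analysis_hz <= 0:
        raise ValueError("f_analysis_hz must be positive")
    if f_analysis_hz > fs / 2.0 + 1e-12:
        raise ValueError(
            f"analysis frequency {f_analysis_hz} Hz above Nyquist ({fs / 2} Hz)"
        )
    n_total = movie.n_frames
    n_cycles = int(np.floor(movie.duration_s * f_analysis_hz + 1e-9))
    if n_cycles < 1:
        raise ValueError("movie shorter than one analysis cycle")
    n_use = min(n_total, int(round(n_cycles * fs / f_analysis_hz)))
    if n_use < n_total:
        logger.info(
            "truncating movie from %d to %d frames (%d integer cycles of %.5f Hz)",
            n_total, n_use, n_cycles, f_analysis_hz,
        )

    t = np.arange(n_use) / fs
    basis = np.exp(-1j * TWO_PI * f_analysis_hz * t)
    x = movie.data[:n_use].reshape(n_use, -1)
    c = (2.0 / n_use) * (basis @ x)
    c = c.reshape(movie.frame_shape)
    magnitude = np.abs(c)
    phase = (-np.angle(c)) % TWO_PI
    return PhaseMap(phase=phase, magnitude=magnitude, f_analysis_hz=f_analysis_hz)
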