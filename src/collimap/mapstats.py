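"""Functional map construction, cross-animal registration and statistics.

From demodulated phase-map pairs this module builds retinotopic maps
(visual-field position in degrees) and orientation-preference maps
(degrees, 180°-periodic), registers maps across animals with a rigid
transform, averages them in the common frame, tests per-pixel
reproducibility with the Moore-Rayleigh test, and quantifies selective
domains and visual-field coverage.

Delay handling.  The two sessions of a pair (opposite sweep directions,
or opposite rotation senses) carry opposite stimulus phases but the
same hemodynamic delay, so half the wrapped phase *sum* isolates the
delay (assuming the delay is below half the analysis period) and the
delay-corrected single-direction phase reads out position/orientation.
This is equivalent in intent to taking half the phase difference but
fixes the wrap convention explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.transform import rotate as sk_rotate

from .circstats import circular_mean, moore_rayleigh_pvalue, _stat_along_axis
from .phasemap import PhaseMap

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# map types

@dataclass
class RetinotopicMap:
    """Per-pixel visual-field coordinate along one axis, in degrees."""

    position_deg: np.ndarray
    magnitude: np.ndarray
    axis: str
    span_deg: float
    delay_estimate_s: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.position_deg = np.asarray(self.position_deg, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.axis not in ("azimuth", "elevation"):
            raise ValueError("axis must be 'azimuth' or 'elevation'")
        if self.delay_estimate_s < 0:
            raise ValueError("delay estimate must be >= 0")

    @property
    def period_deg(self) -> float:
        return self.span_deg


@dataclass
class OrientationMap:
    """Per-pixel preferred orientation in degrees, 180°-periodic."""

    orientation_deg: np.ndarray
    magnitude: np.ndarray
    delay_estimate_s: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.orientation_deg = np.asarray(self.orientation_deg, dtype=float) % 180.0
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def period_deg(self) -> float:
        return 180.0


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (deg, about frame center, CCW) followed by an integer
    pixel shift (dy, dx), mapping an animal's maps into the reference
    frame."""

    rotation_deg: float
    shift: tuple[int, int]


@dataclass
class GroupMaps:
    """Registered per-animal maps of one kind on a common pixel grid.

    ``values`` holds positions (period = span) or orientations
    (period = 180) in degrees, shape (n_animals, h, w).
    """

    values: np.ndarray
    magnitudes: np.ndarray
    valid: np.ndarray
    period_deg: float
    transforms: list[RigidTransform]
    alpha: float = 0.05
    p_map: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    border_mask: np.ndarray | None = None

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# pair -> map

def _check_pair(a: PhaseMap, b: PhaseMap) -> None:
    if a.shape != b.shape:
        raise ValueError("phase maps have different geometry")
    if abs(a.f_analysis_hz - b.f_analysis_hz) > 1e-12:
        raise ValueError("phase maps have different analysis frequencies")


def retinotopy_from_pair(fwd: PhaseMap, rev: PhaseMap, span_deg: float,
                         axis: str = "azimuth") -> RetinotopicMap:
    """Retinotopic map from a forward/reverse sweep-session pair.

    Per pixel, the delay phase is ``((phi_f + phi_r) mod 2pi) / 2``
    (valid while the hemodynamic delay stays below half the stimulus
    period) and the position is ``span * ((phi_f - delay) mod 2pi) / 2pi``.
    The delay estimate reported is the median delay phase converted to
    seconds.
    """
    _check_pair(fwd, rev)
    f = fwd.f_analysis_hz
    valid = fwd.valid_mask & rev.valid_mask
    s = (fwd.phase + rev.phase) % TWO_PI
    # unwrap the per-pixel phase sum around its global circular mean so a
    # shared delay near 0 (or near half the period) cannot flip individual
    # pixels by half a span through the 0/2pi wrap
    s_ref = circular_mean(s[valid].ravel()) if valid.any() else 0.0
    if s_ref > TWO_PI - 1e-9:  # numerically at the wrap: a zero delay
        s_ref -= TWO_PI
    s = s - TWO_PI * np.round((s - s_ref) / TWO_PI)
    delay_phase = s / 2.0
    position = span_deg * ((fwd.phase - delay_phase) % TWO_PI) / TWO_PI
    delay_s = (max(0.0, float(np.median(delay_phase[valid]))) / (TWO_PI * f)
               if valid.any() else 0.0)
    magnitude = 0.5 * (fwd.magnitude + rev.magnitude)
    return RetinotopicMap(position_deg=position, magnitude=magnitude, axis=axis,
                          span_deg=span_deg, delay_estimate_s=delay_s, valid_mask=valid)


def orientation_from_pair(ccw: PhaseMap, cw: PhaseMap) -> OrientationMap:
    """Orientation map from an anticlockwise/clockwise rotation pair.

    The common delay phase is estimated as the magnitude-weighted
    circular mean over valid pixels of ``((phi+ + phi-) mod 2pi) / 2``
    and subtracted from both phase maps; each corrected phase is halved
    (undoing the doubled-angle code) and the two estimates are averaged
    on the 180° circle.
    """
    _check_pair(ccw, cw)
    f = ccw.f_analysis_hz
    valid = ccw.valid_mask & cw.valid_mask
    if not valid.any():
        raise ValueError("no jointly valid pixels")
    s = (ccw.phase + cw.phase) % TWO_PI
    w = (ccw.magnitude + cw.magnitude) * valid
    delay_phase = 0.5 * circular_mean(s.ravel(), weights=w.ravel())
    a = ((ccw.phase - delay_phase) % TWO_PI) / 2.0
    b = (-((cw.phase - delay_phase) % TWO_PI) / 2.0) % np.pi
    z = np.exp(2j * a) + np.exp(2j * b)
    antipodal = np.abs(z) < 1e-9
    theta = (np.angle(z) % TWO_PI) / 2.0
    valid = valid & ~antipodal
    magnitude = 0.5 * (ccw.magnitude + cw.magnitude)
    return OrientationMap(orientation_deg=np.rad2deg(theta), magnitude=magnitude,
                          delay_estimate_s=delay_phase / (TWO_PI * f), valid_mask=valid)


# ---------------------------------------------------------------------------
# registration

def _to_complex(values_deg: np.ndarray, valid: np.ndarray, period: float) -> np.ndarray:
    return np.where(valid, np.exp(1j * TWO_PI * values_deg / period), 0.0)


def _ishift(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _rotate_complex(z: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return z
    re = sk_rotate(z.real, angle_deg, order=1, preserve_range=True, cval=0.0)
    im = sk_rotate(z.imag, angle_deg, order=1, preserve_range=True, cval=0.0)
    return re + 1j * im


def _warp_complex(z: np.ndarray, tf: RigidTransform) -> np.ndarray:
    return _ishift(_rotate_complex(z, tf.rotation_deg), *tf.shift)


def _objective(z_ref: list[np.ndarray], z_mov: list[np.ndarray]) -> float:
    """Mean squared wrapped phase difference over the overlap of a pair
    of complex map stacks (one entry per axis)."""
    total, count = 0.0, 0
    for zr, zm in zip(z_ref, z_mov):
        overlap = (np.abs(zr) > 0.5) & (np.abs(zm) > 0.5)
        if overlap.any():
            d = np.angle(zr[overlap] * np.conj(zm[overlap]))
            total += float(np.sum(d**2))
            count += int(overlap.sum())
    if count == 0:
        raise ValueError("empty overlap after transform")
    return total / count


def _best_shift(z_ref: list[np.ndarray], z_rot: list[np.ndarray], max_shift: int) -> tuple[int, int]:
    """Integer shift minimising the mean circular mismatch of the complex
    fields over their overlap, evaluated for all shifts at once with
    zero-padded FFT cross-correlations and restricted to +/- max_shift.

    The real cross-correlation sums cos(phase difference) over the
    overlap, so (overlap - corr) / overlap is the mean 1 - cos mismatch;
    normalising by the overlap keeps large shifts from being penalised
    merely for covering fewer pixels.  Shifts whose overlap falls below
    a quarter of the maximum are excluded.
    """
    h, w = z_ref[0].shape
    ph, pw = 2 * h, 2 * w
    corr = np.zeros((ph, pw))
    overlap = np.zeros((ph, pw))
    for zr, zm in zip(z_ref, z_rot):
        mr = (np.abs(zr) > 0.5).astype(float)
        mm = (np.abs(zm) > 0.5).astype(float)
        fr = np.fft.fft2(zr * mr, s=(ph, pw))
        fm = np.fft.fft2(zm * mm, s=(ph, pw))
        corr += np.fft.ifft2(fr * np.conj(fm)).real
        gr = np.fft.fft2(mr, s=(ph, pw))
        gm = np.fft.fft2(mm, s=(ph, pw))
        overlap += np.fft.ifft2(gr * np.conj(gm)).real
    shifts_y = np.fft.fftfreq(ph, 1.0 / ph).astype(int)
    shifts_x = np.fft.fftfreq(pw, 1.0 / pw).astype(int)
    oky = np.abs(shifts_y) <= max_shift
    okx = np.abs(shifts_x) <= max_shift
    corr = corr[np.ix_(oky, okx)]
    overlap = overlap[np.ix_(oky, okx)]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (overlap - corr) / overlap
    score[overlap < 0.25 * overlap.max()] = np.inf
    iy, ix = np.unravel_index(np.argmin(score), score.shape)
    return int(shifts_y[oky][iy]), int(shifts_x[okx][ix])


def _register_to_reference(z_mov: list[np.ndarray], z_ref: list[np.ndarray],
                           rot_range_deg: float, rot_step_deg: float,
                           max_shift_px: int) -> RigidTransform:
    best: tuple[float, RigidTransform] | None = None
    coarse = np.arange(-rot_range_deg, rot_range_deg + rot_step_deg / 2, rot_step_deg)

    def evaluate(angles) -> None:
        nonlocal best
        for ang in angles:
            z_rot = [_rotate_complex(z, ang) for z in z_mov]
            dy, dx = _best_shift(z_ref, z_rot, max_shift_px)
            tf = RigidTransform(float(ang), (dy, dx))
            obj = _objective(z_ref, [_ishift(z, dy, dx) for z in z_rot])
            if best is None or obj < best[0]:
                best = (obj, tf)

    evaluate(coarse)
    assert best is not None
    center = best[1].rotation_deg
    fine = np.arange(center - rot_step_deg, center + rot_step_deg * 1.01, rot_step_deg / 5)
    evaluate(fine)
    return best[1]


def register_group(map_pairs: list[tuple[RetinotopicMap, RetinotopicMap]],
                   rot_range_deg: float = 10.0, rot_step_deg: float = 0.5,
                   max_shift_px: int = 20, n_iter: int = 2,
                   ) -> tuple[list[RigidTransform], GroupMaps, GroupMaps]:
    """Rigidly align each animal's (azimuth, elevation) map pair.

    The transform for each animal minimises the summed squared circular
    position difference to the reference over both axes: coarse rotation
    grid + FFT shift search, then local rotation refinement.  The first
    pass uses animal 0 as reference; subsequent passes re-register every
    animal against the running circular-mean average.

    Returns the transforms plus azimuth and elevation :class:`GroupMaps`
    holding the registered maps.
    """
    if len(map_pairs) < 2:
        raise ValueError("registration needs at least 2 animals")
    shape = map_pairs[0][0].position_deg.shape
    spans = (map_pairs[0][0].span_deg, map_pairs[0][1].span_deg)
    for az, el in map_pairs:
        if az.position_deg.shape != shape or el.position_deg.shape != shape:
            raise ValueError("all maps must share geometry")

    z_all = [
        [_to_complex(az.position_deg, az.valid_mask, az.span_deg),
         _to_complex(el.position_deg, el.valid_mask, el.span_deg)]
        for az, el in map_pairs
    ]
    transforms = [RigidTransform(0.0, (0, 0)) for _ in map_pairs]
    z_ref = z_all[0]
    for it in range(n_iter):
        new_tf = []
        for i, z_mov in enumerate(z_all):
            if it == 0 and i == 0:
                new_tf.append(RigidTransform(0.0, (0, 0)))
                continue
            new_tf.append(_register_to_reference(z_mov, z_ref, rot_range_deg,
                                                 rot_step_deg, max_shift_px))
        transforms = new_tf
        if it < n_iter - 1:
            # running reference: per-pixel circular mean of registered maps
            z_ref = []
            for ax in range(2):
                stack = np.array([_warp_complex(z_all[i][ax], transforms[i])
                                  for i in range(len(z_all))])
                mean = stack.mean(axis=0)
                mag = np.abs(mean)
                z_ref.append(np.where(mag > 1e-6, mean / np.maximum(mag, 1e-12), 0.0))

    groups = []
    for ax, span in enumerate(spans):
        vals = np.zeros((len(map_pairs),) + shape)
        mags = np.zeros_like(vals)
        valid = np.zeros(vals.shape, dtype=bool)
        for i, (az, el) in enumerate(map_pairs):
            m = (az, el)[ax]
            zw = _warp_complex(_to_complex(m.position_deg, m.valid_mask, span), transforms[i])
            magw = _ishift(sk_rotate(m.magnitude * m.valid_mask, transforms[i].rotation_deg,
                                     order=1, preserve_range=True, cval=0.0),
                           *transforms[i].shift)
            ok = np.abs(zw) > 0.5
            vals[i] = np.where(ok, (np.angle(zw) % TWO_PI) * span / TWO_PI, 0.0)
            mags[i] = np.where(ok, magw, 0.0)
            valid[i] = ok
        groups.append(GroupMaps(values=vals, magnitudes=mags, valid=valid,
                                period_deg=span, transforms=transforms))
    return transforms, groups[0], groups[1]


def group_from_maps(maps: list[RetinotopicMap] | list[OrientationMap],
                    transforms: list[RigidTransform] | None = None) -> GroupMaps:
    """Stack per-animal maps (applying transforms if given) into a
    :class:`GroupMaps`, e.g. to carry orientation maps with transforms
    obtained from retinotopy registration."""
    if len(maps) < 1:
        raise ValueError("no maps given")
    if transforms is None:
        transforms = [RigidTransform(0.0, (0, 0)) for _ in maps]
    period = maps[0].period_deg
    values_attr = "position_deg" if isinstance(maps[0], RetinotopicMap) else "orientation_deg"
    shape = getattr(maps[0], values_attr).shape
    vals = np.zeros((len(maps),) + shape)
    mags = np.zeros_like(vals)
    valid = np.zeros(vals.shape, dtype=bool)
    for i, (m, tf) in enumerate(zip(maps, transforms)):
        v = getattr(m, values_attr)
        zw = _warp_complex(_to_complex(v, m.valid_mask, period), tf)
        magw = _ishift(sk_rotate(m.magnitude * m.valid_mask, tf.rotation_deg, order=1,
                                 preserve_range=True, cval=0.0), *tf.shift)
        ok = np.abs(zw) > 0.5
        vals[i] = np.where(ok, (np.angle(zw) % TWO_PI) * period / TWO_PI, 0.0)
        mags[i] = np.where(ok, magw, 0.0)
        valid[i] = ok
    return GroupMaps(values=vals, magnitudes=mags, valid=valid, period_deg=period,
                     transforms=list(transforms))


# ---------------------------------------------------------------------------
# group statistics

def average_registered_maps(group: GroupMaps) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude-weighted per-pixel circular average across animals.

    Returns ``(values_deg, mean_magnitude, valid)``; a pixel is valid
    where at least two animals contribute and the weighted resultant is
    non-degenerate (antipodal contributions are flagged invalid).
    """
    w = group.magnitudes * group.valid
    z = np.sum(w * np.exp(1j * TWO_PI * group.values / group.period_deg), axis=0)
    wsum = w.sum(axis=0)
    count = group.valid.sum(axis=0)
    resultant = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (np.angle(z) % TWO_PI) * group.period_deg / TWO_PI
        mean_mag = np.where(count > 0, group.magnitudes.sum(axis=0) / np.maximum(count, 1), 0.0)
    valid = (count >= 2) & (resultant > 1e-9 * np.maximum(wsum, 1e-300)) & (wsum > 0)
    values = np.where(valid, values, 0.0)
    return values, mean_mag, valid


def pixelwise_reproducibility(group: GroupMaps, alpha: float = 0.05,
                              n_mc: int = 100_000, seed: int = 0,
                              border_mask: np.ndarray | None = None,
                              center_phases: bool = False,
                              weights: str = "magnitude",
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Moore-Rayleigh reproducibility test at every pixel.

    Each pixel contributes one (phase, magnitude) vector per animal —
    the registered value mapped onto the full circle via the map period
    (orientation values are thereby angle-doubled) with the response
    magnitude as weight (``weights="unit"`` ignores magnitudes;
    ``center_phases=True`` removes each animal's circular-mean phase
    first).  Pixels where any animal is invalid get p = 1.  The
    significance mask is ``p < alpha`` restricted to the structure
    border if one is given.  No multiple-testing correction is applied;
    ``alpha`` is the per-pixel threshold.
    """
    n = group.n_animals
    if n < 2:
        raise ValueError("reproducibility test needs >= 2 animals")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if weights not in ("magnitude", "unit"):
        raise ValueError("weights must be 'magnitude' or 'unit'")
    shape = group.values.shape[1:]
    angles = (TWO_PI * group.values / group.period_deg).reshape(n, -1)
    if center_phases:
        for i in range(n):
            sel = group.valid.reshape(n, -1)[i]
            if sel.any():
                angles[i] = angles[i] - circular_mean(angles[i][sel])
    mags = group.magnitudes.reshape(n, -1)
    if weights == "unit":
        mags = np.ones_like(mags)
    all_valid = group.valid.reshape(n, -1).all(axis=0)
    p = np.ones(angles.shape[1])
    if all_valid.any():
        r = _stat_along_axis(angles[:, all_valid], mags[:, all_valid])
        p[all_valid] = moore_rayleigh_pvalue(r, n=n, n_mc=n_mc, seed=seed)
    p_map = p.reshape(shape)
    mask = p_map < alpha
    if border_mask is not None:
        mask = mask & np.asarray(border_mask, dtype=bool)
        group.border_mask = np.asarray(border_mask, dtype=bool)
    group.p_map, group.significance_mask, group.alpha = p_map, mask, alpha
    return p_map, mask


def selective_domain_fraction(group: GroupMaps, pixel_pitch_um: float | None = None,
                              ) -> tuple[float, float | None]:
    """Fraction of the structure that maps reproducibly across animals.

    Returns ``(fraction, area_mm2)`` where the fraction is significant
    pixels over border pixels (over all tested pixels when no border
    mask is set) and the area uses the camera pixel pitch when given.
    """
    if group.significance_mask is None:
        raise ValueError("run pixelwise_reproducibility first")
    sig = group.significance_mask
    denom_mask = group.border_mask if group.border_mask is not None else np.ones_like(sig)
    denom = int(denom_mask.sum())
    if denom == 0:
        raise ValueError("empty structure border")
    frac = float(sig.sum()) / denom
    area = None
    if pixel_pitch_um is not None:
        area = float(sig.sum()) * (pixel_pitch_um / 1000.0) ** 2
    return frac, area


def visual_field_coverage(az_group: GroupMaps, el_group: GroupMaps,
                          cell_deg: float = 5.0,
                          ) -> tuple[set[tuple[int, int]], float]:
    """Visual-field locations represented reproducibly by the structure.

    Pixels significant in BOTH the azimuth and the elevation group maps
    contribute their averaged (azimuth, elevation) coordinate; coverage
    is the set of occupied cells of a ``cell_deg`` x ``cell_deg`` grid
    and the area is ``n_cells * cell_deg**2``.
    """
    if az_group.significance_mask is None or el_group.significance_mask is None:
        raise ValueError("run pixelwise_reproducibility on both groups first")
    if az_group.values.shape[1:] != el_group.values.shape[1:]:
        raise ValueError("groups are on different pixel grids")
    both = az_group.significance_mask & el_group.significance_mask
    az_avg, _, az_ok = average_registered_maps(az_group)
    el_avg, _, el_ok = average_registered_maps(el_group)
    use = both & az_ok & el_ok
    cells: set[tuple[int, int]] = set()
    if use.any():
        ia = np.floor(az_avg[use] / cell_deg).astype(int)
        ie = np.floor(el_avg[use] / cell_deg).astype(int)
        cells = set(zip(ia.tolist(), ie.tolist()))
    return cells, len(cells) * cell_deg**2


def detect_structure_border(mean_magnitude: np.ndarray, threshold: float = 0.5,
                            closing_radius: int = 2) -> np.ndarray:
    """Structure border from the averaged response magnitude.

    Pixels above ``threshold`` times the maximum magnitude are kept,
    morphologically closed, and the largest connected component is
    returned.  An all-zero magnitude map yields an empty mask with a
    warning.
    """
    mag = np.asarray(mean_magnitude, dtype=float)
    peak = mag.max()
    if peak <= 0:
        warnings.warn("magnitude map is all zero; empty structure border", stacklevel=2)
        return np.zeros(mag.shape, dtype=bool)
    mask = mag >= threshold * peak
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius)).astype(bool)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(mag.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


# ---------------------------------------------------------------------------
# convenience pipelines

def analyze_retinotopy_pair(fwd_movie, rev_movie, protocol, axis: str = "azimuth",
                            span_deg: float | None = None) -> RetinotopicMap:
    """Detrend, demodulate at the sweep frequency and build the map."""
    from .phasemap import extract_fourier_component, remove_slow_components

    if span_deg is None:
        span_deg = protocol.span_deg(axis)
    f = protocol.f_stim_hz
    fwd = extract_fourier_component(remove_slow_components(fwd_movie, f), f)
    rev = extract_fourier_component(remove_slow_components(rev_movie, f), f)
    return retinotopy_from_pair(fwd, rev, span_deg=span_deg, axis=axis)


def analyze_orientation_pair(ccw_movie, cw_movie, protocol) -> OrientationMap:
    """Detrend, demodulate at the orientation frequency and build the map."""
    from .phasemap import extract_fourier_component, remove_slow_components

    f = protocol.f_orientation_hz
    ccw = extract_fourier_component(remove_slow_components(ccw_movie, f), f)
    cw = extract_fourier_component(remove_slow_components(cw_movie, f), f)
    return orientation_from_pair(ccw, cw)
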