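"""Dye-coupling network geometry.

A biocytin-filled astrocyte passes tracer through gap junctions into its
network; the labelled cells form a cloud around the injection site.
This module quantifies the size and directional geometry of such clouds
in a sagittal/coronal slice: how far the network spreads dorsally
(toward the tissue surface), ventrally, medially and laterally, whether
the spread is isotropic, and how the dorsal spread scales with the depth
of the injection below the surface.

Coordinates are in micrometres with x running medio-laterally and y
increasing ventrally (deeper = larger y); the tissue surface is an
ordered polyline.  The direction frame is anchored to the surface: the
dorsal axis points from the injection site to the foot of the
perpendicular dropped onto the surface polyline, and the medio-lateral
axis is the surface tangent there, signed by a hemisphere flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

DIRECTIONS = ("dorsal", "ventral", "medial", "lateral")


@dataclass
class CouplingNetwork:
    """One dye-filled network: injection site, coupled cells, anatomy.

    ``cells_xy`` includes the injected (patched) cell as its first row.
    """

    injection_xy: np.ndarray
    cells_xy: np.ndarray
    surface_polyline: np.ndarray
    layer_border_polyline: np.ndarray | None = None
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.injection_xy = np.asarray(self.injection_xy, dtype=float).reshape(2)
        self.cells_xy = np.atleast_2d(np.asarray(self.cells_xy, dtype=float))
        if self.cells_xy.shape[0] < 1 or self.cells_xy.shape[1] != 2:
            raise ValueError("cells_xy must be an (n, 2) array with n >= 1")
        self.surface_polyline = np.atleast_2d(np.asarray(self.surface_polyline, dtype=float))
        if self.surface_polyline.shape[0] < 2:
            raise ValueError("surface polyline needs at least 2 points")
        if not LineString(self.surface_polyline).is_simple:
            raise ValueError("surface polyline is self-intersecting")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    @property
    def n_cells(self) -> int:
        return self.cells_xy.shape[0]


@dataclass
class DirectionalExtents:
    dorsal: float
    ventral: float
    medial: float
    lateral: float
    statistic: str
    n_cells: int
    injection_depth_um: float

    def __getitem__(self, direction: str) -> float:
        if direction not in DIRECTIONS:
            raise KeyError(direction)
        return getattr(self, direction)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    R_squared: float
    F_statistic: float
    df: tuple[int, int]
    p_value: float


def direction_frame(network: CouplingNetwork) -> dict[str, np.ndarray]:
    """Orthonormal anatomical direction frame anchored at the surface.

    dorsal = unit vector from injection site to its foot point on the
    surface polyline; medial = surface tangent at the foot point, signed
    by the hemisphere flag (for a left-hemisphere slice, medial points
    along increasing polyline order), re-orthogonalised against dorsal.
    """
    line = LineString(network.surface_polyline)
    p = Point(network.injection_xy)
    foot = np.asarray(nearest_points(line, p)[0].coords[0])
    depth = float(np.linalg.norm(foot - network.injection_xy))
    if depth < 1e-9:
        raise ValueError("injection site lies on the surface polyline; frame undefined")
    dorsal = (foot - network.injection_xy) / depth

    s = line.project(p)
    eps = max(line.length * 1e-6, 1e-9)
    a = np.asarray(line.interpolate(max(0.0, s - eps)).coords[0])
    b = np.asarray(line.interpolate(min(line.length, s + eps)).coords[0])
    tangent = b - a
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        raise ValueError("degenerate surface polyline at foot point")
    tangent /= norm
    # project out the dorsal component so the frame is orthonormal even
    # at polyline corners
    tangent = tangent - np.dot(tangent, dorsal) * dorsal
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        raise ValueError("surface tangent parallel to dorsal axis")
    medial = tangent / norm
    if network.hemisphere == "right":
        medial = -medial
    return {
        "dorsal": dorsal,
        "ventral": -dorsal,
        "medial": medial,
        "lateral": -medial,
        "injection_depth_um": depth,  # type: ignore[dict-item]
    }


def directional_extents(network: CouplingNetwork, statistic: str = "median") -> DirectionalExtents:
    """Spread of coupled cells along each anatomical direction.

    For each direction, the cells with a positive projection of
    (cell - injection) onto that axis contribute, and the requested
    statistic (``median`` or ``max``) of those projections is the
    extent.  Directions with no contributing cell have extent 0.
    """
    if statistic not in ("median", "max"):
        raise ValueError("statistic must be 'median' or 'max'")
    frame = direction_frame(network)
    offsets = network.cells_xy - network.injection_xy
    reduce = np.median if statistic == "median" else np.max
    extents = {}
    for d in DIRECTIONS:
        proj = offsets @ frame[d]
        pos = proj[proj > 0]
        extents[d] = float(reduce(pos)) if pos.size else 0.0
    return DirectionalExtents(
        statistic=statistic,
        n_cells=count_coupled_cells(network),
        injection_depth_um=float(frame["injection_depth_um"]),
        **extents,
    )


def directional_ratio(extents: DirectionalExtents, dir_a: str = "dorsal",
                      dir_b: str = "lateral") -> float:
    """Isotropy ratio ``a / (a + b)`` between two directional extents.

    0.5 indicates isotropy between the two directions; values above 0.5
    a bias toward ``dir_a``.
    """
    a, b = extents[dir_a], extents[dir_b]
    if a + b <= 0:
        raise ValueError(f"both {dir_a} and {dir_b} extents are zero")
    return a / (a + b)


def extent_vs_depth_regression(depths_um, extents_um) -> RegressionResult:
    """OLS regression of coupling extent on injection depth.

    Returns slope, intercept, R², the F(1, n-2) statistic and its
    two-sided p-value, mirroring a standard linear-regression report.
    """
    x = np.asarray(depths_um, dtype=float)
    y = np.asarray(extents_um, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("depths and extents must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in injection depth")
    df = (1, n - 2)
    if np.ptp(y) == 0:
        # constant response: slope 0, no variance explained
        return RegressionResult(slope=0.0, intercept=float(y[0]), R_squared=0.0,
                                F_statistic=0.0, df=df, p_value=1.0)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    with np.errstate(divide="ignore"):
        f_stat = r2 * df[1] / (1.0 - r2) if r2 < 1.0 else np.inf
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R_squared=float(r2),
        F_statistic=float(f_stat),
        df=df,
        p_value=float(res.pvalue),
    )


def count_coupled_cells(network: CouplingNetwork, include_injected: bool = False) -> int:
    """Number of coupled cells; by default the patched cell is excluded."""
    n = network.n_cells
    return n if include_injected else n - 1
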