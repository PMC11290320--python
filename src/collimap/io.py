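"""File formats: movies (TIFF/HDF5), maps (NPZ + PNG previews), cell
tables and pose tables (CSV).

Image coordinate convention used by every writer: row 0 is the top of
the frame and x increases rightward.  Anatomical orientation (which
image axis is medial, which hemisphere) is supplied via configuration,
never inferred from the data.  Cell coordinates are in micrometres with
y increasing ventrally.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib.colors import hsv_to_rgb

from .behavior import PoseTrack
from .coupling import CouplingNetwork
from .phasemap import Movie
from .protocol import StimulusProtocol

TWO_PI = 2.0 * np.pi

_PROTOCOL_ATTRS = ("frame_rate_hz", "f_stim_hz", "f_rot_rpm", "n_repeats", "n_cycles",
                   "span_azimuth_deg", "span_elevation_deg", "direction")


# ---------------------------------------------------------------------------
# movies

def write_movie(path, movie: Movie) -> None:
    """Write a movie as a multi-page TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5).

    HDF5 files carry the stack in dataset ``"movie"`` with the frame
    rate and protocol stored as attributes; TIFF stacks carry them in
    the ImageDescription JSON-ish metadata.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    attrs = {"frame_rate_hz": movie.frame_rate_hz}
    if movie.protocol is not None:
        attrs.update({k: getattr(movie.protocol, k) for k in _PROTOCOL_ATTRS})
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.data.astype(np.float32), metadata=attrs)
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("movie", data=movie.data)
            for k, v in attrs.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported movie format {suffix!r}")


def read_movie(path) -> Movie:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if not path.exists():
        raise FileNotFoundError(path)
    if suffix in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                data = tif.asarray()
                meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        except Exception as exc:  # corrupt file
            raise ValueError(f"cannot read TIFF movie {path}: {exc}") from exc
        attrs = dict(meta)
    elif suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as fh:
                ds = fh["movie"]
                data = ds[...]
                attrs = {k: ds.attrs[k] for k in ds.attrs}
        except (OSError, KeyError) as exc:
            raise ValueError(f"cannot read HDF5 movie {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported movie format {suffix!r}")
    frame_rate = float(attrs.get("frame_rate_hz", 0.0))
    if frame_rate <= 0:
        raise ValueError(f"movie {path} is missing a positive frame_rate_hz attribute")
    protocol = None
    if "f_stim_hz" in attrs:
        protocol = StimulusProtocol(
            frame_rate_hz=frame_rate, f_stim_hz=float(attrs["f_stim_hz"]),
            f_rot_rpm=float(attrs["f_rot_rpm"]), n_repeats=int(attrs["n_repeats"]),
            n_cycles=int(attrs["n_cycles"]),
            span_azimuth_deg=float(attrs["span_azimuth_deg"]),
            span_elevation_deg=float(attrs["span_elevation_deg"]),
            direction=str(attrs["direction"]),
        )
    return Movie(np.asarray(data, dtype=float), frame_rate, protocol)


# ---------------------------------------------------------------------------
# maps

def phase_preview_rgb(phase_like_deg: np.ndarray, magnitude: np.ndarray,
                      period_deg: float) -> np.ndarray:
    """8-bit RGB preview: hue encodes the cyclic value, value the magnitude."""
    hue = (np.asarray(phase_like_deg, dtype=float) % period_deg) / period_deg
    mag = np.asarray(magnitude, dtype=float)
    peak = mag.max()
    val = mag / peak if peak > 0 else np.zeros_like(mag)
    hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
    return (hsv_to_rgb(hsv) * 255).astype(np.uint8)


def write_maps(path, arrays: dict[str, np.ndarray], previews: dict | None = None) -> None:
    """Save named map arrays as one NPZ, plus optional PNG previews.

    ``previews`` maps a preview name to ``(values_deg, magnitude,
    period_deg)``; each becomes ``<stem>_<name>.png`` next to the NPZ.
    """
    import imageio.v3 as iio

    path = Path(path)
    np.savez(path, **arrays)
    if previews:
        stem = path.with_suffix("")
        for name, (vals, mag, period) in previews.items():
            iio.imwrite(f"{stem}_{name}.png", phase_preview_rgb(vals, mag, period))


def read_maps(path) -> dict[str, np.ndarray]:
    try:
        with np.load(path) as data:
            return {k: data[k] for k in data.files}
    except Exception as exc:
        raise ValueError(f"cannot read map archive {path}: {exc}") from exc


def write_group(path, group) -> None:
    """Save a registered :class:`~collimap.mapstats.GroupMaps` as NPZ."""
    arrays = {
        "values": group.values, "magnitudes": group.magnitudes,
        "valid": group.valid, "period_deg": np.array(group.period_deg),
        "alpha": np.array(group.alpha),
        "transforms": np.array([(tf.rotation_deg, tf.shift[0], tf.shift[1])
                                for tf in group.transforms]),
    }
    for name in ("p_map", "significance_mask", "border_mask"):
        val = getattr(group, name)
        if val is not None:
            arrays[name] = val
    np.savez(path, **arrays)


def read_group(path):
    from .mapstats import GroupMaps, RigidTransform

    data = read_maps(path)
    transforms = [RigidTransform(float(r), (int(dy), int(dx)))
                  for r, dy, dx in data["transforms"]]
    group = GroupMaps(values=data["values"], magnitudes=data["magnitudes"],
                      valid=data["valid"].astype(bool),
                      period_deg=float(data["period_deg"]),
                      transforms=transforms, alpha=float(data["alpha"]))
    for name in ("p_map", "significance_mask", "border_mask"):
        if name in data:
            arr = data[name]
            setattr(group, name, arr.astype(bool) if "mask" in name else arr)
    return group


# ---------------------------------------------------------------------------
# cell tables

def write_cells_csv(path, network: CouplingNetwork) -> None:
    """Write cells as CSV (cell_id, x_um, y_um; 1-based ids, injected
    cell first) with a ``<stem>_geometry.yaml`` sidecar for the
    injection site, polylines and hemisphere."""
    path = Path(path)
    df = pd.DataFrame({
        "cell_id": np.arange(1, network.n_cells + 1),
        "x_um": network.cells_xy[:, 0],
        "y_um": network.cells_xy[:, 1],
    })
    df.to_csv(path, index=False)
    geometry = {
        "injection_xy_um": [float(v) for v in network.injection_xy],
        "surface_polyline_um": network.surface_polyline.tolist(),
        "layer_border_polyline_um": (
            network.layer_border_polyline.tolist()
            if network.layer_border_polyline is not None else None),
        "hemisphere": network.hemisphere,
    }
    with open(_geometry_path(path), "w") as fh:
        yaml.safe_dump(geometry, fh)


def _geometry_path(path: Path) -> Path:
    return path.with_name(path.stem + "_geometry.yaml")


def read_cells_csv(path) -> CouplingNetwork:
    """Read a cell table and its geometry sidecar into a network."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("cell_id", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"cell table {path} is missing column {col!r}")
    geom_path = _geometry_path(path)
    if not geom_path.exists():
        raise ValueError(f"missing geometry sidecar {geom_path} (injection site unknown)")
    with open(geom_path) as fh:
        geometry = yaml.safe_load(fh)
    if not geometry or "injection_xy_um" not in geometry:
        raise ValueError(f"geometry sidecar {geom_path} has no injection site")
    border = geometry.get("layer_border_polyline_um")
    return CouplingNetwork(
        injection_xy=np.asarray(geometry["injection_xy_um"], dtype=float),
        cells_xy=df[["x_um", "y_um"]].to_numpy(),
        surface_polyline=np.asarray(geometry["surface_polyline_um"], dtype=float),
        layer_border_polyline=np.asarray(border, dtype=float) if border else None,
        hemisphere=geometry.get("hemisphere", "left"),
    )


# ---------------------------------------------------------------------------
# pose tables

def write_pose_csv(path, track: PoseTrack) -> None:
    """Write a pose table with a two-row header (bodyparts, coords) and
    a leading frame index column, plus a ``<stem>_flashes.yaml`` sidecar
    with the frame rate and flash onsets."""
    path = Path(path)
    columns = pd.MultiIndex.from_product([list(track.parts), ["x", "y", "likelihood"]],
                                         names=["bodyparts", "coords"])
    data = np.hstack([track.parts[p] for p in track.parts])
    df = pd.DataFrame(data, columns=columns)
    df.index.name = "frame"
    df.to_csv(path)
    meta = {
        "frame_rate_hz": float(track.frame_rate_hz),
        "flash_onsets_s": [float(v) for v in track.flash_onsets_s or []],
    }
    with open(path.with_name(path.stem + "_flashes.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_pose_csv(path, frame_rate_hz: float | None = None,
                  flash_onsets_s=None) -> PoseTrack:
    """Read a pose table (two-row bodyparts/coords header).

    Frame rate and flash onsets come from the ``<stem>_flashes.yaml``
    sidecar when present; explicit arguments override.  Raises on
    likelihood values outside [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    meta_path = path.with_name(path.stem + "_flashes.yaml")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        if frame_rate_hz is None:
            frame_rate_hz = meta.get("frame_rate_hz")
        if flash_onsets_s is None:
            flash_onsets_s = meta.get("flash_onsets_s")
    if frame_rate_hz is None:
        frame_rate_hz = 25.0
    parts = {}
    for part in df.columns.get_level_values(0).unique():
        sub = df[part]
        missing = {"x", "y", "likelihood"} - set(sub.columns)
        if missing:
            raise ValueError(f"pose table {path}: part {part!r} missing {sorted(missing)}")
        parts[part] = sub[["x", "y", "likelihood"]].to_numpy(dtype=float)
    n = len(df)
    time_s = np.arange(n) / float(frame_rate_hz)
    return PoseTrack(time_s=time_s, parts=parts, frame_rate_hz=float(frame_rate_hz),
                     flash_onsets_s=tuple(flash_onsets_s) if flash_onsets_s else None)
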