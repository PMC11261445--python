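"""On-disk formats: TIFF voxel stacks, hyperspectral cubes, cohort tables.

Volumes travel as multi-page TIFF stacks with a JSON sidecar carrying the
voxel size and provenance.  Cubes use a minimal interchange format — a
JSON header (spatial shape, pixel size, axis start/step/count) plus a flat
little-endian float32 payload in band-fastest order — with a long-format
CSV alternative for small cubes.  Cohorts are long-format CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .types import HyperCube, VoxelVolume, WavenumberAxis

log = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# voxel volumes
# --------------------------------------------------------------------------

def write_image_stack(data: np.ndarray, path, voxel_size_um: float, extra: dict | None = None):
    """Write a 3D array (bool or 8/16-bit grayscale) as a multi-page TIFF
    with a JSON sidecar holding the voxel size."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise FormatError("image stack must be 3D")
    if data.dtype == bool:
        stored, dtype_tag = data.astype(np.uint8) * 255, "bool"
    elif data.dtype in (np.uint8, np.uint16):
        stored, dtype_tag = data, str(data.dtype)
    else:
        raise FormatError(f"unsupported stack dtype {data.dtype}")
    tifffile.imwrite(path, stored, photometric="minisblack")
    sidecar = {"voxel_size_um": float(voxel_size_um), "dtype": dtype_tag,
               "shape": list(data.shape)}
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_image_stack(path, voxel_size_um: float | None = None) -> tuple[np.ndarray, float, dict]:
    """Read a multi-page TIFF stack; returns (data, voxel_size_um, sidecar).

    The voxel size comes from the sidecar unless given explicitly; missing
    in both places is a format error.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D stack with uniform pages, got shape {data.shape}")
    sidecar = {}
    sp = _sidecar_path(path)
    if sp.exists():
        sidecar = json.loads(sp.read_text())
    if voxel_size_um is None:
        voxel_size_um = sidecar.get("voxel_size_um")
    if voxel_size_um is None:
        raise FormatError(f"voxel size missing: no sidecar value for {path} and none given")
    if sidecar.get("dtype") == "bool":
        data = data > 0
    return data, float(voxel_size_um), sidecar


def write_volume(vol: VoxelVolume, path, extra: dict | None = None):
    write_image_stack(vol.occupancy, path, vol.voxel_size_um, extra)


def read_volume(path, voxel_size_um: float | None = None) -> VoxelVolume:
    data, vs, sidecar = read_image_stack(path, voxel_size_um)
    if data.dtype != bool:
        raise FormatError(
            f"{path} holds grayscale data; binarize it (see morphometry.binarize) "
            "or read it with read_image_stack"
        )
    return VoxelVolume(data, vs)


# --------------------------------------------------------------------------
# hyperspectral cubes
# --------------------------------------------------------------------------

def write_cube(cube: HyperCube, path):
    """Write header JSON to ``path`` and the float32 payload next to it."""
    path = Path(path)
    payload = path.with_suffix(".f32")
    header = {
        "spatial_shape": list(cube.spatial_shape),
        "pixel_size_um": cube.pixel_size_um,
        "axis": {
            "start_cm1": float(cube.axis.values[0]),
            "step_cm1": float(cube.axis.step),
            "count": len(cube.axis),
        },
        "dtype": "<f4",
        "order": "band_fastest",
        "payload": payload.name,
    }
    path.write_text(json.dumps(header, indent=2, sort_keys=True))
    cube.absorbance.astype("<f4").tofile(payload)


def read_cube(path) -> HyperCube:
    path = Path(path)
    try:
        header = json.loads(path.read_text())
        ny, nx = header["spatial_shape"]
        ax = header["axis"]
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise FormatError(f"bad cube header {path}: {exc}") from exc
    payload = path.parent / header["payload"]
    data = np.fromfile(payload, dtype="<f4")
    expected = ny * nx * ax["count"]
    if data.size != expected:
        raise FormatError(
            f"payload length {data.size} does not match header ({expected} values)"
        )
    values = ax["start_cm1"] - ax["step_cm1"] * np.arange(ax["count"])
    if ax["step_cm1"] < 0:  # stored ascending; enforce the descending convention
        warnings.warn("cube axis stored ascending; reversing to descending", stacklevel=2)
        values = values[::-1]
        data = data.reshape(ny, nx, ax["count"])[..., ::-1].ravel()
    axis = WavenumberAxis(values)
    return HyperCube(axis, data.reshape(ny, nx, ax["count"]).astype(float),
                     header.get("pixel_size_um", 2.56))


def write_cube_csv(cube: HyperCube, path):
    """Long-format CSV (x, y, wavenumber_cm1, absorbance) for small cubes."""
    ny, nx = cube.spatial_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    n_b = len(cube.axis)
    df = pd.DataFrame(
        {
            "y": np.repeat(yy.ravel(), n_b),
            "x": np.repeat(xx.ravel(), n_b),
            "wavenumber_cm1": np.tile(cube.axis.values, ny * nx),
            "absorbance": cube.absorbance.reshape(-1),
        }
    )
    df.to_csv(path, index=False)


def read_cube_csv(path, pixel_size_um: float = 2.56) -> HyperCube:
    df = pd.read_csv(path)
    required = {"y", "x", "wavenumber_cm1", "absorbance"}
    if not required.issubset(df.columns):
        raise FormatError(f"cube CSV must have columns {sorted(required)}")
    ny = int(df["y"].max()) + 1
    nx = int(df["x"].max()) + 1
    wn = np.sort(df["wavenumber_cm1"].unique())[::-1]
    axis = WavenumberAxis(wn)
    cube = np.full((ny, nx, wn.size), np.nan)
    wn_idx = {w: i for i, w in enumerate(wn)}
    rows = df["y"].to_numpy(int)
    cols = df["x"].to_numpy(int)
    bands = df["wavenumber_cm1"].map(wn_idx).to_numpy(int)
    cube[rows, cols, bands] = df["absorbance"].to_numpy(float)
    if np.isnan(cube).any():
        raise FormatError("cube CSV does not cover the full (y, x, wavenumber) grid")
    return HyperCube(axis, cube, pixel_size_um)


def write_map_tiff(map2d: np.ndarray, path):
    """False-color-ready 16-bit TIFF of a 2D band-integration map."""
    m = np.asarray(map2d, dtype=float)
    lo, hi = float(m.min()), float(m.max())
    scaled = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    tifffile.imwrite(Path(path), (scaled * 65535).astype(np.uint16), photometric="minisblack")


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "stage", "region", "variable", "value"]


def write_cohort(table: pd.DataFrame, path):
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV missing columns {missing}")
    return df
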