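"""Voxel phantoms with analytically known ground truth.

These stand in for the segmented collagen volumes of fibrous tissue: every
generator returns, next to the occupancy grid, a truth record computed
independently of the downstream estimators (closed-form volume fractions,
recursive voxel counts, known fractal dimensions), so estimator recovery can
be asserted without circularity.

Rasterization rule throughout: a voxel is foreground when its *center* lies
within the solid (within distance ``radius`` of a fiber axis, inside the
sphere, ...).  Voxel centers sit at integer coordinates + 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import ConvergenceError, InvalidSpecError
from ..types import VoxelVolume

MENGER_DIMENSION = math.log(20.0) / math.log(3.0)

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidSpecError("zero direction vector")
    return v / n


def _resolve_axis(axis) -> np.ndarray:
    if isinstance(axis, str):
        try:
            return _AXIS_VECTORS[axis.lower()].copy()
        except KeyError:
            raise InvalidSpecError(f"unknown axis name {axis!r}") from None
    return _unit(axis)


def _voxel_centers(grid_shape):
    """Three broadcastable center-coordinate arrays (voxel units)."""
    return np.meshgrid(
        *(np.arange(n, dtype=float) + 0.5 for n in grid_shape), indexing="ij", sparse=True
    )


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = _unit(np.cross(u, helper))
    w = np.cross(u, v)
    return v, w


@dataclass(frozen=True)
class FiberPhantomSpec:
    """Specification for a random fiber phantom.

    ``orientation_concentration`` interpolates between isotropic axes (0)
    and axes parallel to ``principal_axis`` (large values).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_um: float = 1.0
    fiber_radius_um: float = 3.0
    target_volume_fraction: float = 0.25
    orientation_concentration: float = 0.0
    principal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) < 2 for n in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be three integers >= 2, got {self.grid_shape}")
        if not 0.0 < self.target_volume_fraction < 1.0:
            raise InvalidSpecError("target volume fraction must be strictly in (0, 1)")
        if self.voxel_size_um <= 0:
            raise InvalidSpecError("voxel size must be positive")
        if self.fiber_radius_um < self.voxel_size_um:
            raise InvalidSpecError("fiber radius must be at least one voxel")
        if self.orientation_concentration < 0:
            raise InvalidSpecError("orientation concentration must be nonnegative")


def make_parallel_rods(
    grid_shape,
    radius_um: float,
    pitch_um: float,
    axis="z",
    voxel_size_um: float = 1.0,
) -> tuple[VoxelVolume, dict]:
    """Square lattice of straight parallel cylinders.

    Returns the voxelized volume plus a truth record with the analytic
    volume fraction pi * r^2 / pitch^2 and the realized voxel-count
    fraction.  The extreme anisotropy of this phantom probes the DA = 1
    endpoint of the MIL estimator.
    """
    if pitch_um < 2.0 * radius_um:
        raise InvalidSpecError(
            f"rods overlap: pitch {pitch_um} < 2 * radius {radius_um}"
        )
    u = _resolve_axis(axis)
    r_vox = radius_um / voxel_size_um
    p_vox = pitch_um / voxel_size_um
    v, w = _perp_basis(u)
    zi, yi, xi = _voxel_centers(grid_shape)  # ij-indexed axes 0,1,2
    # perpendicular-plane coordinates of each voxel center
    pp = zi * v[0] + yi * v[1] + xi * v[2]
    qq = zi * w[0] + yi * w[1] + xi * w[2]
    # distance to the nearest lattice line; lattice anchored at half pitch
    dp = np.mod(pp, p_vox) - 0.5 * p_vox
    dq = np.mod(qq, p_vox) - 0.5 * p_vox
    occ = dp * dp + dq * dq <= r_vox * r_vox
    vol = VoxelVolume(occ, voxel_size_um)
    truth = {
        "analytic_vol_fraction": math.pi * radius_um**2 / pitch_um**2,
        "realized_vol_fraction": vol.n_foreground / vol.n_voxels,
        "axis": u.tolist(),
        "radius_um": float(radius_um),
        "pitch_um": float(pitch_um),
    }
    return vol, truth


def _menger_mask(level: int) -> np.ndarray:
    n = 3**level
    idx = np.arange(n)
    keep = np.ones((n, n, n), dtype=bool)
    for lv in range(level):
        d = (idx // 3**lv) % 3
        di = (d[:, None, None] == 1).astype(int)
        dj = (d[None, :, None] == 1).astype(int)
        dk = (d[None, None, :] == 1).astype(int)
        keep &= (di + dj + dk) < 2
    return keep


def make_geometric_phantom(kind: str, grid_shape, **params) -> tuple[VoxelVolume, dict]:
    """Named solids with known topology/geometry.

    Kinds: ``filled``, ``plane`` (one voxel thick, mid-grid), ``ball``,
    ``torus``, ``two_balls``, ``menger`` (grid side must be 3**level).
    The truth record carries the analytic quantity each solid is for
    (voxel counts, Euler characteristic, fractal dimension).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel_size_um = float(params.pop("voxel_size_um", 1.0))
    truth: dict = {"kind": kind}
    nz, ny, nx = grid_shape

    if kind == "filled":
        occ = np.ones(grid_shape, dtype=bool)
        truth["fractal_dimension"] = 3.0
    elif kind == "plane":
        axis = int(params.pop("axis", 0))
        occ = np.zeros(grid_shape, dtype=bool)
        sl = [slice(None)] * 3
        sl[axis] = grid_shape[axis] // 2
        occ[tuple(sl)] = True
        truth["fractal_dimension"] = 2.0
    elif kind == "ball":
        radius = float(params.pop("radius", min(grid_shape) // 4))
        center = params.pop("center", None)
        c = np.array([s / 2.0 for s in grid_shape]) if center is None else np.asarray(center, float)
        if radius < 1 or np.any(c - radius < 0) or np.any(c + radius > np.array(grid_shape)):
            raise InvalidSpecError("grid too small for the requested ball")
        zi, yi, xi = _voxel_centers(grid_shape)
        occ = (zi - c[0]) ** 2 + (yi - c[1]) ** 2 + (xi - c[2]) ** 2 <= radius**2
        truth.update(radius=radius, euler_characteristic=1, connectivity=0)
    elif kind == "two_balls":
        radius = float(params.pop("radius", min(grid_shape) // 6))
        gap = float(params.pop("gap", 2.0))
        c0 = np.array([nz / 2.0, ny / 2.0, nx / 4.0])
        c1 = np.array([nz / 2.0, ny / 2.0, 3.0 * nx / 4.0])
        if nx / 2.0 < 2 * radius + gap or radius < 1 or nz / 2.0 < radius or ny / 2.0 < radius:
            raise InvalidSpecError("grid too small for two disjoint balls")
        zi, yi, xi = _voxel_centers(grid_shape)
        occ = ((zi - c0[0]) ** 2 + (yi - c0[1]) ** 2 + (xi - c0[2]) ** 2 <= radius**2) | (
            (zi - c1[0]) ** 2 + (yi - c1[1]) ** 2 + (xi - c1[2]) ** 2 <= radius**2
        )
        truth.update(radius=radius, euler_characteristic=2, connectivity=-1)
    elif kind == "torus":
        major = float(params.pop("major_radius", min(grid_shape) / 4.0))
        minor = float(params.pop("minor_radius", min(grid_shape) / 10.0))
        if major + minor >= min(ny, nx) / 2.0 or minor >= nz / 2.0 or minor < 1:
            raise InvalidSpecError("grid too small for the requested torus")
        c = np.array([s / 2.0 for s in grid_shape])
        zi, yi, xi = _voxel_centers(grid_shape)
        rho = np.sqrt((yi - c[1]) ** 2 + (xi - c[2]) ** 2)
        occ = (rho - major) ** 2 + (zi - c[0]) ** 2 <= minor**2
        truth.update(
            major_radius=major, minor_radius=minor, euler_characteristic=0, connectivity=1
        )
    elif kind == "menger":
        level = int(params.pop("level", 3))
        side = 3**level
        if grid_shape != (side, side, side):
            raise InvalidSpecError(f"menger level {level} requires a {side}^3 grid")
        occ = _menger_mask(level)
        truth.update(
            level=level,
            voxel_count=20**level,
            fractal_dimension=MENGER_DIMENSION,
        )
    else:
        raise InvalidSpecError(f"unknown phantom kind {kind!r}")

    if params:
        raise InvalidSpecError(f"unused parameters for kind {kind!r}: {sorted(params)}")
    vol = VoxelVolume(occ, voxel_size_um)
    truth["realized_vol_fraction"] = vol.n_foreground / vol.n_voxels
    return vol, truth


def make_random_spheres(
    grid_shape,
    radius_vox: float,
    target_volume_fraction: float,
    seed: int,
    voxel_size_um: float = 1.0,
    max_spheres: int = 200_000,
) -> tuple[VoxelVolume, dict]:
    """Overlapping spheres at uniform random centers: an isotropic phantom.

    Spheres are added until the realized volume fraction reaches the target;
    probes the DA = 0 endpoint of the MIL estimator.
    """
    if not 0.0 < target_volume_fraction < 1.0:
        raise InvalidSpecError("target volume fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    grid_shape = tuple(int(n) for n in grid_shape)
    occ = np.zeros(grid_shape, dtype=bool)
    r = float(radius_vox)
    ir = int(math.ceil(r))
    span = np.arange(-ir, ir + 1, dtype=float)
    ball = (
        span[:, None, None] ** 2 + span[None, :, None] ** 2 + span[None, None, :] ** 2
    ) <= r * r
    n_target = target_volume_fraction * occ.size
    n_spheres = 0
    while occ.sum() < n_target:
        if n_spheres >= max_spheres:
            raise ConvergenceError("sphere budget exhausted before reaching target fraction")
        c = np.floor(rng.uniform(0, grid_shape)).astype(int)
        lo = np.maximum(c - ir, 0)
        hi = np.minimum(c + ir + 1, grid_shape)
        bl = lo - (c - ir)
        bh = bl + (hi - lo)
        occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= ball[
            bl[0] : bh[0], bl[1] : bh[1], bl[2] : bh[2]
        ]
        n_spheres += 1
    vol = VoxelVolume(occ, voxel_size_um)
    truth = {
        "realized_vol_fraction": vol.n_foreground / vol.n_voxels,
        "n_spheres": n_spheres,
        "radius_vox": r,
        "seed": int(seed),
    }
    return vol, truth


def _random_axis(rng, concentration: float, principal: np.ndarray) -> np.ndarray:
    """One fiber axis: normalized mix of a uniform direction and the principal
    axis, weighted by the concentration parameter."""
    raw = rng.normal(size=3)
    iso = raw / np.linalg.norm(raw)
    if concentration == 0.0:
        return iso
    mixed = concentration * principal + iso
    n = np.linalg.norm(mixed)
    if n == 0:  # pathological cancellation; fall back to the isotropic draw
        return iso
    return mixed / n


def make_fiber_phantom(spec: FiberPhantomSpec) -> tuple[VoxelVolume, dict]:
    """Random straight cylinders until the target volume fraction is reached.

    Cylinder axes follow the concentration-parameterized directional law of
    ``spec``; each cylinder spans the whole grid.  The truth record holds
    the realized fraction, fiber radius, and the mean axis (normalized mean
    of the drawn directions, sign-aligned with the principal axis).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    principal = _unit(spec.principal_axis)
    r_vox = spec.fiber_radius_um / spec.voxel_size_um
    occ = np.zeros(shape, dtype=bool)
    centers = _voxel_centers(shape)
    coords = np.stack(np.broadcast_arrays(*centers), axis=-1)  # (nz,ny,nx,3)
    box_center = np.array([s / 2.0 for s in shape])
    half_diag = np.linalg.norm(box_center)

    axes = []
    n_target_lo = (spec.target_volume_fraction - 0.02) * occ.size
    n_target = spec.target_volume_fraction * occ.size
    max_fibers = 50_000
    n_fibers = 0
    while occ.sum() < n_target_lo:
        if n_fibers >= max_fibers:
            raise ConvergenceError("fiber budget exhausted before reaching target fraction")
        u = _random_axis(rng, spec.orientation_concentration, principal)
        # random point within the box, pushed so the infinite line meets the box
        point = rng.uniform(0, shape, size=3)
        d = coords - point
        along = d @ u
        perp2 = np.einsum("...i,...i", d, d) - along**2
        occ |= perp2 <= r_vox * r_vox
        axes.append(u if u @ principal >= 0 else -u)
        n_fibers += 1
        del d, along, perp2

    vol = VoxelVolume(occ, spec.voxel_size_um)
    mean_axis = np.mean(axes, axis=0) if axes else principal
    mean_axis = mean_axis / np.linalg.norm(mean_axis)
    truth = {
        "realized_vol_fraction": vol.n_foreground / vol.n_voxels,
        "target_vol_fraction": spec.target_volume_fraction,
        "fiber_radius_um": spec.fiber_radius_um,
        "n_fibers": n_fibers,
        "mean_axis": mean_axis.tolist(),
        "seed": spec.seed,
        "half_diagonal_vox": float(half_diag),
    }
    return vol, truth
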