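"""Shared domain containers.

Two substrates flow through the pipeline: :class:`VoxelVolume` (a binary
occupancy grid with isotropic voxel size, the 3D morphometry input) and
:class:`HyperCube` (a spatial grid of absorbance spectra on a common
wavenumber axis, the FTIR imaging input).  The remaining classes are light
result records.  Cohort tables are plain :class:`pandas.DataFrame` objects
in long format (``patient_id, stage, region, variable, value``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnisotropyFitError, InvalidSpecError, WindowError

STAGES = ("I", "II", "III", "IV")
REGIONS = ("IntraT", "PeriT", "ExtraT")

#: Analysis windows (cm^-1): amide I+II (total proteins), amide III subrange
#: used for the collagen map, and the full amide III interval used as the
#: denominator of the secondary-structure ratios.
PROTEIN_WINDOW = (1720.0, 1470.0)
COLLAGEN_WINDOW = (1299.0, 1184.0)
AMIDE_III_WINDOW = (1360.0, 1184.0)

#: Band centroids (cm^-1) used throughout: amide I, amide II, proline CH2
#: wagging, alpha helix, triple helix (1280 and 1240), random coil, and
#: amino-acid side chains.
AMIDE_I = 1655.0
AMIDE_II = 1550.0
PROLINE_BAND = 1342.0
ALPHA_HELIX_BAND = 1319.0
TRIPLE_HELIX_BAND = 1280.0
RANDOM_COIL_BAND = 1262.0
TRIPLE_HELIX_BAND_2 = 1240.0
SIDE_CHAIN_BAND = 1205.0

AMIDE_III_BANDS = (
    PROLINE_BAND,
    ALPHA_HELIX_BAND,
    TRIPLE_HELIX_BAND,
    RANDOM_COIL_BAND,
    TRIPLE_HELIX_BAND_2,
    SIDE_CHAIN_BAND,
)


@dataclass
class VoxelVolume:
    """3D boolean occupancy grid with isotropic voxel size in micrometres."""

    occupancy: np.ndarray
    voxel_size_um: float = 1.0

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise InvalidSpecError(f"occupancy must be 3D, got ndim={occ.ndim}")
        if min(occ.shape) < 2:
            raise InvalidSpecError(f"all dimensions must be >= 2, got {occ.shape}")
        if occ.dtype != bool:
            occ = occ.astype(bool)
        if not (np.isfinite(self.voxel_size_um) and self.voxel_size_um > 0):
            raise InvalidSpecError(f"voxel size must be finite positive, got {self.voxel_size_um}")
        self.occupancy = occ
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.size)

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    @property
    def physical_volume_um3(self) -> float:
        return self.n_voxels * self.voxel_size_um**3

    def complement(self) -> "VoxelVolume":
        return VoxelVolume(~self.occupancy, self.voxel_size_um)


@dataclass
class WavenumberAxis:
    """Strictly descending, uniformly spaced wavenumber axis (cm^-1)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 16:
            raise InvalidSpecError("axis needs >= 16 points in one dimension")
        steps = np.diff(v)
        if not np.all(steps < 0):
            raise InvalidSpecError("axis must be strictly descending")
        step = steps.mean()
        if np.max(np.abs(steps - step)) > 1e-6 * abs(step):
            raise InvalidSpecError("axis must be uniformly spaced")
        if v.max() > 4000.0 or v.min() < 900.0:
            raise InvalidSpecError("axis must lie within [900, 4000] cm^-1")
        self.values = v

    @classmethod
    def from_range(cls, hi: float = 1800.0, lo: float = 900.0, step: float = 4.0) -> "WavenumberAxis":
        """Descending axis from ``hi`` down to ``lo`` inclusive, ``step`` cm^-1."""
        n = int(round((hi - lo) / step)) + 1
        return cls(hi - step * np.arange(n))

    @property
    def step(self) -> float:
        return float(self.values[0] - self.values[1])

    def __len__(self) -> int:
        return self.values.size

    def window_slice(self, window: "BandWindow") -> np.ndarray:
        """Boolean mask of axis points inside [lo, hi]."""
        if not (self.values.max() >= window.hi_cm1 and self.values.min() <= window.lo_cm1):
            raise WindowError(
                f"window {window.hi_cm1}-{window.lo_cm1} outside axis "
                f"{self.values.max()}-{self.values.min()}"
            )
        return (self.values <= window.hi_cm1) & (self.values >= window.lo_cm1)


@dataclass
class BandWindow:
    """Spectral integration window, stated high-to-low in cm^-1."""

    hi_cm1: float
    lo_cm1: float

    def __post_init__(self):
        if not self.hi_cm1 > self.lo_cm1:
            raise WindowError(f"window requires hi > lo, got {self.hi_cm1} <= {self.lo_cm1}")

    @property
    def width(self) -> float:
        return self.hi_cm1 - self.lo_cm1


@dataclass
class Spectrum:
    """One absorbance spectrum on a :class:`WavenumberAxis`."""

    axis: WavenumberAxis
    absorbance: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.axis),):
            raise InvalidSpecError("absorbance length must match axis")
        if not np.all(np.isfinite(a)):
            raise InvalidSpecError("absorbance must be finite")
        self.absorbance = a


@dataclass
class HyperCube:
    """ny x nx grid of absorbance spectra sharing one wavenumber axis."""

    axis: WavenumberAxis
    absorbance: np.ndarray  # (ny, nx, n_bands)
    pixel_size_um: float = 2.56

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 3 or a.shape[2] != len(self.axis):
            raise InvalidSpecError("cube must be (ny, nx, n_bands) with band dim matching axis")
        if min(a.shape[:2]) < 2:
            raise InvalidSpecError("spatial dimensions must be >= 2")
        if self.pixel_size_um <= 0:
            raise InvalidSpecError("pixel size must be positive")
        self.absorbance = a
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.absorbance.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.absorbance.shape[0] * self.absorbance.shape[1]

    @property
    def side_um(self) -> tuple[float, float]:
        ny, nx = self.spatial_shape
        return (ny * self.pixel_size_um, nx * self.pixel_size_um)

    def pixel_spectrum(self, iy: int, ix: int) -> Spectrum:
        return Spectrum(self.axis, self.absorbance[iy, ix])


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band; area = height * sigma * sqrt(2*pi)."""

    centroid_cm1: float
    height: float
    sigma_cm1: float

    def __post_init__(self):
        if not 900.0 <= self.centroid_cm1 <= 1800.0:
            raise InvalidSpecError(f"centroid {self.centroid_cm1} outside [900, 1800] cm^-1")
        if self.height < 0:
            raise InvalidSpecError("band height must be nonnegative")
        if self.sigma_cm1 <= 0:
            raise InvalidSpecError("band sigma must be positive")

    @property
    def area(self) -> float:
        return self.height * self.sigma_cm1 * math.sqrt(2.0 * math.pi)

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, dtype=float)
        return self.height * np.exp(-0.5 * ((x - self.centroid_cm1) / self.sigma_cm1) ** 2)


@dataclass
class RatioPanel:
    """The five spectral ratios summarising collagen amount and structure.

    ``coll_prt`` and ``pro_prt`` track relative collagen/proline content
    against total proteins; ``triple_helix``, ``alpha_helix`` and
    ``random_coil`` are secondary-structure fractions of the amide III
    interval and therefore lie in [0, 1].
    """

    coll_prt: float
    pro_prt: float
    triple_helix: float
    alpha_helix: float
    random_coil: float

    FIELDS = ("coll_prt", "pro_prt", "triple_helix", "alpha_helix", "random_coil")

    def __post_init__(self):
        for name in self.FIELDS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidSpecError(f"{name} must be finite and nonnegative, got {v}")
        for name in ("triple_helix", "alpha_helix", "random_coil"):
            v = getattr(self, name)
            if v > 1.0 + 1e-9:
                raise InvalidSpecError(f"{name} is a fraction of the amide III area, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.FIELDS}


@dataclass
class ClusterMap:
    """Pixel cluster labels (1..k) with the collagen-rich cluster flagged."""

    labels: np.ndarray
    k: int
    collagen_label: int

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise InvalidSpecError("label grid must be 2D")
        if self.k < 1:
            raise InvalidSpecError("k must be >= 1")
        if not 1 <= self.collagen_label <= self.k:
            raise InvalidSpecError("collagen_label must be in [1, k]")
        if lab.min() < 1 or lab.max() > self.k:
            raise InvalidSpecError("labels must be in [1, k]")
        self.labels = lab.astype(int)


@dataclass(frozen=True)
class PeakComponent:
    centroid_cm1: float
    height: float
    sigma_cm1: float

    @property
    def area(self) -> float:
        return self.height * self.sigma_cm1 * math.sqrt(2.0 * math.pi)


@dataclass
class PeakModel:
    """Result of Gaussian deconvolution inside one fit window."""

    components: list[PeakComponent]
    fit_window: BandWindow
    residual_rms: float
    flags: list[str] = field(default_factory=list)

    def nearest(self, centroid_cm1: float, tol_cm1: float = 6.0) -> PeakComponent | None:
        best, best_d = None, float("inf")
        for c in self.components:
            d = abs(c.centroid_cm1 - centroid_cm1)
            if d < best_d:
                best, best_d = c, d
        return best if best is not None and best_d <= tol_cm1 else None

    @property
    def total_area(self) -> float:
        return float(sum(c.area for c in self.components))


@dataclass
class MILResult:
    """Mean-intercept-length fan and the fitted anisotropy ellipsoid."""

    directions: np.ndarray  # (n, 3) unit vectors retained after dropping
    mil_values: np.ndarray  # (n,) mean intercept lengths, um
    ellipsoid_radii: np.ndarray  # three radii sorted descending
    da: float
    n_dropped: int = 0

    def __post_init__(self):
        if np.any(self.mil_values <= 0):
            raise InvalidSpecError("MIL values must be positive")
        r = np.sort(np.asarray(self.ellipsoid_radii, dtype=float))[::-1]
        if np.any(r <= 0):
            raise AnisotropyFitError("ellipsoid radii must be strictly positive")
        self.ellipsoid_radii = r
        self.da = float(min(max(self.da, 0.0), 1.0))


@dataclass(frozen=True)
class BoxCountConfig:
    """Box-counting schedule: geometric box sizes from 48 px down to 6 px
    at factor 1.2, grid anchored at the origin (translation 0)."""

    initial_box_px: int = 48
    smallest_box_px: int = 6
    scale_factor: float = 1.2
    grid_translation: int = 0

    def __post_init__(self):
        if self.initial_box_px < 1 or self.smallest_box_px < 1:
            raise InvalidSpecError("box sizes must be positive integers")
        if self.smallest_box_px > self.initial_box_px:
            raise InvalidSpecError("smallest box must not exceed initial box")
        if self.scale_factor <= 1.0:
            raise InvalidSpecError("scale factor must exceed 1")
        if self.grid_translation < 0:
            raise InvalidSpecError("grid translation must be nonnegative")

    def sizes(self) -> list[int]:
        """Rounded geometric sequence, duplicates removed, descending."""
        out, s = [], float(self.initial_box_px)
        while round(s) >= self.smallest_box_px:
            r = int(round(s))
            if not out or r != out[-1]:
                out.append(r)
            s /= self.scale_factor
        return out


@dataclass
class MorphometrySummary:
    """The seven 3D morphometric indices for one volume of interest."""

    vol_fraction: float
    thickness_um: float
    spacing_um: float
    da: float
    conn_density_per_um3: float
    fr_dim: float
    mean_fiber_length_um: float
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    FIELDS = (
        "vol_fraction",
        "thickness_um",
        "spacing_um",
        "da",
        "conn_density_per_um3",
        "fr_dim",
        "mean_fiber_length_um",
    )

    def __post_init__(self):
        if not 0.0 <= self.vol_fraction <= 1.0:
            raise InvalidSpecError("volume fraction must be in [0, 1]")
        if not 0.0 <= self.da <= 1.0:
            raise InvalidSpecError("DA must be in [0, 1]")
        if not 0.0 <= self.fr_dim <= 3.0 + 1e-9:
            raise InvalidSpecError("fractal dimension must be in [0, 3]")
        # the usual reading band for 3D structures is [2, 3]; flag excursions
        if not 2.0 <= self.fr_dim <= 3.0 and "fr_dim_outside_2_3" not in self.flags:
            self.flags.append("fr_dim_outside_2_3")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.FIELDS}
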