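"""Synthetic FTIR hyperspectral cubes built from Gaussian bands.

Each pixel spectrum is the sum of its class's Gaussian bands plus an
optional baseline and i.i.d. Gaussian noise.  The generator returns a
:class:`CubeTruth` holding the planted class map and, per class, the
analytic ratio panel computed from closed-form Gaussian areas (no noise,
no baseline), which is the ground truth every spectral estimator is
checked against.

The default geometry mirrors a focal-plane-array acquisition: 64 x 64
pixels of 2.56 um (4,096 spectra, 163.84 um per side) on a descending
1800 -> 900 cm^-1 axis in 4 cm^-1 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from ..errors import InvalidSpecError
from ..types import (
    ALPHA_HELIX_BAND,
    AMIDE_I,
    AMIDE_II,
    AMIDE_III_WINDOW,
    COLLAGEN_WINDOW,
    PROLINE_BAND,
    PROTEIN_WINDOW,
    RANDOM_COIL_BAND,
    SIDE_CHAIN_BAND,
    TRIPLE_HELIX_BAND,
    TRIPLE_HELIX_BAND_2,
    BandSpec,
    HyperCube,
    RatioPanel,
)

DEFAULT_SPATIAL_SHAPE = (64, 64)
DEFAULT_PIXEL_SIZE_UM = 2.56


def gaussian_window_area(band: BandSpec, hi: float, lo: float) -> float:
    """Closed-form area of one Gaussian band inside [lo, hi] cm^-1."""
    s = band.sigma_cm1 * math.sqrt(2.0)
    frac = 0.5 * (erf((hi - band.centroid_cm1) / s) - erf((lo - band.centroid_cm1) / s))
    return band.area * float(frac)


def bands_window_area(bands, window: tuple[float, float]) -> float:
    hi, lo = window
    return sum(gaussian_window_area(b, hi, lo) for b in bands)


def _band_near(bands, centroid: float, tol: float = 6.0) -> BandSpec:
    best = min(bands, key=lambda b: abs(b.centroid_cm1 - centroid), default=None)
    if best is None or abs(best.centroid_cm1 - centroid) > tol:
        raise InvalidSpecError(f"band table lacks a band near {centroid} cm^-1")
    return best


def analytic_ratio_panel(bands) -> RatioPanel:
    """Ratio panel from closed-form band areas alone (no noise, no baseline).

    The COLL/PRT numerator uses the 1299-1184 window integral; PRO/PRT the
    full area of the 1342 band; the three structure ratios the full areas of
    the 1280 / 1319 / 1262 bands over the 1360-1184 window integral.
    """
    prt = bands_window_area(bands, PROTEIN_WINDOW)
    coll = bands_window_area(bands, COLLAGEN_WINDOW)
    amide3 = bands_window_area(bands, AMIDE_III_WINDOW)
    if prt <= 0 or amide3 <= 0:
        raise InvalidSpecError(
            "band table has no absorption in the protein or amide III window"
        )
    return RatioPanel(
        coll_prt=coll / prt,
        pro_prt=_band_near(bands, PROLINE_BAND).area / prt,
        triple_helix=_band_near(bands, TRIPLE_HELIX_BAND).area / amide3,
        alpha_helix=_band_near(bands, ALPHA_HELIX_BAND).area / amide3,
        random_coil=_band_near(bands, RANDOM_COIL_BAND).area / amide3,
    )


def collagen_band_table(
    collagen_scale: float = 1.0,
    protein_scale: float = 1.0,
    random_height: float = 0.18,
) -> tuple[BandSpec, ...]:
    """Band table of a collagenous protein spectrum.

    ``collagen_scale`` multiplies the collagen-specific amide III bands
    (proline 1342, alpha helix 1319, triple helix 1280/1240, side chains
    1205); ``protein_scale`` the amide I/II bands; the random-coil band
    height is absolute, so lowering ``collagen_scale`` at fixed
    ``random_height`` both lowers COLL/PRT and raises the RANDOM fraction,
    the direction expected when ordered collagen is lost.
    """
    return (
        BandSpec(AMIDE_I, 1.00 * protein_scale, 18.0),
        BandSpec(AMIDE_II, 0.70 * protein_scale, 16.0),
        BandSpec(PROLINE_BAND, 0.30 * collagen_scale, 8.0),
        BandSpec(ALPHA_HELIX_BAND, 0.25 * collagen_scale, 8.0),
        BandSpec(TRIPLE_HELIX_BAND, 0.35 * collagen_scale, 8.0),
        BandSpec(RANDOM_COIL_BAND, random_height, 8.0),
        BandSpec(TRIPLE_HELIX_BAND_2, 0.33 * collagen_scale, 9.0),
        BandSpec(SIDE_CHAIN_BAND, 0.20 * collagen_scale, 8.0),
    )


@dataclass
class CubeTruth:
    """Planted ground truth of one synthetic cube."""

    class_map: np.ndarray
    band_tables: dict[int, tuple[BandSpec, ...]]
    panels: dict[int, RatioPanel]
    noise_sd: float
    seed: int
    baseline: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        cm = np.asarray(self.class_map)
        if cm.ndim != 2:
            raise InvalidSpecError("class map must be 2D")
        self.class_map = cm.astype(int)
        if self.noise_sd < 0:
            raise InvalidSpecError("noise sd must be nonnegative")


def make_class_map(spatial_shape=DEFAULT_SPATIAL_SHAPE, kind: str = "halves") -> np.ndarray:
    """Spatially structured two-class label maps (labels 1 and 2).

    ``halves`` splits the field left/right; ``disk`` places a class-2 disk
    (protein-rich nest, say) in a class-1 matrix; ``stripes`` alternates
    8-pixel bands.
    """
    ny, nx = spatial_shape
    cm = np.ones((ny, nx), dtype=int)
    if kind == "halves":
        cm[:, nx // 2 :] = 2
    elif kind == "disk":
        yy, xx = np.mgrid[0:ny, 0:nx]
        cm[(yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2 <= (min(ny, nx) / 3.5) ** 2] = 2
    elif kind == "stripes":
        cm[:, (np.arange(nx) // 8) % 2 == 1] = 2
    else:
        raise InvalidSpecError(f"unknown class map kind {kind!r}")
    return cm


def make_hypercube(
    class_map: np.ndarray,
    band_tables: dict[int, tuple[BandSpec, ...]],
    axis=None,
    baseline: float = 0.0,
    baseline_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[HyperCube, CubeTruth]:
    """Assemble a cube from per-class Gaussian band tables.

    ``baseline`` adds a constant offset, ``baseline_slope`` a linear ramp
    (absorbance per cm^-1, zero at the axis midpoint) as a stress test.
    Noise is i.i.d. Gaussian per pixel and band.
    """
    from ..types import WavenumberAxis  # local import to avoid cycle at module load

    if axis is None:
        axis = WavenumberAxis.from_range()
    class_map = np.asarray(class_map, dtype=int)
    labels = sorted(np.unique(class_map))
    missing = [lab for lab in labels if lab not in band_tables]
    if missing:
        raise InvalidSpecError(f"class map labels without band tables: {missing}")
    wn = axis.values
    for lab in labels:
        for band in band_tables[lab]:
            if not (wn.min() <= band.centroid_cm1 <= wn.max()):
                raise InvalidSpecError(
                    f"band centroid {band.centroid_cm1} cm^-1 outside axis range"
                )

    mid = 0.5 * (wn.max() + wn.min())
    base = baseline + baseline_slope * (wn - mid)
    templates = {
        lab: sum(b.profile(wn) for b in band_tables[lab]) + base for lab in labels
    }
    ny, nx = class_map.shape
    cube = np.empty((ny, nx, wn.size), dtype=float)
    for lab in labels:
        cube[class_map == lab] = templates[lab]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)

    panels: dict[int, RatioPanel | None] = {}
    panel_flags = []
    for lab in labels:
        try:
            panels[lab] = analytic_ratio_panel(band_tables[lab])
        except InvalidSpecError:
            # band table lacks the ratio-defining bands (stress/edge cubes)
            panels[lab] = None
            panel_flags.append(f"panel_unavailable_class_{lab}")
    truth = CubeTruth(
        class_map=class_map,
        band_tables={lab: tuple(band_tables[lab]) for lab in labels},
        panels=panels,
        noise_sd=float(noise_sd),
        seed=int(seed),
        baseline=float(baseline),
        flags=panel_flags,
    )
    return HyperCube(axis, cube, pixel_size_um), truth


def make_two_class_cube(
    spatial_shape=DEFAULT_SPATIAL_SHAPE,
    kind: str = "halves",
    noise_sd: float = 0.0,
    seed: int = 0,
    collagen_scale_rich: float = 1.0,
    collagen_scale_poor: float = 0.3,
) -> tuple[HyperCube, CubeTruth]:
    """Convenience cube: collagen-rich (label 1) vs collagen-poor (label 2)."""
    cm = make_class_map(spatial_shape, kind)
    tables = {
        1: collagen_band_table(collagen_scale=collagen_scale_rich),
        2: collagen_band_table(collagen_scale=collagen_scale_poor, protein_scale=1.1),
    }
    return make_hypercube(cm, tables, noise_sd=noise_sd, seed=seed)


#: Collagen amplitude scaling of each synthetic region, declining from
#: normal stroma through the staged invasion-front series to the tumor core.
REGION_COLLAGEN_SCALE = {
    "ExtraT": 1.0,
    "PeriT S-I": 0.90,
    "PeriT S-II": 0.75,
    "PeriT S-III": 0.60,
    "PeriT S-IV": 0.45,
    "IntraT": 0.30,
}


def make_stage_series(
    spatial_shape=(24, 24),
    noise_sd: float = 0.0,
    seed: int = 0,
    regions=tuple(REGION_COLLAGEN_SCALE),
) -> dict[str, tuple[HyperCube, CubeTruth]]:
    """One cube per region with monotonically declining collagen amplitude."""
    rng = np.random.default_rng(seed)
    out = {}
    for name in regions:
        scale = REGION_COLLAGEN_SCALE[name]
        cm = make_class_map(spatial_shape, "disk")
        tables = {
            1: collagen_band_table(collagen_scale=scale),
            2: collagen_band_table(collagen_scale=0.3 * scale, protein_scale=1.1),
        }
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out[name] = make_hypercube(cm, tables, noise_sd=noise_sd, seed=sub_seed)
    return out
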