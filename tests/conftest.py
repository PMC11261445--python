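import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def euler_characteristic_bruteforce(occ: np.ndarray) -> int:
    """chi = V - E + F - C by explicit set enumeration of the cubical
    complex of the closed-voxel union.  Only for small grids."""
    V, E, F = set(), set(), set()
    C = 0
    for i, j, k in zip(*np.nonzero(occ)):
        C += 1
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    V.add((i + di, j + dj, k + dk))
        for dj in (0, 1):
            for dk in (0, 1):
                E.add(("x", i, j + dj, k + dk))
        for di in (0, 1):
            for dk in (0, 1):
                E.add(("y", i + di, j, k + dk))
        for di in (0, 1):
            for dj in (0, 1):
                E.add(("z", i + di, j + dj, k))
        for di in (0, 1):
            F.add(("yz", i + di, j, k))
        for dj in (0, 1):
            F.add(("xz", i, j + dj, k))
        for dk in (0, 1):
            F.add(("xy", i, j, k + dk))
    return len(V) - len(E) + len(F) - C


def local_thickness_bruteforce(occ: np.ndarray) -> np.ndarray:
    """Per-voxel largest-inscribed-sphere diameter (voxel units) by painting
    the exact-radius sphere of every foreground voxel.  Only for small grids."""
    from scipy import ndimage

    edt = ndimage.distance_transform_edt(occ)
    out = np.zeros(occ.shape, dtype=float)
    shape = np.array(occ.shape)
    for c in np.argwhere(occ):
        r = edt[tuple(c)]
        ir = int(np.ceil(r))
        lo = np.maximum(c - ir, 0)
        hi = np.minimum(c + ir + 1, shape)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 < r * r
        region = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        region[inside] = np.maximum(region[inside], 2.0 * r)
    out[~occ] = 0.0
    return out


def spearman_hand_formula(x, y) -> float:
    """1 - 6 * sum(d^2) / (n (n^2 - 1)); valid without ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(((rx - ry) ** 2).sum())
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


@pytest.fixture(scope="session")
def rods_small():
    """64^3 parallel-rod phantom shared across tests."""
    from stromakit import synthetic as syn

    vol, truth = syn.make_parallel_rods((64, 64, 64), 4.0, 16.0, "z")
    return vol, truth


@pytest.fixture(scope="session")
def two_class_cube_clean():
    from stromakit import synthetic as syn

    return syn.make_two_class_cube((32, 32), noise_sd=0.0)
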