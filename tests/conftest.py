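import numpy as np
import pytest

from seedspectra.io_envi import Hypercube


@pytest.fixture
def tiny_cube() -> Hypercube:
    """2x2x3 cube with distinct values in every cell."""
    data = np.arange(12, dtype=np.float64).reshape(2, 2, 3) / 12.0
    return Hypercube(data=data, wavelengths=np.array([450.0, 550.0, 650.0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_wavelengths(n: int, lo: float = 400.0, hi: float = 1000.0) -> np.ndarray:
    return np.linspace(lo, hi, n)


def otsu_objective_by_level(img: np.ndarray, nbins: int = 256):
    """Exhaustive between-class variance per candidate level (the brute-force
    oracle for Otsu's method). Returns (levels, variances)."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts / counts.sum()
    levels, variances = [], []
    for t in range(1, nbins):
        w0, w1 = w[:t].sum(), w[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (w[:t] * centers[:t]).sum() / w0
        mu1 = (w[t:] * centers[t:]).sum() / w1
        levels.append(centers[t - 1])
        variances.append(w0 * w1 * (mu0 - mu1) ** 2)
    return np.array(levels), np.array(variances)


def assert_otsu_matches_bruteforce(level: float, img: np.ndarray) -> None:
    """The implementation's level must attain the exhaustive maximum of the
    between-class variance (ties between adjacent bins are equally optimal)."""
    levels, variances = otsu_objective_by_level(img)
    attained = variances[np.argmin(np.abs(levels - level))]
    assert attained >= variances.max() * (1 - 1e-9)
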