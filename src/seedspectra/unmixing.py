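"""Linear spectral unmixing: endmember count estimation (NWHFC), MNF rotation,
PPI endmember extraction, MSE-based endmember consolidation, constrained
abundance estimation and reconstruction scoring (rRMSE).

The pixel model is the linear mixing model: every pixel spectrum is a convex
combination of a small set of pure endmember spectra plus sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .io_envi import Hypercube

__all__ = [
    "EndmemberSet",
    "AbundanceStack",
    "estimate_num_endmembers",
    "mnf_transform",
    "MnfResult",
    "ppi_extract",
    "consolidate_endmembers",
    "spectral_mse",
    "estimate_abundances",
    "reconstruct",
    "rrmse",
]


@dataclass
class EndmemberSet:
    """P pure spectra on a shared wavelength grid, with labels and scene roles."""

    spectra: np.ndarray  # (P, n_bands)
    wavelengths: np.ndarray
    labels: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)  # foreground|background|unassigned

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError("spectra and wavelengths disagree on band count")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("endmember spectra must be finite")
        if not self.labels:
            self.labels = [f"EM#{i + 1}" for i in range(len(self))]
        if not self.roles:
            self.roles = ["unassigned"] * len(self)
        if len(self.labels) != len(self) or len(self.roles) != len(self):
            raise ValueError("labels/roles length must match number of spectra")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def foreground_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "foreground"]

    def background_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "background"]


@dataclass
class AbundanceStack:
    """Per-pixel endmember proportions: (rows, cols, P) maps."""

    maps: np.ndarray
    endmembers: EndmemberSet

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("abundance maps must be (rows, cols, P)")
        if self.maps.shape[2] != len(self.endmembers):
            raise ValueError("number of maps must match number of endmembers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape


def _shift_difference_noise(data: np.ndarray) -> np.ndarray:
    """Noise covariance from horizontal/vertical first differences.

    Neighbouring pixels share signal, so their difference is dominated by
    noise; Var(x1 - x2) = 2 sigma^2 for i.i.d. noise, hence the factor 1/2.
    """
    dh = data[:, 1:, :] - data[:, :-1, :]
    dv = data[1:, :, :] - data[:-1, :, :]
    diffs = np.concatenate([dh.reshape(-1, data.shape[2]),
                            dv.reshape(-1, data.shape[2])], axis=0)
    return (diffs.T @ diffs) / (2.0 * diffs.shape[0])


def estimate_num_endmembers(cube: Hypercube, pfa: float = 1e-3) -> int:
    """Estimate the number of spectrally distinct sources by the noise-whitened
    Harsanyi-Farrand-Chang (NWHFC) eigen-test.

    After whitening by the shift-difference noise covariance, eigenvalues of
    the sample correlation matrix are compared pairwise with those of the
    covariance matrix; a source with non-zero mean energy inflates the
    correlation eigenvalue. Each pair is tested by a Neyman-Pearson detector
    at false-alarm probability ``pfa``.
    """
    if not (0.0 < pfa < 0.5):
        raise ValueError("pfa must be in (0, 0.5)")
    rows, cols, n_bands = cube.shape
    if rows * cols < 2 * n_bands:
        raise ValueError("need at least 2 spatial pixels per band")
    x = cube.pixels()
    n_pix = x.shape[0]

    noise_cov = _shift_difference_noise(cube.data)
    # Regularize minimally for invertibility, then whiten.
    eps = 1e-12 * max(np.trace(noise_cov) / n_bands, 1e-30)
    try:
        f = linalg.cholesky(noise_cov + eps * np.eye(n_bands), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "noise covariance is singular; denoise or pass a cube with spatial "
            "noise variation (regularization option)"
        ) from exc
    xw = linalg.solve_triangular(f, x.T, lower=True).T

    corr = (xw.T @ xw) / n_pix
    mean = xw.mean(axis=0)
    cov = corr - np.outer(mean, mean)
    l_corr = np.sort(linalg.eigvalsh(corr))[::-1]
    l_cov = np.sort(linalg.eigvalsh(cov))[::-1]

    # Under H0 the eigenvalue pair sits at the whitened noise floor (unity by
    # construction), so the asymptotic variance of the difference is 4/n_pix;
    # evaluating it at the observed (signal-sized) eigenvalues instead would
    # destroy power exactly where both members of a pair carry signal.
    sigma = np.sqrt(2.0 * (1.0 + 1.0) / n_pix)
    tau = -stats.norm.ppf(pfa) * sigma
    return int(np.sum((l_corr - l_cov) > tau))


@dataclass
class MnfResult:
    """Outcome of a minimum-noise-fraction rotation."""

    cube: Hypercube  # components ordered by descending SNR
    noise_cov: np.ndarray
    eigenvalues: np.ndarray
    _inverse: np.ndarray  # maps component space back to band space
    _mean: np.ndarray

    def inverse(self, n_components: int | None = None) -> Hypercube:
        """Back-transform, optionally keeping only the first components."""
        comp = self.cube.data
        k = comp.shape[2] if n_components is None else int(n_components)
        rows, cols, _ = comp.shape
        flat = comp.reshape(-1, comp.shape[2])[:, :k]
        recon = flat @ self._inverse[:k, :] + self._mean
        return Hypercube(data=recon.reshape(rows, cols, -1),
                         wavelengths=self.cube.meta["original_wavelengths"],
                         meta={"mnf_inverse": True})


def mnf_transform(cube: Hypercube) -> MnfResult:
    """Minimum Noise Fraction rotation.

    Whitens by the shift-difference noise covariance, then rotates onto the
    principal axes of the whitened signal covariance so components come out
    ordered by decreasing signal-to-noise eigenvalue.
    """
    rows, cols, n_bands = cube.shape
    if rows < 2 or cols < 2:
        raise ValueError("MNF needs at least 2 rows and 2 columns")
    x = cube.pixels()
    mean = x.mean(axis=0)
    xc = x - mean
    sig_cov = (xc.T @ xc) / x.shape[0]
    if np.allclose(sig_cov, 0):
        raise ValueError("constant cube: zero signal covariance")

    noise_cov = _shift_difference_noise(cube.data)
    eps = 1e-12 * max(np.trace(sig_cov) / n_bands, 1e-30)
    noise_reg = noise_cov + eps * np.eye(n_bands)
    # Generalized eigenproblem sig_cov v = lambda noise_cov v.
    eigvals, eigvecs = linalg.eigh(sig_cov, noise_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    comps = xc @ eigvecs
    inverse = linalg.inv(eigvecs)  # rows map components -> bands
    meta = {"original_wavelengths": cube.wavelengths.copy()}
    comp_cube = Hypercube(data=comps.reshape(rows, cols, n_bands),
                          wavelengths=np.arange(1.0, n_bands + 1.0), meta=meta)
    return MnfResult(cube=comp_cube, noise_cov=noise_cov,
                     eigenvalues=eigvals, _inverse=inverse, _mean=mean)


def ppi_extract(cube: Hypercube, p: int, n_skewers: int = 10_000,
                extremity_threshold: int | None = None, seed: int = 0,
                n_mnf_components: int | None = None) -> EndmemberSet:
    """Pixel Purity Index endmember extraction.

    Pixels (MNF-reduced) are projected onto random unit skewers; the extremes
    of each projection earn a purity hit. Pixels whose hit count exceeds
    ``extremity_threshold`` (default: the 99th-percentile count) form the
    candidate pool, which k-means consolidates to ``p`` endmembers; each
    cluster is represented by its purest member (highest hit count), since a
    cluster centroid is dragged inward by partially mixed candidates.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if n_skewers < 100:
        raise ValueError("n_skewers must be >= 100")
    rows, cols, n_bands = cube.shape
    n_pix = rows * cols
    if p > n_pix:
        raise ValueError("p exceeds the number of pixels")
    x = cube.pixels()

    if np.allclose(x, x[0]):  # degenerate: every pixel identical
        spectra = np.repeat(x[:1], p, axis=0)
        return EndmemberSet(spectra=spectra, wavelengths=cube.wavelengths.copy())

    k = min(n_bands, max(p + 2, 10)) if n_mnf_components is None else n_mnf_components
    k = min(k, n_bands)
    if rows >= 2 and cols >= 2 and n_bands > k:
        reduced = mnf_transform(cube).cube.pixels()[:, :k]
    else:
        reduced = x - x.mean(axis=0)

    rng = np.random.default_rng(seed)
    skewers = rng.standard_normal((reduced.shape[1], n_skewers))
    skewers /= np.linalg.norm(skewers, axis=0)
    hits = np.zeros(n_pix, dtype=np.int64)
    block = max(1, int(2e7 // n_pix))  # cap the projection buffer at ~160 MB
    for start in range(0, n_skewers, block):
        proj = reduced @ skewers[:, start:start + block]
        hits += np.bincount(np.argmax(proj, axis=0), minlength=n_pix)
        hits += np.bincount(np.argmin(proj, axis=0), minlength=n_pix)

    if extremity_threshold is None:
        extremity_threshold = np.percentile(hits, 99.0)
    candidates = np.where(hits > extremity_threshold)[0]
    if candidates.size < p:  # fall back to the top-p scorers
        candidates = np.argsort(hits)[::-1][:max(p, min(n_pix, 4 * p))]

    cand_spectra = x[candidates]
    cand_hits = hits[candidates]
    km = KMeans(n_clusters=p, n_init=10, random_state=seed & 0x7FFFFFFF)
    assign = km.fit_predict(cand_spectra)
    spectra = np.empty((p, n_bands))
    for j in range(p):
        members = np.where(assign == j)[0]
        if members.size == 0:  # empty cluster: take the globally purest leftover
            members = np.array([int(np.argmax(cand_hits))])
        spectra[j] = cand_spectra[members[int(np.argmax(cand_hits[members]))]]
    # Stable ordering: by descending mean reflectance.
    order = np.argsort(spectra.mean(axis=1))[::-1]
    return EndmemberSet(spectra=spectra[order], wavelengths=cube.wavelengths.copy())


def spectral_mse(m: np.ndarray, m_hat: np.ndarray) -> float:
    """Mean-squared error between two spectra: ``(1/n) sum (m_i - m_hat_i)^2``."""
    m = np.asarray(m, dtype=np.float64)
    m_hat = np.asarray(m_hat, dtype=np.float64)
    if m.shape != m_hat.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {m_hat.shape}")
    return float(np.mean((m - m_hat) ** 2))


def consolidate_endmembers(candidates: list[EndmemberSet],
                           mse_cutoff: float = 5e-5) -> EndmemberSet:
    """Merge redundant endmembers across extractions.

    Spectra whose pairwise MSE lies strictly inside ``(0, mse_cutoff)`` are
    linked; connected components of this graph (single linkage) are averaged.
    Group means are returned ordered by group size, largest first.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    wl = candidates[0].wavelengths
    for c in candidates[1:]:
        if not np.allclose(c.wavelengths, wl):
            raise ValueError("candidate sets must share one wavelength grid")
    allspec = np.vstack([c.spectra for c in candidates])
    n = allspec.shape[0]

    # Single-linkage = connected components of the strict-threshold MSE graph.
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            mse = spectral_mse(allspec[i], allspec[j])
            if 0.0 < mse < mse_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
            elif mse == 0.0 and i != j:
                # Identical spectra are trivially the same endmember.
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    means = np.array([allspec[g].mean(axis=0) for g in ordered])
    labels = [f"EM#{i + 1}" for i in range(len(ordered))]
    return EndmemberSet(spectra=means, wavelengths=wl.copy(), labels=labels)


def _fcls_pixel(e_aug: np.ndarray, y_aug: np.ndarray) -> np.ndarray:
    coeff, _ = nnls(e_aug, y_aug)
    s = coeff.sum()
    return coeff / s if s > 0 else coeff


def estimate_abundances(cube: Hypercube, ems: EndmemberSet,
                        constraint: str = "full") -> AbundanceStack:
    """Per-pixel least-squares mixture coefficients.

    ``constraint`` is one of ``none`` (plain least squares), ``nonneg``
    (non-negative least squares) or ``full`` (non-negative + sum-to-one; the
    classic fully constrained solution via a heavily weighted sum-to-one row,
    renormalized so the simplex constraint holds exactly).
    """
    if constraint not in ("none", "nonneg", "full"):
        raise ValueError(f"unknown constraint '{constraint}'")
    e = ems.spectra  # (P, n)
    p, n_bands = e.shape
    if p > n_bands:
        raise ValueError("more endmembers than bands")
    if np.linalg.matrix_rank(e) < p:
        raise ValueError("endmember matrix is rank-deficient")
    if cube.n_bands != n_bands:
        raise ValueError("cube and endmembers disagree on band count")

    x = cube.pixels()  # (n_pix, n_bands)
    if constraint == "none":
        coeffs, *_ = np.linalg.lstsq(e.T, x.T, rcond=None)
        maps = coeffs.T
    elif constraint == "nonneg":
        maps = np.array([nnls(e.T, y)[0] for y in x])
    else:
        delta = 1e4 / max(np.abs(e).max(), 1e-12)
        e_aug = np.vstack([e.T, delta * np.ones((1, p))])
        ones = np.array([delta])
        maps = np.array([_fcls_pixel(e_aug, np.concatenate([y, ones])) for y in x])
    return AbundanceStack(maps=maps.reshape(cube.shape[0], cube.shape[1], p),
                          endmembers=ems)


def reconstruct(ems: EndmemberSet, ab: AbundanceStack) -> Hypercube:
    """Linear mixing: pixel spectrum = sum_k abundance_k * endmember_k."""
    if ab.maps.shape[2] != len(ems):
        raise ValueError("abundance stack and endmember set sizes differ")
    rows, cols, p = ab.maps.shape
    data = ab.maps.reshape(-1, p) @ ems.spectra
    return Hypercube(data=data.reshape(rows, cols, -1),
                     wavelengths=ems.wavelengths.copy(),
                     meta={"reconstructed": True})


def rrmse(recon: Hypercube, ref: Hypercube) -> float:
    """Relative RMSE in percent: RMSE / (max(ref) - min(ref)) * 100."""
    if recon.shape != ref.shape:
        raise ValueError("cubes must share a shape")
    spread = float(ref.data.max() - ref.data.min())
    if spread == 0.0:
        raise ValueError("reference cube is constant (zero dynamic range)")
    rmse = float(np.sqrt(np.mean((recon.data - ref.data) ** 2)))
    return rmse / spread * 100.0
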