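"""Spectral distance measures (SAM, SID, Euclidean-RMS, NS3) and
similarity-driven hierarchical clustering of mean spectra.

All measures accept plain 1-D arrays or ``Spectrum`` objects. SID is computed
on the raw reflectance values with natural logarithms, the symmetric sum of
both directed divergences:

    SID(t, r) = sum_i t_i ln(t_i / r_i) + sum_i r_i ln(r_i / t_i)

which reduces to the familiar symmetrized Kullback-Leibler divergence when the
spectra are normalized to unit sum (``normalize=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Spectrum",
    "ClusterResult",
    "sam",
    "sid",
    "euclid_rms",
    "ns3",
    "pairwise_distance",
    "cluster_spectra",
    "linkage_to_newick",
]

_METRICS = {}


@dataclass
class Spectrum:
    """A reflectance vector on a wavelength grid (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
            if self.wavelengths.size != self.values.size:
                raise ValueError("values and wavelengths lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


def _vec(s) -> np.ndarray:
    v = s.values if isinstance(s, Spectrum) else np.asarray(s, dtype=np.float64)
    return np.ravel(v)


def _pair(t, r) -> tuple[np.ndarray, np.ndarray]:
    tv, rv = _vec(t), _vec(r)
    if tv.size != rv.size:
        raise ValueError(f"length mismatch: {tv.size} vs {rv.size}")
    return tv, rv


def sam(t, r) -> float:
    """Spectral angle mapper (radians in [0, pi]); invariant to positive scaling."""
    tv, rv = _pair(t, r)
    nt, nr = np.linalg.norm(tv), np.linalg.norm(rv)
    if nt == 0 or nr == 0:
        raise ValueError("SAM undefined for a zero-norm spectrum")
    c = float(np.dot(tv, rv) / (nt * nr))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def sid(t, r, normalize: bool = False) -> float:
    """Spectral information divergence: symmetric sum of directed divergences.

    Requires strictly positive values. With ``normalize=True`` each spectrum is
    first divided by its sum (the probabilistic form).
    """
    tv, rv = _pair(t, r)
    for name, v in (("t", tv), ("r", rv)):
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise ValueError(f"SID requires positive values; {name}[{bad[0]}] <= 0")
    if normalize:
        tv = tv / tv.sum()
        rv = rv / rv.sum()
    lr = np.log(tv / rv)
    return float(np.sum(tv * lr) - np.sum(rv * lr))


def euclid_rms(t, r) -> float:
    """Root-mean-square Euclidean distance: sqrt((1/n) sum (t_i - r_i)^2)."""
    tv, rv = _pair(t, r)
    return float(np.sqrt(np.mean((tv - rv) ** 2)))


def ns3(t, r) -> float:
    """Normalized spectral similarity score:
    sqrt(EuclidRMS^2 + (1 - cos(SAM))^2)."""
    e = euclid_rms(t, r)
    a = sam(t, r)
    return float(np.sqrt(e ** 2 + (1.0 - np.cos(a)) ** 2))


_METRICS.update({"sam": sam, "sid": sid, "ns3": ns3, "euclid": euclid_rms})


@dataclass
class ClusterResult:
    """Flat cluster labels plus the agglomerative merge history."""

    labels: np.ndarray
    linkage_record: np.ndarray
    metric_name: str
    distances: np.ndarray = field(repr=False, default=None)


def pairwise_distance(spectra, metric: str = "sam") -> np.ndarray:
    """Symmetric pairwise distance matrix under the named spectral measure."""
    metric = metric.lower()
    if metric not in _METRICS:
        raise ValueError(f"unknown metric '{metric}'; choose from {sorted(_METRICS)}")
    fn = _METRICS[metric]
    vecs = [_vec(s) for s in spectra]
    n = len(vecs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(vecs[i], vecs[j])
    return d


def cluster_spectra(spectra, metric: str = "ns3", k: int = 2,
                    linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of spectra under a spectral similarity measure.

    Builds the full pairwise distance matrix, runs scipy hierarchical
    clustering with the requested linkage, and cuts the tree at ``k`` flat
    clusters. Deterministic for fixed inputs.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to cluster")
    if not (1 <= k <= len(spectra)):
        raise ValueError("k must be between 1 and the number of spectra")
    d = pairwise_distance(spectra, metric=metric)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, linkage_record=z,
                         metric_name=metric.lower(), distances=d)


def linkage_to_newick(z: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = z.shape[0] + 1
    names = leaf_names or [f"S{i}" for i in range(n)]
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[2 * n - 2] + ";"
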