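"""Linear discriminant classification of seeds, confusion-matrix metrics,
cross-validation, predictor importance and OSP informative-band selection.

The LDA is the classic Gaussian equal-covariance discriminant: predictors are
z-scored on training statistics, the pooled within-class covariance is
ridge-regularized, and a sample is assigned to the class maximizing the linear
discriminant score. Per-predictor importance is the largest magnitude, over
all class pairs, of that predictor's coefficient in the pairwise discriminant
direction (the "delta" used for predictor thresholding).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureTable

__all__ = [
    "ConfusionMatrix",
    "LdaModel",
    "BandSelection",
    "split_train_test",
    "train_lda",
    "predict_lda",
    "cross_validate",
    "metrics",
    "select_bands_osp",
    "selection_frequency",
    "SubspaceLdaEnsemble",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix: rows are truth, columns predictions."""

    counts: np.ndarray
    class_names: list[str]

    @classmethod
    def from_predictions(cls, y_true, y_pred, class_names=None) -> "ConfusionMatrix":
        names = (list(class_names) if class_names is not None
                 else sorted(set(map(str, y_true)) | set(map(str, y_pred))))
        idx = {c: i for i, c in enumerate(names)}
        counts = np.zeros((len(names), len(names)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[str(t)], idx[str(p)]] += 1
        return cls(counts=counts, class_names=names)


def metrics(cm: ConfusionMatrix, average: str = "macro") -> dict[str, float]:
    """Accuracy (micro), precision/recall/F1 from a confusion matrix.

    Accuracy is (TP + TN) / total, which for a multiclass confusion matrix is
    trace / sum. With ``average="macro"`` (default) precision, recall and F1
    are one-vs-rest means over classes; ``average="binary"`` scores the first
    class as the positive class (the textbook two-class formulas
    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)). A class that is never
    predicted contributes precision 0 (with a warning).
    """
    if average not in ("macro", "binary"):
        raise ValueError("average must be 'macro' or 'binary'")
    c = np.asarray(cm.counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(c) / total
    classes = [0] if average == "binary" else range(c.shape[0])
    precisions, recalls, f1s = [], [], []
    for k in classes:
        tp = c[k, k]
        fp = c[:, k].sum() - tp
        fn = c[k, :].sum() - tp
        if tp + fp == 0:
            warnings.warn(f"class '{cm.class_names[k]}' never predicted; "
                          "precision defined as 0", stacklevel=2)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return {
        "accuracy": float(accuracy),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
    }


def split_train_test(table: FeatureTable, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split; singleton classes are forced into train."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(table.class_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = set(uniq[counts < 2])
    if singletons:
        warnings.warn(f"classes with a single seed forced into train: "
                      f"{sorted(map(str, singletons))}", stacklevel=2)
    splittable = ~np.isin(labels, list(singletons))
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx[splittable], test_size=test_fraction,
                              random_state=seed & 0x7FFFFFFF,
                              stratify=labels[splittable])
    tr = np.sort(np.concatenate([tr, idx[~splittable]]))
    te = np.sort(te)

    def subset(rows: np.ndarray) -> FeatureTable:
        return FeatureTable(frame=table.frame.iloc[rows].reset_index(drop=True),
                            predictor_names=list(table.predictor_names),
                            class_labels=labels[rows],
                            manifest=dict(table.manifest))

    return subset(tr), subset(te)


@dataclass
class LdaModel:
    """Fitted Gaussian equal-covariance discriminant."""

    class_names: list[str]
    class_means: np.ndarray  # (K, d) in standardized space
    precision: np.ndarray  # (d, d) inverse pooled covariance
    priors: np.ndarray
    mu: np.ndarray  # standardization constants
    sigma: np.ndarray
    predictor_names: list[str]
    delta_importance: np.ndarray = field(default=None)
    dropped: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "class_names": self.class_names,
            "class_means": self.class_means.tolist(),
            "precision": self.precision.tolist(),
            "priors": self.priors.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "predictor_names": self.predictor_names,
            "delta_importance": self.delta_importance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LdaModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(class_names=d["class_names"],
                   class_means=np.array(d["class_means"]),
                   precision=np.array(d["precision"]),
                   priors=np.array(d["priors"]), mu=np.array(d["mu"]),
                   sigma=np.array(d["sigma"]),
                   predictor_names=d["predictor_names"],
                   delta_importance=np.array(d["delta_importance"]))


def _design(table: FeatureTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    x = table.matrix()
    y = np.asarray([str(c) for c in table.class_labels])
    return x, y, list(table.predictor_names)


def train_lda(table: FeatureTable, regularization: float = 1e-6) -> LdaModel:
    """Fit the discriminant on a feature table.

    Zero-variance predictors are dropped with a warning. The pooled covariance
    receives a ridge of ``regularization * trace / d`` on its diagonal, which
    keeps the fit defined when predictors outnumber per-class samples.
    """
    x, y, names = _design(table)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    keep = np.nanstd(x, axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance predictors: {dropped}", stacklevel=2)
        names = [n for n, k in zip(names, keep) if k]
        x = x[:, keep]
    else:
        dropped = []
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    z = (x - mu) / sigma

    d = z.shape[1]
    k = len(classes)
    means = np.zeros((k, d))
    pooled = np.zeros((d, d))
    priors = np.zeros(k)
    for i, c in enumerate(classes):
        zc = z[y == c]
        priors[i] = zc.shape[0] / z.shape[0]
        means[i] = zc.mean(axis=0)
        dev = zc - means[i]
        pooled += dev.T @ dev
    pooled /= max(z.shape[0] - k, 1)
    pooled += regularization * (np.trace(pooled) / d) * np.eye(d)
    precision = linalg.inv(pooled)

    # Delta importance: per predictor, the largest |coefficient| of any
    # pairwise discriminant direction Sigma^-1 (mu_a - mu_b).
    importance = np.zeros(d)
    for a in range(k):
        for b in range(a + 1, k):
            coef = precision @ (means[a] - means[b])
            importance = np.maximum(importance, np.abs(coef))

    return LdaModel(class_names=classes, class_means=means, precision=precision,
                    priors=priors, mu=mu, sigma=sigma, predictor_names=names,
                    delta_importance=importance, dropped=dropped)


def predict_lda(model: LdaModel, table: FeatureTable) -> np.ndarray:
    """Class labels maximizing the linear discriminant score."""
    cols = [table.predictor_names.index(n) for n in model.predictor_names]
    x = table.matrix()[:, cols]
    z = (x - model.mu) / model.sigma
    # score_k = z Sigma^-1 mu_k - 0.5 mu_k Sigma^-1 mu_k + log prior_k
    w = model.precision @ model.class_means.T  # (d, K)
    scores = z @ w - 0.5 * np.sum(model.class_means * w.T, axis=1) \
        + np.log(model.priors)
    return np.asarray(model.class_names)[np.argmax(scores, axis=1)]


def cross_validate(table: FeatureTable, k: int = 5, seed: int = 0,
                   regularization: float = 1e-6) -> dict:
    """Stratified k-fold cross-validation of the LDA.

    Returns per-fold metric dicts plus their mean and standard deviation.
    Classes with fewer rows than ``k`` degrade the stratification with a
    warning (scikit-learn falls back as best it can).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x, y, _ = _design(table)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn("some classes have fewer rows than folds; "
                      "stratification degraded", stacklevel=2)
        k = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    folds = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in skf.split(x, y):
            sub_tr = FeatureTable(frame=table.frame.iloc[tr].reset_index(drop=True),
                                  predictor_names=list(table.predictor_names),
                                  class_labels=y[tr])
            sub_te = FeatureTable(frame=table.frame.iloc[te].reset_index(drop=True),
                                  predictor_names=list(table.predictor_names),
                                  class_labels=y[te])
            model = train_lda(sub_tr, regularization=regularization)
            pred = predict_lda(model, sub_te)
            cm = ConfusionMatrix.from_predictions(y[te], pred,
                                                  class_names=sorted(set(y)))
            folds.append(metrics(cm))
    summary = {}
    for key in folds[0]:
        vals = np.array([f[key] for f in folds])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return {"folds": folds, "summary": summary, "n_folds": k}


@dataclass
class BandSelection:
    """Greedy OSP band choice: indices in selection order + residual norms."""

    selected_indices: list[int]
    residual_norms: list[float]


def select_bands_osp(x: np.ndarray, n_bands: int, pixel_fraction: float = 0.10,
                     seed: int = 0) -> BandSelection:
    """Informative-band selection by orthogonal subspace projection.

    On a random ``pixel_fraction`` subsample of rows, greedily grow the band
    subset: start from the band of maximal variance, then repeatedly add the
    band whose residual Y = X - P_B(X) after projection onto the span of the
    selected bands has the largest norm. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:  # a cube: flatten the spatial axes
        x = x.reshape(-1, x.shape[2])
    n_pix, n_total = x.shape
    if not (1 <= n_bands <= n_total):
        raise ValueError("n_bands must be between 1 and the band count")
    rng = np.random.default_rng(seed)
    take = max(int(round(pixel_fraction * n_pix)), min(n_pix, n_total + 1))
    rows = rng.choice(n_pix, size=min(take, n_pix), replace=False)
    sub = x[rows]

    selected: list[int] = []
    norms: list[float] = []
    first = int(np.argmax(sub.var(axis=0)))
    selected.append(first)
    norms.append(float(np.linalg.norm(sub[:, first])))
    for _ in range(1, n_bands):
        basis = sub[:, selected]  # (rows, |B|)
        q, _ = np.linalg.qr(basis)
        resid = sub - q @ (q.T @ sub)
        resid_norm = np.linalg.norm(resid, axis=0)
        resid_norm[selected] = -1.0
        j = int(np.argmax(resid_norm))
        if resid_norm[j] <= 1e-10 * max(np.linalg.norm(sub), 1e-30):
            break  # data fully explained by the selected bands
        selected.append(j)
        norms.append(float(resid_norm[j]))
    return BandSelection(selected_indices=selected, residual_norms=norms)


def selection_frequency(selections: list[BandSelection], n_total: int | None = None
                        ) -> dict:
    """Per-band selection counts across accessions.

    Reports the full histogram, the bands chosen more than once, and the bands
    present in every selection.
    """
    if not selections:
        raise ValueError("no selections given")
    max_idx = max(max(s.selected_indices) for s in selections)
    n = (max_idx + 1) if n_total is None else n_total
    freq = np.zeros(n, dtype=int)
    in_all = None
    for s in selections:
        idx = set(s.selected_indices)
        for i in idx:
            freq[i] += 1
        in_all = idx if in_all is None else (in_all & idx)
    return {
        "frequency": freq,
        "bands_selected_more_than_once": np.where(freq > 1)[0].tolist(),
        "bands_in_every_selection": sorted(in_all),
    }


class SubspaceLdaEnsemble:
    """Random-subspace LDA ensemble: B discriminants on random predictor
    subsets of size d, combined by majority vote."""

    def __init__(self, n_members: int = 30, subspace_dim: int | None = None,
                 seed: int = 0, regularization: float = 1e-6):
        self.n_members = n_members
        self.subspace_dim = subspace_dim
        self.seed = seed
        self.regularization = regularization
        self.members_: list[tuple[list[str], LdaModel]] = []

    def fit(self, table: FeatureTable) -> "SubspaceLdaEnsemble":
        rng = np.random.default_rng(self.seed)
        names = list(table.predictor_names)
        d = self.subspace_dim or int(np.ceil(np.sqrt(len(names))))
        self.members_ = []
        for _ in range(self.n_members):
            chosen = sorted(rng.choice(len(names), size=min(d, len(names)),
                                       replace=False).tolist())
            sub_names = [names[i] for i in chosen]
            sub = FeatureTable(frame=table.frame, predictor_names=sub_names,
                               class_labels=table.class_labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.members_.append((sub_names, train_lda(
                    sub, regularization=self.regularization)))
        return self

    def predict(self, table: FeatureTable) -> np.ndarray:
        votes = []
        for sub_names, model in self.members_:
            sub = FeatureTable(frame=table.frame, predictor_names=sub_names,
                               class_labels=table.class_labels)
            votes.append(predict_lda(model, sub))
        votes = np.array(votes)  # (B, n)
        out = []
        for col in votes.T:
            vals, counts = np.unique(col, return_counts=True)
            out.append(vals[np.argmax(counts)])
        return np.array(out)
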