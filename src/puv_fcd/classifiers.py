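"""Gaussian discriminant base classifiers: NB, LDA, QDA and MDA.

All four model the two voxel classes w1 (lesional, positive) and w2
(non-lesional) with Gaussian class-conditional densities and differ only in
the covariance structure:

* NB  - diagonal, per-class: product of univariate Gaussians per feature.
* LDA - full, pooled across classes; linear discriminant
        g_i(x) = mu_i' S^-1 x - 1/2 mu_i' S^-1 mu_i + ln p_i.
* QDA - full, per-class. The default discriminant is the standard quadratic
        one (with the -1/2 x' S_i^-1 x and -1/2 ln|S_i| terms); a linear-only
        "printed" variant that keeps per-class covariances but drops those
        terms is available via ``variant="printed"``.
* MDA - nearest class in Mahalanobis distance under the pooled covariance;
        identical to LDA when the priors are equal.

Scores are signed (positive => lesional); exact ties resolve to the negative
class, the conservative choice for a lesion detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["KINDS", "ClassifierModel", "FeatureScaler", "fit",
           "nb_label", "lda_label", "qda_label", "mda_label",
           "predict_label", "score", "subsample_negatives"]

KINDS = ("NB", "LDA", "QDA", "MDA")
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ClassifierModel:
    """Fitted parameters of one base classifier.

    Index 0 refers to the positive class w1 (lesional), index 1 to w2.
    """

    kind: str
    means: np.ndarray                 # (2, d)
    priors: np.ndarray                # (2,)
    nb_sds: Optional[np.ndarray] = None       # (2, d), NB only
    pooled_cov: Optional[np.ndarray] = None   # (d, d), LDA/MDA
    class_covs: Optional[np.ndarray] = None   # (2, d, d), QDA
    feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        self.means = np.asarray(self.means, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.means.shape[0] != 2 or self.priors.shape != (2,):
            raise ValueError("two classes (w1, w2) are required")
        if np.any(self.priors <= 0) or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must be positive and sum to 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "means": self.means.tolist(),
            "priors": self.priors.tolist(),
            "nb_sds": None if self.nb_sds is None else self.nb_sds.tolist(),
            "pooled_cov": None if self.pooled_cov is None else self.pooled_cov.tolist(),
            "class_covs": None if self.class_covs is None else self.class_covs.tolist(),
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(kind=d["kind"], means=arr(d["means"]), priors=arr(d["priors"]),
                   nb_sds=arr(d["nb_sds"]), pooled_cov=arr(d["pooled_cov"]),
                   class_covs=arr(d["class_covs"]),
                   feature_names=tuple(d["feature_names"]))


def fit(kind: str, X: np.ndarray, y: np.ndarray,
        ridge: float = 1e-6,
        priors: Optional[Sequence[float]] = None,
        feature_names: Sequence[str] = ()) -> ClassifierModel:
    """Estimate a classifier from a labeled feature matrix.

    ``y`` holds 1 for the positive (lesional) class w1 and 0 for w2. Every
    covariance receives a ridge of ``ridge * trace(S)/d`` on the diagonal
    (``ridge=0`` keeps exact sample moments). Priors default to the class
    frequencies of the training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with matching labels")
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more samples than features (n={n}, d={d})")
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes (w1 and w2) must be present")
    var = X.var(axis=0)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        names = feature_names or [f"feature_{i}" for i in range(d)]
        raise ValueError(f"zero-variance feature: {names[dead[0]]}")

    means = np.stack([pos.mean(axis=0), neg.mean(axis=0)])
    if priors is None:
        priors = np.array([len(pos) / n, len(neg) / n])
    else:
        priors = np.asarray(priors, dtype=float)

    def _ridged(cov):
        eps = ridge * np.trace(cov) / d
        return cov + eps * np.eye(d)

    model = ClassifierModel(kind=kind, means=means, priors=priors,
                            feature_names=tuple(feature_names))
    if kind == "NB":
        sds = np.stack([pos.std(axis=0, ddof=1), neg.std(axis=0, ddof=1)])
        if np.any(sds <= 0):
            names = feature_names or [f"feature_{i}" for i in range(d)]
            bad = int(np.argwhere(sds <= 0)[0][1])
            raise ValueError(f"zero-variance feature: {names[bad]}")
        model.nb_sds = sds
    elif kind in ("LDA", "MDA"):
        s1 = np.cov(pos, rowvar=False, ddof=1).reshape(d, d)
        s2 = np.cov(neg, rowvar=False, ddof=1).reshape(d, d)
        pooled = ((len(pos) - 1) * s1 + (len(neg) - 1) * s2) / (n - 2)
        model.pooled_cov = _ridged(pooled)
    elif kind == "QDA":
        covs = [np.cov(c, rowvar=False, ddof=1).reshape(d, d) for c in (pos, neg)]
        model.class_covs = np.stack([_ridged(c) for c in covs])
    return model


def _solve(cov: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(cov, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc


def _check(model: ClassifierModel, kind: str, X: np.ndarray) -> np.ndarray:
    if model.kind != kind:
        raise ValueError(f"expected a {kind} model, got {model.kind}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension mismatch")
    return X


def nb_score(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Log posterior ratio ln p(w1|x) - ln p(w2|x) under the NB model."""
    X = _check(model, "NB", X)
    ll = []
    for i in range(2):
        mu, sd = model.means[i], model.nb_sds[i]
        z = (X - mu) / sd
        ll.append(-0.5 * (z * z + _LOG_2PI).sum(axis=1)
                  - np.log(sd).sum() + np.log(model.priors[i]))
    return ll[0] - ll[1]


def _lda_g(model: ClassifierModel, X: np.ndarray, i: int) -> np.ndarray:
    w = _solve(model.pooled_cov, model.means[i])
    return X @ w - 0.5 * model.means[i] @ w + np.log(model.priors[i])


def lda_score(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    X = _check(model, "LDA", X)
    return _lda_g(model, X, 0) - _lda_g(model, X, 1)


def qda_score(model: ClassifierModel, X: np.ndarray,
              variant: str = "full") -> np.ndarray:
    """QDA discriminant difference g1 - g2.

    ``variant="full"`` is the standard quadratic discriminant;
    ``variant="printed"`` keeps per-class covariances but only the linear
    terms mu_i' S_i^-1 x - 1/2 mu_i' S_i^-1 mu_i + ln p_i.
    """
    X = _check(model, "QDA", X)
    if variant not in ("full", "printed"):
        raise ValueError(f"unknown qda variant {variant!r}")
    g = []
    for i in range(2):
        cov, mu = model.class_covs[i], model.means[i]
        if variant == "printed":
            w = _solve(cov, mu)
            g.append(X @ w - 0.5 * mu @ w + np.log(model.priors[i]))
        else:
            diff = X - mu
            sol = _solve(cov, diff.T).T
            maha = (diff * sol).sum(axis=1)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ValueError("singular covariance matrix")
            g.append(-0.5 * (maha + logdet) + np.log(model.priors[i]))
    return g[0] - g[1]


def mahalanobis_sq(model: ClassifierModel, X: np.ndarray, i: int) -> np.ndarray:
    diff = X - model.means[i]
    sol = _solve(model.pooled_cov, diff.T).T
    return (diff * sol).sum(axis=1)


def mda_score(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """D(w2, x) - D(w1, x): positive when x is closer to the lesional class."""
    X = _check(model, "MDA", X)
    return mahalanobis_sq(model, X, 1) - mahalanobis_sq(model, X, 0)


def _labels(scores: np.ndarray) -> np.ndarray:
    # ties (score exactly 0) resolve to the negative class
    return (scores > 0).astype(np.uint8)


def nb_label(model, X):
    return _labels(nb_score(model, X))


def lda_label(model, X):
    return _labels(lda_score(model, X))


def qda_label(model, X, variant: str = "full"):
    return _labels(qda_score(model, X, variant))


def mda_label(model, X):
    return _labels(mda_score(model, X))


def score(model: ClassifierModel, X: np.ndarray,
          qda_variant: str = "full") -> np.ndarray:
    if model.kind == "NB":
        return nb_score(model, X)
    if model.kind == "LDA":
        return lda_score(model, X)
    if model.kind == "QDA":
        return qda_score(model, X, qda_variant)
    return mda_score(model, X)


def predict_label(model: ClassifierModel, X: np.ndarray,
                  qda_variant: str = "full") -> np.ndarray:
    return _labels(score(model, X, qda_variant))


def subsample_negatives(X: np.ndarray, y: np.ndarray,
                        rng: np.random.Generator,
                        neg_per_pos: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Cap the negative class at ``neg_per_pos`` times the positive count.

    Voxelwise training sets are hugely imbalanced (lesions are a tiny fraction
    of the cortex); subsampling keeps covariance estimation conditioned and
    training fast. A no-op when the cap is not exceeded.
    """
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    cap = neg_per_pos * len(pos_idx)
    if len(neg_idx) <= cap or len(pos_idx) == 0:
        return X, y
    keep = rng.choice(neg_idx, size=cap, replace=False)
    sel = np.sort(np.concatenate([pos_idx, keep]))
    return X[sel], y[sel]


@dataclass
class FeatureScaler:
    """Per-feature z-scoring using training-set statistics.

    Label decisions of all four classifiers are affine-covariant, so scaling
    only improves numerical conditioning.
    """

    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd
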