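"""Positive unanimous voting: the intersection of classifier positives.

A voxel is labeled lesional only when every base classifier labels it
lesional. The combined positive set is therefore contained in each single
classifier's positive set, which bounds the false-positive count of the
ensemble by the smallest false-positive count of its members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import classifiers as clf

__all__ = ["LabelVolume", "puv_combine", "puv_decision"]


@dataclass
class LabelVolume:
    """A binary 3D label grid from one classifier (or the PUV ensemble)."""

    labels: np.ndarray
    classifier_id: str
    domain_mask: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        labels = labels.astype(np.uint8)
        if self.domain_mask.shape != labels.shape:
            raise ValueError("domain mask grid mismatch")
        if labels[~self.domain_mask].any():
            raise ValueError("positive labels outside the domain mask")
        self.labels = labels

    @property
    def positive_count(self) -> int:
        return int(self.labels.sum())


def puv_combine(label_volumes: Sequence[LabelVolume]) -> LabelVolume:
    """Voxelwise product of binary label volumes (set intersection of positives)."""
    if len(label_volumes) < 1:
        raise ValueError("need at least one label volume")
    first = label_volumes[0]
    out = first.labels.copy()
    for lv in label_volumes[1:]:
        if lv.labels.shape != first.labels.shape:
            raise ValueError("label volume grid mismatch")
        if lv.domain_mask.shape != first.domain_mask.shape or \
                not np.array_equal(lv.domain_mask, first.domain_mask):
            raise ValueError("label volume domain mask mismatch")
        out &= lv.labels
    return LabelVolume(labels=out, classifier_id="PUV",
                       domain_mask=first.domain_mask)


def puv_decision(models: Mapping[str, clf.ClassifierModel],
                 X: np.ndarray, qda_variant: str = "full") -> np.ndarray:
    """Closed-form PUV decision on feature vectors.

    Evaluates the four decision indicators directly - the NB posterior ratio
    p(w1|x)/p(w2|x) > 1, the LDA and QDA discriminant differences g1 - g2 > 0,
    and the Mahalanobis distance ratio D(w2,x)/D(w1,x) > 1 - and returns 1
    only where all four are positive. Ratios of strictly positive quantities
    are treated as indicators (not signs), which makes the product form agree
    bitwise with combining the four single-classifier labels.
    """
    if set(models) != set(clf.KINDS):
        raise ValueError(f"need exactly one model per kind {clf.KINDS}")
    for kind, m in models.items():
        if m.kind != kind:
            raise ValueError(f"model registered under {kind} has kind {m.kind}")
    X = np.atleast_2d(np.asarray(X, dtype=float))

    nb = models["NB"]
    # log posterior-ratio via the per-feature factor product of Gaussian densities
    log_ratio = np.log(nb.priors[0] / nb.priors[1]) * np.ones(X.shape[0])
    for f in range(nb.n_features):
        s1, s2 = nb.nb_sds[0, f], nb.nb_sds[1, f]
        m1, m2 = nb.means[0, f], nb.means[1, f]
        log_ratio += (np.log(s2 / s1)
                      + (X[:, f] - m2) ** 2 / (2 * s2 ** 2)
                      - (X[:, f] - m1) ** 2 / (2 * s1 ** 2))
    vote_nb = log_ratio > 0

    lda = models["LDA"]
    w = np.linalg.solve(lda.pooled_cov, (lda.means[0] - lda.means[1]))
    quad = 0.5 * (lda.means[0] @ np.linalg.solve(lda.pooled_cov, lda.means[0])
                  - lda.means[1] @ np.linalg.solve(lda.pooled_cov, lda.means[1]))
    vote_lda = (X @ w - quad + np.log(lda.priors[0] / lda.priors[1])) > 0

    vote_qda = clf.qda_score(models["QDA"], X, qda_variant) > 0

    mda = models["MDA"]
    d1 = clf.mahalanobis_sq(mda, X, 0)
    d2 = clf.mahalanobis_sq(mda, X, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d1 > 0, d2 / d1, np.where(d2 > 0, np.inf, 1.0))
    vote_mda = ratio > 1

    return (vote_nb & vote_lda & vote_qda & vote_mda).astype(np.uint8)
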