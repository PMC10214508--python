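"""Shapley-value feature attribution and global feature ranking.

Attributions are interventional Shapley values of the model's score: the
value of a feature coalition is the expected score when coalition features
take the explained subject's values and all other features are drawn from a
background sample (here, the training fold). Two estimators are provided:

* ``exact`` -- exhaustive enumeration of all 2^p coalitions, tractable for
  p <= ~14. This is the reference implementation: it satisfies the Shapley
  axioms (local accuracy, symmetry, null player) to machine precision and
  serves as the oracle for the sampled estimator.
* ``sampled`` -- permutation sampling. For each random feature ordering the
  features are switched one by one from a background draw to the subject's
  value, and each feature is credited with its marginal score change. The
  estimate is the average over orderings and background draws; it is
  unbiased, and each permutation is *exactly* locally accurate (the credits
  telescope to ``f(x) - f(background draw)``), so additivity holds for the
  averaged estimate as well.

The sampling budget counts model-evaluated coalitions per explained subject:
one permutation costs ``p + 1`` evaluations (per background draw), so the
number of permutations is ``max(1, budget // (p + 1))``. Estimator noise is
driven down both by the per-subject budget and, for global rankings, by
averaging |attributions| over all test subjects of all bootstrap iterations.

A feature's global importance ("SHAP score") is the mean of absolute
attributions over all bootstraps and subjects; its regulation direction is
the sign of the abundance-label Pearson correlation (positive = higher in
the disease class).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .feature_tables import CohortLabels, FeatureTable

__all__ = [
    "AttributionMatrix",
    "FeatureRanking",
    "shapley_attributions",
    "aggregate_shap",
    "regulation_direction",
    "rank_features",
]

#: Largest p for which the exact estimator is selected automatically.
EXACT_MAX_FEATURES = 12


@dataclass
class AttributionMatrix:
    """Per-subject, per-feature Shapley attributions for one model.

    ``base_value`` is the mean model score over the background draws used;
    for every row, ``base_value + row.sum()`` equals the model's score for
    that subject (exactly for both estimators, by construction).
    """

    values: np.ndarray  # (n_subjects, n_features)
    base_value: float
    feature_ids: list[str] | None = None


def _as_predict_fn(model, background, instances):
    """Resolve (predict, background, instances) in one feature space.

    For a TrainedModel the preprocessing is feature-wise (median imputation
    plus affine standardization), so coordinate masking commutes with it:
    background and instances are transformed once up front and the estimator
    is called directly on masked standardized rows, which yields identical
    attributions at a fraction of the cost.
    """
    if callable(model) and not hasattr(model, "predict_scores"):
        return model, background, instances
    prep = model.preprocessor
    est = model.estimator
    from sklearn.svm import SVC

    if isinstance(est, SVC):
        def predict(Z):
            return 1.0 / (1.0 + np.exp(-est.decision_function(Z)))
    else:
        positive = list(est.classes_).index(1)

        def predict(Z):
            return est.predict_proba(Z)[:, positive]

    return predict, prep.transform(background), prep.transform(instances)


def shapley_attributions(
    model,
    background: np.ndarray,
    instances: np.ndarray,
    budget: int = 128,
    method: str = "auto",
    seed: int = 0,
    background_size: int | None = None,
    feature_ids: list[str] | None = None,
) -> AttributionMatrix:
    """Attribute each instance's score to its features.

    Parameters
    ----------
    model
        A :class:`~crankms.models.TrainedModel` or any callable mapping a
        2-D feature matrix to a score vector.
    background
        Reference sample (training fold) supplying out-of-coalition values.
    instances
        Rows to explain (test fold), in the same feature space.
    budget
        Model-evaluated coalitions per instance for the sampled estimator.
    method
        ``"exact"``, ``"sampled"``, or ``"auto"`` (exact iff
        p <= ``EXACT_MAX_FEATURES``).
    background_size
        If set, the background is subsampled (seeded) to this many rows.
    """
    background = np.asarray(background, dtype=float)
    instances = np.asarray(instances, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D matrix")
    if instances.ndim != 2 or instances.shape[1] != background.shape[1]:
        raise ValueError("instances and background must share the feature space")
    predict, background, instances = _as_predict_fn(model, background, instances)
    rng = np.random.default_rng(seed)
    if background_size is not None and background.shape[0] > background_size:
        keep = rng.choice(background.shape[0], size=background_size, replace=False)
        background = background[keep]
    p = instances.shape[1]
    if method == "auto":
        method = "exact" if p <= EXACT_MAX_FEATURES else "sampled"
    if method == "exact":
        values, base = _exact(predict, background, instances)
    elif method == "sampled":
        n_perms = max(1, budget // (p + 1))
        values, base = _sampled(predict, background, instances, n_perms, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AttributionMatrix(values, base, feature_ids)


def _exact(predict, background, instances) -> tuple[np.ndarray, float]:
    """Exhaustive-subset Shapley values with full background averaging."""
    n, p = instances.shape
    b = background.shape[0]
    n_masks = 1 << p
    # coalition values v[i, mask] = mean over background of the masked score
    v = np.empty((n, n_masks))
    chunk = max(1, 65536 // max(1, n * b))
    for start in range(0, n_masks, chunk):
        masks = np.arange(start, min(start + chunk, n_masks))
        bits = (masks[:, None] >> np.arange(p)[None, :]) & 1  # (m, p)
        # rows: mask-major, then instance, then background draw
        X = np.where(
            bits[:, None, None, :].astype(bool),
            instances[None, :, None, :],
            background[None, None, :, :],
        ).reshape(-1, p)
        scores = np.asarray(predict(X)).reshape(len(masks), n, b)
        v[:, masks] = scores.mean(axis=2).T
    weights = np.array(
        [1.0 / (comb(p - 1, s) * p) for s in range(p)]
    )  # s!(p-1-s)!/p! indexed by |S|
    popcount = np.array([bin(m).count("1") for m in range(n_masks)])
    phi = np.zeros((n, p))
    for j in range(p):
        bit = 1 << j
        without = np.flatnonzero((np.arange(n_masks) & bit) == 0)
        w = weights[popcount[without]]
        phi[:, j] = ((v[:, without | bit] - v[:, without]) * w[None, :]).sum(axis=1)
    return phi, float(v[0, 0]) if n else float("nan")


def _sampled(predict, background, instances, n_perms, rng) -> tuple[np.ndarray, float]:
    """Permutation-sampling estimator; exactly locally accurate on average."""
    n, p = instances.shape
    b = background.shape[0]
    phi = np.zeros((n, p))
    # explained units = (instance, background draw) pairs; chunked so the
    # (units, p+1, p) step tensor stays below ~200 MB
    inst_rep = np.repeat(np.arange(n), b)
    bg_rep = np.tile(np.arange(b), n)
    chunk = max(1, int(2.5e7 // ((p + 1) * p)))
    for _ in range(n_perms):
        perm = rng.permutation(p)
        rank = np.empty(p, dtype=int)
        rank[perm] = np.arange(p)
        cummask = rank[None, :] < np.arange(p + 1)[:, None]  # (p+1, p)
        acc = np.zeros((n, p))  # permutation-order credits per instance
        for start in range(0, n * b, chunk):
            sl = slice(start, min(start + chunk, n * b))
            X_steps = np.where(
                cummask[None, :, :],
                instances[inst_rep[sl], None, :],
                background[bg_rep[sl], None, :],
            )
            preds = np.asarray(predict(X_steps.reshape(-1, p))).reshape(-1, p + 1)
            diffs = np.diff(preds, axis=1)  # column s credits feature perm[s]
            np.add.at(acc, inst_rep[sl], diffs)
        phi[:, perm] += acc
    phi /= n_perms * b
    base = float(np.asarray(predict(background)).mean())
    return phi, base


def aggregate_shap(matrices, mode: str = "mean_abs") -> np.ndarray:
    """Collapse per-bootstrap attribution matrices to one score per feature.

    ``mean_abs`` (default) averages |attribution| over every subject of every
    bootstrap; ``abs_mean`` takes |average attribution| instead (exposed for
    comparison; it cancels opposing effects and is not the default).
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no attribution matrices given")
    ref_ids = matrices[0].feature_ids
    p = matrices[0].values.shape[1]
    for m in matrices[1:]:
        if m.values.shape[1] != p or m.feature_ids != ref_ids:
            raise ValueError("attribution matrices disagree on the feature set")
    stacked = np.vstack([m.values for m in matrices])
    if mode == "mean_abs":
        return np.abs(stacked).mean(axis=0)
    if mode == "abs_mean":
        return np.abs(stacked.mean(axis=0))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def regulation_direction(table: FeatureTable, labels: CohortLabels) -> list[str]:
    """Per-feature "up"/"down"/"none" from the abundance-label correlation.

    "up" means higher abundance in the positive (disease) class. Features
    with zero variance (or fewer than two observed values) get "none".
    Missing cells are ignored pairwise.
    """
    y = labels.aligned_to(table.subject_ids).y.astype(float)
    X = table.values
    out = []
    for j in range(X.shape[1]):
        x = X[:, j]
        ok = ~np.isnan(x)
        xj, yj = x[ok], y[ok]
        if len(xj) < 2 or np.std(xj) == 0 or np.std(yj) == 0:
            out.append("none")
            continue
        r = np.corrcoef(xj, yj)[0, 1]
        out.append("up" if r > 0 else "down" if r < 0 else "none")
    return out


@dataclass
class FeatureRanking:
    """Full descending-importance ranking with regulation directions."""

    feature_ids: list[str]
    scores: np.ndarray  # aggregated SHAP score, input order
    ranks: np.ndarray  # 1 = most important, input order
    directions: list[str]
    top_k: int

    def top(self) -> list[tuple[str, float, int, str]]:
        order = np.argsort(self.ranks)
        k = min(self.top_k, len(self.feature_ids))
        return [
            (self.feature_ids[i], float(self.scores[i]), int(self.ranks[i]), self.directions[i])
            for i in order[:k]
        ]

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.ranks)
        return pd.DataFrame(
            {
                "feature_id": [self.feature_ids[i] for i in order],
                "shap_score": self.scores[order],
                "rank": self.ranks[order],
                "direction": [self.directions[i] for i in order],
            }
        )


def rank_features(
    feature_ids: list[str],
    scores: np.ndarray,
    directions: list[str],
    top_k: int = 10,
) -> FeatureRanking:
    """Rank features by descending score; ties go to the lower feature index."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) != len(feature_ids) or len(directions) != len(scores):
        raise ValueError("scores, feature_ids and directions must align")
    if (scores < 0).any():
        raise ValueError("aggregated SHAP scores must be non-negative")
    order = np.argsort(-scores, kind="stable")  # stable: ties keep input order
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return FeatureRanking(list(feature_ids), scores, ranks, list(directions), top_k)
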