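"""Bootstrap evaluation engine, MCC-maximizing grid search, permutation control.

The evaluation protocol is Monte-Carlo cross-validation: the cohort is split
``n_iterations`` times (default 100) into a random 60% training / 40% test
partition *without replacement*. Each iteration fits preprocessing and the
classifier on the training fold only, scores the held-out fold, and records
a confusion matrix and the full metric vector; metrics are then aggregated
to mean +- one sample SD across iterations. The whole feature table goes in
as-is -- no feature preselection.

Hyperparameter search runs the identical split sequence for every candidate
(variance reduction for a fair comparison) and selects the candidate with
the highest mean MCC, first-enumerated winning ties.

The label-permutation control re-runs the full protocol after shuffling the
cohort labels once per replicate; on any dataset this should collapse mean
accuracy to chance (0.5 for balanced cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feature_tables import CohortLabels, FeatureTable
from .metrics import (
    ConfusionMatrix,
    Curve,
    MetricSummary,
    MetricVector,
    aggregate,
    confusion,
    metric_vector,
    pr_curve_auc,
    roc_curve_auc,
)
from .models import HyperparameterGrid, ModelSpec, TrainedModel, enumerate_grid, train

__all__ = [
    "BootstrapPlan",
    "IterationRecord",
    "BootstrapResult",
    "make_splits",
    "run_evaluation",
    "grid_search",
    "permutation_control",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapPlan:
    """Split protocol: ``n_iterations`` random train/test partitions with
    ``floor(train_fraction * n)`` training subjects drawn without replacement."""

    n_iterations: int = 100
    train_fraction: float = 0.6
    stratified: bool = False
    seed: int = 0

    def validate(self, n: int) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        n_train = int(self.train_fraction * n)
        if n < 5 or n_train < 2 or n - n_train < 2:
            raise ValueError(
                f"cohort of {n} subjects leaves train={n_train}, "
                f"test={n - n_train}; need at least 2 in each fold"
            )


@dataclass
class IterationRecord:
    train_idx: np.ndarray
    test_idx: np.ndarray
    cm: ConfusionMatrix
    metrics: MetricVector
    roc: Curve | None = None
    pr: Curve | None = None
    scores: np.ndarray | None = None


@dataclass
class BootstrapResult:
    spec: ModelSpec
    plan: BootstrapPlan
    iterations: list[IterationRecord]
    summary: MetricSummary
    attributions: list | None = None  # AttributionMatrix per iteration
    manifest: dict = field(default_factory=dict)

    def metric_rows(self) -> list[MetricVector]:
        return [it.metrics for it in self.iterations]


def make_splits(
    n: int,
    plan: BootstrapPlan,
    labels: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic list of (train, test) index pairs under ``plan.seed``.

    Stratified splits preserve per-class proportions within rounding and
    require ``labels``.
    """
    plan.validate(n)
    rng = np.random.default_rng(plan.seed)
    n_train = int(plan.train_fraction * n)
    splits = []
    if plan.stratified:
        if labels is None:
            raise ValueError("stratified splits require labels")
        labels = np.asarray(labels)
        class_idx = [np.flatnonzero(labels == c) for c in (0, 1)]
        # per-class train counts: floor, then top up from the larger remainder
        counts = [int(plan.train_fraction * len(ci)) for ci in class_idx]
        while sum(counts) < n_train:
            remainders = [
                plan.train_fraction * len(ci) - c for ci, c in zip(class_idx, counts)
            ]
            counts[int(np.argmax(remainders))] += 1
        for _ in range(plan.n_iterations):
            train = np.concatenate(
                [rng.choice(ci, size=c, replace=False) for ci, c in zip(class_idx, counts)]
            )
            train = np.sort(train)
            mask = np.zeros(n, dtype=bool)
            mask[train] = True
            splits.append((train, np.flatnonzero(~mask)))
    else:
        for _ in range(plan.n_iterations):
            perm = rng.permutation(n)
            splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def _data_arrays(table: FeatureTable, labels: CohortLabels) -> tuple[np.ndarray, np.ndarray]:
    if set(table.subject_ids) != set(labels.subject_ids):
        raise ValueError("table and labels must cover identical subjects")
    y = labels.aligned_to(table.subject_ids).y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return table.values, y


def run_evaluation(
    table: FeatureTable,
    labels: CohortLabels,
    spec: ModelSpec,
    plan: BootstrapPlan | None = None,
    compute_attributions: bool = False,
    attribution_budget: int = 128,
    background_size: int | None = 8,
    store_curves: bool = False,
    store_scores: bool = False,
) -> BootstrapResult:
    """Run the full bootstrap protocol for one model spec.

    When ``compute_attributions`` is set, Shapley attributions are computed
    on each iteration's test fold with that iteration's training fold as the
    background distribution (subsampled to ``background_size`` rows).
    """
    if plan is None:
        plan = BootstrapPlan()
    X, y = _data_arrays(table, labels)
    splits = make_splits(len(y), plan, labels=y)
    seed_seq = np.random.SeedSequence(plan.seed)
    attr_seeds = seed_seq.generate_state(plan.n_iterations) % (2**31)

    if compute_attributions:
        from .interpretation import shapley_attributions

    records: list[IterationRecord] = []
    attributions = [] if compute_attributions else None
    for it, (train_idx, test_idx) in enumerate(splits):
        model = train(spec, X[train_idx], y[train_idx])
        scores = model.predict_scores(X[test_idx])
        y_test = y[test_idx]
        cm = confusion(y_test, scores)
        mv = metric_vector(cm)
        roc = pr = None
        if len(np.unique(y_test)) == 2:
            roc, mv.auc_roc = roc_curve_auc(y_test, scores)
            pr, mv.auc_pr = pr_curve_auc(y_test, scores)
        else:
            logger.warning("iteration %d: single-class test fold; AUCs undefined", it)
        if compute_attributions:
            attributions.append(
                shapley_attributions(
                    model,
                    background=X[train_idx],
                    instances=X[test_idx],
                    budget=attribution_budget,
                    seed=int(attr_seeds[it]),
                    background_size=background_size,
                    feature_ids=table.feature_ids,
                )
            )
        records.append(
            IterationRecord(
                train_idx,
                test_idx,
                cm,
                mv,
                roc=roc if store_curves else None,
                pr=pr if store_curves else None,
                scores=scores if store_scores else None,
            )
        )
    summary = aggregate([r.metrics for r in records])
    manifest = {
        "spec": spec.to_json(),
        "plan": {
            "n_iterations": plan.n_iterations,
            "train_fraction": plan.train_fraction,
            "stratified": plan.stratified,
            "seed": plan.seed,
        },
        "n_subjects": len(y),
        "n_features": X.shape[1],
    }
    return BootstrapResult(spec, plan, records, summary, attributions, manifest)


def grid_search(
    table: FeatureTable,
    labels: CohortLabels,
    grid: HyperparameterGrid,
    plan: BootstrapPlan | None = None,
) -> tuple[ModelSpec, list[MetricSummary]]:
    """Exhaustive search; every candidate sees the identical split sequence.

    Returns the spec with the highest mean MCC (ties: first enumerated) and
    the per-candidate summaries in enumeration order.
    """
    specs = enumerate_grid(grid)
    if not specs:
        raise ValueError("empty grid")
    if plan is None:
        plan = BootstrapPlan()
    summaries = []
    best_i, best_mcc = 0, -np.inf
    for i, spec in enumerate(specs):
        summary = run_evaluation(table, labels, spec, plan).summary
        summaries.append(summary)
        mcc = summary.mean["mcc"]
        if mcc > best_mcc:
            best_i, best_mcc = i, mcc
    return specs[best_i], summaries


def permutation_control(
    table: FeatureTable,
    labels: CohortLabels,
    spec: ModelSpec,
    plan: BootstrapPlan | None = None,
    n_permutations: int = 1,
    seed: int = 0,
    permutations: list[np.ndarray] | None = None,
) -> list[MetricSummary]:
    """Label-permutation null: shuffle labels once per replicate, re-run the
    full bootstrap evaluation, and return each replicate's summary.

    ``permutations`` may inject explicit label orderings (e.g. the identity,
    to verify the control reproduces the unpermuted run).
    """
    if plan is None:
        plan = BootstrapPlan()
    y = labels.aligned_to(table.subject_ids).y
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(len(y)) for _ in range(n_permutations)]
    out = []
    for perm in permutations:
        permuted = CohortLabels(table.subject_ids, y[np.asarray(perm)])
        out.append(run_evaluation(table, labels=permuted, spec=spec, plan=plan).summary)
    return out
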