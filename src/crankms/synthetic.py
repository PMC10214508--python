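"""Synthetic untargeted-metabolomics cohorts with known planted biomarkers.

Real plasma/sebum feature tables in this problem regime have a few dozen to a
few hundred subjects, tens to thousands of features, log-normally distributed
abundances spanning decades, blocks of strongly correlated features (isotopes,
adducts, co-regulated metabolites), and sporadic missing cells. The generator
reproduces those shapes with a simple latent-factor model on the log scale:

    log x_ij = mu_j + delta_j * y_i + sigma * (sqrt(rho) * g_{i,b(j)}
                                               + sqrt(1 - rho) * eps_ij)

where ``mu_j`` is a per-feature baseline drawn once, ``g_{i,b}`` is a shared
standard-normal factor per subject and feature block (giving a within-block
log-abundance correlation of ``rho``), ``eps_ij`` is independent noise, and
``delta_j = +-log(effect_fold)`` for the planted informative features (zero
otherwise), with signs alternating so both up- and down-regulated markers
exist. Labels ``y_i`` are 0/1 with a configurable class balance. Missing
cells are placed uniformly at random.

Because the planted feature set and directions are recorded, every
downstream stage (classification, attribution, ranking, direction calls) can
be scored against ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .feature_tables import (
    CohortLabels,
    FeatureTable,
    read_feature_table,
    write_feature_table,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_dataset",
    "generate_xor_dataset",
    "write_fixture",
    "read_fixture",
]

#: Default block width when ``block_sizes`` is not given: features are grouped
#: into clusters of 50, emulating co-eluting / co-regulated metabolite groups.
DEFAULT_BLOCK_WIDTH = 50

#: Baseline log-abundance location and spread (natural log of arbitrary
#: instrument counts; exp(7) ~ 1100).
BASELINE_LOG_MEAN = 7.0
BASELINE_LOG_SD = 1.5


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a small plasma case/control study: 72 subjects, 500
    features of which 10 are informative with a two-fold abundance shift,
    within-block correlation 0.3 and unit log-scale noise.
    """

    n_subjects: int = 72
    n_features: int = 500
    n_informative: int = 10
    effect_fold: float = 2.0
    class_balance: float = 0.5
    block_sizes: list[int] | None = None
    correlation_rho: float = 0.3
    noise_sigma: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.correlation_rho < 1:
            raise ValueError("correlation_rho must lie in [0, 1)")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.block_sizes is not None:
            if any(b < 1 for b in self.block_sizes):
                raise ValueError("block sizes must be positive")
            if sum(self.block_sizes) != self.n_features:
                raise ValueError("block_sizes must sum to n_features")


@dataclass
class SyntheticDataset:
    """A generated cohort plus its planted ground truth."""

    table: FeatureTable
    labels: CohortLabels
    truth: list[str]
    truth_direction: dict[str, str]
    spec: SyntheticSpec | None = None


def _block_assignment(spec: SyntheticSpec) -> np.ndarray:
    sizes = spec.block_sizes
    if sizes is None:
        width = min(DEFAULT_BLOCK_WIDTH, spec.n_features)
        n_blocks = -(-spec.n_features // width)
        return np.repeat(np.arange(n_blocks), width)[: spec.n_features]
    return np.repeat(np.arange(len(sizes)), sizes)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one cohort from ``spec``; bit-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_subjects, spec.n_features, spec.n_informative

    n_pos = int(round(spec.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)  # keep both classes represented
    y = np.zeros(n, dtype=np.int64)
    y[rng.choice(n, size=n_pos, replace=False)] = 1

    # feature IDs look like measured m/z values, unique to 4 decimals
    mz = np.sort(rng.uniform(60.0, 1000.0, size=p))
    while len({f"{v:.4f}" for v in mz}) < p:  # pragma: no cover - astronomically rare
        mz = np.sort(rng.uniform(60.0, 1000.0, size=p))
    feature_ids = [f"{v:.4f}" for v in mz]

    mu = rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=p)
    delta = np.zeros(p)
    planted = np.sort(rng.choice(p, size=k, replace=False))
    directions: dict[str, str] = {}
    for rank, j in enumerate(planted):
        sign = 1.0 if rank % 2 == 0 else -1.0  # alternate up / down
        delta[j] = sign * np.log(spec.effect_fold)
        directions[feature_ids[j]] = "up" if sign > 0 else "down"

    block = _block_assignment(spec)
    g = rng.standard_normal((n, block.max() + 1))
    eps = rng.standard_normal((n, p))
    rho = spec.correlation_rho
    noise = spec.noise_sigma * (np.sqrt(rho) * g[:, block] + np.sqrt(1 - rho) * eps)
    log_x = mu[None, :] + np.outer(y, delta) + noise
    values = np.exp(log_x)

    if spec.missing_rate > 0:
        values[rng.random((n, p)) < spec.missing_rate] = np.nan

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    table = FeatureTable(subject_ids, feature_ids, values)
    labels = CohortLabels(subject_ids, y)
    return SyntheticDataset(table, labels, [feature_ids[j] for j in planted], directions, spec)


def generate_xor_dataset(
    n_subjects: int = 160,
    n_noise: int = 8,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """Cohort whose label is a pure two-feature interaction (XOR-style).

    Two latent log-abundances are drawn standard normal and the label is 1
    iff their signs agree, so no single feature carries marginal signal and
    no linear decision boundary can separate the classes. The remaining
    ``n_noise`` features are uninformative. Used to probe whether a
    classifier can exploit nonlinear structure.
    """
    rng = np.random.default_rng(seed)
    n = n_subjects
    z = rng.standard_normal((n, 2))
    y = (z[:, 0] * z[:, 1] > 0).astype(np.int64)
    noise = rng.standard_normal((n, n_noise))
    log_x = np.hstack([z + noise_sigma * rng.standard_normal((n, 2)), noise])
    values = np.exp(BASELINE_LOG_MEAN + log_x)
    p = 2 + n_noise
    feature_ids = [f"x{j + 1}" for j in range(p)]
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    table = FeatureTable(subject_ids, feature_ids, values)
    labels = CohortLabels(subject_ids, y)
    return SyntheticDataset(table, labels, ["x1", "x2"], {"x1": "none", "x2": "none"})


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Persist a dataset as table.csv / labels.csv / truth.json (+ spec.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": directory / "table.csv",
        "labels": directory / "labels.csv",
        "truth": directory / "truth.json",
    }
    write_feature_table(dataset.table, paths["table"], format="csv")
    labels_frame = {
        "subject": dataset.labels.subject_ids,
        "label": dataset.labels.y.tolist(),
    }
    import pandas as pd

    pd.DataFrame(labels_frame).to_csv(paths["labels"], index=False)
    paths["truth"].write_text(
        json.dumps(
            {"truth": dataset.truth, "direction": dataset.truth_direction},
            indent=2,
        )
    )
    if dataset.spec is not None:
        paths["spec"] = directory / "spec.json"
        paths["spec"].write_text(json.dumps(asdict(dataset.spec), indent=2))
    return paths


def read_fixture(directory: str | Path) -> SyntheticDataset:
    """Inverse of :func:`write_fixture`."""
    import pandas as pd

    directory = Path(directory)
    table, _ = read_feature_table(directory / "table.csv", format="csv")
    labels_frame = pd.read_csv(directory / "labels.csv", dtype={"subject": str})
    labels = CohortLabels(list(labels_frame["subject"]), labels_frame["label"].to_numpy())
    truth_doc = json.loads((directory / "truth.json").read_text())
    spec = None
    spec_path = directory / "spec.json"
    if spec_path.exists():
        spec = SyntheticSpec(**json.loads(spec_path.read_text()))
    return SyntheticDataset(table, labels, truth_doc["truth"], truth_doc["direction"], spec)
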