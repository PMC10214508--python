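"""End-to-end orchestration: simulate/load -> (tune) -> evaluate -> interpret
-> annotate -> report, with a manifest sufficient to re-run bit-identically."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    NEGATIVE_MODE_ADDUCTS,
    POSITIVE_MODE_ADDUCTS,
    annotate_mz,
    bundled_pd_marker_compounds,
    read_compound_table,
)
from .evaluation import BootstrapPlan, BootstrapResult, grid_search, run_evaluation
from .feature_tables import read_feature_table
from .interpretation import (
    FeatureRanking,
    aggregate_shap,
    rank_features,
    regulation_direction,
)
from .metrics import METRIC_NAMES, pooled_rsd
from .models import HyperparameterGrid, ModelSpec, default_grid, default_spec
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    # exactly one of (table, synthetic) must be set
    table: str | None = None
    label_column: str = "label"
    synthetic: dict | None = None
    compound_db: str | None = None  # None -> bundled PD marker table

    family: str = "NN"
    grid: str | None = None  # grid JSON path; "default" -> packaged grid
    tune: bool = False

    n_iterations: int = 100
    train_fraction: float = 0.6
    stratified: bool = False

    interpret: bool = True
    attribution_budget: int = 128
    background_size: int | None = 8

    annotate: bool = True
    tolerance_ppm: float = 20.0
    adduct_mode: str = "positive"
    top_k: int = 10

    output_dir: str = "crankms_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if (self.table is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'table' or 'synthetic' must be given")
        if self.table is not None and not Path(self.table).exists():
            raise FileNotFoundError(self.table)
        if self.compound_db is not None and not Path(self.compound_db).exists():
            raise FileNotFoundError(self.compound_db)
        if self.adduct_mode not in ("positive", "negative"):
            raise ValueError("adduct_mode must be 'positive' or 'negative'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"crankms {__version__}",
        "config": dataclasses.asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {},
        "outputs": [],
        "stages": [],
    }

    if config.synthetic is not None:
        spec = SyntheticSpec(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        dataset = generate_dataset(spec)
        table, labels = dataset.table, dataset.labels
        manifest["stages"].append("simulate")
    else:
        table, labels = read_feature_table(config.table, label_column=config.label_column)
        if labels is None:
            raise ValueError(f"label column {config.label_column!r} not found in table")
        manifest["inputs"][config.table] = _sha256(Path(config.table))

    plan = BootstrapPlan(config.n_iterations, config.train_fraction, config.stratified, config.seed)

    spec = default_spec(config.family, seed=config.seed)
    if config.tune:
        if config.grid in (None, "default"):
            grid = default_grid(config.family)
        else:
            grid = HyperparameterGrid.from_json(Path(config.grid).read_text())
            manifest["inputs"][config.grid] = _sha256(Path(config.grid))
        spec, _ = grid_search(table, labels, grid, plan)
        spec = ModelSpec(spec.family, spec.hyperparameters, config.seed)
        manifest["stages"].append("tune")
        manifest["tuned_spec"] = json.loads(spec.to_json())

    result = run_evaluation(
        table, labels, spec, plan,
        compute_attributions=config.interpret,
        attribution_budget=config.attribution_budget,
        background_size=config.background_size,
    )
    manifest["stages"].append("evaluate")
    _write_metric_tables(result, out, manifest)

    ranking = None
    if config.interpret:
        scores = aggregate_shap(result.attributions)
        directions = regulation_direction(table, labels)
        ranking = rank_features(table.feature_ids, scores, directions, top_k=config.top_k)
        ranking.to_frame().to_csv(out / "ranking.csv", index=False)
        manifest["outputs"].append("ranking.csv")
        manifest["stages"].append("interpret")

    annotations = None
    if config.annotate and ranking is not None:
        db = (
            read_compound_table(config.compound_db)
            if config.compound_db
            else bundled_pd_marker_compounds()
        )
        if config.compound_db:
            manifest["inputs"][config.compound_db] = _sha256(Path(config.compound_db))
        adducts = POSITIVE_MODE_ADDUCTS if config.adduct_mode == "positive" else NEGATIVE_MODE_ADDUCTS
        annotations = annotate_ranking(ranking, db, adducts, config.tolerance_ppm)
        annotations.to_csv(out / "annotations.csv", index=False)
        manifest["outputs"].append("annotations.csv")
        manifest["stages"].append("annotate")

    report_path = out / "report.md"
    write_report(result, ranking, annotations, report_path)
    manifest["outputs"].append("report.md")
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def annotate_ranking(ranking: FeatureRanking, db, adducts, tolerance_ppm: float) -> pd.DataFrame:
    """Annotate the top-ranked features whose IDs parse as m/z values.

    Composite block prefixes (``"LC-MS+:123.4567"``) are stripped before
    parsing.
    """
    rows = []
    for feature_id, score, rank, direction in ranking.top():
        raw = feature_id.rsplit(":", 1)[-1]
        try:
            mz = float(raw)
        except ValueError:
            continue  # opaque feature name; nothing to annotate
        matches = annotate_mz(mz, db, adducts, tolerance_ppm)
        for m in matches:
            rows.append(
                {
                    "feature_id": feature_id,
                    "rank": rank,
                    "shap_score": score,
                    "direction": direction,
                    "observed_mz": mz,
                    "compound_id": m.compound.id,
                    "compound_name": m.compound.name,
                    "adduct": m.adduct.name,
                    "theoretical_mz": m.theoretical_mz,
                    "ppm": m.ppm,
                    "mass_defect": m.mass_defect,
                    "exogenous_flag": m.exogenous_flag,
                }
            )
    columns = [
        "feature_id", "rank", "shap_score", "direction", "observed_mz",
        "compound_id", "compound_name", "adduct", "theoretical_mz", "ppm",
        "mass_defect", "exogenous_flag",
    ]
    return pd.DataFrame(rows, columns=columns)


def _write_metric_tables(result: BootstrapResult, out: Path, manifest: dict) -> None:
    rows = []
    for i, rec in enumerate(result.iterations):
        for name, value in rec.metrics.as_dict().items():
            rows.append(
                {"family": result.spec.family, "iteration": i, "metric": name, "value": value}
            )
    pd.DataFrame(rows).to_csv(out / "metrics_iterations.csv", index=False)
    summary_rows = [
        {
            "family": result.spec.family,
            "metric": name,
            "mean": result.summary.mean[name],
            "sd": result.summary.sd[name],
            "n_undefined": result.summary.n_undefined[name],
        }
        for name in METRIC_NAMES
    ]
    pd.DataFrame(summary_rows).to_csv(out / "metrics_summary.csv", index=False)
    manifest["outputs"] += ["metrics_iterations.csv", "metrics_summary.csv"]


def write_report(
    result: BootstrapResult | list[BootstrapResult],
    ranking: FeatureRanking | None,
    annotations: pd.DataFrame | None,
    path: str | Path,
) -> Path:
    """Human-readable markdown summary of one or several evaluation runs."""
    results = result if isinstance(result, list) else [result]
    lines = ["# CRANK-MS run report", ""]
    lines += ["## Diagnostic performance (mean ± SD over bootstrap iterations)", ""]
    header = "| model | " + " | ".join(METRIC_NAMES) + " | pooled RSD % |"
    lines += [header, "|" + "---|" * (len(METRIC_NAMES) + 2)]
    for res in results:
        cells = [res.spec.family]
        for name in METRIC_NAMES:
            m, s = res.summary.mean[name], res.summary.sd[name]
            cells.append("undefined" if np.isnan(m) else f"{m:.3f} ± {s:.3f}")
        try:
            cells.append(f"{pooled_rsd(res.summary):.2f}")
        except ValueError:
            cells.append("n/a")
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    if ranking is not None:
        top = ranking.top()
        lines += [f"## Top {len(top)} features by SHAP score", ""]
        if not top:
            lines.append("No features ranked.")
        else:
            lines += ["| rank | feature | SHAP score | direction |", "|---|---|---|---|"]
            lines += [
                f"| {rank} | {fid} | {score:.5g} | {direction} |"
                for fid, score, rank, direction in top
            ]
        lines.append("")
    if annotations is not None:
        lines += ["## Annotations (within ppm tolerance)", ""]
        if annotations.empty:
            lines.append("No annotation matched.")
        else:
            cols = list(annotations.columns)
            lines += ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
            for _, row in annotations.iterrows():
                cells = [
                    f"{v:.4f}" if isinstance(v, float) else str(v) for v in row.tolist()
                ]
                lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path
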