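"""End-to-end pipeline: simulate -> preprocess -> grid -> meta -> stats -> transfer.

A :class:`PipelineConfig` carries every tunable with defaults matching the
analysis design (sparse threshold 1%, minimum cluster fraction 10%, at most
10 clusters, dims 2-6, 10 iterations per combination, 80:20 split, alpha
0.05, 3-D meta-embedding). ``run_pipeline`` persists each stage's outputs
under the run directory and writes a manifest of SHA-256 checksums, so
reruns with the same master seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import grid as grid_mod
from .cohort import Cohort, generate_cohort, generate_external_cohort, write_cohort
from .meta import build_membership_matrix, export_embedding, reduce_and_cluster
from .preprocess import Preprocessor
from .stats import outcome_report, report_to_frame
from .transfer import assign_external, train_and_evaluate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "amlmeta_run"
    cohort_csv: str | None = None  # None -> simulate
    cohort_schema: str | None = None
    external_csv: str | None = None
    external_schema: str | None = None
    master_seed: int = 0
    # stage parameters (defaults = analysis design constants)
    sparse_threshold: float = 0.01
    min_frac: float = 0.10
    max_clusters: int = 10
    dims: tuple[int, ...] = (2, 3, 4, 5, 6)
    iterations: int = 10
    split: float = 0.8
    alpha: float = 0.05
    meta_dims: int = 3
    bandwidth: float | str = "auto"
    registry: str = "demo"  # "demo" | "full"
    n_jobs: int = 1
    simulate_n: int = 400
    simulate_external_n: int = 200
    simulate_spec: str = "demo"  # "demo" | "aml" | "separated"
    stages: tuple[str, ...] = ("simulate", "preprocess", "grid", "meta", "stats", "transfer")

    def registry_object(self) -> grid_mod.AlgorithmRegistry:
        if self.registry == "full":
            reg = grid_mod.default_registry()
            return grid_mod.AlgorithmRegistry(reg.transforms, tuple(self.dims), reg.clusterers)
        return grid_mod.reduced_registry()


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> PipelineConfig:
    """Parse a YAML config; unknown keys are rejected, absent keys default."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dims", "stages"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return every violation/warning, not just the first."""
    issues: list[str] = []
    if not 0 < config.sparse_threshold < 1:
        issues.append("sparse_threshold must lie in (0, 1)")
    if not 0 < config.min_frac <= 1:
        issues.append("min_frac must lie in (0, 1]")
    if config.max_clusters < 2:
        issues.append("max_clusters must be >= 2")
    if config.min_frac > 0 and int(1.0 / config.min_frac) < 2:
        issues.append("min_frac > 0.5: no multi-cluster partition can pass the sanity check")
    elif config.min_frac > 0 and int(1.0 / config.min_frac) < config.max_clusters:
        issues.append(
            f"warning: min_frac {config.min_frac} caps passable clusters at "
            f"{int(1.0 / config.min_frac)} < max_clusters {config.max_clusters}"
        )
    if config.master_seed < 0:
        issues.append("master_seed must be non-negative")
    if not 0 < config.split < 1:
        issues.append("split must lie in (0, 1)")
    if config.iterations < 1:
        issues.append("iterations must be >= 1")
    if config.meta_dims < 1:
        issues.append("meta_dims must be >= 1")
    if not 0 < config.alpha < 1:
        issues.append("alpha must lie in (0, 1)")
    if any(d < 1 for d in config.dims):
        issues.append("dims must be positive")
    if config.registry not in ("demo", "full"):
        issues.append("registry must be 'demo' or 'full'")
    unknown_stages = set(config.stages) - {
        "simulate", "preprocess", "grid", "meta", "stats", "transfer"
    }
    if unknown_stages:
        issues.append(f"unknown stages: {sorted(unknown_stages)}")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_spec(config: PipelineConfig) -> cohort_mod.CohortSpec:
    if config.simulate_spec == "aml":
        return cohort_mod.default_aml_spec(config.simulate_n, seed=config.master_seed)
    if config.simulate_spec == "separated":
        return cohort_mod.separated_spec(config.simulate_n, seed=config.master_seed)
    return cohort_mod.demo_spec(config.simulate_n, seed=config.master_seed)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Hard errors (invalid config, stage preconditions) halt with a
    stage-attributed message; per-combination grid failures do not.
    """
    issues = [i for i in validate_config(config) if not i.startswith("warning")]
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def persist(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    # --- stage: cohort ------------------------------------------------------
    external = None
    if "simulate" in config.stages and config.cohort_csv is None:
        spec = _simulate_spec(config)
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort.csv", out / "cohort.schema.yaml")
        persist("cohort.csv", out / "cohort.csv")
        persist("cohort.schema.yaml", out / "cohort.schema.yaml")
        if "transfer" in config.stages:
            external = generate_external_cohort(
                spec, [], config.simulate_external_n, seed=config.master_seed + 1
            )
            write_cohort(external, out / "external.csv", out / "external.schema.yaml")
            persist("external.csv", out / "external.csv")
    elif config.cohort_csv is not None:
        cohort = cohort_mod.read_cohort(config.cohort_csv, config.cohort_schema)
        if config.external_csv is not None:
            external = cohort_mod.read_cohort(config.external_csv, config.external_schema)
    else:
        raise ValueError("stage 'simulate' disabled but no cohort_csv given")

    # --- stage: preprocess --------------------------------------------------
    pre = Preprocessor(threshold=config.sparse_threshold)
    matrix = pre.fit_transform(cohort)
    np.savetxt(
        out / "matrix.csv",
        matrix.matrix,
        delimiter=",",
        header=",".join(matrix.feature_names),
        comments="",
    )
    persist("matrix.csv", out / "matrix.csv")

    if "grid" not in config.stages:
        _write_manifest(out, config, artifacts)
        return out

    # --- stage: grid --------------------------------------------------------
    registry = config.registry_object()
    results = grid_mod.run_grid(
        registry,
        matrix,
        master_seed=config.master_seed,
        n_iterations=config.iterations,
        min_frac=config.min_frac,
        max_clusters=config.max_clusters,
        n_jobs=config.n_jobs,
    )
    summary = grid_mod.summarize_results(results)
    summary.to_csv(out / "grid_results.csv", index=False)
    persist("grid_results.csv", out / "grid_results.csv")
    passing = grid_mod.collect_passing(results)
    logger.info("%d of %d grid runs passed the sanity check", len(passing), len(results))

    if "meta" not in config.stages:
        _write_manifest(out, config, artifacts)
        return out

    # --- stage: meta --------------------------------------------------------
    membership = build_membership_matrix(passing)
    model = reduce_and_cluster(
        membership, d=config.meta_dims, bandwidth=config.bandwidth, seed=config.master_seed
    )
    export_embedding(model, out / "meta_embedding.csv")
    persist("meta_embedding.csv", out / "meta_embedding.csv")

    # --- stage: stats -------------------------------------------------------
    if "stats" in config.stages:
        baseline_vars = [c.name for c in cohort.schema.clustering_columns()]
        report = outcome_report(
            cohort, model.labels, baseline_variables=baseline_vars, seed=config.master_seed
        )
        report_to_frame(report).to_csv(out / "outcome_report.csv", index=False)
        persist("outcome_report.csv", out / "outcome_report.csv")
        for ep, surv in report.survival.items():
            surv.at_risk.to_csv(out / f"at_risk_{ep}.csv")
            persist(f"at_risk_{ep}.csv", out / f"at_risk_{ep}.csv")

    # --- stage: transfer ----------------------------------------------------
    if "transfer" in config.stages and external is not None and model.n_final_clusters >= 2:
        transfer = train_and_evaluate(
            matrix, model.labels, split=config.split, seed=config.master_seed
        )
        ext_labels, features = assign_external(
            pre, cohort, model.labels, external, transfer.selected_model,
            seed=config.master_seed,
        )
        rows = {
            "selected_model": transfer.selected_model,
            "n_features": len(features),
            "metrics": {
                name: dataclasses.asdict(m) for name, m in transfer.metrics.items()
            },
        }
        (out / "transfer_report.json").write_text(json.dumps(rows, indent=2, sort_keys=True))
        persist("transfer_report.json", out / "transfer_report.json")
        np.savetxt(out / "external_labels.csv", ext_labels, fmt="%d", header="meta_cluster", comments="")
        persist("external_labels.csv", out / "external_labels.csv")

    _write_manifest(out, config, artifacts)
    return out


def _write_manifest(out: Path, config: PipelineConfig, artifacts: dict[str, str]) -> None:
    manifest = {
        "master_seed": config.master_seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "artifacts": dict(sorted(artifacts.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
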