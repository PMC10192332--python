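"""Synthetic AML-like cohort generation.

Real multi-center AML registries are not redistributable, so every stage of
the pipeline is exercised on synthetic cohorts with planted cluster
structure: mixed-type baseline features (binary mutation flags, categorical
karyotype, skewed continuous labs), missing-completely-at-random masking,
and outcomes (complete-remission flag, exponential survival times with
independent exponential censoring) drawn conditionally on the planted
cluster.

Feature kinds mirror a clinical schema: ``continuous`` / ``binary`` /
``categorical`` columns are eligible for clustering; ``outcome_*`` and
``post_baseline`` columns never are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

CLUSTERING_KINDS = frozenset({"continuous", "binary", "categorical"})
OUTCOME_KINDS = frozenset({"outcome_binary", "outcome_time", "outcome_event"})
ALL_KINDS = CLUSTERING_KINDS | OUTCOME_KINDS | {"post_baseline"}


@dataclass(frozen=True)
class ColumnSpec:
    """Declared type of a single cohort column."""

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"categorical column {self.name!r} declares no levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered column declarations for a cohort table."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise ValueError("duplicate column names in schema")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    def by_kind(self, *kinds: str) -> list[ColumnSpec]:
        return [c for c in self.columns if c.kind in kinds]

    def clustering_columns(self) -> list[ColumnSpec]:
        """Columns eligible as clustering inputs (baseline features only)."""
        return [c for c in self.columns if c.kind in CLUSTERING_KINDS]

    def outcome_columns(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.kind in OUTCOME_KINDS or c.kind == "post_baseline"]

    def drop(self, names: list[str]) -> "FeatureSchema":
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"columns not in schema: {missing}")
        return FeatureSchema(tuple(c for c in self.columns if c.name not in names))


@dataclass
class Cohort:
    """Patient-by-feature table with schema and optional planted labels.

    Missing entries are ``NaN`` in ``values``; ``true_labels`` is present
    only for synthetic cohorts.
    """

    values: pd.DataFrame
    schema: FeatureSchema
    true_labels: np.ndarray | None = None
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.schema.names):
            raise ValueError("cohort columns do not match schema")
        self.values = self.values[self.schema.names]
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)
            if len(self.true_labels) != len(self.values):
                raise ValueError("true_labels length mismatch")

    @property
    def n_patients(self) -> int:
        return len(self.values)

    def copy(self) -> "Cohort":
        labels = None if self.true_labels is None else self.true_labels.copy()
        return Cohort(self.values.copy(), self.schema, labels, self.cohort_id)


@dataclass(frozen=True)
class ContinuousParams:
    """Cluster-specific location/scale; on log scale when ``log`` is set."""

    loc: tuple[float, ...]
    scale: tuple[float, ...]
    log: bool = False
    units: str = ""


@dataclass(frozen=True)
class CategoricalParams:
    levels: tuple[str, ...]
    probs: tuple[tuple[float, ...], ...]  # cluster x level


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic cohort."""

    n_patients: int
    n_clusters: int
    cluster_weights: tuple[float, ...]
    binary_prevalence: dict[str, tuple[float, ...]]  # feature -> per-cluster rate
    categorical_probs: dict[str, CategoricalParams]
    continuous_params: dict[str, ContinuousParams]
    missing_rates: dict[str, float]
    cr_prob: tuple[float, ...]
    survival_hazards: dict[str, tuple[float, ...]]  # endpoint -> per-cluster rate
    censoring_rate: float
    seed: int = 0
    post_baseline_prob: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        w = np.asarray(self.cluster_weights, dtype=float)
        if len(w) != self.n_clusters:
            raise ValueError("cluster_weights length != n_clusters")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9) or (w < 0).any():
            raise ValueError("cluster_weights must be a probability vector summing to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name, rates in {**self.binary_prevalence, "cr": self.cr_prob}.items():
            arr = np.asarray(rates, dtype=float)
            if len(arr) != self.n_clusters or ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"invalid per-cluster probabilities for {name!r}")
        for name, cp in self.categorical_probs.items():
            p = np.asarray(cp.probs, dtype=float)
            if p.shape != (self.n_clusters, len(cp.levels)):
                raise ValueError(f"categorical_probs shape mismatch for {name!r}")
            if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError(f"categorical level probabilities for {name!r} must sum to 1")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")
        for ep, haz in self.survival_hazards.items():
            arr = np.asarray(haz, dtype=float)
            if len(arr) != self.n_clusters or (arr <= 0).any():
                raise ValueError(f"hazards for {ep!r} must be positive, one per cluster")
        if self.censoring_rate <= 0:
            raise ValueError("censoring_rate must be positive")

    def build_schema(self) -> FeatureSchema:
        cols: list[ColumnSpec] = []
        for name, cp in self.continuous_params.items():
            cols.append(ColumnSpec(name, "continuous", units=cp.units))
        for name in self.binary_prevalence:
            cols.append(ColumnSpec(name, "binary"))
        for name, cp in self.categorical_probs.items():
            cols.append(ColumnSpec(name, "categorical", categories=cp.levels))
        cols.append(ColumnSpec("cr", "outcome_binary"))
        for ep in self.survival_hazards:
            cols.append(ColumnSpec(f"{ep}_time", "outcome_time", units="months"))
            cols.append(ColumnSpec(f"{ep}_event", "outcome_event"))
        for name in self.post_baseline_prob:
            cols.append(ColumnSpec(name, "post_baseline"))
        return FeatureSchema(tuple(cols))


def generate_cohort(spec: CohortSpec, cohort_id: str = "cohort") -> Cohort:
    """Draw a cohort from ``spec``; deterministic given ``spec.seed``.

    Features are conditionally independent given the planted cluster.
    Survival endpoints are exponential per cluster with shared independent
    exponential censoring; observed time is the minimum of the two and the
    event flag marks an uncensored event.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    labels = rng.choice(spec.n_clusters, size=n, p=np.asarray(spec.cluster_weights))

    data: dict[str, np.ndarray] = {}
    for name, cp in spec.continuous_params.items():
        loc = np.asarray(cp.loc)[labels]
        scale = np.asarray(cp.scale)[labels]
        x = loc + scale * rng.standard_normal(n)
        data[name] = np.exp(x) if cp.log else x
    for name, prev in spec.binary_prevalence.items():
        data[name] = (rng.random(n) < np.asarray(prev)[labels]).astype(float)
    for name, cp in spec.categorical_probs.items():
        probs = np.asarray(cp.probs)
        # inverse-CDF draw vectorised over per-patient cluster-specific rows
        u = rng.random(n)
        cum = probs.cumsum(axis=1)[labels]
        idx = (u[:, None] > cum).sum(axis=1)
        data[name] = np.asarray(cp.levels, dtype=object)[idx]

    data["cr"] = (rng.random(n) < np.asarray(spec.cr_prob)[labels]).astype(float)
    for ep, haz in spec.survival_hazards.items():
        t_event = rng.exponential(1.0 / np.asarray(haz)[labels])
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
        data[f"{ep}_time"] = np.minimum(t_event, t_cens)
        data[f"{ep}_event"] = (t_event <= t_cens).astype(float)
    for name, prob in spec.post_baseline_prob.items():
        data[name] = (rng.random(n) < np.asarray(prob)[labels]).astype(float)

    schema = spec.build_schema()
    cohort = Cohort(pd.DataFrame(data), schema, true_labels=labels, cohort_id=cohort_id)
    if any(r > 0 for r in spec.missing_rates.values()):
        mask_seed = int(rng.integers(0, 2**31 - 1))
        cohort = inject_missingness(cohort, spec.missing_rates, seed=mask_seed)
    return cohort


def inject_missingness(cohort: Cohort, missing_rates: dict[str, float], seed: int = 0) -> Cohort:
    """Mask entries missing-completely-at-random, per-feature.

    Features absent from ``missing_rates`` (or with rate 0) are untouched.
    Outcome columns may be masked too — downstream analyses drop rather than
    impute them.
    """
    for name, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {name!r} outside [0, 1]")
        if name not in cohort.schema:
            raise KeyError(f"missing-rate feature {name!r} not in schema")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for name, rate in missing_rates.items():
        if rate == 0.0:
            continue
        mask = rng.random(cohort.n_patients) < rate
        col = out.values[name]
        if col.dtype == object:
            out.values.loc[mask, name] = None
        else:
            out.values.loc[mask, name] = np.nan
    return out


def generate_external_cohort(
    spec: CohortSpec,
    drop_features: list[str],
    n: int,
    seed: int,
    cohort_id: str = "external",
) -> Cohort:
    """Second cohort from the same generative process minus named features.

    Emulates an external validation cohort in which a couple of mutation
    assays were unavailable.
    """
    base_schema = spec.build_schema()
    unknown = [f for f in drop_features if f not in base_schema]
    if unknown:
        raise KeyError(f"drop_features not in schema: {unknown}")
    ext_spec = replace(spec, n_patients=n, seed=seed)
    cohort = generate_cohort(ext_spec, cohort_id=cohort_id)
    if drop_features:
        cohort = Cohort(
            cohort.values.drop(columns=list(drop_features)),
            cohort.schema.drop(list(drop_features)),
            cohort.true_labels,
            cohort_id,
        )
    return cohort


# ---------------------------------------------------------------------------
# shipped generative specs


def default_aml_spec(n_patients: int = 1383, seed: int = 0) -> CohortSpec:
    """AML-like cohort with 4 planted clusters.

    Cluster weights, mutation prevalences, karyotype mix, lab medians and
    outcome parameters loosely follow the published landscape of intensively
    treated adult AML: a NPM1/FLT3-ITD-driven cluster (0), an adverse
    TP53/complex-karyotype cluster (1), an intermediate CBF-enriched cluster
    (2) and a favorable CEBPA-driven cluster (3). Continuous labs are
    log-normal where right-skewed (WBC, LDH, platelets), normal otherwise.
    """
    ln = math.log
    binary = {
        "NPM1": (0.78, 0.06, 0.19, 0.14),
        "FLT3_ITD": (0.61, 0.05, 0.08, 0.15),
        "DNMT3A": (0.53, 0.16, 0.19, 0.17),
        "TP53": (0.02, 0.28, 0.05, 0.01),
        "ASXL1": (0.03, 0.23, 0.08, 0.03),
        "RUNX1": (0.03, 0.23, 0.09, 0.13),
        "TET2": (0.17, 0.18, 0.15, 0.27),
        "IDH1": (0.16, 0.08, 0.08, 0.05),
        "IDH2": (0.17, 0.18, 0.14, 0.08),
        "NRAS": (0.11, 0.14, 0.23, 0.14),
        "CEBPA": (0.02, 0.03, 0.05, 0.95),
        "GATA2": (0.03, 0.02, 0.04, 0.31),
        "WT1": (0.08, 0.04, 0.06, 0.13),
        "STAG2": (0.04, 0.12, 0.05, 0.03),
        "BCOR": (0.04, 0.10, 0.04, 0.03),
        "PTPN11": (0.12, 0.05, 0.07, 0.04),
        "FLT3_TKD": (0.18, 0.04, 0.06, 0.07),
        "IKZF1": (0.02, 0.03, 0.02, 0.01),
        # deliberately sparse flags, removed by the <1% prevalence filter
        "rare_fusion_1": (0.004, 0.004, 0.004, 0.004),
        "rare_fusion_2": (0.002, 0.008, 0.002, 0.002),
    }
    karyotype = CategoricalParams(
        levels=("normal", "complex", "del5q", "inv16_t16", "t8_21", "other"),
        probs=(
            (0.78, 0.01, 0.01, 0.01, 0.01, 0.18),
            (0.33, 0.31, 0.23, 0.01, 0.01, 0.11),
            (0.33, 0.12, 0.05, 0.13, 0.08, 0.29),
            (0.71, 0.02, 0.01, 0.01, 0.02, 0.23),
        ),
    )
    continuous = {
        "age": ContinuousParams((52.0, 60.5, 55.0, 49.0), (12.0,) * 4, units="years"),
        "wbc": ContinuousParams(
            (ln(52.5), ln(4.0), ln(15.0), ln(25.0)), (0.9,) * 4, log=True, units="1e9/l"
        ),
        "platelets": ContinuousParams(
            (ln(62.0), ln(50.0), ln(55.0), ln(39.0)), (0.6,) * 4, log=True, units="1e9/l"
        ),
        "ldh": ContinuousParams(
            (ln(613.0), ln(293.0), ln(350.0), ln(420.0)), (0.5,) * 4, log=True, units="U/l"
        ),
        "bm_blasts": ContinuousParams((77.0, 45.0, 34.0, 60.0), (18.0,) * 4, units="%"),
        "hb": ContinuousParams((9.3,) * 4, (1.5,) * 4, units="g/dl"),
    }
    missing = {
        "karyotype": 0.059,
        "wbc": 0.002,
        "platelets": 0.01,
        "ldh": 0.074,
        "bm_blasts": 0.03,
        "hb": 0.002,
        "os_time": 0.02,
        "os_event": 0.02,
    }
    m = math.log(2)  # hazards from target median survival (months)
    hazards = {
        "efs": (m / 6.0, m / 1.9, m / 9.1, m / 11.2),
        "rfs": (m / 14.8, m / 11.9, m / 30.7, m / 40.0),
        "os": (m / 18.0, m / 10.5, m / 25.8, m / 54.0),
    }
    return CohortSpec(
        n_patients=n_patients,
        n_clusters=4,
        cluster_weights=(424 / 1383, 256 / 1383, 536 / 1383, 167 / 1383),
        binary_prevalence=binary,
        categorical_probs={"karyotype": karyotype},
        continuous_params=continuous,
        missing_rates=missing,
        cr_prob=(0.75, 0.35, 0.65, 0.85),
        survival_hazards=hazards,
        censoring_rate=m / 60.0,
        seed=seed,
        post_baseline_prob={"hsct": (0.30, 0.28, 0.31, 0.29)},
    )


def separated_spec(
    n_patients: int = 800,
    n_clusters: int = 4,
    n_binary: int = 40,
    n_continuous: int = 5,
    prevalence_low: float = 0.1,
    prevalence_high: float = 0.65,
    shift_sd: float = 1.5,
    seed: int = 42,
) -> CohortSpec:
    """Strongly separated planted-partition cohort for recovery experiments.

    Each binary feature is frequent (``prevalence_high``) in exactly one
    cluster and rare (``prevalence_low``) elsewhere, giving between-cluster
    prevalence gaps of ``prevalence_high - prevalence_low``; continuous
    features carry cluster-staggered mean shifts of ``shift_sd`` standard
    deviations. Outcomes are cluster-graded so the worst planted cluster has
    the highest hazard.
    """
    binary = {
        f"mut_{j:02d}": tuple(
            prevalence_high if k == j % n_clusters else prevalence_low
            for k in range(n_clusters)
        )
        for j in range(n_binary)
    }
    continuous = {
        f"lab_{j}": ContinuousParams(
            tuple(shift_sd * ((k + j) % n_clusters) for k in range(n_clusters)),
            (1.0,) * n_clusters,
        )
        for j in range(n_continuous)
    }
    missing = {f"lab_{j}": 0.03 for j in range(n_continuous)}
    m = math.log(2)
    medians = np.linspace(36.0, 8.0, n_clusters)  # cluster 0 best, last worst
    hazards = {ep: tuple(m / medians) for ep in ("efs", "rfs", "os")}
    cr = tuple(np.linspace(0.85, 0.35, n_clusters))
    return CohortSpec(
        n_patients=n_patients,
        n_clusters=n_clusters,
        cluster_weights=(1.0 / n_clusters,) * n_clusters,
        binary_prevalence=binary,
        categorical_probs={},
        continuous_params=continuous,
        missing_rates=missing,
        cr_prob=cr,
        survival_hazards=hazards,
        censoring_rate=m / 60.0,
        seed=seed,
    )


def demo_spec(n_patients: int = 400, seed: int = 0) -> CohortSpec:
    """Small, well-separated cohort used by the demo pipeline and smoke tests."""
    return separated_spec(n_patients=n_patients, n_binary=24, seed=seed)


# ---------------------------------------------------------------------------
# I/O: CSV table + YAML schema sidecar (empty cell = missing)


def write_cohort(cohort: Cohort, csv_path, schema_path) -> None:
    cohort.values.to_csv(csv_path, index=False)
    doc = {
        "cohort_id": cohort.cohort_id,
        "columns": [
            {
                "name": c.name,
                "kind": c.kind,
                **({"categories": list(c.categories)} if c.categories else {}),
                **({"units": c.units} if c.units else {}),
            }
            for c in cohort.schema.columns
        ],
    }
    if cohort.true_labels is not None:
        doc["true_labels"] = [int(x) for x in cohort.true_labels]
    with open(schema_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_cohort(csv_path, schema_path) -> Cohort:
    with open(schema_path) as fh:
        doc = yaml.safe_load(fh)
    cols = tuple(
        ColumnSpec(
            d["name"], d["kind"], tuple(d.get("categories", ())), d.get("units", "")
        )
        for d in doc["columns"]
    )
    schema = FeatureSchema(cols)
    df = pd.read_csv(csv_path)
    for c in schema.columns:
        if c.kind == "categorical":
            df[c.name] = df[c.name].astype(object)
            df.loc[df[c.name].isna(), c.name] = None
    labels = doc.get("true_labels")
    return Cohort(
        df,
        schema,
        None if labels is None else np.asarray(labels),
        doc.get("cohort_id", "cohort"),
    )
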