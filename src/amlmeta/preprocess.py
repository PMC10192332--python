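"""Preprocessing of a mixed-type cohort into a numeric clustering matrix.

Pipeline order is fixed: sparse-feature filter -> one-hot encoding ->
median imputation -> z-scoring. Sparse filtering happens on source
features/levels before one-hot expansion; imputation precedes scaling so
the scaler sees a complete column. Outcome and post-baseline columns are
excluded from the matrix unconditionally (the outcome firewall).

A patient with an unknown (missing) categorical value receives an all-zero
indicator block for that feature: the feature then contributes nothing to
that patient's position in the model space, while the matrix stays
rectangular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ColumnSpec, FeatureSchema

logger = logging.getLogger(__name__)


@dataclass
class ClusteringMatrix:
    """Finite numeric patient x feature matrix with column provenance."""

    matrix: np.ndarray
    feature_names: list[str]
    provenance: dict[str, str]  # expanded column -> source schema column
    n_source_features: int
    source_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("clustering matrix contains non-finite entries")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        bad = [
            col
            for col, kind in self.source_kinds.items()
            if kind not in ("continuous", "binary", "categorical")
        ]
        if bad:
            raise ValueError(f"outcome/post-baseline columns leaked into matrix: {bad}")

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ZScoreParams:
    """Per-column standardization parameters; inverse recovers original units."""

    means: dict[str, float]
    sds: dict[str, float]


def _prevalence(col: pd.Series, n: int) -> float:
    return float((col == 1).sum()) / n


def filter_sparse_features(
    cohort: Cohort, threshold: float = 0.01
) -> tuple[Cohort, list[str]]:
    """Drop binary features (and categorical levels) present in < ``threshold``
    of patients; the boundary is strictly exclusive, so exactly-at-threshold
    features survive. Continuous features are never removed.

    Returns the filtered cohort and the list of removed features/levels.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    n = cohort.n_patients
    removed: list[str] = []
    drop_cols: list[str] = []
    new_cols: list[ColumnSpec] = []
    df = cohort.values.copy()
    for spec in cohort.schema.columns:
        if spec.kind == "binary":
            if _prevalence(df[spec.name], n) < threshold:
                drop_cols.append(spec.name)
                removed.append(spec.name)
                continue
            new_cols.append(spec)
        elif spec.kind == "categorical":
            kept_levels = []
            for lvl in spec.categories:
                if float((df[spec.name] == lvl).sum()) / n < threshold:
                    removed.append(f"{spec.name}={lvl}")
                else:
                    kept_levels.append(lvl)
            if not kept_levels:
                drop_cols.append(spec.name)
                removed.append(spec.name)
                continue
            # values at removed levels become unknown (all-zero after one-hot)
            dropped_lvls = set(spec.categories) - set(kept_levels)
            if dropped_lvls:
                mask = df[spec.name].isin(dropped_lvls)
                df.loc[mask, spec.name] = None
            new_cols.append(
                ColumnSpec(spec.name, "categorical", tuple(kept_levels), spec.units)
            )
        else:
            new_cols.append(spec)
    if drop_cols:
        df = df.drop(columns=drop_cols)
    if removed:
        logger.info("sparse filter removed %d features/levels: %s", len(removed), removed)
    if not any(c.kind in ("continuous", "binary", "categorical") for c in new_cols):
        logger.warning("sparse filter removed every clustering feature")
    out = Cohort(df, FeatureSchema(tuple(new_cols)), cohort.true_labels, cohort.cohort_id)
    return out, removed


def one_hot_encode(cohort: Cohort) -> Cohort:
    """Expand each categorical column into one indicator column per level.

    Missing/unknown category -> all indicators zero. Binary columns are kept
    as single 0/1 columns. Indicator columns are named ``source=level``.
    """
    df_parts: dict[str, pd.Series | np.ndarray] = {}
    new_cols: list[ColumnSpec] = []
    for spec in cohort.schema.columns:
        if spec.kind == "categorical":
            if not spec.categories:
                raise ValueError(f"categorical column {spec.name!r} has no levels")
            col = cohort.values[spec.name]
            for lvl in spec.categories:
                name = f"{spec.name}={lvl}"
                df_parts[name] = (col == lvl).astype(float).to_numpy()
                new_cols.append(ColumnSpec(name, "binary"))
        else:
            df_parts[spec.name] = cohort.values[spec.name]
            new_cols.append(spec)
    return Cohort(
        pd.DataFrame(df_parts), FeatureSchema(tuple(new_cols)), cohort.true_labels, cohort.cohort_id
    )


def impute_median(
    cohort: Cohort, medians: dict[str, float] | None = None
) -> tuple[Cohort, dict[str, float]]:
    """Fill missing continuous entries with the column median.

    ``medians`` overrides the learned values (used to preprocess an external
    cohort with the original cohort's statistics). Binary columns with
    missing entries are filled with 0 — absence of evidence contributes
    nothing, mirroring the unknown-categorical convention.
    """
    out = cohort.copy()
    learned: dict[str, float] = {}
    for spec in cohort.schema.columns:
        col = out.values[spec.name]
        if spec.kind == "continuous":
            if medians is not None:
                med = medians[spec.name]
            else:
                observed = col.dropna()
                if observed.empty:
                    raise ValueError(f"continuous column {spec.name!r} has no observed values")
                med = float(observed.median())
            learned[spec.name] = med
            out.values[spec.name] = col.fillna(med)
        elif spec.kind == "binary" and col.isna().any():
            out.values[spec.name] = col.fillna(0.0)
    return out, learned


def zscore(
    cohort: Cohort, params: ZScoreParams | None = None
) -> tuple[Cohort, ZScoreParams]:
    """Standardize continuous columns to zero mean and unit sample (n-1) sd.

    Zero-variance columns map to all zeros. Pass ``params`` to reuse another
    cohort's scaling (external-cohort preprocessing); the returned params
    allow exact inverse transformation to original units.
    """
    out = cohort.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for spec in cohort.schema.columns:
        if spec.kind != "continuous":
            continue
        col = out.values[spec.name].astype(float)
        if params is not None:
            mean, sd = params.means[spec.name], params.sds[spec.name]
        else:
            mean = float(col.mean())
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        means[spec.name], sds[spec.name] = mean, sd
        if sd == 0.0 or not np.isfinite(sd):
            out.values[spec.name] = 0.0
        else:
            out.values[spec.name] = (col - mean) / sd
    return out, ZScoreParams(means, sds)


def inverse_zscore(cohort: Cohort, params: ZScoreParams) -> Cohort:
    """Map z-scored continuous columns back to original units."""
    out = cohort.copy()
    for name, mean in params.means.items():
        sd = params.sds[name]
        if sd > 0:
            out.values[name] = out.values[name].astype(float) * sd + mean
    return out


@dataclass
class Preprocessor:
    """Fit-once/apply-many preprocessing so an external cohort is transformed
    with the original cohort's filter decisions, medians, scaling and one-hot
    vocabulary (no statistic leaks from the external data)."""

    threshold: float = 0.01
    fitted_: bool = field(default=False, repr=False)

    def fit(self, cohort: Cohort) -> "Preprocessor":
        filtered, self.removed_ = filter_sparse_features(cohort, self.threshold)
        self.kept_schema_ = FeatureSchema(tuple(filtered.schema.clustering_columns()))
        encoded = one_hot_encode(filtered)
        imputed, self.medians_ = impute_median(encoded)
        _, self.zscore_params_ = zscore(imputed)
        self.fitted_ = True
        return self

    def transform(self, cohort: Cohort) -> ClusteringMatrix:
        if not self.fitted_:
            raise RuntimeError("Preprocessor not fitted")
        # restrict to the intersection of fitted features and cohort columns
        cols = [c for c in self.kept_schema_.columns if c.name in cohort.schema]
        df = cohort.values[[c.name for c in cols]].copy()
        sub = Cohort(df, FeatureSchema(tuple(cols)), cohort.true_labels, cohort.cohort_id)
        encoded = one_hot_encode(sub)
        medians = {k: v for k, v in self.medians_.items() if k in encoded.schema}
        imputed, _ = impute_median(encoded, medians=medians)
        scaled, _ = zscore(imputed, params=self.zscore_params_)
        return _to_matrix(scaled, n_source_features=len(cols))

    def fit_transform(self, cohort: Cohort) -> ClusteringMatrix:
        return self.fit(cohort).transform(cohort)


def _to_matrix(cohort: Cohort, n_source_features: int) -> ClusteringMatrix:
    provenance: dict[str, str] = {}
    kinds: dict[str, str] = {}
    names: list[str] = []
    for spec in cohort.schema.clustering_columns():
        source = spec.name.split("=", 1)[0] if "=" in spec.name else spec.name
        provenance[spec.name] = source
        kinds[spec.name] = spec.kind
        names.append(spec.name)
    mat = cohort.values[names].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("residual missing values after preprocessing")
    return ClusteringMatrix(mat, names, provenance, n_source_features, kinds)


def assemble_matrix(cohort: Cohort, threshold: float = 0.01) -> ClusteringMatrix:
    """Full preprocessing chain on a single cohort.

    Equivalent to ``Preprocessor(threshold).fit_transform(cohort)``.
    """
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    return Preprocessor(threshold).fit_transform(cohort)
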