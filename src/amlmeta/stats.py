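"""Per-cluster outcome statistics: response, survival and baseline contrasts.

Every comparison is cluster-vs-remainder on an indicator variable, two-sided
at alpha = 0.05:

* complete remission -> logistic regression odds ratio with Wald 95% CI
  (identical to the 2x2 cross-product ratio; Haldane-Anscombe 0.5 correction
  on zero cells, flagged),
* survival endpoints -> Kaplan-Meier curves and medians, k-group log-rank
  test, Cox proportional-hazards ratios (Efron ties) with optional extra
  covariates,
* baseline variables -> Fisher's exact test for categorical variables
  (Monte-Carlo beyond 2x2), and ANOVA gated on per-group Shapiro-Wilk
  normality, falling back to Kruskal-Wallis,
* Benjamini-Hochberg step-up adjustment within each declared test family.

Patients with missing outcome values are dropped from the respective
analysis, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

logger = logging.getLogger(__name__)

ALPHA = 0.05
SHAPIRO_MAX_N = 5000  # per-group cap inside the normality gate


@dataclass
class EffectEstimate:
    """Point estimate with 95% CI and p-value; ``flag`` notes corrections."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    flag: str | None = None


@dataclass
class SurvivalSummary:
    endpoint: str
    medians: dict[int, float]  # cluster -> median (NaN = not reached)
    logrank_p: float
    hazard_ratios: dict[int, EffectEstimate]
    at_risk: pd.DataFrame | None = None


@dataclass
class BaselineTest:
    variable: str
    test_name: str
    p_value: float
    adjusted_p: float | None = None
    flag: str | None = None


@dataclass
class OutcomeReport:
    cluster_sizes: dict[int, int]
    cr_rates: dict[int, float]
    cr_odds: dict[int, EffectEstimate]
    cr_adjusted_p: dict[int, float]
    survival: dict[str, SurvivalSummary]
    baseline: list[BaselineTest] = field(default_factory=list)


def _usable(*arrays: np.ndarray) -> np.ndarray:
    """Row mask where every array is non-missing."""
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a)
    return mask


def cr_odds_ratio(
    cr_flags: np.ndarray, cluster_labels: np.ndarray, cluster_id: int
) -> EffectEstimate:
    """Odds ratio of response for one cluster versus all remaining patients.

    Computed from the 2x2 table (equivalently, the exponentiated coefficient
    of a logistic regression on the membership indicator) with a Wald 95%
    interval. A zero cell triggers the Haldane-Anscombe 0.5 correction,
    recorded in ``flag``.
    """
    cr = np.asarray(cr_flags, dtype=float)
    labels = np.asarray(cluster_labels)
    mask = np.isfinite(cr)
    cr, labels = cr[mask], labels[mask]
    in_cluster = labels == cluster_id
    if not in_cluster.any() or in_cluster.all():
        raise ValueError("need patients both inside and outside the cluster")
    a = float(np.sum(in_cluster & (cr == 1)))  # cluster responders
    b = float(np.sum(in_cluster & (cr == 0)))
    c = float(np.sum(~in_cluster & (cr == 1)))
    d = float(np.sum(~in_cluster & (cr == 0)))
    flag = None
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flag = "haldane_anscombe"
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - ALPHA / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=float(p),
        flag=flag,
    )


def km_and_logrank(
    times: np.ndarray,
    events: np.ndarray,
    cluster_labels: np.ndarray,
    at_risk_times: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0),
    endpoint: str = "os",
) -> SurvivalSummary:
    """Kaplan-Meier medians per cluster, k-group log-rank p, numbers at risk.

    Patients with missing time or event indicator are excluded. A median is
    NaN when the curve never reaches 0.5 (not reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    labels = np.asarray(cluster_labels)
    mask = _usable(times, events)
    times, events, labels = times[mask], events[mask], labels[mask]
    if (times < 0).any():
        raise ValueError("negative survival times")
    clusters = np.unique(labels)
    medians: dict[int, float] = {}
    at_risk_rows = {}
    for k in clusters:
        sel = labels == k
        if not sel.any():
            raise ValueError(f"cluster {k} has no usable patients")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        medians[int(k)] = float(kmf.median_survival_time_)
        at_risk_rows[int(k)] = [
            int((times[sel] >= t).sum()) for t in at_risk_times
        ]
    lr = multivariate_logrank_test(times, labels, events)
    hrs = {int(k): cox_hazard_ratio(times, events, labels, int(k)) for k in clusters}
    at_risk = pd.DataFrame.from_dict(
        at_risk_rows, orient="index", columns=[f"t={t:g}" for t in at_risk_times]
    )
    at_risk.index.name = "cluster"
    return SurvivalSummary(
        endpoint=endpoint,
        medians=medians,
        logrank_p=float(lr.p_value),
        hazard_ratios=hrs,
        at_risk=at_risk,
    )


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit curve (timeline, survival probability) for one group."""
    mask = _usable(np.asarray(times, float), np.asarray(events, float))
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float)[mask], np.asarray(events, float)[mask])
    df = kmf.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


def cox_hazard_ratio(
    times: np.ndarray,
    events: np.ndarray,
    cluster_labels: np.ndarray,
    cluster_id: int,
    covariates: pd.DataFrame | None = None,
) -> EffectEstimate:
    """Cox partial-likelihood hazard ratio for one cluster versus the rest.

    Efron tie handling; ``covariates`` (aligned with the label vector)
    extends the model for multivariable analysis. Non-convergence /
    separation is flagged rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    labels = np.asarray(cluster_labels)
    mask = _usable(times, events)
    df = pd.DataFrame(
        {
            "T": times[mask],
            "E": events[mask],
            "in_cluster": (labels[mask] == cluster_id).astype(float),
        }
    )
    if covariates is not None:
        cov = covariates.loc[mask].reset_index(drop=True)
        df = pd.concat([df.reset_index(drop=True), cov], axis=1)
    if df["in_cluster"].nunique() < 2:
        raise ValueError("need patients both inside and outside the cluster")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="T", event_col="E", fit_options={"precision": 1e-9})
    except Exception as exc:  # monotone likelihood / separation
        logger.warning("Cox fit failed for cluster %s: %s", cluster_id, exc)
        return EffectEstimate(np.nan, np.nan, np.nan, np.nan, flag=f"fit_failed: {exc}")
    row = cph.summary.loc["in_cluster"]
    flag = None
    if not np.isfinite(row["coef"]) or abs(row["coef"]) > 10:
        flag = "possible_separation"
    return EffectEstimate(
        estimate=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        flag=flag,
    )


def _fisher_exact_rc(table: np.ndarray, n_resamples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo Fisher exact p for an r x c table with fixed margins.

    Samples tables from the multivariate hypergeometric null and counts
    those no more probable than the observed table (probability ordering).
    """
    table = np.asarray(table, dtype=int)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(table.sum(axis=1), table.sum(axis=0))
    logp_obs = dist.logpmf(table)
    samples = dist.rvs(n_resamples, random_state=rng)
    logp = dist.logpmf(samples)
    # +1 correction keeps the estimate a valid p-value
    return float((np.sum(logp <= logp_obs + 1e-12) + 1) / (n_resamples + 1))


def compare_baseline(
    values: np.ndarray,
    cluster_labels: np.ndarray,
    kind: str,
    variable: str = "",
    seed: int = 0,
) -> BaselineTest:
    """Across-cluster test of one baseline variable.

    Categorical/binary -> Fisher exact (exact 2x2, else seeded Monte-Carlo).
    Continuous -> ANOVA when Shapiro-Wilk accepts normality in every group
    (each group subsampled to at most ``SHAPIRO_MAX_N``), else
    Kruskal-Wallis. A variable constant over all patients yields p = 1,
    flagged.
    """
    labels = np.asarray(cluster_labels)
    values = np.asarray(values)
    if kind in ("categorical", "binary"):
        obs_mask = pd.notna(values)
    else:
        obs_mask = np.isfinite(np.asarray(values, dtype=float))
    values, labels = values[obs_mask], labels[obs_mask]
    clusters = np.unique(labels)
    if len(pd.unique(values)) < 2:
        return BaselineTest(variable, "constant", 1.0, flag="constant_variable")
    if kind in ("categorical", "binary"):
        levels = pd.unique(values)
        table = np.array(
            [[(values[labels == k] == lvl).sum() for lvl in levels] for k in clusters]
        )
        if table.shape == (2, 2):
            _, p = sps.fisher_exact(table)
            return BaselineTest(variable, "fisher_exact", float(p))
        p = _fisher_exact_rc(table, seed=seed)
        return BaselineTest(variable, "fisher_exact_mc", p)
    groups = [np.asarray(values[labels == k], dtype=float) for k in clusters]
    normal = True
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            normal = False
            break
        sub = g if len(g) <= SHAPIRO_MAX_N else g[:SHAPIRO_MAX_N]
        if sps.shapiro(sub).pvalue < ALPHA:
            normal = False
            break
    if normal:
        _, p = sps.f_oneway(*groups)
        return BaselineTest(variable, "anova", float(p))
    stat, p = sps.kruskal(*groups)
    return BaselineTest(variable, "kruskal_wallis", float(p))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one test family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outcome_report(
    cohort: Cohort,
    cluster_labels: np.ndarray,
    endpoints: tuple[str, ...] = ("efs", "rfs", "os"),
    baseline_variables: list[str] | None = None,
    seed: int = 0,
) -> OutcomeReport:
    """Full per-cluster outcome analysis of a labelled cohort.

    BH adjustment is applied within families: one family for the CR odds
    ratios, and one per set of baseline-variable tests.
    """
    labels = np.asarray(cluster_labels)
    clusters = [int(k) for k in np.unique(labels)]
    cr = cohort.values["cr"].to_numpy(dtype=float)
    sizes = {k: int((labels == k).sum()) for k in clusters}
    cr_rates = {
        k: float(np.nanmean(cr[labels == k])) for k in clusters
    }
    cr_odds = {k: cr_odds_ratio(cr, labels, k) for k in clusters}
    adj = bh_adjust([cr_odds[k].p_value for k in clusters])
    cr_adj = {k: float(a) for k, a in zip(clusters, adj)}
    survival = {}
    for ep in endpoints:
        tcol, ecol = f"{ep}_time", f"{ep}_event"
        if tcol not in cohort.schema or ecol not in cohort.schema:
            continue
        survival[ep] = km_and_logrank(
            cohort.values[tcol].to_numpy(dtype=float),
            cohort.values[ecol].to_numpy(dtype=float),
            labels,
            endpoint=ep,
        )
    baseline: list[BaselineTest] = []
    if baseline_variables:
        for var in baseline_variables:
            spec = cohort.schema[var]
            baseline.append(
                compare_baseline(
                    cohort.values[var].to_numpy(), labels, spec.kind, var, seed=seed
                )
            )
        adj_b = bh_adjust([b.p_value for b in baseline])
        for b, a in zip(baseline, adj_b):
            b.adjusted_p = float(a)
    return OutcomeReport(sizes, cr_rates, cr_odds, cr_adj, survival, baseline)


def report_to_frame(report: OutcomeReport) -> pd.DataFrame:
    """Flat per-cluster summary table (one row per cluster)."""
    rows = []
    for k in sorted(report.cluster_sizes):
        row = {
            "cluster": k,
            "n": report.cluster_sizes[k],
            "cr_rate": report.cr_rates[k],
            "cr_or": report.cr_odds[k].estimate,
            "cr_or_ci_low": report.cr_odds[k].ci_low,
            "cr_or_ci_high": report.cr_odds[k].ci_high,
            "cr_or_p": report.cr_odds[k].p_value,
            "cr_or_p_adj": report.cr_adjusted_p[k],
        }
        for ep, surv in report.survival.items():
            hr = surv.hazard_ratios[k]
            row[f"{ep}_median"] = surv.medians[k]
            row[f"{ep}_hr"] = hr.estimate
            row[f"{ep}_hr_ci_low"] = hr.ci_low
            row[f"{ep}_hr_ci_high"] = hr.ci_high
            row[f"{ep}_hr_p"] = hr.p_value
            row[f"{ep}_logrank_p"] = surv.logrank_p
        rows.append(row)
    return pd.DataFrame(rows)
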