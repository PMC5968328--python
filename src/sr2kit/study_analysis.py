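"""Statistical battery for spatial-release sessions.

Reproduces, on any :class:`~sr2kit.session.SessionTable`, the standard
analysis suite for the rapid spatial-release test:

* condition × run summary tables (mean/SD thresholds, mean/SD release);
* grand means across runs;
* repeated-measures ANOVA with Greenhouse–Geisser sphericity correction and
  partial eta-squared effect sizes;
* SPSS-style stepwise multiple linear regression (probability-of-F entry
  .05, removal .10) with standardized coefficients;
* Bonferroni-corrected Pearson correlation matrices;
* test–retest "relative change": the per-listener mean |run 1 − run k|.

Computation is delegated to pandas/statsmodels/pingouin; this module owns
the study-specific arithmetic (per-listener release, count identities,
selection logic) and the report containers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm

from .exceptions import DegenerateDesignError, SchemaError
from .session import SessionTable

__all__ = [
    "summarize",
    "grand_means",
    "relative_change",
    "stepwise_regression",
    "rm_anova",
    "correlation_matrix",
    "bonferroni_critical_p",
    "RegressionReport",
    "AnovaReport",
    "ReliabilityReport",
    "CorrelationReport",
]

logger = logging.getLogger(__name__)

PREDICTORS = ["age", "pta_standard", "pta_hf"]


# ---------------------------------------------------------------------------
# summaries


def summarize(sessions: SessionTable) -> pd.DataFrame:
    """Condition × run summary: threshold mean/SD, release mean/SD, n.

    Release is computed per listener per run (colocated − separated) and then
    averaged, so the mean-release column obeys the difference-of-means
    identity with the threshold columns.
    """
    th = sessions.thresholds
    summary = (
        th.groupby(["test", "separation_deg", "run"])
        .agg(
            mean_threshold=("threshold_db", "mean"),
            sd_threshold=("threshold_db", "std"),
            n=("threshold_db", "size"),
        )
        .reset_index()
    )
    srm = sessions.srm_table()
    if len(srm):
        srm_summary = (
            srm.groupby(["test", "separation_deg", "run"])
            .agg(mean_srm=("srm_db", "mean"), sd_srm=("srm_db", "std"))
            .reset_index()
        )
        summary = summary.merge(
            srm_summary, on=["test", "separation_deg", "run"], how="left"
        )
    else:
        summary["mean_srm"] = np.nan
        summary["sd_srm"] = np.nan
    return summary.sort_values(["test", "separation_deg", "run"]).reset_index(drop=True)


def grand_means(
    summary: pd.DataFrame, test: str, separation_deg: int
) -> dict[str, float]:
    """Unweighted across-run means for one test × separation cell.

    Returns ``mean_threshold`` and (for separated conditions) ``mean_srm``.
    """
    cell = summary[
        (summary.test == test) & (summary.separation_deg == separation_deg)
    ]
    if cell.empty:
        raise SchemaError(f"no rows for {test} at {separation_deg}° in summary")
    out = {"mean_threshold": float(cell.mean_threshold.mean())}
    if separation_deg != 0 and cell.mean_srm.notna().any():
        out["mean_srm"] = float(cell.mean_srm.mean())
    return out


# ---------------------------------------------------------------------------
# reliability


@dataclass(frozen=True)
class ReliabilityReport:
    """Relative change = per-listener mean |run1 − run k|, k = 2..K."""

    per_listener: pd.Series  # indexed by listener_id
    group_mean: float
    group_sd: float
    n_listeners: int
    n_excluded: int


def relative_change(run_matrix: pd.DataFrame) -> ReliabilityReport:
    """Test–retest relative change from a listener × run threshold matrix.

    ``run_matrix`` has one row per listener and one column per run (the first
    column is run 1).  Listeners with any missing run are excluded with a
    logged warning.
    """
    if run_matrix.shape[1] < 2:
        raise SchemaError("relative change needs at least two runs")
    complete = run_matrix.dropna()
    n_excluded = len(run_matrix) - len(complete)
    if n_excluded:
        logger.warning(
            "relative_change: excluded %d listener(s) with missing runs", n_excluded
        )
    if complete.empty:
        raise SchemaError("no listener has a complete set of runs")
    first = complete.iloc[:, 0]
    rest = complete.iloc[:, 1:]
    per_listener = rest.sub(first, axis=0).abs().mean(axis=1)
    return ReliabilityReport(
        per_listener=per_listener,
        group_mean=float(per_listener.mean()),
        group_sd=float(per_listener.std()),
        n_listeners=len(complete),
        n_excluded=n_excluded,
    )


def run_matrix(
    sessions: SessionTable, test: str, separation_deg: int, value: str = "threshold_db"
) -> pd.DataFrame:
    """Pivot one condition to a listener × run matrix (columns sorted by run)."""
    if value == "srm_db":
        th = sessions.srm_table()
    else:
        th = sessions.thresholds
    sub = th[(th.test == test) & (th.separation_deg == separation_deg)]
    mat = sub.pivot(index="listener_id", columns="run", values=value)
    return mat[sorted(mat.columns)]


# ---------------------------------------------------------------------------
# stepwise regression


@dataclass(frozen=True)
class PredictorStats:
    name: str
    selected: bool
    std_coefficient: float
    p_value: float


@dataclass(frozen=True)
class RegressionReport:
    """Stepwise selection outcome in the layout of a standard regression table.

    ``predictors`` covers every candidate: selected ones carry their final
    standardized coefficient; excluded ones carry their "beta-in" — the
    standardized coefficient and p-value they would have if added to the
    selected model.
    """

    response: str
    selected: tuple[str, ...]
    predictors: tuple[PredictorStats, ...]
    adjusted_r2: float
    r2: float
    f_statistic: float
    df_model: int
    df_resid: int
    model_p: float

    def coefficient(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


def _zscore(a: np.ndarray, what: str) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDesignError(f"predictor/response {what!r} is constant")
    return (a - a.mean()) / sd


def _fit(z_y: np.ndarray, Z: np.ndarray):
    X = sm.add_constant(Z) if Z.size else np.ones((len(z_y), 1))
    return sm.OLS(z_y, X).fit()


def stepwise_regression(
    response,
    covariates: pd.DataFrame,
    *,
    response_label: str = "response",
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> RegressionReport:
    """SPSS-style stepwise OLS on z-scored response and predictors.

    Forward step: among predictors not in the model, enter the one with the
    smallest partial-F p-value if it is below ``entry_p``.  Backward step:
    remove any in-model predictor whose p-value exceeds ``removal_p``.
    Iterate to a fixed point.  Standardization makes the reported
    coefficients "standard regression coefficients", invariant to affine
    rescaling of the inputs.
    """
    y = np.asarray(response, dtype=float)
    names = list(covariates.columns)
    if len(y) != len(covariates):
        raise SchemaError("response and covariates have different lengths")
    if len(y) <= len(names) + 1:
        raise DegenerateDesignError(
            f"n={len(y)} too small for {len(names)} candidate predictors"
        )
    z_y = _zscore(y, response_label)
    Z = {c: _zscore(np.asarray(covariates[c], dtype=float), c) for c in names}

    selected: list[str] = []
    seen_states: set[tuple[str, ...]] = set()
    while True:
        state = tuple(sorted(selected))
        if state in seen_states:
            break  # guard against entry/removal cycling on degenerate data
        seen_states.add(state)
        changed = False
        # forward entry — skipped once the model already fits perfectly
        # (no residual variance left for another predictor to explain)
        saturated = (
            bool(selected)
            and _fit(z_y, np.column_stack([Z[v] for v in selected])).rsquared
            > 1 - 1e-10
        )
        candidates = [] if saturated else [c for c in names if c not in selected]
        best: tuple[float, str] | None = None
        for c in candidates:
            fit = _fit(z_y, np.column_stack([Z[v] for v in selected + [c]]))
            p = float(fit.pvalues[-1])
            if math.isnan(p) and fit.rsquared > 1 - 1e-12:
                p = 0.0  # perfect fit: zero residual variance degenerates the t test
            if not math.isnan(p) and (best is None or p < best[0]):
                best = (p, c)
        if best is not None and best[0] < entry_p:
            selected.append(best[1])
            changed = True
        # backward removal
        while len(selected):
            fit = _fit(z_y, np.column_stack([Z[v] for v in selected]))
            pvals = dict(zip(selected, fit.pvalues[1:]))
            worst = max(selected, key=lambda v: pvals[v])
            if pvals[worst] > removal_p:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        final = _fit(z_y, np.column_stack([Z[v] for v in selected]))
        coef = dict(zip(selected, final.params[1:]))
        pval = dict(zip(selected, final.pvalues[1:]))
        adjusted_r2 = float(final.rsquared_adj)
        r2 = float(final.rsquared)
        f_stat = float(final.fvalue)
        model_p = float(final.f_pvalue)
        df_model = int(final.df_model)
        df_resid = int(final.df_resid)
    else:
        coef, pval = {}, {}
        adjusted_r2, r2 = 0.0, 0.0
        f_stat, model_p = float("nan"), float("nan")
        df_model, df_resid = 0, len(y) - 1

    stats = []
    for name in names:
        if name in selected:
            stats.append(
                PredictorStats(name, True, float(coef[name]), float(pval[name]))
            )
        else:
            # beta-in: the coefficient the predictor would take if entered
            fit = _fit(z_y, np.column_stack([Z[v] for v in selected + [name]]))
            stats.append(
                PredictorStats(
                    name, False, float(fit.params[-1]), float(fit.pvalues[-1])
                )
            )
    return RegressionReport(
        response=response_label,
        selected=tuple(selected),
        predictors=tuple(stats),
        adjusted_r2=adjusted_r2,
        r2=r2,
        f_statistic=f_stat,
        df_model=df_model,
        df_resid=df_resid,
        model_p=model_p,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    f_statistic: float
    df1: float
    df2: float
    epsilon: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaReport:
    effects: tuple[AnovaEffect, ...]

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] | str,
    subject: str,
) -> AnovaReport:
    """Within-subject ANOVA with Greenhouse–Geisser correction.

    Requires a complete, balanced design (exactly one observation per
    subject × cell); missing or duplicated cells raise
    :class:`DegenerateDesignError` rather than being imputed.  Degrees of
    freedom are multiplied by the GG epsilon (epsilon is exactly 1 for a
    two-level factor, where sphericity holds trivially); effect size is
    partial eta-squared, SS_effect / (SS_effect + SS_error).
    """
    within_list = [within] if isinstance(within, str) else list(within)
    counts = data.groupby([subject, *within_list], observed=True)[dv].size()
    if (counts != 1).any():
        raise DegenerateDesignError(
            "design is not complete/balanced: each subject needs exactly one "
            "observation per within-cell"
        )
    n_cells = int(np.prod([data[w].nunique() for w in within_list]))
    per_subject = data.groupby(subject, observed=True)[dv].size()
    if (per_subject != n_cells).any():
        raise DegenerateDesignError("some subjects are missing within-cells")

    aov = pg.rm_anova(
        data=data,
        dv=dv,
        within=within_list if len(within_list) > 1 else within_list[0],
        subject=subject,
        correction=True,
        detailed=True,
    )
    effects = []
    for _, row in aov.iterrows():
        if row["Source"] in ("Error", "Residual"):
            continue
        df1 = float(row.get("ddof1", row.get("DF", np.nan)))
        df2 = float(row["ddof2"]) if "ddof2" in row else np.nan
        if math.isnan(df2):
            # one-way detailed output: error df on the Error row
            err = aov[aov["Source"] == "Error"]
            df2 = float(err["DF"].iloc[0])
        eps = float(row["eps"]) if not pd.isna(row["eps"]) else 1.0
        F = float(row["F"])
        p_gg = float(row.get("p_GG_corr", row.get("p_unc", np.nan)))
        if math.isnan(p_gg):
            p_gg = float(row["p_unc"])
        # partial eta² from the F identity: SSe/(SSe+SSerr) = F·df1/(F·df1+df2)
        np2 = F * df1 / (F * df1 + df2)
        effects.append(
            AnovaEffect(
                effect=str(row["Source"]),
                f_statistic=F,
                df1=df1,
                df2=df2,
                epsilon=eps,
                df1_gg=eps * df1,
                df2_gg=eps * df2,
                p_gg=p_gg,
                partial_eta_sq=float(np2),
            )
        )
    return AnovaReport(effects=tuple(effects))


# ---------------------------------------------------------------------------
# correlations


def bonferroni_critical_p(alpha: float, m: int) -> float:
    """Family-wise critical p for ``m`` comparisons: alpha / m."""
    if m < 1:
        raise SchemaError("number of comparisons must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    critical_p: float
    significant: pd.DataFrame  # boolean, p < critical_p
    undefined: tuple[str, ...]  # constant variables
    n_correlations: int


def correlation_matrix(
    variables: pd.DataFrame,
    *,
    alpha: float = 0.05,
    n_comparisons: Optional[int] = None,
) -> CorrelationReport:
    """Pearson correlations over all variable pairs with a Bonferroni criterion.

    ``n_comparisons`` defaults to the number of distinct pairs.  Constant
    variables are reported in ``undefined`` and their rows/columns carry NaN
    instead of propagating silently.
    """
    from scipy import stats

    cols = list(variables.columns)
    if len(variables) < 3:
        raise SchemaError("correlations need at least 3 observations")
    constant = tuple(
        c for c in cols if np.asarray(variables[c], dtype=float).std(ddof=1) == 0
    )
    k = len(cols)
    m = n_comparisons if n_comparisons is not None else k * (k - 1) // 2
    crit = bonferroni_critical_p(alpha, m)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cols[i], cols[j]
            if a in constant or b in constant:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(
                    np.asarray(variables[a], dtype=float),
                    np.asarray(variables[b], dtype=float),
                )
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    for c in constant:
        r.loc[c, c] = np.nan
    sig = p < crit
    np.fill_diagonal(sig.values, False)
    return CorrelationReport(
        r=r,
        p=p,
        critical_p=crit,
        significant=sig,
        undefined=constant,
        n_correlations=m,
    )
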