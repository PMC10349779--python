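"""Sex-stratified regression layer with multiplicity control.

Simple linear regressions report the adjusted R², the standardized slope
(which equals the Pearson correlation for simple OLS) and the two-sided
slope p-value.  Multiple regressions adjust for the configured
confounder set and report the exposure's standardized coefficient.
P-values are adjusted per table and stratum by Benjamini-Hochberg FDR
(default) or the Hochberg step-up FWER procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, DegenerateInputError, InputError

LOG10_OUTCOMES = ("triglycerides", "total_chol", "hdl", "ldl", "homa_ir")

#: exposures anchored on the midsleep point; their adjusted models use
#: sleep duration instead of the midsleep point as the sleep confounder
#: (adjusting an exposure for its own ingredient is avoided).
MIDSLEEP_ANCHORED = ("msp_to_first", "last_to_msp")


@dataclass
class AssociationResult:
    """One exposure x outcome regression row."""

    exposure: str
    outcome: str
    stratum: str
    n: int
    adj_r2: float
    beta_std: float
    p: float
    p_adj: float | None = None
    adjusted_for: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["adjusted_for"] = ";".join(self.adjusted_for)
        return d


def transform_outcomes(panel: pd.DataFrame, variables=LOG10_OUTCOMES) -> pd.DataFrame:
    """Replace skewed outcome columns by their log10 values for analysis.

    Nonpositive values are set missing (excluded from that outcome)
    rather than transformed.  Mean BP and the risk score are left
    untouched.
    """
    out = panel.copy()
    for var in variables:
        if var not in out.columns:
            continue
        x = out[var].astype(float)
        out[var] = np.where(x > 0, np.log10(np.where(x > 0, x, 1.0)), np.nan)
    out.attrs["log10_transformed"] = list(variables)
    return out


def simple_regression(x, y, exposure="x", outcome="y", stratum="all") -> AssociationResult:
    """OLS of y on x: standardized slope, adjusted R², two-sided slope p.

    beta_std = slope * SD(x)/SD(y), identical to the Pearson r;
    adj_r2 = 1 - (1 - R²)(n-1)/(n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"{exposure} vs {outcome}: need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(f"{exposure} vs {outcome}: zero variance input")
    fit = stats.linregress(x, y)
    beta_std = fit.slope * np.std(x, ddof=1) / np.std(y, ddof=1)
    r2 = fit.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AssociationResult(
        exposure=exposure,
        outcome=outcome,
        stratum=stratum,
        n=n,
        adj_r2=float(adj_r2),
        beta_std=float(beta_std),
        p=float(fit.pvalue),
    )


def _name_collinear(X: pd.DataFrame) -> list[str]:
    """Greedy identification of columns involved in a rank deficiency."""
    offenders = []
    kept: list[str] = []
    for col in X.columns:
        trial = X[kept + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            offenders.append(col)
        else:
            kept.append(col)
    return offenders


def multiple_regression(
    y,
    x,
    covariates: pd.DataFrame,
    exposure="x",
    outcome="y",
    stratum="all",
) -> AssociationResult:
    """OLS of y on exposure + covariates; reports the exposure's
    standardized coefficient, the model adjusted R² and the exposure's
    two-sided p-value.

    Constant covariate columns are dropped (they are absorbed by the
    intercept); a rank-deficient design raises
    :class:`CollinearityError` naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cov = covariates.reset_index(drop=True).astype(float)
    ok = ~(np.isnan(y) | np.isnan(x) | cov.isna().any(axis=1).to_numpy())
    y, x, cov = y[ok], x[ok], cov.loc[ok]
    cov = cov.loc[:, cov.std(ddof=0) > 0]
    n = y.size
    if n < len(cov.columns) + 3:
        raise DegenerateInputError(
            f"{exposure} vs {outcome}: n={n} too small for {len(cov.columns)} covariates"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError(f"{exposure} vs {outcome}: zero variance input")
    X = pd.DataFrame({exposure: x}).join(cov.reset_index(drop=True))
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design for {exposure} vs {outcome}",
            columns=_name_collinear(design.drop(columns="const")),
        )
    fit = sm.OLS(y, design).fit()
    beta_std = fit.params[exposure] * np.std(x, ddof=1) / np.std(y, ddof=1)
    return AssociationResult(
        exposure=exposure,
        outcome=outcome,
        stratum=stratum,
        n=n,
        adj_r2=float(fit.rsquared_adj),
        beta_std=float(beta_std),
        p=float(fit.pvalues[exposure]),
        adjusted_for=list(cov.columns),
    )


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InputError("Welch's t requires at least 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def sex_comparison_anova(values, groups) -> tuple[float, float]:
    """One-way ANOVA across the sex groups; with two groups F equals the
    square of the pooled-variance t statistic."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise InputError("one-way ANOVA requires at least two groups")
    samples = [values[groups == lv] for lv in levels]
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Step-up multiplicity adjustment over one declared family.

    ``method``: "bh" (Benjamini-Hochberg FDR) or "hochberg" (step-up
    FWER).  Adjusted values are monotone in the sorted order and capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "hochberg": "simes-hochberg"}.get(method)
    if sm_method is None:
        raise InputError(f"unknown multiplicity method: {method!r}")
    return multipletests(p, method=sm_method)[1]


def association_table(
    df: pd.DataFrame,
    exposures: list[str],
    outcomes: list[str],
    strata=("all", "men", "women"),
    adjusted: bool = False,
    multiplicity: str = "bh",
    sleep_confounder_map: dict | None = None,
) -> pd.DataFrame:
    """Exposure x outcome regression grid, one multiplicity family per
    stratum (the family is the grid of one table within one stratum).

    ``df`` must already hold log10-transformed outcomes where
    applicable, plus covariate columns (``sex``, ``med_diet_score``,
    ``light_pa_min``, ``midsleep_week``, ``sleep_duration_week``,
    ``bmi``) when ``adjusted``.
    """
    stratum_frames = {
        "all": df,
        "men": df[df["sex"] == "man"],
        "women": df[df["sex"] == "woman"],
    }
    rows: list[AssociationResult] = []
    for stratum in strata:
        sub = stratum_frames[stratum]
        batch: list[AssociationResult] = []
        for outcome in outcomes:
            for exposure in exposures:
                if adjusted:
                    cov = _confounders(sub, exposure, outcome, stratum, sleep_confounder_map)
                    res = multiple_regression(
                        sub[outcome], sub[exposure], cov, exposure, outcome, stratum
                    )
                else:
                    res = simple_regression(
                        sub[exposure], sub[outcome], exposure, outcome, stratum
                    )
                batch.append(res)
        adj = adjust_pvalues([r.p for r in batch], method=multiplicity)
        for r, pa in zip(batch, adj):
            r.p_adj = float(pa)
        rows.extend(batch)
    out = pd.DataFrame([r.to_dict() for r in rows])
    out["significant"] = out["p"] < 0.05
    out["significant_adj"] = out["p_adj"] < 0.05
    return out


def _confounders(sub, exposure, outcome, stratum, sleep_map=None):
    """Confounder set: sex (pooled stratum only), Mediterranean diet
    pattern, light PA, midsleep point or sleep duration, and BMI."""
    sleep_map = sleep_map or {}
    default_sleep = (
        "sleep_duration_week" if exposure in MIDSLEEP_ANCHORED else "midsleep_week"
    )
    sleep_var = sleep_map.get(exposure, default_sleep)
    cols = {}
    if stratum == "all":
        cols["sex_man"] = (sub["sex"] == "man").astype(float)
    cols["med_diet_score"] = sub["med_diet_score"].astype(float)
    cols["light_pa_min"] = sub["light_pa_min"].astype(float)
    cols[sleep_var] = sub[sleep_var].astype(float)
    if outcome != "bmi":
        cols["bmi"] = sub["bmi"].astype(float)
    return pd.DataFrame(cols)


def table_to_wide(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long association table into the published wide shape
    (rows = outcome x exposure, columns = stratum x statistic)."""
    wide = long_table.pivot_table(
        index=["outcome", "exposure"],
        columns="stratum",
        values=["n", "adj_r2", "beta_std", "p", "p_adj"],
        sort=False,
    )
    wide.columns = [f"{stat}_{stratum}" for stat, stratum in wide.columns]
    return wide.reset_index()
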