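"""Group comparisons, dependent-correlation tests, and adjusted models.

The layer mirrors a typical observational-study analysis: automatic test
selection with Bonferroni correction per table family, Pearson/Spearman
correlations, Williams' test for the difference of two dependent
correlations sharing one variable, ordinary least-squares models with a
fixed confounder set (age, sex, BMI, diabetes, smoking history),
variance inflation factors, Hommel adjustment across a model family, and
an outlier/influence sensitivity re-run.

Standard tests come from scipy/statsmodels; Williams' test is implemented
here (no installed package provides it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import (OLSInfluence,
                                                  variance_inflation_factor)

from .errors import ConfigurationError, DegenerateDesign, DegenerateInput

DEFAULT_CONFOUNDERS = ("age", "sex", "bmi", "diabetes", "smoking_history")


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

@dataclass
class VariableSpec:
    name: str
    kind: str                   # "continuous" | "categorical"
    test: Optional[str] = None  # force a specific test


@dataclass
class GroupComparison:
    variable: str
    summaries: Dict[str, str]
    test: str                   # welch_t | wilcoxon | kruskal_wallis | chi_squared | fisher_exact
    p: float
    q: float = float("nan")     # Bonferroni over the table family


def _summarise_continuous(values: pd.Series) -> str:
    return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"


def _summarise_categorical(values: pd.Series) -> str:
    n = int(values.sum())
    return f"{n} ({100.0 * n / max(len(values), 1):.0f}%)"


def _choose_continuous_test(groups: List[np.ndarray], alpha: float = 0.05) -> str:
    if len(groups) > 2:
        return "kruskal_wallis"
    resid = np.concatenate([g - g.mean() for g in groups])
    if len(resid) >= 3 and np.ptp(resid) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(resid).pvalue < alpha:
                return "wilcoxon"
    return "welch_t"


def compare_groups(table: pd.DataFrame, grouping: str,
                   variables: Sequence[VariableSpec],
                   normality_alpha: float = 0.05) -> List[GroupComparison]:
    """Compare each variable between groups; Bonferroni Q over the family.

    Continuous variables: Welch's t for two groups (Wilcoxon rank-sum if a
    Shapiro-Wilk check on pooled residuals rejects normality),
    Kruskal-Wallis for more than two.  Categorical: chi-squared, or
    Fisher's exact when any expected 2x2 cell count is below 5.
    """
    levels = [g for g in pd.unique(table[grouping].dropna())]
    if len(levels) < 2:
        raise ConfigurationError("grouping must have >= 2 non-empty groups")
    results: List[GroupComparison] = []
    for spec in variables:
        if spec.name not in table.columns:
            raise ConfigurationError(f"variable not in table: {spec.name}")
        col = table[[spec.name, grouping]].dropna()
        groups = [col.loc[col[grouping] == lev, spec.name] for lev in levels]
        if spec.kind == "continuous":
            arrs = [np.asarray(g, dtype=float) for g in groups]
            test = spec.test or _choose_continuous_test(arrs, normality_alpha)
            if all(np.ptp(a) == 0 for a in arrs) and len({a[0] for a in arrs if len(a)}) <= 1:
                p = 1.0
            elif test == "welch_t":
                p = float(sps.ttest_ind(arrs[0], arrs[1], equal_var=False).pvalue)
            elif test == "wilcoxon":
                p = float(sps.mannwhitneyu(arrs[0], arrs[1],
                                           alternative="two-sided").pvalue)
            else:
                p = float(sps.kruskal(*arrs).pvalue)
            summaries = {str(lev): _summarise_continuous(g)
                         for lev, g in zip(levels, groups)}
        else:
            contingency = pd.crosstab(col[grouping], col[spec.name])
            test = spec.test
            if test is None:
                expected = sps.chi2_contingency(contingency.values,
                                                correction=False)[3]
                test = ("fisher_exact"
                        if contingency.shape == (2, 2) and expected.min() < 5
                        else "chi_squared")
            if test == "fisher_exact":
                p = float(sps.fisher_exact(contingency.values)[1])
            else:
                p = float(sps.chi2_contingency(contingency.values)[1])
            summaries = {str(lev): _summarise_categorical(g.astype(bool))
                         for lev, g in zip(levels, groups)}
        results.append(GroupComparison(variable=spec.name, summaries=summaries,
                                       test=test, p=p))
    m = len(results)
    for r in results:
        r.q = min(1.0, m * r.p)
    return results


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def correlate(x, y, method: str = "pearson") -> Tuple[float, float, int]:
    """Pairwise-complete correlation; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ConfigurationError(f"unknown correlation method: {method}")
    return float(r), float(p), int(ok.sum())


def williams_test(r12: float, r13: float, r23: float, n: int) -> Tuple[float, int, float]:
    """Williams' test for H0: rho12 = rho13 with variable 1 shared.

    Uses the determinant form of Williams' statistic

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r23)^3 ) )

    with |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 and
    rbar = (r12 + r13)/2, referred to Student's t with n-3 df.
    """
    if n < 4:
        raise DegenerateInput("n must be >= 4")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise DegenerateInput("correlations must lie strictly in (-1, 1)")
    det = 1.0 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2.0 * r12 * r13 * r23
    if det <= -1e-12:
        raise DegenerateInput("correlation matrix is not positive semi-definite")
    det = max(det, 0.0)
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * (n - 1) / (n - 3) * det + rbar ** 2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise DegenerateInput("degenerate correlation structure")
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    df = n - 3
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p


def correlation_difference(r12: float, r13: float) -> Tuple[float, Optional[float]]:
    """Absolute and relative (%) difference of two correlation magnitudes."""
    absolute = abs(r12) - abs(r13)
    relative = None if r13 == 0 else absolute / abs(r13) * 100.0
    return absolute, relative


# --------------------------------------------------------------------------
# multiplicity adjustment
# --------------------------------------------------------------------------

def bonferroni_adjust(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


def hommel_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Hommel (1988) adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 1:
        return p.copy()
    return multipletests(p, method="hommel")[1]


# --------------------------------------------------------------------------
# adjusted regressions
# --------------------------------------------------------------------------

@dataclass
class AdjustedModel:
    outcome: str
    exposure: str
    confounders: Tuple[str, ...]
    n: int
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    vif: Dict[str, float]
    diagnostics: Dict[str, float]
    hommel_adjusted_p: Optional[float] = None
    removed_rows: Optional[List] = None
    results: object = field(default=None, repr=False)

    @property
    def exposure_coef(self) -> float:
        return float(self.params[self.exposure])

    @property
    def exposure_p(self) -> float:
        return float(self.pvalues[self.exposure])


def _design(table: pd.DataFrame, outcome: str, exposure: str,
            confounders: Sequence[str]) -> Tuple[pd.Series, pd.DataFrame]:
    cols = [outcome, exposure, *confounders]
    df = table[cols].copy()
    for c in cols:
        if df[c].dtype == object:
            uniq = sorted(df[c].dropna().unique())
            if len(uniq) > 2:
                raise ConfigurationError(f"cannot encode multi-level column {c}")
            df[c] = (df[c] == uniq[-1]).astype(float)
        elif df[c].dtype == bool:
            df[c] = df[c].astype(float)
    df = df.dropna().astype(float)
    y = df[outcome]
    X = df[[exposure, *confounders]]
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise DegenerateDesign(const_cols)
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.values) < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise DegenerateDesign([corr.index[i], corr.columns[j]])
    return y, Xc


def adjusted_regression(table: pd.DataFrame, outcome: str,
                        exposure: str = "osi",
                        confounders: Sequence[str] = DEFAULT_CONFOUNDERS
                        ) -> AdjustedModel:
    """OLS of outcome on exposure plus the fixed confounder set.

    Emits per-term variance inflation factors and residual diagnostics
    (Shapiro-Wilk on residuals, maximum Cook's distance and externally
    studentized residual).
    """
    y, Xc = _design(table, outcome, exposure, confounders)
    if len(y) <= Xc.shape[1] + 2:
        raise DegenerateDesign(["insufficient observations"])
    res = sm.OLS(y, Xc).fit()
    vif = {c: float(variance_inflation_factor(Xc.values, i))
           for i, c in enumerate(Xc.columns) if c != "const"}
    infl = OLSInfluence(res)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(sps.shapiro(res.resid).pvalue) if len(y) >= 3 else np.nan
    diagnostics = {
        "resid_shapiro_p": shapiro_p,
        "max_cooks_distance": float(np.max(infl.cooks_distance[0])),
        "max_abs_studentized": float(np.max(np.abs(infl.resid_studentized_external))),
        "r_squared": float(res.rsquared),
    }
    return AdjustedModel(
        outcome=outcome, exposure=exposure, confounders=tuple(confounders),
        n=int(len(y)), params=res.params, conf_int=res.conf_int(),
        pvalues=res.pvalues, vif=vif, diagnostics=diagnostics, results=res)


def adjust_family(models: Sequence[AdjustedModel]) -> List[AdjustedModel]:
    """Hommel-adjust the exposure p-values across a family of models."""
    adj = hommel_adjust([m.exposure_p for m in models])
    for m, a in zip(models, adj):
        m.hommel_adjusted_p = float(a)
    return list(models)


def sensitivity_rerun(table: pd.DataFrame, outcome: str,
                      exposure: str = "osi",
                      confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
                      cooks_factor: float = 4.0,
                      studentized_max: float = 3.0
                      ) -> Tuple[AdjustedModel, AdjustedModel]:
    """Refit after removing influential observations.

    Removal rule: Cook's distance > ``cooks_factor``/n or externally
    studentized residual beyond ``studentized_max`` in magnitude, judged
    on the base fit; deterministic for fixed data.
    """
    base = adjusted_regression(table, outcome, exposure, confounders)
    infl = OLSInfluence(base.results)
    cooks = infl.cooks_distance[0]
    student = infl.resid_studentized_external
    drop = (cooks > cooks_factor / base.n) | (np.abs(student) > studentized_max)
    used_index = base.results.model.data.row_labels
    removed = [used_index[i] for i in np.flatnonzero(drop)]
    if len(removed) > 0.2 * base.n:
        warnings.warn(f"sensitivity trim removed {len(removed)}/{base.n} rows",
                      stacklevel=2)
    trimmed_table = table.drop(index=removed)
    # a rare binary confounder can become constant once its carriers are
    # trimmed; refit without it rather than failing
    kept = [c for c in confounders
            if trimmed_table[c].dropna().nunique() > 1]
    trimmed = adjusted_regression(trimmed_table, outcome, exposure, kept)
    base.removed_rows = []
    trimmed.removed_rows = removed
    return base, trimmed
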