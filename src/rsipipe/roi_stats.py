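"""ROI regression analysis: moderation models, Rubin pooling, FDR, effect sizes.

For each diffusion metric, region of interest and anthropometric predictor,
the analysis fits the moderation model

    metric ~ predictor * group + age + sex + parent_education + movement   (1)

on every imputed dataset, pools the interaction term with Rubin's rules, and
Benjamini-Hochberg-corrects the interaction p-values across ROIs within the
metric.  If no interaction survives, the simplified model

    metric ~ predictor + group + age + sex + parent_education + movement   (2)

is fitted and the pooled main effect of the predictor is reported, again with
within-metric FDR across ROIs.  Coefficients are standardized (outcome and
continuous predictors z-scored; 0/1 binaries left as is) and accompanied by
the semipartial correlation r_sp = t * sqrt(1 - R^2) / sqrt(df_resid).

The module also houses the anthropometric derivations (BMI, CDC-style LMS
percentile status) and Table-1-style group contrasts (pooled-SD t test,
Cohen's d with CI, and the continuity-corrected chi-square / phi for binary
measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imputation import ImputationSet, PooledResult, pool_rubin

__all__ = [
    "ModelSpec",
    "standardize",
    "fit_ols",
    "semipartial_r",
    "fdr_bh",
    "run_roi_pipeline",
    "bmi",
    "lms_zscore",
    "bmi_status",
    "group_compare",
    "group_compare_summary",
    "proportion_compare",
    "DEFAULT_ROIS",
    "DEFAULT_METRICS",
    "DEFAULT_PREDICTORS",
]

DEFAULT_COVARIATES = ("age", "sex", "parent_education", "movement")
DEFAULT_METRICS = ("rni", "rnd", "rnt", "hnt")
#: eight hemisphere-averaged subcortical ROIs plus left/right anterior insula
DEFAULT_ROIS = (
    "nacc", "putamen", "caudate", "pallidum", "ventral_dc",
    "thalamus", "amygdala", "hippocampus",
    "left_anterior_insula", "right_anterior_insula",
)
DEFAULT_PREDICTORS = ("bmi", "body_fat", "waist", "obesity")


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome, main predictor, group moderator, covariates."""

    outcome: str
    predictor: str
    moderator: str = "group"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_interaction: bool = True


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Z-score continuous numeric columns; leave 0/1 binaries untouched.

    ``columns`` restricts the transformation; by default every numeric column
    with more than two distinct values is standardized.  The per-column
    (mean, sd) pairs are recorded in ``result.attrs['standardization']``.
    Idempotent: standardizing a standardized table is a no-op up to rounding.
    Raises on zero-variance continuous columns.
    """
    out = table.copy()
    params = {}
    if columns is None:
        columns = [
            c for c in table.select_dtypes(include=[np.number]).columns
            if table[c].dropna().nunique() > 2
        ]
    for c in columns:
        x = out[c].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - mu) / sd
        params[c] = (mu, sd)
    out.attrs["standardization"] = params
    return out


def _design_matrix(table: pd.DataFrame, spec: ModelSpec):
    terms = [spec.predictor, spec.moderator, *spec.covariates]
    cols = [table[t].to_numpy(dtype=float) for t in terms]
    if spec.include_interaction:
        inter = f"{spec.predictor}:{spec.moderator}"
        cols.append(
            table[spec.predictor].to_numpy(float) * table[spec.moderator].to_numpy(float)
        )
        terms.append(inter)
    x = np.column_stack([np.ones(len(table))] + cols)
    return x, ["intercept"] + terms


def fit_ols(table: pd.DataFrame, spec: ModelSpec) -> dict:
    """OLS fit of one model on one completed dataset.

    Returns ``{'terms': {name: (estimate, variance)}, 'df_resid': ...,
    'r2': ...}``.  Raises on rank deficiency, naming the collinear terms.
    """
    if table[spec.outcome].isna().any():
        raise ValueError("fit_ols requires a complete table (impute first)")
    x, names = _design_matrix(table, spec)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify columns not adding rank
        bad = []
        rank = 0
        for j in range(x.shape[1]):
            r = np.linalg.matrix_rank(x[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    if len(table) <= x.shape[1]:
        raise ValueError("fewer observations than model terms")
    y = table[spec.outcome].to_numpy(dtype=float)
    res = sm.OLS(y, x).fit()
    terms = {
        name: (float(res.params[j]), float(res.bse[j] ** 2))
        for j, name in enumerate(names)
    }
    return {"terms": terms, "df_resid": float(res.df_resid), "r2": float(res.rsquared)}


def semipartial_r(t_stat: float, r2_full: float, df_resid: float) -> float:
    """Semipartial correlation of one predictor from its t statistic.

    r_sp = sign(t) * |t| * sqrt(1 - R^2_full) / sqrt(df_resid): the
    correlation between the outcome and the part of the predictor unique
    among the model terms.  Equals Pearson r in simple regression.
    """
    if df_resid <= 0:
        raise ValueError("df_resid must be positive")
    if not (0 <= r2_full < 1):
        raise ValueError("r2_full must be in [0, 1)")
    return float(t_stat * np.sqrt(1.0 - r2_full) / np.sqrt(df_resid))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pool_term(
    tables: list[pd.DataFrame], spec: ModelSpec, term: str
) -> tuple[PooledResult, float, float]:
    """Fit ``spec`` on each table, Rubin-pool ``term``; also mean R2 and df."""
    fits = [fit_ols(t, spec) for t in tables]
    est = [f["terms"][term][0] for f in fits]
    var = [f["terms"][term][1] for f in fits]
    df_com = fits[0]["df_resid"]
    pooled = pool_rubin(est, var, df_complete=df_com)
    r2 = float(np.mean([f["r2"] for f in fits]))
    return pooled, r2, df_com


def run_roi_pipeline(
    imputations: ImputationSet,
    metrics=DEFAULT_METRICS,
    rois=DEFAULT_ROIS,
    predictors=DEFAULT_PREDICTORS,
    covariates=DEFAULT_COVARIATES,
    moderator: str = "group",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderation-then-reduction ROI analysis over all imputed datasets.

    Outcome columns are named ``<metric>_<roi>``.  Within each metric and
    predictor: the interaction of Model 1 is pooled per ROI and FDR-corrected
    across ROIs; when no interaction survives at ``alpha`` the interaction is
    dropped and the pooled Model 2 main effect is reported (with its own
    within-metric FDR across ROIs), otherwise the Model 1 rows are reported.

    Returns ``(all_rows, survived)`` where ``survived`` keeps rows with
    FDR-adjusted main-effect p < alpha.
    """
    # z-score outcome and continuous predictors once per completed dataset
    tables = []
    for t in imputations.completed_tables:
        cont = [c for c in t.select_dtypes(include=[np.number]).columns
                if t[c].dropna().nunique() > 2]
        tables.append(standardize(t, columns=cont))

    rows = []
    for metric in metrics:
        outcomes = [f"{metric}_{roi}" for roi in rois]
        missing = [c for c in outcomes if c not in tables[0].columns]
        if missing:
            raise ValueError(f"outcome columns absent from table: {missing}")
        for predictor in predictors:
            spec1 = [
                ModelSpec(out, predictor, moderator, tuple(covariates), True)
                for out in outcomes
            ]
            inter_name = f"{predictor}:{moderator}"
            inter = [_pool_term(tables, s, inter_name) for s in spec1]
            inter_fdr = fdr_bh([p.p for p, _, _ in inter])
            keep_interaction = bool(np.any(inter_fdr < alpha))

            for i, roi in enumerate(rois):
                if keep_interaction:
                    pooled, r2, df_com = _pool_term(tables, spec1[i], predictor)
                    model_used = 1
                else:
                    spec2 = ModelSpec(
                        outcomes[i], predictor, moderator, tuple(covariates), False
                    )
                    pooled, r2, df_com = _pool_term(tables, spec2, predictor)
                    model_used = 2
                rows.append(
                    {
                        "metric": metric,
                        "roi": roi,
                        "predictor": predictor,
                        "model": model_used,
                        "beta": pooled.qbar,
                        "se": np.sqrt(pooled.t_total),
                        "t_stat": pooled.t_stat,
                        "p": pooled.p,
                        "ci_low": pooled.ci_low,
                        "ci_high": pooled.ci_high,
                        "df": pooled.df,
                        "r_sp": semipartial_r(pooled.t_stat, r2, df_com),
                        "interaction_p": inter[i][0].p,
                        "interaction_fdr_p": inter_fdr[i],
                    }
                )

    result = pd.DataFrame(rows)
    # FDR across ROIs within (metric, predictor) family
    result["fdr_p"] = np.nan
    for (_, _), idx in result.groupby(["metric", "predictor"]).groups.items():
        result.loc[idx, "fdr_p"] = fdr_bh(result.loc[idx, "p"].to_numpy())
    survived = result[result["fdr_p"] < alpha].reset_index(drop=True)
    return result, survived


# ---------------------------------------------------------------------------
# anthropometrics
# ---------------------------------------------------------------------------

def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by squared height (m)."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def lms_zscore(value: float, l: float, m: float, s: float) -> float:
    """Box-Cox (LMS) z-score: ((value/M)^L - 1)/(L S), or ln(value/M)/S at L=0."""
    if value <= 0 or m <= 0 or s <= 0:
        raise ValueError("value, M and S must be positive")
    if l == 0:
        return float(np.log(value / m) / s)
    return float(((value / m) ** l - 1.0) / (l * s))


def bmi_status(
    bmi_value: float,
    age: float | None = None,
    sex: int | None = None,
    lms_table: pd.DataFrame | None = None,
    cutoff_percentile: float = 85.0,
    reference: np.ndarray | None = None,
) -> bool:
    """Overweight/obese status from a growth reference or empirical sample.

    With an LMS reference table (columns ``age``, ``sex``, ``L``, ``M``,
    ``S``) the age/sex-matched row (linear interpolation in age within sex)
    converts BMI to a z-score and percentile; status is percentile >=
    ``cutoff_percentile``.  Without a table, ``reference`` must supply an
    empirical BMI distribution against which the percentile is computed.
    """
    if bmi_value <= 0:
        raise ValueError("BMI must be positive")
    if lms_table is not None:
        if age is None or sex is None:
            raise ValueError("age and sex are required with an LMS table")
        sub = lms_table[lms_table["sex"] == sex].sort_values("age")
        if sub.empty:
            raise ValueError(f"no LMS rows for sex={sex}")
        ages = sub["age"].to_numpy(dtype=float)
        if age < ages.min() or age > ages.max():
            raise ValueError(
                f"age {age} outside LMS table range [{ages.min()}, {ages.max()}]"
            )
        l, m, s = (
            float(np.interp(age, ages, sub[c].to_numpy(dtype=float)))
            for c in ("L", "M", "S")
        )
        z = lms_zscore(bmi_value, l, m, s)
        pct = 100.0 * stats.norm.cdf(z)
    elif reference is not None:
        ref = np.asarray(reference, dtype=float)
        pct = 100.0 * np.mean(ref <= bmi_value)
    else:
        raise ValueError("either lms_table or reference must be supplied")
    return bool(pct >= cutoff_percentile)


# ---------------------------------------------------------------------------
# group contrasts (Table-1 style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupContrast:
    t_stat: float
    p: float
    d: float
    d_ci: tuple[float, float]


@dataclass(frozen=True)
class BinaryContrast:
    chi2: float
    p: float
    phi: float


def group_compare_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> GroupContrast:
    """Pooled-SD two-sample contrast from summary statistics.

    Group A is the reference listed first (ADHD in the study); Cohen's
    d = (mean_b - mean_a) / pooled SD, so a higher first-group mean gives a
    negative d.  The d CI uses the normal approximation with
    Var(d) = (n_a + n_b)/(n_a n_b) + d^2 / (2 (n_a + n_b)).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    d = (mean_b - mean_a) / sp
    t = d * np.sqrt(n_a * n_b / (n_a + n_b))
    df = n_a + n_b - 2
    p = 2 * stats.t.sf(abs(t), df)
    var_d = (n_a + n_b) / (n_a * n_b) + d**2 / (2 * (n_a + n_b))
    half = 1.959963984540054 * np.sqrt(var_d)
    return GroupContrast(float(t), float(p), float(d), (float(d - half), float(d + half)))


def proportion_compare(k_a: int, n_a: int, k_b: int, n_b: int) -> BinaryContrast:
    """Yates continuity-corrected chi-square and phi for a 2x2 table."""
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    if np.any(table < 0) or n_a <= 0 or n_b <= 0:
        raise ValueError("invalid 2x2 counts")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    phi = float(np.sqrt(chi2 / table.sum()))
    return BinaryContrast(float(chi2), float(p), phi)


def group_compare(
    table: pd.DataFrame, measure: str, group_col: str = "group", ref_group=1
):
    """Group contrast on raw data; binary measures get the chi-square path.

    The reference group (``ref_group``, ADHD=1 by default) plays the role of
    group A in :func:`group_compare_summary`.
    """
    groups = table[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    other = [g for g in groups if g != ref_group][0]
    a = table.loc[table[group_col] == ref_group, measure].dropna()
    b = table.loc[table[group_col] == other, measure].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    values = table[measure].dropna().unique()
    if set(np.unique(values)).issubset({0, 1}):
        return proportion_compare(int(a.sum()), len(a), int(b.sum()), len(b))
    return group_compare_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )
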