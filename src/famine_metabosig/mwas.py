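"""Metabolome-wide association study with sibship-clustered GEE.

One linear model per biomarker regresses the standardized log
concentration on a famine-exposure indicator plus covariates, estimated
by Gaussian identity-link generalized estimating equations with an
exchangeable working correlation within sibships and robust (sandwich)
standard errors.  Multiple testing uses the effective number of
independent tests: the number of principal components explaining at
least 95% of biomarker variance, as the Bonferroni denominator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .preprocessing import LOG_SCALED, BiomarkerMatrix

__all__ = [
    "fit_gee",
    "run_mwas",
    "effective_tests",
    "bonferroni_threshold",
    "sensitivity_suite",
    "describe_cohort",
    "MAIN_COVARIATES",
]

MAIN_COVARIATES = ("age", "sex", "medication")


def _check_design(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns involved in the collinearity for the message
        bad = []
        cols = list(design.columns)
        for j in range(x.shape[1]):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(cols[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_gee(
    outcome: pd.Series | np.ndarray,
    design: pd.DataFrame,
    clusters: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Gaussian GEE with exchangeable working correlation.

    ``design`` must already contain an intercept column if one is
    wanted.  Returns a DataFrame indexed by coefficient name with
    columns beta, se (robust sandwich), p (two-sided Wald), ci_low,
    ci_high, n.
    """
    y = np.asarray(outcome, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant outcome")
    _check_design(design)
    groups = np.asarray(clusters)
    x = design.to_numpy(dtype=float)
    ols_beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    if np.max(np.abs(y - x @ ols_beta)) < 1e-12 * max(np.max(np.abs(y)), 1.0):
        # perfect fit: dispersion is 0 and the moment updates degenerate
        zeros = np.zeros_like(ols_beta)
        return pd.DataFrame(
            {"beta": ols_beta, "se": zeros, "p": zeros,
             "ci_low": ols_beta, "ci_high": ols_beta, "n": len(y)},
            index=list(design.columns),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y,
            design.to_numpy(dtype=float),
            groups=groups,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
    beta = res.params
    se = res.bse  # robust by default
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 0.0)
    ci = 1.959963984540054 * se
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": p,
            "ci_low": beta - ci,
            "ci_high": beta + ci,
            "n": len(y),
        },
        index=list(design.columns),
    )


def _design_matrix(
    cohort: pd.DataFrame,
    exposure_cols: list[str],
    covariates: list[str],
    interaction: tuple[str, str] | None = None,
) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(cohort))}
    for c in exposure_cols + list(covariates):
        cols[c] = cohort[c].astype(float).to_numpy()
    if interaction is not None:
        a, b = interaction
        cols[f"{a}:{b}"] = (
            cohort[a].astype(float) * cohort[b].astype(float)
        ).to_numpy()
    return pd.DataFrame(cols, index=cohort.index)


def run_mwas(
    matrix: BiomarkerMatrix,
    cohort: pd.DataFrame,
    exposure_col: str = "any_exposure",
    covariates: tuple[str, ...] = MAIN_COVARIATES,
    cluster_col: str = "sibship_id",
    alpha: float = 0.05,
    m_eff: int | None = None,
    model_tag: str = "main",
    biomarkers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-biomarker exposure association table (one GEE per biomarker).

    Rows whose model fails are recorded with NaN estimates rather than
    aborting the run.  ``m_eff`` defaults to
    ``effective_tests(matrix)``; significance is flagged at
    ``bonferroni_threshold(alpha, m_eff)``.
    """
    matrix._require_state(LOG_SCALED, "run_mwas")
    cohort = _aligned(cohort, matrix)
    if m_eff is None:
        m_eff = effective_tests(matrix)
    threshold = bonferroni_threshold(alpha, m_eff)
    design = _design_matrix(cohort, [exposure_col], list(covariates))
    clusters = cohort[cluster_col]
    rows = []
    for bm in biomarkers or matrix.biomarkers:
        row = {"biomarker": bm, "model": model_tag, "term": exposure_col}
        try:
            fit = fit_gee(matrix.values[bm], design, clusters)
            est = fit.loc[exposure_col]
            row.update(
                beta=est["beta"], se=est["se"], p=est["p"],
                ci_low=est["ci_low"], ci_high=est["ci_high"], n=int(est["n"]),
            )
            row["error"] = ""
        except Exception as exc:  # recorded, not fatal
            row.update(
                beta=np.nan, se=np.nan, p=np.nan,
                ci_low=np.nan, ci_high=np.nan, n=len(cohort), error=str(exc),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["m_eff"] = m_eff
    out["significant"] = out["p"] < threshold
    return out


def effective_tests(
    matrix: BiomarkerMatrix | pd.DataFrame, variance_threshold: float = 0.95
) -> int:
    """Effective number of independent tests via PCA.

    Smallest k such that the top-k principal components of the
    standardized biomarker matrix (correlation scale) explain at least
    ``variance_threshold`` of total variance.
    """
    values = matrix.values if isinstance(matrix, BiomarkerMatrix) else matrix
    if isinstance(matrix, BiomarkerMatrix):
        matrix._require_state(LOG_SCALED, "effective_tests")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 biomarkers")
    if values.isna().to_numpy().any():
        raise ValueError("missing values; impute or drop upstream")
    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance biomarker column")
    x = x / sd
    eigvals = np.linalg.eigvalsh(np.cov(x, rowvar=False))[::-1]
    eigvals = np.clip(eigvals, 0, None)
    cum = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return alpha / m


WINDOW_COLS = (
    "win_weeks_31_delivery",
    "win_weeks_21_30",
    "win_weeks_11_20",
    "win_weeks_1_10",
    "win_weeks_minus9_0",
)


def sensitivity_suite(
    matrix: BiomarkerMatrix,
    cohort: pd.DataFrame,
    targets: list[str],
    pgs: pd.DataFrame | None = None,
    exposure_col: str = "any_exposure",
    cluster_col: str = "sibship_id",
    alpha: float = 0.05,
    m_eff: int | None = None,
) -> pd.DataFrame:
    """Sensitivity models for a set of target biomarkers.

    Model tags: main; bmi / waist / t2d (main plus one extra covariate);
    pgs (main plus the biomarker's polygenic score, skipped with a
    warning for biomarkers without a configured score); sex_M / sex_F
    (sex-stratified); sex_interaction (pooled model with a
    sex-by-exposure product term, reporting that term); timing (the
    single exposure indicator replaced by the five gestational-window
    indicators, one row per window coefficient).
    """
    matrix._require_state(LOG_SCALED, "sensitivity_suite")
    unknown = [t for t in targets if t not in matrix.biomarkers]
    if unknown:
        raise ValueError(f"unknown target biomarkers: {unknown}")
    cohort = _aligned(cohort, matrix)
    if m_eff is None:
        m_eff = effective_tests(matrix)
    threshold = bonferroni_threshold(alpha, m_eff)
    base = list(MAIN_COVARIATES)
    frames = []

    def _run(sub_matrix, sub_cohort, covs, tag, bms, exposure=exposure_col):
        return run_mwas(
            sub_matrix, sub_cohort, exposure, tuple(covs), cluster_col,
            alpha, m_eff, tag, bms,
        )

    frames.append(_run(matrix, cohort, base, "main", targets))
    for extra, tag in (("bmi", "bmi"), ("waist", "waist"), ("t2d", "t2d")):
        if extra in cohort:
            frames.append(_run(matrix, cohort, base + [extra], tag, targets))
        else:
            warnings.warn(f"covariate {extra!r} missing; tag {tag!r} skipped")

    # PGS adjustment: per-biomarker score
    if pgs is not None:
        for bm in targets:
            if bm not in pgs.columns:
                warnings.warn(f"no polygenic score for {bm!r}; pgs tag skipped")
                continue
            c = cohort.copy()
            c["pgs"] = pgs[bm].reindex(matrix.values.index).to_numpy()
            ok = ~c["pgs"].isna()
            sub = BiomarkerMatrix(
                matrix.values.loc[ok.to_numpy()],
                matrix.below_lod.loc[ok.to_numpy()],
                LOG_SCALED,
            )
            frames.append(
                _run(sub, c.loc[ok.to_numpy()], base + ["pgs"], "pgs", [bm])
            )

    # sex-stratified + interaction
    for sex_val, tag in ((1, "sex_M"), (0, "sex_F")):
        sel = (cohort["sex"].astype(int) == sex_val).to_numpy()
        sub = BiomarkerMatrix(
            matrix.values.loc[sel], matrix.below_lod.loc[sel], LOG_SCALED
        )
        covs = [c for c in base if c != "sex"]
        frames.append(_run(sub, cohort.loc[sel], covs, tag, targets))
    inter_rows = []
    design = _design_matrix(
        cohort, [exposure_col], base, interaction=("sex", exposure_col)
    )
    term = f"sex:{exposure_col}"
    for bm in targets:
        fit = fit_gee(matrix.values[bm], design, cohort[cluster_col])
        est = fit.loc[term]
        inter_rows.append(
            {
                "biomarker": bm, "model": "sex_interaction", "term": term,
                "beta": est["beta"], "se": est["se"], "p": est["p"],
                "ci_low": est["ci_low"], "ci_high": est["ci_high"],
                "n": int(est["n"]), "error": "", "m_eff": m_eff,
                "significant": est["p"] < threshold,
            }
        )
    frames.append(pd.DataFrame(inter_rows))

    # timing: five window indicators replace the single exposure flag
    window_cols = [c for c in WINDOW_COLS if c in cohort]
    if window_cols:
        design = _design_matrix(cohort, window_cols, base)
        timing_rows = []
        for bm in targets:
            fit = fit_gee(matrix.values[bm], design, cohort[cluster_col])
            for w in window_cols:
                est = fit.loc[w]
                timing_rows.append(
                    {
                        "biomarker": bm, "model": "timing", "term": w,
                        "beta": est["beta"], "se": est["se"], "p": est["p"],
                        "ci_low": est["ci_low"], "ci_high": est["ci_high"],
                        "n": int(est["n"]), "error": "", "m_eff": m_eff,
                        "significant": est["p"] < threshold,
                    }
                )
        frames.append(pd.DataFrame(timing_rows))
    else:
        warnings.warn("no gestational-window columns; timing tag skipped")

    return pd.concat(frames, ignore_index=True)


def describe_cohort(
    cohort: pd.DataFrame,
    group_col: str = "any_exposure",
    continuous: tuple[str, ...] = ("age", "bmi"),
    categorical: tuple[str, ...] = ("sex", "medication", "t2d"),
    ttest: str = "pooled",
) -> pd.DataFrame:
    """Table-1-style group comparison.

    Continuous fields: mean (SD) per group with a two-sample t-test
    (pooled variance by default, Welch optional).  Categorical fields:
    n (%) per group with a chi-square test without continuity
    correction.
    """
    groups = sorted(cohort[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("group variable must be binary")
    g0 = cohort[cohort[group_col] == groups[0]]
    g1 = cohort[cohort[group_col] == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for var in continuous:
        a, b = g0[var].dropna().astype(float), g1[var].dropna().astype(float)
        t, p = stats.ttest_ind(a, b, equal_var=(ttest == "pooled"))
        rows.append(
            {
                "variable": var, "type": "continuous",
                "group0": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                "group1": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                "statistic": t, "p": p,
            }
        )
    for var in categorical:
        a, b = g0[var].dropna().astype(int), g1[var].dropna().astype(int)
        table = np.array(
            [[(a == 1).sum(), (a == 0).sum()], [(b == 1).sum(), (b == 0).sum()]]
        )
        if (a.nunique() == 1) and (b.nunique() == 1) and a.iloc[0] == b.iloc[0]:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {
                "variable": var, "type": "categorical",
                "group0": f"{table[0, 0]} ({100 * table[0, 0] / len(a):.1f})",
                "group1": f"{table[1, 0]} ({100 * table[1, 0] / len(b):.1f})",
                "statistic": chi2, "p": p,
            }
        )
    return pd.DataFrame(rows)


def _aligned(cohort: pd.DataFrame, matrix: BiomarkerMatrix) -> pd.DataFrame:
    c = cohort.set_index(cohort["participant_id"].astype(str), drop=False)
    if not c.index.equals(matrix.values.index):
        c = c.loc[matrix.values.index]
    return c
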