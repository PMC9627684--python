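"""Cohort statistics: correlations, PCA, group comparisons, trajectories.

Mirrors the analysis plan of a longitudinal first-trimester vascular
morphometry study: Spearman rank correlations between characteristics,
per-gestational-week PCA of the seven characteristics (standardized,
correlation-matrix form), Mann-Whitney U comparisons between the
complication strata, and linear mixed models with a quadratic
gestational-age trend and a random intercept per pregnancy, fitted by
maximum likelihood so nested models can be compared with likelihood-ratio
tests.  No multiple-testing correction is applied by default; Benjamini-
Hochberg adjustment is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: The seven characteristics, reporting order.
CHARACTERISTICS = ("n_end", "n_vessel", "n_bif", "n_cross",
                   "total_length_mm", "avg_vessel_length_mm", "avg_thickness_mm")

SCHEDULED_WEEKS = (7.0, 9.0, 11.0)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all permutations of one variable."""
    from itertools import permutations

    rho_obs = sps.spearmanr(x, y).statistic
    if np.isnan(rho_obs):
        return math.nan
    hits = total = 0
    for perm in permutations(y):
        r = sps.spearmanr(x, perm).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def spearman_matrix(table: pd.DataFrame, variables,
                    exact_max_n: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with p-values.

    Ties are handled by midranks.  Requires >= 3 complete pairs per variable
    pair; a constant variable yields NaN (flagged undefined) entries.  For
    small samples (n <= ``exact_max_n``) the p-value is computed exactly by
    permutation enumeration; otherwise the usual t-approximation is used.
    Returns (rho, p) as symmetric DataFrames with unit diagonal.
    """
    variables = list(variables)
    data = table[variables].astype(float)
    n = len(variables)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = data.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >=3 complete pairs for {variables[i]} vs {variables[j]}")
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = sps.spearmanr(x, y)
                if len(pair) <= exact_max_n:
                    p = _spearman_exact_p(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=variables, columns=variables),
            pd.DataFrame(pval, index=variables, columns=variables))


@dataclass(frozen=True)
class PCAResult:
    """Standardized (correlation-matrix) PCA of the characteristics.

    ``components`` holds unit-norm loadings, one column per component in
    descending explained-variance order, sign-fixed so each component's
    largest-magnitude loading is positive.  ``explained_fraction`` sums to 1
    over all components; the two leading components are the reported pair.
    """

    components: pd.DataFrame
    explained_fraction: np.ndarray
    dropped: tuple[str, ...] = ()

    @property
    def pc1_fraction(self) -> float:
        return float(self.explained_fraction[0])

    @property
    def pc2_fraction(self) -> float:
        return float(self.explained_fraction[1])


def pca_characteristics(table: pd.DataFrame, variables=CHARACTERISTICS) -> PCAResult:
    """PCA of standardized characteristics at one gestational week.

    Variables are centred and scaled to unit variance before the
    eigendecomposition (counts and lengths differ by orders of magnitude, so
    covariance-matrix PCA would be dominated by the vessel-point count).
    Zero-variance columns are dropped with a warning.
    """
    variables = list(variables)
    data = table[variables].dropna().astype(float)
    if len(data) < 2:
        raise ValueError("PCA requires at least 2 complete rows")
    std = data.std(ddof=1)
    dropped = tuple(std.index[std == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        variables = [v for v in variables if v not in dropped]
        data = data[variables]
    z = (data - data.mean()) / data.std(ddof=1)
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[imax, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    frac = eigval / eigval.sum()
    comps = pd.DataFrame(eigvec, index=variables,
                         columns=[f"PC{i + 1}" for i in range(len(variables))])
    return PCAResult(components=comps, explained_fraction=frac, dropped=dropped)


@dataclass(frozen=True)
class MwuResult:
    u: float
    p: float
    method: str


def mwu_compare(values_group0, values_group1) -> MwuResult:
    """Two-sided Mann-Whitney U test.

    Exact p-value for combined n <= 20 without ties; otherwise the normal
    approximation with tie and continuity corrections.  ``u`` is the U
    statistic of the first group.
    """
    x = np.asarray(values_group0, float)
    y = np.asarray(values_group1, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return MwuResult(u=float(res.statistic), p=float(res.pvalue), method=method)


@dataclass(frozen=True)
class LmmFit:
    """Maximum-likelihood fit of the quadratic-GA random-intercept model."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    random_intercept_var: float
    loglike: float
    converged: bool
    lrt_p: float | None = None
    lrt_df: int | None = None
    lrt_stat: float | None = None


def _fit_ml(formula: str, df: pd.DataFrame) -> tuple:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        res = model.fit(reml=False)
    return res


def lmm_trajectories(cohort: pd.DataFrame, characteristic: str,
                     interaction: str | None = None) -> LmmFit:
    """Quadratic-in-GA linear mixed model with a random intercept per pregnancy.

    Fitted by maximum likelihood (not REML) so that the optional covariate
    interaction block (main effect + interactions with GA and GA^2) can be
    tested against the base model with a likelihood-ratio test.
    Non-convergence is reported through ``converged``, never silently
    ignored.
    """
    df = cohort.dropna(subset=[characteristic, "ga_weeks", "subject"]).copy()
    if df.empty:
        raise ValueError("no complete rows for the requested characteristic")
    df["_ga2"] = df["ga_weeks"] ** 2
    base = f"Q('{characteristic}') ~ ga_weeks + _ga2"
    if interaction is None:
        res = _fit_ml(base, df)
        lrt = (None, None, None)
    else:
        full = (base + f" + Q('{interaction}') + Q('{interaction}'):ga_weeks"
                + f" + Q('{interaction}'):_ga2")
        res0 = _fit_ml(base, df)
        res = _fit_ml(full, df)
        stat = 2.0 * (res.llf - res0.llf)
        df_lrt = 3
        lrt = (float(sps.chi2.sf(max(stat, 0.0), df_lrt)), df_lrt, float(stat))
    return LmmFit(
        params=res.params, bse=res.bse, conf_int=res.conf_int(),
        random_intercept_var=float(np.asarray(res.cov_re).ravel()[0]),
        loglike=float(res.llf), converged=bool(res.converged),
        lrt_p=lrt[0], lrt_df=lrt[1], lrt_stat=lrt[2],
    )


def assign_scheduled_week(ga: float, weeks=SCHEDULED_WEEKS,
                          window: float = 1.0) -> float | None:
    """Nearest scheduled week within +/- window, else None (visit excluded)."""
    weeks = np.asarray(weeks, float)
    d = np.abs(weeks - ga)
    i = int(np.argmin(d))
    return float(weeks[i]) if d[i] <= window else None


def compare_groups_at_ga(cohort: pd.DataFrame, ga_week: float, variables,
                         group_col: str = "complication",
                         adjust: bool = False) -> pd.DataFrame:
    """Median (IQR) per stratum and Mann-Whitney p per variable at one week.

    Visits are assigned to the nearest scheduled week within one week;
    unassignable visits are excluded.  An empty stratum raises.  With
    ``adjust=True`` a Benjamini-Hochberg adjusted p column is added.
    """
    weeks = cohort["ga_weeks"].map(assign_scheduled_week)
    sub = cohort[weeks == ga_week]
    g0 = sub[sub[group_col] == 0]
    g1 = sub[sub[group_col] == 1]
    if g0.empty or g1.empty:
        raise ValueError(f"empty stratum at GA week {ga_week}")
    rows = []
    for var in variables:
        a = g0[var].dropna().to_numpy()
        b = g1[var].dropna().to_numpy()
        res = mwu_compare(a, b)
        rows.append({
            "variable": var,
            "median_without": float(np.median(a)),
            "q1_without": float(np.percentile(a, 25)),
            "q3_without": float(np.percentile(a, 75)),
            "median_with": float(np.median(b)),
            "q1_with": float(np.percentile(b, 25)),
            "q3_with": float(np.percentile(b, 75)),
            "n_without": len(a), "n_with": len(b),
            "u": res.u, "p": res.p,
        })
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
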