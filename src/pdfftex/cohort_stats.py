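"""Cohort-level statistics: rank tests and adjusted partial correlations.

Sex comparisons use two-sided Wilcoxon-Mann-Whitney tests, muscle
comparisons use pairwise Wilcoxon signed-rank tests, and associations are
quantified as Pearson partial correlations after residualizing both
variables on age and BMI. Exact null distributions are used for small
tie-free samples; otherwise the tie-corrected normal approximation with
continuity correction. Significance threshold is p < 0.05 two-sided; no
multiple-testing correction by default (a Benjamini-Hochberg option is
available).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import ALL_FEATURES, MUSCLES

EXACT_MAX_N = 12  # combined-sample bound for full enumeration
ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    feature: str
    grouping: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]  # group -> {n, mean, sd}
    method: str  # 'exact' | 'asymptotic-tie-corrected' | 'degenerate'

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PartialCorrResult:
    x: str
    y: str
    covariates: tuple[str, ...]
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
    }


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney(x: np.ndarray, y: np.ndarray, feature: str = "",
                 grouping: str = "") -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact p by full enumeration when n1 + n2 <= 12 and the combined sample
    is tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    exact = (x.size + y.size) <= EXACT_MAX_N and not _has_ties(combined)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return TestResult(
        feature=feature,
        grouping=grouping,
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        group_summaries={"x": _summary(x), "y": _summary(y)},
        method="exact" if exact else "asymptotic-tie-corrected",
    )


def wilcoxon_signed_rank(differences: np.ndarray, feature: str = "",
                         grouping: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Exact p by sign-pattern enumeration for
    <= 12 nonzero tie-free differences, else the tie-corrected normal
    approximation. All-zero input is flagged degenerate with p = 1.
    """
    d = np.asarray(differences, dtype=np.float64)
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestResult(
            feature=feature, grouping=grouping, statistic=0.0, p_value=1.0,
            group_summaries={"differences": _summary(d)}, method="degenerate",
        )
    exact = nz.size <= EXACT_MAX_N and not _has_ties(np.abs(nz))
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         correction=True, method="exact" if exact else "approx")
    return TestResult(
        feature=feature,
        grouping=grouping,
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        group_summaries={"differences": _summary(d)},
        method="exact" if exact else "asymptotic-tie-corrected",
    )


def partial_correlation(x: np.ndarray, y: np.ndarray, covariates: np.ndarray,
                        x_name: str = "x", y_name: str = "y",
                        covariate_names: tuple[str, ...] = ("age", "bmi"),
                        method: str = "pearson") -> PartialCorrResult:
    """Partial correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares and
    the Pearson correlation of the residuals is returned, with a two-sided
    p-value from t = r * sqrt(df / (1 - r^2)), df = n - 2 - n_cov.
    ``method='spearman'`` rank-transforms x and y first.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != x.size and cov.shape[1] == x.size:
        cov = cov.T
    n = x.size
    if y.size != n or cov.shape[0] != n:
        raise ValueError("x, y and covariates must have matching length")
    n_cov = cov.shape[1]
    df = n - 2 - n_cov
    if df <= 0:
        raise ValueError(f"not enough observations: n={n} with {n_cov} covariates")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    # constant covariates carry no adjustment: keep the reduction to plain
    # Pearson well-defined instead of failing on collinearity with the intercept
    cov = cov[:, cov.std(axis=0) > 0]
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("collinear covariate design (rank deficient)")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0.0:
        r = float("nan")
        p = float("nan")
    else:
        r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(x=x_name, y=y_name, covariates=covariate_names,
                             r=r, p_value=p, n=n)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


def _feature_column(feature: str, muscle: str) -> str:
    return f"{feature}_{muscle}"


def sex_comparisons(table: pd.DataFrame, features: tuple[str, ...] = ALL_FEATURES,
                    ) -> pd.DataFrame:
    """Mann-Whitney male-vs-female tests for age, BMI, and feature x muscle."""
    male = table[table["sex"] == "male"]
    female = table[table["sex"] == "female"]
    rows = []
    if male.empty or female.empty:
        return pd.DataFrame(rows)
    columns = ["age", "bmi"] + [
        _feature_column(f, m) for f in features for m in MUSCLES
        if _feature_column(f, m) in table.columns
    ]
    for col in columns:
        xm = male[col].to_numpy(dtype=float)
        xf = female[col].to_numpy(dtype=float)
        xm = xm[np.isfinite(xm)]
        xf = xf[np.isfinite(xf)]
        res = mann_whitney(xm, xf, feature=col, grouping="male_vs_female")
        rows.append({
            "feature": col,
            "groups": "male_vs_female",
            "n_male": res.group_summaries["x"]["n"],
            "n_female": res.group_summaries["y"]["n"],
            "mean_male": res.group_summaries["x"]["mean"],
            "sd_male": res.group_summaries["x"]["sd"],
            "mean_female": res.group_summaries["y"]["mean"],
            "sd_female": res.group_summaries["y"]["sd"],
            "statistic": res.statistic,
            "p": res.p_value,
            "method": res.method,
        })
    return pd.DataFrame(rows)


def muscle_comparisons(table: pd.DataFrame, features: tuple[str, ...] = ALL_FEATURES,
                       ) -> pd.DataFrame:
    """Pairwise signed-rank tests between muscles for every feature.

    Reports each pairwise test plus, per feature, a conservative combined
    row whose p is the maximum of the three pairwise p-values (the
    all-three-differ criterion).
    """
    rows = []
    for feature in features:
        pair_ps = []
        for m1, m2 in combinations(MUSCLES, 2):
            c1, c2 = _feature_column(feature, m1), _feature_column(feature, m2)
            if c1 not in table.columns or c2 not in table.columns:
                continue
            d = (table[c1] - table[c2]).to_numpy(dtype=float)
            d = d[np.isfinite(d)]
            res = wilcoxon_signed_rank(d, feature=feature, grouping=f"{m1}_vs_{m2}")
            pair_ps.append(res.p_value)
            rows.append({
                "feature": feature,
                "pair": f"{m1}_vs_{m2}",
                "n": res.group_summaries["differences"]["n"],
                "statistic": res.statistic,
                "p": res.p_value,
                "method": res.method,
            })
        if pair_ps:
            rows.append({
                "feature": feature,
                "pair": "all_pairwise_max",
                "n": int(len(table)),
                "statistic": float("nan"),
                "p": max(pair_ps),
                "method": "max-of-pairwise",
            })
    return pd.DataFrame(rows)


def partial_correlations(table: pd.DataFrame, features: tuple[str, ...] = ALL_FEATURES,
                         by_sex: bool = True, method: str = "pearson") -> pd.DataFrame:
    """Age/BMI-adjusted pairwise partial correlations.

    Two families: (a) the same feature between muscle pairs (inter-muscle),
    and (b) each texture feature vs mean PDFF within a muscle. Computed on
    the whole cohort and, if ``by_sex``, per sex.
    """
    cohorts = {"all": table}
    if by_sex:
        cohorts["male"] = table[table["sex"] == "male"]
        cohorts["female"] = table[table["sex"] == "female"]
    rows = []
    for cohort_name, sub in cohorts.items():
        if len(sub) < 5:  # df = n - 4 must be positive
            continue
        cov = sub[["age", "bmi"]].to_numpy(dtype=float)
        for feature in features:
            for m1, m2 in combinations(MUSCLES, 2):
                c1, c2 = _feature_column(feature, m1), _feature_column(feature, m2)
                if c1 not in sub.columns or c2 not in sub.columns:
                    continue
                res = partial_correlation(
                    sub[c1].to_numpy(dtype=float), sub[c2].to_numpy(dtype=float),
                    cov, x_name=c1, y_name=c2, method=method)
                rows.append({
                    "cohort": cohort_name, "kind": "inter_muscle",
                    "feature": feature, "x": c1, "y": c2,
                    "r": res.r, "p": res.p_value, "n": res.n, "method": method,
                })
        for muscle in MUSCLES:
            pdff_col = _feature_column("mean_pdff", muscle)
            if pdff_col not in sub.columns:
                continue
            for feature in features:
                if feature == "mean_pdff":
                    continue
                col = _feature_column(feature, muscle)
                if col not in sub.columns:
                    continue
                res = partial_correlation(
                    sub[col].to_numpy(dtype=float), sub[pdff_col].to_numpy(dtype=float),
                    cov, x_name=col, y_name=pdff_col, method=method)
                rows.append({
                    "cohort": cohort_name, "kind": "within_muscle",
                    "feature": feature, "x": col, "y": pdff_col,
                    "r": res.r, "p": res.p_value, "n": res.n, "method": method,
                })
    return pd.DataFrame(rows)


def run_paper_statistics(table: pd.DataFrame,
                         features: tuple[str, ...] = ALL_FEATURES,
                         by_sex: bool = True,
                         fdr: bool = False,
                         method: str = "pearson") -> dict[str, pd.DataFrame]:
    """The full statistical stage on a cohort feature table.

    Returns {'sex_tests', 'muscle_tests', 'partial_correlations'} as tidy
    frames; with ``fdr`` a BH-adjusted ``p_adj`` column is appended.
    """
    out = {
        "sex_tests": sex_comparisons(table, features),
        "muscle_tests": muscle_comparisons(table, features),
        "partial_correlations": partial_correlations(table, features,
                                                     by_sex=by_sex, method=method),
    }
    if fdr:
        for df in out.values():
            finite = np.isfinite(df["p"].to_numpy(dtype=float))
            adj = np.full(len(df), np.nan)
            if finite.any():
                adj[finite] = benjamini_hochberg(df.loc[finite, "p"].to_numpy(dtype=float))
            df["p_adj"] = adj
    return out
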