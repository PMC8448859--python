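"""Subtype characterisation statistics.

Per variable the test is selected automatically: Levene's test (mean
centred, alpha 0.05) screens for heteroscedasticity and a Shapiro-Wilk
test on pooled within-group residuals stands in for visual QQ inspection.
Unequal variances lead to an ANOVA with heteroscedasticity-consistent
("White") covariance and Welch pairwise t-tests; equal variances and
normal residuals to classical one-way ANOVA with Tukey HSD post-hoc;
equal variances and non-normal residuals to Kruskal-Wallis with pairwise
Wilcoxon rank-sum tests (Benjamini-Hochberg adjusted).  Categorical
variables get Fisher's exact test, generalised to r x c tables by exact
enumeration or seeded Monte Carlo.  ANOVA-eligible variables can
additionally be covariate-adjusted (ANCOVA on age and disease duration).
Panel-wide nominal p-values receive a Benjamini-Hochberg FDR correction.

The proteomics screen drops proteins with missing values or standard
deviation below 0.3, runs per-protein one-way ANOVA with BH correction
across proteins, and reports Tukey HSD post-hoc pairs for each hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ComparisonTable",
    "ProteinScreenResult",
    "choose_test",
    "compare_continuous",
    "compare_categorical",
    "ancova_adjust",
    "fdr_correct",
    "protein_screen",
    "characterize",
]

ALPHA = 0.05


@dataclass
class TestResult:
    variable: str
    test_used: str
    p_nominal: float
    p_fdr: float = float("nan")
    posthoc: list[tuple[tuple, float, bool]] = field(default_factory=list)
    ancova_p: float | None = None


@dataclass
class ComparisonTable:
    rows: list[TestResult]
    grouping: list
    n_per_group: dict
    descriptives: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            sig_pairs = [p for p, _, s in r.posthoc if s]
            recs.append(
                {
                    "variable": r.variable,
                    "test": r.test_used,
                    "p": r.p_nominal,
                    "p_fdr": r.p_fdr,
                    "ancova_p": r.ancova_p if r.ancova_p is not None else np.nan,
                    "posthoc_significant": "; ".join(
                        f"{a} vs {b}" for a, b in sig_pairs
                    )
                    or "-",
                }
            )
        frame = pd.DataFrame(recs).set_index("variable")
        if self.descriptives is not None:
            frame = self.descriptives.join(frame, how="right")
        return frame


@dataclass
class ProteinScreenResult:
    n_input: int
    n_after_missing_filter: int
    n_after_sd_filter: int
    hits: pd.DataFrame
    all_tests: pd.DataFrame


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    parts = [values[groups == g] for g in levels]
    return levels, parts


def choose_test(values, groups) -> str:
    """Select the continuous-variable test branch for grouped data.

    Levene (mean-centred) at alpha 0.05 screens variance homogeneity;
    Shapiro-Wilk on pooled within-group residuals screens normality.
    Returns ``anova_white`` (heteroscedastic), ``anova`` (homoscedastic
    normal) or ``kruskal_wallis`` (homoscedastic non-normal).
    """
    levels, parts = _split_groups(values, groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g, part in zip(levels, parts):
        if len(part) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    _, p_levene = stats.levene(*parts, center="mean")
    if p_levene < ALPHA:
        return "anova_white"
    residuals = np.concatenate([part - part.mean() for part in parts])
    _, p_shapiro = stats.shapiro(residuals)
    return "anova" if p_shapiro >= ALPHA else "kruskal_wallis"


def _bh_pairs(levels, parts, pair_test) -> list[tuple[tuple, float, bool]]:
    pairs = list(combinations(range(len(levels)), 2))
    raw = [pair_test(parts[i], parts[j]) for i, j in pairs]
    adj = fdr_correct(raw)
    return [
        ((levels[i], levels[j]), float(p), bool(p < ALPHA))
        for (i, j), p in zip(pairs, adj)
    ]


def _anova_white_p(values, groups) -> float:
    # Wald F-test on the group dummies of a group-means linear model with
    # HC3 heteroscedasticity-consistent covariance.
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X = np.column_stack([np.ones(len(groups)), dummies])
    res = OLS(np.asarray(values, dtype=float), X).fit(cov_type="HC3")
    R = np.zeros((len(levels) - 1, X.shape[1]))
    R[:, 1:] = np.eye(len(levels) - 1)
    return float(res.f_test(R).pvalue)


def compare_continuous(values, groups, branch: str, variable: str = "") -> TestResult:
    """Run the selected continuous test with its post-hoc battery.

    Post-hoc pairwise comparisons are reported when the omnibus p-value is
    below 0.05: Tukey HSD after classical ANOVA, Welch t-tests (BH
    adjusted) after White-adjusted ANOVA, Wilcoxon rank-sum (BH adjusted)
    after Kruskal-Wallis.
    """
    levels, parts = _split_groups(values, groups)
    if all(np.ptp(part) == 0 for part in parts) and np.ptp(np.asarray(values, dtype=float)) == 0:
        raise ValueError("values are constant; no test is defined")
    posthoc: list[tuple[tuple, float, bool]] = []
    if branch == "anova":
        F, p = stats.f_oneway(*parts)
        if not np.isfinite(p) and F <= 0:
            # between-group variance is zero up to roundoff
            p = 1.0
        if p < ALPHA:
            tuk = stats.tukey_hsd(*parts)
            posthoc = [
                ((levels[i], levels[j]), float(tuk.pvalue[i, j]), bool(tuk.pvalue[i, j] < ALPHA))
                for i, j in combinations(range(len(levels)), 2)
            ]
    elif branch == "anova_white":
        p = _anova_white_p(values, groups)
        if p < ALPHA:
            posthoc = _bh_pairs(
                levels, parts,
                lambda a, b: stats.ttest_ind(a, b, equal_var=False).pvalue,
            )
    elif branch == "kruskal_wallis":
        _, p = stats.kruskal(*parts)
        if p < ALPHA:
            posthoc = _bh_pairs(
                levels, parts, lambda a, b: stats.ranksums(a, b).pvalue
            )
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return TestResult(variable=variable, test_used=branch, p_nominal=float(p), posthoc=posthoc)


def _log_table_prob(T: np.ndarray, row_sums, col_sums, n) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(T + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums, cap):
    """Yield all contingency tables with the given margins (or None if > cap)."""
    r, c = len(row_sums), len(col_sums)
    out: list[np.ndarray] = []

    def rec(i, remaining_cols, current):
        if len(out) > cap:
            raise OverflowError
        if i == r - 1:
            row = remaining_cols
            if np.all(row >= 0):
                out.append(np.vstack(current + [row]))
            return
        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]), current + [np.array(row + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, row_sums[i], [])

    try:
        rec(0, np.asarray(col_sums, dtype=int), [])
    except OverflowError:
        return None
    return out


def compare_categorical(
    table,
    variable: str = "",
    seed: int = 0,
    n_mc: int = 100_000,
    enumeration_cap: int = 200_000,
) -> TestResult:
    """Fisher's exact test on a group-by-level count table.

    2x2 tables use the exact hypergeometric test; larger tables use the
    exact conditional (Freeman-Halton) generalisation by full enumeration
    when the table space is small, otherwise a seeded Monte-Carlo
    approximation with ``n_mc`` sampled tables at fixed margins.  Post-hoc
    pairwise group comparisons are BH adjusted.
    """
    T = np.asarray(table, dtype=int)
    if np.any(T < 0):
        raise ValueError("counts must be non-negative")
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("table has an all-zero margin")
    p = _fisher_p(T, seed=seed, n_mc=n_mc, enumeration_cap=enumeration_cap)
    posthoc: list[tuple[tuple, float, bool]] = []
    if T.shape[0] > 2 and p < ALPHA:
        pairs = list(combinations(range(T.shape[0]), 2))
        raw = []
        for i, j in pairs:
            sub = T[[i, j]]
            keep = sub.sum(axis=0) > 0
            raw.append(_fisher_p(sub[:, keep], seed=seed + 1, n_mc=n_mc, enumeration_cap=enumeration_cap))
        adj = fdr_correct(raw)
        posthoc = [((i, j), float(q), bool(q < ALPHA)) for (i, j), q in zip(pairs, adj)]
    return TestResult(variable=variable, test_used="fisher_exact", p_nominal=float(p), posthoc=posthoc)


def _fisher_p(T: np.ndarray, seed: int, n_mc: int, enumeration_cap: int) -> float:
    if T.shape == (2, 2):
        return float(stats.fisher_exact(T)[1])
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    n = T.sum()
    lp_obs = _log_table_prob(T, row_sums, col_sums, n)
    tables = _enumerate_tables(row_sums, col_sums, enumeration_cap)
    if tables is not None:
        lps = np.array([_log_table_prob(t, row_sums, col_sums, n) for t in tables])
        return float(np.exp(lps[lps <= lp_obs + 1e-9]).sum())
    rng = np.random.default_rng(seed)
    samples = stats.random_table(row_sums, col_sums, seed=rng).rvs(n_mc)
    lps = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
        - gammaln(samples + 1).sum(axis=(1, 2))
    )
    hits = int(np.sum(lps <= lp_obs + 1e-9))
    return (hits + 1.0) / (n_mc + 1.0)


def ancova_adjust(values, groups, covariates) -> float:
    """Partial F-test p-value for the group effect adjusting for covariates.

    Fits ``value ~ group indicators + covariates`` by OLS and compares it
    to the covariates-only model.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    base = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("covariates are collinear (or constant)")
    levels = pd.unique(groups)
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    full = np.column_stack([base, dummies])
    res_full = OLS(y, full).fit()
    res_base = OLS(y, base).fit()
    df1 = len(levels) - 1
    df2 = len(y) - full.shape[1]
    F = ((res_base.ssr - res_full.ssr) / df1) / (res_full.ssr / df2)
    return float(stats.f.sf(F, df1, df2))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def protein_screen(
    proteins: pd.DataFrame,
    groups,
    sd_min: float = 0.3,
    alpha: float = 0.05,
) -> ProteinScreenResult:
    """Group-comparison screen over a patient-by-protein matrix.

    Proteins with any missing value are dropped, then proteins with
    standard deviation strictly below ``sd_min``; each remaining protein is
    tested by one-way ANOVA, BH-corrected across proteins, and each hit
    (FDR p < alpha) gets Tukey HSD post-hoc pairs.
    """
    if sd_min < 0:
        raise ValueError("sd_min must be non-negative")
    groups = np.asarray(groups)
    n_input = proteins.shape[1]
    complete = proteins.loc[:, ~proteins.isna().any(axis=0)]
    n_after_missing = complete.shape[1]
    sds = complete.std(axis=0, ddof=1)
    kept = complete.loc[:, sds >= sd_min]
    n_after_sd = kept.shape[1]
    levels = pd.unique(groups)
    records = []
    for name in kept.columns:
        parts = [kept[name].to_numpy()[groups == g] for g in levels]
        _, p = stats.f_oneway(*parts)
        records.append({"protein": name, "anova_p": float(p)})
    all_tests = pd.DataFrame(records)
    if len(all_tests):
        all_tests["fdr_p"] = fdr_correct(all_tests["anova_p"].to_numpy())
    else:
        all_tests = pd.DataFrame(columns=["protein", "anova_p", "fdr_p"])
    hit_rows = []
    for _, row in all_tests.iterrows():
        if row["fdr_p"] >= alpha:
            continue
        parts = [kept[row["protein"]].to_numpy()[groups == g] for g in levels]
        tuk = stats.tukey_hsd(*parts)
        sig = [
            f"{levels[i]} vs {levels[j]}"
            for i, j in combinations(range(len(levels)), 2)
            if tuk.pvalue[i, j] < alpha
        ]
        hit_rows.append(
            {
                "protein": row["protein"],
                "anova_p": row["anova_p"],
                "fdr_p": row["fdr_p"],
                "posthoc": "; ".join(sig) or "-",
            }
        )
    hits = pd.DataFrame(hit_rows, columns=["protein", "anova_p", "fdr_p", "posthoc"])
    return ProteinScreenResult(
        n_input=n_input,
        n_after_missing_filter=n_after_missing,
        n_after_sd_filter=n_after_sd,
        hits=hits,
        all_tests=all_tests,
    )


def _describe_continuous(series: pd.Series, groups: pd.Series) -> dict:
    return {
        f"subtype_{g}": f"{series[groups == g].mean():.3f} ({series[groups == g].std(ddof=1):.3f})"
        for g in sorted(pd.unique(groups))
    }


def _describe_categorical(series: pd.Series, groups: pd.Series) -> dict:
    out = {}
    top = series.value_counts().index[0]
    for g in sorted(pd.unique(groups)):
        sub = series[groups == g]
        n = int((sub == top).sum())
        out[f"subtype_{g}"] = f"{n} ({100.0 * n / len(sub):.1f}%) {top}"
    return out


def characterize(
    data: pd.DataFrame,
    labels,
    continuous: list[str],
    categorical: list[str] | None = None,
    covariate_columns: tuple[str, str] = ("age", "pd_duration"),
    ancova_variables: list[str] | None = None,
    seed: int = 0,
) -> ComparisonTable:
    """Full characterisation battery over a variable panel.

    Runs the automatic test selection and comparison for every continuous
    variable, Fisher's exact test for every categorical variable, ANCOVA
    (age and disease duration) for the ANOVA-eligible variables named in
    ``ancova_variables``, and a panel-wide Benjamini-Hochberg correction
    over all nominal p-values.
    """
    labels = pd.Series(np.asarray(labels), index=data.index)
    categorical = categorical or []
    ancova_variables = ancova_variables or []
    rows: list[TestResult] = []
    desc: dict[str, dict] = {}
    for var in continuous:
        values = data[var].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        branch = choose_test(values[ok], labels[ok])
        res = compare_continuous(values[ok], labels[ok], branch, variable=var)
        if var in ancova_variables and branch in ("anova", "anova_white"):
            cov = data.loc[ok, list(covariate_columns)].to_numpy(dtype=float)
            res.ancova_p = ancova_adjust(values[ok], labels[ok], cov)
        rows.append(res)
        desc[var] = _describe_continuous(data.loc[ok, var], labels[ok])
    for var in categorical:
        series = data[var].dropna()
        tab = pd.crosstab(labels.loc[series.index], series)
        res = compare_categorical(tab.to_numpy(), variable=var, seed=seed)
        rows.append(res)
        desc[var] = _describe_categorical(series, labels.loc[series.index])
    adjusted = fdr_correct([r.p_nominal for r in rows])
    for r, q in zip(rows, adjusted):
        r.p_fdr = float(q)
    group_levels = sorted(pd.unique(labels))
    return ComparisonTable(
        rows=rows,
        grouping=group_levels,
        n_per_group={g: int((labels == g).sum()) for g in group_levels},
        descriptives=pd.DataFrame(desc).T,
    )
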