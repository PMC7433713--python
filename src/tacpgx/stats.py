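"""Ordered-trend and group-comparison statistics.

Three procedures cover the analysis battery applied to each PK parameter:

* a two-sided Jonckheere-Terpstra (JT) test for a monotone trend across the
  ordered metabolic-composite groups (Poor < Intermediate < Extensive), with
  half-counting of ties and the tie-corrected null variance (doses are
  rounded to 0.5 mg, so ties are guaranteed), and an exact permutation
  p-value for small samples;
* post-hoc pairwise two-sided Wilcoxon rank-sum tests with Holm-Bonferroni
  step-down adjustment;
* a two-factor analysis of each PK parameter over the 3x2
  composite x ABCB1-3435-T-carrier grid: main-effects linear model with
  Type-II sums of squares on the unbalanced design, cell means with both
  sample and model-based standard errors, and an optional Wilks-lambda
  joint multivariate test across a parameter set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendResult",
    "PairwiseResult",
    "TwoFactorResult",
    "jonckheere_terpstra",
    "pairwise_wilcoxon_holm",
    "holm_adjust",
    "combined_two_factor",
]


@dataclass(frozen=True)
class TrendResult:
    statistic: float  # JT count (ties count 1/2)
    z: float  # tie-corrected standardized statistic
    p_two_sided: float
    method: str  # "asymptotic" | "exact"
    n_groups: int
    n_total: int


@dataclass(frozen=True)
class PairwiseResult:
    group_pair: tuple[str, str]
    raw_p: float
    holm_adjusted_p: float


@dataclass
class TwoFactorResult:
    phenotype_name: str
    cell_means: pd.DataFrame  # 3x2 grid of means
    cell_se_sample: pd.DataFrame  # per-cell sample SEs
    cell_se_model: pd.DataFrame  # pooled-variance model SEs
    cell_n: pd.DataFrame
    p_abcb1: float
    p_composite: float
    anova_table: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """JT count: sum over ordered group pairs i<j of #(x_i < x_j) + 0.5 #(=)."""
    total = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        total += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(total)


def _jt_null_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Mean and tie-corrected variance of the JT statistic under the null."""
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    pooled = np.concatenate(groups)
    _, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)

    mean = (N**2 - np.sum(n**2)) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(n * (n - 1) * (n - 2))
        * np.sum(t * (t - 1) * (t - 2))
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = np.sum(n * (n - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
    return mean, term1 + term2 + term3


def _jt_exact_pvalue(groups: list[np.ndarray], observed: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates all distinct splits of the pooled sample into groups of the
    observed sizes (multinomial coefficient of them); feasible for total
    n <= ~14.
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    stats_out: list[float] = []

    def recurse(remaining_idx: tuple[int, ...], gi: int, chosen: list[np.ndarray]) -> None:
        if gi == len(sizes) - 1:
            chosen.append(pooled[list(remaining_idx)])
            stats_out.append(_jt_statistic(chosen))
            chosen.pop()
            return
        for comb in itertools.combinations(remaining_idx, sizes[gi]):
            rest = tuple(i for i in remaining_idx if i not in set(comb))
            chosen.append(pooled[list(comb)])
            recurse(rest, gi + 1, chosen)
            chosen.pop()

    recurse(tuple(range(len(pooled))), 0, [])
    stats_arr = np.array(stats_out)
    m = len(stats_arr)
    eps = 1e-9
    lower = np.sum(stats_arr <= observed + eps) / m
    upper = np.sum(stats_arr >= observed - eps) / m
    return float(min(1.0, 2.0 * min(lower, upper)))


def jonckheere_terpstra(
    groups,
    method: str = "auto",
    exact_n_max: int = 12,
) -> TrendResult:
    """Two-sided Jonckheere-Terpstra trend test over ordered groups.

    ``groups`` is a sequence of numeric samples in increasing hypothesised
    order.  ``method`` is "asymptotic", "exact", or "auto" (exact when the
    total sample size is <= ``exact_n_max``).  Ties contribute half counts
    to the statistic and the asymptotic variance is tie-corrected.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two ordered groups")
    for i, g in enumerate(arrs):
        if g.size < 1:
            raise ValueError(f"group {i} is empty")
    N = sum(g.size for g in arrs)

    stat = _jt_statistic(arrs)
    mean, var = _jt_null_moments(arrs)

    if method == "auto":
        method = "exact" if N <= exact_n_max else "asymptotic"
    if method == "exact":
        p = _jt_exact_pvalue(arrs, stat)
        z = (stat - mean) / np.sqrt(var) if var > 0 else 0.0
    elif method == "asymptotic":
        if var <= 0:  # all observations identical
            return TrendResult(stat, 0.0, 1.0, "asymptotic", len(arrs), N)
        # continuity-corrected normal approximation (the statistic moves in
        # half-unit steps, so 0.5 is the conventional correction)
        z = (stat - mean) / np.sqrt(var)
        z_cc = max(abs(stat - mean) - 0.5, 0.0) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(z_cc)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrendResult(stat, float(z), float(min(p, 1.0)), method, len(arrs), N)


# ---------------------------------------------------------------------------
# Pairwise Wilcoxon rank-sum with Holm-Bonferroni
# ---------------------------------------------------------------------------


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def pairwise_wilcoxon_holm(
    groups: dict[str, np.ndarray],
    exact_n_max: int = 25,
) -> list[PairwiseResult]:
    """All pairwise two-sided Wilcoxon rank-sum tests, Holm-adjusted.

    Exact p-values when both groups have <= ``exact_n_max`` observations and
    no ties; normal approximation with continuity correction otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if x.size == 1 and y.size == 1 and x[0] == y[0]:
            warnings.warn(f"identical single-point groups {a}/{b}; p set to 1")
            raw.append(1.0)
            continue
        use_exact = (
            x.size <= exact_n_max
            and y.size <= exact_n_max
            and np.unique(np.concatenate([x, y])).size == x.size + y.size
        )
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
        )
        raw.append(float(res.pvalue))
    adj = holm_adjust(raw)
    return [
        PairwiseResult(pair, r, float(a)) for pair, r, a in zip(pairs, raw, adj)
    ]


# ---------------------------------------------------------------------------
# Combined composite x ABCB1-3435-carrier two-factor analysis
# ---------------------------------------------------------------------------


def _carrier_code(genotype_dosage: int) -> str:
    """Collapse 3435 variant dosage to carrier status: CC vs CT-and-TT."""
    return "CC" if genotype_dosage == 0 else "T-carrier"


def combined_two_factor(
    data: pd.DataFrame,
    phenotypes,
    composite_col: str = "composite_class",
    carrier_col: str = "abcb1_3435_carrier",
    joint: bool = False,
) -> list[TwoFactorResult]:
    """Two-factor main-effects analysis of each PK parameter.

    ``data`` holds one row per subject with the composite class, the 3435
    carrier status (``"CC"`` / ``"T-carrier"``), and the phenotype columns.
    For each phenotype a linear model ``y ~ composite + carrier`` (no
    interaction) is fit and Type-II sums of squares give the two main-effect
    p-values, matching the unbalanced 3x2 design.  Empty cells produce a
    warning naming the cell; the main-effects model remains estimable as
    long as every factor level is observed.

    With ``joint=True`` a Wilks-lambda multivariate test across all
    phenotypes is appended to the last result's ``anova_table`` attrs.
    """
    results: list[TwoFactorResult] = []
    comp_levels = [c for c in ("Poor", "Intermediate", "Extensive") if c in set(data[composite_col])]
    carr_levels = [c for c in ("CC", "T-carrier") if c in set(data[carrier_col])]

    for comp in comp_levels:
        for carr in carr_levels:
            if ((data[composite_col] == comp) & (data[carrier_col] == carr)).sum() == 0:
                warnings.warn(f"empty cell: composite={comp}, 3435={carr}")

    for pheno in phenotypes:
        df = data[[composite_col, carrier_col, pheno]].dropna().copy()
        df.columns = ["composite", "carrier", "y"]
        df["composite"] = pd.Categorical(df["composite"], categories=comp_levels)
        df["carrier"] = pd.Categorical(df["carrier"], categories=carr_levels)

        grp = df.groupby(["composite", "carrier"], observed=False)["y"]
        means = grp.mean().unstack("carrier")
        ns = grp.size().unstack("carrier")
        se_sample = (grp.std(ddof=1) / np.sqrt(grp.size())).unstack("carrier")

        if df["y"].nunique() <= 1:
            # Constant phenotype: no variance to test.
            results.append(
                TwoFactorResult(pheno, means, se_sample, se_sample * 0.0, ns, 1.0, 1.0)
            )
            continue

        # a factor with one observed level is dropped from the model (its
        # main effect is not estimable); its p-value is reported as NaN
        terms = []
        if df["composite"].nunique() > 1:
            terms.append("C(composite)")
        if df["carrier"].nunique() > 1:
            terms.append("C(carrier)")
        if not terms:
            results.append(
                TwoFactorResult(pheno, means, se_sample, se_sample * np.nan, ns, np.nan, np.nan)
            )
            continue
        model = smf.ols("y ~ " + " + ".join(terms), data=df).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        sigma = np.sqrt(model.mse_resid)
        se_model = sigma / np.sqrt(ns)

        p_comp = float(aov.loc["C(composite)", "PR(>F)"]) if "C(composite)" in aov.index else np.nan
        p_carr = float(aov.loc["C(carrier)", "PR(>F)"]) if "C(carrier)" in aov.index else np.nan
        results.append(
            TwoFactorResult(
                phenotype_name=pheno,
                cell_means=means,
                cell_se_sample=se_sample,
                cell_se_model=se_model,
                cell_n=ns,
                p_abcb1=p_carr,
                p_composite=p_comp,
                anova_table=aov,
            )
        )

    if joint and len(list(phenotypes)) > 1 and results:
        sub = data[[composite_col, carrier_col, *phenotypes]].dropna().copy()
        sub = sub.rename(columns={composite_col: "composite", carrier_col: "carrier"})
        endog = " + ".join(phenotypes)
        mv = MANOVA.from_formula(f"{endog} ~ C(composite) + C(carrier)", data=sub)
        results[-1].anova_table.attrs["manova"] = mv.mv_test()
    return results
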