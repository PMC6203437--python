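"""Two-group mean AND variance testing with normality-driven branching.

Each trait is compared between the control (CTRL) and enriched (ENR)
groups twice: once for a difference in means and once for a difference in
variances, because an intervention can individualize a phenotype (spread
the group out) without moving its center.  The test pair depends on a
per-group Shapiro-Wilk normality gate:

* both groups normal     -> Welch's t (means) and the two-tailed variance
                            ratio F test (variances);
* otherwise              -> Wilcoxon rank-sum (means) and Brown-Forsythe,
                            i.e. Levene's test on absolute deviations from
                            the group medians (variances).

All tests are two-tailed at alpha = 0.05, interpreted marginally per
trait; a Benjamini-Hochberg adjusted view can be computed alongside but
never alters the primary significance flags.  The module also provides
the exact power of the two-tailed F test for a given variance ratio — the
design quantity for sizing individualization studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
GROUPS = ("CTRL", "ENR")

#: combined sample size up to which the Wilcoxon rank-sum p-value is exact
#: (tie-free samples only); larger or tied samples use the tie- and
#: continuity-corrected normal approximation.
WILCOXON_EXACT_MAX_N = 50


class StatsInputError(ValueError):
    """Raised when a sample violates a test's preconditions."""


# ---------------------------------------------------------------------------
# transforms


def log_transform(values, trait: str = "") -> np.ndarray:
    """Natural-log transform of a positively valued trait.

    Applied to right-skewed traits (e.g. plasma corticosterone and
    triglycerides) before both the normality gate and the tests.  Missing
    values pass through; non-positive values are rejected with the
    offending positions identified.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.where(~np.isnan(arr) & (arr <= 0))[0]
    if bad.size:
        raise StatsInputError(
            f"log transform of trait {trait!r}: non-positive values at rows {bad.tolist()}"
        )
    return np.log(arr)


# ---------------------------------------------------------------------------
# primitive two-sample tests


def _clean(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < min_n:
        raise StatsInputError(f"{name}: needs >= {min_n} non-missing values, got {arr.size}")
    return arr


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    arr = _clean(values, "shapiro_wilk", 3)
    if arr.size > 5000:
        raise StatsInputError("shapiro_wilk: n must be <= 5000")
    if np.ptp(arr) == 0:
        raise StatsInputError("shapiro_wilk: sample is constant")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, p) two-tailed.

    Degrees of freedom follow the Welch-Satterthwaite approximation, so
    the test does not assume equal group variances — essential here, where
    unequal variances are the hypothesis of interest, not a nuisance.
    """
    x = _clean(x, "welch_t", 2)
    y = _clean(y, "welch_t", 2)
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test; returns (U, p).

    The p-value is computed from the exact null distribution for small
    tie-free samples (combined n <= 50) and from the normal approximation
    with midrank tie correction and continuity correction otherwise.
    """
    x = _clean(x, "wilcoxon_rank_sum", 1)
    y = _clean(y, "wilcoxon_rank_sum", 1)
    combined = np.concatenate([x, y])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= WILCOXON_EXACT_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def f_variance_test(x, y) -> tuple[float, float, float, float]:
    """Two-tailed variance-ratio F test; returns (F, df1, df2, p).

    F = s_x^2 / s_y^2 with (n_x - 1, n_y - 1) degrees of freedom; the
    two-tailed p doubles the smaller tail probability, capped at 1 (the
    convention of R's ``var.test``), which makes p invariant under group
    swap.  Assumes normality within groups — hence the Shapiro-Wilk gate.
    """
    x = _clean(x, "f_variance_test", 2)
    y = _clean(y, "f_variance_test", 2)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise StatsInputError("f_variance_test: second sample has zero variance")
    f = vx / vy
    df1, df2 = x.size - 1, y.size - 1
    dist = sps.f(df1, df2)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return float(f), float(df1), float(df2), float(p)


def brown_forsythe(x, y) -> tuple[float, float]:
    """Brown-Forsythe variance-homogeneity test; returns (F, p).

    A robust Levene-type test: a one-way ANOVA on the absolute deviations
    of each observation from its group *median*, with p from
    F(1, n1 + n2 - 2).  Valid without normality, unlike the F test.
    """
    x = _clean(x, "brown_forsythe", 2)
    y = _clean(y, "brown_forsythe", 2)
    stat, p = sps.levene(x, y, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# per-trait comparison


@dataclass
class GroupComparisonResult:
    """Full record of one trait's two-group mean/variance comparison."""

    trait: str
    n_ctrl: int
    n_enr: int
    transform: str  # "none" | "log"
    shapiro_p_ctrl: float
    shapiro_p_enr: float
    branch: str  # "parametric" | "nonparametric"
    mean_test: str  # "Welch t" | "Wilcoxon rank-sum"
    mean_statistic: float
    mean_p: float
    variance_test: str  # "F" | "Brown-Forsythe"
    variance_statistic: float
    variance_p: float
    alpha: float
    significant_mean: bool
    significant_variance: bool
    note: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_trait(
    table: pd.DataFrame,
    trait: str,
    alpha: float = DEFAULT_ALPHA,
    log_traits: set[str] | frozenset[str] = frozenset(),
) -> GroupComparisonResult:
    """Compare one trait between the CTRL and ENR groups.

    Missing values are dropped per group (pairwise-complete per trait) and
    the remaining n is recorded per group.  Traits listed in
    ``log_traits`` are log-transformed before the normality gate and both
    tests.  The branch is parametric iff BOTH groups pass Shapiro-Wilk at
    ``alpha``.

    Raises
    ------
    StatsInputError
        If either group has fewer than 3 non-missing values — the trait is
        untestable and the caller must record it as such, never skip it.
    """
    if "group" not in table.columns or trait not in table.columns:
        raise StatsInputError(f"table must have 'group' and {trait!r} columns")
    use_log = trait in log_traits
    samples = {}
    for g in GROUPS:
        v = table.loc[table["group"] == g, trait].to_numpy(dtype=float)
        if use_log:
            v = log_transform(v, trait)
        v = v[~np.isnan(v)]
        if v.size < 3:
            raise StatsInputError(
                f"trait {trait!r}: group {g} has only {v.size} non-missing values (< 3)"
            )
        samples[g] = v
    ctrl, enr = samples["CTRL"], samples["ENR"]

    _, sp_ctrl = shapiro_wilk(ctrl)
    _, sp_enr = shapiro_wilk(enr)
    parametric = sp_ctrl > alpha and sp_enr > alpha

    if parametric:
        t, _, mean_p = welch_t(ctrl, enr)
        fstat, _, _, var_p = f_variance_test(ctrl, enr)
        names = ("Welch t", "F")
        mean_stat, var_stat = t, fstat
    else:
        u, mean_p = wilcoxon_rank_sum(ctrl, enr)
        bf, var_p = brown_forsythe(ctrl, enr)
        names = ("Wilcoxon rank-sum", "Brown-Forsythe")
        mean_stat, var_stat = u, bf

    return GroupComparisonResult(
        trait=trait,
        n_ctrl=int(ctrl.size),
        n_enr=int(enr.size),
        transform="log" if use_log else "none",
        shapiro_p_ctrl=sp_ctrl,
        shapiro_p_enr=sp_enr,
        branch="parametric" if parametric else "nonparametric",
        mean_test=names[0],
        mean_statistic=float(mean_stat),
        mean_p=float(mean_p),
        variance_test=names[1],
        variance_statistic=float(var_stat),
        variance_p=float(var_p),
        alpha=alpha,
        significant_mean=bool(mean_p < alpha),
        significant_variance=bool(var_p < alpha),
    )


def compare_all_traits(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    log_traits: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Run :func:`compare_trait` over every trait column; one row per trait.

    Untestable traits (insufficient non-missing n) appear with NaN test
    fields and a ``note`` explaining why — they are flagged, not skipped.
    """
    if traits is None:
        traits = [c for c in table.columns if c not in ("animal_id", "group")]
    rows = []
    for trait in traits:
        try:
            rows.append(compare_trait(table, trait, alpha=alpha, log_traits=log_traits).as_dict())
        except StatsInputError as err:
            logger.warning("trait %s untestable: %s", trait, err)
            rows.append({"trait": trait, "alpha": alpha, "note": str(err)})
    return pd.DataFrame(rows)


def multiplicity_policy(results: pd.DataFrame) -> pd.DataFrame:
    """Attach a Benjamini-Hochberg adjusted view without changing the flags.

    The primary analysis is deliberately marginal: each trait's response
    is a separate question, so per-test p-values are interpreted at alpha
    with no family-wise correction.  For readers who want the adjusted
    view, BH-FDR columns (``mean_p_bh``, ``variance_p_bh``) are appended;
    the ``significant_*`` flags are never altered by this policy.
    """
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    for col in ("mean_p", "variance_p"):
        if col not in out.columns:
            continue
        p = out[col].to_numpy(dtype=float)
        adj = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[col + "_bh"] = adj
    return out


# ---------------------------------------------------------------------------
# power of the two-tailed variance-ratio F test


def variance_power(
    n1: int, n2: int, variance_ratio: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Exact power of the two-tailed F test for a variance ratio.

    If group 1 has true variance ``variance_ratio`` times that of group 2,
    the sample variance ratio divided by the true ratio is central
    F(n1-1, n2-1).  With two-tailed critical values c_lo = F^{-1}(alpha/2)
    and c_hi = F^{-1}(1 - alpha/2), the rejection probability is

        power = P(F < c_lo / rho) + P(F > c_hi / rho),   rho = variance_ratio.

    At rho = 1 this reduces to alpha (the size of the test); it increases
    monotonically as rho moves away from 1 and as the group sizes grow.
    With 40 animals per group at alpha = 0.05, a variance ratio of 2.5 is
    detected with power ~0.8.
    """
    if n1 < 2 or n2 < 2:
        raise StatsInputError("variance_power: each group needs n >= 2")
    if variance_ratio <= 0:
        raise StatsInputError("variance_power: variance_ratio must be > 0")
    if not 0 < alpha < 1:
        raise StatsInputError("variance_power: alpha must lie in (0, 1)")
    dist = sps.f(n1 - 1, n2 - 1)
    c_lo = dist.ppf(alpha / 2)
    c_hi = dist.ppf(1 - alpha / 2)
    rho = variance_ratio
    return float(dist.cdf(c_lo / rho) + dist.sf(c_hi / rho))
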