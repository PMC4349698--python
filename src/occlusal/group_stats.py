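"""Diet-group assignment and group-level statistics.

Species are binned into three diet categories from feeding records:
folivore (>50% of feeding time on leaves), hard-object feeder (substantial
hard seed/nut consumption), frugivore (fruit the primary component).

Group comparisons use the study's toolkit: Kruskal–Wallis across groups,
pairwise Wilcoxon rank-sum with a Bonferroni family-wise criterion, and —
for traits carrying phylogenetic signal — a simulation-based phylogenetic
ANOVA whose F null distribution comes from Brownian-motion simulation on
the tree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from occlusal import phylo
from occlusal.errors import DegenerateInputError, DomainError, InputError

DIET_CATEGORIES = ("folivore", "frugivore", "hard_object")


@dataclass
class GroupSummary:
    group: str
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_sim: int | None = None
    seed: int | None = None
    groups: tuple[str, ...] | None = None
    significant: bool | None = None


# ---------------------------------------------------------------------------
# Diet assignment
# ---------------------------------------------------------------------------

def assign_diet(pct_leaves: float, primary_component: str,
                hard_object_flag: bool) -> str:
    """Apply the categorical diet rule.

    >50% leaf feeding -> folivore; else substantial hard-object feeding ->
    hard_object; else fruit primary -> frugivore.  Anything else is
    unclassifiable under the three-category scheme.
    """
    if not 0.0 <= pct_leaves <= 100.0:
        raise DomainError(f"pct_leaves must be in [0, 100], got {pct_leaves}")
    if pct_leaves > 50.0:
        return "folivore"
    if hard_object_flag:
        return "hard_object"
    if primary_component.strip().lower() == "fruit":
        return "frugivore"
    raise InputError(
        f"unclassifiable diet: leaves={pct_leaves}%, "
        f"primary={primary_component!r}, hard_object={hard_object_flag}")


# ---------------------------------------------------------------------------
# Group summaries (Table 3 analog)
# ---------------------------------------------------------------------------

def group_summary(values, groups, weights=None,
                  conf_level: float = 0.95) -> list[GroupSummary]:
    """Per-group mean with 95% CI.

    Unweighted: mean and two-sided t-interval over individual values.
    Weighted (integer weights, e.g. species sample sizes): weighted mean
    sum(w x)/sum(w) — the reconstruction used to roll species means up to
    diet-group means — with a t-interval on the weighted SE (effective n =
    sum of weights).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if weights is not None:
        weights = np.asarray(weights)
        if len(weights) != len(values) or (weights <= 0).any():
            raise InputError("weights must be positive and aligned with values")
    out: list[GroupSummary] = []
    for g in pd.unique(groups):
        mask = groups == g
        x = values[mask]
        if len(x) == 0:
            warnings.warn(f"empty group {g!r} omitted", stacklevel=2)
            continue
        if weights is None:
            m = float(x.mean())
            n = len(x)
            if n < 2:
                warnings.warn(f"group {g!r} has a single value: degenerate CI",
                              stacklevel=2)
                out.append(GroupSummary(str(g), m, np.nan, np.nan, n))
                continue
            se = x.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + conf_level / 2, df=n - 1)
            out.append(GroupSummary(str(g), m, m - tcrit * se, m + tcrit * se, n))
        else:
            w = weights[mask].astype(float)
            n = int(w.sum())
            m = float((w * x).sum() / w.sum())
            if len(x) < 2:
                out.append(GroupSummary(str(g), m, np.nan, np.nan, n))
                continue
            var = float((w * (x - m) ** 2).sum() / (w.sum() - 1))
            se = np.sqrt(var / w.sum())
            tcrit = stats.t.ppf(0.5 + conf_level / 2, df=n - 1)
            out.append(GroupSummary(str(g), m, m - tcrit * se, m + tcrit * se, n))
    return out


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with a chi^2(k-1) p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise InputError("need >= 2 non-empty groups")
    if sum(len(s) for s in samples) < 3:
        raise InputError("need >= 3 total observations")
    if np.ptp(values) == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          method="kruskal-wallis (constant data)")
    h, p = stats.kruskal(*samples)
    return TestResult(statistic=float(h), p_value=float(p),
                      method="kruskal-wallis")


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Per-comparison criterion alpha / k (0.05 / 3 = 0.0167 for 3 groups)."""
    if n_comparisons < 1:
        raise InputError("need at least one comparison")
    return alpha / n_comparisons


def _rank_sum_exact_ok(x: np.ndarray, y: np.ndarray) -> bool:
    both_small = len(x) <= 10 and len(y) <= 10
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    return both_small and no_ties


def pairwise_wilcoxon(values, groups, alpha: float = 0.05) -> list[TestResult]:
    """Wilcoxon rank-sum for every unordered group pair, Bonferroni-flagged.

    Exact enumeration when both groups have <= 10 observations and no ties;
    otherwise the normal approximation with tie and continuity correction.
    The per-comparison criterion is alpha divided by the number of pairs
    actually tested.  The reported statistic is the rank sum W of the first
    group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise InputError("need >= 2 groups")
    pairs = []
    for a, b in itertools.combinations(labels, 2):
        x = values[groups == a]
        y = values[groups == b]
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: group of size < 2",
                          stacklevel=2)
            continue
        pairs.append((a, b, x, y))
    if not pairs:
        raise InputError("no testable pairs")
    crit = bonferroni_alpha(alpha, len(pairs))
    out = []
    for a, b, x, y in pairs:
        exact = _rank_sum_exact_ok(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact" if exact else "asymptotic",
                                 use_continuity=True)
        w = float(res.statistic + len(x) * (len(x) + 1) / 2)  # U -> rank sum
        out.append(TestResult(
            statistic=w, p_value=float(res.pvalue),
            method="wilcoxon rank-sum "
                   + ("(exact)" if exact else "(normal approx., tie+continuity)"),
            groups=(str(a), str(b)),
            significant=bool(res.pvalue < crit)))
    return out


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(k):
        x = values[codes == g]
        if len(x) == 0:
            continue
        ss_between += len(x) * (x.mean() - grand) ** 2
        ss_within += ((x - x.mean()) ** 2).sum()
    df_b = k - 1
    df_w = n - k
    if df_w <= 0 or ss_within == 0:
        raise DegenerateInputError("within-group variance is zero or undefined")
    return float((ss_between / df_b) / (ss_within / df_w))


def phylo_anova(species_means, groups, tree: dendropy.Tree,
                n_sim: int = 1000, seed: int | None = None) -> TestResult:
    """Simulation-based phylogenetic ANOVA on species means.

    The observed one-way F is compared against F values from ``n_sim``
    Brownian-motion simulations on the tree (sigma^2 estimated from the
    data by ML under a single-mean Brownian model), keeping the group
    labels fixed: p = (1 + #{F_sim >= F_obs}) / (1 + n_sim).  Deterministic
    under a fixed seed.
    """
    if n_sim < 100:
        raise InputError("n_sim must be >= 100")
    y = pd.Series(species_means, dtype=float)
    g = pd.Series(groups)
    g = g.reindex(y.index)
    if g.isna().any():
        raise InputError("groups must cover every species in species_means")
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise InputError("need >= 2 groups")
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateInputError("trait is constant across species")
    sizes = g.value_counts()
    if (sizes < 2).any():
        warnings.warn(f"groups with a single species: "
                      f"{sizes[sizes < 2].index.tolist()}", stacklevel=2)
    codes = g.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    k = len(labels)
    f_obs = _anova_f(y.to_numpy(), codes, k)

    cov = phylo.bm_covariance(tree, list(y.index))
    _, sigma2, mu = phylo._mean_model_loglik(y.to_numpy(), cov.C)
    sims = phylo.simulate_bm_gaussian(cov, sigma2, root_state=mu,
                                      size=n_sim, seed=seed)
    f_sim = np.array([_anova_f(sims[i], codes, k) for i in range(n_sim)])
    p = float((1 + np.sum(f_sim >= f_obs)) / (1 + n_sim))
    return TestResult(statistic=f_obs, p_value=p,
                      method="phylogenetic ANOVA (BM simulation)",
                      n_sim=n_sim, seed=seed)
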