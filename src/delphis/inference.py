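"""Statistical comparisons between control and interaction chains.

The comparisons mirror the study design: two-proportion Z-tests on budgets
and on individual transition probabilities, a delta-method t-test on bout
lengths, a Pearson chi-square between the two chain-construction schemes,
and Kruskal-Wallis for vessel-traffic summaries. p-values are reported raw
(no multiple-testing adjustment).

Sign conventions follow the control-first habit of the field: ``diff`` is
interaction minus control, while the Z statistic is computed control minus
interaction — so a drop in a proportion under interaction yields a positive z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chain_builder import TransitionCounts
from .io_model import BehaviouralState, ValidationError
from .markov_core import bout_length, summarize, transition_matrix

__all__ = [
    "ProportionTestResult",
    "BoutTestResult",
    "two_proportion_z",
    "proportion_z_from_rates",
    "compare_budgets",
    "compare_transitions",
    "bout_t_test",
    "chi_square_approaches",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class ProportionTestResult:
    p1: float            # control-side proportion
    p2: float            # interaction-side proportion
    n1: int
    n2: int
    diff: float          # p2 - p1
    rel_change: float    # diff / p1 (nan when p1 == 0)
    ci_low: float
    ci_high: float
    z: float             # (p1 - p2) / pooled SE
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.diff + 1e-12 and
                self.diff - 1e-12 <= self.ci_high):
            raise ValidationError("confidence interval must bracket the difference")


@dataclass(frozen=True)
class BoutTestResult:
    bout1: float
    bout2: float
    diff: float          # bout2 - bout1
    t: float             # (bout1 - bout2) / SE
    df: int
    ci_low: float
    ci_high: float
    p_value: float


def proportion_z_from_rates(p1: float, n1: int, p2: float, n2: int,
                            alpha: float = 0.05) -> ProportionTestResult:
    """Two-sample Z-test given proportions and effective trial counts.

    Pooled variance for the statistic, unpooled for the CI on the
    difference. Accepts non-integral proportions (eigenvector budgets).
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples need at least one trial")
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValidationError("proportions must lie in [0, 1]")
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    se_pooled = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    diff = p2 - p1
    if se_pooled == 0:
        z, p_value = 0.0, 1.0
    else:
        z = (p1 - p2) / se_pooled
        p_value = 2 * stats.norm.sf(abs(z))
    se_un = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    zc = stats.norm.ppf(1 - alpha / 2)
    return ProportionTestResult(
        p1=p1, p2=p2, n1=n1, n2=n2, diff=diff,
        rel_change=diff / p1 if p1 > 0 else float("nan"),
        ci_low=diff - zc * se_un, ci_high=diff + zc * se_un,
        z=z, p_value=p_value,
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     alpha: float = 0.05) -> ProportionTestResult:
    """Binomial two-proportion Z-test from success counts."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValidationError("zero trials")
        if not 0 <= x <= n:
            raise ValidationError("successes must lie in [0, n]")
    return proportion_z_from_rates(x1 / n1, n1, x2 / n2, n2, alpha)


def compare_budgets(counts_control: TransitionCounts,
                    counts_interaction: TransitionCounts,
                    alpha: float = 0.05,
                    ) -> dict[BehaviouralState, ProportionTestResult]:
    """Per-state Z-tests on the stationary budgets of the two conditions.

    The effective sample size for each condition is its total transition
    count — the only sample size the sequence data define.
    """
    sc = summarize(counts_control)
    si = summarize(counts_interaction)
    if sc.states != si.states:
        raise ValidationError("conditions summarise different state sets")
    return {
        s: proportion_z_from_rates(float(sc.pi[k]), sc.n, float(si.pi[k]), si.n, alpha)
        for k, s in enumerate(sc.states)
    }


def compare_transitions(counts_control: TransitionCounts,
                        counts_interaction: TransitionCounts,
                        alpha: float = 0.05,
                        ) -> dict[tuple[BehaviouralState, BehaviouralState],
                                  ProportionTestResult | None]:
    """Per-cell Z-tests on p_ij, with n = the row totals a_i.

    Rows with no outgoing transitions in either condition cannot be
    normalised; their tests are reported as ``None``.
    """
    if counts_control.states != counts_interaction.states:
        raise ValidationError("conditions count different state sets")
    states = counts_control.states
    rc = counts_control.row_totals
    ri = counts_interaction.row_totals
    out: dict = {}
    for i, si_ in enumerate(states):
        if rc[i] == 0 or ri[i] == 0:
            for j, sj in enumerate(states):
                out[(si_, sj)] = None
            continue
        for j, sj in enumerate(states):
            out[(si_, sj)] = two_proportion_z(
                int(counts_control.a[i, j]), int(rc[i]),
                int(counts_interaction.a[i, j]), int(ri[i]), alpha)
    return out


def bout_t_test(p_ii_c: float, nrow_c: int, p_ii_i: float, nrow_i: int,
                alpha: float = 0.05) -> BoutTestResult:
    """t-test on bout lengths via the delta method.

    Bout length is t = 1/(1-p); the binomial SE of p propagates as
    SE(t) = SE(p) / (1-p)^2. Degrees of freedom follow the two-sample
    pattern nrow_c + nrow_i - 2.
    """
    if nrow_c < 2 or nrow_i < 2:
        raise ValidationError("need at least two transitions per row")
    b_c = bout_length(p_ii_c)
    b_i = bout_length(p_ii_i)
    se_c = math.sqrt(p_ii_c * (1 - p_ii_c) / nrow_c) / (1 - p_ii_c) ** 2
    se_i = math.sqrt(p_ii_i * (1 - p_ii_i) / nrow_i) / (1 - p_ii_i) ** 2
    se = math.sqrt(se_c ** 2 + se_i ** 2)
    df = nrow_c + nrow_i - 2
    diff = b_i - b_c
    if se == 0:
        t, p_value = 0.0, 1.0
    else:
        t = (b_c - b_i) / se
        p_value = 2 * stats.t.sf(abs(t), df)
    tc = stats.t.ppf(1 - alpha / 2, df)
    return BoutTestResult(bout1=b_c, bout2=b_i, diff=diff, t=t, df=df,
                          ci_low=diff - tc * se, ci_high=diff + tc * se,
                          p_value=p_value)


def chi_square_approaches(budget_a, budget_b) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test between two counts-by-state vectors.

    ``budget_a``/``budget_b`` map states to observed counts (e.g. time spent
    per state under the two chain-construction schemes); df = states - 1.
    """
    if set(budget_a) != set(budget_b):
        raise ValidationError("state sets differ")
    keys = list(budget_a)
    table = np.array([[budget_a[k] for k in keys], [budget_b[k] for k in keys]],
                     dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("zero expected cell in chi-square table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), len(keys) - 1, float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H across groups (tie-corrected); df = groups - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)
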