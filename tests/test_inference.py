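"""Z-tests, bout t-test, chi-square and Kruskal-Wallis against oracles."""

import numpy as np
import pytest
from scipy import stats

from delphis import (
    Condition,
    ValidationError,
    bout_t_test,
    chi_square_approaches,
    compare_budgets,
    compare_transitions,
    kruskal_wallis,
    two_proportion_z,
)
from delphis.chain_builder import TransitionCounts
from delphis.io_model import ANALYSIS_STATES
from delphis.markov_core import bout_length


def counts(a, condition=Condition.CONTROL):
    return TransitionCounts(condition, ANALYSIS_STATES, np.asarray(a))


# ---------------------------------------------------------------------------
# Two-proportion Z
# ---------------------------------------------------------------------------

def test_z_equal_proportions_null():
    r = two_proportion_z(30, 100, 15, 50)
    assert r.z == 0.0 and r.p_value == 1.0
    assert r.ci_low <= 0.0 <= r.ci_high


def test_z_matches_statsmodels_oracle():
    from statsmodels.stats.proportion import (
        confint_proportions_2indep,
        proportions_ztest,
    )
    r = two_proportion_z(50, 100, 25, 100)
    z_ref, p_ref = proportions_ztest([50, 25], [100, 100])
    assert abs(r.z - z_ref) < 1e-6
    assert abs(r.p_value - p_ref) < 1e-6
    lo, hi = confint_proportions_2indep(25, 100, 50, 100, method="wald",
                                        compare="diff")
    assert abs(r.ci_low - lo) < 1e-6 and abs(r.ci_high - hi) < 1e-6


def test_z_antisymmetric_under_swap():
    a = two_proportion_z(40, 90, 10, 60)
    b = two_proportion_z(10, 60, 40, 90)
    assert np.isclose(a.z, -b.z)
    assert np.isclose(a.p_value, b.p_value)


def test_z_input_validation():
    with pytest.raises(ValidationError):
        two_proportion_z(1, 0, 1, 10)
    with pytest.raises(ValidationError):
        two_proportion_z(11, 10, 1, 10)


# ---------------------------------------------------------------------------
# Budget and transition comparisons
# ---------------------------------------------------------------------------

def test_identical_counts_give_null_results():
    a = [[20, 5, 10], [6, 15, 9], [8, 7, 30]]
    res = compare_budgets(counts(a), counts(a, Condition.INTERACTION))
    for r in res.values():
        assert r.p_value == 1.0 and r.diff == 0.0
    tr = compare_transitions(counts(a), counts(a, Condition.INTERACTION))
    assert all(r.diff == 0.0 for r in tr.values())


def test_compare_transitions_consistent_with_generic_z():
    ac = np.array([[20, 5, 10], [6, 15, 9], [8, 7, 30]])
    ai = np.array([[10, 9, 12], [5, 10, 4], [15, 6, 21]])
    tr = compare_transitions(counts(ac), counts(ai, Condition.INTERACTION))
    for i, si in enumerate(ANALYSIS_STATES):
        for j, sj in enumerate(ANALYSIS_STATES):
            ref = two_proportion_z(int(ac[i, j]), int(ac[i].sum()),
                                   int(ai[i, j]), int(ai[i].sum()))
            got = tr[(si, sj)]
            assert np.isclose(got.z, ref.z) and np.isclose(got.p_value, ref.p_value)


def test_compare_transitions_flags_zero_rows():
    ac = np.array([[2, 1, 3], [0, 0, 0], [1, 2, 5]])
    ai = np.array([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
    tr = compare_transitions(counts(ac), counts(ai, Condition.INTERACTION))
    mil = ANALYSIS_STATES[1]
    assert all(tr[(mil, sj)] is None for sj in ANALYSIS_STATES)
    assert tr[(ANALYSIS_STATES[0], mil)] is not None


def test_relative_change_arithmetic():
    tr = compare_transitions(counts([[70, 30, 0], [1, 98, 1], [1, 1, 98]]),
                             counts([[90, 10, 0], [1, 98, 1], [1, 1, 98]],
                                    Condition.INTERACTION))
    r = tr[(ANALYSIS_STATES[0], ANALYSIS_STATES[1])]  # 0.30 -> 0.10
    assert np.isclose(r.rel_change, -2 / 3)


def test_transition_test_type_one_error_calibrated(rng):
    """Cell-level Z-tests reject at about the nominal rate under a
    row-multinomial null."""
    p_row = np.array([0.6, 0.25, 0.15])
    rej = trials = 0
    for _ in range(400):
        x1 = rng.multinomial(200, p_row)
        x2 = rng.multinomial(150, p_row)
        r = two_proportion_z(int(x1[0]), 200, int(x2[0]), 150)
        rej += r.p_value < 0.05
        trials += 1
    assert 0.02 < rej / trials < 0.09


# ---------------------------------------------------------------------------
# Bout t-test
# ---------------------------------------------------------------------------

def test_bout_t_equal_inputs_null():
    r = bout_t_test(0.6, 100, 0.6, 80)
    assert r.t == 0.0 and r.p_value == 1.0
    assert r.df == 178


def test_bout_t_monotone_in_n():
    small = bout_t_test(0.5, 50, 0.7, 50)
    big = bout_t_test(0.5, 100, 0.7, 100)
    assert abs(big.t) > abs(small.t)


@pytest.mark.parametrize("seed", range(20))
def test_bout_t_agrees_with_parametric_bootstrap(seed):
    """Sign and significance match a parametric bootstrap of the bout-length
    difference under binomial resampling of the self-transition proportions."""
    rng = np.random.default_rng(seed)
    p_c = rng.uniform(0.3, 0.85)
    p_i = rng.uniform(0.3, 0.85)
    n_c, n_i = int(rng.integers(80, 300)), int(rng.integers(80, 300))
    r = bout_t_test(p_c, n_c, p_i, n_i)
    boots = (1 / (1 - rng.binomial(n_i, p_i, 10_000) / (n_i + 1e-12))
             - 1 / (1 - rng.binomial(n_c, p_c, 10_000) / (n_c + 1e-12)))
    diff = bout_length(p_i) - bout_length(p_c)
    p_boot = 2 * stats.norm.sf(abs(diff) / boots.std())
    assert np.sign(r.diff) == np.sign(diff) or diff == 0
    both_agree = (r.p_value < 0.05) == (p_boot < 0.05)
    borderline = 0.01 < min(r.p_value, p_boot) < 0.2
    assert both_agree or borderline


# ---------------------------------------------------------------------------
# Chi-square and Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_chi_square_identical_distributions():
    chi2, df, p = chi_square_approaches(
        {"F": 352, "M": 86, "T": 160}, {"F": 352, "M": 86, "T": 160})
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 2


def test_chi_square_matches_hand_formula(rng):
    for _ in range(20):
        a = {k: int(v) for k, v in zip("FMT", rng.integers(5, 200, 3))}
        b = {k: int(v) for k, v in zip("FMT", rng.integers(5, 200, 3))}
        chi2, df, p = chi_square_approaches(a, b)
        table = np.array([[a[k] for k in "FMT"], [b[k] for k in "FMT"]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        ref = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(ref, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(ref, 2), abs=1e-12)


def test_kruskal_wallis_basics(rng):
    h, df, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
    assert h == 0.0 and df == 1 and p == 1.0
    with pytest.raises(ValidationError):
        kruskal_wallis([[1.0]])


def test_kruskal_wallis_matches_hand_formula(rng):
    """Tie-corrected H recomputed from rank sums."""
    for _ in range(20):
        g1 = rng.integers(0, 8, size=int(rng.integers(4, 12))).astype(float)
        g2 = rng.integers(0, 8, size=int(rng.integers(4, 12))).astype(float)
        if np.all(np.concatenate([g1, g2]) == g1[0]):
            continue
        h, df, p = kruskal_wallis([g1, g2])
        pooled = np.concatenate([g1, g2])
        ranks = stats.rankdata(pooled)
        n = pooled.size
        r1, r2 = ranks[:g1.size], ranks[g1.size:]
        h_ref = (12 / (n * (n + 1))
                 * (r1.sum() ** 2 / g1.size + r2.sum() ** 2 / g2.size)
                 - 3 * (n + 1))
        _, counts_ = np.unique(pooled, return_counts=True)
        tie = 1 - ((counts_ ** 3 - counts_).sum() / (n ** 3 - n))
        h_ref /= tie
        assert h == pytest.approx(h_ref, abs=1e-9)


def test_kruskal_wallis_uniform_p_under_exchangeability(rng):
    """Exchangeable groups give roughly uniform p-values."""
    ps = []
    for _ in range(300):
        pool = rng.normal(size=24)
        ps.append(kruskal_wallis([pool[:12], pool[12:]])[2])
    ps = np.asarray(ps)
    assert 0.35 < (ps < 0.5).mean() < 0.65
    assert 0.02 < (ps < 0.1).mean() < 0.2
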