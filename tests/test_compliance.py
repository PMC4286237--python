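"""Compliance rule engine and traffic/swim summaries."""

from dataclasses import replace

import numpy as np
import pytest

from delphis import (
    AnalysisConfig,
    FocalFollow,
    Rule,
    ScanSample,
    SwimAttempt,
    SwimEndReason,
    SwimResponse,
    VesselCategory,
    VesselObservation,
    check_follow,
    default_parameters,
    simulate_dataset,
    summarize_swims,
    summarize_traffic,
)
from conftest import F, T, make_follow


def obs(vid="v1", t=0.0, speed=4.0, cat=VesselCategory.TOUR, within=True):
    return VesselObservation(vid, cat, t, speed, within)


def swim(attempt_id="s1", start=10.0, end=14.0, calf=False):
    return SwimAttempt("T2", attempt_id, start, end,
                       SwimResponse.NEUTRAL_PRESENCE,
                       SwimEndReason.SKIPPER_DECISION, calf, T)


def test_boundary_compliant_follow_clean():
    """89-min encounter, 3 vessels, 4 kts, no calves: nothing to flag."""
    n = 31  # 93 min of scans
    observations = [obs(f"v{k}", t=3.0 * s, speed=4.0)
                    for k in range(1, 4) for s in range(30)]  # 87-90 min each
    follow = make_follow(states=[T] * n, observations=observations,
                         swims=[swim(end=10.0 + 55.0)])
    assert check_follow(follow, AnalysisConfig()) == []


@pytest.mark.parametrize("mutate,rule", [
    ("speed", Rule.SPEED),
    ("fourth_vessel", Rule.VESSEL_COUNT),
    ("long_encounter", Rule.DURATION),
    ("calf_swim", Rule.SWIM_WITH_CALVES),
    ("long_swim", Rule.SWIM_DURATION),
], ids=lambda v: str(v))
def test_single_breach_yields_single_matching_violation(mutate, rule):
    base_obs = [obs(f"v{k}", t=3.0 * s, speed=4.0)
                for k in range(1, 3) for s in range(10)]
    swims = [swim()]
    if mutate == "speed":
        base_obs.append(obs("v9", t=60.0, speed=10.0))
    elif mutate == "fourth_vessel":
        base_obs += [obs(f"x{k}", t=60.0, speed=4.0) for k in range(1, 5)]
    elif mutate == "long_encounter":
        base_obs += [obs("v9", t=3.0 * s, speed=4.0) for s in range(32)]  # 96 min
    elif mutate == "calf_swim":
        swims.append(swim("s2", start=20.0, end=24.0, calf=True))
    elif mutate == "long_swim":
        swims.append(swim("s2", start=20.0, end=20.0 + 61.0))
    follow = make_follow(states=[T] * 35, observations=base_obs, swims=swims)
    violations = check_follow(follow, AnalysisConfig())
    assert len(violations) == 1
    assert violations[0].rule is rule


def test_compliant_simulation_has_zero_violations():
    follows, _ = simulate_dataset(default_parameters("compliant"),
                                  n_follows=20, seed=7)
    cfg = AnalysisConfig()
    assert sum(len(check_follow(f, cfg)) for f in follows) == 0


def test_violation_detail_must_breach():
    from delphis.compliance import Violation
    from delphis import ValidationError
    with pytest.raises(ValidationError):
        Violation(Rule.SPEED, "f", "v", measured=4.0, threshold=5.0,
                  time_span=(0, 0), detail="not actually a breach")


# ---------------------------------------------------------------------------
# Traffic summary
# ---------------------------------------------------------------------------

def test_single_continuous_encounter():
    observations = [obs("v1", t=3.0 * s) for s in range(10)]  # 30 min
    follow = make_follow(states=[T] * 12, observations=observations)
    ts = summarize_traffic([follow])
    assert ts.per_vessel_minutes[("T2", "v1")] == 30.0
    assert ts.per_vessel_approaches[("T2", "v1")] == 1


def test_leave_and_return_sums_times_and_counts_two_approaches():
    observations = ([obs("v1", t=3.0 * s) for s in range(4)]
                    + [obs("v1", t=3.0 * s) for s in range(10, 14)])
    follow = make_follow(states=[T] * 20, observations=observations)
    ts = summarize_traffic([follow])
    assert ts.per_vessel_minutes[("T2", "v1")] == 24.0
    assert ts.per_vessel_approaches[("T2", "v1")] == 2


def test_speed_stats_match_sort_oracle(rng):
    speeds = rng.uniform(1, 20, size=40).round(1)
    observations = [obs("v1", t=3.0 * k, speed=float(v)) for k, v in enumerate(speeds)]
    follow = make_follow(states=[T] * 41, observations=observations)
    ts = summarize_traffic([follow])
    st = ts.speed_stats[VesselCategory.TOUR]
    srt = np.sort(speeds)
    assert st["median"] == pytest.approx(np.percentile(srt, 50))
    assert st["iqr"] == pytest.approx(np.percentile(srt, 75) - np.percentile(srt, 25))
    assert st["n"] == 40


def test_traffic_summary_order_invariant(small_dataset):
    follows, _ = small_dataset
    ts1 = summarize_traffic(follows)
    ts2 = summarize_traffic(list(reversed(follows)))
    assert ts1.per_vessel_minutes == ts2.per_vessel_minutes
    assert ts1.simultaneous_counts == ts2.simultaneous_counts


def test_simultaneous_episode_classification():
    # two vessels overlap for scans 2-4, a third joins at scan 3
    observations = ([obs("a", t=3.0 * s) for s in range(1, 6)]
                    + [obs("b", t=3.0 * s) for s in range(2, 5)]
                    + [obs("c", t=9.0)])
    follow = make_follow(states=[T] * 8, observations=observations)
    ts = summarize_traffic([follow])
    assert ts.simultaneous_counts == {3: 1}
    assert ts.share_two_or_three == 1.0


# ---------------------------------------------------------------------------
# Swim summary
# ---------------------------------------------------------------------------

def test_swim_band_shares():
    attempts = ([swim(f"a{k}", 0.0, 4.0) for k in range(36)]
                + [swim(f"b{k}", 0.0, 7.0) for k in range(18)]
                + [swim(f"c{k}", 0.0, 12.0) for k in range(7)])
    ss = summarize_swims(attempts)
    assert ss.n == 61
    assert ss.band_proportions["<5"] == pytest.approx(36 / 61)
    assert round(100 * ss.band_proportions["<5"], 1) == 59.0


def test_swim_empty_summary():
    ss = summarize_swims([])
    assert ss.n == 0 and ss.response_chi2 is None
    assert ss.band_proportions == {}


def test_swim_chi2_matches_hand_formula():
    attempts = ([replace(swim(f"n{k}"), response=SwimResponse.NEUTRAL_PRESENCE)
                 for k in range(12)]
                + [replace(swim(f"m{k}"), response=SwimResponse.NEUTRAL_ABSENCE)
                   for k in range(9)]
                + [replace(swim(f"i{k}"), response=SwimResponse.INTERACTION)
                   for k in range(12)]
                + [replace(swim(f"a{k}"), response=SwimResponse.AVOIDANCE)
                   for k in range(4)])
    ss = summarize_swims(attempts)
    chi2, df, p = ss.response_chi2
    observed = np.array([21, 12, 4])
    expected = observed.sum() / 3
    ref = ((observed - expected) ** 2 / expected).sum()
    assert chi2 == pytest.approx(ref, abs=1e-9)
    assert df == 2
    assert round(ref, 2) == 11.73  # neutral responses dominate this mix
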