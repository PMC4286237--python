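"""Chain-construction schemes, filtering stages and transition counting."""

import numpy as np
import pytest

from delphis import (
    Approach,
    Condition,
    build_chains,
    count_transitions,
    drop_double_states,
    filter_min_transitions,
    label_conditions,
    restrict_states,
    simulate_dataset,
    default_parameters,
)
from delphis.chain_builder import pool_chains
from delphis.io_model import ANALYSIS_STATES
from conftest import F, M, R, S, T, make_follow, scan_indices

BETWEEN = [("v1", 7.5, 19.5)]      # approach S3/S4, departure S7/S8
AT_SCAN = [("v1", 9.0, 18.0)]      # approach at S4, departure at S7


# ---------------------------------------------------------------------------
# The four worked construction scenarios (10 scans, no post-window)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("events,approach,expected_seqs,expected_disc", [
    (BETWEEN, Approach.CONSERVATIVE,
     [("CONTROL", (1, 2, 3)), ("INTERACTION", (5, 6, 7)), ("CONTROL", (9, 10))],
     [4, 8]),
    (AT_SCAN, Approach.CONSERVATIVE,
     [("CONTROL", (1, 2, 3)), ("INTERACTION", (5, 6)), ("CONTROL", (8, 9, 10))],
     [4, 7]),
    (BETWEEN, Approach.LESS_CONSERVATIVE,
     [("CONTROL", (1, 2)), ("INTERACTION", (3, 4, 5, 6, 7)), ("CONTROL", (9, 10))],
     [8]),
    (AT_SCAN, Approach.LESS_CONSERVATIVE,
     [("CONTROL", (1, 2)), ("INTERACTION", (3, 4, 5, 6, 7)), ("CONTROL", (9, 10))],
     [8]),
], ids=["cons-between", "cons-at-scan", "lesscons-between", "lesscons-at-scan"])
def test_construction_scenarios(events, approach, expected_seqs, expected_disc):
    chains = build_chains(make_follow(events=events), approach, post_window=0.0)
    seqs, disc = scan_indices(chains)
    assert seqs == expected_seqs
    assert disc == expected_disc


def test_post_window_appends_to_interaction_chain():
    """With a 6-min window the departure-side rule fires at window expiry
    and the post-departure scans stay on the interaction chain."""
    chains = build_chains(make_follow(events=BETWEEN),
                          Approach.CONSERVATIVE, post_window=6.0)
    seqs, disc = scan_indices(chains)
    # effective departure 25.5 (between S9/S10): S8, S9 join the interaction run
    assert ("INTERACTION", (5, 6, 7, 8, 9)) in seqs
    assert disc == [4, 10]


def test_no_events_identical_single_condition():
    follow = make_follow(states=[F, M, T, F, M, T, F, M, T, F])
    for approach in Approach:
        chains = build_chains(follow, approach, post_window=0.0)
        assert len(chains.sequences) == 1
        assert chains.sequences[0].condition is Condition.CONTROL
        assert len(chains.sequences[0].samples) == 10
        assert not chains.discarded


def test_label_conditions_matches_set_membership(small_dataset):
    follows, _ = small_dataset
    for f in follows:
        labels = label_conditions(f)
        naive = [Condition.INTERACTION if s.vessels_within_300m else Condition.CONTROL
                 for s in f.samples]
        assert labels == naive


def test_partition_property(small_dataset):
    """Every input scan lands in exactly one sequence or in the discard list."""
    follows, _ = small_dataset
    for approach in Approach:
        for post_window in (0.0, 15.0):
            for f in follows:
                chains = build_chains(f, approach, post_window)
                chains = filter_min_transitions(
                    restrict_states(drop_double_states(chains)), 5)
                kept = [(s.follow_id, s.scan_time)
                        for seq in chains.sequences for s in seq.samples]
                disc = [(d.follow_id, d.scan_time) for d in chains.discarded]
                combined = sorted(kept + disc)
                assert combined == sorted((f.follow_id, s.scan_time)
                                          for s in f.samples)
                assert len(set(combined)) == len(combined)


# ---------------------------------------------------------------------------
# Filtering stages
# ---------------------------------------------------------------------------

def test_drop_double_states_splits():
    follow = make_follow(states=[F, (F, M), T])
    chains = drop_double_states(build_chains(follow, "CONSERVATIVE", 0.0))
    seqs, disc = scan_indices(chains)
    assert seqs == [("CONTROL", (1,)), ("CONTROL", (3,))]
    assert disc == [2]
    # both remnants then fail the length filter
    filtered = filter_min_transitions(chains, 5)
    assert not filtered.sequences


def test_drop_double_states_identity_without_doubles():
    chains = build_chains(make_follow(states=[F, M, T]), "CONSERVATIVE", 0.0)
    assert drop_double_states(chains).sequences == chains.sequences


def test_restrict_states_splits_around_rare_states():
    follow = make_follow(states=[F, R, T])
    chains = restrict_states(build_chains(follow, "CONSERVATIVE", 0.0))
    seqs, disc = scan_indices(chains)
    assert seqs == [("CONTROL", (1,)), ("CONTROL", (3,))]
    assert disc == [2]

    follow = make_follow(states=[F, M, T])
    chains = build_chains(follow, "CONSERVATIVE", 0.0)
    assert restrict_states(chains).sequences == chains.sequences


def test_min_transitions_boundary():
    retained = build_chains(make_follow(states=[F, M, T, F, M, T]), "CONSERVATIVE", 0.0)
    assert filter_min_transitions(retained, 5).sequences  # 5 transitions kept
    short = build_chains(make_follow(states=[F, M, T, F, M]), "CONSERVATIVE", 0.0)
    assert not filter_min_transitions(short, 5).sequences  # 4 transitions dropped
    assert filter_min_transitions(short, 0).sequences == short.sequences


# ---------------------------------------------------------------------------
# Transition counting
# ---------------------------------------------------------------------------

def test_count_transitions_examples():
    chains = build_chains(make_follow(states=[F, F, T]), "CONSERVATIVE", 0.0)
    counts = count_transitions(chains)[Condition.CONTROL]
    i = {s: k for k, s in enumerate(ANALYSIS_STATES)}
    assert counts.a[i[F], i[F]] == 1 and counts.a[i[F], i[T]] == 1
    assert counts.n == 2

    two = pool_chains([
        build_chains(make_follow(states=[F, T], follow_id="a"), "CONSERVATIVE", 0.0),
        build_chains(make_follow(states=[T, M], follow_id="b"), "CONSERVATIVE", 0.0),
    ])
    counts = count_transitions(two)[Condition.CONTROL]
    assert counts.a[i[F], i[T]] == 1 and counts.a[i[T], i[M]] == 1
    assert counts.a[i[T], i[T]] == 0  # never bridges the sequence gap
    assert counts.n == 2


def test_count_transitions_matches_naive_counter(rng):
    """Pooled counts equal a sliding-window tally over each sequence."""
    states = list(ANALYSIS_STATES)
    for _ in range(100):
        seq_states = [states[k] for k in rng.integers(0, 3, size=rng.integers(2, 30))]
        chains = build_chains(make_follow(states=seq_states), "CONSERVATIVE", 0.0)
        counts = count_transitions(chains)[Condition.CONTROL]
        naive = np.zeros((3, 3), dtype=int)
        for a, b in zip(seq_states, seq_states[1:]):
            naive[states.index(a), states.index(b)] += 1
        assert (counts.a == naive).all()


def test_transition_totals_after_double_removal_match_naive(rng):
    states_all = [F, M, T]
    for _ in range(30):
        raw = []
        for _k in range(rng.integers(4, 25)):
            if rng.random() < 0.2:
                pair = rng.choice(3, size=2, replace=False)
                raw.append((states_all[pair[0]], states_all[pair[1]]))
            else:
                raw.append(states_all[rng.integers(0, 3)])
        chains = drop_double_states(
            build_chains(make_follow(states=raw), "CONSERVATIVE", 0.0))
        total = count_transitions(chains)[Condition.CONTROL].n
        # naive: count adjacent single-state pairs not separated by a double
        naive = sum(
            1 for a, b in zip(raw, raw[1:])
            if not isinstance(a, tuple) and not isinstance(b, tuple)
        )
        assert total == naive
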