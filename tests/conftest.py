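"""Shared fixtures: hand-built follows and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from delphis import (
    BehaviouralState,
    EventKind,
    FocalFollow,
    ScanSample,
    VesselCategory,
    VesselEvent,
    VesselObservation,
    default_parameters,
    simulate_dataset,
)

F = BehaviouralState.FORAGING
M = BehaviouralState.MILLING
R = BehaviouralState.RESTING
S = BehaviouralState.SOCIALISING
T = BehaviouralState.TRAVELLING


def make_follow(states=None, n_scans=10, events=(), follow_id="T2",
                interval=3.0, observations=(), swims=()):
    """A follow with scans S1..Sn at t = 0, interval, ...; events are
    (vessel_id, approach_min, departure_min) triples."""
    if states is None:
        states = [T] * n_scans
    samples = tuple(
        ScanSample(follow_id=follow_id, scan_time=k * interval,
                   states=st if isinstance(st, tuple) else (st,),
                   group_size=10)
        for k, st in enumerate(states)
    )
    evs = []
    for vid, app, dep in events:
        evs.append(VesselEvent(vid, EventKind.APPROACH, app))
        evs.append(VesselEvent(vid, EventKind.DEPARTURE, dep))
    return FocalFollow(follow_id=follow_id, samples=samples,
                       vessel_events=tuple(evs),
                       vessel_observations=tuple(observations),
                       swim_attempts=tuple(swims))


def scan_indices(chain_set):
    """Sequences and discards as 1-based scan numbers (S1 = first scan)."""
    def num(t):
        return int(round(t / 3.0)) + 1
    seqs = [
        (seq.condition.value, tuple(num(s.scan_time) for s in seq.samples))
        for seq in chain_set.sequences
    ]
    disc = sorted(num(d.scan_time) for d in chain_set.discarded)
    return seqs, disc


@pytest.fixture(scope="session")
def small_dataset():
    params = default_parameters("default")
    follows, truth = simulate_dataset(params, n_follows=8, seed=42)
    return follows, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
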