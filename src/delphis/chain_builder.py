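"""Build control/interaction behavioural chains from a focal follow.

Two construction schemes decide what happens to the scans recorded around a
vessel approach or departure, where the condition the group experienced is
ambiguous:

* **conservative** — every ambiguous sample is thrown away: when the crossing
  falls strictly between two scans, the first sample recorded under the new
  condition is discarded; when it coincides with a scan instant, that scan is
  discarded.
* **less conservative** — the behavioural transition at the onset of an
  interaction is itself treated as affected: the interaction chain is seeded
  with the last control sample preceding the approach, and only the first
  post-departure sample is discarded.

A post-interaction window (15 min by default) treats the group as still
affected after the last vessel leaves: samples inside the window are appended
to the interaction chain and the departure-side discard shifts to the window's
expiry.

After construction, double states are removed, states outside the analysis
subset are removed (splitting sequences so no transition bridges a removal),
short sequences are dropped, and adjacent same-condition pairs are pooled into
transition counts.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .io_model import (
    ANALYSIS_STATES,
    BehaviouralState,
    FocalFollow,
    ScanSample,
    ValidationError,
)

__all__ = [
    "Condition",
    "Approach",
    "StateSequence",
    "DiscardRecord",
    "ChainSet",
    "TransitionCounts",
    "label_conditions",
    "presence_intervals",
    "build_chains",
    "drop_double_states",
    "restrict_states",
    "filter_min_transitions",
    "count_transitions",
    "build_condition_counts",
]


class Condition(str, Enum):
    CONTROL = "CONTROL"
    INTERACTION = "INTERACTION"
    DISCARDED = "DISCARDED"


class Approach(str, Enum):
    CONSERVATIVE = "CONSERVATIVE"
    LESS_CONSERVATIVE = "LESS_CONSERVATIVE"


@dataclass(frozen=True)
class StateSequence:
    """A contiguous run of retained scans sharing one condition."""

    condition: Condition
    samples: tuple[ScanSample, ...]
    follow_id: str

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("empty state sequence")

    @property
    def states(self) -> tuple[BehaviouralState, ...]:
        return tuple(s.state for s in self.samples)

    @property
    def start_time(self) -> float:
        return self.samples[0].scan_time

    @property
    def end_time(self) -> float:
        return self.samples[-1].scan_time

    @property
    def n_transitions(self) -> int:
        return len(self.samples) - 1


@dataclass(frozen=True)
class DiscardRecord:
    follow_id: str
    scan_time: float
    rule: str


@dataclass(frozen=True)
class ChainSet:
    """All sequences produced for one approach, with a discard audit trail."""

    approach: Approach
    sequences: tuple[StateSequence, ...]
    discarded: tuple[DiscardRecord, ...] = ()

    def with_(self, sequences, extra_discards=()) -> "ChainSet":
        return ChainSet(self.approach, tuple(sequences),
                        self.discarded + tuple(extra_discards))

    def n_scans(self) -> int:
        return sum(len(s.samples) for s in self.sequences) + len(self.discarded)


@dataclass(frozen=True)
class TransitionCounts:
    """Counts a[i][j] of observed i->j transitions pooled over sequences."""

    condition: Condition
    states: tuple[BehaviouralState, ...]
    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=int)
        if a.shape != (len(self.states), len(self.states)) or (a < 0).any():
            raise ValidationError("transition count matrix malformed")
        object.__setattr__(self, "a", a)

    @property
    def n(self) -> int:
        return int(self.a.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.a.sum(axis=1)


# ---------------------------------------------------------------------------
# Condition labelling and presence intervals
# ---------------------------------------------------------------------------

def label_conditions(follow: FocalFollow) -> list[Condition]:
    """Label each scan CONTROL/INTERACTION from vessel presence at the instant.

    A scan is INTERACTION iff at least one non-research vessel is within
    300 m at the scan instant, taken from the scan's own vessel set or from
    within-300 m vessel observations at that time.
    """
    obs_times: dict[float, bool] = {}
    for ob in follow.vessel_observations:
        if ob.within_300m:
            obs_times[ob.scan_time] = True
    return [
        Condition.INTERACTION
        if s.vessels_within_300m or obs_times.get(s.scan_time, False)
        else Condition.CONTROL
        for s in follow.samples
    ]


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    iv = sorted(iv)
    out: list[list[float]] = []
    for a, b in iv:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def presence_intervals(follow: FocalFollow,
                       sampling_interval: float = 3.0) -> list[tuple[float, float]]:
    """Union of per-vessel [approach, departure] intervals.

    With explicit events the intervals are exact. Without events, presence
    is inferred from the per-scan labels: each maximal run of interaction
    scans becomes one interval whose boundaries fall halfway between scans
    (crossings are then strictly between scans, which is all the scan data
    can resolve).
    """
    if follow.vessel_events:
        per_vessel: dict[str, list] = {}
        for ev in sorted(follow.vessel_events, key=lambda e: e.event_time):
            per_vessel.setdefault(ev.vessel_id, []).append(ev)
        iv = []
        end_time = follow.samples[-1].scan_time if follow.samples else 0.0
        for evs in per_vessel.values():
            k = 0
            while k < len(evs):
                start = evs[k].event_time
                stop = evs[k + 1].event_time if k + 1 < len(evs) else end_time
                if stop < start:
                    raise ValidationError("departure precedes approach")
                iv.append((start, stop))
                k += 2
        return _merge_intervals(iv)

    labels = label_conditions(follow)
    half = sampling_interval / 2.0
    iv = []
    run_start = None
    for s, lab in zip(follow.samples, labels):
        if lab is Condition.INTERACTION and run_start is None:
            run_start = s.scan_time - half
        elif lab is Condition.CONTROL and run_start is not None:
            iv.append((run_start, prev_time + half))
            run_start = None
        if lab is Condition.INTERACTION:
            prev_time = s.scan_time
    if run_start is not None:
        iv.append((run_start, prev_time + half))
    return _merge_intervals(iv)


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def build_chains(follow: FocalFollow, approach: Approach | str,
                 post_window: float = 15.0,
                 sampling_interval: float = 3.0) -> ChainSet:
    """Apply one construction scheme to a follow.

    With ``post_window > 0`` the departure of the last vessel is treated as
    taking effect only ``post_window`` minutes later, so post-interaction
    samples are appended to the interaction chain and the departure-side
    rule fires at the window's expiry.
    """
    approach = Approach(approach)
    samples = follow.samples
    if not samples:
        return ChainSet(approach, ())
    times = [s.scan_time for s in samples]
    n = len(samples)
    eps = 1e-9

    intervals = presence_intervals(follow, sampling_interval)
    if post_window > 0:
        intervals = _merge_intervals([(a, b + post_window) for a, b in intervals])

    label = [Condition.CONTROL] * n
    rule = [""] * n

    def _at_instant(t: float) -> int | None:
        k = bisect_left(times, t - eps)
        if k < n and abs(times[k] - t) <= eps:
            return k
        return None

    for app, dep in intervals:
        inside_lo = bisect_right(times, app + eps)      # first scan strictly after app
        inside_hi = bisect_left(times, dep - eps)       # first scan at/after dep
        app_scan = _at_instant(app)
        dep_scan = _at_instant(dep)

        # scans strictly inside (app, dep) are unambiguous interaction
        for k in range(inside_lo, inside_hi):
            label[k] = Condition.INTERACTION

        if approach is Approach.CONSERVATIVE:
            # approach side
            if app_scan is not None:
                label[app_scan] = Condition.DISCARDED
                rule[app_scan] = "approach at scan instant"
            else:
                k = bisect_left(times, app)  # first scan after the crossing
                if k < n and label[k] is Condition.INTERACTION:
                    label[k] = Condition.DISCARDED
                    rule[k] = "first sample after approach"
            # departure side
            if dep_scan is not None:
                label[dep_scan] = Condition.DISCARDED
                rule[dep_scan] = "departure at scan instant"
            else:
                k = bisect_left(times, dep)  # first scan after the crossing
                if k < n and label[k] is Condition.CONTROL:
                    label[k] = Condition.DISCARDED
                    rule[k] = "first sample after departure"
        else:  # LESS_CONSERVATIVE
            # the scan at the approach instant counts as the last pre-approach
            # sample; the chain is seeded with the control sample preceding the
            # first affected scan so the onset transition is counted as affected
            first_affected = app_scan if app_scan is not None else bisect_left(times, app)
            if first_affected < n:
                label[first_affected] = Condition.INTERACTION
                if first_affected > 0 and label[first_affected - 1] is Condition.CONTROL:
                    label[first_affected - 1] = Condition.INTERACTION
            # the scan at the departure instant is the last interaction sample
            if dep_scan is not None:
                label[dep_scan] = Condition.INTERACTION
                k = dep_scan + 1
            else:
                k = bisect_left(times, dep)
            if k < n and label[k] is Condition.CONTROL:
                label[k] = Condition.DISCARDED
                rule[k] = "first sample after departure"

    sequences: list[StateSequence] = []
    discarded: list[DiscardRecord] = []
    run: list[ScanSample] = []
    run_cond: Condition | None = None

    def flush() -> None:
        nonlocal run, run_cond
        if run:
            sequences.append(StateSequence(run_cond, tuple(run), follow.follow_id))
        run, run_cond = [], None

    for k, s in enumerate(samples):
        if label[k] is Condition.DISCARDED:
            flush()
            discarded.append(DiscardRecord(follow.follow_id, s.scan_time, rule[k]))
            continue
        if label[k] is not run_cond:
            flush()
            run_cond = label[k]
        run.append(s)
    flush()
    return ChainSet(approach, tuple(sequences), tuple(discarded))


def pool_chains(chain_sets: Iterable[ChainSet]) -> ChainSet:
    """Concatenate per-follow chain sets (sequences never span follows)."""
    chain_sets = list(chain_sets)
    if not chain_sets:
        raise ValidationError("nothing to pool")
    approach = chain_sets[0].approach
    if any(cs.approach is not approach for cs in chain_sets):
        raise ValidationError("cannot pool chain sets built with different schemes")
    seqs: list[StateSequence] = []
    disc: list[DiscardRecord] = []
    for cs in chain_sets:
        seqs.extend(cs.sequences)
        disc.extend(cs.discarded)
    return ChainSet(approach, tuple(seqs), tuple(disc))


# ---------------------------------------------------------------------------
# Filtering stages (order: doubles -> state restriction -> length filter)
# ---------------------------------------------------------------------------

def _split_sequence(seq: StateSequence, keep_mask: Sequence[bool]
                    ) -> list[StateSequence]:
    out: list[StateSequence] = []
    run: list[ScanSample] = []
    for s, keep in zip(seq.samples, keep_mask):
        if keep:
            run.append(s)
        elif run:
            out.append(StateSequence(seq.condition, tuple(run), seq.follow_id))
            run = []
    if run:
        out.append(StateSequence(seq.condition, tuple(run), seq.follow_id))
    return out


def drop_double_states(chains: ChainSet) -> ChainSet:
    """Remove tied double-state scans, splitting sequences at each removal."""
    seqs: list[StateSequence] = []
    disc: list[DiscardRecord] = []
    for seq in chains.sequences:
        mask = [not s.is_double for s in seq.samples]
        for s, keep in zip(seq.samples, mask):
            if not keep:
                disc.append(DiscardRecord(seq.follow_id, s.scan_time, "double state"))
        seqs.extend(_split_sequence(seq, mask))
    return chains.with_(seqs, disc)


def restrict_states(chains: ChainSet,
                    keep: Sequence[BehaviouralState] = ANALYSIS_STATES) -> ChainSet:
    """Drop scans outside the analysis subset; no transition bridges a removal."""
    keep_set = set(keep)
    seqs: list[StateSequence] = []
    disc: list[DiscardRecord] = []
    for seq in chains.sequences:
        mask = [s.state in keep_set for s in seq.samples]
        for s, k in zip(seq.samples, mask):
            if not k:
                disc.append(DiscardRecord(
                    seq.follow_id, s.scan_time, f"state {s.state.value} not analysed"))
        seqs.extend(_split_sequence(seq, mask))
    return chains.with_(seqs, disc)


def filter_min_transitions(chains: ChainSet, k: int = 5) -> ChainSet:
    """Move sequences with fewer than ``k`` transitions to the discard list."""
    seqs: list[StateSequence] = []
    disc: list[DiscardRecord] = []
    for seq in chains.sequences:
        if seq.n_transitions >= k:
            seqs.append(seq)
        else:
            disc.extend(DiscardRecord(
                seq.follow_id, s.scan_time,
                f"sequence shorter than {k} transitions") for s in seq.samples)
    return chains.with_(seqs, disc)


# ---------------------------------------------------------------------------
# Transition counting
# ---------------------------------------------------------------------------

def count_transitions(chains: ChainSet,
                      states: Sequence[BehaviouralState] = ANALYSIS_STATES,
                      ) -> dict[Condition, TransitionCounts]:
    """Pool adjacent same-sequence pairs into per-condition count matrices."""
    index = {s: i for i, s in enumerate(states)}
    mats = {c: np.zeros((len(states), len(states)), dtype=int)
            for c in (Condition.CONTROL, Condition.INTERACTION)}
    for seq in chains.sequences:
        a = mats[seq.condition]
        st = seq.states
        for s1, s2 in zip(st, st[1:]):
            a[index[s1], index[s2]] += 1
    return {c: TransitionCounts(c, tuple(states), a) for c, a in mats.items()}


def build_condition_counts(follows: Sequence[FocalFollow],
                           approach: Approach | str,
                           post_window: float = 15.0,
                           min_transitions: int = 5,
                           sampling_interval: float = 3.0,
                           states: Sequence[BehaviouralState] = ANALYSIS_STATES,
                           ) -> tuple[ChainSet, dict[Condition, TransitionCounts]]:
    """Full chain pipeline over many follows, in the fixed stage order."""
    pooled = pool_chains([
        build_chains(f, approach, post_window, sampling_interval) for f in follows
    ])
    pooled = drop_double_states(pooled)
    pooled = restrict_states(pooled, states)
    pooled = filter_min_transitions(pooled, min_transitions)
    return pooled, count_transitions(pooled, states)
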