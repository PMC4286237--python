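"""Rule engine and summaries for tour-regulation compliance.

Five coded rules from the New Zealand marine-mammal regulations and permit
conditions are checked per follow: no-wake speed (5 kt) within 300 m, at most
3 vessels engaged at once, 90 min of interaction per vessel, 60 min of
swimming per trip, and no swimming with calves; an optional harbour flag per
scan supports the area restriction for tour vessels.

"Engaged" is operationalised as within 300 m at the same scan instant — the
only observable the scan-sampled data model offers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .inference import kruskal_wallis
from .io_model import (
    AnalysisConfig,
    BehaviouralState,
    FocalFollow,
    SwimAttempt,
    SwimEndReason,
    SwimResponse,
    ValidationError,
    VesselCategory,
)

__all__ = [
    "Rule",
    "Violation",
    "check_follow",
    "summarize_traffic",
    "summarize_swims",
    "TrafficSummary",
    "SwimSummary",
]


class Rule(str, Enum):
    SPEED = "SPEED"
    VESSEL_COUNT = "VESSEL_COUNT"
    DURATION = "DURATION"
    SWIM_DURATION = "SWIM_DURATION"
    SWIM_WITH_CALVES = "SWIM_WITH_CALVES"
    AREA = "AREA"


@dataclass(frozen=True)
class Violation:
    rule: Rule
    follow_id: str
    subject_id: str        # vessel_id or attempt_id
    measured: float
    threshold: float
    time_span: tuple[float, float]
    detail: str

    def __post_init__(self) -> None:
        breach = (self.measured > self.threshold if self.rule is not Rule.SWIM_WITH_CALVES
                  else self.measured > 0)
        if self.rule is Rule.AREA:
            breach = self.measured > 0
        if not breach:
            raise ValidationError("recorded violation does not breach its threshold")


def _vessel_minutes(follow: FocalFollow, interval: float) -> dict[str, float]:
    """Cumulative within-300 m time per vessel.

    Event intervals give exact times where available; vessels observed only
    at scans accrue one sampling interval per within-300 m observation.
    """
    out: dict[str, float] = {}
    per_vessel: dict[str, list] = {}
    for ev in sorted(follow.vessel_events, key=lambda e: e.event_time):
        per_vessel.setdefault(ev.vessel_id, []).append(ev)
    end_time = follow.samples[-1].scan_time if follow.samples else 0.0
    for vid, evs in per_vessel.items():
        total = 0.0
        k = 0
        while k < len(evs):
            stop = evs[k + 1].event_time if k + 1 < len(evs) else end_time
            total += max(0.0, stop - evs[k].event_time)
            k += 2
        out[vid] = total
    for ob in follow.vessel_observations:
        if ob.within_300m and ob.vessel_id not in per_vessel:
            out[ob.vessel_id] = out.get(ob.vessel_id, 0.0) + interval
    return out


def check_follow(follow: FocalFollow,
                 config: AnalysisConfig | None = None) -> list[Violation]:
    """Evaluate all five rules (plus the harbour rule) on one follow."""
    config = config or AnalysisConfig()
    violations: list[Violation] = []
    interval = config.sampling_interval

    # SPEED: per within-300 m speed sample
    for ob in follow.vessel_observations:
        if ob.within_300m and ob.speed > config.speed_limit:
            violations.append(Violation(
                Rule.SPEED, follow.follow_id, ob.vessel_id,
                measured=ob.speed, threshold=config.speed_limit,
                time_span=(ob.scan_time, ob.scan_time),
                detail=f"{ob.speed:g} kts within 300 m (limit {config.speed_limit:g})",
            ))

    # VESSEL_COUNT: per scan instant with more than max_vessels engaged
    by_time: dict[float, set[str]] = {}
    for ob in follow.vessel_observations:
        if ob.within_300m:
            by_time.setdefault(ob.scan_time, set()).add(ob.vessel_id)
    for s in follow.samples:
        by_time.setdefault(s.scan_time, set()).update(s.vessels_within_300m)
    for t in sorted(by_time):
        n = len(by_time[t])
        if n > config.max_vessels:
            violations.append(Violation(
                Rule.VESSEL_COUNT, follow.follow_id, ";".join(sorted(by_time[t])),
                measured=n, threshold=config.max_vessels,
                time_span=(t, t),
                detail=f"{n} vessels engaged (limit {config.max_vessels})",
            ))

    # DURATION: cumulative encounter time per vessel
    for vid, minutes in sorted(_vessel_minutes(follow, interval).items()):
        if minutes > config.max_encounter:
            violations.append(Violation(
                Rule.DURATION, follow.follow_id, vid,
                measured=minutes, threshold=config.max_encounter,
                time_span=(0.0, minutes),
                detail=f"{minutes:g} min of interaction "
                       f"(limit {config.max_encounter:g})",
            ))

    # SWIM_DURATION: total swim time per trip/follow
    swim_total = sum(a.duration for a in follow.swim_attempts)
    if swim_total > config.max_swim:
        violations.append(Violation(
            Rule.SWIM_DURATION, follow.follow_id, follow.follow_id,
            measured=swim_total, threshold=config.max_swim,
            time_span=(0.0, swim_total),
            detail=f"{swim_total:g} min of swimming (limit {config.max_swim:g})",
        ))

    # SWIM_WITH_CALVES: any attempt with calves present
    for a in follow.swim_attempts:
        if a.calf_present:
            violations.append(Violation(
                Rule.SWIM_WITH_CALVES, follow.follow_id, a.attempt_id,
                measured=1.0, threshold=0.0,
                time_span=(a.start_time, a.end_time),
                detail="swim attempt with calf present",
            ))

    # AREA: tour vessel engaged while the group is inside the harbour
    tour_ids = {ob.vessel_id for ob in follow.vessel_observations
                if ob.category is VesselCategory.TOUR}
    for s in follow.samples:
        if s.in_harbour and (s.vessels_within_300m & tour_ids):
            violations.append(Violation(
                Rule.AREA, follow.follow_id,
                ";".join(sorted(s.vessels_within_300m & tour_ids)),
                measured=1.0, threshold=0.0,
                time_span=(s.scan_time, s.scan_time),
                detail="tour vessel engaged inside harbour",
            ))
    return violations


# ---------------------------------------------------------------------------
# Traffic summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrafficSummary:
    per_vessel_minutes: dict[tuple[str, str], float]      # (follow, vessel) -> min
    per_vessel_approaches: dict[tuple[str, str], int]
    category_of: dict[tuple[str, str], VesselCategory]
    speed_stats: dict[VesselCategory, dict]               # median/iqr/n
    speed_kw: tuple[float, int, float] | None             # across categories
    time_kw: tuple[float, int, float] | None              # TV vs non-TV minutes
    simultaneous_counts: dict[int, int]                   # max concurrent -> episodes
    share_two_or_three: float | None                      # of simultaneous episodes


def _episodes(follow: FocalFollow, vid: str, interval: float
              ) -> list[tuple[float, float]]:
    """Presence episodes for one vessel, from events or from scan runs."""
    evs = sorted((e for e in follow.vessel_events if e.vessel_id == vid),
                 key=lambda e: e.event_time)
    if evs:
        out = []
        end_time = follow.samples[-1].scan_time if follow.samples else 0.0
        k = 0
        while k < len(evs):
            stop = evs[k + 1].event_time if k + 1 < len(evs) else end_time
            out.append((evs[k].event_time, stop))
            k += 2
        return out
    times = sorted(ob.scan_time for ob in follow.vessel_observations
                   if ob.vessel_id == vid and ob.within_300m)
    out = []
    for t in times:
        if out and t - out[-1][1] <= interval + 1e-9:
            out[-1] = (out[-1][0], t)
        else:
            out.append((t, t))
    return out


def summarize_traffic(follows: Sequence[FocalFollow],
                      sampling_interval: float = 3.0) -> TrafficSummary:
    """Cumulative encounter times, approach counts, speeds, and their tests."""
    minutes: dict[tuple[str, str], float] = {}
    approaches: dict[tuple[str, str], int] = {}
    cat_of: dict[tuple[str, str], VesselCategory] = {}
    speeds: dict[VesselCategory, list[float]] = {}
    simultaneous: dict[int, int] = {}

    for f in follows:
        vm = _vessel_minutes(f, sampling_interval)
        vids = {ob.vessel_id for ob in f.vessel_observations}
        vids |= set(vm)
        for vid in vids:
            key = (f.follow_id, vid)
            minutes[key] = vm.get(vid, 0.0)
            approaches[key] = len(_episodes(f, vid, sampling_interval))
        for ob in f.vessel_observations:
            cat_of[(f.follow_id, ob.vessel_id)] = ob.category
            if ob.within_300m:
                speeds.setdefault(ob.category, []).append(ob.speed)

        # simultaneous-interaction episodes: maximal scan runs with >= 2 vessels
        counts = []
        for s in f.samples:
            obs_now = {ob.vessel_id for ob in f.vessel_observations
                       if ob.within_300m and ob.scan_time == s.scan_time}
            counts.append(len(s.vessels_within_300m | obs_now))
        run_max = 0
        for c in counts + [0]:
            if c >= 2:
                run_max = max(run_max, c)
            elif run_max:
                simultaneous[run_max] = simultaneous.get(run_max, 0) + 1
                run_max = 0

    speed_stats = {}
    for cat, vals in speeds.items():
        arr = np.asarray(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        speed_stats[cat] = {"median": float(med), "iqr": float(q3 - q1),
                            "n": int(arr.size)}

    speed_kw = None
    if len(speeds) >= 2:
        speed_kw = kruskal_wallis([speeds[c] for c in sorted(speeds)])

    tv = [m for (fid, vid), m in minutes.items()
          if cat_of.get((fid, vid)) is VesselCategory.TOUR]
    non_tv = [m for (fid, vid), m in minutes.items()
              if cat_of.get((fid, vid)) not in (None, VesselCategory.TOUR)]
    time_kw = kruskal_wallis([tv, non_tv]) if tv and non_tv else None

    n_sim = sum(simultaneous.values())
    share23 = (sum(v for k, v in simultaneous.items() if k in (2, 3)) / n_sim
               if n_sim else None)
    return TrafficSummary(minutes, approaches, cat_of, speed_stats,
                          speed_kw, time_kw, simultaneous, share23)


# ---------------------------------------------------------------------------
# Swim summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwimSummary:
    n: int
    mean_duration: float | None
    sd_duration: float | None
    band_proportions: dict[str, float]        # "<5", "5-10", ">10"
    response_proportions: dict[SwimResponse, float]
    response_chi2: tuple[float, int, float] | None  # neutral/interaction/avoidance
    end_reason_proportions: dict[SwimEndReason, float]
    state_at_start: dict[BehaviouralState, float]
    calf_incidence: float | None


def summarize_swims(attempts: Sequence[SwimAttempt]) -> SwimSummary:
    """Durations, response categories (with chi-square) and end reasons.

    Neutral presence and neutral absence merge into a single "neutral" cell
    for the three-category goodness-of-fit chi-square (against equal
    expected frequencies), which is why its df is 2.
    """
    n = len(attempts)
    if n == 0:
        return SwimSummary(0, None, None, {}, {}, None, {}, {}, None)
    durations = np.array([a.duration for a in attempts])
    bands = {
        "<5": float(np.mean(durations < 5)),
        "5-10": float(np.mean((durations >= 5) & (durations <= 10))),
        ">10": float(np.mean(durations > 10)),
    }
    resp = {r: sum(a.response is r for a in attempts) / n for r in SwimResponse}
    neutral = sum(a.response in (SwimResponse.NEUTRAL_PRESENCE,
                                 SwimResponse.NEUTRAL_ABSENCE) for a in attempts)
    inter = sum(a.response is SwimResponse.INTERACTION for a in attempts)
    avoid = sum(a.response is SwimResponse.AVOIDANCE for a in attempts)
    chi2 = None
    if n >= 3:
        from scipy import stats
        res = stats.chisquare([neutral, inter, avoid])
        chi2 = (float(res.statistic), 2, float(res.pvalue))
    reasons = {r: sum(a.end_reason is r for a in attempts) / n for r in SwimEndReason}
    starts: dict[BehaviouralState, float] = {}
    for a in attempts:
        starts[a.state_at_start] = starts.get(a.state_at_start, 0) + 1 / n
    return SwimSummary(
        n=n,
        mean_duration=float(durations.mean()),
        sd_duration=float(durations.std(ddof=1)) if n > 1 else None,
        band_proportions=bands,
        response_proportions=resp,
        response_chi2=chi2,
        end_reason_proportions=reasons,
        state_at_start=starts,
        calf_incidence=sum(a.calf_present for a in attempts) / n,
    )
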