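"""Domain types, validation, file round-trips and reporting for focal-follow data.

The data model mirrors a boat-based focal-group follow protocol: the behavioural
state of one dolphin group is scan-sampled on a fixed grid (3 min by default),
while every non-research vessel near the group is logged (category, per-scan
speed, a within-300 m flag) together with its approach/departure times and any
swim attempts made from tour vessels.

All on-disk formats are plain delimited text (CSV) so that datasets survive
version control and can be inspected by hand; see the reader docstrings for the
exact headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "BehaviouralState",
    "ANALYSIS_STATES",
    "VesselCategory",
    "EventKind",
    "SwimResponse",
    "SwimEndReason",
    "ScanSample",
    "VesselObservation",
    "VesselEvent",
    "SwimAttempt",
    "FocalFollow",
    "AnalysisConfig",
    "ValidationError",
    "round1",
    "format_percent",
    "read_scan_log",
    "read_vessel_log",
    "read_event_log",
    "read_swim_log",
    "read_dataset",
    "write_scan_log",
    "write_vessel_log",
    "write_event_log",
    "write_swim_log",
    "write_dataset",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class BehaviouralState(str, Enum):
    """Ethogram states of a dolphin group.

    Five states are scored in the field; resting and socialising are too rare
    to support transition estimates, so chain analyses run on the
    three-state analysis subset (:data:`ANALYSIS_STATES`).
    """

    FORAGING = "FORAGING"
    MILLING = "MILLING"
    RESTING = "RESTING"
    SOCIALISING = "SOCIALISING"
    TRAVELLING = "TRAVELLING"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The subset of states retained for Markov-chain analysis.
ANALYSIS_STATES: tuple[BehaviouralState, ...] = (
    BehaviouralState.FORAGING,
    BehaviouralState.MILLING,
    BehaviouralState.TRAVELLING,
)


class VesselCategory(str, Enum):
    TOUR = "TOUR"
    NON_MOTORISED = "NON_MOTORISED"
    REC_LAUNCH = "REC_LAUNCH"
    REC_TRAILER = "REC_TRAILER"
    PERSONAL_CRAFT = "PERSONAL_CRAFT"
    COMMERCIAL = "COMMERCIAL"


class EventKind(str, Enum):
    APPROACH = "APPROACH"
    DEPARTURE = "DEPARTURE"


class SwimResponse(str, Enum):
    NEUTRAL_PRESENCE = "NEUTRAL_PRESENCE"
    NEUTRAL_ABSENCE = "NEUTRAL_ABSENCE"
    AVOIDANCE = "AVOIDANCE"
    INTERACTION = "INTERACTION"


class SwimEndReason(str, Enum):
    DOLPHIN_BEHAVIOUR = "DOLPHIN_BEHAVIOUR"
    LOST_SIGHT = "LOST_SIGHT"
    SKIPPER_DECISION = "SKIPPER_DECISION"
    CALF_PRESENCE = "CALF_PRESENCE"


class ValidationError(ValueError):
    """Raised when an input record violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanSample:
    """One instantaneous scan of the focal group.

    ``states`` holds one state normally, or two when the group split evenly
    between behaviours (a "double state", later excluded from chain
    analyses). ``vessels_within_300m`` names the non-research vessels inside
    the 300 m interaction radius at the scan instant.
    """

    follow_id: str
    scan_time: float  # minutes from follow start, on the sampling grid
    states: tuple[BehaviouralState, ...]
    group_size: int = 1
    n_calves: int = 0
    n_juveniles: int = 0
    vessels_within_300m: frozenset[str] = frozenset()
    in_harbour: bool = False

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("scan needs at least one behavioural state")
        if len(self.states) > 2:
            raise ValidationError("at most two tied states per scan")
        if len(set(self.states)) != len(self.states):
            raise ValidationError("duplicate state in scan")
        if self.scan_time < 0:
            raise ValidationError("scan_time must be non-negative")
        if self.group_size < 1:
            raise ValidationError("group_size must be positive")
        if self.n_calves < 0 or self.n_juveniles < 0:
            raise ValidationError("calf/juvenile counts must be non-negative")
        if self.n_calves + self.n_juveniles > self.group_size:
            raise ValidationError("immatures cannot outnumber the group")

    @property
    def is_double(self) -> bool:
        return len(self.states) == 2

    @property
    def state(self) -> BehaviouralState:
        """The single recorded state; invalid for double states."""
        if self.is_double:
            raise ValidationError("double state has no unique state")
        return self.states[0]


@dataclass(frozen=True)
class VesselObservation:
    """Per-scan record of one vessel near the focal group."""

    vessel_id: str
    category: VesselCategory
    scan_time: float
    speed: float  # knots
    within_300m: bool

    def __post_init__(self) -> None:
        if not (self.speed >= 0 and self.speed == self.speed and self.speed != float("inf")):
            raise ValidationError("speed must be finite and non-negative")


@dataclass(frozen=True)
class VesselEvent:
    """A vessel crossing the 300 m interaction radius (either direction).

    Event times are real-valued minutes and need not lie on the scan grid.
    """

    vessel_id: str
    kind: EventKind
    event_time: float


@dataclass(frozen=True)
class SwimAttempt:
    follow_id: str
    attempt_id: str
    start_time: float
    end_time: float
    response: SwimResponse
    end_reason: SwimEndReason
    calf_present: bool
    state_at_start: BehaviouralState

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValidationError("swim attempt must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class FocalFollow:
    """One focal-group follow with its companion vessel and swim records."""

    follow_id: str
    samples: tuple[ScanSample, ...]
    vessel_observations: tuple[VesselObservation, ...] = ()
    vessel_events: tuple[VesselEvent, ...] = ()
    swim_attempts: tuple[SwimAttempt, ...] = ()
    season_label: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        times = [s.scan_time for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"follow {self.follow_id}: scan times must be strictly increasing"
            )
        # events must alternate approach/departure per vessel
        per_vessel: dict[str, list[VesselEvent]] = {}
        for ev in sorted(self.vessel_events, key=lambda e: e.event_time):
            per_vessel.setdefault(ev.vessel_id, []).append(ev)
        for vid, evs in per_vessel.items():
            for k, ev in enumerate(evs):
                want = EventKind.APPROACH if k % 2 == 0 else EventKind.DEPARTURE
                if ev.kind is not want:
                    raise ValidationError(
                        f"follow {self.follow_id}: events for vessel {vid} do not "
                        f"alternate APPROACH/DEPARTURE"
                    )
        # category fixed per vessel within the follow
        cats: dict[str, VesselCategory] = {}
        for ob in self.vessel_observations:
            prev = cats.setdefault(ob.vessel_id, ob.category)
            if prev is not ob.category:
                raise ValidationError(
                    f"follow {self.follow_id}: vessel {ob.vessel_id} changes category"
                )

    @property
    def duration(self) -> float:
        """Follow span in minutes, counting one interval per scan."""
        if not self.samples:
            return 0.0
        times = [s.scan_time for s in self.samples]
        if len(times) == 1:
            return 0.0
        return times[-1] - times[0] + (times[1] - times[0])


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the whole pipeline.

    Defaults encode the study protocol and New Zealand marine-mammal rules:
    3-min scans, a 300 m interaction radius, sequences of >= 5 transitions,
    a 15-min post-interaction window, 5 kt no-wake speed within 300 m, at
    most 3 vessels engaged, 90 min per encounter of which 60 min swimming.
    """

    sampling_interval: float = 3.0
    approach: str = "BOTH"  # CONSERVATIVE | LESS_CONSERVATIVE | BOTH
    min_transitions: int = 5
    post_window: float = 15.0
    alpha: float = 0.05
    interaction_radius: float = 300.0
    speed_limit: float = 5.0
    max_vessels: int = 3
    max_encounter: float = 90.0
    max_swim: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_interval", "interaction_radius", "speed_limit",
                     "max_encounter", "max_swim"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_transitions < 0 or self.max_vessels < 1:
            raise ValidationError("count thresholds out of range")
        if self.post_window < 0:
            raise ValidationError("post_window must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.approach not in ("CONSERVATIVE", "LESS_CONSERVATIVE", "BOTH"):
            raise ValidationError(f"unknown approach {self.approach!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# Rounding conventions
# ---------------------------------------------------------------------------

def round1(x: float) -> float:
    """Round to one decimal, half away from zero (the tables' convention)."""
    q = Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


def format_percent(p: float) -> str:
    """Render a proportion as a one-decimal percent string, e.g. 0.60192 -> '60.2%'."""
    return f"{round1(100.0 * p):.1f}%"


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_SCAN_COLS = ["follow_id", "scan_time_min", "state_1", "state_2",
              "group_size", "n_calves", "n_juveniles"]
_VESSEL_COLS = ["follow_id", "vessel_id", "category", "scan_time_min",
                "speed_kts", "within_300m"]
_EVENT_COLS = ["follow_id", "vessel_id", "kind", "event_time_min"]
_SWIM_COLS = ["follow_id", "attempt_id", "start_min", "end_min", "response",
              "end_reason", "calf_present", "state_at_start"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path, optional=()) -> None:
    missing = [c for c in cols if c not in df.columns and c not in optional]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _parse_state(raw: str, row: int, path) -> BehaviouralState:
    try:
        return BehaviouralState(str(raw).strip().upper())
    except ValueError:
        raise ValidationError(f"{path}, row {row}: unknown state code {raw!r}") from None


def read_scan_log(path: str | Path, config: AnalysisConfig | None = None,
                  ) -> list[FocalFollow]:
    """Read a scan-log CSV into validated follows.

    Header: ``follow_id, scan_time_min, state_1, state_2, group_size,
    n_calves, n_juveniles`` (``state_2`` optional/blank; an optional
    ``in_harbour`` column is honoured). Scan times must sit on consecutive
    multiples of the sampling interval within each follow; violations are
    rejected with the offending row number.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _SCAN_COLS, path, optional=("state_2",))
    follows: dict[str, list[ScanSample]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        d = row._asdict()
        t = float(d["scan_time_min"])
        k = t / config.sampling_interval
        if abs(k - round(k)) > 1e-9:
            raise ValidationError(
                f"{path}, row {idx}: scan_time {t} not a multiple of the "
                f"{config.sampling_interval}-min sampling interval"
            )
        states = [_parse_state(d["state_1"], idx, path)]
        if d.get("state_2", "").strip():
            states.append(_parse_state(d["state_2"], idx, path))
        try:
            sample = ScanSample(
                follow_id=str(d["follow_id"]),
                scan_time=t,
                states=tuple(states),
                group_size=int(d["group_size"]),
                n_calves=int(d["n_calves"]),
                n_juveniles=int(d["n_juveniles"]),
                in_harbour=str(d.get("in_harbour", "")).strip().lower()
                in ("1", "true", "yes"),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {idx}: {exc}") from None
        follows.setdefault(sample.follow_id, []).append(sample)

    out = []
    for fid, samples in follows.items():
        samples.sort(key=lambda s: s.scan_time)
        for a, b in zip(samples, samples[1:]):
            if abs(b.scan_time - a.scan_time - config.sampling_interval) > 1e-9:
                raise ValidationError(
                    f"{path}: follow {fid} has a gap or duplicate between "
                    f"scan_time {a.scan_time} and {b.scan_time}"
                )
        out.append(FocalFollow(follow_id=fid, samples=tuple(samples)))
    return out


def _read_enum(cls, raw, row, path):
    try:
        return cls(str(raw).strip().upper())
    except ValueError:
        raise ValidationError(
            f"{path}, row {row}: unknown {cls.__name__} value {raw!r}"
        ) from None


def read_vessel_log(path: str | Path) -> dict[str, list[VesselObservation]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _VESSEL_COLS, path)
    out: dict[str, list[VesselObservation]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ob = VesselObservation(
            vessel_id=str(d["vessel_id"]),
            category=_read_enum(VesselCategory, d["category"], idx, path),
            scan_time=float(d["scan_time_min"]),
            speed=float(d["speed_kts"]),
            within_300m=str(d["within_300m"]).strip().lower() in ("1", "true", "yes"),
        )
        out.setdefault(str(d["follow_id"]), []).append(ob)
    return out


def read_event_log(path: str | Path) -> dict[str, list[VesselEvent]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _EVENT_COLS, path)
    out: dict[str, list[VesselEvent]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        ev = VesselEvent(
            vessel_id=str(d["vessel_id"]),
            kind=_read_enum(EventKind, d["kind"], idx, path),
            event_time=float(d["event_time_min"]),
        )
        out.setdefault(str(d["follow_id"]), []).append(ev)
    return out


def read_swim_log(path: str | Path) -> dict[str, list[SwimAttempt]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _SWIM_COLS, path)
    out: dict[str, list[SwimAttempt]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        at = SwimAttempt(
            follow_id=str(d["follow_id"]),
            attempt_id=str(d["attempt_id"]),
            start_time=float(d["start_min"]),
            end_time=float(d["end_min"]),
            response=_read_enum(SwimResponse, d["response"], idx, path),
            end_reason=_read_enum(SwimEndReason, d["end_reason"], idx, path),
            calf_present=str(d["calf_present"]).strip().lower() in ("1", "true", "yes"),
            state_at_start=_parse_state(d["state_at_start"], idx, path),
        )
        out.setdefault(str(d["follow_id"]), []).append(at)
    return out


def read_dataset(scan_path: str | Path,
                 vessel_path: str | Path | None = None,
                 event_path: str | Path | None = None,
                 swim_path: str | Path | None = None,
                 config: AnalysisConfig | None = None,
                 meta_path: str | Path | None = None) -> list[FocalFollow]:
    """Read the scan log and merge any companion logs into the follows.

    Scans carry their own ``vessels_within_300m`` only when an event or
    vessel log supplies presence; the merge recomputes the per-scan vessel
    sets from within-300 m observations so the two representations agree.
    """
    follows = read_scan_log(scan_path, config)
    vessels = read_vessel_log(vessel_path) if vessel_path else {}
    events = read_event_log(event_path) if event_path else {}
    swims = read_swim_log(swim_path) if swim_path else {}
    meta: dict[str, dict] = {}
    if meta_path:
        meta = {str(k): v for k, v in json.loads(Path(meta_path).read_text()).items()}

    merged = []
    for f in follows:
        obs = tuple(vessels.get(f.follow_id, ()))
        by_time: dict[float, set[str]] = {}
        for ob in obs:
            if ob.within_300m:
                by_time.setdefault(ob.scan_time, set()).add(ob.vessel_id)
        samples = tuple(
            replace(s, vessels_within_300m=frozenset(by_time.get(s.scan_time, ())))
            for s in f.samples
        )
        m = meta.get(f.follow_id, {})
        merged.append(FocalFollow(
            follow_id=f.follow_id,
            samples=samples,
            vessel_observations=obs,
            vessel_events=tuple(events.get(f.follow_id, ())),
            swim_attempts=tuple(swims.get(f.follow_id, ())),
            season_label=m.get("season_label", ""),
            date=m.get("date", ""),
        ))
    return merged


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_scan_log(follows: Iterable[FocalFollow], path: str | Path) -> None:
    rows = []
    for f in follows:
        for s in f.samples:
            rows.append({
                "follow_id": f.follow_id,
                "scan_time_min": s.scan_time,
                "state_1": s.states[0].value,
                "state_2": s.states[1].value if s.is_double else "",
                "group_size": s.group_size,
                "n_calves": s.n_calves,
                "n_juveniles": s.n_juveniles,
                "in_harbour": int(s.in_harbour),
            })
    pd.DataFrame(rows, columns=_SCAN_COLS + ["in_harbour"]).to_csv(path, index=False)


def write_vessel_log(follows: Iterable[FocalFollow], path: str | Path) -> None:
    rows = []
    for f in follows:
        for ob in f.vessel_observations:
            rows.append({
                "follow_id": f.follow_id,
                "vessel_id": ob.vessel_id,
                "category": ob.category.value,
                "scan_time_min": ob.scan_time,
                "speed_kts": ob.speed,
                "within_300m": int(ob.within_300m),
            })
    pd.DataFrame(rows, columns=_VESSEL_COLS).to_csv(path, index=False)


def write_event_log(follows: Iterable[FocalFollow], path: str | Path) -> None:
    rows = []
    for f in follows:
        for ev in f.vessel_events:
            rows.append({
                "follow_id": f.follow_id,
                "vessel_id": ev.vessel_id,
                "kind": ev.kind.value,
                "event_time_min": ev.event_time,
            })
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False)


def write_swim_log(follows: Iterable[FocalFollow], path: str | Path) -> None:
    rows = []
    for f in follows:
        for at in f.swim_attempts:
            rows.append({
                "follow_id": f.follow_id,
                "attempt_id": at.attempt_id,
                "start_min": at.start_time,
                "end_min": at.end_time,
                "response": at.response.value,
                "end_reason": at.end_reason.value,
                "calf_present": int(at.calf_present),
                "state_at_start": at.state_at_start.value,
            })
    pd.DataFrame(rows, columns=_SWIM_COLS).to_csv(path, index=False)


def write_dataset(follows: Sequence[FocalFollow], directory: str | Path,
                  prefix: str = "focal") -> dict[str, Path]:
    """Write the four companion CSV logs plus a follow-metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "scans": directory / f"{prefix}_scans.csv",
        "vessels": directory / f"{prefix}_vessels.csv",
        "events": directory / f"{prefix}_events.csv",
        "swims": directory / f"{prefix}_swims.csv",
        "meta": directory / f"{prefix}_meta.json",
    }
    write_scan_log(follows, paths["scans"])
    write_vessel_log(follows, paths["vessels"])
    write_event_log(follows, paths["events"])
    write_swim_log(follows, paths["swims"])
    meta = {f.follow_id: {"season_label": f.season_label, "date": f.date}
            for f in follows}
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REPORT_SECTIONS = ("budgets", "tests", "sweep", "compliance")


def write_report(results: Mapping, path: str | Path) -> Path:
    """Write a results bundle as JSON plus a human-readable text summary.

    ``results`` may hold any subset of the sections ``budgets``, ``tests``,
    ``sweep`` and ``compliance``; missing sections are emitted empty.
    Percentages in the text summary follow the one-decimal convention of
    the reference tables.
    """
    path = Path(path)
    bundle = {sec: results.get(sec, {}) for sec in _REPORT_SECTIONS}
    path.write_text(json.dumps(bundle, indent=1, default=_jsonify))

    lines = ["Focal-follow analysis report", "=" * 28, ""]
    budgets = bundle["budgets"]
    if budgets:
        lines.append("Behavioural budgets (stationary, % of time):")
        for cond, per_state in budgets.items():
            parts = ", ".join(f"{s}: {format_percent(v)}" for s, v in per_state.items())
            lines.append(f"  {cond}: {parts}")
        lines.append("")
    if bundle["tests"]:
        lines.append(f"Statistical tests: {len(bundle['tests'])} entries "
                     "(p-values unadjusted).")
        lines.append("")
    swp = bundle["sweep"]
    if swp:
        crit = swp.get("critical", {})
        for state, a in crit.items():
            lines.append(
                f"Critical traffic intensity for {state}: "
                + (format_percent(a) if a is not None else "not reached")
            )
        lines.append("")
    comp = bundle["compliance"]
    if comp:
        lines.append(f"Compliance violations: {comp.get('n_violations', 0)}")
        lines.append("")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, Enum):
        return obj.value
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
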