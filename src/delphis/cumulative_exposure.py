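"""Traffic intensity, cumulative behavioural budgets and the exposure sweep.

The interaction budget is instantaneous; to judge seasonal impact it is mixed
with the control budget in proportion to the traffic intensity ``a`` — the
share of (daylight) time the dolphins spend with interacting vessels:

    cumulative = a * interaction + (1 - a) * control

Sweeping ``a`` from 0 to 1 and Z-testing the cumulative budget against the
control budget per state locates the critical traffic intensity beyond which
a state's time share is significantly altered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chain_builder import Condition, TransitionCounts, label_conditions
from .inference import proportion_z_from_rates
from .io_model import BehaviouralState, FocalFollow, ValidationError
from .markov_core import summarize

__all__ = [
    "TrafficIntensity",
    "SweepResult",
    "traffic_intensity",
    "cumulative_budget",
    "effective_n",
    "sweep",
    "critical_intensity",
]


@dataclass(frozen=True)
class TrafficIntensity:
    a: float
    minutes_exposed: float
    minutes_total: float
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if self.minutes_total <= 0:
            raise ValidationError("no observation time in stratum")
        if abs(self.a - self.minutes_exposed / self.minutes_total) > 1e-9:
            raise ValidationError("a must equal exposed/total")


def traffic_intensity(follows: Sequence[FocalFollow],
                      sampling_interval: float = 3.0,
                      stratify_by_season: bool = False
                      ) -> list[TrafficIntensity]:
    """Exposure share(s): scan intervals with >=1 vessel within 300 m.

    Each scan contributes one sampling interval of observation time and
    counts as exposed when its instant falls under vessel presence. Returns
    the overall stratum first, then per-season strata when requested.
    """
    def tally(fs):
        total = exposed = 0
        for f in fs:
            labels = label_conditions(f)
            total += len(f.samples)
            exposed += sum(lab is Condition.INTERACTION for lab in labels)
        return exposed * sampling_interval, total * sampling_interval

    exposed, total = tally(follows)
    out = [TrafficIntensity(exposed / total, exposed, total, "overall")]
    if stratify_by_season:
        seasons = sorted({f.season_label for f in follows})
        for season in seasons:
            fs = [f for f in follows if f.season_label == season]
            e, t = tally(fs)
            out.append(TrafficIntensity(e / t, e, t, season or "unlabelled"))
    return out


def cumulative_budget(control: np.ndarray, interaction: np.ndarray,
                      a: float) -> np.ndarray:
    """Convex combination of the two budgets at traffic intensity ``a``."""
    control = np.asarray(control, dtype=float)
    interaction = np.asarray(interaction, dtype=float)
    if control.shape != interaction.shape:
        raise ValidationError("budgets cover different state sets")
    if not 0 <= a <= 1:
        raise ValidationError("traffic intensity must lie in [0, 1]")
    for b in (control, interaction):
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValidationError("budgets must sum to 1")
    return a * interaction + (1.0 - a) * control


def effective_n(a: float, n_control: int, n_interaction: int) -> int:
    """Effective transition count behind a cumulative budget at intensity ``a``.

    An exposure-weighted blend of the two conditions' totals; isolated here
    so the convention can be swapped in one place.
    """
    return max(1, round(a * n_interaction + (1.0 - a) * n_control))


@dataclass(frozen=True)
class SweepResult:
    states: tuple[BehaviouralState, ...]
    grid: np.ndarray                     # ascending a values
    budgets: np.ndarray                  # len(grid) x len(states)
    p_values: np.ndarray                 # len(grid) x len(states)
    critical: dict[BehaviouralState, float | None]
    alpha: float
    p_at: Callable[[float, int], float]  # p-value function, for refinement


def _make_p_at(pi_c, pi_i, n_c, n_i, alpha):
    def p_at(a: float, state_idx: int) -> float:
        cum = cumulative_budget(pi_c, pi_i, a)
        n_cum = effective_n(a, n_c, n_i)
        res = proportion_z_from_rates(float(pi_c[state_idx]), n_c,
                                      float(cum[state_idx]), n_cum, alpha)
        return res.p_value
    return p_at


def sweep(counts_control: TransitionCounts,
          counts_interaction: TransitionCounts,
          grid_step: float = 0.005,
          alpha: float = 0.05,
          refine: bool = True) -> SweepResult:
    """Cumulative budgets and per-state significance across the exposure grid."""
    if not 0 < grid_step <= 1:
        raise ValidationError("grid_step must lie in (0, 1]")
    sc = summarize(counts_control)
    si = summarize(counts_interaction)
    if sc.states != si.states:
        raise ValidationError("conditions summarise different state sets")
    states = sc.states
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    grid[-1] = min(grid[-1], 1.0)
    p_at = _make_p_at(sc.pi, si.pi, sc.n, si.n, alpha)

    budgets = np.vstack([cumulative_budget(sc.pi, si.pi, a) for a in grid])
    p_values = np.array([[p_at(a, k) for k in range(len(states))] for a in grid])

    critical: dict[BehaviouralState, float | None] = {}
    for k, s in enumerate(states):
        sig = np.flatnonzero(p_values[:, k] < alpha)
        if sig.size == 0:
            critical[s] = None
            continue
        hi = float(grid[sig[0]])
        lo = float(grid[sig[0] - 1]) if sig[0] > 0 else 0.0
        critical[s] = _bisect_threshold(p_at, k, lo, hi, alpha) if refine else hi
    return SweepResult(states, grid, budgets, p_values, critical, alpha, p_at)


def _bisect_threshold(p_at, state_idx: int, lo: float, hi: float,
                      alpha: float, resolution: float = 1e-3) -> float:
    """Smallest a with p < alpha, refined to ``resolution`` by bisection."""
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if p_at(mid, state_idx) < alpha:
            hi = mid
        else:
            lo = mid
    return hi


def critical_intensity(result: SweepResult, state: BehaviouralState
                       ) -> float | None:
    """The critical traffic intensity for one state (None if never reached)."""
    if state not in result.critical:
        raise ValidationError(f"state {state} not in sweep")
    return result.critical[state]
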