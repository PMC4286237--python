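"""First-order Markov-chain estimation on behavioural transition counts.

The behavioural budget — the long-run share of time the group spends in each
state — is the stationary distribution of the fitted chain, obtained as the
left eigenvector of the dominant (Perron) eigenvalue of the row-stochastic
transition matrix. Two closed-form summaries follow:

* recovery time  E(T_j) = 1 / pi_j  (transition units; multiply by the
  sampling interval for minutes) — the mean recurrence time of state j;
* bout length  t_ii = 1 / (1 - p_ii) — the mean of the geometric sojourn
  in state i implied by its self-transition probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_builder import Condition, TransitionCounts
from .io_model import BehaviouralState, ValidationError

__all__ = [
    "TransitionMatrix",
    "MarkovSummary",
    "transition_matrix",
    "stationary_distribution",
    "expected_return_time",
    "bout_length",
    "summarize",
]


@dataclass(frozen=True)
class TransitionMatrix:
    states: tuple[BehaviouralState, ...]
    p: np.ndarray           # row-stochastic
    n_row: np.ndarray       # transitions observed out of each state

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValidationError("transition probabilities outside [0, 1]")
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValidationError("rows must sum to 1")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "n_row", np.asarray(self.n_row, dtype=int))


@dataclass(frozen=True)
class MarkovSummary:
    """Budget, recovery times and bout lengths for one condition."""

    condition: Condition
    states: tuple[BehaviouralState, ...]
    matrix: TransitionMatrix
    pi: np.ndarray
    return_units: np.ndarray
    return_minutes: np.ndarray
    bout_units: np.ndarray
    n: int

    def budget(self) -> dict[str, float]:
        return {s.value: float(v) for s, v in zip(self.states, self.pi)}


def transition_matrix(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalise counts: p_ij = a_ij / sum_j a_ij."""
    a = counts.a
    row = a.sum(axis=1)
    zero = np.flatnonzero(row == 0)
    if zero.size:
        names = ", ".join(counts.states[i].value for i in zero)
        raise ValidationError(f"no outgoing transitions observed from: {names}")
    return TransitionMatrix(counts.states, a / row[:, None], row)


def _is_irreducible(p: np.ndarray) -> bool:
    # reachability closure of the adjacency pattern
    k = p.shape[0]
    reach = ((p > 0) | np.eye(k, dtype=bool)).astype(np.int64)
    for _ in range(max(1, k - 1)):
        reach = np.clip(reach @ reach, 0, 1)
    return bool(reach.all())


def _power_iteration(p: np.ndarray, tol: float = 1e-14, max_iter: int = 200000
                     ) -> np.ndarray:
    pi = np.full(p.shape[0], 1.0 / p.shape[0])
    for _ in range(max_iter):
        nxt = pi @ p
        if np.abs(nxt - pi).max() < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def stationary_distribution(p: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution via the dominant left eigenvector.

    The eigenvector of the eigenvalue closest to 1 is sign-fixed and
    normalised to sum to one; a power-iteration fallback handles the rare
    case of complex contamination in the solver output. Reducible chains
    (no unique strictly positive stationary vector) are refused.
    """
    mat = p.p if isinstance(p, TransitionMatrix) else np.asarray(p, dtype=float)
    if not _is_irreducible(mat):
        raise ValidationError("chain is reducible; stationary budget undefined")
    w, v = np.linalg.eig(mat.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    vec = v[:, idx]
    if np.abs(vec.imag).max() > 1e-10:
        pi = _power_iteration(mat)
    else:
        vec = vec.real
        if vec.sum() < 0:
            vec = -vec
        if (vec < -1e-10).any():
            pi = _power_iteration(mat)
        else:
            pi = np.clip(vec, 0.0, None)
            pi = pi / pi.sum()
    if (pi <= 0).any():
        raise ValidationError("stationary distribution not strictly positive")
    return pi


def expected_return_time(pi_j: float, interval: float = 3.0
                         ) -> tuple[float, float]:
    """Mean recurrence time of a state: (units, minutes) = (1/pi, interval/pi)."""
    if not 0 < pi_j <= 1:
        raise ValidationError("return time needs a stationary probability in (0, 1]")
    units = 1.0 / pi_j
    return units, units * interval


def bout_length(p_ii: float) -> float:
    """Mean sojourn (in sampling units) of the geometric bout: 1 / (1 - p_ii)."""
    if not 0 <= p_ii < 1:
        raise ValidationError("bout length needs a self-transition probability in [0, 1)")
    return 1.0 / (1.0 - p_ii)


def summarize(counts: TransitionCounts, interval: float = 3.0) -> MarkovSummary:
    """Fit the chain and bundle budget, recovery times and bout lengths."""
    tm = transition_matrix(counts)
    pi = stationary_distribution(tm)
    units = 1.0 / pi
    bouts = np.array([bout_length(tm.p[i, i]) for i in range(len(counts.states))])
    return MarkovSummary(
        condition=counts.condition,
        states=counts.states,
        matrix=tm,
        pi=pi,
        return_units=units,
        return_minutes=units * interval,
        bout_units=bouts,
        n=counts.n,
    )
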