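"""Cohort-by-cohort conduct of a single interval-design dose-finding trial.

The engine alternates cohort accrual at the current dose with three checks:

1. *safety elimination* — a dose (and all higher doses) is removed when its
   Beta(1 + y_j, 1 + n_j - y_j) posterior puts more than ``elimination_cutoff``
   mass above the target phi (once at least ``elimination_min_n`` patients
   have been treated there); elimination of the lowest dose terminates the
   trial with no MTD,
2. *dose decision* — the observed rate ``phat_j`` is compared against the
   variant's (lambda1, lambda2) at the current per-dose sample size, with
   edge adjustments at the lowest/highest dose and a block on escalating
   into an eliminated dose,
3. *lead-in switching* — the adaptive variants run the fixed boundaries until
   ``lead_in`` patients have been treated in total, then switch to the
   shrinking (and, for aboin_prior, prior-informed) boundaries.

At the end the MTD is estimated by weighted isotonic regression (PAVA) of the
observed rates and selecting the non-eliminated dose whose monotone estimate
is closest to phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.special import betainc

from .boundaries import BoundaryPair, DesignSpec, boundaries_for
from .priors import PriorTable

__all__ = [
    "Decision",
    "TrialState",
    "TrialResult",
    "decide",
    "effective_boundaries",
    "safety_eliminate",
    "elimination_min_dlt",
    "select_mtd",
    "run_trial",
]


class Decision(str, Enum):
    ESCALATE = "escalate"
    STAY = "stay"
    DEESCALATE = "de-escalate"


@dataclass
class TrialState:
    """Mutable per-trial bookkeeping: counts, current dose, eliminations."""

    J: int
    current_dose: int = 1  # 1-based dose level
    n: np.ndarray = None  # patients treated per dose
    y: np.ndarray = None  # DLTs observed per dose
    eliminated: np.ndarray = None
    terminated_early: bool = False

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("need at least one dose")
        if self.n is None:
            self.n = np.zeros(self.J, dtype=np.int64)
        if self.y is None:
            self.y = np.zeros(self.J, dtype=np.int64)
        if self.eliminated is None:
            self.eliminated = np.zeros(self.J, dtype=bool)
        self._check()

    def _check(self) -> None:
        if np.any(self.y > self.n) or np.any(self.n < 0):
            raise ValueError("require 0 <= y_j <= n_j at every dose")
        if not 1 <= self.current_dose <= self.J:
            raise ValueError(f"current_dose must be in 1..{self.J}")

    @property
    def total_n(self) -> int:
        return int(self.n.sum())

    def phat(self, dose: int) -> float:
        """Observed toxicity rate at 1-based dose level."""
        j = dose - 1
        if self.n[j] == 0:
            raise ValueError(f"no patients treated at dose {dose}")
        return self.y[j] / self.n[j]


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial: the selected MTD (or None) and a full audit log."""

    selected_mtd: int | None
    n: np.ndarray
    y: np.ndarray
    eliminated: np.ndarray
    terminated_early: bool
    decisions: tuple  # (dose, n_j, y_j, lambda1, lambda2, Decision) per decision

    @property
    def total_n(self) -> int:
        return int(self.n.sum())


def effective_boundaries(
    state: TrialState,
    design: DesignSpec,
    prior: PriorTable | None = None,
    dose_j: int | None = None,
) -> BoundaryPair:
    """Boundaries in force at ``dose_j`` given the trial's progress.

    Adaptive variants use the fixed pair until ``state.total_n >= lead_in``
    (the lead-in conducts plain BOIN, without the prior), then the shrinking
    pair at the dose's own sample size.
    """
    dose = state.current_dose if dose_j is None else dose_j
    n_j = max(int(state.n[dose - 1]), 1)  # never-visited dose: prior term at n_j = 1
    col = prior.column(dose) if prior is not None else None
    active = (not design.adaptive) or state.total_n >= design.lead_in
    return boundaries_for(design, n_j, col, adaptive_active=active)


def decide(
    state: TrialState, design: DesignSpec, prior: PriorTable | None = None
) -> Decision:
    """Escalate / stay / de-escalate for the next cohort.

    Edge rules: at the lowest dose an indicated de-escalation becomes *stay*;
    at the highest dose an indicated escalation becomes *stay*; escalation
    into an eliminated dose becomes *stay*.
    """
    j = state.current_dose
    if state.n[j - 1] == 0:
        raise RuntimeError(f"decide() called with no data at current dose {j}")
    lam1, lam2 = effective_boundaries(state, design, prior, j)
    phat = state.phat(j)
    if phat <= lam1:
        if j == state.J or state.eliminated[j]:  # state.eliminated[j] is dose j+1
            return Decision.STAY
        return Decision.ESCALATE
    if phat >= lam2:
        return Decision.DEESCALATE if j > 1 else Decision.STAY
    return Decision.STAY


@lru_cache(maxsize=None)
def elimination_min_dlt(n: int, phi: float, cutoff: float) -> int | None:
    """Smallest DLT count y with Pr(p > phi | Beta(1+y, 1+n-y)) > cutoff, or None.

    The posterior tail is the regularised incomplete beta function
    ``1 - I_phi(1+y, 1+n-y)``.
    """
    y = np.arange(n + 1)
    tail = 1.0 - betainc(1.0 + y, 1.0 + n - y, phi)
    hits = np.nonzero(tail > cutoff)[0]
    return int(hits[0]) if hits.size else None


def safety_eliminate(state: TrialState, design: DesignSpec) -> TrialState:
    """Apply the over-toxicity elimination rule at every treated dose.

    Eliminating dose j removes all higher doses as well; eliminating the
    lowest dose terminates the trial (no dose is tolerable).
    """
    for j in range(state.J):
        if state.n[j] >= design.elimination_min_n and not state.eliminated[j]:
            cut = elimination_min_dlt(int(state.n[j]), design.phi, design.elimination_cutoff)
            if cut is not None and state.y[j] >= cut:
                state.eliminated[j:] = True
                break
    if state.eliminated[0]:
        state.terminated_early = True
    return state


def select_mtd(state: TrialState, design: DesignSpec) -> int | None:
    """Final MTD estimate: isotonic regression of observed rates, closest to phi.

    Pool-adjacent-violators with weights n_j over the treated doses yields a
    monotone toxicity estimate; the non-eliminated treated dose whose estimate
    is closest to the target is selected.  Ties go to the higher dose when the
    tied estimates sit below the target (escalation still plausible) and to
    the lower dose otherwise.  Returns None when the trial terminated early.
    """
    if state.terminated_early or bool(state.eliminated[0]):
        return None
    treated = np.nonzero(state.n > 0)[0]
    if treated.size == 0:
        raise RuntimeError("select_mtd() called before any patient was treated")
    phat = state.y[treated] / state.n[treated]
    iso = isotonic_regression(phat, weights=state.n[treated].astype(float), increasing=True).x
    eligible = ~state.eliminated[treated]
    if not np.any(eligible):
        return None
    dist = np.abs(iso - design.phi)
    dist[~eligible] = np.inf
    best = dist.min()
    tied = np.nonzero(dist <= best + 1e-12)[0]
    if np.all(iso[tied] < design.phi):
        pick = tied[-1]
    else:
        pick = tied[0]
    return int(treated[pick]) + 1


def run_trial(
    scenario,
    design: DesignSpec,
    prior: PriorTable | None = None,
    rng_seed=None,
    start_dose: int = 1,
    keep_log: bool = True,
) -> TrialResult:
    """Simulate one complete trial under true DLT probabilities ``scenario``.

    ``scenario`` may be a :class:`~aboin.simulate.DoseScenario` or a plain
    probability vector.  Outcomes are per-patient Bernoulli draws from a
    generator seeded with ``rng_seed`` (anything accepted by
    ``numpy.random.default_rng``).
    """
    probs = np.asarray(getattr(scenario, "probs", scenario), dtype=float)
    if np.any((probs < 0.0) | (probs > 1.0)):
        raise ValueError(f"scenario probabilities must lie in [0, 1], got {probs}")
    J = probs.size
    if design.uses_prior:
        if prior is None:
            raise ValueError(f"variant {design.variant!r} requires a prior table")
        if prior.J != J:
            raise ValueError(f"prior table has J={prior.J} doses but scenario has {J}")
    rng = np.random.default_rng(rng_seed)
    state = TrialState(J=J, current_dose=start_dose)
    log: list[tuple] = []

    while True:
        d = state.current_dose
        c = min(design.cohort_size, design.max_n - state.total_n)
        dlts = int(np.count_nonzero(rng.random(c) < probs[d - 1]))
        state.n[d - 1] += c
        state.y[d - 1] += dlts
        safety_eliminate(state, design)
        if state.terminated_early:
            break
        if state.total_n >= design.max_n:
            break
        lam1, lam2 = effective_boundaries(state, design, prior, d)
        if state.eliminated[d - 1]:
            # current dose was just eliminated: move to the highest surviving
            # dose regardless of the interval comparison (a strong prior can
            # push lambda2 above 1, which would otherwise trap the trial here)
            decision = Decision.DEESCALATE
        else:
            decision = decide(state, design, prior)
        if keep_log:
            log.append((d, int(state.n[d - 1]), int(state.y[d - 1]), lam1, lam2, decision))
        if decision is Decision.ESCALATE:
            state.current_dose = d + 1
        elif decision is Decision.DEESCALATE:
            state.current_dose = int(np.nonzero(~state.eliminated[: d - 1])[0][-1]) + 1 if state.eliminated[d - 1] else d - 1

    selected = select_mtd(state, design)
    return TrialResult(
        selected_mtd=selected,
        n=state.n.copy(),
        y=state.y.copy(),
        eliminated=state.eliminated.copy(),
        terminated_early=state.terminated_early,
        decisions=tuple(log),
    )
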