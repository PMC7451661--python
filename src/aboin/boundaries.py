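"""Escalation/de-escalation boundaries for BOIN-family interval designs.

The Bayesian optimal interval (BOIN) design compares the observed toxicity
rate ``phat_j = y_j / n_j`` at the current dose against two thresholds
``lambda1 < lambda2``: escalate when ``phat_j <= lambda1``, de-escalate when
``phat_j >= lambda2``, otherwise stay.  The thresholds are chosen to minimise
the probability of an incorrect escalation/de-escalation decision under three
point hypotheses about the true toxicity probability ``p_j``::

    H0: p_j = phi      (dose is the MTD)
    H1: p_j = phi1     (sub-therapeutic, escalation warranted)
    H2: p_j = phi2     (over-toxic, de-escalation warranted)

With equal prior weight on the hypotheses the optimal thresholds are

    lambda1 = log[(1-phi1)/(1-phi)] / log[phi(1-phi1) / (phi1(1-phi))]
    lambda2 = log[(1-phi)/(1-phi2)] / log[phi2(1-phi) / (phi(1-phi2))]

Unequal prior weights (pi0, pi1, pi2) elicited from historical data add a
``log(pi1/pi0)/n_j`` term to lambda1's numerator and ``log(pi0/pi2)/n_j`` to
lambda2's, so the prior is discounted as evidence at dose j accumulates.

The adaptive variant (aBOIN) replaces the fixed hypothesis rates by
``phi1 = phi - Delta1 * n_j**-g1`` and ``phi2 = phi + Delta2 * n_j**-g2``:
the decision interval shrinks toward the target as patients accrue, with
discount exponents g1, g2 in (0, 1) controlling the shrinkage speed per side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "DesignSpec",
    "BoundaryPair",
    "VARIANTS",
    "boin_boundaries",
    "prior_boin_boundaries",
    "aboin_boundaries",
    "aboin_prior_boundaries",
    "shrunk_hypothesis_rates",
    "decision_table",
]

VARIANTS = ("boin", "boin_prior", "aboin", "aboin_prior")


class BoundaryPair(NamedTuple):
    """An escalation threshold ``lambda1`` and de-escalation threshold ``lambda2``."""

    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class DesignSpec:
    """All tuning constants of one design variant.

    Parameters
    ----------
    phi
        Target dose-limiting-toxicity (DLT) probability, in (0, 1).
    variant
        One of ``boin``, ``boin_prior``, ``aboin``, ``aboin_prior``.
    phi1, phi2
        Fixed sub-therapeutic / over-toxic hypothesis rates for the
        non-adaptive variants.  Default 0.6*phi and 1.4*phi.
    delta1, delta2
        Effect sizes of the shrinking hypothesis rates for the adaptive
        variants.  Default 0.4*phi each, which makes the adaptive design
        coincide with the fixed one at n_j = 1.
    g1, g2
        Discount exponents in (0, 1) controlling how fast the lower / upper
        hypothesis rate shrinks toward phi.  Defaults 0.4 and 0.9 (the upper
        boundary shrinks faster, penalising over-dosing).
    lead_in
        Number of patients treated under the fixed boundaries before the
        adaptive shrinkage activates (total across doses).  Default 6.
    cohort_size, max_n
        Accrual cohort size and maximum sample size.
    elimination_cutoff
        Posterior probability threshold of the over-toxicity elimination rule.
    """

    phi: float
    variant: str = "boin"
    phi1: float | None = None
    phi2: float | None = None
    delta1: float | None = None
    delta2: float | None = None
    g1: float = 0.4
    g2: float = 0.9
    lead_in: int = 6
    cohort_size: int = 3
    max_n: int = 30
    elimination_cutoff: float = 0.95
    elimination_min_n: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        # fill defaults recommended for interval designs
        if self.phi1 is None:
            object.__setattr__(self, "phi1", 0.6 * self.phi)
        if self.phi2 is None:
            object.__setattr__(self, "phi2", 1.4 * self.phi)
        if self.delta1 is None:
            object.__setattr__(self, "delta1", 0.4 * self.phi)
        if self.delta2 is None:
            object.__setattr__(self, "delta2", 0.4 * self.phi)
        if not 0.0 < self.phi1 < self.phi:
            raise ValueError(f"need 0 < phi1 < phi, got phi1={self.phi1}, phi={self.phi}")
        if not self.phi < self.phi2 < 1.0:
            raise ValueError(f"need phi < phi2 < 1, got phi2={self.phi2}, phi={self.phi}")
        if self.delta1 <= 0 or self.delta2 <= 0:
            raise ValueError("effect sizes delta1, delta2 must be positive")
        if not (0.0 < self.g1 < 1.0 and 0.0 < self.g2 < 1.0):
            raise ValueError("discount exponents g1, g2 must lie in (0, 1)")
        # shrinking rates must stay inside (0, 1) at the widest point, n_j = 1
        if self.phi - self.delta1 <= 0.0:
            raise ValueError(
                f"phi - delta1 = {self.phi - self.delta1:.4g} <= 0 at n_j=1; choose a smaller delta1"
            )
        if self.phi + self.delta2 >= 1.0:
            raise ValueError(
                f"phi + delta2 = {self.phi + self.delta2:.4g} >= 1 at n_j=1; choose a smaller delta2"
            )
        if self.lead_in < 0:
            raise ValueError("lead_in must be >= 0")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.max_n < self.cohort_size:
            raise ValueError("max_n must be >= cohort_size")
        if not 0.0 < self.elimination_cutoff < 1.0:
            raise ValueError("elimination_cutoff must be in (0, 1)")

    @property
    def uses_prior(self) -> bool:
        return self.variant in ("boin_prior", "aboin_prior")

    @property
    def adaptive(self) -> bool:
        return self.variant in ("aboin", "aboin_prior")


def _check_rates(phi: float, phi1: float, phi2: float) -> None:
    if not 0.0 < phi1:
        raise ValueError(f"violated 0 < phi1: phi1={phi1}")
    if not phi1 < phi:
        raise ValueError(f"violated phi1 < phi: phi1={phi1}, phi={phi}")
    if not phi < phi2:
        raise ValueError(f"violated phi < phi2: phi={phi}, phi2={phi2}")
    if not phi2 < 1.0:
        raise ValueError(f"violated phi2 < 1: phi2={phi2}")


def _interval(phi: float, phi1: float, phi2: float, t1: float = 0.0, t2: float = 0.0) -> BoundaryPair:
    """Decision-error-minimising thresholds with optional prior log-odds offsets.

    ``t1``/``t2`` are the already-discounted prior terms log(pi1/pi0)/n_j and
    log(pi0/pi2)/n_j; zero under the uniform hypothesis prior.
    """
    lam1 = (math.log((1.0 - phi1) / (1.0 - phi)) + t1) / math.log(
        phi * (1.0 - phi1) / (phi1 * (1.0 - phi))
    )
    lam2 = (math.log((1.0 - phi) / (1.0 - phi2)) + t2) / math.log(
        phi2 * (1.0 - phi) / (phi * (1.0 - phi2))
    )
    if lam1 >= lam2:
        raise ValueError(
            f"degenerate boundaries lambda1={lam1:.4g} >= lambda2={lam2:.4g}; "
            "the prior is too strong for this sample size"
        )
    return BoundaryPair(lam1, lam2)


def boin_boundaries(phi: float, phi1: float | None = None, phi2: float | None = None) -> BoundaryPair:
    """Fixed BOIN thresholds for target ``phi``.

    ``phi1``/``phi2`` default to the recommended 0.6*phi and 1.4*phi.

    >>> boin_boundaries(0.3)            # doctest: +ELLIPSIS
    BoundaryPair(lambda1=0.2364..., lambda2=0.3585...)
    """
    phi1 = 0.6 * phi if phi1 is None else phi1
    phi2 = 1.4 * phi if phi2 is None else phi2
    _check_rates(phi, phi1, phi2)
    return _interval(phi, phi1, phi2)


def _prior_terms(n_j: int, pi0: float, pi1: float, pi2: float) -> tuple[float, float]:
    if n_j < 1:
        raise ValueError(f"n_j must be >= 1, got {n_j}")
    for name, v in (("pi0", pi0), ("pi1", pi1), ("pi2", pi2)):
        if v <= 0.0:
            raise ValueError(f"prior probability {name}={v} must be > 0 (log undefined otherwise)")
    if abs(pi0 + pi1 + pi2 - 1.0) > 1e-6:
        raise ValueError(f"hypothesis prior must sum to 1, got {pi0 + pi1 + pi2}")
    return math.log(pi1 / pi0) / n_j, math.log(pi0 / pi2) / n_j


def prior_boin_boundaries(
    phi: float,
    phi1: float,
    phi2: float,
    n_j: int,
    pi0: float,
    pi1: float,
    pi2: float,
) -> BoundaryPair:
    """Fixed-rate thresholds with unequal hypothesis prior weights at dose j.

    The prior enters as log-odds offsets discounted by the per-dose sample
    size ``n_j``, so the thresholds converge to :func:`boin_boundaries` as
    evidence accumulates.  A strong prior at small ``n_j`` may push lambda1
    below 0 or lambda2 above 1 (the corresponding move is then impossible);
    lambda1 < phi < lambda2 is not guaranteed and a warning is emitted when
    it fails.
    """
    _check_rates(phi, phi1, phi2)
    t1, t2 = _prior_terms(n_j, pi0, pi1, pi2)
    pair = _interval(phi, phi1, phi2, t1, t2)
    if not pair.lambda1 < phi < pair.lambda2:
        warnings.warn(
            f"prior-informed boundaries ({pair.lambda1:.3f}, {pair.lambda2:.3f}) do not "
            f"bracket phi={phi} at n_j={n_j}; the prior dominates the interval",
            stacklevel=2,
        )
    return pair


def shrunk_hypothesis_rates(
    phi: float, delta1: float, delta2: float, g1: float, g2: float, n_j: int
) -> tuple[float, float]:
    """Sample-size-dependent hypothesis rates phi1(n_j), phi2(n_j) of the adaptive design."""
    if n_j < 1:
        raise ValueError(f"n_j must be >= 1, got {n_j}")
    phi1 = phi - delta1 * n_j ** (-g1)
    phi2 = phi + delta2 * n_j ** (-g2)
    if phi1 <= 0.0:
        raise ValueError(
            f"implied phi1 = {phi1:.4g} <= 0 at n_j={n_j}; choose a smaller delta1"
        )
    if phi2 >= 1.0:
        raise ValueError(
            f"implied phi2 = {phi2:.4g} >= 1 at n_j={n_j}; choose a smaller delta2"
        )
    return phi1, phi2


def aboin_boundaries(
    phi: float, delta1: float, delta2: float, g1: float, g2: float, n_j: int
) -> BoundaryPair:
    """Adaptive (shrinking) thresholds at per-dose sample size ``n_j``.

    Identical to :func:`boin_boundaries` evaluated at the shrunk rates
    ``phi -/+ Delta * n_j**-g``; both thresholds contract toward ``phi`` as
    ``n_j`` grows, while always satisfying lambda1 < phi < lambda2.
    """
    phi1, phi2 = shrunk_hypothesis_rates(phi, delta1, delta2, g1, g2, n_j)
    return _interval(phi, phi1, phi2)


def aboin_prior_boundaries(
    phi: float,
    delta1: float,
    delta2: float,
    g1: float,
    g2: float,
    n_j: int,
    pi0: float,
    pi1: float,
    pi2: float,
) -> BoundaryPair:
    """Adaptive thresholds combined with the discounted hypothesis-prior offsets."""
    phi1, phi2 = shrunk_hypothesis_rates(phi, delta1, delta2, g1, g2, n_j)
    t1, t2 = _prior_terms(n_j, pi0, pi1, pi2)
    return _interval(phi, phi1, phi2, t1, t2)


def boundaries_for(
    design: DesignSpec,
    n_j: int,
    prior_column: tuple[float, float, float] | None = None,
    adaptive_active: bool = True,
) -> BoundaryPair:
    """Thresholds of ``design`` at per-dose sample size ``n_j``.

    ``prior_column`` is the (pi0, pi1, pi2) column of the prior table for the
    current dose; required by the *_prior variants.  ``adaptive_active=False``
    forces the fixed lead-in boundaries of the adaptive variants (during the
    lead-in the prior is not applied either: the trial conducts plain BOIN).
    """
    if design.variant == "boin":
        return boin_boundaries(design.phi, design.phi1, design.phi2)
    if design.variant == "boin_prior":
        if prior_column is None:
            raise ValueError("variant 'boin_prior' requires a prior table")
        return prior_boin_boundaries(design.phi, design.phi1, design.phi2, n_j, *prior_column)
    # adaptive variants
    if not adaptive_active:
        return boin_boundaries(design.phi, design.phi1, design.phi2)
    if design.variant == "aboin":
        return aboin_boundaries(design.phi, design.delta1, design.delta2, design.g1, design.g2, n_j)
    if prior_column is None:
        raise ValueError("variant 'aboin_prior' requires a prior table")
    return aboin_prior_boundaries(
        design.phi, design.delta1, design.delta2, design.g1, design.g2, n_j, *prior_column
    )


def decision_table(
    design: DesignSpec,
    prior_column: tuple[float, float, float] | None = None,
    n_max: int | None = None,
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Per-``n_j`` decision table (escalate/de-escalate cutoffs in DLT counts).

    Mirrors the flowchart tables practitioners print for interval designs:
    for each per-dose sample size the thresholds, the largest DLT count that
    still escalates, the smallest that de-escalates, and the smallest that
    triggers safety elimination.
    """
    import pandas as pd

    from .trial import elimination_min_dlt

    n_max = design.max_n if n_max is None else n_max
    rows = []
    for n in range(1, n_max + 1):
        lam1, lam2 = boundaries_for(design, n, prior_column, adaptive_active=n >= 1)
        esc = math.floor(lam1 * n + 1e-12)
        deesc = math.ceil(lam2 * n - 1e-12)
        elim = elimination_min_dlt(n, design.phi, design.elimination_cutoff)
        rows.append(
            {
                "n_j": n,
                "lambda1": lam1,
                "lambda2": lam2,
                "escalate_if_dlt_le": max(esc, -1),
                "deescalate_if_dlt_ge": deesc,
                "eliminate_if_dlt_ge": elim if (elim is not None and n >= design.elimination_min_n) else None,
            }
        )
    df = pd.DataFrame(rows)
    df["eliminate_if_dlt_ge"] = df["eliminate_if_dlt_ge"].astype("Int64")
    return df
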