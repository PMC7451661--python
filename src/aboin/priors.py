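"""Elicitation and validation of the 3 x J hypothesis-prior table.

For each dose j the design carries prior probabilities (pi_{0,j}, pi_{1,j},
pi_{2,j}) of the three point hypotheses: the dose is at the MTD (H0), below
it (H1, under-dosing), or above it (H2, over-dosing).  An investigator states
only the H0 row — "how confident am I that dose j is the MTD" — typically
informed by a completed adult trial when planning a paediatric study.  The
remaining two rows are filled automatically:

* at the lowest dose the odds pi1/pi2 are anchored high (default 10:1 —
  the lowest dose is almost surely an under-dose),
* at the highest dose they are anchored low (default 1:10),
* at the guessed MTD the remainder 1 - pi0 is split equally (odds 1),
* H1 values at intermediate doses are linearly interpolated in dose index
  between the anchors, and H2 completes each column to 1.

The resulting rows are monotone (H1 non-increasing, H2 non-decreasing in
dose), as the under-/over-dosing interpretations require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PriorTable", "elicit_prior_table", "validate_prior_table", "uniform_prior_table"]

_COLUMN_TOL = 1e-9


@dataclass(frozen=True)
class PriorTable:
    """Hypothesis prior probabilities, rows (H0, H1, H2) by dose column.

    ``pi`` is a 3 x J array; ``pi[0]`` is the MTD row, ``pi[1]`` the
    under-dose row, ``pi[2]`` the over-dose row.  Columns sum to 1.
    """

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 2 or pi.shape[0] != 3 or pi.shape[1] < 2:
            raise ValueError(f"prior table must be 3 x J with J >= 2, got shape {pi.shape}")
        pi = pi.copy()
        pi.flags.writeable = False
        object.__setattr__(self, "pi", pi)
        violations = validate_prior_table(self)
        if violations:
            raise ValueError("invalid prior table: " + "; ".join(violations))

    @property
    def J(self) -> int:
        return self.pi.shape[1]

    def column(self, dose: int) -> tuple[float, float, float]:
        """(pi0, pi1, pi2) at 1-based dose level ``dose``."""
        if not 1 <= dose <= self.J:
            raise IndexError(f"dose must be in 1..{self.J}, got {dose}")
        return tuple(self.pi[:, dose - 1])


def uniform_prior_table(J: int) -> PriorTable:
    """The non-informative table: every hypothesis equally likely at every dose."""
    return PriorTable(np.full((3, J), 1.0 / 3.0))


def validate_prior_table(table: PriorTable | np.ndarray) -> list[str]:
    """Return a list of constraint violations (empty iff the table is valid).

    Checks, per the table's interpretation: entries strictly inside (0, 1),
    columns summing to 1, the under-dose row non-increasing and the over-dose
    row non-decreasing in dose.  Never raises.
    """
    pi = np.asarray(table.pi if isinstance(table, PriorTable) else table, dtype=float)
    violations: list[str] = []
    J = pi.shape[1]
    for j in range(J):
        col = pi[:, j]
        if not np.all((col > 0.0) & (col < 1.0)):
            violations.append(f"dose {j + 1}: entries must lie strictly in (0, 1), got {col}")
        s = float(col.sum())
        if abs(s - 1.0) > _COLUMN_TOL:
            violations.append(f"dose {j + 1}: column sums to {s!r}, not 1")
    for j in range(1, J):
        if pi[1, j] > pi[1, j - 1] + _COLUMN_TOL:
            violations.append(
                f"dose {j + 1}: under-dose row must be non-increasing "
                f"({pi[1, j - 1]:.6g} -> {pi[1, j]:.6g})"
            )
        if pi[2, j] < pi[2, j - 1] - _COLUMN_TOL:
            violations.append(
                f"dose {j + 1}: over-dose row must be non-decreasing "
                f"({pi[2, j - 1]:.6g} -> {pi[2, j]:.6g})"
            )
    return violations


def elicit_prior_table(
    pi0,
    mtd_guess: int,
    odds_low: float = 10.0,
    odds_high: float = 0.1,
) -> PriorTable:
    """Expand an H0 confidence vector into the full 3 x J prior table.

    Parameters
    ----------
    pi0
        Length-J vector of prior MTD probabilities per dose, each in (0, 1).
        Must attain its maximum at ``mtd_guess``.
    mtd_guess
        1-based index of the dose believed closest to the MTD.
    odds_low, odds_high
        Anchor odds pi1/pi2 at the lowest and highest dose.  When the guessed
        MTD *is* the lowest (or highest) dose, that anchor's odds are forced
        to 1 and the remainder is split equally there.

    Raises
    ------
    ValueError
        If ``pi0`` leaves no room for a positive over-dose probability or the
        elicited rows violate the monotonicity constraints.
    """
    pi0 = np.asarray(pi0, dtype=float)
    J = pi0.size
    if J < 2:
        raise ValueError(f"need at least two doses, got J={J}")
    if not np.all((pi0 > 0.0) & (pi0 < 1.0)):
        raise ValueError(f"pi0 entries must lie strictly in (0, 1), got {pi0}")
    if not 1 <= mtd_guess <= J:
        raise ValueError(f"mtd_guess must be in 1..{J}, got {mtd_guess}")
    if pi0[mtd_guess - 1] < pi0.max() - _COLUMN_TOL:
        raise ValueError(
            f"pi0 must attain its maximum at mtd_guess={mtd_guess} "
            f"(pi0[{mtd_guess}]={pi0[mtd_guess - 1]}, max={pi0.max()})"
        )
    if odds_low <= 0.0 or odds_high <= 0.0:
        raise ValueError("anchor odds must be positive")

    m = mtd_guess - 1  # 0-based
    o_low = 1.0 if m == 0 else odds_low
    o_high = 1.0 if m == J - 1 else odds_high

    pi1 = np.empty(J)
    pi1[0] = (1.0 - pi0[0]) * o_low / (1.0 + o_low)
    pi1[J - 1] = (1.0 - pi0[J - 1]) * o_high / (1.0 + o_high)
    pi1[m] = (1.0 - pi0[m]) / 2.0
    # linear interpolation in dose index between the anchor doses
    if m > 1:
        pi1[1:m] = np.interp(np.arange(1, m), [0, m], [pi1[0], pi1[m]])
    if m < J - 2:
        pi1[m + 1 : J - 1] = np.interp(np.arange(m + 1, J - 1), [m, J - 1], [pi1[m], pi1[J - 1]])

    pi2 = 1.0 - pi0 - pi1
    bad = np.nonzero(pi2 <= 0.0)[0]
    if bad.size:
        raise ValueError(
            f"elicited over-dose probability is non-positive at dose {bad[0] + 1} "
            f"(pi2={pi2[bad[0]]:.4g}); lower pi0 or weaken the anchor odds"
        )
    table = np.vstack([pi0, pi1, pi2])
    violations = validate_prior_table(table)
    if violations:
        raise ValueError("elicited table violates prior constraints: " + "; ".join(violations))
    return PriorTable(table)
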