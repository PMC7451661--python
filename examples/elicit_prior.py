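"""Expand an investigator's MTD confidence vector into a full hypothesis prior.

A clinician planning a five-dose paediatric trial after a completed adult
trial states only how confident they are that each dose is the MTD (here 70%
on dose 3, 45% on its neighbours, 20% at the ends).  The algorithm anchors
the under-/over-dose odds at 10:1 for the lowest dose and 1:10 for the
highest, splits the remainder evenly at the guessed MTD, and interpolates.
"""

import pandas as pd

from aboin import elicit_prior_table

pi0 = (0.2, 0.45, 0.7, 0.45, 0.2)
table = elicit_prior_table(pi0, mtd_guess=3)

df = pd.DataFrame(
    table.pi,
    index=["H0 (at MTD)", "H1 (under-dose)", "H2 (over-dose)"],
    columns=[f"dose {j + 1}" for j in range(table.J)],
)
print(df.round(4).to_string())
print(
    "\nEach column sums to 1.  The under-dose row falls with dose and the"
    "\nover-dose row rises, as the hypotheses' meanings require; at dose 3 the"
    "\nremaining 30% splits evenly (0.15/0.15) because the odds there are 1."
)
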