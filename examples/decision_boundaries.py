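"""Print the escalation/de-escalation decision table for a target DLT rate.

The table is what a trial team pins to the protocol: for each number of
patients treated at the current dose, the thresholds lambda1 (escalate at or
below) and lambda2 (de-escalate at or above) and the equivalent DLT-count
cutoffs, including the safety-elimination count.
"""

from aboin import DesignSpec, decision_table

fixed = DesignSpec(phi=0.3, variant="boin", max_n=12)
print("Fixed boundaries, target DLT rate 30%:")
print(decision_table(fixed).to_string(index=False, float_format="%.4f"))

adaptive = DesignSpec(phi=0.3, variant="aboin", max_n=12)
print("\nShrinking boundaries (Delta = 0.4*phi, g1 = 0.4, g2 = 0.9):")
print(decision_table(adaptive).to_string(index=False, float_format="%.4f"))

print(
    "\nWith fixed boundaries the interval (lambda1, lambda2) is the same at every"
    "\nn_j; with shrinking boundaries it contracts toward 0.30 as evidence at the"
    "\ncurrent dose accumulates, so late-trial moves need stronger signals."
)
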