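"""Compare designs by simulated operating characteristics.

Runs the fixed-boundary and adaptive designs (and the adaptive design with
the packaged dose-3 prior) over three benchmark scenarios at target 20%,
500 replicates per cell, and prints the percentage of correct MTD selection.
A full-scale version of this study (all 20 scenarios, 10,000 replicates) is
what scripts/acceptance.py reproduces.
"""

from aboin import builtin_fixtures, pivot_metric, run_grid

fx = builtin_fixtures()
scenarios = [fx["scenarios"][0.2][i] for i in (0, 2, 4)]  # MTD at dose 1, 3, 5

grid = run_grid(
    scenarios,
    fx["designs"][0.2],
    priors={"aboin_prior": fx["prior"]},
    n_replicates=500,
    master_seed=7,
)

print("PCS (% of trials selecting the true MTD):")
print(pivot_metric(grid, "pcs_pct").round(1).to_string())
print("\nMean patients treated at the true MTD:")
print(pivot_metric(grid, "mean_n_at_mtd").round(1).to_string())
print(
    "\nThe dose-3 prior concentrates allocation near dose 3: it helps when the"
    "\ntrue MTD is dose 3 and costs accuracy when the MTD is elsewhere —"
    "\nprior information should only be used when it is genuinely strong."
)
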