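# Methods

## Decision model

The package implements interval designs for phase I dose finding. At the
current dose j with n_j patients and y_j dose-limiting toxicities (DLTs),
the observed rate p̂_j = y_j/n_j is compared against thresholds λ₁ < λ₂
derived by minimising the probability of an incorrect escalation or
de-escalation decision under three point hypotheses for the true toxicity
probability p_j: at the target (H₀: p_j = φ), sub-therapeutic
(H₁: p_j = φ₁ < φ) and over-toxic (H₂: p_j = φ₂ > φ). The resulting
thresholds are the Bayes decision boundaries of the binomial likelihood-
ratio test between adjacent hypotheses:

    λ₁ = [ log((1−φ₁)/(1−φ)) + n_j⁻¹ log(π₁ⱼ/π₀ⱼ) ] / log[ φ(1−φ₁)/(φ₁(1−φ)) ]
    λ₂ = [ log((1−φ)/(1−φ₂)) + n_j⁻¹ log(π₀ⱼ/π₂ⱼ) ] / log[ φ₂(1−φ)/(φ(1−φ₂)) ]

with hypothesis prior weights π_kj. Under uniform weights the log-odds terms
vanish; λ₁ < φ < λ₂ then holds for any admissible (φ₁, φ₂), which implies
long-term-memory coherence: the design never escalates from a dose whose
cumulative observed rate exceeds φ, and never de-escalates from one below φ.
These properties are verified numerically in the test suite over a grid of
targets and sample sizes rather than re-derived symbolically.

A derivation note: the λ₂ prior term is log(π₀ⱼ/π₂ⱼ)·n_j⁻¹. This follows
from the symmetric Bayes comparison of H₀ against H₂ (the H₂ weight must
enter λ₂, mirrored against the H₀ weight); an alternative rendering that
repeats the λ₁ term log(π₁ⱼ/π₀ⱼ) in λ₂ circulates in the literature and is
treated here as a typographical slip. No switch is provided for it.

## Variants and parameters

| parameter | meaning | default | why |
|---|---|---|---|
| φ | target DLT probability | user input | protocol quantity |
| φ₁, φ₂ | fixed hypothesis rates | 0.6φ, 1.4φ | standard recommendation for interval designs |
| Δ₁, Δ₂ | adaptive effect sizes | 0.4φ | makes the adaptive design equal the fixed one at n_j = 1 |
| g₁, g₂ | shrink discount exponents in (0,1) | 0.4, 0.9 | upper margin tightens faster, penalising overdosing |
| lead-in N₁ | patients under fixed rules before shrinkage | 6 | small-trial performance is insensitive between 6 and 9 |
| cohort size / max n | accrual pattern | 3 / 30 | typical phase I protocol |
| elimination cutoff | posterior Pr(p_j > φ) threshold | 0.95 | conventional safety rule |

The adaptive variants substitute φ₁(n_j) = φ − Δ₁n_j^(−g₁) and
φ₂(n_j) = φ + Δ₂n_j^(−g₂) into the same formulas. The lead-in counts *total*
patients in the trial (not per dose): the first decision with total ≥ N₁
uses the shrinking boundaries, and during the lead-in the prior is not
applied either (the trial conducts the plain fixed design). A dose never
visited contributes n_j = 1 to the prior discount; in practice decisions
only occur after at least one cohort, so n_j ≥ cohort size.

Note on asymptotics: λ₁, λ₂ → φ as n_j → ∞ for any g ∈ (0,1), but the
sampling noise of p̂_j is of order n_j^(−1/2), so a margin with g > 1/2
(the default g₂ = 0.9) eventually shrinks *inside* the noise and the design
oscillates at the MTD rather than absorbing. The large-sample advantage of
the adaptive design therefore shows up in *selection* accuracy (better
separated per-dose estimates), not in allocation share; the test suite
asserts the selection claim.

## Prior elicitation

The investigator supplies one vector: π₀ⱼ = "confidence that dose j is the
MTD", peaking at a designated guess. The under-dose row is anchored at the
lowest dose by odds π₁/π₂ = 10 (this dose is almost surely below the MTD),
at the highest dose by odds 1/10, and at the guessed MTD by odds 1 (even
split of 1 − π₀). Anchor values follow π₁ = (1−π₀)·odds/(1+odds);
intermediate doses are filled by linear interpolation *in dose index*
between anchors, and the over-dose row completes each column to 1. The
literal published interpolation formula, "(left + right)/j′", equals the
midpoint only in the single-intermediate case its worked example exercises
and is not monotone for two or more intermediates; index-linear
interpolation reproduces the worked example exactly and preserves
monotonicity in general, so it is used throughout.

Elicitation fails loudly (no clipping) when the confidence vector leaves no
room for a positive over-dose probability or breaks row monotonicity —
clipping would silently destroy column normalisation. Multi-modal
confidence vectors are rejected: the guess must sit at a maximum.

Exactness caveat: published two-decimal renderings of the worked
five-dose table round the exact anchor 8/11 = 0.7273 down to 0.72 and its
complement 0.0727 up to 0.08, and complete the third row from the rounded
second row. No single rounding rule reproduces all fifteen printed cells
from the formulas; this package keeps exact arithmetic (agreement with
every printed cell to within 0.009) rather than replicating the rounding.

## Trial conduct

Per cohort: accrue at the current dose, update counts, apply the safety
rule, then decide. The safety rule eliminates dose j and all higher doses
when n_j ≥ 3 and the Beta(1 + y_j, 1 + n_j − y_j) posterior puts more than
0.95 mass above φ; eliminating the lowest dose terminates the trial with no
MTD. Edge rules: at dose 1 an indicated de-escalation becomes *stay*, at
dose J an indicated escalation becomes *stay*, and escalation into an
eliminated dose becomes *stay*. If the current dose itself is eliminated
the trial moves to the highest surviving dose unconditionally — necessary
because a strong hypothesis prior can push λ₂ above 1, which would
otherwise trap the walk on an eliminated dose.

Final selection: weighted pool-adjacent-violators isotonic regression of
p̂_j (weights n_j) over treated doses; the non-eliminated dose whose
monotone estimate is closest to φ is selected, ties going to the higher
dose when the tied estimates are below φ and to the lower dose otherwise.
The safety rule and this estimator are conventional defaults of interval
designs rather than part of the threshold derivation; the simulator's
agreement with the published benchmark (below) confirms they match the
reference behaviour closely. The smoothed-posterior-mean variant of the
selection step (adding 0.05 pseudo-events) is not replicated; its effect is
absorbed by the benchmark tolerances.

## Simulation study

`run_oc` replays seeded independent trials and reports: PCS (% selecting
the true MTD; early-terminated trials count as failures), mean patients at
the true MTD, and the risks of over-/under-dosing — the percentage of
trials in which more than a fraction f (default 0.6) of patients were
treated above/below the MTD. Risk denominators default to each trial's
realized size; a "planned" option divides by the design maximum instead,
under which early-terminated trials rarely register (this is the convention
behind the published benchmark's under-dosing rows). Seeding is two-level:
each grid cell's stream derives from a CRC of (master seed, scenario label,
design label), so adding scenarios never perturbs existing cells, and each
replicate spawns an independent substream.

The packaged benchmark uses ten five-dose scenarios per target (20% and
30%), one design per variant, and **twelve cohorts of three (36 patients)**.
The source protocol text says 30 patients, but its reported results are
only attainable at 36: reported overdosing risks of 3.71%/3.67% on
scenarios whose MTD is dose 4 are combinatorially impossible at N = 30
(at most 18 of 30 patients can sit above dose 4 — exactly 60%, never
more), and at N = 36 every PCS, allocation and overdosing cell of the
no-prior designs matches within Monte-Carlo error. The package treats 36 as
the benchmark's true condition and keeps 30 as the general default.

Known discrepancy: the benchmark's *prior-informed* row is not reproducible
from the prior-adjusted threshold formulas above. With the packaged dose-3
prior (π column 0.7/0.15/0.15), the discounted log-odds log(0.15/0.7)/n_j
keeps λ₁ negative at dose 3 for every n_j reachable in a 36-patient trial,
so doses 4–5 are unreachable and the design concentrates at dose 3 far more
strongly than the published row (which shows small, mixed-sign shifts, and
nonzero selection above dose 3). All plausible re-readings tested
(total-n discounting, planned-N discounting, log base 10, the λ₂ sign
variant, prior only during lead-in, prior as starting dose) fail to
reproduce it; the faithful formulas are kept and the corresponding
benchmark comparisons are expected to disagree. Practical reading,
which matches the source's own caution: a strong hypothesis prior
dominates small-sample decisions, and should only be used when the prior
guess is genuinely reliable.

## What the simulator does and does not emulate

Patient outcomes are independent Bernoulli draws at fixed per-dose
probabilities: no accrual-time modelling, no late-onset or time-to-event
toxicity, no patient heterogeneity, no cohort-size adaptation. Passing
benchmarks therefore validates the decision logic and its operating
characteristics under the design's own probability model, not robustness
to real-world accrual patterns.

## Numerical choices

Thresholds are computed fresh at every decision as pure functions of their
inputs (no caching contract); "converges to" test tolerances are 1e-6
unless the check itself states otherwise; threshold-vs-count comparisons
use the exact rate comparison p̂ ≤ λ (the thresholds are irrational, so
float equality cannot bind); selection ties are detected within 1e-12;
Beta posterior tails use the regularised incomplete beta function, with
per-(n, φ) elimination counts memoised. Degenerate prior-dominated
boundaries (λ₁ ≥ λ₂, possible under extreme priors) raise immediately
rather than conducting an incoherent trial.

Problem sizes in the shipped checks: the test suite runs the benchmark
cells at 2,000 replicates with correspondingly widened tolerances (±3
percentage points, ±1 patient) and the large-sample comparison at 500
replicates of 3,000-patient trials; `scripts/acceptance.py` runs the full
10,000 replicates per cell.
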