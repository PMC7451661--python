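"""Trial conduct: decisions, edge rules, elimination, lead-in, MTD selection."""

import math

import numpy as np
import pytest

from aboin import (
    Decision,
    DesignSpec,
    TrialState,
    boin_boundaries,
    aboin_boundaries,
    decide,
    effective_boundaries,
    run_trial,
    safety_eliminate,
    select_mtd,
)
from aboin.trial import elimination_min_dlt


def make_state(n, y, dose=1, eliminated=None):
    J = len(n)
    s = TrialState(J=J, current_dose=dose, n=np.array(n, dtype=np.int64), y=np.array(y, dtype=np.int64))
    if eliminated is not None:
        s.eliminated = np.array(eliminated, dtype=bool)
    return s


class TestDecide:
    def test_zero_toxicity_escalates_from_interior_dose(self, design_03):
        s = make_state([3, 3, 0, 0, 0], [0, 0, 0, 0, 0], dose=2)
        assert decide(s, design_03) is Decision.ESCALATE

    def test_top_dose_stays_instead_of_escalating(self, design_03):
        s = make_state([3, 3, 3, 3, 3], [0, 0, 0, 0, 0], dose=5)
        assert decide(s, design_03) is Decision.STAY

    def test_high_rate_deescalates(self, design_03):
        # 2/3 = 0.667 exceeds lambda2 = 0.3585 at target 0.3
        s = make_state([3, 3, 0, 0, 0], [0, 2, 0, 0, 0], dose=2)
        assert decide(s, design_03) is Decision.DEESCALATE

    def test_lowest_dose_stays_instead_of_deescalating(self, design_03):
        s = make_state([3, 0, 0, 0, 0], [2, 0, 0, 0, 0], dose=1)
        assert decide(s, design_03) is Decision.STAY

    def test_never_escalates_into_eliminated_dose(self, design_03):
        s = make_state([3, 3, 3, 0, 0], [0, 0, 0, 0, 0], dose=2,
                       eliminated=[False, False, True, True, True])
        assert decide(s, design_03) is Decision.STAY

    def test_requires_data_at_current_dose(self, design_03):
        s = make_state([3, 0, 0, 0, 0], [0, 0, 0, 0, 0], dose=2)
        with pytest.raises(RuntimeError, match="no data"):
            decide(s, design_03)


class TestEffectiveBoundaries:
    def test_lead_in_uses_fixed_pair(self):
        d = DesignSpec(phi=0.3, variant="aboin")
        s = make_state([3, 0, 0, 0, 0], [0, 0, 0, 0, 0])
        assert effective_boundaries(s, d) == boin_boundaries(0.3, 0.18, 0.42)

    def test_switch_point_uses_per_dose_sample_size(self):
        d = DesignSpec(phi=0.3, variant="aboin")
        s = make_state([6, 0, 0, 0, 0], [1, 0, 0, 0, 0])
        assert effective_boundaries(s, d) == aboin_boundaries(0.3, 0.12, 0.12, 0.4, 0.9, 6)

    def test_zero_lead_in_is_adaptive_from_the_start(self):
        d = DesignSpec(phi=0.3, variant="aboin", lead_in=0)
        s = make_state([3, 0, 0, 0, 0], [0, 0, 0, 0, 0])
        assert effective_boundaries(s, d) == aboin_boundaries(0.3, 0.12, 0.12, 0.4, 0.9, 3)


def _beta_tail_oracle(y: int, n: int, phi: float) -> float:
    """Pr(p > phi) under Beta(1+y, 1+n-y): binomial closed form for integer shapes."""
    return sum(
        math.comb(n + 1, k) * phi**k * (1 - phi) ** (n + 1 - k) for k in range(y + 1)
    )


class TestElimination:
    def test_three_of_three_is_eliminated_at_target_30(self):
        # Pr(p > 0.3 | 3/3) = 1 - 0.3^4 = 0.9919 > 0.95
        assert elimination_min_dlt(3, 0.3, 0.95) == 3
        assert _beta_tail_oracle(3, 3, 0.3) == pytest.approx(0.9919)
        assert _beta_tail_oracle(2, 3, 0.3) < 0.95

    def test_thresholds_match_closed_form_oracle_on_grid(self):
        for phi in (0.1, 0.2, 0.3):
            for n in range(3, 21):
                cut = elimination_min_dlt(n, phi, 0.95)
                oracle = next(
                    (y for y in range(n + 1) if _beta_tail_oracle(y, n, phi) > 0.95), None
                )
                assert cut == oracle

    def test_zero_toxicity_never_eliminates(self, design_03):
        s = make_state([9, 0, 0, 0, 0], [0, 0, 0, 0, 0])
        safety_eliminate(s, design_03)
        assert not s.eliminated.any()

    def test_elimination_cascades_upward(self, design_03):
        s = make_state([3, 3, 0, 0, 0], [0, 3, 0, 0, 0], dose=2)
        safety_eliminate(s, design_03)
        assert s.eliminated.tolist() == [False, True, True, True, True]
        assert not s.terminated_early

    def test_eliminating_lowest_dose_terminates(self, design_03):
        s = make_state([3, 0, 0, 0, 0], [3, 0, 0, 0, 0])
        safety_eliminate(s, design_03)
        assert s.terminated_early


def _pava_oracle(values, weights):
    """Hand-rolled pool-adjacent-violators, returning per-dose monotone estimates."""
    blocks = [[v, w, 1] for v, w in zip(values, weights)]  # value, weight, #doses
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]) / (
                blocks[i][1] + blocks[i + 1][1]
            )
            blocks[i] = [v, blocks[i][1] + blocks[i + 1][1], blocks[i][2] + blocks[i + 1][2]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = []
    for v, _, c in blocks:
        out.extend([v] * c)
    return out


class TestSelectMtd:
    def test_exact_match_selected(self):
        d = DesignSpec(phi=0.2)
        s = make_state([5, 5, 5], [0, 1, 2])
        assert select_mtd(s, d) == 2

    def test_pooled_tie_above_target_breaks_low(self):
        # phat (0.25, 0.15) pools to (0.20, 0.20) >= phi: lower dose wins
        d = DesignSpec(phi=0.2, cohort_size=1, max_n=40)
        s = make_state([20, 20], [5, 3])
        assert select_mtd(s, d) == 1

    def test_tie_below_target_breaks_high(self):
        d = DesignSpec(phi=0.3)
        s = make_state([3, 3, 3], [0, 0, 0])
        assert select_mtd(s, d) == 3

    def test_early_terminated_trial_selects_nothing(self, design_03):
        s = make_state([3, 0, 0], [3, 0, 0])
        safety_eliminate(s, design_03)
        assert select_mtd(s, design_03) is None

    def test_eliminated_doses_are_ineligible(self):
        d = DesignSpec(phi=0.3)
        s = make_state([6, 6, 3], [0, 1, 1], eliminated=[False, False, True])
        # dose 3's estimate (0.33) is closest to phi but it is eliminated
        assert select_mtd(s, d) == 2

    def test_matches_hand_pava_with_weights(self):
        d = DesignSpec(phi=0.25)
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(1, 12, size=4)
            y = rng.binomial(n, 0.3)
            s = make_state(n.tolist(), y.tolist())
            iso = np.array(_pava_oracle((y / n).tolist(), n.tolist()))
            dist = np.abs(iso - d.phi)
            best = dist.min()
            tied = np.nonzero(dist <= best + 1e-12)[0]
            expect = int(tied[-1]) + 1 if all(iso[tied] < d.phi) else int(tied[0]) + 1
            assert select_mtd(s, d) == expect


class TestRunTrial:
    def test_certain_toxicity_terminates_without_mtd(self, design_03):
        res = run_trial((1.0, 1.0, 1.0, 1.0, 1.0), design_03, rng_seed=0)
        assert res.terminated_early
        assert res.selected_mtd is None
        assert res.total_n == 3

    def test_zero_toxicity_climbs_to_top_dose(self, design_03):
        res = run_trial((0.0, 0.0, 0.0, 0.0, 0.0), design_03, rng_seed=0)
        assert not res.terminated_early
        assert res.selected_mtd == 5
        assert res.total_n == design_03.max_n
        assert [d for d, *_ in res.decisions[:4]] == [1, 2, 3, 4]

    def test_identical_seed_reproduces_the_decision_log(self, design_02):
        scen = (0.05, 0.1, 0.2, 0.3, 0.35)
        a = run_trial(scen, design_02, rng_seed=123)
        b = run_trial(scen, design_02, rng_seed=123)
        assert a.decisions == b.decisions
        assert a.selected_mtd == b.selected_mtd
        np.testing.assert_array_equal(a.n, b.n)

    def test_counts_are_conserved_and_bounded(self, design_02):
        for seed in range(30):
            res = run_trial((0.05, 0.1, 0.2, 0.3, 0.35), design_02, rng_seed=seed)
            assert res.total_n == res.n.sum() <= design_02.max_n
            assert np.all(res.y <= res.n)
            # eliminated doses form an upper set
            if res.eliminated.any():
                first = int(np.argmax(res.eliminated))
                assert res.eliminated[first:].all()

    def test_decisions_are_coherent(self, design_03):
        """Never escalate above the target's evidence, never flee below it."""
        scen = (0.1, 0.2, 0.3, 0.4, 0.45)
        for seed in range(200):
            res = run_trial(scen, design_03, rng_seed=seed)
            for dose, n_j, y_j, lam1, lam2, decision in res.decisions:
                phat = y_j / n_j
                if phat > design_03.phi:
                    assert decision is not Decision.ESCALATE
                if phat < design_03.phi:
                    assert decision is not Decision.DEESCALATE

    def test_invalid_probabilities_rejected(self, design_03):
        with pytest.raises(ValueError, match="lie in"):
            run_trial((0.1, 0.2, 1.3, 0.4, 0.5), design_03, rng_seed=0)

    def test_prior_variant_requires_table(self):
        d = DesignSpec(phi=0.2, variant="aboin_prior")
        with pytest.raises(ValueError, match="requires a prior"):
            run_trial((0.1, 0.2, 0.3, 0.4, 0.5), d, rng_seed=0)
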