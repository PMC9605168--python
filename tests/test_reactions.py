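"""Reaction primitives, the gate-window subsystem, and full-cell stepping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protolattice import (
    CellState,
    NetworkDefinition,
    apply_catalytic,
    apply_first_order,
    apply_pair_annihilation,
    apply_ratio_conversion,
    apply_window_subsystem,
    step_cell_reactions,
)
from protolattice.reactions import apply_reaction_stages


def make_cell(**counts) -> CellState:
    inv = np.zeros(15, dtype=np.int64)
    for k, v in counts.items():
        inv[int(k[1:]) - 1] = v
    return CellState(inventory=inv)


class TestFirstOrder:
    def test_integral_expectation_is_deterministic(self, rng):
        remaining, converted = apply_first_order(100, 0.05, rng)
        assert (remaining, converted) == (95, 5)

    def test_fractional_expectation_is_fair_bernoulli(self):
        outcomes = [apply_first_order(10, 0.05, np.random.default_rng(s))[1]
                    for s in range(4000)]
        assert set(outcomes) <= {0, 1}
        assert abs(np.mean(outcomes) - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_unit_probability_converts_all(self, rng):
        assert apply_first_order(37, 1.0, rng) == (0, 37)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_first_order(10, 1.5, rng)


class TestCatalytic:
    @pytest.mark.parametrize(
        "substrate,catalyst,expected",
        [(1_000_000, 50, 50), (10, 50, 10), (123, 0, 0)],
    )
    def test_full_rate_converts_min(self, substrate, catalyst, expected, rng):
        assert apply_catalytic(substrate, catalyst, 1.0, rng) == expected


class TestPairAnnihilation:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((30, 20), None, (10, 0, 40)),
         ((0, 7), None, (0, 7, 0)),
         ((5, 5), None, (0, 0, 10))],
    )
    def test_min_pair_arithmetic(self, a, b, expected):
        assert apply_pair_annihilation(*a) == expected

    def test_at_most_one_side_survives(self):
        a_left, b_left, _ = apply_pair_annihilation(17, 31)
        assert min(a_left, b_left) == 0


class TestRatioConversion:
    @pytest.mark.parametrize("count,w,expected", [(200, 0.65, 130), (200, 0.0, 0), (200, 1.0, 200)])
    def test_rounded_share(self, count, w, expected):
        assert apply_ratio_conversion(count, w) == expected

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            apply_ratio_conversion(10, 1.2)


class TestWindowSubsystem:
    def test_persistence_window_for_standard_gates(self):
        # brute-force enumeration: with 3 gate-low and 9 gate-high molecules
        # the membrane trigger survives exactly for incoming 11-counts 4..20
        surviving = [n11 for n11 in range(61)
                     if apply_window_subsystem(n11, 0, 3, 9)[1] > 0]
        assert surviving == list(range(4, 21))

    def test_no_substrate_no_change(self):
        assert apply_window_subsystem(0, 5, 3, 9) == (0, 5, 0)

    def test_no_gates_no_trigger(self):
        for n11 in range(50):
            assert apply_window_subsystem(n11, 0, 0, 0)[1] == 0

    def test_conserves_total(self):
        for n11 in range(0, 60, 7):
            n11_out, n13_out, released = apply_window_subsystem(n11, 2, 3, 9)
            assert n11_out + n13_out + released == n11 + 2

    @pytest.mark.parametrize("c14,c15", [(1, 5), (3, 9), (5, 9), (3, 15)])
    def test_window_is_single_contiguous_interval(self, c14, c15):
        persists = [apply_window_subsystem(n11, 0, c14, c15)[1] > 0
                    for n11 in range(201)]
        runs = np.flatnonzero(np.diff(np.array([False] + persists + [False])))
        assert len(runs) == 2  # one rise, one fall

    def test_window_bounds_monotone_in_gates(self):
        def bounds(c14, c15):
            p = [n11 for n11 in range(201)
                 if apply_window_subsystem(n11, 0, c14, c15)[1] > 0]
            return p[0], p[-1]

        lo_by_c14 = [bounds(c14, 9)[0] for c14 in range(1, 6)]
        hi_by_c15 = [bounds(3, c15)[1] for c15 in range(5, 13)]
        assert lo_by_c14 == sorted(lo_by_c14)
        assert hi_by_c15 == sorted(hi_by_c15)

    def test_iterated_policy_erases_trigger_when_11_survives(self):
        n11_out, n13_out, _ = apply_window_subsystem(30, 0, 3, 9, policy="iterated")
        assert n11_out > 0
        assert n13_out == 0


class TestStepCellReactions:
    def test_empty_cell_unchanged(self, rng):
        cell = make_cell()
        out = step_cell_reactions(cell, NetworkDefinition(), None, rng)
        assert out.inventory.sum() == 0

    def test_background_cell_inert_under_trigger_gate(self, rng):
        # with regeneration gated on the membrane trigger, feedstock plus
        # ubiquitous gate molecules alone produce no morphogens
        cell = make_cell(m1=1000, m14=3, m15=9)
        out = step_cell_reactions(cell, NetworkDefinition(), None, rng)
        assert out.count(2) == 0 and out.count(3) == 0

    def test_ungated_regeneration_runs_off_gate_molecule(self, rng):
        cell = make_cell(m1=1000, m14=3, m15=9)
        net = NetworkDefinition(stage_f_gate="none")
        out = step_cell_reactions(cell, net, None, rng)
        assert out.count(2) == 3 and out.count(3) == 3

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 5000), min_size=15, max_size=15),
        w=st.one_of(st.none(), st.floats(0, 1)),
        seed=st.integers(0, 20),
    )
    def test_total_count_conserved(self, counts, w, seed):
        cell = CellState(inventory=np.array(counts, dtype=np.int64))
        out = step_cell_reactions(cell, NetworkDefinition(), w,
                                  np.random.default_rng(seed))
        assert out.inventory.sum() == cell.inventory.sum()
        assert (out.inventory >= 0).all()


class TestThresholdEquivalence:
    def test_comparator_realizes_threshold_inequality(self):
        # after ratio conversion and annihilation, molecule 11 survives
        # exactly when n11 > round((n8 + n9) * w) — the CA threshold rule
        rng = np.random.default_rng(7)
        net = NetworkDefinition()
        for _ in range(1000):
            n8, n9, n11 = rng.integers(0, 200, size=3)
            w = float(rng.uniform(0, 1))
            species = np.zeros((15, 1, 1), dtype=np.int64)
            species[7, 0, 0], species[8, 0, 0], species[10, 0, 0] = n8, n9, n11
            apply_reaction_stages(species, net, w, rng, stages=("C", "D"))
            survived = species[10, 0, 0] > 0
            rnd = lambda x: int(np.floor(x + 0.5 + 1e-9))  # noqa: E731
            threshold = rnd(n8 * w) + rnd(n9 * w)
            assert survived == (n11 > threshold)
            # the realized threshold tracks the CA's N2*w within rounding
            assert abs(threshold - (n8 + n9) * w) <= 1.0
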