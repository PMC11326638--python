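"""Maximal states, MIP search, integrated cause/effect information."""

import math

import numpy as np
import pytest

from iitbounds import (
    copy_system,
    difference_measure,
    integrated_cause_information,
    integrated_effect_information,
    maximal_effect_state,
    mechanism_phi,
    partitioned_cause_repertoire,
    partitioned_effect_repertoire,
    random_deterministic,
    random_stochastic,
    threshold_system,
    unconstrained_effect,
)
from iitbounds.partitions import Partition, enumerate_partitions
from iitbounds.phi import TIE_TOL, maximal_cause_state, mip
from iitbounds.tpm import Purview, effect_repertoire

from conftest import mech, pv

LOG2_16_9 = math.log2(16 / 9)


class TestDifferenceMeasure:
    @pytest.mark.parametrize("variant", ["positive-part", "absolute-value",
                                         "pointwise-mutual-information", "kl"])
    def test_identity_is_zero(self, variant):
        assert difference_measure(0.7, 0.7, variant) == pytest.approx(0.0)

    def test_doubling_gives_one_bit(self):
        assert difference_measure(1.0, 0.5) == pytest.approx(1.0)

    def test_positive_part_clamps_decreases(self):
        assert difference_measure(0.5, 1.0) == 0.0
        assert difference_measure(0.5, 1.0, "absolute-value") == pytest.approx(0.5)
        assert difference_measure(0.5, 1.0, "kl") == pytest.approx(-0.5)

    def test_zero_p_is_zero(self):
        assert difference_measure(0.0, 0.0) == 0.0

    def test_impossible_zero_q_raises(self):
        with pytest.raises(RuntimeError):
            difference_measure(0.5, 0.0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            difference_measure(0.5, 0.5, "emd")


class TestMaximalStates:
    def test_copy_single_unit(self, copy2):
        state, value = maximal_effect_state(copy2, mech([0], [1]), pv([0]))
        assert state == (1,)
        assert value == pytest.approx(1.0)

    def test_and_pair_full_mechanism(self, and_pair):
        # point mass on (1,1); unconstrained (average of joint repertoires) is 1/4
        state, value = maximal_effect_state(and_pair, mech([0, 1], [1, 1]), pv([0, 1]))
        assert state == (1, 1)
        assert value == pytest.approx(2.0)

    def test_constant_on_purview_unit(self, constant_on):
        # the constant unit's maximal state is ON with zero log-ratio there
        state, _ = maximal_effect_state(constant_on, mech([1], [1]), pv([0, 1]))
        assert state[0] == 1

    def test_mechanism_always_raises_probability(self):
        for seed in range(10):
            tpm = random_stochastic(3, seed=seed)
            m = mech([0, 1], [1, 0])
            Z = pv([1, 2])
            state, value = maximal_effect_state(tpm, m, Z)
            p = effect_repertoire(tpm, m, Z).prob(state)
            q = unconstrained_effect(tpm, Z, m.units).prob(state)
            assert p > q - 1e-12

    def test_cause_state_copy(self, copy2):
        state, _ = maximal_cause_state(copy2, mech([0], [1]), pv([0]))
        assert state == (1,)


class TestPartitionedRepertoires:
    def test_aligned_copy_partition_changes_nothing(self, copy2):
        theta = Partition((((0,), (0,)), ((1,), (1,))))
        m = mech([0, 1], [1, 1])
        intact = effect_repertoire(copy2, m, pv([0, 1])).probs
        cut = partitioned_effect_repertoire(copy2, m, pv([0, 1]), theta).probs
        np.testing.assert_allclose(cut, intact, atol=1e-12)

    def test_complete_cut_is_product_of_unconstrained(self, and_pair):
        theta = Partition((((0, 1), ()), ((), (0, 1))))
        cut = partitioned_effect_repertoire(and_pair, mech([0, 1], [1, 1]),
                                            pv([0, 1]), theta)
        # each unit fully marginalized: P(ON) = 1/4, combined as a product
        assert cut.prob([1, 1]) == pytest.approx(1 / 16)

    def test_and_pair_unit_bipartition(self, and_pair):
        theta = Partition((((0,), (0,)), ((1,), (1,))))
        cut = partitioned_effect_repertoire(and_pair, mech([0, 1], [1, 1]),
                                            pv([0, 1]), theta)
        assert cut.prob([1, 1]) == pytest.approx(0.25)

    def test_inconsistent_partition_rejected(self, copy2):
        theta = Partition((((0,), (0,)), ((1,), (1,))))
        with pytest.raises(ValueError):
            partitioned_effect_repertoire(copy2, mech([0], [1]), pv([0]), theta)

    def test_cause_partition_product_normalized(self, and_pair):
        theta = Partition((((0,), (0,)), ((1,), (1,))))
        cut = partitioned_cause_repertoire(and_pair, mech([0, 1], [1, 1]),
                                           pv([0, 1]), theta)
        assert cut.probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestMip:
    def test_copy_pair_mip_is_unit_aligned_with_zero_loss(self, copy2):
        res = integrated_effect_information(copy2, mech([0, 1], [1, 1]), pv([0, 1]))
        assert res.phi == pytest.approx(0.0)
        assert res.mip == Partition((((0,), (0,)), ((1,), (1,))))

    def test_one_by_one_mip_is_the_complete_cut(self, copy2):
        theta = mip(copy2, mech([0], [1]), pv([0]))
        assert theta == Partition((((0,), ()), ((), (0,))))

    def test_threshold_32_normalized_loss(self):
        tpm = threshold_system(3, 2)
        res = integrated_effect_information(tpm, mech([0, 1], [1, 1]), pv([0, 1]),
                                            scheme="bipartitions")
        assert res.normalized_loss == pytest.approx(LOG2_16_9 / 2)
        assert res.normalized_loss <= 1 + TIE_TOL  # Lemma 2 corollary

    def test_normalized_loss_never_exceeds_one(self):
        for seed in range(5):
            tpm = random_stochastic(3, seed=seed)
            res = integrated_effect_information(tpm, mech([0, 1], [1, 0]), pv([0, 2]))
            assert res.normalized_loss <= 1 + TIE_TOL


class TestIntegratedEffectInformation:
    def test_copy_single_unit_phi_one(self, copy3):
        res = integrated_effect_information(copy3, mech([0], [1]), pv([0]))
        assert res.phi == pytest.approx(1.0)
        assert res.selectivity == pytest.approx(1.0)

    def test_copy_composites_reducible(self, copy3):
        res = integrated_effect_information(copy3, mech([0, 1], [1, 1]), pv([0, 1]))
        assert res.phi == pytest.approx(0.0)

    def test_threshold_32_phi(self):
        tpm = threshold_system(3, 2)
        res = integrated_effect_information(tpm, mech([0, 1], [1, 1]), pv([0, 1]))
        assert res.phi == pytest.approx(LOG2_16_9)

    def test_phi_equals_selectivity_times_informativeness(self):
        tpm = random_stochastic(3, seed=42)
        res = integrated_effect_information(tpm, mech([0, 1], [1, 1]), pv([0, 1]))
        assert res.phi == pytest.approx(res.selectivity * res.informativeness)

    def test_mip_loss_matches_explicit_partition_enumeration(self):
        """Dual route: the class-based MIP equals a brute-force minimum over
        explicitly enumerated partitions evaluated with the repertoire code."""
        for seed in range(6):
            tpm = random_stochastic(3, seed=seed)
            m = mech([0, 1], [1, 0])
            Z = pv([0, 2])
            state, _ = maximal_effect_state(tpm, m, Z)
            p = effect_repertoire(tpm, m, Z).prob(state)
            best = math.inf
            best_phi = None
            for theta in enumerate_partitions(m.units, Z.units):
                q = partitioned_effect_repertoire(tpm, m, Z, theta).prob(state)
                loss = difference_measure(p, q)
                if loss / theta.severed < best - 1e-12:
                    best = loss / theta.severed
                    best_phi = loss
            res = integrated_effect_information(tpm, m, Z)
            assert res.normalized_loss == pytest.approx(best, abs=1e-9)
            assert res.phi == pytest.approx(best_phi, abs=1e-9)


class TestIntegratedCauseInformation:
    def test_copy_single_unit_phi_one(self, copy2):
        res = integrated_cause_information(copy2, mech([0], [1]), pv([0]))
        assert res.phi == pytest.approx(1.0)

    def test_constant_on_mechanism_phi_zero(self, constant_on):
        res = integrated_cause_information(constant_on, mech([0], [1]), pv([0, 1]))
        assert res.phi == pytest.approx(0.0)

    def test_undefined_cause_gives_zero(self, constant_on):
        res = integrated_cause_information(constant_on, mech([0], [0]), pv([0, 1]))
        assert res.phi == 0.0
        assert not res.defined

    def test_and_pair_matches_explicit_enumeration(self, and_pair):
        m = mech([0], [1])
        Z = pv([0, 1])
        state, _ = maximal_cause_state(and_pair, m, Z)
        from iitbounds import cause_repertoire
        p = cause_repertoire(and_pair, m, Z).prob(state)
        best = math.inf
        best_phi = None
        for theta in enumerate_partitions(m.units, Z.units):
            q = partitioned_cause_repertoire(and_pair, m, Z, theta).prob(state)
            loss = difference_measure(p, q)
            if loss / theta.severed < best - 1e-12:
                best = loss / theta.severed
                best_phi = loss
        res = integrated_cause_information(and_pair, m, Z)
        assert res.phi == pytest.approx(best_phi, abs=1e-9)


class TestBoundsProperties:
    def test_theorem1_phi_at_most_connection_count(self):
        for seed in range(8):
            tpm = random_stochastic(3, seed=100 + seed)
            for munits in [(0,), (0, 1), (0, 1, 2)]:
                m = mech(munits, [1] * len(munits))
                for zunits in [(0,), (1, 2), (0, 1, 2)]:
                    res = integrated_effect_information(tpm, m, pv(zunits))
                    assert res.phi <= len(munits) * len(zunits) + 1e-9

    def test_lemma4_max_phi_implies_selectivity_one(self):
        tpm = threshold_system(3, 3)
        res = integrated_effect_information(tpm, mech([0, 1, 2], [1, 1, 1]),
                                            pv([0, 1, 2]))
        assert res.phi == pytest.approx(9.0)
        assert res.selectivity == pytest.approx(1.0)

    def test_lemma3_superset_of_deterministic_is_deterministic(self):
        from iitbounds import effect_repertoire_single
        for seed in range(10):
            tpm = random_deterministic(3, seed=seed)
            for z in (0, 1):
                for unit in range(3):
                    p_small = effect_repertoire_single(tpm, mech([0], [1]), unit).prob([z])
                    p_big = effect_repertoire_single(tpm, mech([0, 1], [1, 1]), unit).prob([z])
                    if p_small == 1.0:
                        assert p_big == pytest.approx(1.0)
                    if p_small == 0.0:
                        assert p_big == pytest.approx(0.0)

    def test_theorem2_sharing_purview_caps_neighbours(self, copy3):
        """With φe(m, Z) = |M||Z| attained (single-unit copy over itself),
        every super-mechanism sharing purview units stays strictly below its
        own connection count."""
        base = integrated_effect_information(copy3, mech([0], [1]), pv([0]))
        assert base.phi == pytest.approx(1.0)  # = |M||Z|
        for munits in [(0, 1), (0, 2), (0, 1, 2)]:
            for zunits in [(0,), (0, 1), (0, 1, 2)]:
                res = integrated_effect_information(
                    copy3, mech(munits, [1] * len(munits)), pv(zunits))
                assert res.phi < len(munits) * len(zunits) - 1e-9


class TestMechanismPhi:
    def test_copy_single_unit_distinction(self, copy2):
        res = mechanism_phi(copy2, mech([0], [1]))
        assert res.irreducible
        d = res.distinction
        assert d.phi == pytest.approx(1.0)
        assert d.cause.units == (0,) and d.cause.state == (1,)
        assert d.effect.units == (0,) and d.effect.state == (1,)

    def test_copy_pair_reducible(self, copy2):
        res = mechanism_phi(copy2, mech([0, 1], [1, 1]))
        assert not res.irreducible
        assert res.phi == 0.0
        assert res.distinction is None

    def test_threshold_full_mechanism_attains_n_squared_effect(self):
        tpm = threshold_system(3, 3)
        res = mechanism_phi(tpm, mech([0, 1, 2], [1, 1, 1]))
        assert res.effect.phi == pytest.approx(9.0)
        assert res.effect.purview.units == (0, 1, 2)

    def test_reflexive_search_space(self, copy3):
        res = mechanism_phi(copy3, mech([1], [1]), purview_space="self")
        assert res.effect.purview.units == (1,)
        assert res.phi == pytest.approx(1.0)
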