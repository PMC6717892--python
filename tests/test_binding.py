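"""Binding thermodynamics: entropy bookkeeping, occupancy models, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from allosense.binding import (
    ConvergenceError,
    DomainError,
    OccupancyState,
    SequentialParams,
    ThermoConstants,
    TwoSetsParams,
    cooperativity_index,
    delta_S_from_K_dH,
    free_ligand,
    free_ligand_many,
    kd_from_kass,
    occupancy_sequential,
    occupancy_two_sets,
)

# published per-class constants: (K_ass / M^-1, dH / cal/mol, dS / cal/K/mol)
TABLE_ROWS = [
    pytest.param(1.29e6, -12070.0, -12.50, id="cAMP-class1"),
    pytest.param(4.46e4, -7139.0, -2.66, id="cAMP-class2"),
    pytest.param(8.79e4, -5203.0, 5.18, id="cGMP-class1"),
    pytest.param(1.30e6, -9023.0, -2.28, id="cGMP-class2"),
]


class TestThermoDerivation:
    @pytest.mark.parametrize("K, dH, dS_expect", TABLE_ROWS)
    def test_entropies_reproduce_published_values(self, K, dH, dS_expect):
        """dS = (dH + RT ln K)/T reproduces all four published entropies."""
        d = delta_S_from_K_dH(K, dH)
        assert d.dS == pytest.approx(dS_expect, abs=0.05)
        assert d.dG == pytest.approx(dH - ThermoConstants().T * d.dS, rel=1e-6)

    @pytest.mark.parametrize(
        "K, kd_uM",
        [(1.29e6, 0.775), (4.46e4, 22.4), (8.79e4, 11.38), (1.30e6, 0.769)],
    )
    def test_dissociation_constants_invert_association(self, K, kd_uM):
        assert kd_from_kass(K) * 1e6 == pytest.approx(kd_uM, rel=5e-3)

    def test_unit_association_constant_gives_zero_free_energy(self):
        d = delta_S_from_K_dH(1.0, 0.0)
        assert d.dG == 0.0 and d.dS == 0.0 and d.Kd == 1.0

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_K_rejected(self, bad):
        with pytest.raises(DomainError):
            delta_S_from_K_dH(bad, -1000.0)
        with pytest.raises(DomainError):
            kd_from_kass(bad)


class TestTwoSetsOccupancy:
    def test_zero_ligand_means_zero_saturation(self, camp_params):
        assert occupancy_two_sets(camp_params, 0.0) == (0.0, 0.0)

    def test_half_saturation_at_the_dissociation_constant(self, camp_params):
        theta1, _ = occupancy_two_sets(camp_params, 1.0 / camp_params.K1)
        assert theta1 == pytest.approx(0.5, rel=1e-12)

    def test_matches_direct_isotherm_evaluation(self, camp_params):
        L = 5e-6
        theta1, theta2 = occupancy_two_sets(camp_params, L)
        for theta, K in [(theta1, camp_params.K1), (theta2, camp_params.K2)]:
            assert theta == pytest.approx(K * L / (1 + K * L), rel=1e-14)

    def test_negative_ligand_rejected(self, camp_params):
        with pytest.raises(DomainError):
            occupancy_two_sets(camp_params, -1e-9)


CAMP_SEQ = SequentialParams.from_stepwise_kds(0.775e-6, 22.4e-6)


class TestSequentialOccupancy:
    def test_apo_at_zero_ligand(self):
        occ = occupancy_sequential(CAMP_SEQ, 0.0)
        assert occ.f0 == 1.0 and occ.nu == 0.0

    def test_agrees_with_bruteforce_partition_function(self):
        """f_i must equal the Boltzmann weight of the i-ligand species."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            sp = SequentialParams(
                beta1=10.0 ** rng.uniform(3, 8), beta2=10.0 ** rng.uniform(6, 14)
            )
            L = 10.0 ** rng.uniform(-9, -2)
            weights = np.array([1.0, sp.beta1 * L, sp.beta2 * L * L])
            expect = weights / weights.sum()
            occ = occupancy_sequential(sp, L)
            np.testing.assert_allclose([occ.f0, occ.f1, occ.f2], expect, rtol=1e-13)
            assert occ.nu == pytest.approx(expect[1] + 2 * expect[2], rel=1e-12)

    def test_double_occupancy_half_point_near_23_uM_for_cAMP(self):
        """Bisection on f2(L) = 1/2 for the cAMP stepwise constants."""
        L = brentq(lambda x: occupancy_sequential(CAMP_SEQ, x).f2 - 0.5, 1e-9, 1e-2)
        assert L * 1e6 == pytest.approx(23.0, abs=0.5)

    def test_species_fractions_normalized_on_log_grid(self):
        for L in np.geomspace(1e-10, 1e-2, 100):
            occ = occupancy_sequential(CAMP_SEQ, L)
            assert abs(occ.f0 + occ.f1 + occ.f2 - 1.0) < 1e-10

    def test_stepwise_constant_ratio_is_ligand_independent(self):
        vals = [
            occupancy_sequential(CAMP_SEQ, L).f2
            / (occupancy_sequential(CAMP_SEQ, L).f1 * L)
            for L in np.geomspace(1e-8, 1e-3, 20)
        ]
        np.testing.assert_allclose(vals, CAMP_SEQ.beta2 / CAMP_SEQ.beta1, rtol=1e-10)

    def test_f2_and_nu_strictly_increasing_in_ligand(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sp = SequentialParams(
                beta1=10.0 ** rng.uniform(3, 8), beta2=10.0 ** rng.uniform(6, 14)
            )
            grid = np.geomspace(1e-9, 1e-2, 200)
            f2 = np.array([occupancy_sequential(sp, L).f2 for L in grid])
            nu = np.array([occupancy_sequential(sp, L).nu for L in grid])
            assert np.all(np.diff(f2) > 0)
            assert np.all(np.diff(nu) > 0)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(DomainError):
            OccupancyState(f0=0.5, f1=0.5, f2=0.5, nu=1.5)


class TestFreeLigand:
    def test_trivial_limits(self, camp_params):
        assert free_ligand(camp_params, Ptot=1e-4, Ltot=0.0) == 0.0
        assert free_ligand(camp_params, Ptot=0.0, Ltot=5e-5) == pytest.approx(5e-5, rel=1e-10)

    def test_matches_independent_brentq_oracle(self, camp_params):
        p, Ptot, Ltot = camp_params, 100e-6, 50e-6

        def balance(L):
            return (
                L
                + Ptot * (p.n1 * p.K1 * L / (1 + p.K1 * L) + p.n2 * p.K2 * L / (1 + p.K2 * L))
                - Ltot
            )

        oracle = brentq(balance, 0.0, Ltot, xtol=1e-13, rtol=8.9e-16)
        assert free_ligand(p, Ptot, Ltot) == pytest.approx(oracle, rel=1e-9)

    def test_mass_balance_round_trip_on_random_cases(self):
        """Ltot reconstructed from the returned free L within 1e-9 relative."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = TwoSetsParams(
                n1=rng.uniform(0.2, 1.5), n2=rng.uniform(0.2, 1.5),
                K1=10.0 ** rng.uniform(3, 8), K2=10.0 ** rng.uniform(3, 8),
                dH1=-1e4, dH2=-5e3,
            )
            Ptot = 10.0 ** rng.uniform(-6, -3)
            Ltot = 10.0 ** rng.uniform(-7, -2)
            L = free_ligand(p, Ptot, Ltot)
            theta1, theta2 = occupancy_two_sets(p, L)
            back = L + Ptot * (p.n1 * theta1 + p.n2 * theta2)
            assert back == pytest.approx(Ltot, rel=1e-9)

    def test_negative_inputs_rejected(self, camp_params):
        with pytest.raises(DomainError):
            free_ligand_many(camp_params, np.array([-1e-6]), np.array([1e-6]))


class TestCooperativityIndex:
    def test_cAMP_order_is_negative(self):
        c, label = cooperativity_index(0.775e-6, 22.4e-6)
        assert c == pytest.approx(0.138, abs=0.002)
        assert label == "negative"

    def test_cGMP_order_is_positive(self):
        c, label = cooperativity_index(11.38e-6, 0.769e-6)
        assert c == pytest.approx(59.0, rel=0.01)
        assert label == "positive"

    def test_statistical_factor_identity_is_noncooperative(self):
        c, label = cooperativity_index(1e-6, 4e-6)
        assert c == pytest.approx(1.0, rel=1e-12)
        assert label == "non-cooperative"

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(DomainError):
            cooperativity_index(0.0, 1e-6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    logb1=st.floats(3, 8),
    dlogb2=st.floats(-2, 4),
    logL=st.floats(-9, -2),
)
def test_sequential_occupancy_invariants_hold_everywhere(logb1, dlogb2, logL):
    """Species fractions are a probability simplex and nu is within [0, 2]."""
    sp = SequentialParams(beta1=10.0**logb1, beta2=10.0 ** (2 * logb1 + dlogb2))
    occ = occupancy_sequential(sp, 10.0**logL)
    assert 0.0 <= occ.f0 <= 1.0 and 0.0 <= occ.f1 <= 1.0 and 0.0 <= occ.f2 <= 1.0
    assert 0.0 <= occ.nu <= 2.0
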