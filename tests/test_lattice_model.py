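"""Lattice model: enumeration oracle, recursion, mass balance, titrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clefmap.lattice_model import (
    BindingConfiguration,
    EnumerationCapError,
    LatticeConstruct,
    LigandParams,
    _oracle_occupancy,
    configuration_weight,
    count_saturating_ligands,
    enumerate_configurations,
    log_partition_function,
    mean_bound_and_coverage,
    partition_function,
    saturated_exponent,
    solve_mass_balance,
    titration_curve,
)


class TestCountSaturatingLigands:
    def test_21mer_holds_three(self):
        assert count_saturating_ligands(21, 7) == 3

    def test_28mer_holds_four(self):
        assert count_saturating_ligands(28, 7) == 4

    def test_ligand_longer_than_lattice(self):
        assert count_saturating_ligands(6, 7) == 0

    def test_invalid_site_size(self):
        with pytest.raises(ValueError):
            count_saturating_ligands(21, 0)


class TestEnumeration:
    def test_single_site_two_configurations(self):
        configs = enumerate_configurations(7, 7)
        assert len(configs) == 2
        assert sorted(c.m for c in configs) == [0, 1]

    def test_21mer_m1_count(self):
        configs = [c for c in enumerate_configurations(21, 7) if c.m == 1]
        assert len(configs) == 15  # C(15, 1)

    def test_21mer_unique_saturated_tiling(self):
        configs = [c for c in enumerate_configurations(21, 7) if c.m == 3]
        assert len(configs) == 1
        assert configs[0].j == 2
        assert configs[0].start_positions == (1, 8, 15)

    @pytest.mark.parametrize("N,n", [(12, 3), (14, 7), (20, 3), (28, 7)])
    def test_counts_match_binomial_formula(self, N, n):
        configs = enumerate_configurations(N, n)
        for m in range(N // n + 1):
            expected = math.comb(N - m * n + m, m)
            assert sum(1 for c in configs if c.m == m) == expected

    def test_cap_enforced(self):
        with pytest.raises(EnumerationCapError):
            enumerate_configurations(41, 7)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            BindingConfiguration((1, 5), 7, 21)


class TestConfigurationWeight:
    def test_empty_reference_state(self, params):
        empty = BindingConfiguration((), 7, 21)
        assert configuration_weight(empty, params, 1e-6) == 1.0

    def test_saturated_21mer(self, params):
        sat = BindingConfiguration((1, 8, 15), 7, 21)
        assert sat.m == 3 and sat.j == 2
        x = params.K_a * 1e-6
        expected = x**3 * params.omega**2
        assert configuration_weight(sat, params, 1e-6) == pytest.approx(expected)

    def test_two_abutting_on_14mer(self, params):
        configs = [c for c in enumerate_configurations(14, 7) if c.m == 2]
        assert len(configs) == 1  # unique tiling
        (c,) = configs
        assert c.j == 1
        x = params.K_a * 2e-7
        assert configuration_weight(c, params, 2e-7) == pytest.approx(
            x**2 * params.omega
        )


class TestPartitionFunction:
    def test_single_site(self, params):
        L = 3e-7
        assert partition_function(7, params, L) == pytest.approx(
            1 + params.K_a * L, rel=1e-12
        )

    def test_14mer_polynomial(self, params):
        L = 5e-7
        x = params.K_a * L
        expected = 1 + 8 * x + x**2 * params.omega
        assert partition_function(14, params, L) == pytest.approx(expected, rel=1e-12)

    def test_empty_lattice_limit(self, params):
        assert partition_function(21, params, 0.0) == 1.0

    def test_log_route_matches_linear(self, params):
        L = 1e-6
        assert log_partition_function(21, params, L) == pytest.approx(
            math.log(partition_function(21, params, L)), rel=1e-12
        )

    def test_extreme_parameters_do_not_overflow(self):
        p = LigandParams(K_a=1e100, omega=1e80)
        lz = log_partition_function(21, p, 1.0)
        assert np.isfinite(lz) and lz > 0


def _random_draws(rng, k):
    for _ in range(k):
        yield (
            10 ** rng.uniform(3, 8),
            10 ** rng.uniform(-1, 5),
            10 ** rng.uniform(-9, -5),
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "N,n", [(7, 7), (10, 7), (14, 7), (21, 7), (28, 7),
                (3, 3), (5, 3), (9, 3), (12, 3), (20, 3)]
    )
    def test_recursion_matches_enumeration(self, N, n, rng):
        for K_a, omega, L in _random_draws(rng, 10):
            p = LigandParams(K_a, omega, n)
            z_rec = partition_function(N, p, L)
            configs = enumerate_configurations(N, n)
            z_enum = sum(configuration_weight(c, p, L) for c in configs)
            assert z_rec == pytest.approx(z_enum, rel=1e-9)
            a = mean_bound_and_coverage(N, p, L)
            b = _oracle_occupancy(N, p, L)
            assert a.mean_bound == pytest.approx(b.mean_bound, rel=1e-9, abs=1e-15)
            np.testing.assert_allclose(
                a.coverage, b.coverage, rtol=1e-9, atol=1e-15
            )

    def test_log_route_occupancy_matches_linear(self):
        # parameters large enough to force the log-domain branch
        p_big = LigandParams(K_a=1e70, omega=1e60)
        prof = mean_bound_and_coverage(21, p_big, 1.0)
        assert prof.mean_bound == pytest.approx(3.0, rel=1e-9)
        assert all(t == pytest.approx(1.0, rel=1e-9) for t in prof.coverage)


class TestOccupancyInvariants:
    def test_zero_ligand(self, params):
        prof = mean_bound_and_coverage(21, params, 0.0)
        assert prof.mean_bound == 0.0
        assert all(t == 0.0 for t in prof.coverage)

    def test_saturation_limit(self, params):
        prof = mean_bound_and_coverage(21, LigandParams(1e12, 1e6), 1e-2)
        assert prof.mean_bound == pytest.approx(3.0, rel=1e-6)
        assert min(prof.coverage) > 0.999999

    def test_14mer_noncooperative_mean(self):
        # Z = 1 + 8x + x^2 at omega = 1, x = 1: mbar = (8 + 2) / 10 = 1.0
        p = LigandParams(K_a=1.0, omega=1.0)
        prof = mean_bound_and_coverage(14, p, 1.0)
        assert prof.mean_bound == pytest.approx(1.0, rel=1e-12)

    def test_coverage_sums_to_n_mean_bound(self, params, rng):
        for K_a, omega, L in _random_draws(rng, 10):
            p = LigandParams(K_a, omega)
            prof = mean_bound_and_coverage(21, p, L)
            assert sum(prof.coverage) == pytest.approx(
                7 * prof.mean_bound, rel=1e-9, abs=1e-15
            )

    def test_reversal_symmetry(self, rng):
        for K_a, omega, L in _random_draws(rng, 10):
            p = LigandParams(K_a, omega)
            cov = mean_bound_and_coverage(24, p, L).coverage
            np.testing.assert_allclose(cov, cov[::-1], rtol=1e-9)

    def test_omega_one_reduces_to_noncooperative_closed_form(self, rng):
        # enumeration with interfaces ignored == model at omega = 1
        for K_a, _, L in _random_draws(rng, 5):
            p1 = LigandParams(K_a, 1.0)
            x = K_a * L
            configs = enumerate_configurations(21, 7)
            z = sum(x**c.m for c in configs)
            mbar = sum(c.m * x**c.m for c in configs) / z
            assert mean_bound_and_coverage(21, p1, L).mean_bound == pytest.approx(
                mbar, rel=1e-9, abs=1e-15
            )

    @given(
        lf=st.floats(1e-9, 1e-5),
        factor=st.floats(1.1, 10.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_mean_bound_increases_with_free_ligand(self, lf, factor):
        p = LigandParams(1e6, 50.0)
        low = mean_bound_and_coverage(21, p, lf).mean_bound
        high = mean_bound_and_coverage(21, p, lf * factor).mean_bound
        assert high > low

    @given(
        ka=st.floats(1e3, 1e8),
        factor=st.floats(1.1, 10.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_mean_bound_increases_with_affinity(self, ka, factor):
        L = 1e-6
        low = mean_bound_and_coverage(21, LigandParams(ka, 50.0), L).mean_bound
        high = mean_bound_and_coverage(
            21, LigandParams(ka * factor, 50.0), L
        ).mean_bound
        assert high > low


class TestSaturatedExponent:
    def test_21mer_two_thirds(self):
        assert saturated_exponent(21, 7) == pytest.approx(2 / 3)
        assert round(saturated_exponent(21, 7), 2) == 0.67

    def test_28mer_three_quarters(self):
        assert saturated_exponent(28, 7) == 0.75

    def test_single_ligand_no_interfaces(self):
        assert saturated_exponent(7, 7) == 0.0

    def test_short_lattice_raises(self):
        with pytest.raises(ValueError):
            saturated_exponent(6, 7)


class TestMassBalance:
    def test_zero_total(self, params):
        st_ = solve_mass_balance(0.0, 1e-6, 21, params)
        assert st_.free_ligand == 0.0

    def test_zero_lattice(self, params):
        st_ = solve_mass_balance(2e-6, 0.0, 21, params)
        assert st_.free_ligand == 2e-6

    def test_free_bounded_by_total(self, params, rng):
        for _ in range(5):
            total = 10 ** rng.uniform(-8, -5)
            st_ = solve_mass_balance(total, 1e-6, 21, params)
            assert 0 <= st_.free_ligand <= total

    def test_matches_enumeration_based_balance(self):
        # independent route: bisection against the enumeration occupancy
        p = LigandParams(1e7, 1e3)
        total, D = 1.5e-6, 1e-6

        def residual(L):
            return L + D * _oracle_occupancy(21, p, L).mean_bound - total

        lo, hi = 0.0, total
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if residual(mid) > 0:
                hi = mid
            else:
                lo = mid
        st_ = solve_mass_balance(total, D, 21, p)
        assert st_.free_ligand == pytest.approx(0.5 * (lo + hi), rel=1e-9)
        mb_model = mean_bound_and_coverage(21, p, st_.free_ligand).mean_bound
        mb_oracle = _oracle_occupancy(21, p, 0.5 * (lo + hi)).mean_bound
        assert mb_model == pytest.approx(mb_oracle, rel=1e-8)

    def test_mass_conserved_along_titration(self, strong_params):
        c = LatticeConstruct(21, (9,), "monomer", "21T9")
        D = 1e-6
        for r, prof in titration_curve(c, strong_params, [0.5, 1.5, 3.0, 5.0], D):
            st_ = solve_mass_balance(r * D, D, 21, strong_params)
            bound = D * prof.mean_bound
            assert st_.free_ligand + bound == pytest.approx(r * D, rel=1e-7)


class TestTitrationCurve:
    def test_zero_ratio(self, params):
        c = LatticeConstruct(21, (9,), "monomer", "21T9")
        (r0, prof0), *_ = titration_curve(c, params, [0.0, 1.0], 1e-6)
        assert prof0.mean_bound == 0.0

    def test_strong_binding_saturates_at_capacity(self, strong_params):
        c = LatticeConstruct(21, (9,), "monomer", "21T9")
        curve = titration_curve(c, strong_params, [6.0], 1e-6)
        assert curve[0][1].mean_bound == pytest.approx(3.0, abs=1e-3)

    def test_weak_binding_stays_empty(self):
        weak = LigandParams(1e-3, 1.0)
        c = LatticeConstruct(21, (9,), "monomer", "21T9")
        curve = titration_curve(c, weak, [6.0], 1e-6)
        assert curve[0][1].mean_bound < 1e-6

    def test_unsorted_ratios_rejected(self, params):
        c = LatticeConstruct(21, (9,), "monomer", "21T9")
        with pytest.raises(ValueError):
            titration_curve(c, params, [1.0, 0.5], 1e-6)


class TestTypes:
    def test_ligand_params_validation(self):
        with pytest.raises(ValueError):
            LigandParams(K_a=-1.0, omega=1.0)
        with pytest.raises(ValueError):
            LigandParams(K_a=1.0, omega=-0.5)
        with pytest.raises(ValueError):
            LigandParams(K_a=1.0, omega=1.0, site_size_n=0)
        assert LigandParams(1.0, 1.0).site_size_n == 7

    def test_construct_validation(self):
        with pytest.raises(ValueError):
            LatticeConstruct(21, (22,), "monomer")
        with pytest.raises(ValueError):
            LatticeConstruct(21, (8, 10), "dimer")
        c = LatticeConstruct(21, (8, 9), "dimer", "21T8,9")
        assert c.probe_midpoint == 8.5

    def test_interfaces_bounded(self):
        for c in enumerate_configurations(21, 7):
            if c.m >= 1:
                assert c.j <= c.m - 1
            else:
                assert c.j == 0
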