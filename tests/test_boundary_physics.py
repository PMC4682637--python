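"""Binding equilibria, boundary-zone solution and permeability calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatrans.boundary_physics import (
    CompartmentSpec,
    alpha_ratio,
    aqueous_permeability,
    boundary_bvp_oracle,
    boundary_permeability,
    boundary_profiles,
    boundary_shift,
    compartment_storage,
    decay_length,
    equilibrium_free_fa,
    membrane_permeability,
    membrane_storage,
    series_permeability,
)

CAP_LIKE = CompartmentSpec("cap", D_Fa=4.8e-10, D_Cp=9.35e-11, K_CpFa=9e-6,
                           tau_CpFa=0.01, Cp_total=2.1, volume_fraction=0.094)
IS1_LIKE = CompartmentSpec("is1", D_Fa=4.8e-10, D_Cp=9.35e-11, K_CpFa=9e-6,
                           tau_CpFa=0.01, Cp_total=1.806, volume_fraction=0.019,
                           h_diff=160e-9)
MYO_LIKE = CompartmentSpec("myo", D_Fa=4.8e-10, D_Cp=1.87e-10, K_CpFa=9e-6,
                           tau_CpFa=0.01, Cp_total=0.170, volume_fraction=0.731)
EC_LIKE = CompartmentSpec("ec", D_Fa=4.8e-10, D_Cp=1.87e-10, K_CpFa=9e-6,
                          tau_CpFa=0.01, Cp_total=0.007, volume_fraction=0.018,
                          h_diff=187e-9)


class TestBindingEquilibrium:
    def test_no_ligand(self):
        s = equilibrium_free_fa(2.1, 0.0, 9e-6)
        assert s.Fa_free == 0.0 and s.CpFa == 0.0 and s.Cp_free == 2.1

    def test_physiological_bound_to_free_ratio_exceeds_1e5(self):
        # plasma albumin 0.7 mmol/l (2.1 binding sites), total Fa 0.35
        s = equilibrium_free_fa(2.1, 0.35, 9e-6)
        assert s.Fa_free == pytest.approx(1.8e-6, rel=1e-3)
        assert s.CpFa == pytest.approx(0.35, rel=1e-4)
        assert s.Fa_total / s.Fa_free > 1e5

    def test_weak_binding_limit(self):
        s = equilibrium_free_fa(1.0, 0.5, 1e6)
        assert s.Fa_free == pytest.approx(0.5, rel=1e-5)
        assert s.CpFa < 1e-6

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_free_fa(-1.0, 0.1, 9e-6)
        with pytest.raises(ValueError):
            equilibrium_free_fa(1.0, 0.1, 0.0)

    @settings(max_examples=300, derandomize=True)
    @given(
        Cp=st.floats(1e-4, 10.0),
        Fa=st.floats(0.0, 10.0),
        K=st.floats(1e-8, 1e-2),
    )
    def test_mass_balance_closes(self, Cp, Fa, K):
        s = equilibrium_free_fa(Cp, Fa, K)
        assert s.Fa_free >= 0 and s.Cp_free >= 0 and s.CpFa >= 0
        assert s.Fa_total == pytest.approx(Fa, rel=1e-10, abs=1e-300)
        assert s.Cp_total == pytest.approx(Cp, rel=1e-10)
        assert s.Fa_free * s.Cp_free == pytest.approx(K * s.CpFa, rel=1e-8, abs=1e-250)


class TestDecayLengthAndAlpha:
    def test_decay_length_arithmetic(self):
        # sqrt(4.8e-10 * 9e-6 * 0.1 / 2.1)
        assert decay_length(4.8e-10, 9e-6, 0.1, 2.1) == pytest.approx(1.434e-8, rel=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_decay_scaling_laws(self, scale):
        base = decay_length(4.8e-10, 9e-6, 0.1, 2.1)
        assert decay_length(4.8e-10, 9e-6, 0.4, 2.1) == pytest.approx(2 * base, rel=1e-12)
        assert decay_length(4.8e-10, 9e-6, 0.1, 2.1 * scale) == pytest.approx(
            base / math.sqrt(scale), rel=1e-12
        )

    def test_decay_vanishes_at_high_carrier(self):
        assert decay_length(4.8e-10, 9e-6, 0.1, 1e12) < 1e-13

    def test_alpha_arithmetic_and_bound(self):
        a = alpha_ratio(4.8e-10, 9e-6, 2.1, 9.35e-11, 2.1)
        assert a == pytest.approx(2.20e-5, rel=1e-3)
        assert a < 0.002  # carrier-mediated diffusion dominates in plasma

    def test_alpha_scaling_and_degenerate(self):
        a = alpha_ratio(4.8e-10, 9e-6, 2.1, 9.35e-11, 1.0)
        assert alpha_ratio(4.8e-10, 9e-6, 2.1, 9.35e-11, 2.0) == pytest.approx(a / 4, rel=1e-12)
        assert alpha_ratio(0.0, 9e-6, 2.1, 9.35e-11, 2.1) == 0.0


class TestBoundaryShift:
    def test_detach_only_is_zero(self):
        assert boundary_shift(1.3e-8, 0.0) == 0.0

    def test_arithmetic(self):
        assert boundary_shift(1.15e-8, 5e-9) == pytest.approx(-4.15e-9, rel=1e-3)

    def test_small_d_cp_first_order(self):
        d_Cp = 1e-12
        assert boundary_shift(1.3e-8, d_Cp) == pytest.approx(-d_Cp, rel=1e-4)


class TestPermeabilities:
    def test_boundary_permeability_pure_detach_limit(self):
        spec = CAP_LIKE
        d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, 2.1)
        p = boundary_permeability(spec, 2.1, d_Cp=0.0, h=100 * d)
        assert p == pytest.approx(spec.D_Fa / d, rel=1e-3)

    def test_boundary_permeability_myo_value(self):
        # approximate form at d_Fa = 14.9e-9, d_Cp = 5e-9 is ~0.043 m/s,
        # within ~2% of the tabulated sarcolemma-face value 0.0424
        d = 1.49e-8
        Cp0 = MYO_LIKE.D_Fa * MYO_LIKE.K_CpFa * MYO_LIKE.tau_CpFa / d**2
        p = boundary_permeability(MYO_LIKE, Cp0, d_Cp=5e-9, h=1e-6, approximate=True)
        assert p == pytest.approx(0.0430, rel=2e-3)
        assert p == pytest.approx(0.0424, rel=0.02)

    def test_boundary_permeability_monotone_in_d_cp(self):
        p1 = boundary_permeability(CAP_LIKE, 2.1, d_Cp=5e-9, h=1e-6)
        p2 = boundary_permeability(CAP_LIKE, 2.1, d_Cp=10e-9, h=1e-6)
        assert p2 > p1 > boundary_permeability(CAP_LIKE, 2.1, d_Cp=0.0, h=1e-6)

    def test_full_form_vs_approximate(self):
        for spec, Cp0 in ((CAP_LIKE, 1.9), (EC_LIKE, 0.0069), (MYO_LIKE, 0.169)):
            h = 187e-9
            full = boundary_permeability(spec, Cp0, 5e-9, h)
            approx = boundary_permeability(spec, Cp0, 5e-9, h, approximate=True)
            d = decay_length(spec.D_Fa, spec.K_CpFa, spec.tau_CpFa, Cp0)
            assert full >= approx * (1 - math.exp(-h / d)) * (1 - 1e-12)

    def test_aqueous_permeability(self):
        p = aqueous_permeability(1.6e-7, 4.8e-10, 9.35e-11, 9e-6, 0.284, 0.284)
        assert p == pytest.approx(18.443, rel=1e-3)  # (D_Fa + D_Cp*Cp0/K)/h
        assert aqueous_permeability(0.8e-7, 4.8e-10, 9.35e-11, 9e-6, 0.284, 0.284) == pytest.approx(2 * p, rel=1e-12)
        assert aqueous_permeability(1e-7, 4.8e-10, 9.35e-11, 9e-6, 0.0, 1.0) == pytest.approx(4.8e-3, rel=1e-12)

    @pytest.mark.parametrize(
        "C_lipid,D,h,expected",
        [(9e5, 5e-10, 5e-9, 9e4), (1.0, 5e-10, 5e-9, 0.1), (8e5, 4e-12, 5e-9, 640.0)],
    )
    def test_membrane_permeability(self, C_lipid, D, h, expected):
        assert membrane_permeability(C_lipid, D, h) == pytest.approx(expected, rel=1e-12)

    def test_series_permeability_composite(self):
        # capillary-endothelium composite from the tabulated face values
        assert series_permeability([0.0655, 0.0060, 700]) == pytest.approx(0.0055, abs=5e-5)

    @settings(max_examples=100, derandomize=True)
    @given(ps=st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=6))
    def test_series_permeability_properties(self, ps):
        total = series_permeability(ps)
        assert total <= min(ps) * (1 + 1e-12)
        assert series_permeability(list(reversed(ps))) == pytest.approx(total, rel=1e-12)

    def test_series_identity_and_pair(self):
        assert series_permeability([0.3]) == pytest.approx(0.3)
        assert series_permeability([0.3, 0.3]) == pytest.approx(0.15)
        assert series_permeability([0.3, 1e30]) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            series_permeability([])
        with pytest.raises(ValueError):
            series_permeability([0.1, 0.0])


class TestStorageCapacity:
    def test_compartment_storage(self):
        assert compartment_storage(0.0, 9e-6, 0.7) == 0.0
        assert compartment_storage(0.170, 9e-6, 0.731) == pytest.approx(13807, rel=1e-3)
        assert compartment_storage(0.170, 1e12, 0.731) < 1e-10

    @pytest.mark.parametrize(
        "S,expected,printed",
        [(75200, 300.8, 300), (82200, 328.8, 328), (89100, 356.4, 356)],
    )
    def test_membrane_storage_matches_printed(self, S, expected, printed):
        v = membrane_storage(8e5, S, 5e-9)
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(printed, rel=0.01)

    def test_membrane_storage_zero_area(self):
        assert membrane_storage(8e5, 0.0, 5e-9) == 0.0


class TestBoundaryProfiles:
    def test_zero_flux_is_equilibrium(self):
        x = -np.linspace(0, 3e-7, 50)[::-1]
        prof = boundary_profiles(CAP_LIKE, 1.9, 0.0, x)
        fa_eq = CAP_LIKE.K_CpFa * (CAP_LIKE.Cp_total / 1.9 - 1.0)
        assert np.allclose(prof.Fa, fa_eq)
        assert np.allclose(prof.CpFa, CAP_LIKE.Cp_total - 1.9)
        assert np.allclose(prof.phi_CpFa, 0.0) and np.allclose(prof.phi_Fa, 0.0)

    def test_far_field_flux_is_carrier_mediated(self):
        prof = boundary_profiles(CAP_LIKE, 1.9, 1e-9, np.array([-1e-5]))
        assert prof.phi_CpFa[0] / 1e-9 == pytest.approx(1.0 / (1.0 + prof.alpha), rel=1e-12)

    def test_flux_symmetry(self):
        x = -np.linspace(0, 2e-7, 40)[::-1]
        fwd = boundary_profiles(CAP_LIKE, 1.9, 1e-9, x, d_Cp=5e-9)
        bwd = boundary_profiles(CAP_LIKE, 1.9, -1e-9, x, d_Cp=5e-9)
        fa_eq = CAP_LIKE.K_CpFa * (CAP_LIKE.Cp_total / 1.9 - 1.0)
        assert np.allclose(fwd.phi_CpFa, -bwd.phi_CpFa)
        assert np.allclose(fwd.Fa - fa_eq, -(bwd.Fa - fa_eq))
        assert fwd.d_Fa == bwd.d_Fa and fwd.x_b == bwd.x_b

    def test_positive_x_rejected(self):
        with pytest.raises(ValueError):
            boundary_profiles(CAP_LIKE, 1.9, 0.0, np.array([1e-9]))


class TestBvpOracle:
    def test_zero_flux_equilibrium_everywhere(self):
        orc = boundary_bvp_oracle(CAP_LIKE, 1.9, 0.0, n_nodes=300)
        fa_eq = CAP_LIKE.K_CpFa * (CAP_LIKE.Cp_total / 1.9 - 1.0)
        assert np.allclose(orc.Fa, fa_eq, rtol=1e-10)
        # flux scale of the problem is ~D_Cp * CpFa / d_Fa ~ 4e-3; anything
        # below 1e-14 is zero to machine precision
        assert np.abs(orc.phi_CpFa).max() < 1e-14

    def test_detach_only_complex_flux_vanishes_at_membrane(self):
        orc = boundary_bvp_oracle(CAP_LIKE, 1.9, 1e-9, d_Cp=0.0, n_nodes=1200)
        assert abs(orc.phi_CpFa[-1]) / 1e-9 < 1e-3

    @pytest.mark.parametrize(
        "spec,Cp0",
        [(CAP_LIKE, 1.9), (IS1_LIKE, 1.6), (MYO_LIKE, 0.169)],
        ids=["cap", "is1", "myo"],
    )
    def test_oracle_matches_analytic_profiles(self, spec, Cp0):
        """Flux partition and boundary permeability to 0.1% where alpha << 1."""
        flux = 1e-10
        d_Cp = 5e-9
        orc = boundary_bvp_oracle(spec, Cp0, flux, d_Cp=d_Cp, n_nodes=2000)
        ana = boundary_profiles(spec, Cp0, flux, orc.x + orc.x_b, d_Cp=d_Cp)
        assert np.max(np.abs(orc.phi_CpFa - ana.phi_CpFa)) / flux < 1e-3
        # gauge-free P_b: flux over (bulk ramp extrapolated to membrane - Fa there)
        m = orc.x < -10 * orc.d_Fa
        ramp = np.polyfit(orc.x[m], orc.Fa[m], 1)
        Pb_oracle = flux / (np.polyval(ramp, 0.0) - orc.Fa[-1])
        Pb_analytic = (1 + ana.alpha) * (spec.D_Fa / ana.d_Fa) * (1 + d_Cp / ana.d_Fa)
        assert Pb_oracle == pytest.approx(Pb_analytic, rel=1e-3)

    def test_oracle_ec_like_within_alpha_order(self):
        """The analytic solution is first order in alpha; ec has alpha~3e-3."""
        flux = 1e-12
        orc = boundary_bvp_oracle(EC_LIKE, 0.0069, flux, d_Cp=5e-9, n_nodes=2000)
        ana = boundary_profiles(EC_LIKE, 0.0069, flux, orc.x + orc.x_b, d_Cp=5e-9)
        assert np.max(np.abs(orc.phi_CpFa - ana.phi_CpFa)) / flux < 5 * ana.alpha

    def test_linearity_of_small_flux_regime(self):
        o1 = boundary_bvp_oracle(CAP_LIKE, 1.9, 1e-10, d_Cp=5e-9, n_nodes=800)
        o2 = boundary_bvp_oracle(CAP_LIKE, 1.9, 2e-10, d_Cp=5e-9, n_nodes=800)
        fa_eq = CAP_LIKE.K_CpFa * (CAP_LIKE.Cp_total / 1.9 - 1.0)
        assert np.allclose(o2.Fa - fa_eq, 2 * (o1.Fa - fa_eq), rtol=1e-4)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            boundary_bvp_oracle(CAP_LIKE, 1.9, 0.0, n_nodes=50)
        with pytest.raises(ValueError):
            boundary_bvp_oracle(CAP_LIKE, 1.9, 0.0, h=1e-12)
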