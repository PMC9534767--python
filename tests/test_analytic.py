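"""Deterministic density equations: conservation laws and closed forms."""

import numpy as np
import pytest

from ecdna_dyn.analytic import (
    DensityState,
    delta_density,
    density_rhs,
    integrate_density,
    moment_scaling_check,
    neutral_fraction_positive,
    selection_m1,
    selection_m2,
    two_population_selection,
)
from ecdna_dyn.errors import ParameterError


class TestNeutralFractionPositive:
    def test_closed_form_values(self):
        assert neutral_fraction_positive(0.0) == 1.0
        assert neutral_fraction_positive(2.0) == 0.5
        t = 1e8
        assert t * neutral_fraction_positive(t) == pytest.approx(2.0, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            neutral_fraction_positive(-0.1)


class TestDensityRhs:
    def test_absorbing_ecdna_free_state(self):
        state = delta_density(0, 32)
        for s in (1.0, 2.0):
            assert np.allclose(density_rhs(state, s), 0.0, atol=1e-14)

    def test_single_copy_inflow_to_zero_class(self):
        """From delta_1, cells lose all copies at rate 2 * C(2,0) / 4 = 1/2."""
        rhs = density_rhs(delta_density(1, 32), 1.0)
        assert rhs[0] == pytest.approx(0.5)

    def test_density_conservation_neutral(self, rng):
        # support kept well inside the truncation so no kernel mass escapes
        rho = np.zeros(65)
        rho[:20] = rng.random(20)
        rho /= rho.sum()
        rhs = density_rhs(DensityState(0.0, rho), 1.0)
        assert abs(rhs.sum()) < 1e-10

    def test_density_conservation_under_selection(self, rng):
        """The bilinear selection terms must also sum to zero."""
        rho = np.zeros(65)
        rho[:20] = rng.random(20)
        rho /= rho.sum()
        for s in (0.5, 1.5, 3.0):
            rhs = density_rhs(DensityState(0.0, rho), s)
            assert abs(rhs.sum()) < 1e-10


class TestIntegrateDensity:
    def test_neutral_first_moment_conserved(self):
        res = integrate_density(delta_density(1, 512), s=1.0, t_max=10.0, k_max=512)
        assert np.all(np.abs(res.moment(1) - 1.0) < 1e-6)
        assert np.abs(res.rhos.sum(axis=1) - 1.0).max() < 1e-8

    def test_neutral_second_moment_linear(self):
        res = integrate_density(delta_density(1, 512), s=1.0, t_max=10.0, k_max=512)
        m2 = res.moment(2)
        growth = m2 - m2[0]
        late = res.times >= 1.0
        assert np.all(np.abs(growth[late] - res.times[late]) / res.times[late] < 0.01)

    def test_selection_first_moment_self_consistency(self):
        res = integrate_density(
            delta_density(1, 512), s=1.5, t_max=8.0, k_max=512,
            t_eval=np.linspace(0, 8, 801),
        )
        closed = selection_m1(1.5, res.times, res.rho0)
        assert np.max(np.abs(closed / res.moment(1) - 1.0)) < 1e-4

    def test_non_normalized_initial_rejected(self):
        rho = np.zeros(33)
        rho[1] = 0.7
        with pytest.raises(ParameterError):
            integrate_density(DensityState(0.0, rho), s=1.0, t_max=1.0, k_max=32)

    def test_fraction_positive_decays_like_one_over_t(self):
        """log f+ vs log t slope in [10, 50] should be close to -1."""
        res = integrate_density(
            delta_density(1, 512), s=1.0, t_max=50.0, k_max=512,
            t_eval=np.linspace(0.0, 50.0, 201),
        )
        mask = res.times >= 10.0
        slope = np.polyfit(np.log(res.times[mask]), np.log(res.frac_pos[mask]), 1)[0]
        assert -1.15 <= slope <= -0.85


class TestSelectionMoments:
    def test_neutral_m1_is_flat(self):
        t = np.linspace(0, 5, 50)
        assert np.allclose(selection_m1(1.0, t, np.full(50, 0.3)), 1.0)

    def test_saturated_rho0_gives_exponential(self):
        t = np.linspace(0, 3, 301)
        m1 = selection_m1(2.0, t, np.ones_like(t))
        assert np.allclose(m1, np.exp(t), rtol=1e-6)

    def test_m1_input_validation(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ParameterError):
            selection_m1(1.5, t, np.array([0.1, 0.2, 1.4, 0.2, 0.1]))

    def test_m2_closed_form(self):
        t = np.linspace(0, 10, 11)
        m2 = selection_m2(np.ones_like(t), t)
        assert np.allclose(m2, t)
        assert m2[0] == 0.0

    def test_m2_variants_agree_at_neutrality(self):
        t = np.linspace(0, 5, 501)
        rho0 = 1.0 - neutral_fraction_positive(t)
        m1 = np.ones_like(t)
        closed = selection_m2(m1, t)
        general = selection_m2(m1, t, variant="general", rho0_path=rho0, s=1.0)
        assert np.allclose(closed, general, atol=1e-8)

    def test_m2_variants_deviation_under_selection_documented(self):
        """The s-weighted moment hierarchy deviates from the printed closed
        form by a bounded relative amount; record, do not assert a value."""
        s = 1.2
        res = integrate_density(
            delta_density(1, 512), s=s, t_max=10.0, k_max=512,
            t_eval=np.linspace(0, 10, 1001),
        )
        m1 = res.moment(1)
        closed = selection_m2(m1, res.times)
        general = selection_m2(m1, res.times, variant="general",
                               rho0_path=res.rho0, s=s)
        late = res.times >= 2.0
        rel = np.abs(general[late] / closed[late] - 1.0)
        assert np.all(np.isfinite(rel))  # documented comparison only


class TestTwoPopulationSelection:
    def test_pure_exponential_when_no_negative_compartment(self):
        t = np.linspace(0, 3, 31)
        states = two_population_selection(2.0, 3.0, f_minus_path=(t, np.zeros_like(t)))
        n_plus = np.array([st.n_plus for st in states])
        assert np.allclose(n_plus, np.exp(2.0 * t), rtol=1e-9)
        assert states[0].n_plus == pytest.approx(1.0)

    def test_fraction_approaches_one_under_positive_selection(self):
        """From a mostly ecDNA-free start, s=2 drives f+ monotonically up."""
        rho = np.zeros(513)
        rho[0] = 0.85
        rho[1] = 0.15
        res = integrate_density(DensityState(0.0, rho), s=2.0, t_max=40.0, k_max=512)
        f_plus = res.frac_pos
        assert f_plus[-1] > 0.97
        # monotone after the short induction transient in which single-copy
        # cells still lose their whole complement to one daughter
        late = res.times >= 1.0
        assert np.all(np.diff(f_plus[late]) > -1e-9)

    def test_neutral_branch_rejected(self):
        with pytest.raises(ParameterError):
            two_population_selection(1.0, 5.0)


class TestMomentScaling:
    @pytest.mark.parametrize("l,expected", [(2, 1.0), (3, 2.0)])
    def test_neutral_moment_scaling_exponents(self, l, expected):
        res = integrate_density(
            delta_density(1, 512), s=1.0, t_max=50.0, k_max=512,
            t_eval=np.linspace(0.0, 50.0, 201),
        )
        slope = moment_scaling_check(res.times, res.moment(l))
        assert abs(slope - expected) / expected < 0.10

    def test_constant_series_slope_zero(self):
        t = np.linspace(0.1, 20, 100)
        assert moment_scaling_check(t, np.full(100, 3.0)) == 0.0

    def test_insufficient_range_rejected(self):
        with pytest.raises(ParameterError):
            moment_scaling_check(np.linspace(1, 5, 10), np.linspace(1, 5, 10))
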