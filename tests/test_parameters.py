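import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conesens.parameters import (
    DarkStateExistenceError,
    DomainError,
    ParameterSet,
    beta_dark_from_activity,
    chi_existence_root,
    cyclase_bounds_estimate,
    eta_factor,
    gsa_ranges,
    k_hyd_dark,
    k_hyd_light,
    mcmc_hard_constraints,
    mcmc_soft_ranges,
    mouse_cone_printed_dark_values,
    nu_GE_of,
    parameter_set_from_draw,
    resolve_alpha_min,
    surface_density_from_volumic,
)


class TestEtaFactor:
    def test_published_geometry_gives_5p5_nm(self):
        assert eta_factor(0.66, 16.8) == pytest.approx(5.5, abs=0.05)

    def test_direct_arithmetic(self):
        assert eta_factor(0.65, 16.8) == pytest.approx(5.46)

    @pytest.mark.parametrize("nu,eps0", [(0.0, 16.8), (0.65, 0.0), (-1.0, 16.8)])
    def test_degenerate_geometry_rejected(self, nu, eps0):
        with pytest.raises(DomainError):
            eta_factor(nu, eps0)

    @given(st.floats(0.1, 10), st.floats(0.1, 100), st.floats(0.5, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_each_argument(self, nu, eps0, c):
        assert eta_factor(c * nu, eps0) == pytest.approx(c * eta_factor(nu, eps0))
        assert eta_factor(nu, c * eps0) == pytest.approx(c * eta_factor(nu, eps0))


class TestSurfaceDensity:
    @pytest.mark.parametrize(
        "c_vol,expected",
        [(210, 700), (15, 50), (3000, 10000)],
        ids=["transducin", "PDE", "rhodopsin"],
    )
    def test_tabulated_membrane_densities(self, c_vol, expected):
        # volumic concentrations → surface densities at η = 5.5 nm, ~1 s.f.
        got = surface_density_from_volumic(c_vol, 5.5)
        assert got == pytest.approx(expected, rel=0.05)

    @given(st.floats(0.1, 1e4), st.floats(0.5, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_concentration(self, c, k):
        assert surface_density_from_volumic(k * c, 5.5) == pytest.approx(
            k * surface_density_from_volumic(c, 5.5)
        )


class TestHydrolysisRates:
    def test_light_rate_best_fit(self):
        assert k_hyd_light(540, 1.8) == pytest.approx(0.50, abs=0.005)

    def test_unit_conversion_identity(self):
        assert k_hyd_light(602.214, 1.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert k_hyd_light(500, 1.0) == pytest.approx(0.830, abs=5e-4)

    def test_dark_rate_best_fit(self):
        assert k_hyd_dark(8.57, 5.46, 115) == pytest.approx(4.1e-4, rel=0.02)

    def test_dark_rate_zero_turnover(self):
        assert k_hyd_dark(0.0, 5.5, 50) == 0.0

    def test_dark_rate_hand_arithmetic(self):
        assert k_hyd_dark(54, 5.5, 50) == pytest.approx(5.94e-3)

    @given(st.floats(0.1, 1000), st.floats(1, 10), st.floats(10, 500))
    @settings(max_examples=50, derandomize=True)
    def test_dark_rate_roundtrip_recovers_beta(self, beta, eta, pde):
        k = k_hyd_dark(beta, eta, pde)
        assert k * pde / (eta * 1e-3) == pytest.approx(beta, rel=1e-12)

    def test_zero_buffering_rejected(self):
        with pytest.raises(DomainError):
            k_hyd_light(540, 0.0)


class TestCouplingAndActivity:
    def test_nu_GE_best_fit(self):
        assert nu_GE_of(0.33, 115) == pytest.approx(37.95)

    @pytest.mark.parametrize("k_GE,pde,expected", [(0.0, 115, 0.0), (0.1, 50, 5.0)])
    def test_nu_GE_arithmetic(self, k_GE, pde, expected):
        assert nu_GE_of(k_GE, pde) == pytest.approx(expected)

    @pytest.mark.parametrize("frac,expected", [(0.003, 54), (0.047, 846), (0.0, 0.0)])
    def test_dark_turnover_from_spontaneous_activity(self, frac, expected):
        assert beta_dark_from_activity(frac, 18, 3000, 3) == pytest.approx(expected)

    def test_cyclase_ratio_near_two(self):
        amin, amax, ratio = cyclase_bounds_estimate(39, 1.7, 33, 5.7)
        assert amax == pytest.approx(254.4)
        assert round(ratio) == 2

    def test_no_gcap_effect_means_unit_ratio(self):
        _, _, ratio = cyclase_bounds_estimate(39, 1.7, 33, 1.7)
        assert ratio == pytest.approx(1.0)


class TestAlphaMinResolution:
    def test_existence_root_best_fit(self, table10):
        chi = chi_existence_root(8.57, 14.2, 2.9, 8.79, 3138, 0.26)
        assert chi == pytest.approx(32.6, abs=0.1)
        # the root satisfies the existence equality
        lhs = 1.0 + (chi / (8.57 * 14.2)) ** 2.9
        assert lhs == pytest.approx(1.0 / (1.0 - 2 * 8.79 / (3138 * 0.26)), rel=1e-9)
        assert lhs == pytest.approx(1.02202, abs=1e-5)
        d = resolve_alpha_min(table10)
        assert d.xi == pytest.approx(chi)  # chi < alpha_max = 55.8

    def test_a_min_zero_gives_zero_alpha_min(self, table10):
        p = table10.replace(a_min=0.0)
        assert resolve_alpha_min(p).alpha_min == 0.0

    def test_zero_exchanger_collapses_interval(self, table10):
        p = table10.replace(Jex_sat=1e-300, a_min=0.5)
        d = resolve_alpha_min(p)
        assert d.chi == pytest.approx(0.0, abs=1e-6)
        assert d.alpha_min == pytest.approx(0.0, abs=1e-6)

    def test_impossible_current_balance_raises_with_ratio(self, table10):
        p = table10.replace(Jex_sat=3138 * 0.26)  # 2·Jex ≥ JcG_max·f_Ca
        with pytest.raises(DarkStateExistenceError) as exc:
            resolve_alpha_min(p)
        assert exc.value.ratio >= 1.0

    def test_existence_inequality_holds_under_a_min_sampler(self, gsa_draws):
        """Plugging α_min = a_min·ξ back into the existence inequality must
        satisfy it strictly for every draw with a_min < 1 (10^4 draws)."""
        r, cols = gsa_draws
        q = 2 * cols["Jex_sat"] / (cols["JcG_max"] * cols["f_Ca"])
        assert (q < 1).all()
        rhs = 1.0 / (1.0 - q)
        chi = cols["beta_dark"] * cols["K_cG"] * (rhs - 1.0) ** (1.0 / cols["m_cG"])
        alpha_min = cols["a_min"] * np.minimum(cols["alpha_max"], chi)
        lhs = 1.0 + (alpha_min / (cols["beta_dark"] * cols["K_cG"])) ** cols["m_cG"]
        strict = cols["a_min"] < 1.0
        assert (lhs[strict] < rhs[strict]).all()


class TestParameterSetContracts:
    def test_requires_exactly_one_alpha_min_spec(self, table10):
        d = table10.to_dict()
        d["a_min"] = 0.3
        with pytest.raises(DomainError):
            ParameterSet(**d)
        d["a_min"] = None
        d["alpha_min"] = None
        with pytest.raises(DomainError):
            ParameterSet(**d)

    @pytest.mark.parametrize(
        "field,value", [("f_Ca", 1.5), ("m_cG", 0.5), ("R_t", 0.9), ("beta_dark", -1.0)]
    )
    def test_invariant_violations_rejected(self, table10, field, value):
        with pytest.raises(DomainError):
            table10.replace(**{field: value})

    def test_alpha_ratio_accepted_at_input(self, table10):
        p = parameter_set_from_draw({"alpha_ratio": 5.51, "alpha_max": 55.8})
        assert p.alpha_min == pytest.approx(55.8 / 5.51)
        assert not p.a_min_authoritative

    def test_best_fit_a_min_position(self, table10):
        # α_min = 55.8/5.51 sits at relative position ~0.31 of [0, ξ]
        d = resolve_alpha_min(table10)
        assert 0.0 < d.a_min < 1.0
        assert d.alpha_min == pytest.approx(10.13, abs=0.01)


class TestPackagedTables:
    def test_fixture_shapes(self):
        assert len(gsa_ranges()) == 32
        assert len(mcmc_hard_constraints()) == 11
        assert len(mcmc_soft_ranges()) == 24

    def test_spot_values(self):
        g = gsa_ranges()
        assert (g["beta_dark"].lo, g["beta_dark"].hi) == (1.0, 1000.0)
        assert (g["a_min"].lo, g["a_min"].hi) == (0.0, 1.0)
        h = mcmc_hard_constraints()
        assert (h["J_dark"].lo, h["J_dark"].hi) == (25.75, 27.0)
        s = mcmc_soft_ranges()
        assert (s["m_cG"].lo, s["m_cG"].hi) == (2.5, 3.5)

    def test_printed_dark_values_carried_separately(self):
        printed = mouse_cone_printed_dark_values()
        assert printed == {"cG_dark": 2.65, "Ca_dark": 0.204, "J_dark": 26.1}

    def test_ranges_csv_roundtrip(self, tmp_path):
        g = gsa_ranges()
        path = tmp_path / "ranges.csv"
        g.to_csv(path)
        from conesens.parameters import ParameterRanges

        g2 = ParameterRanges.from_csv(path)
        assert g2.names == g.names
        assert all(g2[n].lo == g[n].lo and g2[n].hi == g[n].hi for n in g.names)
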