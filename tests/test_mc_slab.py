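"""Layered-slab Monte Carlo engine: analytic limits, conservation, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinoptics.mc_slab import Layer, SlabStack, glass_mounted_stack, simulate_slab
from skinoptics.optics_core import OpticalProperties
from skinoptics.reference import reference_slab


def single_layer(mu_a, mu_s, g=0.9, n=1.0, d=1.0):
    return SlabStack(layers=(Layer("t", OpticalProperties(mu_a, mu_s, g, n), d),))


class TestAnalyticLimits:
    def test_beer_lambert_transmittance(self):
        """Matched-index absorber without scattering: Tt = exp(-mu_a d)."""
        res = simulate_slab(single_layer(1.0, 0.0, g=0.0), 200_000, seed=11)
        expected = np.exp(-1.0)
        se = np.sqrt(expected * (1 - expected) / res.n_photons)
        assert res.rd == 0.0
        assert res.rs == 0.0
        assert abs(res.tt - expected) < 3 * se

    def test_no_absorption_everything_escapes(self):
        res = simulate_slab(single_layer(0.0, 10.0), 50_000, seed=12)
        assert res.a == pytest.approx(0.0, abs=1e-12)
        assert res.rd + res.tt == pytest.approx(1.0, abs=1e-9)

    def test_specular_two_interface_formula_for_glass_mount(self):
        """Glass-topped stack: Rs follows the two-interface Fresnel chain."""
        p = OpticalProperties.from_reduced(0.07, 3.06, 0.9, 1.39)
        res = simulate_slab(glass_mounted_stack(p, 1.5), 1_000, seed=1)
        r1 = ((1.0 - 1.52) / (1.0 + 1.52)) ** 2
        r2 = ((1.52 - 1.39) / (1.52 + 1.39)) ** 2
        assert res.rs == pytest.approx(r1 + (1 - r1) ** 2 * r2 / (1 - r1 * r2))

    def test_deep_absorption_slope_matches_diffusion_mueff(self):
        """Scattering-dominated slab decays as exp(-mu_eff z) at depth."""
        p = OpticalProperties.from_reduced(0.05, 1.34, 0.9, 1.0)
        stack = SlabStack(layers=(Layer("t", p, 6.0),))
        res = simulate_slab(stack, 300_000, seed=3, nz_bins=120)
        z = (np.arange(120) + 0.5) * 0.05
        sel = (z > 1.0) & (z < 3.0)
        slope = np.polyfit(z[sel], np.log(res.absorbed_z[sel]), 1)[0]
        mu_eff = np.sqrt(3 * 0.05 * (0.05 + 1.34))
        assert slope == pytest.approx(-mu_eff, rel=0.05)


class TestConservationAndDeterminism:
    @given(
        mu_a=st.floats(0.01, 5.0),
        mu_sp=st.floats(0.1, 10.0),
        g=st.floats(0.0, 0.95),
        n=st.floats(1.0, 1.6),
        d=st.floats(0.2, 3.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_energy_ledger_exact(self, mu_a, mu_sp, g, n, d):
        """Rs + Rd + Tt + A = 1 to 1e-9 for arbitrary single-layer slabs."""
        stack = single_layer(mu_a, mu_sp / (1 - g) if g < 1 else mu_sp, g=g, n=n, d=d)
        res = simulate_slab(stack, 5_000, seed=99)
        assert res.rd + res.rs + res.tt + res.a == pytest.approx(1.0, abs=1e-9)

    def test_fixed_seed_bit_identical(self, dermis_632):
        stack = glass_mounted_stack(dermis_632, 1.5)
        r1 = simulate_slab(stack, 20_000, seed=5)
        r2 = simulate_slab(stack, 20_000, seed=5)
        assert (r1.rd, r1.tt, r1.a) == (r2.rd, r2.tt, r2.a)
        r3 = simulate_slab(stack, 20_000, seed=6)
        assert (r3.rd, r3.tt) != (r1.rd, r1.tt)

    def test_symmetric_stack_reversal_statistically_unchanged(self):
        """Reversing layer order of a symmetric stack leaves Rd/Tt unchanged."""
        a = Layer("a", OpticalProperties(0.05, 20.0, 0.9, 1.4), 0.5)
        b = Layer("b", OpticalProperties(0.2, 10.0, 0.8, 1.37), 0.7)
        fwd = SlabStack(layers=(a, b, a))
        rev = SlabStack(layers=tuple(reversed(fwd.layers)))
        r_f = simulate_slab(fwd, 150_000, seed=21)
        r_r = simulate_slab(rev, 150_000, seed=22)
        assert abs(r_f.rd - r_r.rd) < 4 * np.hypot(r_f.se_rd, r_r.se_rd)
        assert abs(r_f.tt - r_r.tt) < 4 * np.hypot(r_f.se_tt, r_r.se_tt)


class TestValidation:
    def test_rejects_nonpositive_photons(self, dermis_632):
        with pytest.raises(ValueError):
            simulate_slab(glass_mounted_stack(dermis_632, 1.5), 0, seed=1)

    def test_rejects_empty_stack(self):
        with pytest.raises(ValueError):
            SlabStack(layers=())

    def test_rejects_nonpositive_thickness(self, dermis_632):
        with pytest.raises(ValueError):
            Layer("t", dermis_632, 0.0)


class TestReferenceCrossCheck:
    def test_engine_matches_scalar_reference_glass_mounted(self):
        """Optimized engine vs independently coded scalar MC, 632-nm dermis."""
        p = OpticalProperties.from_reduced(0.07, 3.06, 0.9, 1.39)
        eng = simulate_slab(glass_mounted_stack(p, 1.5), 200_000, seed=11)
        ref = reference_slab(
            [(0.0, 0.0, 0.0, 1.52, 1.0), (0.07, 30.6, 0.9, 1.39, 1.5),
             (0.0, 0.0, 0.0, 1.52, 1.0)],
            10_000, seed=42,
        )
        assert abs(eng.rd - ref["rd"]) < 3 * np.hypot(eng.se_rd, ref["se_rd"])
        assert abs(eng.tt - ref["tt"]) < 3 * np.hypot(eng.se_tt, ref["se_tt"])
        assert eng.rs == pytest.approx(ref["rs"], rel=1e-12)
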