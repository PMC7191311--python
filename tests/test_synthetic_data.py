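"""Synthetic chromophore spectra and noisy Rd/Tt measurement generation."""

import numpy as np
import pytest

from skinoptics.mc_slab import glass_mounted_stack, simulate_slab
from skinoptics.imc_fit import derive_seed
from skinoptics.optics_core import TABLE_WAVELENGTHS_NM
from skinoptics.synthetic_data import (
    ChromophoreModel,
    NoiseModel,
    PRESETS,
    make_tissue_spectrum,
    synth_measurement,
)


class TestChromophoreModel:
    def test_zero_chromophores_flat_baseline(self, tables):
        _, blood, _ = tables
        model = ChromophoreModel(baseline_mu_a=0.05)
        props = make_tissue_spectrum(model, np.array([450.0, 700.0, 1050.0]), blood)
        assert [p.mu_a for p in props] == pytest.approx([0.05] * 3)

    def test_musp_strictly_decreasing_for_positive_mie_exponent(self, tables):
        _, blood, _ = tables
        wl = np.linspace(400, 1100, 50)
        for model in PRESETS.values():
            musp = [p.mu_s_prime for p in make_tissue_spectrum(model, wl, blood)]
            assert (np.diff(musp) < 0).all()

    def test_wavelength_range_enforced(self, tables):
        _, blood, _ = tables
        with pytest.raises(ValueError, match="400"):
            make_tissue_spectrum(ChromophoreModel(), np.array([350.0]), blood)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ChromophoreModel(melanin_fraction=1.2)
        with pytest.raises(ValueError):
            ChromophoreModel(scatter_amplitude=0.0)

    @pytest.mark.parametrize(
        "preset,tissue",
        [
            ("epidermis-like", "epidermis"),
            ("dermis-like", "dermis"),
            ("fat-like", "subcutaneous_fat"),
        ],
    )
    def test_presets_within_two_sd_of_measured_layers(self, tables, preset, tissue):
        """Presets track the measured layer envelopes at all nine wavelengths."""
        table, blood, _ = tables
        wl = np.array(TABLE_WAVELENGTHS_NM, dtype=float)
        props = make_tissue_spectrum(PRESETS[preset], wl, blood)
        for p, w in zip(props, wl):
            row = table.lookup(tissue, w)
            assert abs(p.mu_a - row["mu_a_mean"]) <= 2 * row["mu_a_sd"], (preset, w)
            assert abs(p.mu_s_prime - row["mu_s_prime_mean"]) <= 2 * row["mu_s_prime_sd"], (preset, w)

    def test_dermis_preset_at_632_within_one_sd(self, tables):
        _, blood, _ = tables
        (p,) = make_tissue_spectrum(PRESETS["dermis-like"], np.array([632.0]), blood)
        assert 0.05 <= p.mu_a <= 0.09
        assert 2.44 <= p.mu_s_prime <= 3.68


class TestSynthMeasurement:
    def test_zero_noise_single_replicate_equals_forward_model(self, tables, dermis_632):
        _, blood, _ = tables
        wl = np.array([632.0])
        stack = glass_mounted_stack(dermis_632, 1.5)
        spectrum, truth = synth_measurement(
            [dermis_632], wl, stack, 1.5, noise=None, n_photons=20_000, seed=5
        )
        direct = simulate_slab(stack, 20_000, derive_seed(5, 0, "synth"), nz_bins=1)
        assert spectrum.rd[0] == direct.rd
        assert spectrum.tt[0] == direct.tt
        assert truth["mu_a"][0] == pytest.approx(0.07)

    def test_noise_magnitude_matches_model(self, tables, dermis_632):
        """Across many replicates the injected Rd scatter is ~0.7% relative."""
        _, blood, _ = tables
        wl = np.array([600.0])
        stack = glass_mounted_stack(dermis_632, 1.5)
        noise = NoiseModel(replicates=1)
        vals = []
        base_photons = 40_000
        for k in range(40):
            spectrum, _ = synth_measurement(
                [dermis_632], wl, stack, 1.5, noise, base_photons, seed=1000 + k
            )
            vals.append(spectrum.rd[0])
        vals = np.asarray(vals)
        total_rel_sd = vals.std(ddof=1) / vals.mean()
        # subtract the Monte Carlo binomial noise in quadrature
        mc = simulate_slab(stack, base_photons, seed=0)
        mc_rel = mc.se_rd / mc.rd
        injected = np.sqrt(max(total_rel_sd**2 - mc_rel**2, 0.0))
        assert injected == pytest.approx(0.007, rel=0.5)

    def test_replicate_averaging_reported_in_sd_columns(self, tables, dermis_632):
        wl = np.array([632.0])
        stack = glass_mounted_stack(dermis_632, 1.5)
        spectrum, _ = synth_measurement(
            [dermis_632], wl, stack, 1.5, NoiseModel(), 10_000, seed=2
        )
        assert spectrum.sd_rd is not None and spectrum.sd_rd[0] > 0

    def test_generated_spectra_satisfy_physical_invariants(self, tables):
        """All presets produce valid spectra (Rd + Tt <= 1 everywhere)."""
        _, blood, _ = tables
        wl = np.array([450.0, 632.0, 1000.0])
        for name, model in PRESETS.items():
            props = make_tissue_spectrum(model, wl, blood)
            stack = glass_mounted_stack(props[0], 1.0)
            spectrum, _ = synth_measurement(
                props, wl, stack, 1.0, NoiseModel(), 5_000, seed=3
            )
            assert (spectrum.rd + spectrum.tt <= 1.0).all()
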