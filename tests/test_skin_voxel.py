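"""Voxel skin model construction and voxel Monte Carlo transport."""

import numpy as np
import pytest

from skinoptics.optics_core import OpticalProperties
from skinoptics.skin_voxel import (
    LABELS,
    BeamSpec,
    VoxelGrid,
    _plexus_spacing_vox,
    _rasterized_disc_offsets,
    build_skin_model,
    simulate_voxel,
)

from conftest import homogeneous_grid


def default_model(tables, shape=(500, 500, 400), pitch_mm=0.01, seed=0, **kw):
    _, blood, vessels = tables
    mu_a_b, mu_sp_b = blood.lookup(632)
    blood_props = OpticalProperties.from_reduced(mu_a_b, mu_sp_b, 0.9, 1.39)
    layer_props = {
        "epidermis": OpticalProperties.from_reduced(0.94, 5.55, 0.9, 1.34),
        "dermis": OpticalProperties.from_reduced(0.07, 3.06, 0.9, 1.39),
        "subcutaneous_fat": OpticalProperties.from_reduced(0.07, 1.72, 0.9, 1.44),
    }
    return build_skin_model(
        vessels, blood_props, layer_props, shape=shape, pitch_mm=pitch_mm,
        seed=seed, **kw,
    )


@pytest.fixture(scope="module")
def model(tables):
    return default_model(tables)


class TestModelGeometry:
    def test_physical_extent_and_epidermis_planes(self, model):
        assert model.extent_mm == pytest.approx((5.0, 5.0, 4.0))
        epi = model.labels[:, :, :15]
        assert (epi == LABELS["epidermis"]).all()
        assert not (model.labels[:, :, 15] == LABELS["epidermis"]).any()

    def test_layer_ordering_with_depth(self, model):
        # below the dermis band only fat (vessels live inside the dermis)
        deep = model.labels[:, :, 165:]
        assert set(np.unique(deep)) == {LABELS["subcutaneous_fat"]}
        mid = model.labels[:, :, 15:165]
        assert set(np.unique(mid)) <= {LABELS["dermis"], LABELS["blood"]}

    def test_capillary_band_blood_fraction(self, model, tables):
        _, _, vessels = tables
        frac = model.blood_fraction(0.16, 0.31)
        # 4% target, quantized by one random segment (50 voxels) in the band
        assert frac == pytest.approx(0.04, abs=50 / (500 * 500 * 15) + 1e-6)

    def test_upper_plexus_blood_fraction(self, model):
        frac = model.blood_fraction(0.32, 0.37)
        # one clipped edge cylinder over ~36 periods bounds the quantization
        assert frac == pytest.approx(0.30, abs=0.01)

    def test_deep_plexus_blood_fraction(self, model):
        frac = model.blood_fraction(1.17, 1.25)
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_capillary_placement_is_seeded(self, tables):
        m1 = default_model(tables, shape=(80, 80, 200), seed=5)
        m2 = default_model(tables, shape=(80, 80, 200), seed=5)
        m3 = default_model(tables, shape=(80, 80, 200), seed=6)
        assert (m1.labels == m2.labels).all()
        assert (m1.labels != m3.labels).any()


class TestRasterization:
    @pytest.mark.parametrize(
        "d_vox,expected_area", [(1, 1), (5, 21), (8, 52)]
    )
    def test_disc_footprint(self, d_vox, expected_area):
        offs = _rasterized_disc_offsets(d_vox)
        assert offs.shape[0] == expected_area
        # footprint spans exactly d_vox planes
        assert offs[:, 1].max() - offs[:, 1].min() == d_vox - 1

    def test_spacing_makes_fraction_exact(self):
        # 50-um vessels at 30%: area 21 over band height 5 -> spacing 14
        assert _plexus_spacing_vox(5, 0.30) == 14
        # 80-um vessels at 10%: area 52 over band height 8 -> spacing 65
        assert _plexus_spacing_vox(8, 0.10) == 65

    def test_overlapping_request_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            _plexus_spacing_vox(5, 0.95)


class TestVoxelTransport:
    def test_energy_ledger_exact(self, dermis_632):
        grid = homogeneous_grid(dermis_632)
        field = simulate_voxel(grid, BeamSpec(1.5), 30_000, seed=4)
        assert field.ledger_balance() == pytest.approx(1.0, abs=1e-9)

    def test_no_absorption_all_weight_escapes(self):
        p = OpticalProperties(mu_a=0.0, mu_s=13.4, g=0.9, n=1.39)
        grid = homogeneous_grid(p)
        field = simulate_voxel(grid, BeamSpec(1.5), 20_000, seed=4)
        assert field.absorbed == pytest.approx(0.0, abs=1e-12)
        assert sum(field.escaped.values()) == pytest.approx(1.0, abs=1e-9)

    def test_fixed_seed_bit_identical(self, dermis_632):
        grid = homogeneous_grid(dermis_632, shape=(60, 60, 60))
        f1 = simulate_voxel(grid, BeamSpec(0.8), 5_000, seed=9)
        f2 = simulate_voxel(grid, BeamSpec(0.8), 5_000, seed=9)
        assert (f1.fluence == f2.fluence).all()
        assert f1.escaped == f2.escaped

    def test_xy_reflection_symmetry_statistical(self, dermis_632):
        """Vessel-free fluence is statistically symmetric under x <-> y."""
        grid = homogeneous_grid(dermis_632, shape=(80, 80, 80))
        field = simulate_voxel(grid, BeamSpec(1.0), 150_000, seed=13)
        prof_x = field.fluence.sum(axis=(1, 2))
        prof_y = field.fluence.sum(axis=(0, 2))
        rel = np.abs(prof_x - prof_y) / prof_x.max()
        assert rel.max() < 0.02

    def test_beam_wider_than_grid_rejected(self, dermis_632):
        grid = homogeneous_grid(dermis_632, shape=(60, 60, 60))
        with pytest.raises(ValueError, match="beam"):
            simulate_voxel(grid, BeamSpec(2.0), 100, seed=1)

    def test_unlabelled_voxels_rejected(self, dermis_632):
        labels = np.ones((10, 10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="properties"):
            VoxelGrid(labels=labels, pitch_mm=0.01, properties={0: dermis_632})
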