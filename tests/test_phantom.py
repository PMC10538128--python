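"""Thorax phantom sampling, disease partitioning and rasterization."""

import math

import numpy as np
import pytest

from cceit.geometry import Grid
from cceit.phantom import (
    EPS0,
    OMEGA_DEFAULT,
    TISSUES,
    DiseaseSpec,
    EllipseRegion,
    apply_disease,
    class_to_states,
    complex_permittivity,
    rasterize,
    sample_phantom,
    states_to_class,
)

GRID = Grid(fine_n=64)


class TestComplexPermittivity:
    def test_lossless_tissue_is_purely_real(self):
        t = TISSUES["fat"]
        lossless = type(t)("x", 12.7, 0.0)
        assert complex_permittivity(lossless) == 12.7 + 0j

    def test_effusion_fluid_loss_term(self):
        # 1.4 / (2 pi 1e8 * eps0) = 251.7
        eps = complex_permittivity(TISSUES["effusion_fluid"])
        assert eps.real == 70.0
        assert np.isclose(-eps.imag, 1.4 / (2 * np.pi * 1e8 * EPS0))
        assert np.isclose(-eps.imag, 251.7, atol=0.05)

    def test_pneumothorax_air_is_numerically_one(self):
        eps = complex_permittivity(TISSUES["pneumothorax_air"])
        assert eps.real == 1.0
        assert abs(eps.imag) < 1e-12

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            complex_permittivity(TISSUES["fat"], omega=0.0)

    @pytest.mark.parametrize("name", sorted(TISSUES))
    def test_table_values_roundtrip(self, name):
        t = TISSUES[name]
        eps = complex_permittivity(t)
        assert eps.real == t.rel_permittivity
        assert np.isclose(-eps.imag * OMEGA_DEFAULT * EPS0, t.conductivity)


class TestClassMapping:
    def test_class_one_is_both_healthy(self):
        assert class_to_states(1) == ("none", "none")

    def test_bijection_over_sixteen_classes(self):
        seen = {class_to_states(c) for c in range(1, 17)}
        assert len(seen) == 16
        for c in range(1, 17):
            assert states_to_class(*class_to_states(c)) == c

    def test_unknown_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_phantom(18, rng)
        with pytest.raises(ValueError):
            sample_phantom(0, rng)


class TestSamplePhantom:
    def test_healthy_class_has_no_disease(self):
        spec = sample_phantom(1, np.random.default_rng(1))
        assert spec.disease_left.kind == "none"
        assert spec.disease_right.kind == "none"

    def test_random_ellipse_class_replaces_anatomy(self):
        from cceit.phantom import RANDOM_ELLIPSE_TISSUES

        spec = sample_phantom(17, np.random.default_rng(1))
        assert spec.organs[0].tissue == "fat"  # thorax outline retained
        blobs = spec.organs[1:]
        assert 1 <= len(blobs) <= 4
        assert all(o.tissue in RANDOM_ELLIPSE_TISSUES for o in blobs)

    def test_same_seed_reproduces_spec_exactly(self):
        a = sample_phantom(6, np.random.default_rng(42))
        b = sample_phantom(6, np.random.default_rng(42))
        assert a.to_json() == b.to_json()

    @pytest.mark.parametrize("label", [2, 5, 11, 16])
    def test_disease_fields_match_class(self, label):
        spec = sample_phantom(label, np.random.default_rng(3))
        left, right = class_to_states(label)
        assert spec.disease_left.kind == left
        assert spec.disease_right.kind == right
        if left != "none":
            assert spec.disease_left.clip is not None


class TestApplyDisease:
    def _masks(self):
        lung = EllipseRegion((0.0, 0.0), (0.4, 0.5), 0.2, "lung_inspiration")
        clip = lung.shifted(0.1, -0.3)
        n = 200
        xs = np.linspace(-1, 1, n)
        x, y = np.meshgrid(xs, xs)
        return lung.contains(x, y), clip.contains(x, y), y

    def test_partition_conserves_lung_pixels(self):
        lung, clip, y = self._masks()
        for kind in ("pneumothorax", "effusion", "hydro"):
            parts = apply_disease(lung, clip, kind, y, split_y=0.0)
            total = parts["lung"] | parts["air"] | parts["fluid"]
            assert np.array_equal(total, lung)
            assert not (parts["lung"] & parts["air"]).any()
            assert not (parts["air"] & parts["fluid"]).any()

    def test_full_clip_means_zero_severity(self):
        lung, _, y = self._masks()
        parts = apply_disease(lung, np.ones_like(lung), "pneumothorax", y)
        assert np.array_equal(parts["lung"], lung)
        assert not parts["air"].any()

    def test_hydro_requires_split_level(self):
        lung, clip, y = self._masks()
        with pytest.raises(ValueError):
            apply_disease(lung, clip, "hydro", y, split_y=None)

    def test_unknown_kind_rejected(self):
        lung, clip, y = self._masks()
        with pytest.raises(ValueError):
            apply_disease(lung, clip, "gout", y)


class TestRasterize:
    def test_painted_values_come_from_tissue_tables(self):
        spec = sample_phantom(6, np.random.default_rng(5))
        eps = rasterize(spec, GRID).fine_map
        allowed = {complex_permittivity(t) for t in TISSUES.values()}
        assert set(np.unique(eps)) <= allowed

    def test_organ_centre_pixels_have_table_values(self):
        spec = sample_phantom(1, np.random.default_rng(7))
        eps = rasterize(spec, GRID).fine_map
        x, y = GRID.fine_centers()
        R, (cx, cy) = GRID.fov_radius, GRID.fov_center
        by_name = {o.tissue: o for o in spec.organs}
        for tissue in ("heart", "spine"):
            o = by_name[tissue]
            px = cx + R * o.center[0]
            py = cy + R * o.center[1]
            i = np.argmin(np.abs(y[:, 0] - py))
            j = np.argmin(np.abs(x[0] - px))
            assert eps[i, j] == complex_permittivity(TISSUES[tissue])

    def test_passive_media_have_nonpositive_imaginary_part(self):
        for label in (1, 8, 17):
            spec = sample_phantom(label, np.random.default_rng(label))
            m = rasterize(spec, GRID)
            assert np.all(m.fine_map.imag <= 0)
            assert np.all(m.recon_map.imag <= 1e-12)

    def test_recon_map_is_block_average(self):
        spec = sample_phantom(4, np.random.default_rng(2))
        m = rasterize(spec, GRID)
        b = GRID.block
        manual = m.fine_map.reshape(64, b, 64, b).mean(axis=(1, 3))
        assert np.array_equal(m.recon_map, manual)

    def test_same_seed_gives_bit_identical_maps(self):
        a = rasterize(sample_phantom(9, np.random.default_rng(11)), GRID)
        b = rasterize(sample_phantom(9, np.random.default_rng(11)), GRID)
        assert np.array_equal(a.fine_map, b.fine_map)

    def test_pneumothorax_air_sits_above_kept_lung(self):
        # y increases toward the anterior wall (image top)
        grid = Grid(fine_n=128)
        x, y = grid.fine_centers()
        air = complex_permittivity(TISSUES["pneumothorax_air"])
        lung_vals = {
            complex_permittivity(TISSUES["lung_inspiration"]),
            complex_permittivity(TISSUES["lung_expiration"]),
        }
        checked = 0
        for seed in range(12):
            spec = sample_phantom(states_to_class("pneumothorax", "none"), np.random.default_rng(seed))
            eps = rasterize(spec, grid).fine_map
            air_mask = eps == air
            lung_mask = np.isin(eps, list(lung_vals))
            if air_mask.sum() > 20 and lung_mask.sum() > 20:
                assert y[air_mask].mean() > y[lung_mask].mean()
                checked += 1
        assert checked >= 6

    def test_effusion_fluid_sits_below_kept_lung(self):
        grid = Grid(fine_n=128)
        x, y = grid.fine_centers()
        fluid = complex_permittivity(TISSUES["effusion_fluid"])
        lung_vals = {
            complex_permittivity(TISSUES["lung_inspiration"]),
            complex_permittivity(TISSUES["lung_expiration"]),
        }
        checked = 0
        for seed in range(12):
            spec = sample_phantom(states_to_class("effusion", "none"), np.random.default_rng(seed))
            eps = rasterize(spec, grid).fine_map
            fluid_mask = eps == fluid
            lung_mask = np.isin(eps, list(lung_vals))
            if fluid_mask.sum() > 20 and lung_mask.sum() > 20:
                assert y[fluid_mask].mean() < y[lung_mask].mean()
                checked += 1
        assert checked >= 6
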