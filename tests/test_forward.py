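"""Forward solver: fields, capacitances, calibration and sensitivity."""

import math

import numpy as np
import pytest

from cceit.geometry import Grid, build_fov_mask, build_measurement_index, build_sensor
from cceit.forward import (
    CalibrationError,
    ForwardProblem,
    MeasurementFrame,
    SolverError,
    capacitance_frame,
    normalize_channels,
    normalize_frame,
    sensitivity_matrix,
    uniform_map,
)
from cceit.phantom import (
    EPS0,
    ComplexPermittivityMap,
    TISSUES,
    complex_permittivity,
    rasterize,
    sample_phantom,
)

TOY_GRID = Grid(fine_n=64, recon_n=16)
TOY_SENSOR = build_sensor(K=8)


@pytest.fixture(scope="module")
def toy_problem():
    return ForwardProblem(uniform_map(TOY_GRID, "air"), TOY_SENSOR, TOY_GRID)


class TestSolveField:
    def test_residual_below_tolerance(self, toy_problem):
        f = toy_problem.solve(0)
        assert f.residual_norm <= 1e-10

    def test_dirichlet_values_honored_exactly(self, toy_problem):
        f = toy_problem.solve(3)
        phi = f.phi
        assert np.all(phi[toy_problem.electrode_id == 3] == 1.0)
        for k in range(8):
            if k != 3:
                assert np.all(phi[toy_problem.electrode_id == k] == 0.0)
        assert np.all(phi[toy_problem.screen] == 0.0)

    def test_discrete_maximum_principle_for_lossless_medium(self, toy_problem):
        f = toy_problem.solve(0)
        assert f.phi.real.min() >= -1e-12
        assert f.phi.real.max() <= 1.0 + 1e-12

    def test_rotational_symmetry_of_uniform_medium(self, toy_problem):
        # K=8: electrode 2 sits a quarter turn from electrode 0, so its
        # field is the 90-degree rotation of electrode 0's field
        f0 = toy_problem.solve(0).phi.real
        f2 = toy_problem.solve(2).phi.real
        rotated = np.rot90(f0, k=1)
        assert np.abs(f2 - rotated).max() < 1e-3

    def test_invalid_electrode_rejected(self, toy_problem):
        with pytest.raises(SolverError):
            toy_problem.solve(8)


class TestCapacitance:
    def test_reciprocity_on_lossy_phantoms(self):
        for seed in range(3):
            spec = sample_phantom(6, np.random.default_rng(seed))
            emap = rasterize(spec, TOY_GRID)
            frame = capacitance_frame(emap, TOY_SENSOR, TOY_GRID)
            cm = dict(zip(frame.index.pairs, frame.c))
            for i in range(8):
                for j in range(i + 1, 8):
                    rel = abs(cm[(i, j)] - cm[(j, i)]) / abs(cm[(i, j)])
                    assert rel < 1e-6

    def test_charge_conservation(self, toy_problem):
        f = toy_problem.solve(0)
        total = sum(toy_problem.electrode_charge(f.phi, k) for k in range(8))
        total += toy_problem.screen_charge(f.phi)
        scale = abs(toy_problem.electrode_charge(f.phi, 0))
        assert abs(total) / scale < 1e-8

    def test_capacitance_linear_under_global_permittivity_scaling(self):
        # doubling the permittivity of EVERY material (interior and sleeve)
        # doubles every capacitance: the field equation is homogeneous
        import cceit.phantom as ph

        T = type(TISSUES["fat"])
        ph.TISSUES["_u"] = T("_u", 3.0, 0.0)
        c1 = capacitance_frame(uniform_map(TOY_GRID, "_u"), TOY_SENSOR, TOY_GRID).c
        old = ph.TISSUES["insulation_plastic"]
        try:
            ph.TISSUES["_u"] = T("_u", 6.0, 0.0)
            ph.TISSUES["insulation_plastic"] = T(
                "insulation_plastic", 2 * old.rel_permittivity, 2 * old.conductivity
            )
            c2 = capacitance_frame(uniform_map(TOY_GRID, "_u"), TOY_SENSOR, TOY_GRID).c
        finally:
            ph.TISSUES["insulation_plastic"] = old
            del ph.TISSUES["_u"]
        assert np.allclose(c2, 2.0 * c1, rtol=1e-10)

    def test_coaxial_analytic_convergence(self):
        # full-ring excitation via superposition of both K=2 electrodes;
        # annulus between electrode band and screen is the plastic sleeve
        errors = []
        for n in (64, 128):
            grid = Grid(fine_n=n)
            sensor = build_sensor(
                K=2, electrode_coverage=0.999, electrode_thickness=0.02, screen_radius=1.15
            )
            prob = ForwardProblem(uniform_map(grid, "air"), sensor, grid)
            Q = sum(prob.screen_charge(prob.solve(k).phi) for k in (0, 1))
            eff = max(0.02, 1.5 * grid.fine_h)
            ri, ro = 1.0 + eff, 1.15
            eps_r = TISSUES["insulation_plastic"].rel_permittivity
            C_analytic = 2 * math.pi * EPS0 * eps_r / math.log(ro / ri)
            errors.append(abs(abs(Q) - C_analytic) / C_analytic)
        assert errors[1] < errors[0]
        assert errors[1] < 0.05


class TestNormalization:
    def _frames(self):
        index = build_measurement_index(4)
        rng = np.random.default_rng(0)
        low = MeasurementFrame(rng.random(12) + 1j * rng.random(12), "raw", index)
        high = MeasurementFrame(low.c + rng.random(12) + 1j * (1 + rng.random(12)), "raw", index)
        return index, low, high

    def test_calibration_points_map_to_zero_and_one(self):
        index, low, high = self._frames()
        assert np.allclose(normalize_frame(low, low, high).c, 0.0)
        assert np.allclose(normalize_frame(high, low, high).c, 1.0)

    def test_midpoint_maps_to_half(self):
        index, low, high = self._frames()
        mid = MeasurementFrame(0.5 * (low.c + high.c), "raw", index)
        assert np.allclose(normalize_frame(mid, low, high).c, 0.5)

    def test_degenerate_calibration_rejected(self):
        index, low, high = self._frames()
        with pytest.raises(CalibrationError):
            normalize_frame(low, low, low)

    def test_channel_normalization_fixed_points(self):
        index, low, high = self._frames()
        assert np.allclose(normalize_channels(low, low, high).c, 0.0)
        assert np.allclose(normalize_channels(high, low, high).c, 1.0 + 1.0j)

    def test_channel_normalization_monotone_in_conductivity(self):
        # uniform fills of increasing conductivity give increasing imaginary
        # channel values, with the high calibration material at exactly 1
        gen_low = capacitance_frame(uniform_map(TOY_GRID, "air"), TOY_SENSOR, TOY_GRID)
        gen_high = capacitance_frame(
            uniform_map(TOY_GRID, "effusion_fluid"), TOY_SENSOR, TOY_GRID
        )
        means = []
        for tissue in ("fat", "lung_inspiration", "lung_expiration", "heart"):
            raw = capacitance_frame(uniform_map(TOY_GRID, tissue), TOY_SENSOR, TOY_GRID)
            means.append(normalize_channels(raw, gen_low, gen_high).c.imag.mean())
        assert all(b > a for a, b in zip(means, means[1:]))
        assert 0 < means[0] and means[-1] < 1


@pytest.fixture(scope="module")
def toy_S():
    fov = build_fov_mask(TOY_GRID)
    index = build_measurement_index(8)
    return sensitivity_matrix(TOY_SENSOR, TOY_GRID, fov, index=index), fov, index


class TestSensitivityMatrix:
    def test_shape_matches_geometry(self, toy_S):
        S, fov, index = toy_S
        assert S.S.shape == (index.M, fov.n_fov)
        assert np.all(np.isfinite(S.S.real))

    def test_full_scale_shape_is_992_by_1856(self):
        # shape check only: derived from index and mask sizes
        fov = build_fov_mask(Grid())
        index = build_measurement_index(32)
        assert (index.M, fov.n_fov) == (992, 1856)

    def test_reciprocal_pairs_share_rows(self, toy_S):
        S, fov, index = toy_S
        rows = {p: m for m, p in enumerate(index.pairs)}
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            assert np.array_equal(S.S[rows[(i, j)]], S.S[rows[(j, i)]])

    def test_row_normalized_variant_has_unit_max(self, toy_S):
        S, _, _ = toy_S
        assert np.allclose(np.abs(S.S_norm).max(axis=1), 1.0)

    def test_matches_finite_difference_jacobian(self, toy_S):
        S, fov, index = toy_S
        ref = uniform_map(TOY_GRID, "air")
        base = capacitance_frame(ref, TOY_SENSOR, TOY_GRID, index).c
        delta = 1e-3
        block = TOY_GRID.block
        full = np.flatnonzero(fov.mask.ravel())
        rng = np.random.default_rng(0)
        for k in rng.choice(fov.n_fov, size=10, replace=False):
            r, c = divmod(full[k], TOY_GRID.recon_n)
            fine = ref.fine_map.copy()
            fine[r * block : (r + 1) * block, c * block : (c + 1) * block] += delta
            pert = ComplexPermittivityMap(fine, ref.recon_map, ref.omega)
            fd = (capacitance_frame(pert, TOY_SENSOR, TOY_GRID, index).c - base) / delta
            an = S.S[:, k]
            mask = np.abs(fd) > np.abs(fd).max() * 1e-2
            rel = np.abs(an[mask] - fd[mask]) / np.abs(fd[mask])
            assert rel.max() < 0.01
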