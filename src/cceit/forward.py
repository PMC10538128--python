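"""Electrostatic forward problem: fields, capacitances, sensitivity matrix.

The complex-valued potential phi solves div(eps grad phi) = 0 on the fine
grid with Dirichlet conditions phi = 1 on the excited electrode and phi = 0
on all other electrodes and on the grounded screen.  Discretization is
cell-centred finite volumes with harmonic averaging of the complex
permittivity on faces; Dirichlet cells couple to their free neighbours
through half-cell faces, so the fixed potential is imposed on the cell
boundary.  One sparse LU factorization per permittivity map serves all K
excitations.

Mutual capacitances follow from Gauss' law: the charge on a sensing
electrode is the discrete flux of eps * E through the faces that surround
it.  Capacitances are reported per unit depth (F/m) with a positive sign
convention for the mutual terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import (
    FOVMask,
    Grid,
    MeasurementIndex,
    SensorGeometry,
    build_fov_mask,
    build_measurement_index,
)
from .phantom import (
    EPS0,
    OMEGA_DEFAULT,
    TISSUES,
    ComplexPermittivityMap,
    complex_permittivity,
)


class SolverError(RuntimeError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PotentialField:
    """Solved potential for one excitation, on the full fine grid."""

    phi: np.ndarray
    excitation_electrode: int
    residual_norm: float


@dataclass(frozen=True)
class MeasurementFrame:
    """Vector of M complex mutual capacitances in MeasurementIndex order."""

    c: np.ndarray
    kind: str  # "raw" or "normalized"
    index: MeasurementIndex
    noise_snr_db: float | None = None


@dataclass(frozen=True)
class SensitivityMatrix:
    """Jacobian of the M capacitances w.r.t. the N in-FOV pixel permittivities.

    ``S`` is the raw Jacobian (F/m per unit relative permittivity); ``S_norm``
    has each row scaled to unit maximum absolute value, the form used by
    linear back projection.
    """

    S: np.ndarray
    S_norm: np.ndarray
    index: MeasurementIndex
    fov: FOVMask


class ForwardProblem:
    """Finite-volume discretization for one permittivity map and sensor.

    Builds the cell classification (free / electrode / screen), the face
    conductances and the LU factorization once; individual excitations are
    then cheap triangular solves.
    """

    def __init__(
        self,
        eps_map: ComplexPermittivityMap,
        sensor: SensorGeometry,
        grid: Grid,
    ):
        self.sensor = sensor
        self.grid = grid
        self.omega = eps_map.omega
        n = grid.fine_n
        x, y = grid.fine_centers()
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)

        # cell classification
        self.screen = r > sensor.screen_radius
        # at coarse grids the electrode band is widened to at least 1.5 cells
        # so every electrode is resolved
        eff_thick = max(sensor.electrode_thickness, 1.5 * grid.fine_h)
        band = (r >= sensor.sensor_radius) & (r <= sensor.sensor_radius + eff_thick)
        self.electrode_id = np.full((n, n), -1, dtype=np.int64)
        for k, (a0, a1) in enumerate(sensor.electrode_angular_spans):
            width = a1 - a0
            ang = np.mod(theta - a0, 2.0 * np.pi)
            self.electrode_id[band & (ang <= width)] = k
        if any((self.electrode_id == k).sum() == 0 for k in range(sensor.K)):
            raise SolverError("fine grid too coarse to resolve every electrode")
        self.dirichlet = self.screen | (self.electrode_id >= 0)

        # material map: phantom inside the sensor wall, plastic outside
        eps = np.array(eps_map.fine_map, dtype=np.complex128, copy=True)
        sleeve = r > sensor.sensor_radius
        eps[sleeve] = complex_permittivity(TISSUES["insulation_plastic"], self.omega)
        if not np.all(np.abs(eps) > 0):
            raise SolverError("permittivity map contains zeros")
        self.eps = eps

        self._assemble()

    def _assemble(self) -> None:
        n = self.grid.fine_n
        eps, dirich = self.eps, self.dirichlet
        free = ~dirich
        self.free = free
        self.nfree = int(free.sum())
        idx = np.full((n, n), -1, dtype=np.int64)
        idx[free] = np.arange(self.nfree)
        self.idx = idx

        # face conductances (per unit depth; the h/h geometric factor is 1):
        # harmonic mean between cell centres, half-cell (2 eps) at Dirichlet
        # boundaries.
        def face_g(ea, eb, da, db):
            g = 2.0 * ea * eb / (ea + eb)
            g = np.where(da & ~db, 2.0 * eb, g)
            g = np.where(db & ~da, 2.0 * ea, g)
            return g

        gh = face_g(eps[:, :-1], eps[:, 1:], dirich[:, :-1], dirich[:, 1:])
        gv = face_g(eps[:-1, :], eps[1:, :], dirich[:-1, :], dirich[1:, :])
        self._gh, self._gv = gh, gv

        # derivatives of the face conductances w.r.t. each side's
        # permittivity, used by the discrete-adjoint sensitivity matrix
        def face_dg(ea, eb, da, db):
            dga = 2.0 * eb**2 / (ea + eb) ** 2
            dgb = 2.0 * ea**2 / (ea + eb) ** 2
            dga = np.where(da, 0.0, np.where(db, 2.0, dga))
            dgb = np.where(db, 0.0, np.where(da, 2.0, dgb))
            return dga, dgb

        self._dgh = face_dg(eps[:, :-1], eps[:, 1:], dirich[:, :-1], dirich[:, 1:])
        self._dgv = face_dg(eps[:-1, :], eps[1:, :], dirich[:-1, :], dirich[1:, :])

        rows, cols, vals = [], [], []
        diag = np.zeros(self.nfree, dtype=np.complex128)
        # boundary-contribution bookkeeping for the RHS: for each Dirichlet
        # cell adjacent to a free cell, record (free index, dirichlet flat
        # position, conductance)
        b_free, b_dir, b_g = [], [], []

        def couple(ia, ib, g):
            # ia, ib: index arrays (flattened positions) of the two sides
            fa, fb = idx.ravel()[ia], idx.ravel()[ib]
            da, db = dirich.ravel()[ia], dirich.ravel()[ib]
            both_free = (~da) & (~db)
            np.add.at(diag, fa[~da], g[~da])
            np.add.at(diag, fb[~db], g[~db])
            rows.append(fa[both_free])
            cols.append(fb[both_free])
            vals.append(-g[both_free])
            rows.append(fb[both_free])
            cols.append(fa[both_free])
            vals.append(-g[both_free])
            a_dir = da & ~db  # a Dirichlet, b free
            b_free.append(fb[a_dir]); b_dir.append(ia[a_dir]); b_g.append(g[a_dir])
            bd = db & ~da
            b_free.append(fa[bd]); b_dir.append(ib[bd]); b_g.append(g[bd])

        flat = np.arange(n * n).reshape(n, n)
        couple(flat[:, :-1].ravel(), flat[:, 1:].ravel(), gh.ravel())
        couple(flat[:-1, :].ravel(), flat[1:, :].ravel(), gv.ravel())

        rows.append(np.arange(self.nfree))
        cols.append(np.arange(self.nfree))
        vals.append(diag)
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nfree, self.nfree),
        ).tocsc()
        self.A = A
        try:
            # the system is structurally symmetric and diagonally dominant;
            # symmetric-mode ordering cuts fill-in severalfold
            self.lu = splu(
                A,
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=0.0,
                options={"SymmetricMode": True},
            )
        except RuntimeError as exc:  # pragma: no cover
            raise SolverError(f"singular forward system: {exc}") from exc
        self._b_free = np.concatenate(b_free)
        self._b_dir = np.concatenate(b_dir)
        self._b_g = np.concatenate(b_g)

    def _dirichlet_values(self, excite: int) -> np.ndarray:
        vals = np.zeros(self.grid.fine_n ** 2, dtype=np.complex128)
        vals[(self.electrode_id == excite).ravel()] = 1.0
        return vals

    def solve(self, excite: int) -> PotentialField:
        """Solve the field with unit potential on electrode ``excite``."""
        if not 0 <= excite < self.sensor.K:
            raise SolverError(f"no electrode {excite}")
        dvals = self._dirichlet_values(excite)
        rhs = np.zeros(self.nfree, dtype=np.complex128)
        np.add.at(rhs, self._b_free, self._b_g * dvals[self._b_dir])
        phi_free = self.lu.solve(rhs)
        res = np.linalg.norm(self.A @ phi_free - rhs)
        scale = np.linalg.norm(rhs)
        residual = float(res / scale) if scale > 0 else float(res)
        phi = np.zeros_like(dvals)
        phi[self.free.ravel()] = phi_free
        phi[self.dirichlet.ravel()] = dvals[self.dirichlet.ravel()]
        return PotentialField(
            phi=phi.reshape(self.grid.fine_n, -1),
            excitation_electrode=excite,
            residual_norm=residual,
        )

    def solve_all(self) -> list[PotentialField]:
        """Solve all K excitations with one batched triangular solve."""
        K = self.sensor.K
        n2 = self.grid.fine_n ** 2
        dvals = np.zeros((n2, K), dtype=np.complex128)
        for k in range(K):
            dvals[(self.electrode_id == k).ravel(), k] = 1.0
        rhs = np.zeros((self.nfree, K), dtype=np.complex128)
        np.add.at(rhs, self._b_free, self._b_g[:, None] * dvals[self._b_dir])
        phi_free = self.lu.solve(rhs)
        res = np.linalg.norm(self.A @ phi_free - rhs, axis=0)
        scale = np.linalg.norm(rhs, axis=0)
        fields = []
        for k in range(K):
            phi = np.zeros(n2, dtype=np.complex128)
            phi[self.free.ravel()] = phi_free[:, k]
            phi[self.dirichlet.ravel()] = dvals[self.dirichlet.ravel(), k]
            fields.append(
                PotentialField(
                    phi=phi.reshape(self.grid.fine_n, -1),
                    excitation_electrode=k,
                    residual_norm=float(res[k] / scale[k]) if scale[k] > 0 else float(res[k]),
                )
            )
        return fields

    def capacitance_matrix(self) -> np.ndarray:
        """Full K x K mutual-capacitance matrix (diagonal zero), F/m.

        Entry (i, j) is the Gauss-law flux into sensing electrode j with
        electrode i excited, computed from the precomputed Dirichlet-face
        lists; all K excitations share one batched solve.
        """
        K = self.sensor.K
        n2 = self.grid.fine_n ** 2
        dvals = np.zeros((n2, K), dtype=np.complex128)
        for k in range(K):
            dvals[(self.electrode_id == k).ravel(), k] = 1.0
        rhs = np.zeros((self.nfree, K), dtype=np.complex128)
        np.add.at(rhs, self._b_free, self._b_g[:, None] * dvals[self._b_dir])
        phi_free = self.lu.solve(rhs)
        face_vals = self._b_g[:, None] * (phi_free[self._b_free] - dvals[self._b_dir])
        elec = self.electrode_id.ravel()[self._b_dir]
        grp = np.where(elec >= 0, elec, K)  # screen charge kept in row K
        Q = np.zeros((K + 1, K), dtype=np.complex128)
        np.add.at(Q, grp, face_vals)
        Q *= EPS0
        C = Q[:K].T.copy()  # C[i, j] = flux into j when i excited
        np.fill_diagonal(C, 0.0)
        return C

    def electrode_charge(self, phi: np.ndarray, electrode: int) -> complex:
        """Gauss-law charge on an electrode, per unit depth (divided by eps0
        it would be dimensionless; the eps0 factor is included here)."""
        return self._boundary_flux(phi, self.electrode_id == electrode)

    def screen_charge(self, phi: np.ndarray) -> complex:
        return self._boundary_flux(phi, self.screen)

    def _boundary_flux(self, phi: np.ndarray, cells: np.ndarray) -> complex:
        """Flux of eps * grad(phi) into ``cells`` through their faces."""
        gh, gv = self._gh, self._gv
        total = 0.0 + 0.0j
        a, b = cells[:, :-1], cells[:, 1:]
        d = phi[:, 1:] - phi[:, :-1]
        total += np.sum(gh[a & ~b] * d[a & ~b])
        total += np.sum(gh[b & ~a] * (-d[b & ~a]))
        a, b = cells[:-1, :], cells[1:, :]
        d = phi[1:, :] - phi[:-1, :]
        total += np.sum(gv[a & ~b] * d[a & ~b])
        total += np.sum(gv[b & ~a] * (-d[b & ~a]))
        return complex(EPS0 * total)


def solve_field(
    eps_map: ComplexPermittivityMap,
    sensor: SensorGeometry,
    grid: Grid,
    excite: int,
) -> PotentialField:
    """One-shot field solve (builds the factorization each call)."""
    return ForwardProblem(eps_map, sensor, grid).solve(excite)


def capacitance_frame(
    eps_map: ComplexPermittivityMap,
    sensor: SensorGeometry,
    grid: Grid,
    index: MeasurementIndex | None = None,
    problem: ForwardProblem | None = None,
) -> MeasurementFrame:
    """Raw mutual capacitances for all ordered electrode pairs.

    K field solves produce all M = K(K-1) entries: with electrode i excited
    at unit potential, C(i, j) is the Gauss-law charge flux around sensing
    electrode j divided by the potential difference (with the positive-
    mutual sign convention).
    """
    if index is None:
        index = build_measurement_index(sensor.K)
    if problem is None:
        problem = ForwardProblem(eps_map, sensor, grid)
    charge = problem.capacitance_matrix()
    c = np.array([charge[i, j] for i, j in index.pairs])
    return MeasurementFrame(c=c, kind="raw", index=index)


def normalize_frame(
    raw: MeasurementFrame, low: MeasurementFrame, high: MeasurementFrame
) -> MeasurementFrame:
    """Two-point calibration: (raw - low) / (high - low), componentwise."""
    if raw.index.pairs != low.index.pairs or raw.index.pairs != high.index.pairs:
        raise CalibrationError("calibration frames use a different pair ordering")
    denom = high.c - low.c
    if np.any(denom == 0):
        raise CalibrationError("degenerate calibration: high == low for some pair")
    return MeasurementFrame(
        c=(raw.c - low.c) / denom,
        kind="normalized",
        index=raw.index,
        noise_snr_db=raw.noise_snr_db,
    )


def normalize_channels(
    raw: MeasurementFrame, low: MeasurementFrame, high: MeasurementFrame
) -> MeasurementFrame:
    """Two-point calibration applied per quadrature channel.

    Real and imaginary parts are normalized independently:
    Re -> (Re c - Re c_low) / (Re c_high - Re c_low), likewise for Im.  The
    imaginary channel is then 0 for the empty sensor and 1 for the high-
    conductivity filling and varies monotonically with tissue conductivity,
    which is what the networks and the algebraic methods consume.  (The
    complex-ratio normalization of :func:`normalize_frame` is degenerate in
    its imaginary part: it vanishes at both calibration points.)
    """
    if raw.index.pairs != low.index.pairs or raw.index.pairs != high.index.pairs:
        raise CalibrationError("calibration frames use a different pair ordering")
    dre = high.c.real - low.c.real
    dim = high.c.imag - low.c.imag
    if np.any(dre == 0) or np.any(dim == 0):
        raise CalibrationError("degenerate calibration: high == low in a channel")
    re = (raw.c.real - low.c.real) / dre
    im = (raw.c.imag - low.c.imag) / dim
    return MeasurementFrame(
        c=re + 1j * im, kind="normalized", index=raw.index, noise_snr_db=raw.noise_snr_db
    )


def uniform_map(
    grid: Grid, tissue_name: str, omega: float = OMEGA_DEFAULT
) -> ComplexPermittivityMap:
    """Permittivity map with the whole interior filled by one tissue."""
    value = complex_permittivity(TISSUES[tissue_name], omega)
    fine = np.full((grid.fine_n, grid.fine_n), value, dtype=np.complex128)
    block = grid.block
    recon = fine.reshape(grid.recon_n, block, grid.recon_n, block).mean(axis=(1, 3))
    return ComplexPermittivityMap(fine_map=fine, recon_map=recon, omega=omega)


def calibration_frames(
    sensor: SensorGeometry,
    grid: Grid,
    omega: float = OMEGA_DEFAULT,
    high_tissue: str = "effusion_fluid",
) -> tuple[MeasurementFrame, MeasurementFrame]:
    """Calibration pair: empty sensor (air) and high-conductivity filling."""
    low = capacitance_frame(uniform_map(grid, "air", omega), sensor, grid)
    high = capacitance_frame(uniform_map(grid, high_tissue, omega), sensor, grid)
    return low, high


def sensitivity_matrix(
    sensor: SensorGeometry,
    grid: Grid,
    fov: FOVMask | None = None,
    ref_map: ComplexPermittivityMap | None = None,
    index: MeasurementIndex | None = None,
) -> SensitivityMatrix:
    """Jacobian of the capacitances w.r.t. in-FOV pixel permittivities.

    Uses the discrete adjoint identity on the finite-volume system: the
    derivative of C(i, j) with respect to a cell's permittivity is the sum
    over the cell's faces of the conductance derivative times the product of
    the two unit-excitation fields' face differences.  This is the exact
    Jacobian of the discretized forward map (to rounding), so it agrees with
    finite-difference perturbation entrywise.  The linearization point
    defaults to the empty (air-filled) sensor, matching the low calibration
    point.
    """
    if fov is None:
        fov = build_fov_mask(grid)
    if ref_map is None:
        ref_map = uniform_map(grid, "air")
    if index is None:
        index = build_measurement_index(sensor.K)
    problem = ForwardProblem(ref_map, sensor, grid)
    n = grid.fine_n
    K = sensor.K
    fields = problem.solve_all()
    Dh = np.empty((K, n, n - 1), dtype=np.complex128)
    Dv = np.empty((K, n - 1, n), dtype=np.complex128)
    for k, f in enumerate(fields):
        Dh[k] = f.phi[:, 1:] - f.phi[:, :-1]
        Dv[k] = f.phi[1:, :] - f.phi[:-1, :]
    dgh_a, dgh_b = problem._dgh
    dgv_a, dgv_b = problem._dgv

    block = grid.block
    n64 = grid.recon_n
    pair_to_row = {p: m for m, p in enumerate(index.pairs)}
    S = np.zeros((index.M, fov.n_fov), dtype=np.complex128)
    for i in range(K):
        Ph = Dh[i][None] * Dh[i + 1 :]
        Pv = Dv[i][None] * Dv[i + 1 :]
        Z = np.zeros((K - i - 1, n, n), dtype=np.complex128)
        Z[:, :, :-1] += Ph * dgh_a
        Z[:, :, 1:] += Ph * dgh_b
        Z[:, :-1, :] += Pv * dgv_a
        Z[:, 1:, :] += Pv * dgv_b
        # minus sign: with the positive-mutual capacitance convention,
        # raising the permittivity of an interior pixel lowers C(i, j)
        sums = -EPS0 * Z.reshape(-1, n64, block, n64, block).sum(axis=(2, 4))
        rows = sums[:, fov.mask]
        for jj, j in enumerate(range(i + 1, K)):
            if (i, j) in pair_to_row:
                S[pair_to_row[(i, j)]] = rows[jj]
            if (j, i) in pair_to_row:
                S[pair_to_row[(j, i)]] = rows[jj]
    row_max = np.max(np.abs(S), axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0
    return SensitivityMatrix(S=S, S_norm=S / row_max, index=index, fov=fov)
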