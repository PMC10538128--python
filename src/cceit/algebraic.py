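"""One-step algebraic reconstructions: linear back projection and
Tikhonov-regularized pseudoinverse.

Both methods operate on the real working system obtained from the complex
forward linearization: the data channel is the imaginary component of the
normalized measurements and the unknown is the conductivity of each FOV
pixel on the normalized scale (0 for air, 1 for the high calibration
material).  The working Jacobian folds the two-point calibration and the
complex-permittivity convention into the complex sensitivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .forward import MeasurementFrame, SensitivityMatrix
from .metrics import SIGMA_MAX
from .phantom import EPS0, OMEGA_DEFAULT


@dataclass(frozen=True)
class ReconstructedImage:
    """Reconstructed FOV vector(s) on the normalized conductivity scale."""

    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)


def imaginary_jacobian(
    S: SensitivityMatrix,
    c_low: MeasurementFrame,
    c_high: MeasurementFrame,
    omega: float = OMEGA_DEFAULT,
    sigma_high: float = SIGMA_MAX,
) -> np.ndarray:
    """Real Jacobian of the normalized imaginary channel w.r.t. normalized
    conductivity.

    Derivation: a pixel's complex permittivity depends on its conductivity
    through -j sigma / (omega eps0); the imaginary channel is normalized per
    component by (Im c_high - Im c_low).  With y = sigma / sigma_high this
    gives J[m, k] = -(sigma_high / (omega eps0)) Re(S[m, k]) /
    (Im c_high - Im c_low)[m].
    """
    denom = c_high.c.imag - c_low.c.imag
    return -(sigma_high / (omega * EPS0)) * S.S.real / denom[:, None]


def row_normalize(J: np.ndarray) -> np.ndarray:
    """Scale each row to unit maximum absolute value (the LBP form)."""
    m = np.max(np.abs(J), axis=1, keepdims=True)
    m[m == 0] = 1.0
    return J / m


def lbp(
    S_norm: np.ndarray, c_n: np.ndarray, eps_min: float = 0.0
) -> ReconstructedImage:
    """Linear back projection: eps = eps_min + S_norm^T c_n.

    ``S_norm`` is the row-normalized sensitivity matrix (M, N); ``c_n`` a
    measurement vector (M,) or batch (B, M).  ``eps_min`` defaults to the
    reconstruction-scale value of the low calibration point (0, air).
    """
    S_norm = np.asarray(S_norm)
    c_n = np.asarray(c_n)
    if c_n.shape[-1] != S_norm.shape[0]:
        raise ValueError(
            f"measurement length {c_n.shape[-1]} does not match {S_norm.shape[0]} rows"
        )
    values = eps_min + c_n @ S_norm
    return ReconstructedImage(values=values, method="lbp", params={"eps_min": eps_min})


def tpinv(
    S: np.ndarray, c_n: np.ndarray, alpha: float = 1e-9
) -> ReconstructedImage:
    """Tikhonov-regularized pseudoinverse: solve (S^T S + alpha I) x = S^T c_n.

    The normal system is symmetric positive definite for alpha > 0 and is
    solved with a Cholesky factorization shared across a measurement batch.
    For underdetermined systems (M < N) the equivalent dual form
    x = S^T (S S^T + alpha I)^{-1} c_n is used: it is the same solution but
    the factorized matrix is smaller and much better conditioned.
    """
    if alpha <= 0:
        raise ValueError(f"regularization alpha must be positive, got {alpha}")
    S = np.asarray(S)
    c_n = np.asarray(c_n)
    if c_n.shape[-1] != S.shape[0]:
        raise ValueError(
            f"measurement length {c_n.shape[-1]} does not match {S.shape[0]} rows"
        )
    M, N = S.shape
    if M < N:
        A = S @ S.T + alpha * np.eye(M)
        cho = scipy.linalg.cho_factor(A)
        w = scipy.linalg.cho_solve(cho, c_n.T if c_n.ndim > 1 else c_n)
        x = S.T @ w
    else:
        A = S.T @ S + alpha * np.eye(N)
        cho = scipy.linalg.cho_factor(A)
        x = scipy.linalg.cho_solve(cho, (c_n @ S).T)
    values = x.T if c_n.ndim > 1 else x
    return ReconstructedImage(values=values, method="tpinv", params={"alpha": alpha})
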