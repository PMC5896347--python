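"""Incompressibility-regularized displacement denoising.

Soft tissue is nearly incompressible, so the physical divergence of the
displacement field should be close to zero; ultrasonically measured fields
violate this, mostly through noisy lateral estimates. The denoiser returns
the minimizer of the quadratic energy

    F(u, v) = ||div(u, v)||^2  +  lambda1 ||u - u_meas||^2  +  lambda2 ||v - v_meas||^2

(integrals over the grid; div = d u_axial / d axial + d v_lateral / d
lateral), obtained by solving the linear Euler-Lagrange system with natural
boundary conditions.  Because axial estimates are far more reliable than
lateral ones, the default fidelity weights trust the axial component about
100x more (lambda1 = 100, lambda2 = 1): the divergence term then corrects
mostly the lateral component.

Invalid pixels get zero fidelity weight, so the solution inpaints them from
the incompressibility coupling; a tiny diagonal tie-break regularization on
those pixels keeps the system positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import DisplacementField

__all__ = ["DenoiseParams", "divergence", "regularize", "energy", "divergence_operator"]


@dataclass
class DenoiseParams:
    lambda1: float = 100.0  # axial fidelity weight
    lambda2: float = 1.0  # lateral fidelity weight
    solver_tolerance: float = 1.0e-8
    max_iterations: int = 5000

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("regularization constants must be positive")


def _d1(n: int, h: float) -> sp.csr_matrix:
    """1D first-derivative matrix: central interior, one-sided at the ends."""
    if n < 3:
        raise ValueError("grid must have at least 3 points along each axis")
    D = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        D[i, i - 1] = -0.5 / h
        D[i, i + 1] = 0.5 / h
    D[0, 0], D[0, 1] = -1.0 / h, 1.0 / h
    D[n - 1, n - 2], D[n - 1, n - 1] = -1.0 / h, 1.0 / h
    return D.tocsr()


def divergence_operator(shape: Tuple[int, int], spacing: Tuple[float, float]):
    """Sparse operators (Du, Dv) with div = Du @ u.ravel() + Dv @ v.ravel()."""
    ny, nx = shape
    sy, sx = spacing
    Dy = _d1(ny, sy)
    Dx = _d1(nx, sx)
    Du = sp.kron(Dy, sp.eye(nx), format="csr")  # d u_axial / d axial
    Dv = sp.kron(sp.eye(ny), Dx, format="csr")  # d v_lateral / d lateral
    return Du, Dv


def divergence(field: DisplacementField) -> np.ndarray:
    """Physical divergence of the displacement field on its grid.

    Central differences in the interior, one-sided differences on the
    edges (consistent with the natural boundary conditions of the
    regularizer's variational problem).
    """
    ny, nx = field.shape
    if ny < 3 or nx < 3:
        raise ValueError("divergence requires a grid of at least 3x3")
    Du, Dv = divergence_operator(field.shape, field.grid_spacing_mm)
    div = Du @ field.u_axial.ravel() + Dv @ field.v_lateral.ravel()
    return div.reshape(field.shape)


def energy(
    measured: DisplacementField, candidate: DisplacementField, params: DenoiseParams
) -> float:
    """Discrete regularization energy F(candidate) given the measured field."""
    if measured.shape != candidate.shape:
        raise ValueError("fields must share shape")
    sy, sx = measured.grid_spacing_mm
    cell = sy * sx
    div = divergence(candidate).ravel()
    w = measured.valid_mask.ravel().astype(float)
    du = (measured.u_axial - candidate.u_axial).ravel()
    dv = (measured.v_lateral - candidate.v_lateral).ravel()
    return float(
        cell
        * (
            np.sum(div**2)
            + params.lambda1 * np.sum(w * du**2)
            + params.lambda2 * np.sum(w * dv**2)
        )
    )


def regularize(measured: DisplacementField, params: DenoiseParams) -> DisplacementField:
    """Minimize the incompressibility energy; returns the regularized field.

    The Euler-Lagrange equations of F are linear; the discrete normal
    equations (D^T D + diag(lambda w)) z = diag(lambda w) z_meas are
    symmetric positive definite and solved directly on small grids, by
    preconditioned conjugate gradients on large ones.
    """
    ny, nx = measured.shape
    if ny < 3 or nx < 3:
        raise ValueError("regularize requires a grid of at least 3x3")
    n = ny * nx
    Du, Dv = divergence_operator(measured.shape, measured.grid_spacing_mm)
    D = sp.hstack([Du, Dv], format="csr")  # (n, 2n)

    w = measured.valid_mask.ravel().astype(float)
    lam = np.concatenate([params.lambda1 * w, params.lambda2 * w])
    # tie-break on zero-fidelity (invalid) dofs only: keeps A positive definite
    eps = 1.0e-10 * max(params.lambda1, params.lambda2)
    lam_reg = lam + eps * (lam == 0.0)

    z_meas = np.concatenate([measured.u_axial.ravel(), measured.v_lateral.ravel()])
    z_meas = np.where(np.concatenate([w, w]) > 0, z_meas, 0.0)

    A = (D.T @ D + sp.diags(lam_reg)).tocsr()
    rhs = lam * z_meas

    if 2 * n <= 40_000:
        z = spla.spsolve(A.tocsc(), rhs)
    else:
        M = sp.diags(1.0 / A.diagonal())
        z, info = spla.cg(
            A, rhs, rtol=params.solver_tolerance, maxiter=params.max_iterations, M=M
        )
        if info > 0:
            res = float(np.linalg.norm(A @ z - rhs) / max(np.linalg.norm(rhs), 1e-300))
            raise RuntimeError(
                f"regularize did not converge in {params.max_iterations} iterations "
                f"(relative residual {res:.3e})"
            )
    u = z[:n].reshape(ny, nx)
    v = z[n:].reshape(ny, nx)
    return DisplacementField(
        u_axial=u,
        v_lateral=v,
        grid_spacing_mm=measured.grid_spacing_mm,
        origin_mm=measured.origin_mm,
        valid_mask=measured.valid_mask.copy(),
        state="regularized",
        quality=None if measured.quality is None else measured.quality.copy(),
    )
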