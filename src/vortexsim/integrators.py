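"""Time integration: forward-Euler and Crank-Nicolson diffusion steps and
the coupled model stepper.

The Crank-Nicolson relation for psi = phi^k reads, per node,

    (phi_i' - phi_i)/dt = D/4 [ sum_j w_ij (psi_j + psi_i)(phi_j - phi_i)
                              + sum_j w_ij (psi_j' + psi_i')(phi_j' - phi_i') ]

(primes denote the new time level).  For k = 0 this is a sparse linear
system solved directly; for k = 1 it is solved by the lagged-coefficient
splitting

    [I - (D dt/4) W diag(V) + (D dt/4) Z diag(V)] Phi' = rhs(Phi)

iterated with Gauss-Seidel sweeps (node-index order) from the initial guess
V = Phi, updating V with each new iterate until the successive-iterate
max-norm change drops below tolerance.

Reaction and advection terms are always advanced explicitly; only the
self-diffusion terms go through the implicit machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve_triangular

from .mesh import VRLMesh
from .operators import Field, divergence_values

__all__ = [
    "IntegratorConfig",
    "SystemMatrices",
    "IterationReport",
    "fe_diffusion_step",
    "cn_diffusion_step",
    "step_model",
]


@dataclass(frozen=True)
class IntegratorConfig:
    dt: float = 0.001
    scheme: Literal["forward_euler", "crank_nicolson"] = "forward_euler"
    gs_tol: float = 1e-9
    gs_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.dt < 0:
            raise ValueError("dt must be non-negative")
        if self.gs_tol <= 0:
            raise ValueError("gs_tol must be positive")
        if self.scheme not in ("forward_euler", "crank_nicolson"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class IterationReport:
    iterations: int
    residual: float
    converged: bool


class GaussSeidelError(RuntimeError):
    """Raised when the splitting iteration exceeds its sweep cap."""

    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"Gauss-Seidel splitting did not converge in {iterations} sweeps "
            f"(last successive-iterate change {residual:.3e}); "
            "reduce dt or inspect the mesh"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass
class SystemMatrices:
    """Sparse weighted adjacency W (W_ij = w_ij for natural neighbors) and
    the diagonal Z with Z_ii = sum_j w_ij."""

    W: sp.csr_matrix
    Z: sp.dia_matrix
    mesh: VRLMesh = field(repr=False, default=None)

    @classmethod
    def from_mesh(cls, mesh: VRLMesh) -> "SystemMatrices":
        mesh._require_geometry()
        n = mesh.n_nodes
        i, j = mesh.edges[:, 0], mesh.edges[:, 1]
        w_ij, w_ji = mesh.weights()
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.concatenate([w_ij, w_ji])
        W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        Z = sp.diags(np.asarray(W.sum(axis=1)).ravel())
        return cls(W=W, Z=Z, mesh=mesh)

    @property
    def laplacian_matrix(self) -> sp.csr_matrix:
        """L = W - Z, so (L phi)_i = sum_j w_ij (phi_j - phi_i)."""
        return (self.W - self.Z).tocsr()


_matrix_cache: dict[int, SystemMatrices] = {}


def system_matrices(mesh: VRLMesh) -> SystemMatrices:
    key = id(mesh)
    if key not in _matrix_cache:
        _matrix_cache.clear()  # hold at most one mesh
        _matrix_cache[key] = SystemMatrices.from_mesh(mesh)
    return _matrix_cache[key]


def fe_diffusion_step(phi: Field, k: int, D: float, dt: float) -> Field:
    """phi' = phi + dt * D * div[phi^k grad phi] (explicit)."""
    mesh = phi.mesh
    psi = _power(phi.values, k)
    new = phi.values + dt * D * divergence_values(mesh, phi.values, psi)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            f"forward-Euler diffusion of '{phi.name}' produced non-finite values "
            f"(dt={dt}, D={D}, k={k}): reduce dt"
        )
    return Field(new, mesh, phi.name)


def _power(values: np.ndarray, k) -> np.ndarray:
    """phi^k with the convention 0^0 = 1 (k = 0 means linear diffusion)."""
    if np.ndim(k) == 0:
        if k == 0:
            return np.ones_like(values)
        if k == 1:
            return values
        return values**k
    return np.power(values, k)  # per-node exponents; np.power(0., 0.) == 1.


def cn_diffusion_step(
    phi: Field, k: int, D: float, dt: float, cfg: IntegratorConfig | None = None
) -> tuple[Field, IterationReport]:
    """One Crank-Nicolson diffusion step.

    k = 0 solves the (sparse, symmetric) linear system directly; k = 1 uses
    the Gauss-Seidel-swept lagged-coefficient splitting with initial guess
    V = phi^n.
    """
    if cfg is None:
        cfg = IntegratorConfig(dt=dt, scheme="crank_nicolson")
    if k not in (0, 1):
        raise ValueError("Crank-Nicolson step supports k in {0, 1}")
    mesh = phi.mesh
    if dt == 0:
        return phi.copy(), IterationReport(iterations=1, residual=0.0, converged=True)
    mats = system_matrices(mesh)
    L = mats.laplacian_matrix

    if k == 0:
        c = 0.5 * D * dt
        A = (sp.identity(mesh.n_nodes, format="csr") - c * L).tocsc()
        rhs = phi.values + c * (L @ phi.values)
        new = splu(A).solve(rhs)
        rep = IterationReport(iterations=1, residual=0.0, converged=True)
        return Field(new, mesh, phi.name), rep

    c = 0.25 * D * dt
    W, Z = mats.W, mats.Z
    phin = phi.values
    z = Z.diagonal()
    # explicit side: [I + c W diag(phi) - c Z diag(phi)] phi  (phi2 = phi^2)
    phi2 = phin * phin
    rhs = phin + c * (W @ phi2) - c * (z * phi2)

    v = phin.copy()
    new = phin.copy()
    for it in range(1, cfg.gs_max_iter + 1):
        # linear system A(v) x = rhs with A = I + c diag(z*v) - c W diag(v);
        # one Gauss-Seidel sweep in node order == forward solve with the
        # lower triangle of A applied to (rhs - U x).
        Av = sp.identity(mesh.n_nodes, format="csr") + sp.diags(c * z * v) - c * (W @ sp.diags(v))
        Av = Av.tocsr()
        lower = sp.tril(Av, k=0, format="csr")
        upper = Av - lower
        new = spsolve_triangular(lower, rhs - upper @ new, lower=True)
        change = float(np.max(np.abs(new - v)))
        v = new.copy()
        if change < cfg.gs_tol:
            return Field(new, mesh, phi.name), IterationReport(it, change, True)
    raise GaussSeidelError(cfg.gs_max_iter, change)


def cn_residual(mesh: VRLMesh, phi_old: np.ndarray, phi_new: np.ndarray, k: int, D: float, dt: float) -> np.ndarray:
    """Residual of the Crank-Nicolson relation (zero at the exact solution)."""
    d_old = divergence_values(mesh, phi_old, _power(phi_old, k))
    d_new = divergence_values(mesh, phi_new, _power(phi_new, k))
    return phi_new - phi_old - 0.5 * dt * D * (d_old + d_new)


def step_model(state, params, cfg: IntegratorConfig, phase_cfg=None):
    """Advance a ModelState by one time step.

    Implemented in :mod:`vortexsim.biology` terms: diffusion/advection and
    reactions from the model right-hand side, explicit dead-mass
    accumulation, negativity clipping, then the phase update.  Defined here
    to keep the time-stepping contract in one place; delegates to
    :func:`vortexsim.biology.advance`.
    """
    from .biology import advance

    return advance(state, params, cfg, phase_cfg)
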