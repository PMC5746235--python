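"""Finite-volume spatial operators on a VRL mesh.

All operators are assembled from the two-point edge flux

    J (into i, through face ij) = 1/2 * (f_ij/l_ij) * (psi_i + psi_j) * (phi_j - phi_i)

which is antisymmetric in (i, j), so every divergence built from it
conserves the area-weighted total of phi exactly.  Faces produced by
clipping Voronoi cells to the domain rectangle carry zero flux; that is the
entire no-flux boundary treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import VRLMesh

__all__ = [
    "Field",
    "EdgeFlux",
    "nonlinear_divergence",
    "laplacian",
    "edge_fluxes_fe",
    "total_mass",
]


@dataclass
class Field:
    """One real value per mesh node."""

    values: np.ndarray
    mesh: VRLMesh
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_nodes,):
            raise ValueError(
                f"field '{self.name}': expected {self.mesh.n_nodes} values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field '{self.name}' contains non-finite values")

    @classmethod
    def full(cls, mesh: VRLMesh, value: float, name: str = "") -> "Field":
        return cls(np.full(mesh.n_nodes, float(value)), mesh, name)

    @classmethod
    def from_function(cls, mesh: VRLMesh, fn, name: str = "") -> "Field":
        return cls(fn(mesh.nodes[:, 0], mesh.nodes[:, 1]), mesh, name)

    def copy(self) -> "Field":
        return Field(self.values.copy(), self.mesh, self.name)


@dataclass
class EdgeFlux:
    """Directed fluxes per mesh edge row (i, j).

    ``into_first[e]`` is the flux into node ``edges[e, 0]`` (per unit area of
    that cell), ``into_second[e]`` the flux into ``edges[e, 1]``.  The raw,
    area-free face flux ``raw`` satisfies
    ``A_i * into_first = raw = -A_j * into_second``.
    """

    mesh: VRLMesh
    raw: np.ndarray
    into_first: np.ndarray
    into_second: np.ndarray

    def divergence(self) -> np.ndarray:
        """Sum incoming fluxes per node (equals nonlinear_divergence)."""
        n = self.mesh.n_nodes
        i, j = self.mesh.edges[:, 0], self.mesh.edges[:, 1]
        return np.bincount(i, self.into_first, n) + np.bincount(j, self.into_second, n)


def _check_same_mesh(*fields: Field) -> VRLMesh:
    mesh = fields[0].mesh
    for f in fields[1:]:
        if f.mesh is not mesh:
            raise ValueError("fields live on different meshes")
    mesh._require_geometry()
    return mesh


def _raw_edge_fluxes(mesh: VRLMesh, phi: np.ndarray, psi: np.ndarray | None) -> np.ndarray:
    i, j, fl = mesh.edge_arrays()
    d = phi[j] - phi[i]
    if psi is None:  # psi identically 1: (psi_i + psi_j)/2 == 1
        return fl * d
    return 0.5 * fl * (psi[i] + psi[j]) * d


def divergence_values(
    mesh: VRLMesh, phi: np.ndarray, psi: np.ndarray | None
) -> np.ndarray:
    """Array-level core of :func:`nonlinear_divergence` (hot path).

    ``psi=None`` means psi identically 1 (plain Laplacian).
    """
    raw = _raw_edge_fluxes(mesh, phi, psi)
    i, j, _ = mesh.edge_arrays()
    n = mesh.n_nodes
    return (np.bincount(i, raw, n) - np.bincount(j, raw, n)) / mesh.A


def nonlinear_divergence(phi: Field, psi: Field) -> Field:
    """Discrete div[psi grad(phi)]:

        1/2 * sum_{j in nbr(i)} w_ij (psi_j + psi_i)(phi_j - phi_i)
    """
    mesh = _check_same_mesh(phi, psi)
    out = divergence_values(mesh, phi.values, psi.values)
    return Field(out, mesh, f"div[{psi.name} grad {phi.name}]")


def laplacian(phi: Field) -> Field:
    """Discrete Laplacian: sum_j w_ij (phi_j - phi_i).

    Identical to ``nonlinear_divergence(phi, 1)``.
    """
    mesh = _check_same_mesh(phi)
    out = divergence_values(mesh, phi.values, None)
    return Field(out, mesh, f"lap {phi.name}")


def edge_fluxes_fe(phi: Field, psi: Field) -> EdgeFlux:
    """Forward-Euler edge fluxes; skew-symmetric by construction."""
    mesh = _check_same_mesh(phi, psi)
    raw = _raw_edge_fluxes(mesh, phi.values, psi.values)
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    return EdgeFlux(mesh, raw, raw / mesh.A[i], -raw / mesh.A[j])


def total_mass(phi: Field) -> float:
    """Area-weighted total, sum_i A_i * phi_i."""
    mesh = _check_same_mesh(phi)
    return float(np.dot(mesh.A, phi.values))
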