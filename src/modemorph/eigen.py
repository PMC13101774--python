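"""Laplace-Beltrami eigenmodes of a triangulated surface.

The geometric eigenmodes are the solutions of the Helmholtz equation
``Δψ = −λψ`` on the surface.  We discretize Δ with the standard cotangent
stiffness matrix and a lumped (barycentric) diagonal mass matrix, and solve
the generalized symmetric eigenproblem ``A ψ = λ M ψ`` for the smallest
eigenpairs via shift-invert Lanczos.  The modes form a mass-orthonormal basis
ordered from coarse (low λ) to fine (high λ) spatial scales; mode 1 is the
constant function with λ = 0.

Modes are numbered 1-based in all public structures, matching field usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TriangleMesh, vertex_areas

logger = logging.getLogger(__name__)

__all__ = [
    "EigenmodeBasis",
    "EigensolverError",
    "assemble_operators",
    "compute_eigenmodes",
    "eigengroup_partition",
    "eigengroup_sizes",
    "align_mode_signs",
    "save_basis",
    "load_basis",
]


class EigensolverError(RuntimeError):
    """The sparse eigensolver failed to converge."""


def assemble_operators(mesh: TriangleMesh) -> tuple[sp.csr_matrix, np.ndarray]:
    """Cotangent stiffness matrix and lumped mass weights.

    The stiffness matrix ``A`` is symmetric positive semidefinite with zero
    row sums; the off-diagonal entry for edge (i, j) is ``−(cot α + cot β)/2``
    over the two angles opposite the edge.  The mass weights are the
    barycentric vertex areas in mm^2.
    """
    V, F = mesh.vertices, mesh.faces
    n = mesh.n_vertices

    rows, cols, vals = [], [], []
    # angle at corner c is opposite the edge (a, b)
    for c, a, b in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        u = V[F[:, a]] - V[F[:, c]]
        v = V[F[:, b]] - V[F[:, c]]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        if np.any(cross <= 0):
            raise ValueError("degenerate (zero-area) triangle in mesh")
        cot = np.einsum("ij,ij->i", u, v) / cross
        w = 0.5 * cot
        rows.extend([F[:, a], F[:, b]])
        cols.extend([F[:, b], F[:, a]])
        vals.extend([-w, -w])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A - sp.diags(np.asarray(A.sum(axis=1)).ravel())
    mass = vertex_areas(mesh)
    return A.tocsr(), mass


def eigengroup_partition(n_modes: int) -> np.ndarray:
    """Eigengroup label of each of the first ``n_modes`` modes.

    Group 0 is the constant mode alone; group g >= 1 has 2g + 1 members,
    mirroring the spherical-harmonic degree multiplicities.  The final group
    may be truncated.  Returns an int array of length ``n_modes`` where entry
    k is the group of mode k+1.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    labels = np.empty(n_modes, dtype=np.int64)
    labels[0] = 0
    pos, g = 1, 1
    while pos < n_modes:
        size = 2 * g + 1
        labels[pos : pos + size] = g
        pos += size
        g += 1
    return labels


def eigengroup_sizes(n_groups: int) -> list[int]:
    """Sizes [1, 3, 5, ...] of group 0 through ``n_groups``."""
    return [1] + [2 * g + 1 for g in range(1, n_groups + 1)]


@dataclass
class EigenmodeBasis:
    """Mass-orthonormal eigenmodes ψ (columns of ``modes``) with eigenvalues λ.

    Attributes
    ----------
    mesh
        The surface the modes were computed on.
    modes
        (n_vertices, K) array; column k is mode k+1.
    eigenvalues
        (K,) ascending eigenvalues, units 1/mm^2; λ₁ = 0 (constant mode).
    mass
        (n_vertices,) lumped vertex areas defining the orthonormality inner
        product ``ψ_i^T diag(mass) ψ_j = δ_ij``.
    """

    mesh: TriangleMesh
    modes: np.ndarray
    eigenvalues: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.modes.shape != (self.mesh.n_vertices, len(self.eigenvalues)):
            raise ValueError("modes array shape does not match mesh/eigenvalue count")
        if np.any(np.diff(self.eigenvalues) < 0):
            raise ValueError("eigenvalues must be ascending")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def group_labels(self) -> np.ndarray:
        return eigengroup_partition(self.n_modes)

    def gram(self) -> np.ndarray:
        """Mass-weighted Gram matrix (identity for an orthonormal basis)."""
        return self.modes.T @ (self.mass[:, None] * self.modes)

    def truncated(self, n_modes: int) -> "EigenmodeBasis":
        if not 1 <= n_modes <= self.n_modes:
            raise ValueError(f"n_modes must be in [1, {self.n_modes}]")
        return EigenmodeBasis(
            mesh=self.mesh,
            modes=self.modes[:, :n_modes],
            eigenvalues=self.eigenvalues[:n_modes],
            mass=self.mass,
        )


def _canonical_signs(modes: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|value| vertex is positive.

    ``argmax`` returns the first maximum, so ties break on the lowest vertex
    index.
    """
    out = modes.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        peak = col[np.argmax(np.abs(col))]
        if peak < 0:
            out[:, k] = -col
    return out


def compute_eigenmodes(mesh: TriangleMesh, n_modes: int, seed: int = 0) -> EigenmodeBasis:
    """Smallest ``n_modes`` eigenpairs of the surface Laplace-Beltrami operator.

    Solves ``A ψ = λ M ψ`` (cotangent stiffness, lumped mass) by reducing to a
    standard symmetric problem through the diagonal mass and running
    shift-invert Lanczos near zero with a deterministic start vector, so the
    spectrum is reproducible.  λ₁ is clamped to exactly 0 when it is
    numerically zero relative to λ₂, and every mode's sign follows the
    canonical largest-|value|-positive rule.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes >= mesh.n_vertices:
        raise ValueError(
            f"n_modes ({n_modes}) must be smaller than the vertex count ({mesh.n_vertices})"
        )
    A, mass = assemble_operators(mesh)
    inv_sqrt_m = 1.0 / np.sqrt(mass)
    Dm = sp.diags(inv_sqrt_m)
    B = (Dm @ A @ Dm).tocsc()

    # shift slightly negative so B - sigma*I is positive definite and the
    # shift-invert spectrum targets the smallest eigenvalues
    sigma = -1e-4 * float(B.diagonal().mean())
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(mesh.n_vertices)
    try:
        lam, U = spla.eigsh(B, k=n_modes, sigma=sigma, which="LM", v0=v0)
    except spla.ArpackNoConvergence as exc:  # pragma: no cover - rare
        raise EigensolverError(
            f"eigensolver converged only {len(exc.eigenvalues)}/{n_modes} modes "
            f"on mesh with {mesh.n_vertices} vertices"
        ) from exc

    order = np.argsort(lam)
    lam = lam[order]
    U = U[:, order]
    if n_modes >= 2 and abs(lam[0]) < 1e-8 * abs(lam[1]):
        lam[0] = 0.0
    modes = inv_sqrt_m[:, None] * U
    modes = _canonical_signs(modes)
    return EigenmodeBasis(mesh=mesh, modes=modes, eigenvalues=lam, mass=mass)


def align_mode_signs(basis: EigenmodeBasis, reference: EigenmodeBasis | None = None) -> EigenmodeBasis:
    """Resolve the arbitrary sign of each eigenvector.

    With a ``reference`` basis (same mode count and mesh topology), each mode
    is flipped so its mass-weighted inner product with the reference mode is
    non-negative; a numerically zero inner product falls back to the canonical
    rule for that mode and logs a warning.  Without a reference, the canonical
    rule (largest-|value| vertex positive, ties to the lowest index) applies.
    """
    if reference is None:
        modes = _canonical_signs(basis.modes)
    else:
        if reference.n_modes != basis.n_modes:
            raise ValueError("reference basis must have the same mode count")
        if reference.mesh.n_vertices != basis.mesh.n_vertices:
            raise ValueError("reference basis must share the mesh topology")
        inner = np.einsum(
            "vk,vk->k", basis.modes, basis.mass[:, None] * reference.modes
        )
        modes = basis.modes.copy()
        scale = np.einsum("vk,vk->k", basis.modes, basis.mass[:, None] * basis.modes)
        for k in range(basis.n_modes):
            if abs(inner[k]) < 1e-12 * scale[k]:
                logger.warning(
                    "mode %d has zero inner product with reference; using canonical sign",
                    k + 1,
                )
                modes[:, k : k + 1] = _canonical_signs(modes[:, k : k + 1])
            elif inner[k] < 0:
                modes[:, k] = -modes[:, k]
    return EigenmodeBasis(
        mesh=basis.mesh, modes=modes, eigenvalues=basis.eigenvalues, mass=basis.mass
    )


def save_basis(basis: EigenmodeBasis, directory: str | Path) -> Path:
    """Persist a basis as ``eigenvalues.csv`` (mode, lambda, group),
    ``modes.csv`` (vertex rows, mode_<k> columns) and ``mass.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "mode": np.arange(1, basis.n_modes + 1),
            "lambda": basis.eigenvalues,
            "group": basis.group_labels(),
        }
    ).to_csv(directory / "eigenvalues.csv", index=False)
    cols = {f"mode_{k + 1}": basis.modes[:, k] for k in range(basis.n_modes)}
    pd.DataFrame(cols).to_csv(directory / "modes.csv", index=False, float_format="%.17g")
    pd.DataFrame({"mass": basis.mass}).to_csv(
        directory / "mass.csv", index=False, float_format="%.17g"
    )
    return directory


def load_basis(directory: str | Path, mesh: TriangleMesh) -> EigenmodeBasis:
    directory = Path(directory)
    ev = pd.read_csv(directory / "eigenvalues.csv", float_precision="round_trip")
    modes = pd.read_csv(directory / "modes.csv", float_precision="round_trip").to_numpy()
    mass = pd.read_csv(directory / "mass.csv", float_precision="round_trip")["mass"].to_numpy()
    return EigenmodeBasis(
        mesh=mesh, modes=modes, eigenvalues=ev["lambda"].to_numpy(), mass=mass
    )
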