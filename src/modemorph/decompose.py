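"""Modal decomposition: project per-vertex maps onto eigenmodes and back.

A map ``f`` restricted to the cortex mask is approximated as
``f ≈ Σ_k β_k ψ_k`` by unweighted least squares over the masked-in vertices.
The β coefficients (units of the source map) are the quantities all group
inference and asymmetry indices operate on.  Because the mask breaks the
mass-orthogonality of the modes, a truncated projection refits all retained
columns jointly rather than slicing a longer fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigen import EigenmodeBasis, eigengroup_partition
from .mesh import SurfaceMap

logger = logging.getLogger(__name__)

__all__ = [
    "ModalCoefficients",
    "RankDeficientError",
    "project_map",
    "reconstruct_map",
    "beta_spectrum_table",
]


class RankDeficientError(ValueError):
    """The masked design matrix is rank deficient."""


@dataclass
class ModalCoefficients:
    """Modal loading coefficients β₁…β_K for one map on one basis."""

    betas: np.ndarray
    basis: EigenmodeBasis = field(repr=False)
    source: str | None = None
    mask_id: str | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=np.float64).ravel()
        if len(self.betas) > self.basis.n_modes:
            raise ValueError("more coefficients than basis modes")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("coefficients must be finite")

    @property
    def n_modes(self) -> int:
        return len(self.betas)

    def beta(self, mode: int) -> float:
        """Coefficient of 1-based ``mode``."""
        if not 1 <= mode <= self.n_modes:
            raise IndexError(f"mode {mode} outside 1..{self.n_modes}")
        return float(self.betas[mode - 1])


def project_map(
    basis: EigenmodeBasis, smap: SurfaceMap, n_modes: int | None = None
) -> ModalCoefficients:
    """Least-squares β fitting ``smap`` over its masked-in vertices.

    All ``n_modes`` columns are fitted jointly (default: every basis mode).
    Raises :class:`RankDeficientError`, reporting the condition number, when
    the mask leaves too few or degenerate rows.
    """
    if smap.n_vertices != basis.mesh.n_vertices:
        raise ValueError("map and basis must share the mesh")
    k = basis.n_modes if n_modes is None else int(n_modes)
    if not 1 <= k <= basis.n_modes:
        raise ValueError(f"n_modes must be in [1, {basis.n_modes}]")
    mask = smap.mask
    n_in = int(mask.sum())
    if n_in < k:
        raise RankDeficientError(
            f"masked-in vertex count ({n_in}) is smaller than n_modes ({k})"
        )
    design = basis.modes[mask, :k]
    beta, _, rank, sv = np.linalg.lstsq(design, smap.values[mask], rcond=None)
    if rank < k:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        raise RankDeficientError(
            f"masked design is rank deficient (rank {rank} < {k}, "
            f"condition number {cond:.3g})"
        )
    return ModalCoefficients(
        betas=beta, basis=basis, source=smap.name, mask_id=smap.name
    )


def reconstruct_map(
    basis: EigenmodeBasis,
    coefficients: ModalCoefficients,
    mode_subset: list[int] | np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> SurfaceMap:
    """Map with values ``Σ_{k in subset} β_k ψ_k`` at every vertex.

    ``mode_subset`` holds 1-based mode numbers; by default every fitted mode
    contributes.  The mask (default: all vertices) is passed through
    unchanged.  An empty subset returns a zero map with a logged warning.
    """
    if coefficients.basis is not basis and coefficients.n_modes > basis.n_modes:
        raise ValueError("coefficients do not fit the given basis")
    if mode_subset is None:
        idx = np.arange(coefficients.n_modes)
    else:
        idx = np.asarray(mode_subset, dtype=np.int64).ravel() - 1
        if idx.size and (idx.min() < 0 or idx.max() >= coefficients.n_modes):
            raise ValueError("mode_subset outside fitted mode range")
    if mask is None:
        mask = np.ones(basis.mesh.n_vertices, bool)
    if idx.size == 0:
        logger.warning("reconstruct_map called with an empty mode subset; returning zero map")
        values = np.zeros(basis.mesh.n_vertices)
    else:
        values = basis.modes[:, idx] @ coefficients.betas[idx]
    return SurfaceMap(values=values, mask=mask, mesh=basis.mesh, name="reconstruction")


def beta_spectrum_table(
    coefficient_sets: dict[str, ModalCoefficients] | list[ModalCoefficients] | ModalCoefficients,
) -> pd.DataFrame:
    """Tidy β spectrum: one row per (set, mode), sorted by mode index.

    Columns: ``label, mode, group, beta, abs_rank`` where ``abs_rank`` orders
    modes by descending |β| within each set (1 = most influential; ties break
    toward the lower mode index).  All sets must share one basis.
    """
    if isinstance(coefficient_sets, ModalCoefficients):
        coefficient_sets = {"map": coefficient_sets}
    elif isinstance(coefficient_sets, list):
        coefficient_sets = {
            c.source or f"map{i}": c for i, c in enumerate(coefficient_sets)
        }
    if not coefficient_sets:
        return pd.DataFrame(columns=["label", "mode", "group", "beta", "abs_rank"])
    bases = {id(c.basis) for c in coefficient_sets.values()}
    if len(bases) > 1:
        raise ValueError("all coefficient sets must share the same basis")
    frames = []
    for label, c in coefficient_sets.items():
        modes = np.arange(1, c.n_modes + 1)
        order = np.lexsort((modes, -np.abs(c.betas)))
        rank = np.empty(c.n_modes, dtype=np.int64)
        rank[order] = np.arange(1, c.n_modes + 1)
        frames.append(
            pd.DataFrame(
                {
                    "label": label,
                    "mode": modes,
                    "group": eigengroup_partition(c.n_modes),
                    "beta": c.betas,
                    "abs_rank": rank,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
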