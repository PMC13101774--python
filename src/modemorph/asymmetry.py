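"""Hemispheric asymmetry indices.

Two per-subject indices of interhemispheric asymmetry of cortical thickness:

* **SBM-AI** — the conventional normalized mean-thickness difference within a
  symmetric bilateral region of interest,
  ``AI = (CT_RH − CT_LH) / (0.5 (CT_RH + CT_LH))``.  A perfectly symmetric
  brain gives 0.  The similarity transform ``1 − |AI|`` maps it onto the
  "1 = symmetric" scale used for group comparisons.
* **MBM-AI** — the absolute Pearson correlation between the hemispheres' modal
  coefficient vectors over the first N modes (default 25 = the constant mode
  plus eigengroups 1-4).  1 means identical multiscale thickness profiles;
  lower values mean greater asymmetry.

Both hemispheres are assumed to live on one shared template topology, so
homotopic correspondence is vertex-index identity and one (sign-aligned)
eigenmode basis serves both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import project_map
from .eigen import EigenmodeBasis
from .mesh import SurfaceMap

logger = logging.getLogger(__name__)

__all__ = [
    "AsymmetryResult",
    "UndefinedAsymmetryError",
    "build_symmetric_mask",
    "sbm_ai",
    "mbm_ai",
    "asymmetry_table",
]


class UndefinedAsymmetryError(ValueError):
    """The asymmetry index is undefined for this input (empty mask, zero mean
    thickness, or zero-variance coefficient vector)."""


@dataclass(frozen=True)
class AsymmetryResult:
    """Per-subject asymmetry measurements."""

    subject: str
    sbm_ai_raw: float
    sbm_ai_similarity: float
    mbm_ai: float
    n_modes: int
    mask_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mbm_ai <= 1.0:
            raise ValueError("mbm_ai must lie in [0, 1]")
        if abs(self.sbm_ai_similarity - (1.0 - abs(self.sbm_ai_raw))) > 1e-12:
            raise ValueError("sbm_ai_similarity must equal 1 - |sbm_ai_raw|")


def build_symmetric_mask(
    significance_map: SurfaceMap, p_threshold: float = 0.05
) -> tuple[SurfaceMap, SurfaceMap]:
    """Symmetric bilateral ROI from a dominant-hemisphere p-value map.

    The dominant-hemisphere map is binarized at ``p < p_threshold`` and the
    identical vertex-index set is applied to the contralateral hemisphere
    (homotopic identity on the shared template).  Returns
    (dominant mask, contralateral mask); raises
    :class:`UndefinedAsymmetryError` if thresholding leaves no vertex.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    binary = (significance_map.values < p_threshold) & significance_map.mask
    if not binary.any():
        raise UndefinedAsymmetryError(
            f"no vertex survives p < {p_threshold}; asymmetry index undefined"
        )
    dom = SurfaceMap(
        values=binary.astype(float),
        mask=significance_map.mask,
        mesh=significance_map.mesh,
        name="bilateral_mask_dominant",
    )
    contra = SurfaceMap(
        values=binary.astype(float),
        mask=significance_map.mask,
        mesh=significance_map.mesh,
        name="bilateral_mask_contralateral",
    )
    return dom, contra


def sbm_ai(
    lh_map: SurfaceMap, rh_map: SurfaceMap, bilateral_mask: SurfaceMap
) -> tuple[float, float]:
    """Conventional asymmetry index within the symmetric bilateral ROI.

    Returns ``(raw, similarity)`` with
    ``raw = (mean_RH − mean_LH) / (0.5 (mean_RH + mean_LH))`` over ROI
    vertices and ``similarity = 1 − |raw|``.
    """
    if lh_map.n_vertices != rh_map.n_vertices != bilateral_mask.n_vertices:
        raise ValueError("maps and mask must share the template")
    roi = (bilateral_mask.values > 0) & lh_map.mask & rh_map.mask
    if not roi.any():
        raise UndefinedAsymmetryError("bilateral ROI is empty after masking")
    mean_lh = float(lh_map.values[roi].mean())
    mean_rh = float(rh_map.values[roi].mean())
    denom = 0.5 * (mean_rh + mean_lh)
    if denom == 0:
        raise UndefinedAsymmetryError("mean LH + RH thickness is zero; AI undefined")
    raw = (mean_rh - mean_lh) / denom
    return raw, 1.0 - abs(raw)


def mbm_ai(
    lh_map: SurfaceMap,
    rh_map: SurfaceMap,
    basis: EigenmodeBasis,
    n_modes: int = 25,
    include_constant: bool = True,
) -> float:
    """Eigenmode-correlation asymmetry index in [0, 1].

    Both hemisphere maps are projected (joint least squares) onto the first
    ``n_modes`` modes of the shared sign-aligned basis, and the absolute
    Pearson correlation of the two β vectors is returned.  The constant mode
    participates by default (set ``include_constant=False`` to drop β₁).
    """
    if n_modes < 3:
        raise ValueError("n_modes must be >= 3 for a meaningful correlation")
    beta_lh = project_map(basis, lh_map, n_modes=n_modes).betas
    beta_rh = project_map(basis, rh_map, n_modes=n_modes).betas
    if not include_constant:
        beta_lh, beta_rh = beta_lh[1:], beta_rh[1:]
    if np.std(beta_lh) == 0 or np.std(beta_rh) == 0:
        raise UndefinedAsymmetryError("zero-variance coefficient vector; correlation undefined")
    if np.array_equal(beta_lh, beta_rh):
        return 1.0  # identical profiles: exactly symmetric by definition
    r = float(np.corrcoef(beta_lh, beta_rh)[0, 1])
    return min(abs(r), 1.0)


def asymmetry_table(
    cohort_maps: dict[str, tuple[SurfaceMap | None, SurfaceMap | None]],
    basis: EigenmodeBasis,
    bilateral_mask: SurfaceMap,
    n_modes: int = 25,
    include_constant: bool = True,
) -> pd.DataFrame:
    """Per-subject asymmetry indices for a cohort.

    ``cohort_maps`` maps subject id to (LH map, RH map); subjects missing a
    hemisphere are skipped with a logged warning.  Rows are ordered by subject
    id.  Columns: ``subject, sbm_ai_raw, sbm_ai_similarity, mbm_ai, n_modes,
    mask_id``.
    """
    rows = []
    for subject in sorted(cohort_maps):
        lh, rh = cohort_maps[subject]
        if lh is None or rh is None:
            logger.warning("subject %s is missing a hemisphere map; skipped", subject)
            continue
        raw, sim = sbm_ai(lh, rh, bilateral_mask)
        ai = mbm_ai(lh, rh, basis, n_modes=n_modes, include_constant=include_constant)
        res = AsymmetryResult(
            subject=subject,
            sbm_ai_raw=raw,
            sbm_ai_similarity=sim,
            mbm_ai=ai,
            n_modes=n_modes,
            mask_id=bilateral_mask.name,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(
        rows,
        columns=["subject", "sbm_ai_raw", "sbm_ai_similarity", "mbm_ai", "n_modes", "mask_id"],
    )
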