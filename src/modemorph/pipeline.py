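"""End-to-end analysis pipeline.

Runs every stage of the mode-based morphometry workflow on a cohort:
eigenmode basis → per-contrast permutation mode tests (symptomatic vs HC and
presymptomatic vs HC, both hemispheres) → symmetric bilateral mask from the
symptomatic-vs-HC dominant-hemisphere map → per-subject asymmetry indices →
non-parametric group statistics of the indices (by group and by CDR stage) →
Spearman correlations of the indices with TMT in symptomatic subjects →
mode-wise OLS linking significant-mode weights to clinical scores.

All randomness flows from one master seed; a manifest records the config, the
seed, and a content hash of every written output so a rerun can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import UndefinedAsymmetryError, asymmetry_table, build_symmetric_mask
from .decompose import project_map
from .eigen import compute_eigenmodes
from .inference import mbm_group_test, vertex_tmap
from .io import write_scalar_csv
from .mesh import SurfaceMap
from .simulate import CohortDataset
from .stats import group_test_report, modewise_glm, spearman_correlation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; defaults follow the emulated study protocol."""

    n_modes: int = 150
    ai_n_modes: int = 25
    n_perm: int = 10000
    alpha: float = 0.05
    vertex_p: float = 0.001
    mask_p: float = 0.05
    cluster_area: float = 100.0  # mm^2
    seed: int = 0
    dominant_hemisphere: str = "lh"

    def __post_init__(self) -> None:
        for name in ("alpha", "vertex_p", "mask_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_modes < 1 or self.ai_n_modes < 1:
            raise ValueError("mode counts must be >= 1")

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def _contrast_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def run_full_pipeline(
    cohort: CohortDataset,
    config: PipelineConfig,
    output_dir: str | Path,
) -> dict:
    """Run the complete analysis on ``cohort`` and write all outputs.

    Returns the manifest dict (also written as ``manifest.json``).  Idempotent
    for a fixed config and cohort: rerunning reproduces identical outputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    clinical = cohort.clinical

    n_modes = min(config.n_modes, cohort.basis.n_modes)
    if n_modes < config.n_modes:
        logger.info(
            "basis provides %d modes; using those instead of the configured %d",
            n_modes,
            config.n_modes,
        )
    basis = cohort.basis

    # --- per-contrast mode tests -----------------------------------------
    contrasts = {}
    contrast_specs = [
        ("symptomatic_vs_hc", "symptomatic"),
        ("presymptomatic_vs_hc", "presymptomatic"),
    ]
    idx = 0
    for cname, carrier_group in contrast_specs:
        for hemi in ("lh", "rh"):
            hc_maps = cohort.group_maps("HC", hemi)
            carrier_maps = cohort.group_maps(carrier_group, hemi)
            if len(hc_maps) < 2 or len(carrier_maps) < 2:
                raise PipelineError(
                    f"stage 'mode_test' failed: contrast {cname}/{hemi} "
                    "needs >= 2 subjects per group"
                )
            result = _stage("mode_test")(mbm_group_test)(
                hc_maps,
                carrier_maps,
                basis,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=_contrast_seed(config.seed, idx),
                n_modes=n_modes,
            )
            idx += 1
            contrasts[f"{cname}_{hemi}"] = result
            path = out / f"mode_test_{cname}_{hemi}.json"
            path.write_text(json.dumps(result.to_dict(), indent=1))
            written.append(path)
            written.append(write_scalar_csv(result.tmap, out / f"tmap_{cname}_{hemi}.csv"))

    # --- symmetric bilateral mask from the dominant-hemisphere contrast ---
    from scipy import stats as sps

    key = f"symptomatic_vs_hc_{config.dominant_hemisphere}"
    tmap = contrasts[key].tmap
    df = len(cohort.group_maps("HC")) + len(cohort.group_maps("symptomatic")) - 2
    p_values = np.ones(tmap.n_vertices)
    p_values[tmap.mask] = 2.0 * sps.t.sf(np.abs(tmap.values[tmap.mask]), df)
    p_map = SurfaceMap(values=p_values, mask=tmap.mask, mesh=tmap.mesh, name="p_" + key)
    try:
        dom_mask, _ = build_symmetric_mask(p_map, p_threshold=config.mask_p)
    except UndefinedAsymmetryError:
        logger.warning(
            "no vertex survives the mask threshold; falling back to the full cortex ROI"
        )
        dom_mask = SurfaceMap(
            values=tmap.mask.astype(float), mask=tmap.mask, mesh=tmap.mesh, name="full_cortex"
        )
    written.append(write_scalar_csv(dom_mask, out / "bilateral_mask.csv"))

    # --- per-subject asymmetry indices ------------------------------------
    ai = _stage("asymmetry")(asymmetry_table)(
        cohort.maps, basis, dom_mask, n_modes=min(config.ai_n_modes, n_modes)
    )
    ai = ai.merge(clinical, on="subject")
    ai_path = out / "asymmetry.csv"
    ai.to_csv(ai_path, index=False)
    written.append(ai_path)

    # --- group statistics of the indices ----------------------------------
    stats_report: dict = {}
    for var in ("sbm_ai_similarity", "mbm_ai"):
        by_group = {g: ai.loc[ai.group == g, var].to_numpy() for g in ai.group.unique()}
        rep = _stage("group_stats")(group_test_report)(var, by_group)
        stats_report[f"{var}_by_group"] = {
            "H": rep.h_statistic,
            "p": rep.p_value,
            "pairwise": rep.pairwise.to_dict(orient="records"),
        }
        # CDR staging: HC as reference group, carriers binned by global score
        stage_label = np.where(
            ai.group == "HC", "HC", "CDR_" + ai.cdr.astype(str)
        )
        by_stage = {
            s: ai.loc[stage_label == s, var].to_numpy()
            for s in pd.unique(stage_label)
            if (stage_label == s).sum() >= 2
        }
        if len(by_stage) >= 2:
            rep = group_test_report(var, by_stage)
            stats_report[f"{var}_by_cdr_stage"] = {
                "H": rep.h_statistic,
                "p": rep.p_value,
                "pairwise": rep.pairwise.to_dict(orient="records"),
            }

    # --- Spearman AI vs TMT, symptomatic only ------------------------------
    sym = ai[ai.group == "symptomatic"]
    for var in ("sbm_ai_similarity", "mbm_ai"):
        for test in ("tmt_a", "tmt_b"):
            try:
                rho, p = spearman_correlation(sym[var].to_numpy(), sym[test].to_numpy())
                stats_report[f"spearman_{var}_vs_{test}"] = {"rho": rho, "p": p}
            except ValueError as exc:
                logger.warning("Spearman %s vs %s skipped: %s", var, test, exc)

    # --- mode-wise GLM on significant-mode weights -------------------------
    sig_lh = contrasts["symptomatic_vs_hc_lh"].ranking
    sig_rh = contrasts["symptomatic_vs_hc_rh"].ranking
    if sig_lh or sig_rh:
        sym_subjects = clinical.loc[clinical.group == "symptomatic", "subject"]
        pred = {}
        for m in sig_lh:
            pred[f"lh_mode_{m}"] = [
                project_map(basis, cohort.maps[s][0], n_modes=n_modes).beta(m)
                for s in sym_subjects
            ]
        for m in sig_rh:
            pred[f"rh_mode_{m}"] = [
                project_map(basis, cohort.maps[s][1], n_modes=n_modes).beta(m)
                for s in sym_subjects
            ]
        X = pd.DataFrame(pred)
        sym_clin = clinical[clinical.group == "symptomatic"]
        for outcome in ("cdr", "tmt_a", "tmt_b"):
            y = sym_clin[outcome].to_numpy(float)
            try:
                fit = modewise_glm(y, X)
                stats_report[f"glm_{outcome}"] = fit.to_dict(orient="records")
            except ValueError as exc:
                logger.warning("mode-wise GLM for %s skipped: %s", outcome, exc)
    else:
        stats_report["glm"] = "skipped: no significant modes in the symptomatic contrast"

    stats_path = out / "statistics.json"
    stats_path.write_text(json.dumps(stats_report, indent=1, default=float))
    written.append(stats_path)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": int(len(clinical)),
        "contrasts": sorted(contrasts),
        "significant_modes": {k: list(v.ranking) for k, v in contrasts.items()},
        "outputs": {p.name: _sha256(p) for p in written},
        "complete": True,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
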