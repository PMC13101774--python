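"""Synthetic two-hemisphere cortical-thickness cohorts with planted effects.

The generator emulates a three-group genetic-FTD-like study — healthy
controls, presymptomatic mutation carriers, and symptomatic carriers — on a
shared spherical (optionally gently perturbed) template:

* every subject's thickness map is a shared smooth modal baseline
  (2.5 mm mean plus fixed low-order structure) plus i.i.d. Gaussian vertex
  noise;
* symptomatic subjects additionally carry left-lateralized atrophy expressed
  in a small set of coarse eigenmodes, with a weaker right-hemisphere echo on
  a subset of those modes, and per-subject per-mode severity multipliers;
* clinical scores are linked linearly to the planted left-hemisphere severity
  (TMT-A), left free (TMT-B), with disease stage sampled from per-group CDR
  frequencies.

Amplitudes are parameterized as *peak mm* (mode scaled by its max |ψ|) so
config values carry units independent of the template.  Everything is
reproducible from one master seed through per-subject spawned streams keyed
by (group, within-group index), so changing one group's size never perturbs
another group's data.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asymmetry import asymmetry_table
from .eigen import EigenmodeBasis, compute_eigenmodes
from .inference import mbm_group_test
from .mesh import SurfaceMap, TriangleMesh, make_icosphere
from .stats import modewise_glm

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSpec",
    "ClinicalLinkage",
    "SimulationConfig",
    "GroundTruth",
    "CohortDataset",
    "ConfigError",
    "generate_template_pair",
    "generate_cohort",
    "run_recovery_experiment",
    "write_cohort",
    "load_cohort",
]

GROUPS = ("HC", "presymptomatic", "symptomatic")


class ConfigError(ValueError):
    """Invalid or physically inconsistent simulation configuration."""


@dataclass(frozen=True)
class TemplateSpec:
    """Shared synthetic template surface (a stand-in for a cortical template).

    ``perturbation`` is the relative amplitude of a smooth radial deformation
    that breaks exact sphericity; 0 keeps the pure icosphere.
    """

    subdivisions: int = 3
    radius: float = 50.0  # mm; desk-scale hemisphere
    perturbation: float = 0.0


@dataclass(frozen=True)
class ClinicalLinkage:
    """Linear link between planted LH severity multipliers and test scores.

    TMT-A (seconds) = intercept + Σ_k coef_k · m_k + N(0, noise_sd²) over the
    linked modes' severity multipliers m_k; TMT-B has no modal linkage by
    default, mirroring a null executive association.
    """

    tmt_a_intercept: float = 12.0
    tmt_a_coefficients: dict[int, float] = field(
        default_factory=lambda: {1: 40.0, 9: 35.0, 13: 45.0}
    )
    tmt_a_noise_sd: float = 8.0
    tmt_b_intercept: float = 414.0
    tmt_b_coefficients: dict[int, float] = field(default_factory=dict)
    tmt_b_noise_sd: float = 155.0


def _default_cdr_probs() -> dict[str, dict[float, float]]:
    return {
        "HC": {0.0: 1.0},
        "presymptomatic": {0.0: 9 / 15, 0.5: 6 / 15},
        "symptomatic": {0.5: 6 / 27, 1.0: 7 / 27, 2.0: 11 / 27, 3.0: 3 / 27},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 19/15/27 group sizes, symptomatic-only
    left-lateralized atrophy on coarse modes {1, 2, 13, 9, 10} with a 0.4-ratio
    right-hemisphere echo on modes {9, 13}, and a presymptomatic group with no
    planted effect.  Mode numbers are 1-based (mode 1 = constant).
    """

    n_hc: int = 19
    n_presymptomatic: int = 15
    n_symptomatic: int = 27
    template: TemplateSpec = field(default_factory=TemplateSpec)
    n_modes: int = 50
    baseline_thickness: float = 2.5  # mm
    baseline_pattern: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: -0.10, 4: 0.12, 5: -0.08, 7: 0.10}
    )  # peak mm, shared anatomy
    atrophy_lh: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.25, 13: 0.22, 9: 0.18, 10: 0.15}
    )  # peak mm of symptomatic LH thinning
    rh_ratio: float = 0.4
    rh_modes: tuple[int, ...] = (9, 13)
    severity_sd: float = 0.35  # sd of per-mode multipliers around 1
    noise_sd: float = 0.25  # mm, i.i.d. vertex noise
    spatial_noise_fwhm: float = 0.0  # reserved; 0 = independent vertices
    clinical: ClinicalLinkage = field(default_factory=ClinicalLinkage)
    cdr_probs: dict[str, dict[float, float]] = field(default_factory=_default_cdr_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_presymptomatic, self.n_symptomatic) < 0:
            raise ConfigError("group sizes must be non-negative")
        if self.noise_sd < 0 or self.severity_sd < 0:
            raise ConfigError("noise and severity sds must be non-negative")
        for g, probs in self.cdr_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"CDR stage probabilities for {g!r} must sum to 1")
        for spec in (self.baseline_pattern, self.atrophy_lh):
            if any(not np.isfinite(v) for v in spec.values()):
                raise ConfigError("amplitudes must be finite")
            if any(k < 1 for k in spec):
                raise ConfigError("mode numbers are 1-based (>= 1)")
        linked = set(self.clinical.tmt_a_coefficients) | set(self.clinical.tmt_b_coefficients)
        if not linked <= set(self.atrophy_lh):
            raise ConfigError(
                "clinically linked modes must be a subset of the planted LH atrophy modes"
            )
        needed = max(
            [*self.baseline_pattern, *self.atrophy_lh, 1]
        )
        if self.n_modes < max(needed, 25):
            raise ConfigError(f"n_modes must cover planted modes and the AI truncation (>= {max(needed, 25)})")

    def scaled_atrophy(self, scale: float) -> "SimulationConfig":
        """Copy with every planted atrophy amplitude multiplied by ``scale``."""
        return replace(
            self, atrophy_lh={k: v * scale for k, v in self.atrophy_lh.items()}
        )

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["rh_modes"] = list(self.rh_modes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["template"] = TemplateSpec(**d.get("template", {}))
        d["clinical"] = ClinicalLinkage(**d.get("clinical", {}))
        if "rh_modes" in d:
            d["rh_modes"] = tuple(d["rh_modes"])
        for key in ("baseline_pattern", "atrophy_lh"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if "cdr_probs" in d:
            d["cdr_probs"] = {
                g: {float(k): float(v) for k, v in probs.items()}
                for g, probs in d["cdr_probs"].items()
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted: per-subject modal perturbations and the clinical link.

    ``planted_beta`` has one row per (subject, hemisphere, mode) with the β
    perturbation (map units x mm², negative = thinning) and the severity
    multiplier that produced it.
    """

    planted_beta: pd.DataFrame
    clinical_coefficients: dict[str, dict[int, float]]
    master_seed: int


@dataclass
class CohortDataset:
    """A generated cohort: shared geometry, per-subject maps, clinical table."""

    lh_mesh: TriangleMesh
    rh_mesh: TriangleMesh
    basis: EigenmodeBasis
    clinical: pd.DataFrame  # subject, group, cdr, tmt_a, tmt_b
    maps: dict[str, tuple[SurfaceMap, SurfaceMap]]  # subject -> (LH, RH)

    def group_maps(self, group: str, hemisphere: str = "lh") -> list[SurfaceMap]:
        idx = 0 if hemisphere == "lh" else 1
        subjects = self.clinical.loc[self.clinical.group == group, "subject"]
        return [self.maps[s][idx] for s in subjects]

    @property
    def subjects(self) -> list[str]:
        return list(self.clinical["subject"])


# template geometry and its eigenmodes are deterministic in the spec values,
# so repeated cohort generation (replicate studies) reuses one cached basis
_TEMPLATE_CACHE: dict[tuple, tuple[TriangleMesh, TriangleMesh, EigenmodeBasis]] = {}


def _smooth_radial_field(directions: np.ndarray) -> np.ndarray:
    """A fixed smooth unit-amplitude function on the sphere (low-order
    polynomial in the direction cosines) used for template perturbation."""
    x, y, z = directions.T
    f = 0.6 * x * y + 0.8 * (z**2 - 1.0 / 3.0) + 0.4 * x * z
    return f / np.max(np.abs(f))


def generate_template_pair(config: SimulationConfig) -> tuple[TriangleMesh, TriangleMesh]:
    """Shared-topology LH/RH template meshes.

    LH is an icosphere, optionally radially perturbed by a fixed smooth field;
    RH is its mirror image across x = 0 with identical vertex indexing, so
    homotopic correspondence is index identity and the two surfaces are exact
    isometries (identical Laplace-Beltrami spectra).
    """
    t = config.template
    lh = make_icosphere(subdivisions=t.subdivisions, radius=t.radius)
    if t.perturbation:
        dirs = lh.vertices / np.linalg.norm(lh.vertices, axis=1, keepdims=True)
        radii = t.radius * (1.0 + t.perturbation * _smooth_radial_field(dirs))
        verts = dirs * radii[:, None]
        try:
            lh = TriangleMesh(vertices=verts, faces=lh.faces, name="lh_template")
        except ValueError as exc:
            raise ConfigError(
                f"template perturbation {t.perturbation} degenerates the mesh: {exc}"
            ) from exc
        # a star-shaped surface keeps every face normal pointing outward;
        # a flipped (or inverted) triangle turns its normal against the
        # centroid direction
        tri = lh.vertices[lh.faces]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroids = tri.mean(axis=1)
        if np.any(np.einsum("ij,ij->i", normals, centroids) <= 0):
            raise ConfigError(
                f"template perturbation {t.perturbation} degenerates the mesh: "
                "flipped triangle(s) detected"
            )
    rh_verts = lh.vertices.copy()
    rh_verts[:, 0] *= -1.0
    lh = TriangleMesh(vertices=lh.vertices, faces=lh.faces, name="lh_template", hemisphere="lh")
    rh = TriangleMesh(vertices=rh_verts, faces=lh.faces, name="rh_template", hemisphere="rh")
    return lh, rh


def _template_and_basis(config: SimulationConfig) -> tuple[TriangleMesh, TriangleMesh, EigenmodeBasis]:
    key = (
        config.template.subdivisions,
        config.template.radius,
        config.template.perturbation,
        config.n_modes,
    )
    if key not in _TEMPLATE_CACHE:
        lh, rh = generate_template_pair(config)
        basis = compute_eigenmodes(lh, n_modes=config.n_modes)
        _TEMPLATE_CACHE[key] = (lh, rh, basis)
    return _TEMPLATE_CACHE[key]


def _peak_normalized_modes(basis: EigenmodeBasis) -> np.ndarray:
    return basis.modes / np.max(np.abs(basis.modes), axis=0)


def _sample_cdr(rng: np.random.Generator, probs: dict[float, float]) -> float:
    stages = sorted(probs)
    return float(rng.choice(stages, p=[probs[s] for s in stages]))


def generate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a reproducible synthetic cohort plus its ground truth.

    Subject map = baseline (mean thickness + low-order pattern)
    − group/hemisphere atrophy (peak-mm amplitudes × per-subject per-mode
    severity multipliers) + i.i.d. Gaussian vertex noise, floored at 0.1 mm
    with a logged count.  Raises :class:`ConfigError` when the noise-free
    atrophy drives more than 1 % of vertices non-positive.
    """
    lh_mesh, rh_mesh, basis = _template_and_basis(config)
    n = lh_mesh.n_vertices
    peak_modes = _peak_normalized_modes(basis)

    baseline = np.full(n, config.baseline_thickness)
    for mode, amp in config.baseline_pattern.items():
        baseline = baseline + amp * peak_modes[:, mode - 1]

    atrophy_modes = sorted(config.atrophy_lh)
    lh_amp = np.array([config.atrophy_lh[m] for m in atrophy_modes])
    rh_amp = np.array(
        [config.rh_ratio * config.atrophy_lh[m] if m in config.rh_modes else 0.0 for m in atrophy_modes]
    )
    atro_cols = peak_modes[:, [m - 1 for m in atrophy_modes]]
    peak_scale = np.max(np.abs(basis.modes), axis=0)[[m - 1 for m in atrophy_modes]]

    # physical sanity at nominal severity (multiplier 1), before noise
    det_lh = baseline - atro_cols @ lh_amp
    if np.mean(det_lh <= 0) > 0.01:
        raise ConfigError(
            "planted atrophy drives mean thickness <= 0 at more than 1% of vertices"
        )

    sizes = {
        "HC": config.n_hc,
        "presymptomatic": config.n_presymptomatic,
        "symptomatic": config.n_symptomatic,
    }
    records, maps, truth_rows = [], {}, []
    n_clipped = 0
    counter = 0
    for gi, group in enumerate(GROUPS):
        diseased = group == "symptomatic"
        for si in range(sizes[group]):
            counter += 1
            subject = f"sub-{counter:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(gi, si))
            )
            if diseased:
                m_lh = np.clip(1.0 + config.severity_sd * rng.standard_normal(len(atrophy_modes)), 0.1, None)
                m_rh = np.clip(1.0 + config.severity_sd * rng.standard_normal(len(atrophy_modes)), 0.1, None)
            else:
                m_lh = np.zeros(len(atrophy_modes))
                m_rh = np.zeros(len(atrophy_modes))

            lh_vals = baseline - atro_cols @ (lh_amp * m_lh)
            rh_vals = baseline - atro_cols @ (rh_amp * m_rh)
            if config.noise_sd > 0:
                lh_vals = lh_vals + config.noise_sd * rng.standard_normal(n)
                rh_vals = rh_vals + config.noise_sd * rng.standard_normal(n)
            n_clipped += int((lh_vals < 0.1).sum() + (rh_vals < 0.1).sum())
            lh_vals = np.maximum(lh_vals, 0.1)
            rh_vals = np.maximum(rh_vals, 0.1)
            maps[subject] = (
                SurfaceMap.full(lh_mesh, lh_vals, name=f"{subject}_lh"),
                SurfaceMap.full(rh_mesh, rh_vals, name=f"{subject}_rh"),
            )

            cdr = _sample_cdr(rng, config.cdr_probs[group])
            if diseased:
                cl = config.clinical
                mult = dict(zip(atrophy_modes, m_lh))
                tmt_a = cl.tmt_a_intercept + sum(
                    c * mult[k] for k, c in cl.tmt_a_coefficients.items()
                ) + cl.tmt_a_noise_sd * rng.standard_normal()
                tmt_b = cl.tmt_b_intercept + sum(
                    c * mult[k] for k, c in cl.tmt_b_coefficients.items()
                ) + cl.tmt_b_noise_sd * rng.standard_normal()
                tmt_a, tmt_b = max(tmt_a, 1.0), max(tmt_b, 1.0)
            else:
                tmt_a = tmt_b = np.nan
            records.append(
                {"subject": subject, "group": group, "cdr": cdr, "tmt_a": tmt_a, "tmt_b": tmt_b}
            )

            for hemi, mult, amp in (("lh", m_lh, lh_amp), ("rh", m_rh, rh_amp)):
                for j, mode in enumerate(atrophy_modes):
                    truth_rows.append(
                        {
                            "subject": subject,
                            "hemisphere": hemi,
                            "mode": mode,
                            "multiplier": float(mult[j]),
                            "delta_beta": float(-amp[j] * mult[j] / peak_scale[j]),
                        }
                    )

    if n_clipped:
        logger.info("generate_cohort: floored %d vertex values at 0.1 mm", n_clipped)

    cohort = CohortDataset(
        lh_mesh=lh_mesh,
        rh_mesh=rh_mesh,
        basis=basis,
        clinical=pd.DataFrame(records),
        maps=maps,
    )
    truth = GroundTruth(
        planted_beta=pd.DataFrame(truth_rows),
        clinical_coefficients={
            "tmt_a": dict(config.clinical.tmt_a_coefficients),
            "tmt_b": dict(config.clinical.tmt_b_coefficients),
        },
        master_seed=config.seed,
    )
    return cohort, truth


def _replicate_seed(master: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(cell, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_recovery_experiment(
    base_config: SimulationConfig,
    amplitude_scales: list[float],
    n_replicates: int = 20,
    n_perm: int = 100,
    alpha: float = 0.05,
    n_modes: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Power / type-I / sensitivity table over an atrophy-amplitude grid.

    For every scale in ``amplitude_scales`` and each replicate, a fresh cohort
    is generated (atrophy amplitudes multiplied by the scale), the symptomatic
    vs HC mode test runs on the LH, asymmetry indices are computed with a
    full-cortex ROI, and — when TMT-linked modes exist — the mode-wise OLS is
    fitted on symptomatic LH modal weights.  Rates come back with binomial
    Monte-Carlo standard errors.

    Columns: scale, metric, value, mc_se, n.
    """
    rows = []
    planted = sorted(base_config.atrophy_lh)
    linked = sorted(base_config.clinical.tmt_a_coefficients)
    for ci, scale in enumerate(amplitude_scales):
        cfg = base_config.scaled_atrophy(scale)
        detect = {m: 0 for m in planted}
        any_sig = 0
        ai_means: dict[str, list[float]] = {g: [] for g in GROUPS}
        glm_hits, glm_total = 0, 0
        for rep in range(n_replicates):
            rep_cfg = replace(cfg, seed=_replicate_seed(seed, ci, rep))
            cohort, _ = generate_cohort(rep_cfg)
            result = mbm_group_test(
                cohort.group_maps("HC", "lh"),
                cohort.group_maps("symptomatic", "lh"),
                cohort.basis,
                n_perm=n_perm,
                alpha=alpha,
                seed=_replicate_seed(seed, ci, rep) + 1,
                n_modes=n_modes,
            )
            for m in planted:
                if m in result.ranking:
                    detect[m] += 1
            any_sig += bool(result.ranking)

            full_roi = SurfaceMap.full(
                cohort.lh_mesh, np.ones(cohort.lh_mesh.n_vertices), name="full"
            )
            table = asymmetry_table(cohort.maps, cohort.basis, full_roi, n_modes=n_modes)
            merged = table.merge(cohort.clinical, on="subject")
            for g in GROUPS:
                ai_means[g].append(float(merged.loc[merged.group == g, "mbm_ai"].mean()))

            if linked:
                from .decompose import project_map

                sym = cohort.clinical[cohort.clinical.group == "symptomatic"]
                betas = {
                    f"lh_mode_{m}": [
                        project_map(cohort.basis, cohort.maps[s][0], n_modes=n_modes).beta(m)
                        for s in sym.subject
                    ]
                    for m in linked
                }
                fit = modewise_glm(sym["tmt_a"].to_numpy(), pd.DataFrame(betas))
                glm_hits += int((fit["p"] < 0.05).sum())
                glm_total += len(fit)

        def rate_row(metric: str, hits: int, total: int) -> dict:
            r = hits / total if total else np.nan
            se = np.sqrt(r * (1 - r) / total) if total else np.nan
            return {"scale": scale, "metric": metric, "value": r, "mc_se": se, "n": total}

        for m in planted:
            rows.append(rate_row(f"detect_mode_{m}", detect[m], n_replicates))
        rows.append(rate_row("any_significant_mode", any_sig, n_replicates))
        if glm_total:
            rows.append(rate_row("glm_linked_coefficient_recovery", glm_hits, glm_total))
        for g in GROUPS:
            vals = np.array(ai_means[g])
            rows.append(
                {
                    "scale": scale,
                    "metric": f"mean_mbm_ai_{g}",
                    "value": float(vals.mean()),
                    "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def write_cohort(
    cohort: CohortDataset,
    directory: str | Path,
    truth: GroundTruth | None = None,
    config: SimulationConfig | None = None,
) -> Path:
    """Persist a cohort in the pipeline's standard on-disk layout.

    ``lh_template.vtk`` / ``rh_template.vtk``, ``clinical.csv``,
    ``maps/<subject>_<hemi>.csv`` and, when given, ``ground_truth.csv`` and
    ``config.yaml``.  The eigenmode basis is not stored; it is recomputed
    deterministically from the template on load.
    """
    from .io import write_mesh, write_scalar_csv

    directory = Path(directory)
    (directory / "maps").mkdir(parents=True, exist_ok=True)
    write_mesh(cohort.lh_mesh, directory / "lh_template.vtk")
    write_mesh(cohort.rh_mesh, directory / "rh_template.vtk")
    cohort.clinical.to_csv(directory / "clinical.csv", index=False)
    for subject, (lh, rh) in cohort.maps.items():
        write_scalar_csv(lh, directory / "maps" / f"{subject}_lh.csv")
        write_scalar_csv(rh, directory / "maps" / f"{subject}_rh.csv")
    if truth is not None:
        truth.planted_beta.to_csv(directory / "ground_truth.csv", index=False)
    if config is not None:
        config.to_yaml(directory / "config.yaml")
    return directory


def load_cohort(directory: str | Path, n_modes: int | None = None) -> CohortDataset:
    """Load a cohort written by :func:`write_cohort`, recomputing the basis."""
    from .io import read_mesh, read_scalar_csv

    directory = Path(directory)
    lh_mesh = read_mesh(directory / "lh_template.vtk")
    rh_mesh = read_mesh(directory / "rh_template.vtk")
    clinical = pd.read_csv(directory / "clinical.csv")
    if n_modes is None:
        cfg_path = directory / "config.yaml"
        n_modes = (
            SimulationConfig.from_yaml(cfg_path).n_modes if cfg_path.exists() else 50
        )
    basis = compute_eigenmodes(lh_mesh, n_modes=n_modes)
    maps = {}
    for subject in clinical["subject"]:
        lh = read_scalar_csv(directory / "maps" / f"{subject}_lh.csv", mesh=lh_mesh)
        rh = read_scalar_csv(directory / "maps" / f"{subject}_rh.csv", mesh=rh_mesh)
        maps[subject] = (lh, rh)
    return CohortDataset(
        lh_mesh=lh_mesh, rh_mesh=rh_mesh, basis=basis, clinical=clinical, maps=maps
    )
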