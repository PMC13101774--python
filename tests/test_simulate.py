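"""Synthetic cohort generator: determinism, planted effects, ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from modemorph import (
    ClinicalLinkage,
    ConfigError,
    SimulationConfig,
    TemplateSpec,
    compute_eigenmodes,
    generate_cohort,
    generate_template_pair,
    load_cohort,
    make_icosphere,
    project_map,
    run_recovery_experiment,
    write_cohort,
)

SMALL = SimulationConfig(n_hc=5, n_presymptomatic=3, n_symptomatic=6, seed=11)


def test_template_pair_mirror_geometry():
    cfg = SimulationConfig()
    lh, rh = generate_template_pair(cfg)
    ico = make_icosphere(cfg.template.subdivisions, cfg.template.radius)
    assert np.array_equal(lh.vertices, ico.vertices)  # zero perturbation
    expected_rh = lh.vertices.copy()
    expected_rh[:, 0] *= -1
    assert np.array_equal(rh.vertices, expected_rh)
    assert np.array_equal(lh.faces, rh.faces)


def test_template_pair_spectral_isometry():
    cfg = replace(SimulationConfig(), template=TemplateSpec(subdivisions=2, perturbation=0.05))
    lh, rh = generate_template_pair(cfg)
    bl = compute_eigenmodes(lh, n_modes=15)
    br = compute_eigenmodes(rh, n_modes=15)
    scale = np.maximum(np.abs(bl.eigenvalues), bl.eigenvalues[1])
    assert np.all(np.abs(bl.eigenvalues - br.eigenvalues) <= 1e-10 * scale)


def test_excessive_perturbation_rejected():
    cfg = replace(SimulationConfig(), template=TemplateSpec(subdivisions=1, perturbation=50.0))
    with pytest.raises(ConfigError, match="degenerates"):
        generate_template_pair(cfg)


def test_cohort_bit_identical_for_same_seed():
    c1, t1 = generate_cohort(SMALL)
    c2, t2 = generate_cohort(SMALL)
    for s in c1.subjects:
        assert np.array_equal(c1.maps[s][0].values, c2.maps[s][0].values)
        assert np.array_equal(c1.maps[s][1].values, c2.maps[s][1].values)
    assert c1.clinical.equals(c2.clinical)
    assert t1.planted_beta.equals(t2.planted_beta)


def test_subject_streams_survive_group_size_changes():
    """Per-subject randomness is keyed by (group, index): enlarging one group
    leaves other groups' subjects bit-identical."""
    c1, _ = generate_cohort(SMALL)
    c2, _ = generate_cohort(replace(SMALL, n_symptomatic=SMALL.n_symptomatic + 4))
    hc_1 = c1.clinical[c1.clinical.group == "HC"].subject
    hc_2 = c2.clinical[c2.clinical.group == "HC"].subject
    for s1, s2 in zip(hc_1, hc_2):
        assert np.array_equal(c1.maps[s1][0].values, c2.maps[s2][0].values)


def test_noise_free_cohort_is_baseline_and_symmetric():
    cfg = replace(
        SMALL,
        noise_sd=0.0,
        severity_sd=0.0,
        atrophy_lh={1: 0.0},
        rh_modes=(),
        clinical=ClinicalLinkage(tmt_a_coefficients={}),
    )
    cohort, _ = generate_cohort(cfg)
    from modemorph import mbm_ai

    ref = cohort.maps[cohort.subjects[0]][0].values
    for s in cohort.subjects:
        lh, rh = cohort.maps[s]
        assert np.array_equal(lh.values, ref)
        assert np.array_equal(lh.values, rh.values)
        assert mbm_ai(lh, rh, cohort.basis, n_modes=25) == 1.0


def test_planted_beta_recovery_is_unbiased():
    """Mean recovered mode-13 deficit matches the planted ground truth."""
    cfg = replace(
        SimulationConfig(atrophy_lh={13: 0.22}, rh_modes=(),
                         clinical=ClinicalLinkage(tmt_a_coefficients={13: 45.0})),
        n_hc=20, n_presymptomatic=0, n_symptomatic=20, seed=17,
    )
    cohort, truth = generate_cohort(cfg)
    hc_beta = np.array([
        project_map(cohort.basis, cohort.maps[s][0]).beta(13)
        for s in cohort.clinical[cohort.clinical.group == "HC"].subject
    ])
    sym = cohort.clinical[cohort.clinical.group == "symptomatic"].subject
    sym_beta = np.array([
        project_map(cohort.basis, cohort.maps[s][0]).beta(13) for s in sym
    ])
    planted = truth.planted_beta.query("hemisphere == 'lh' and mode == 13")
    planted_mean = planted.set_index("subject").loc[sym, "delta_beta"].mean()
    observed = sym_beta.mean() - hc_beta.mean()
    se = np.sqrt(sym_beta.var(ddof=1) / len(sym_beta) + hc_beta.var(ddof=1) / len(hc_beta))
    assert abs(observed - planted_mean) < 3 * se


def test_clinical_table_structure():
    cohort, _ = generate_cohort(SMALL)
    clin = cohort.clinical
    assert list(clin.columns) == ["subject", "group", "cdr", "tmt_a", "tmt_b"]
    assert clin.groupby("group").size().to_dict() == {
        "HC": 5, "presymptomatic": 3, "symptomatic": 6,
    }
    sym = clin[clin.group == "symptomatic"]
    assert np.all(sym["tmt_a"] > 0) and np.all(sym["tmt_b"] > 0)
    assert clin.loc[clin.group != "symptomatic", "tmt_a"].isna().all()
    assert set(clin["cdr"]) <= {0.0, 0.5, 1.0, 2.0, 3.0}
    assert np.all(clin.loc[clin.group == "HC", "cdr"] == 0.0)


def test_config_validation():
    with pytest.raises(ConfigError, match="sum to 1"):
        SimulationConfig(cdr_probs={"HC": {0.0: 0.5}, "presymptomatic": {0.0: 1.0},
                                    "symptomatic": {1.0: 1.0}})
    with pytest.raises(ConfigError, match="subset"):
        SimulationConfig(atrophy_lh={2: 0.1},
                         clinical=ClinicalLinkage(tmt_a_coefficients={9: 10.0}))
    with pytest.raises(ConfigError, match="non-negative"):
        SimulationConfig(noise_sd=-0.1)
    with pytest.raises(ConfigError, match="thickness"):
        generate_cohort(SimulationConfig(
            atrophy_lh={1: 5.0}, clinical=ClinicalLinkage(tmt_a_coefficients={1: 1.0})))


def test_config_yaml_round_trip(tmp_path):
    cfg = replace(SMALL, seed=99)
    path = cfg.to_yaml(tmp_path / "sim.yaml")
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_cohort_write_load_round_trip(tmp_path):
    cohort, truth = generate_cohort(SMALL)
    write_cohort(cohort, tmp_path / "cohort", truth=truth, config=SMALL)
    back = load_cohort(tmp_path / "cohort")
    assert back.subjects == cohort.subjects
    for s in cohort.subjects:
        assert np.array_equal(back.maps[s][0].values, cohort.maps[s][0].values)
    assert np.array_equal(back.basis.eigenvalues, cohort.basis.eigenvalues)


def test_recovery_experiment_smoke():
    cfg = replace(SMALL, n_hc=8, n_presymptomatic=0, n_symptomatic=8)
    table = run_recovery_experiment(
        cfg, amplitude_scales=[0.0, 1.0], n_replicates=3, n_perm=50, seed=1
    )
    assert {"scale", "metric", "value", "mc_se", "n"} <= set(table.columns)
    rates = table[table.metric.str.startswith("detect_")]
    assert np.all((rates["value"] >= 0) & (rates["value"] <= 1))
    # planted modes are easier to detect at full amplitude than at zero
    d13 = rates[rates.metric == "detect_mode_13"].set_index("scale")["value"]
    assert d13[1.0] >= d13[0.0]
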