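"""SBM and MBM asymmetry indices."""

import numpy as np
import pytest

from modemorph import (
    SurfaceMap,
    UndefinedAsymmetryError,
    asymmetry_table,
    build_symmetric_mask,
    mbm_ai,
    sbm_ai,
)


def full_roi(mesh):
    return SurfaceMap.full(mesh, np.ones(mesh.n_vertices), name="full")


def test_sbm_ai_symmetric_is_zero(ico1):
    m = SurfaceMap.full(ico1, np.full(ico1.n_vertices, 2.5))
    raw, sim = sbm_ai(m, m, full_roi(ico1))
    assert raw == 0.0 and sim == 1.0


def test_sbm_ai_printed_formula_arithmetic(ico1):
    lh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, 2.2))
    rh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, 2.0))
    raw, sim = sbm_ai(lh, rh, full_roi(ico1))
    assert np.isclose(raw, -0.095238, atol=1e-6)
    assert np.isclose(sim, 0.904762, atol=1e-6)


def test_sbm_ai_ten_percent_thinning(ico1):
    rh_val = 2.5
    lh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, 0.9 * rh_val))
    rh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, rh_val))
    raw, _ = sbm_ai(lh, rh, full_roi(ico1))
    assert np.isclose(raw, 0.1 / 0.95, atol=1e-9)  # +0.105263


def test_sbm_ai_swap_antisymmetry(ico1):
    rng = np.random.default_rng(0)
    lh = SurfaceMap.full(ico1, 2.5 + 0.1 * rng.standard_normal(ico1.n_vertices))
    rh = SurfaceMap.full(ico1, 2.4 + 0.1 * rng.standard_normal(ico1.n_vertices))
    raw1, sim1 = sbm_ai(lh, rh, full_roi(ico1))
    raw2, sim2 = sbm_ai(rh, lh, full_roi(ico1))
    assert np.isclose(raw1, -raw2, atol=1e-12)
    assert np.isclose(sim1, sim2, atol=1e-12)


def test_sbm_ai_zero_thickness_undefined(ico1):
    lh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, 1.0))
    rh = SurfaceMap.full(ico1, np.full(ico1.n_vertices, -1.0))
    with pytest.raises(UndefinedAsymmetryError):
        sbm_ai(lh, rh, full_roi(ico1))


def test_mbm_ai_identical_maps_is_exactly_one(basis_ico3):
    mesh = basis_ico3.mesh
    rng = np.random.default_rng(1)
    vals = 2.5 + 0.2 * rng.standard_normal(mesh.n_vertices)
    m = SurfaceMap.full(mesh, vals)
    assert mbm_ai(m, m, basis_ico3, n_modes=25) == 1.0


def test_mbm_ai_constant_offset_changes_only_beta1(basis_ico3):
    mesh = basis_ico3.mesh
    rng = np.random.default_rng(2)
    vals = 2.5 + 0.3 * rng.standard_normal(mesh.n_vertices)
    lh = SurfaceMap.full(mesh, vals)
    rh = SurfaceMap.full(mesh, vals + 0.5)
    assert mbm_ai(lh, rh, basis_ico3, n_modes=25) >= 0.99
    # excluding the constant mode the profiles are identical
    assert np.isclose(
        mbm_ai(lh, rh, basis_ico3, n_modes=25, include_constant=False), 1.0, atol=1e-9
    )


def test_mbm_ai_white_noise_null(basis_ico3):
    """Independent hemispheric noise gives weak |r| with n = 25 coefficients."""
    mesh = basis_ico3.mesh
    rng = np.random.default_rng(3)
    vals = []
    for _ in range(50):
        lh = SurfaceMap.full(mesh, rng.standard_normal(mesh.n_vertices))
        rh = SurfaceMap.full(mesh, rng.standard_normal(mesh.n_vertices))
        vals.append(mbm_ai(lh, rh, basis_ico3, n_modes=25))
    assert np.mean(vals) < 0.35


def test_mbm_ai_invariances(basis_ico3):
    mesh = basis_ico3.mesh
    rng = np.random.default_rng(4)
    lh = SurfaceMap.full(mesh, 2.5 + 0.2 * rng.standard_normal(mesh.n_vertices))
    rh = SurfaceMap.full(mesh, 2.3 + 0.2 * rng.standard_normal(mesh.n_vertices))
    a = mbm_ai(lh, rh, basis_ico3)
    assert np.isclose(mbm_ai(rh, lh, basis_ico3), a, atol=1e-12)  # swap
    lh2 = SurfaceMap.full(mesh, 3.0 * lh.values)
    rh2 = SurfaceMap.full(mesh, 3.0 * rh.values)
    assert np.isclose(mbm_ai(lh2, rh2, basis_ico3), a, atol=1e-9)  # common scaling


def test_mbm_ai_zero_variance_undefined(basis_ico3):
    mesh = basis_ico3.mesh
    lh = SurfaceMap.full(mesh, np.zeros(mesh.n_vertices) + 0.0)
    rh = SurfaceMap.full(mesh, np.ones(mesh.n_vertices))
    with pytest.raises(UndefinedAsymmetryError, match="zero-variance"):
        mbm_ai(lh, rh, basis_ico3, n_modes=25)


def test_build_symmetric_mask_identity_correspondence(ico1):
    p = np.ones(ico1.n_vertices)
    p[[5, 9]] = 0.01
    p_map = SurfaceMap.full(ico1, p)
    dom, contra = build_symmetric_mask(p_map, p_threshold=0.05)
    assert set(np.flatnonzero(dom.values)) == {5, 9}
    assert np.array_equal(dom.values, contra.values)


def test_build_symmetric_mask_all_and_none(ico1):
    all_sig = SurfaceMap.full(ico1, np.zeros(ico1.n_vertices))
    dom, _ = build_symmetric_mask(all_sig, p_threshold=0.05)
    assert dom.values.sum() == ico1.n_vertices
    none_sig = SurfaceMap.full(ico1, np.ones(ico1.n_vertices))
    with pytest.raises(UndefinedAsymmetryError, match="no vertex"):
        build_symmetric_mask(none_sig, p_threshold=0.05)


def test_asymmetry_table_symmetric_cohort(basis_ico3):
    mesh = basis_ico3.mesh
    rng = np.random.default_rng(5)
    cohort = {}
    for i in range(4):
        vals = 2.5 + 0.2 * rng.standard_normal(mesh.n_vertices)
        m = SurfaceMap.full(mesh, vals)
        cohort[f"sub-{i}"] = (m, m)
    table = asymmetry_table(cohort, basis_ico3, full_roi(mesh), n_modes=25)
    assert np.all(table["mbm_ai"] == 1.0)
    assert np.all(table["sbm_ai_raw"] == 0.0)
    assert list(table["subject"]) == sorted(cohort)


def test_asymmetry_table_skips_missing_hemisphere(basis_ico3, caplog):
    import logging

    mesh = basis_ico3.mesh
    m = SurfaceMap.full(mesh, np.full(mesh.n_vertices, 2.5) + 0.1 * basis_ico3.modes[:, 3])
    cohort = {"sub-ok": (m, m), "sub-half": (m, None)}
    with caplog.at_level(logging.WARNING):
        table = asymmetry_table(cohort, basis_ico3, full_roi(mesh), n_modes=25)
    assert list(table["subject"]) == ["sub-ok"]
    assert any("missing a hemisphere" in r.message for r in caplog.records)


def test_asymmetry_table_empty_cohort(basis_ico3):
    table = asymmetry_table({}, basis_ico3, full_roi(basis_ico3.mesh))
    assert table.empty
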