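"""Community matrix, nMDS embedding, and environmental vector fitting."""

import numpy as np
import pandas as pd
import pytest

from ppmr import dapstom_io
from ppmr.ordination import (
    build_community_matrix,
    fit_env_vectors,
    run_nmds,
)


def _matched_frame():
    rows = [
        # family, rectangle, count, mass
        ("famA", "31F4", 2, 1.0),
        ("famA", "31F4", 3, 4.0),
        ("famA", "32F4", 5, 2.0),
        ("famB", "31F4", 4, 0.05),
        ("famB", "33F4", 6, 0.08),
        ("famC", "32F4", 7, 10.0),
        ("famC", "33F4", 1, 12.0),
        ("famD", "31F4", 1, 0.5),  # below min abundance, dropped
    ]
    return pd.DataFrame(
        {
            "prey_family": [r[0] for r in rows],
            "ices_rectangle": [r[1] for r in rows],
            "prey_count": [r[2] for r in rows],
            "prey_indiv_mass_g": [r[3] for r in rows],
            "sst_c": [8, 8, 12, 8, 15, 12, 15, 8],
            "effort_hours": [100, 100, 500, 100, 900, 500, 900, 100],
        }
    )


def test_community_matrix_additivity_and_weighted_means():
    cm = build_community_matrix(_matched_frame(), min_total_abundance=5)
    # two famA rows in 31F4 with counts 2 and 3 sum to 5
    assert cm.counts.loc["famA", "31F4"] == 5
    # abundance-weighted mean mass of famA: (2*1 + 3*4 + 5*2) / 10 = 2.4
    assert cm.covariates.loc["famA", "mean_mass_g"] == pytest.approx(2.4)
    assert "famD" not in cm.counts.index  # dropped, below threshold


def test_weighted_mean_example():
    df = _matched_frame().iloc[:2].copy()
    df.loc[df.index[0], "prey_count"] = 2
    df.loc[df.index[1], "prey_count"] = 3
    df.loc[df.index[0], "prey_indiv_mass_g"] = 1.0
    df.loc[df.index[1], "prey_indiv_mass_g"] = 4.0
    cm = build_community_matrix(df, min_total_abundance=1)
    assert cm.covariates.loc["famA", "mean_mass_g"] == pytest.approx(2.8)


def test_missing_family_column_rejected():
    with pytest.raises(ValueError, match="prey_family"):
        build_community_matrix(_matched_frame().drop(columns="prey_family"))


def test_identical_profiles_colocate():
    counts = pd.DataFrame(
        {
            "r1": [5.0, 5.0, 5.0, 1.0],
            "r2": [2.0, 2.0, 2.0, 9.0],
            "r3": [1.0, 1.0, 1.0, 4.0],
        },
        index=["a", "b", "c", "d"],
    )
    res = run_nmds(counts, seed=0, n_starts=8)
    # a, b, c have identical composition: pairwise distances ~0
    pts = res.coords.loc[["a", "b", "c"]].to_numpy()
    assert np.linalg.norm(pts[0] - pts[1]) < 1e-3
    assert np.linalg.norm(pts[0] - pts[2]) < 1e-3


def test_equilateral_dissimilarities_embed_stress_free():
    counts = pd.DataFrame(
        {"r1": [9.0, 0.0, 0.0], "r2": [0.0, 9.0, 0.0], "r3": [0.0, 0.0, 9.0]},
        index=["a", "b", "c"],
    )
    res = run_nmds(counts, seed=0, n_starts=8)
    assert res.stress < 1e-3
    d = [
        np.linalg.norm(res.coords.iloc[i].to_numpy() - res.coords.iloc[j].to_numpy())
        for i, j in [(0, 1), (0, 2), (1, 2)]
    ]
    assert max(d) / min(d) == pytest.approx(1.0, abs=0.05)


def test_nmds_determinism_and_row_order_invariance(small_dataset):
    matched = dapstom_io.build_matched_table(
        small_dataset.stomachs, dapstom_io.EnvLayer(small_dataset.sst)
    )
    cm = build_community_matrix(matched)
    r1 = run_nmds(cm, seed=3, n_starts=5)
    r2 = run_nmds(cm, seed=3, n_starts=5)
    assert np.allclose(r1.coords, r2.coords)
    perm = cm.counts.sample(frac=1.0, random_state=7)
    r3 = run_nmds(perm, seed=3, n_starts=5)
    assert np.allclose(
        r1.coords.sort_index(), r3.coords.sort_index(), atol=2e-2
    )


def test_stress_nonincreasing_in_dimensions(small_dataset):
    matched = dapstom_io.build_matched_table(
        small_dataset.stomachs, dapstom_io.EnvLayer(small_dataset.sst)
    )
    cm = build_community_matrix(matched)
    s1 = run_nmds(cm, k=1, seed=3, n_starts=5).stress
    s2 = run_nmds(cm, k=2, seed=3, n_starts=5).stress
    assert s2 <= s1 + 1e-6


def test_degenerate_all_zero_distances_rejected():
    counts = pd.DataFrame(
        {"r1": [1.0, 1.0, 1.0], "r2": [2.0, 2.0, 2.0]}, index=["a", "b", "c"]
    )
    with pytest.raises(ValueError, match="degenerate|undefined"):
        run_nmds(counts, seed=0)


def _coords(n=12, seed=4):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    pts -= pts.mean(axis=0)
    return pd.DataFrame(pts, columns=["axis1", "axis2"])


def test_axis_aligned_covariate_r2_one():
    coords = _coords()
    cov = pd.DataFrame({"v": coords["axis1"]})
    vec = fit_env_vectors(coords, cov, n_permutations=99, seed=0).iloc[0]
    assert vec.r2 == pytest.approx(1.0, abs=1e-9)
    assert vec.dx == pytest.approx(1.0, abs=1e-6)
    assert abs(vec.dy) < 1e-6
    assert vec.p_perm <= 0.02


def test_negative_axis_covariate_points_down_axis2():
    coords = _coords()
    cov = pd.DataFrame({"v": -coords["axis2"]})
    vec = fit_env_vectors(coords, cov, n_permutations=49, seed=0).iloc[0]
    assert vec.dy == pytest.approx(-1.0, abs=1e-6)


def test_r2_invariant_to_affine_rescaling():
    coords = _coords()
    rng = np.random.default_rng(9)
    v = coords["axis1"] * 0.3 + rng.normal(0, 0.5, len(coords))
    cov = pd.DataFrame({"v": v, "w": 100.0 * v - 7.0})
    res = fit_env_vectors(coords, cov, n_permutations=9, seed=0).set_index("covariate")
    assert res.loc["v", "r2"] == pytest.approx(res.loc["w", "r2"], rel=1e-9)


def test_constant_covariate_flagged():
    coords = _coords()
    res = fit_env_vectors(coords, pd.DataFrame({"v": np.ones(len(coords))}), 9, 0)
    assert res.iloc[0].r2 == 0.0
    assert "constant" in res.iloc[0].note


def test_independent_covariate_high_p():
    coords = _coords(n=20, seed=2)
    rng = np.random.default_rng(5)
    cov = pd.DataFrame({"v": rng.normal(size=20)})
    vec = fit_env_vectors(coords, cov, n_permutations=199, seed=1).iloc[0]
    assert vec.r2 < 0.3
    assert vec.p_perm > 0.05
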