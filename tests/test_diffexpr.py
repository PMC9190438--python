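"""Voom weights, moderated F statistics and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ketseq.diffexpr import (
    bh_adjust,
    estimate_moderation,
    fit_moderated,
    group_design,
    voom_weights,
)
from ketseq.io import CountMatrix
from .conftest import simulate_one


def _df(arr):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])])


def test_logcpm_formula_edge():
    genes = ["g0"]
    samples = ["s0"]
    meta = pd.DataFrame({"sample_id": samples, "animal_id": samples,
                         "region": "x", "sex": "male", "group": "Control"})
    cm = CountMatrix(
        counts=pd.DataFrame([[0]], index=genes, columns=samples),
        gene_lengths=pd.Series([1000], index=genes),
        library_sizes=pd.Series([1e6 - 1], index=samples),
        meta=meta,
    )
    c = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    logcpm = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
    assert logcpm[0, 0] == pytest.approx(-1.0)


def test_unmoderated_two_group_f_matches_pooled_t_oracle():
    # hand oracle: groups {2,4,6} vs {8,10,12}: pooled t = 6/(2*sqrt(2/3)),
    # F = t^2 = 13.5 with p from F(1, 4)
    y = _df([[2, 4, 6, 8, 10, 12]])
    w = _df(np.ones((1, 6)))
    design = group_design(["a", "a", "a", "b", "b", "b"], levels=["a", "b"])
    res = fit_moderated(y, w, design, d0=0)
    t = 6.0 / (2.0 * np.sqrt(2.0 / 3.0))
    assert res["F"].iloc[0] == pytest.approx(t**2, rel=1e-12)
    assert res["F"].iloc[0] == pytest.approx(13.5, rel=1e-12)
    assert res["p"].iloc[0] == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)


def test_zero_residuals_with_moderation_is_finite():
    y = _df([[5, 5, 5, 5, 5, 5]])
    w = _df(np.ones((1, 6)))
    design = group_design(["a", "a", "a", "b", "b", "b"], levels=["a", "b"])
    res = fit_moderated(y, w, design, d0=4.0, s0_sq=0.01)
    assert np.isfinite(res["F"].iloc[0])
    assert res["F"].iloc[0] == pytest.approx(0.0)
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_d0_zero_equals_unmoderated_wls_oracle():
    rng = np.random.default_rng(3)
    y = _df(rng.normal(size=(50, 12)))
    w = _df(rng.uniform(0.5, 2.0, size=(50, 12)))
    groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    design = group_design(groups, levels=["a", "b", "c"])
    res = fit_moderated(y, w, design, d0=0)
    # independent oracle: per-gene WLS F computed with numpy polyfit-free math
    X = design.to_numpy()
    Xr = np.ones((12, 1))
    for g in range(50):
        wg = np.diag(w.iloc[g].to_numpy())
        yg = y.iloc[g].to_numpy()
        bf = np.linalg.solve(X.T @ wg @ X, X.T @ wg @ yg)
        br = np.linalg.solve(Xr.T @ wg @ Xr, Xr.T @ wg @ yg)
        rss_f = float((yg - X @ bf) @ wg @ (yg - X @ bf))
        rss_r = float((yg - Xr @ br) @ wg @ (yg - Xr @ br))
        F = ((rss_r - rss_f) / 2) / (rss_f / 9)
        assert res["F"].iloc[g] == pytest.approx(F, rel=1e-9)


def test_d0_infinite_shrinks_all_variances_to_prior():
    rng = np.random.default_rng(4)
    y = _df(rng.normal(size=(20, 8)))
    w = _df(np.ones((20, 8)))
    design = group_design(["a"] * 4 + ["b"] * 4, levels=["a", "b"])
    res = fit_moderated(y, w, design, d0=np.inf, s0_sq=1.7)
    assert np.allclose(res["posterior_var"], 1.7)


def test_moderation_recovers_prior_from_chi_square_variances():
    # s2 drawn as s0^2 * chi2_df/df corresponds to d0 = inf (no extra spread)
    rng = np.random.default_rng(5)
    df = 6
    s2 = 2.5 * rng.chisquare(df, size=4000) / df
    d0, s0_sq = estimate_moderation(s2, df)
    assert s0_sq == pytest.approx(2.5, rel=0.1)
    assert d0 > 20  # little gene-to-gene variance heterogeneity


def test_null_simulation_pvalues_uniform(null_experiment):
    _, _, res = null_experiment
    ks = stats.kstest(res["p"], "uniform").statistic
    assert ks < 0.05
    assert (res["adj_p"] < 0.01).mean() <= 0.01


def test_weights_track_mean_count(mixed_experiment):
    cm, _, _ = mixed_experiment
    sel = cm.meta["region"] == "frontal_cortex"
    ids = list(cm.meta.loc[sel, "sample_id"])
    design = group_design(cm.meta.loc[sel, "group"])
    logcpm, w = voom_weights(cm, design)
    mean_count = cm.counts.mean(axis=1)
    rho = stats.spearmanr(mean_count, w.mean(axis=1)).statistic
    assert rho > 0.8


def test_equal_counts_give_near_equal_weights():
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(6)]
    rng = np.random.default_rng(6)
    counts = rng.integers(1, 2000, size=(30, 6))
    counts[0, :] = 500  # flat gene
    meta = pd.DataFrame({"sample_id": samples, "animal_id": samples,
                         "region": "x", "sex": "male",
                         "group": ["a"] * 3 + ["b"] * 3})
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(2000, index=genes),
        library_sizes=pd.Series(1e6, index=samples),
        meta=meta,
    )
    design = group_design(meta["group"], levels=["a", "b"])
    _, w = voom_weights(cm, design)
    flat = w.iloc[0].to_numpy()
    assert flat.max() / flat.min() == pytest.approx(1.0, abs=1e-9)


def test_design_errors():
    with pytest.raises(ValueError):
        group_design(["a", "a"], levels=["a", "b"])  # empty group column
    y = _df(np.ones((2, 2)))
    with pytest.raises(ValueError):
        fit_moderated(y, y, group_design(["a", "b"], levels=["a", "b"]))


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_known_values(pvals, expected):
    assert np.allclose(bh_adjust(pvals), expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_brute_force_step_up(pvals):
    # oracle: adj_i = min over j with p_j >= p_i of p_j * m / rank_j, capped
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    tail_min = np.minimum.accumulate(ranked[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(tail_min, 1.0)
    assert np.allclose(bh_adjust(p), expected)
    assert (bh_adjust(p) >= p - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
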