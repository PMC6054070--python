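import math

import numpy as np
import pandas as pd
import pytest

from radpair.inference import (
    MixedModelSpec,
    TransformSpec,
    fit_mixed,
    gower_center,
    mdmr,
    transform,
)


@pytest.mark.parametrize(
    "spec,x,expected",
    [
        (TransformSpec("logit_capped", cap=30_000), 15_000, 0.0),
        (TransformSpec("logit_offset"), 0.0, math.log(0.001 / 0.999)),
        (TransformSpec("log"), 1.0, 0.0),
        (TransformSpec("log"), math.e, 1.0),
    ],
)
def test_transform_closed_forms(spec, x, expected):
    assert transform(x, spec) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "spec,bad",
    [
        (TransformSpec("log"), 0.0),
        (TransformSpec("logit_capped", cap=100), 100.0),
        (TransformSpec("logit_offset"), 1.5),
    ],
)
def test_transform_domain_errors(spec, bad):
    with pytest.raises(ValueError):
        transform(bad, spec)


def _labels(n):
    return [f"l{i}" for i in range(n)]


def test_mdmr_scalar_distance_gives_unit_r2():
    x = np.array([1.0, 3.0, 4.0, 7.0, 2.0, 9.0])
    d = np.abs(x[:, None] - x[None, :])
    preds = pd.DataFrame({"x": x}, index=_labels(6))
    dm = pd.DataFrame(d, index=preds.index, columns=preds.index)
    res = mdmr(dm, preds, n_permutations=99, seed=1)
    assert res.omnibus_pseudo_r2 == pytest.approx(1.0, abs=1e-9)


def test_mdmr_matches_brute_force_traces():
    """Omnibus and marginal statistics equal the explicit trace formulas
    tr(HGH)/tr(G) and (tr(HGH)-tr(H-GH-))/tr(G) computed independently."""
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    preds = pd.DataFrame(
        {"a": rng.normal(size=6), "b": rng.normal(size=6)}, index=_labels(6)
    )
    dm = pd.DataFrame(d, index=preds.index, columns=preds.index)
    res = mdmr(dm, preds, n_permutations=9, seed=1)

    n = 6
    A = -0.5 * d**2
    C = np.eye(n) - np.ones((n, n)) / n
    G = C @ A @ C
    X = np.column_stack([np.ones(n), preds["a"], preds["b"]])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    omni = np.trace(H @ G @ H) / np.trace(G)
    assert res.omnibus_pseudo_r2 == pytest.approx(omni, abs=1e-10)
    for j, term in enumerate(["a", "b"]):
        Xm = np.delete(X, j + 1, axis=1)
        Hm = Xm @ np.linalg.inv(Xm.T @ Xm) @ Xm.T
        marg = (np.trace(H @ G @ H) - np.trace(Hm @ G @ Hm)) / np.trace(G)
        assert res.per_predictor.loc[term, "pseudo_r2"] == pytest.approx(marg, abs=1e-10)


def test_mdmr_seed_reproducibility_and_row_exchangeability():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(10, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    preds = pd.DataFrame({"x": rng.normal(size=10)}, index=_labels(10))
    dm = pd.DataFrame(d, index=preds.index, columns=preds.index)
    r1 = mdmr(dm, preds, n_permutations=199, seed=3)
    r2 = mdmr(dm, preds, n_permutations=199, seed=3)
    assert r1.omnibus_p == r2.omnibus_p
    # relabel rows: statistic invariant
    order = list(reversed(preds.index))
    r3 = mdmr(dm.loc[order, order], preds.loc[order], n_permutations=199, seed=3)
    assert r3.omnibus_pseudo_r2 == pytest.approx(r1.omnibus_pseudo_r2, abs=1e-12)


def test_mdmr_categorical_relabel_invariance():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(12, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    grp = ["u", "v", "w"] * 4
    preds = pd.DataFrame({"g": grp}, index=_labels(12))
    dm = pd.DataFrame(d, index=preds.index, columns=preds.index)
    r1 = mdmr(dm, preds, n_permutations=49, seed=0)
    remap = {"u": "zebra", "v": "ant", "w": "moth"}
    preds2 = preds.assign(g=[remap[g] for g in grp])
    r2 = mdmr(dm, preds2, n_permutations=49, seed=0)
    assert r2.omnibus_pseudo_r2 == pytest.approx(r1.omnibus_pseudo_r2, abs=1e-12)
    assert r2.per_predictor["pseudo_r2"].iloc[0] == pytest.approx(
        r1.per_predictor["pseudo_r2"].iloc[0], abs=1e-12
    )


def test_mdmr_rank_deficient_design_rejected():
    x = np.arange(5, dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    preds = pd.DataFrame({"a": x, "b": 2 * x}, index=_labels(5))
    dm = pd.DataFrame(d, index=preds.index, columns=preds.index)
    with pytest.raises(ValueError, match="rank-deficient"):
        mdmr(dm, preds, n_permutations=9, seed=0)


def test_gower_trace_nonnegative_for_random_dissimilarity():
    rng = np.random.default_rng(9)
    for _ in range(10):
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        assert np.trace(gower_center(a)) >= -1e-10


def _sim_mixed(seed, n=150, n_pools=5, beta_x=2.0):
    rng = np.random.default_rng(seed)
    pool = rng.integers(0, n_pools, n).astype(str)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    eff = dict(zip(map(str, range(n_pools)), rng.normal(0, 1, n_pools)))
    y = beta_x * x + np.array([eff[p] for p in pool]) + rng.normal(0, 1, n)
    return pd.DataFrame(dict(y=y, x=x, z=z, pool=pool))


def test_stepwise_keeps_signal_drops_noise():
    df = _sim_mixed(1)
    res = fit_mixed(MixedModelSpec("y", ["x", "z"], random=["pool"]), df)
    assert res.retained == ["x"]
    assert res.estimates["x"] == pytest.approx(2.0, abs=0.25)
    assert res.elimination_trail[0][0] == "z"


def test_alpha_one_keeps_full_model():
    df = _sim_mixed(2)
    res = fit_mixed(
        MixedModelSpec("y", ["x", "z", "x:z"], random=["pool"], alpha=1.0), df
    )
    assert set(res.retained) == {"x", "z", "x:z"}
    assert res.elimination_trail == []


def test_interaction_removed_before_main_effects():
    df = _sim_mixed(3)
    res = fit_mixed(MixedModelSpec("y", ["x", "z", "x:z"], random=["pool"]), df)
    dropped = [t for t, _p in res.elimination_trail]
    if "x:z" in dropped and ("z" in dropped):
        assert dropped.index("x:z") < dropped.index("z")
    assert "x" in res.retained


def test_no_random_factors_reduces_to_ols():
    df = _sim_mixed(4).drop(columns=["pool"])
    res = fit_mixed(MixedModelSpec("y", ["x", "z"], alpha=1.0), df)
    X = np.column_stack([np.ones(len(df)), df["x"], df["z"]])
    beta = np.linalg.lstsq(X, df["y"], rcond=None)[0]
    assert res.estimates["x"] == pytest.approx(beta[1], abs=1e-9)
    assert res.estimates["z"] == pytest.approx(beta[2], abs=1e-9)


def test_missing_values_rejected():
    df = _sim_mixed(5)
    df.loc[df.index[3], "x"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_mixed(MixedModelSpec("y", ["x", "z"], random=["pool"]), df)


def test_nested_random_effect_syntax():
    df = _sim_mixed(6)
    df["taxon"] = np.where(df["pool"].astype(int) < 3, "A", "B")
    res = fit_mixed(
        MixedModelSpec("y", ["x"], random=["pool@taxon"], alpha=1.0), df
    )
    assert "x" in res.retained
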