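import itertools
import math

import numpy as np
import pandas as pd
import pytest

from radpair.popgen import (
    CondenserPolicy,
    condense,
    encode_dosage,
    great_circle_km,
    ibd_analysis,
    mantel,
    pca_kmeans,
    wc_components,
    wc_fst,
)
from radpair.synthetic_data import SimConfig, TaxonConfig, simulate_genotypes


def _dosage_from_truth(truth, taxon):
    tt = truth.taxa[taxon]
    G = np.concatenate([g for g in tt.genotypes if g.shape[1]], axis=1).astype(float)
    dosage = pd.DataFrame(G, index=[i for i, _ in tt.individuals])
    pops = pd.Series([f"p{p}" for _, p in tt.individuals], index=dosage.index)
    return dosage, pops


def test_condense_all_present_keeps_everything():
    pm = pd.DataFrame(True, index=["a", "b", "c"], columns=["L1", "L2"])
    res = condense(pm)
    assert res.kept_samples == ["a", "b", "c"]
    assert res.kept_loci == ["L1", "L2"]


def test_condense_removes_high_missing_sample():
    pm = pd.DataFrame(
        [[1, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 1]],
        index=["a", "b", "c"], columns=["L1", "L2", "L3", "L4"],
    ).astype(bool)
    res = condense(pm, CondenserPolicy(min_samples_grid=(2,)))
    assert "c" not in res.kept_samples
    assert set(res.kept_samples) == {"a", "b"}


def test_condense_postconditions_always_hold():
    rng = np.random.default_rng(1)
    for _ in range(10):
        n, L = rng.integers(4, 11), rng.integers(5, 25)
        pm = pd.DataFrame(
            rng.random((n, L)) < rng.uniform(0.3, 0.95),
            index=[f"s{i}" for i in range(n)],
            columns=[f"L{j}" for j in range(L)],
        )
        try:
            res = condense(pm)
        except ValueError:
            continue
        sub = pm.loc[res.kept_samples, res.kept_loci]
        assert (sub.sum(axis=0) >= res.min_samples).all()
        assert ((1 - sub.mean(axis=1)) <= 0.5).all()


def test_condense_empty_matrix_rejected():
    with pytest.raises(ValueError):
        condense(pd.DataFrame())


def test_encode_dosage_and_multiallelic_drop():
    snps = pd.DataFrame(
        {"s1": list("ARG"), "s2": list("AAT"), "s3": list("RAC")},
    ).T
    snps.columns = ["site0", "site1", "site2"]
    dosage, dropped = encode_dosage(snps)
    assert dropped == 1  # site2 carries G, T and C: more than two alleles
    assert list(dosage.columns) == ["site0", "site1"]
    # site0: most frequent allele A is reference; R = A/G is one alt copy
    assert dosage["site0"].tolist() == [0, 0, 1]
    assert dosage["site1"].tolist() == [1, 0, 0]


def test_wc_theta_zero_when_populations_identical():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.4, size=(50, 80)).astype(float)
    dosage = pd.DataFrame(np.vstack([g, g]),
                          index=[f"i{i}" for i in range(100)])
    pops = pd.Series(["a"] * 50 + ["b"] * 50, index=dosage.index)
    res = wc_fst(dosage, pops)[0]
    # the moment estimator centers near -1/(2n-1) ~ -0.0101 when the two
    # tables are literally identical (s^2 = 0), so bound at 0.015
    assert abs(res.theta) <= 0.015


def test_wc_theta_one_for_fixed_differences():
    n = 30
    dosage = pd.DataFrame(
        np.vstack([np.zeros((n, 40)), np.full((n, 40), 2.0)]),
        index=[f"i{i}" for i in range(2 * n)],
    )
    pops = pd.Series(["a"] * n + ["b"] * n, index=dosage.index)
    res = wc_fst(dosage, pops)[0]
    assert res.theta == pytest.approx(1.0)
    assert not math.isfinite(res.linearized)


def test_wc_theta_allele_label_and_locus_order_invariance():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, rng.uniform(0.1, 0.9, 60), size=(40, 60)).astype(float)
    dosage = pd.DataFrame(g, index=[f"i{i}" for i in range(40)])
    pops = pd.Series(["a"] * 20 + ["b"] * 20, index=dosage.index)
    t0 = wc_fst(dosage, pops)[0].theta
    flipped = 2 - dosage  # swap ref/alt at every site
    assert wc_fst(flipped, pops)[0].theta == pytest.approx(t0, abs=1e-12)
    shuffled = dosage[list(reversed(dosage.columns))]
    assert wc_fst(shuffled, pops)[0].theta == pytest.approx(t0, abs=1e-12)


def test_wc_all_monomorphic_signaled():
    dosage = pd.DataFrame(np.zeros((20, 10)), index=[f"i{i}" for i in range(20)])
    pops = pd.Series(["a"] * 10 + ["b"] * 10, index=dosage.index)
    with pytest.raises(ValueError, match="polymorphic"):
        wc_fst(dosage, pops)


def test_mantel_identity_and_affine_invariance():
    rng = np.random.default_rng(2)
    a = rng.random((6, 6))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    r, p = mantel(a, a, n_permutations=99, seed=0)
    assert r == pytest.approx(1.0)
    r2, _ = mantel(a, 2 * a + 3, n_permutations=99, seed=0)
    assert r2 == pytest.approx(1.0)


def test_mantel_constant_matrix_signaled():
    a = np.zeros((4, 4))
    with pytest.raises(ValueError, match="constant"):
        mantel(a, a, 9, 0)


def test_mantel_seed_reproducible():
    rng = np.random.default_rng(5)
    a = rng.random((8, 8)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
    b = rng.random((8, 8)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
    assert mantel(a, b, 199, 11) == mantel(a, b, 199, 11)


@pytest.mark.parametrize(
    "pts,expected",
    [(((0, 0), (0, 0)), 0.0), (((0, 0), (0, 1)), 111.195)],
)
def test_great_circle_known_values(pts, expected):
    (lat1, lon1), (lat2, lon2) = pts
    assert great_circle_km(lat1, lon1, lat2, lon2) == pytest.approx(expected, abs=0.01)


def test_great_circle_symmetry_and_range_check():
    assert great_circle_km(10, 20, -35, 140) == pytest.approx(
        great_circle_km(-35, 140, 10, 20)
    )
    with pytest.raises(ValueError):
        great_circle_km(95, 0, 0, 0)


def test_pca_kmeans_two_populations_recovered():
    cfg = SimConfig(seed=7, taxa=(TaxonConfig("t", 2, 25, 0.3),), n_loci=300)
    truth = simulate_genotypes(cfg)
    dosage, pops = _dosage_from_truth(truth, "t")
    out = pca_kmeans(dosage, range(1, 6), seed=0)
    assert out["k"] == 2
    lab = out["assignments"].to_numpy()
    truthpop = np.array([int(p[1]) for p in pops])
    agree = max((lab == truthpop).mean(), (lab != truthpop).mean())
    assert agree >= 0.95


def test_pca_kmeans_null_prefers_one_cluster():
    ks = []
    for s in range(10):
        cfg = SimConfig(seed=400 + s, taxa=(TaxonConfig("t", 2, 20, 0.02),),
                        n_loci=200)
        truth = simulate_genotypes(cfg)
        dosage, _ = _dosage_from_truth(truth, "t")
        ks.append(pca_kmeans(dosage, range(1, 5), seed=0)["k"])
    assert sum(k == 1 for k in ks) > len(ks) / 2


def test_pca_kmeans_duplicate_sample_same_cluster():
    cfg = SimConfig(seed=9, taxa=(TaxonConfig("t", 2, 20, 0.3),), n_loci=250)
    truth = simulate_genotypes(cfg)
    dosage, _ = _dosage_from_truth(truth, "t")
    dup = pd.concat([dosage, dosage.iloc[[0]].rename(index={dosage.index[0]: "dup"})])
    out = pca_kmeans(dup, range(1, 5), seed=0)
    assert out["assignments"]["dup"] == out["assignments"][dosage.index[0]]


def test_ibd_gradient_detected_and_island_null():
    coords = pd.DataFrame(
        {"latitude": 0.0, "longitude": np.arange(6, dtype=float)},
        index=[f"p{i}" for i in range(6)],
    )
    cfg = SimConfig(seed=11, taxa=(TaxonConfig("t", 6, 8, 0.05,
                                               structure="stepping_stone"),),
                    n_loci=400)
    truth = simulate_genotypes(cfg)
    dosage, pops = _dosage_from_truth(truth, "t")
    out = ibd_analysis(dosage, pops, coords, n_permutations=199, seed=0)
    assert out["r"] > 0 and out["p"] <= 0.05

    pvals = []
    for s in range(8):
        cfg = SimConfig(seed=500 + s,
                        taxa=(TaxonConfig("t", 6, 6, 0.05),), n_loci=200)
        truth = simulate_genotypes(cfg)
        dosage, pops = _dosage_from_truth(truth, "t")
        out = ibd_analysis(dosage, pops, coords, n_permutations=99, seed=s)
        pvals.append(out["p"])
    assert np.median(pvals) > 0.05


def test_ibd_needs_three_populations():
    cfg = SimConfig(seed=13, taxa=(TaxonConfig("t", 2, 6, 0.1),), n_loci=100)
    truth = simulate_genotypes(cfg)
    dosage, pops = _dosage_from_truth(truth, "t")
    coords = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 1.0]},
                          index=["p0", "p1"])
    with pytest.raises(ValueError, match="3 populations"):
        ibd_analysis(dosage, pops, coords)
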