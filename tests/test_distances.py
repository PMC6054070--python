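import numpy as np
import pandas as pd
import pytest

from radpair.distances import (
    DistanceMatrix,
    flag_problematic_samples,
    genetic_distance,
    locus_overlap_dissimilarity,
    neighbor_joining,
)
from radpair.loci_io import FilterPolicy, LibraryMeta, LociDataset, Locus


def _pm(rows):
    return pd.DataFrame(rows).T.astype(bool)


def test_overlap_dissimilarity_cases():
    pm = _pm({
        "a": [1, 1, 1, 0],
        "b": [0, 1, 1, 1],
        "c": [1, 1, 1, 0],
        "d": [0, 0, 0, 1],
    })
    dm = locus_overlap_dissimilarity(pm)
    assert dm.get("a", "c") == 0.0                       # identical sets
    assert dm.get("a", "d") == 1.0                       # disjoint sets
    assert dm.get("a", "b") == pytest.approx(1 - 2 / 4)  # {1,2,3} vs {2,3,4}
    assert dm.support[0, 1] == 2


def test_overlap_min_denominator_option():
    pm = _pm({"a": [1, 1, 1, 0], "b": [0, 1, 1, 1]})
    dm = locus_overlap_dissimilarity(pm, denominator="min")
    assert dm.get("a", "b") == pytest.approx(1 - 2 / 3)


def test_overlap_empty_pair_is_missing():
    pm = _pm({"a": [1, 0], "b": [0, 0], "c": [0, 0]})
    dm = locus_overlap_dissimilarity(pm)
    assert np.isnan(dm.get("b", "c"))
    assert dm.values[1, 1] == 0.0


def _geno_ds(seqs_flags, depths=None):
    """seqs_flags: list of (members dict, flags array)."""
    names = sorted({n for members, _ in seqs_flags for n in members})
    metas = [LibraryMeta(n, n, "t", "p", "pl", "gDNA") for n in names]
    loci = [
        Locus(f"L{i}", members, flags, depth=None)
        for i, (members, flags) in enumerate(seqs_flags)
    ]
    return LociDataset("t", loci, metas)


GD_POLICY = FilterPolicy(min_coverage=0, min_samples_per_locus=2,
                         min_shared_for_distance=1)


def test_genetic_distance_enumeration_cases():
    v = np.array([1, 0, 0, 0], dtype=np.int8)
    ds = _geno_ds([
        ({"x": "ACGT", "y": "ACGT"}, v),     # identical homozygotes at site 0
        ({"x": "ACGT", "y": "GCGT"}, v),     # A/A vs G/G
        ({"x": "RCGT", "y": "RCGT"}, v),     # R vs R (both A/G)
        ({"x": "ACGT", "y": "RCGT"}, v),     # A/A vs A/G
    ])
    # per-site scores: 0, 1, 0.5, 0.5 -> mean 0.5
    dm = genetic_distance(ds, GD_POLICY)
    assert dm.get("x", "y") == pytest.approx((0 + 1 + 0.5 + 0.5) / 4)
    assert dm.values[0, 0] == 0.0


def test_genetic_distance_ignores_n_and_gap():
    v = np.array([1, 1, 0, 0], dtype=np.int8)
    ds = _geno_ds([
        ({"x": "NCGT", "y": "ACGT"}, v),   # site 0 uncalled in x -> skipped
        ({"x": "-GGT", "y": "AGGT"}, v),
    ])
    # only site 1 of each locus qualifies: C vs C (0), G vs G (0)
    dm = genetic_distance(ds, GD_POLICY)
    assert dm.get("x", "y") == 0.0


def test_genetic_distance_missing_when_no_shared_sites():
    v = np.array([1, 0], dtype=np.int8)
    ds = _geno_ds([
        ({"x": "AC", "y": "NC", "z": "AC"}, v),
    ])
    dm = genetic_distance(ds, GD_POLICY)
    assert np.isnan(dm.get("x", "y"))  # missing, not 0


def test_min_shared_loci_filter_marks_missing():
    v = np.zeros(4, dtype=np.int8)
    v[0] = 1
    ds = _geno_ds([({"x": "ACGT", "y": "GCGT"}, v)])
    strict = FilterPolicy(min_coverage=0, min_samples_per_locus=2,
                          min_shared_for_distance=35)
    dm = genetic_distance(ds, strict)
    assert np.isnan(dm.get("x", "y"))


def _paired_meta():
    return [
        LibraryMeta("s1_g", "s1", "t", "p", "pl", "gDNA"),
        LibraryMeta("s1_m", "s1", "t", "p", "pl", "MDA", 10.0),
        LibraryMeta("s2_g", "s2", "t", "p", "pl", "gDNA"),
        LibraryMeta("s2_m", "s2", "t", "p", "pl", "MDA", 10.0),
    ]


def _dm(labels, d):
    return DistanceMatrix(labels, np.array(d, dtype=float), "genetic")


def test_flag_margin_zero_is_inclusive():
    """d(own pair) equal to the nearest conspecific distance flags."""
    labels = ["s1_g", "s1_m", "s2_g", "s2_m"]
    d = [
        [0.0, 0.2, 0.2, 0.3],
        [0.2, 0.0, 0.25, 0.3],
        [0.2, 0.25, 0.0, 0.1],
        [0.3, 0.3, 0.1, 0.0],
    ]
    flags = flag_problematic_samples(_dm(labels, d), _paired_meta())
    assert bool(flags.loc["s1", "flagged"]) is True   # margin exactly 0
    assert flags.loc["s1", "margin"] == pytest.approx(0.0)
    assert bool(flags.loc["s2", "flagged"]) is False  # 0.2 - 0.1 > 0


def test_flag_identical_pair_not_flagged():
    labels = ["s1_g", "s1_m", "s2_g", "s2_m"]
    d = [
        [0.0, 0.0, 0.2, 0.3],
        [0.0, 0.0, 0.25, 0.3],
        [0.2, 0.25, 0.0, 0.0],
        [0.3, 0.3, 0.0, 0.0],
    ]
    flags = flag_problematic_samples(_dm(labels, d), _paired_meta())
    assert not flags["flagged"].any()
    assert (flags["margin"] > 0).all()


def test_flag_excludes_sample_without_comparator():
    labels = ["s1_g", "s1_m"]
    d = [[0.0, 0.1], [0.1, 0.0]]
    with pytest.warns(UserWarning, match="s1"):
        flags = flag_problematic_samples(_dm(labels, d), _paired_meta()[:2])
    assert len(flags) == 0


def test_nj_three_leaves_solves_three_point_equations():
    labels = ["a", "b", "c"]
    dab, dac, dbc = 0.4, 0.6, 0.8
    d = [[0, dab, dac], [dab, 0, dbc], [dac, 0.8, 0]]
    tree = neighbor_joining(_dm_raw(labels, d))
    dist = {t.name: t.length for t in tree.tips()}
    assert dist["a"] == pytest.approx((dab + dac - dbc) / 2)
    assert dist["b"] == pytest.approx((dab + dbc - dac) / 2)
    assert dist["c"] == pytest.approx((dac + dbc - dab) / 2)


def _dm_raw(labels, d):
    arr = np.array(d, dtype=float)
    arr = (arr + arr.T) / 2
    np.fill_diagonal(arr, 0)
    return DistanceMatrix(labels, arr, "genetic")


def test_nj_recovers_additive_tree():
    """Pairwise path lengths on a random 5-leaf tree are exactly additive;
    neighbor joining must reconstruct them."""
    rng = np.random.default_rng(5)
    # random caterpillar: ((a,b),c),d),e with random positive branch lengths
    bl = dict(zip("abcde", rng.uniform(0.05, 0.5, 5)))
    internal = rng.uniform(0.05, 0.3, 3)
    pos = {"a": 0.0}
    # path distances computed by hand on the caterpillar topology
    labels = list("abcde")
    paths = {
        ("a", "b"): bl["a"] + bl["b"],
        ("a", "c"): bl["a"] + internal[0] + bl["c"],
        ("a", "d"): bl["a"] + internal[0] + internal[1] + bl["d"],
        ("a", "e"): bl["a"] + internal[0] + internal[1] + internal[2] + bl["e"],
        ("b", "c"): bl["b"] + internal[0] + bl["c"],
        ("b", "d"): bl["b"] + internal[0] + internal[1] + bl["d"],
        ("b", "e"): bl["b"] + internal[0] + internal[1] + internal[2] + bl["e"],
        ("c", "d"): bl["c"] + internal[1] + bl["d"],
        ("c", "e"): bl["c"] + internal[1] + internal[2] + bl["e"],
        ("d", "e"): bl["d"] + internal[2] + bl["e"],
    }
    n = 5
    arr = np.zeros((n, n))
    for (x, y), v in paths.items():
        i, j = labels.index(x), labels.index(y)
        arr[i, j] = arr[j, i] = v
    tree = neighbor_joining(DistanceMatrix(labels, arr, "genetic"))
    for (x, y), v in paths.items():
        tx = tree.find(x)
        assert tx.distance(tree.find(y)) == pytest.approx(v, abs=1e-9)


def test_nj_drops_incomplete_and_needs_three():
    labels = ["a", "b", "c"]
    arr = np.array([[0, np.nan, 0.2], [np.nan, 0, 0.3], [0.2, 0.3, 0]])
    with pytest.raises(ValueError, match="3 leaves"):
        with pytest.warns(UserWarning):
            neighbor_joining(DistanceMatrix(labels, arr, "genetic"))


def test_paired_libraries_cluster_as_siblings(small_study):
    """Without contamination, a sample's gDNA and MDA libraries are each
    other's nearest neighbours on the NJ tree."""
    cfg, datasets, metadata, truth = small_study
    ds = datasets["taxon_a"]
    gd = genetic_distance(ds, cfg.filter)
    tree = neighbor_joining(gd)
    n_sib = 0
    samples = {m.sample_id for m in ds.libraries}
    for sid in samples:
        tip = tree.find(f"{sid}_g")
        sibs = {t.name for t in tip.siblings() if t.is_tip()}
        n_sib += f"{sid}_m" in sibs
    assert n_sib >= 0.9 * len(samples)
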