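import numpy as np
import pandas as pd
import pytest

from radpair.loci_io import FilterPolicy, LibraryMeta, LociDataset, Locus
from radpair.synthetic_data import SimConfig, TaxonConfig, simulate_paired_study


@pytest.fixture(scope="session")
def small_study():
    """A deterministic two-taxon paired study used across test modules."""
    cfg = SimConfig(
        seed=1234,
        taxa=(TaxonConfig("taxon_a", 2, 4, 0.1), TaxonConfig("taxon_b", 2, 4, 0.1)),
        n_loci=150,
    )
    datasets, metadata, truth = simulate_paired_study(cfg)
    return cfg, datasets, metadata, truth


@pytest.fixture
def tiny_dataset():
    """Hand-built two-locus dataset with known per-site composition."""
    metas = [
        LibraryMeta("lib1", "s1", "tax", "p0", "pool0", "gDNA"),
        LibraryMeta("lib2", "s2", "tax", "p0", "pool0", "gDNA"),
        LibraryMeta("lib3", "s3", "tax", "p1", "pool0", "gDNA"),
    ]
    loci = [
        Locus(
            "L0",
            {"lib1": "ACGT", "lib2": "ACGT", "lib3": "ACAT"},
            snp_flags=np.array([0, 0, 2, 0]),
            depth={"lib1": 10, "lib2": 8, "lib3": 7},
        ),
        Locus(
            "L1",
            {"lib1": "GGRC", "lib2": "GGAC"},
            snp_flags=np.array([0, 0, 1, 0]),
            depth={"lib1": 12, "lib2": 9},
        ),
    ]
    return LociDataset(taxon="tax", loci=loci, libraries=metas)


@pytest.fixture
def no_depth_policy():
    return FilterPolicy(min_coverage=0, min_samples_per_locus=2)
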