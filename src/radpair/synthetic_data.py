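"""Synthetic ddRAD datasets with paired gDNA/MDA libraries.

The generator emulates the observational design of a paired-library MDA
quality-control study: several taxa, each with island-model (or optionally
stepping-stone) population structure, and for each individual one library
prepared directly from genomic DNA (gDNA) and one from a multiple
displacement amplification (MDA) of the same extract.

Three MDA artifacts are modeled:

* **Locus dropout / coverage overdispersion.**  Per-library locus weights
  are Dirichlet(alpha) and read depths Multinomial over loci.  gDNA
  libraries use a large concentration ``alpha`` (near-even coverage); MDA
  libraries use a concentration that scales linearly with the nanograms
  of template DNA put into the amplification, so low-input MDA gives
  highly uneven coverage, dropping more loci below the assembly depth
  threshold and inflating the depth standard deviation.
* **Allelic imbalance / dropout.**  At heterozygous sites of MDA
  libraries the allele split of the reads is Beta-Binomial with a small
  symmetric Beta parameter, so one allele is often over-amplified; a site
  is called heterozygous only if the minor allele is seen in at least
  ``min_minor_reads`` reads, producing apparent homozygosity.
* **Cross-taxon contamination.**  A fraction of a library's assembled
  locus slots is replaced by loci from a random donor taxon, mimicking
  non-templated amplification of reagent or bench contaminants.

Ground truth (allele frequencies, diploid genotypes, contaminant labels)
is retained so recovery tests can compare estimates against it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .loci_io import (
    HET_CODES,
    FilterPolicy,
    LibraryMeta,
    LociDataset,
    Locus,
    write_loci,
    write_metadata,
)

__all__ = [
    "TaxonConfig",
    "SimConfig",
    "SimTruth",
    "TaxonTruth",
    "LibraryRealization",
    "simulate_genotypes",
    "simulate_library",
    "inject_contamination",
    "simulate_paired_study",
]

_BASES = np.array(list("ACGT"))
_HET_CODE_OF = {frozenset(v): k for k, v in HET_CODES.items()}


@dataclass(frozen=True)
class TaxonConfig:
    name: str
    n_populations: int = 2
    n_individuals_per_pop: int = 6
    fst: float = 0.1
    structure: str = "island"  # or "stepping_stone"

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if self.structure not in ("island", "stepping_stone"):
            raise ValueError("structure must be island or stepping_stone")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic paired-library experiment.

    Defaults mirror a typical reduced-representation study of small
    arthropods: ~100 bp loci, modest polymorphism, paired libraries with
    MDA inputs spanning 6-360 ng of template DNA, an assembly depth
    threshold of 7 reads and a sharing filter of 4 samples per locus.
    """

    seed: int
    taxa: tuple[TaxonConfig, ...] = (TaxonConfig("taxon_a"),)
    n_loci: int = 300
    locus_length: int = 90
    theta: float = 0.02  # per-site polymorphism probability
    reads_per_library: int = 12_000  # ~40x mean locus coverage at 300 loci
    reads_sigma: float = 0.6  # lognormal spread of per-library read counts
    gdna_concentration: float = 200.0
    mda_concentration_at_ref: float = 30.0
    mda_input_ref_ng: float = 300.0
    mda_input_ng_range: tuple[float, float] = (6.0, 360.0)
    imbalance_beta: float = 0.2
    min_minor_reads: int = 2
    contamination_fraction: float = 0.0
    contaminate_first_n_mda: int = 0  # MDA libraries per taxon receiving contamination
    contamination_mode: str = "novel"  # see inject_contamination
    pools_per_taxon: int = 2
    pop_spacing_deg: float = 1.0  # longitudinal spacing of populations
    filter: FilterPolicy = field(default_factory=FilterPolicy)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")
        for name in ("n_loci", "locus_length", "reads_per_library"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must be in [0, 1]")


@dataclass
class TaxonTruth:
    """Ground truth for one taxon."""

    config: TaxonConfig
    ref_seqs: np.ndarray  # (n_loci, L) base characters
    alt_alleles: list[np.ndarray]  # per locus: alt base per variable site
    var_sites: list[np.ndarray]  # per locus: variable column indices
    ancestral_freq: list[np.ndarray]  # per locus: ancestral ref-allele freq
    pop_freqs: list[np.ndarray]  # per locus: (n_pops, n_sites) ref-allele freq
    genotypes: list[np.ndarray]  # per locus: (n_ind_total, n_sites) dosage of alt {0,1,2}
    individuals: list[tuple[str, int]]  # (individual_id, population index)


@dataclass
class SimTruth:
    """Simulator ground truth across taxa plus per-library records."""

    config: SimConfig
    taxa: dict[str, TaxonTruth]
    locus_weights: dict[str, np.ndarray] = field(default_factory=dict)
    contaminant_loci: dict[str, dict[int, tuple[str, int, str]]] = field(default_factory=dict)

    def true_heterozygosity(self, taxon: str, individual_index: int) -> float:
        """Proportion of heterozygous sites over all sites of all loci."""
        tt = self.taxa[taxon]
        n_het = sum(int(np.sum(g[individual_index] == 1)) for g in tt.genotypes)
        total = tt.ref_seqs.shape[0] * tt.ref_seqs.shape[1]
        return n_het / total


@dataclass
class LibraryRealization:
    """Sequenced outcome of one library: depths and called sequences."""

    meta: LibraryMeta
    depths: np.ndarray  # (n_loci,) reads mapped per locus
    sequences: dict[int, str]  # locus index -> called IUPAC sequence (assembled only)
    contaminants: dict[int, tuple[str, int, str]] = field(default_factory=dict)

    @property
    def assembled(self) -> np.ndarray:
        return np.array(sorted(self.sequences), dtype=int)


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """Stable substream: hash the tokens into an offset of the base seed."""
    h = hashlib.sha256(("/".join(map(str, tokens))).encode()).digest()
    sub = int.from_bytes(h[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, sub]))


def simulate_genotypes(config: SimConfig) -> SimTruth:
    """Draw reference loci, population allele frequencies and genotypes.

    Variable-site placement is Binomial(locus_length, theta) per locus.
    Ancestral reference-allele frequencies are Uniform(0.05, 0.95) and
    population frequencies follow the Balding-Nichols model:
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F the configured taxon F_ST.  Under
    ``stepping_stone`` structure the Beta perturbation is applied
    sequentially along the population chain so divergence accumulates
    with distance.  Individuals are diploid Hardy-Weinberg draws within
    their population.
    """
    truth = SimTruth(config=config, taxa={})
    for tc in config.taxa:
        rng = _rng_for(config.seed, "genotypes", tc.name)
        L, nl = config.locus_length, config.n_loci
        ref = _BASES[rng.integers(0, 4, size=(nl, L))]
        alt_alleles, var_sites, anc, pfreqs, genos = [], [], [], [], []
        n_ind = tc.n_populations * tc.n_individuals_per_pop
        F = tc.fst
        for j in range(nl):
            k = rng.binomial(L, config.theta)
            sites = np.sort(rng.choice(L, size=k, replace=False))
            # alt differs from ref at each site
            shift = rng.integers(1, 4, size=k)
            ref_b = ref[j, sites]
            base_idx = np.array([np.where(_BASES == b)[0][0] for b in ref_b], dtype=int)
            alt = _BASES[(base_idx + shift) % 4]
            p_anc = rng.uniform(0.05, 0.95, size=k)
            a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
            if tc.structure == "island":
                pf = rng.beta(a[None, :], b[None, :], size=(tc.n_populations, k)) \
                    if k else np.zeros((tc.n_populations, 0))
            else:
                # stepping stone: chain of Balding-Nichols perturbations
                pf = np.zeros((tc.n_populations, k))
                prev = p_anc
                for pi in range(tc.n_populations):
                    if k:
                        prev = np.clip(prev, 1e-4, 1 - 1e-4)
                        aa = prev * (1 - F) / F
                        bb = (1 - prev) * (1 - F) / F
                        prev = rng.beta(aa, bb)
                    pf[pi] = prev
            g = np.zeros((n_ind, k), dtype=np.int8)
            for pi in range(tc.n_populations):
                sl = slice(pi * tc.n_individuals_per_pop, (pi + 1) * tc.n_individuals_per_pop)
                if k:
                    # dosage of the ALT allele; pf is the REF-allele frequency
                    g[sl] = rng.binomial(2, 1 - pf[pi], size=(tc.n_individuals_per_pop, k))
            alt_alleles.append(alt)
            var_sites.append(sites)
            anc.append(p_anc)
            pfreqs.append(pf)
            genos.append(g)
        individuals = [
            (f"{tc.name}_p{pi}_i{ii}", pi)
            for pi in range(tc.n_populations)
            for ii in range(tc.n_individuals_per_pop)
        ]
        truth.taxa[tc.name] = TaxonTruth(
            config=tc, ref_seqs=ref, alt_alleles=alt_alleles, var_sites=var_sites,
            ancestral_freq=anc, pop_freqs=pfreqs, genotypes=genos,
            individuals=individuals,
        )
    return truth


def _individual_index(tt: TaxonTruth, sample_id: str) -> int:
    for i, (iid, _pi) in enumerate(tt.individuals):
        if iid == sample_id:
            return i
    raise KeyError(sample_id)


def simulate_library(
    truth: SimTruth, meta: LibraryMeta, config: SimConfig
) -> LibraryRealization:
    """Sequence one library: locus depths, genotype calling, dropout.

    Locus weights are Dirichlet(alpha) with alpha = ``gdna_concentration``
    for gDNA and ``mda_concentration_at_ref * input_ng / mda_input_ref_ng``
    (floored at 0.05) for MDA; depths are Multinomial(n_reads, weights).
    A locus is assembled iff its depth reaches ``filter.min_coverage``.
    At heterozygous sites the read split is Binomial(depth, 1/2) for gDNA
    and Beta-Binomial(depth, b, b) with b = ``imbalance_beta`` for MDA; the
    site is called heterozygous only when the minor allele has at least
    ``min_minor_reads`` reads.
    """
    tt = truth.taxa[meta.taxon]
    rng = _rng_for(config.seed, "library", meta.library_id)
    nl = config.n_loci
    if meta.method == "gDNA":
        alpha = config.gdna_concentration
    else:
        ng = meta.input_dna_ng if meta.input_dna_ng is not None else config.mda_input_ref_ng
        alpha = max(config.mda_concentration_at_ref * ng / config.mda_input_ref_ng, 0.05)
    w = rng.dirichlet(np.full(nl, alpha))
    n_reads = meta.n_reads or config.reads_per_library
    depths = rng.multinomial(n_reads, w)
    truth.locus_weights[meta.library_id] = w

    ind = _individual_index(tt, meta.sample_id)
    assembled = np.flatnonzero(depths >= config.filter.min_coverage)
    sequences: dict[int, str] = {}
    for j in assembled:
        seq = tt.ref_seqs[j].copy()
        sites = tt.var_sites[j]
        if sites.size:
            g = tt.genotypes[j][ind]
            alt = tt.alt_alleles[j]
            d = int(depths[j])
            for s_i, col in enumerate(sites):
                if g[s_i] == 0:
                    continue
                if g[s_i] == 2:
                    seq[col] = alt[s_i]
                    continue
                # heterozygote: allele split across d reads
                if meta.method == "MDA":
                    p = rng.beta(config.imbalance_beta, config.imbalance_beta)
                else:
                    p = 0.5
                n_ref = rng.binomial(d, p)
                minor = min(n_ref, d - n_ref)
                if minor >= config.min_minor_reads:
                    seq[col] = _HET_CODE_OF[frozenset({seq[col], alt[s_i]})]
                else:
                    seq[col] = seq[col] if n_ref >= d - n_ref else alt[s_i]
        sequences[int(j)] = "".join(seq)
    return LibraryRealization(meta=meta, depths=depths, sequences=sequences)


def inject_contamination(
    lib: LibraryRealization,
    donor_taxon: str,
    fraction: float,
    truth: SimTruth,
    config: SimConfig,
    mode: str = "novel",
) -> LibraryRealization:
    """Replace a Binomial(n_assembled, fraction) set of locus slots with
    donor-taxon sequences, recording the replacements in the truth.

    ``mode="novel"`` emulates a contaminant too divergent to co-cluster
    with the recipient's loci: each replaced slot becomes a new,
    library-private locus in the assembled dataset, so the sharing
    filter strips it downstream.  ``mode="replace"`` emulates a
    contaminant that out-amplified the template at a homologous locus:
    the donor sequence is recorded under the original locus id,
    corrupting the genotype call — the pathway the genetic-distance
    problematic-sample screen detects.
    """
    if donor_taxon == lib.meta.taxon:
        raise ValueError("donor taxon must differ from the library's taxon")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if mode not in ("novel", "replace"):
        raise ValueError("mode must be 'novel' or 'replace'")
    if fraction == 0:
        return lib
    rng = _rng_for(config.seed, "contam", lib.meta.library_id)
    assembled = lib.assembled
    n = rng.binomial(assembled.size, fraction)
    slots = rng.choice(assembled, size=n, replace=False)
    donor = truth.taxa[donor_taxon]
    donor_loci = rng.integers(0, donor.ref_seqs.shape[0], size=n)
    for slot, dj in zip(slots, donor_loci):
        lib.sequences[int(slot)] = "".join(donor.ref_seqs[dj])
        lib.contaminants[int(slot)] = (donor_taxon, int(dj), mode)
    truth.contaminant_loci[lib.meta.library_id] = dict(lib.contaminants)
    return lib


def _snp_flags_for(column_chars: np.ndarray) -> int:
    """0 invariant, 1 variable, 2 informative (>=2 members carry a minor allele)."""
    counts: dict[str, int] = {}
    for ch in column_chars:
        if ch in "N-":
            continue
        for a in HET_CODES.get(ch, (ch, ch)):
            counts[a] = counts.get(a, 0) + 1
    if len(counts) < 2:
        return 0
    minor = sorted(counts.values())[-2]
    return 2 if minor >= 2 else 1


def build_dataset(
    realizations: list[LibraryRealization],
    metadata: list[LibraryMeta],
    taxon: str,
    truth: SimTruth,
    config: SimConfig,
) -> LociDataset:
    """Assemble per-library realizations into a LociDataset of assembled loci.

    Contaminant slots become loci named after the donor taxon and donor
    locus, so independent contamination events rarely share a locus and
    the sharing filter removes them downstream.
    """
    groups: dict[str, dict[str, str]] = {}
    depth_of: dict[str, dict[str, int]] = {}
    for lib in realizations:
        for j, seq in lib.sequences.items():
            if j in lib.contaminants and lib.contaminants[j][2] == "novel":
                dt, dj, _mode = lib.contaminants[j]
                lid = f"contam_{dt}_L{dj}"
            else:
                lid = f"{taxon}_L{j}"
            groups.setdefault(lid, {})[lib.meta.library_id] = seq
            depth_of.setdefault(lid, {})[lib.meta.library_id] = int(lib.depths[j])
    loci = []
    for lid in sorted(groups, key=_locus_sort_key):
        members = groups[lid]
        L = len(next(iter(members.values())))
        cols = np.array([list(s) for s in members.values()])
        flags = np.array([_snp_flags_for(cols[:, c]) for c in range(L)], dtype=np.int8)
        loci.append(Locus(locus_id=lid, members=members, snp_flags=flags,
                          depth=depth_of[lid]))
    return LociDataset(taxon=taxon, loci=loci, libraries=metadata)


def _locus_sort_key(lid: str):
    return (lid.startswith("contam_"), lid)


def simulate_paired_study(
    config: SimConfig, out_dir=None
) -> tuple[dict[str, LociDataset], list[LibraryMeta], SimTruth]:
    """Run the full synthetic study: genotypes, paired libraries, datasets.

    Every individual gets a gDNA and an MDA library; MDA inputs are
    log-uniform over ``mda_input_ng_range``.  If ``contamination_fraction``
    is positive, the first ``contaminate_first_n_mda`` MDA libraries of
    each taxon (ordered by library id) are contaminated from a random
    other taxon (requires >= 2 taxa).  When ``out_dir`` is given, one
    ``.loci`` file per taxon and a metadata CSV are written there.
    """
    truth = simulate_genotypes(config)
    datasets: dict[str, LociDataset] = {}
    all_meta: list[LibraryMeta] = []
    taxon_names = [tc.name for tc in config.taxa]
    for tc in config.taxa:
        tt = truth.taxa[tc.name]
        rng = _rng_for(config.seed, "design", tc.name)
        metas: list[LibraryMeta] = []
        for iid, pi in tt.individuals:
            lat, lon = 0.0, pi * config.pop_spacing_deg
            pool = f"pool{rng.integers(config.pools_per_taxon)}"
            lo, hi = config.mda_input_ng_range
            ng = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            r_g, r_m = (
                int(max(200, round(config.reads_per_library
                                   * rng.lognormal(0.0, config.reads_sigma))))
                for _ in range(2)
            )
            metas.append(LibraryMeta(f"{iid}_g", iid, tc.name, f"pop{pi}", pool,
                                     "gDNA", None, r_g, lat, lon))
            metas.append(LibraryMeta(f"{iid}_m", iid, tc.name, f"pop{pi}", pool,
                                     "MDA", ng, r_m, lat, lon))
        libs = [simulate_library(truth, m, config) for m in metas]
        if config.contamination_fraction > 0 and len(taxon_names) > 1:
            mda_libs = [l for l in libs if l.meta.method == "MDA"]
            for lib in mda_libs[: config.contaminate_first_n_mda]:
                others = [t for t in taxon_names if t != tc.name]
                d_rng = _rng_for(config.seed, "donor", lib.meta.library_id)
                donor = others[d_rng.integers(len(others))]
                inject_contamination(lib, donor, config.contamination_fraction,
                                     truth, config, mode=config.contamination_mode)
        datasets[tc.name] = build_dataset(libs, metas, tc.name, truth, config)
        all_meta.extend(metas)
    if out_dir is not None:
        import json
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name, ds in datasets.items():
            write_loci(ds, os.path.join(out_dir, f"{name}.loci"))
        write_metadata(all_meta, os.path.join(out_dir, "metadata.csv"))
        # truth JSON schema: seed; per-taxon fst and (individual, population)
        # pairs; per-library contaminant slots as
        # {library_id: {slot: [donor_taxon, donor_locus, mode]}}
        truth_doc = {
            "seed": config.seed,
            "taxa": {
                name: {
                    "fst": tt.config.fst,
                    "structure": tt.config.structure,
                    "individuals": [[iid, pi] for iid, pi in tt.individuals],
                }
                for name, tt in truth.taxa.items()
            },
            "contaminant_loci": {
                lib: {str(slot): list(v) for slot, v in labels.items()}
                for lib, labels in truth.contaminant_loci.items()
            },
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth_doc, fh, indent=2)
    return datasets, all_meta, truth
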