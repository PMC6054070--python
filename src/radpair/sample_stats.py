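"""Per-library summary statistics.

These are the responses and covariates of the downstream models: number
of assembled and final-dataset loci, read-depth mean and standard
deviation across assembled loci, observed heterozygosity over
final-dataset loci, and GC content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loci_io import HET_CODES, FilterPolicy, LociDataset, final_dataset

__all__ = [
    "LibraryStats",
    "count_loci",
    "depth_stats",
    "observed_heterozygosity",
    "gc_content",
    "library_stats",
]

_HET = set(HET_CODES)
_UNCALLED = {"N", "-"}


@dataclass(frozen=True)
class LibraryStats:
    library_id: str
    n_assembled_loci: int
    n_final_loci: int
    mean_depth: float
    sd_depth: float
    heterozygosity: float
    gc_content: float

    def __post_init__(self) -> None:
        if self.n_final_loci > self.n_assembled_loci:
            raise ValueError("n_final_loci cannot exceed n_assembled_loci")


def _assembled_loci(ds: LociDataset, library_id: str, policy: FilterPolicy):
    """Loci in which the library is a member with depth >= min_coverage."""
    out = []
    for loc in ds.loci:
        if library_id not in loc.members:
            continue
        if policy.min_coverage > 0:
            if loc.depth is None:
                raise ValueError(
                    "depth information required for min_coverage filtering"
                )
            if loc.depth.get(library_id, 0) < policy.min_coverage:
                continue
        out.append(loc)
    return out


def count_loci(
    ds: LociDataset, policy: FilterPolicy
) -> pd.DataFrame:
    """Per-library assembled and final-dataset locus counts.

    Assembled = member loci passing the depth threshold; final = the
    subset of those also present in the sharing-filtered dataset.
    """
    fds = final_dataset(ds, policy)
    final_ids = {loc.locus_id for loc in fds.loci}
    rows = []
    for m in ds.libraries:
        assembled = _assembled_loci(ds, m.library_id, policy)
        n_final = sum(1 for loc in assembled if loc.locus_id in final_ids)
        rows.append((m.library_id, len(assembled), n_final))
    return pd.DataFrame(rows, columns=["library_id", "n_assembled_loci", "n_final_loci"]
                        ).set_index("library_id")


def depth_stats(ds: LociDataset, library_id: str,
                policy: FilterPolicy | None = None) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of depth over assembled loci."""
    policy = policy or FilterPolicy()
    loci = _assembled_loci(ds, library_id, policy)
    if not loci:
        raise ValueError(f"library {library_id} has no assembled loci")
    if any(loc.depth is None for loc in loci):
        raise ValueError("dataset carries no per-locus depth information")
    depths = np.array([loc.depth[library_id] for loc in loci], dtype=float)
    sd = float(np.std(depths, ddof=1)) if depths.size > 1 else 0.0
    return float(depths.mean()), sd


def observed_heterozygosity(
    ds: LociDataset, library_id: str, policy: FilterPolicy | None = None
) -> float:
    """Proportion of heterozygous sites among called sites.

    Pooled over the library's sequences in final-dataset loci: a site
    counts as heterozygous when its base is one of the two-allele IUPAC
    codes; N and gaps are excluded from the denominator.
    """
    policy = policy or FilterPolicy()
    fds = final_dataset(ds, policy)
    n_het = n_called = 0
    for loc in fds.loci:
        seq = loc.members.get(library_id)
        if seq is None:
            continue
        for ch in seq:
            if ch in _UNCALLED:
                continue
            n_called += 1
            if ch in _HET:
                n_het += 1
    if n_called == 0:
        raise ValueError(f"library {library_id} has no called sites in final loci")
    return n_het / n_called


def gc_content(ds: LociDataset, library_id: str,
               policy: FilterPolicy | None = None, *, stage: str = "assembled") -> float:
    """GC proportion of called sites over assembled (default) or final loci.

    S counts 1 (G or C either way); the mixed ambiguity codes R/Y/K/M
    count 0.5, which is unbiased under random phase; W counts 0.
    """
    policy = policy or FilterPolicy()
    if stage == "assembled":
        loci = _assembled_loci(ds, library_id, policy)
    elif stage == "final":
        loci = [loc for loc in final_dataset(ds, policy).loci if library_id in loc.members]
    else:
        raise ValueError("stage must be 'assembled' or 'final'")
    gc = 0.0
    n_called = 0
    for loc in loci:
        seq = loc.members.get(library_id)
        if seq is None:
            continue
        for ch in seq:
            if ch in _UNCALLED:
                continue
            n_called += 1
            if ch in "GCS":
                gc += 1.0
            elif ch in "RYKM":
                gc += 0.5
    if n_called == 0:
        raise ValueError(f"library {library_id} has no called sites")
    return gc / n_called


def library_stats(ds: LociDataset, policy: FilterPolicy | None = None) -> pd.DataFrame:
    """Full LibraryStats table for every library in the dataset.

    Libraries with no assembled loci get NaN depth/heterozygosity/GC but
    keep their zero counts.
    """
    policy = policy or FilterPolicy()
    counts = count_loci(ds, policy)
    rows = []
    for m in ds.libraries:
        n_asm = int(counts.loc[m.library_id, "n_assembled_loci"])
        n_fin = int(counts.loc[m.library_id, "n_final_loci"])
        if n_asm:
            try:
                mean_d, sd_d = depth_stats(ds, m.library_id, policy)
            except ValueError:  # no depth information in file-based datasets
                mean_d = sd_d = math.nan
            gc = gc_content(ds, m.library_id, policy)
        else:
            mean_d = sd_d = gc = math.nan
        try:
            het = observed_heterozygosity(ds, m.library_id, policy)
        except ValueError:
            het = math.nan
        rows.append(
            dict(library_id=m.library_id, n_assembled_loci=n_asm, n_final_loci=n_fin,
                 mean_depth=mean_d, sd_depth=sd_d, heterozygosity=het, gc_content=gc)
        )
    return pd.DataFrame(rows).set_index("library_id")
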