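"""Contamination screening against a de-replicated gDNA locus reference.

The reference is built from the final-dataset loci of gDNA libraries of
every taxon, greedily de-replicated at a global-identity threshold
(default 95%), optionally augmented with user-supplied sequences (e.g. a
repeat-masked human genome) registered under a non-self source label.

Each query sequence is classified by best hit: candidate entries are
found through shared k-mers and scored by alignment identity (edit
distance via edlib); a hit requires identity >= ``min_identity`` over at
least ``min_fraction_aligned`` of the query.  Categories: ``correct``
(best entry from the query's own taxon), ``incorrect`` (another taxon),
``human`` (or whatever non-self label), and ``no_match``.

Classification can be run at successive pipeline stages (assembled loci,
final-dataset loci; raw reads for real data) to measure how assembly
filters strip contaminant sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .loci_io import FilterPolicy, LociDataset, final_dataset

__all__ = [
    "ReferenceDB",
    "ClassificationSummary",
    "build_reference",
    "classify",
    "stage_report",
    "write_reference_fasta",
    "read_reference_fasta",
]

CATEGORIES = ("correct", "incorrect", "human", "no_match")


@dataclass
class ReferenceDB:
    """De-replicated reference entries with a k-mer postings index."""

    entries: list[tuple[str, str, str]]  # (entry_id, sequence, source_taxon)
    k: int = 15
    identity: float = 0.95
    index: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k-mer size must be >= 11")
        if not self.index:
            self._build_index()

    def _build_index(self) -> None:
        idx: dict[str, set[int]] = defaultdict(set)
        for i, (_eid, seq, _src) in enumerate(self.entries):
            for p in range(len(seq) - self.k + 1):
                idx[seq[p : p + self.k]].add(i)
        self.index = dict(idx)

    def candidates(self, seq: str, max_candidates: int = 25) -> list[int]:
        hits: dict[int, int] = defaultdict(int)
        for p in range(len(seq) - self.k + 1):
            for i in self.index.get(seq[p : p + self.k], ()):
                hits[i] += 1
        ranked = sorted(hits, key=lambda i: (-hits[i], self.entries[i][0]))
        return ranked[:max_candidates]


def _identity(query: str, target: str) -> float:
    """Global (NW) identity of query vs target: 1 - edits/max_len."""
    res = edlib.align(query, target, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(query), len(target))


def build_reference(
    gdna_final_loci: dict[str, list[str]],
    human_fasta: list[str] | None = None,
    identity: float = 0.95,
    k: int = 15,
) -> ReferenceDB:
    """Greedy length-sorted de-replication of gDNA final-dataset sequences.

    ``gdna_final_loci`` maps taxon name -> sequences from gDNA libraries
    in that taxon's final dataset.  A sequence joins an existing entry of
    the same build when its global identity to the representative is >=
    ``identity`` (forward strand only), otherwise it seeds a new entry.
    Optional ``human_fasta`` sequences are added under source ``human``.
    """
    pool = [
        (taxon, seq.upper())
        for taxon, seqs in sorted(gdna_final_loci.items())
        for seq in seqs
    ]
    if human_fasta:
        pool += [("human", s.upper()) for s in human_fasta]
    if not pool:
        raise ValueError("empty reference input")
    pool.sort(key=lambda t: (-len(t[1]), t[0], t[1]))

    reps: list[tuple[str, str, str]] = []
    # provisional k-mer prefilter over representatives to avoid all-pairs
    idx: dict[str, set[int]] = defaultdict(set)
    for taxon, seq in pool:
        cand: dict[int, int] = defaultdict(int)
        for p in range(len(seq) - k + 1):
            for i in idx.get(seq[p : p + k], ()):
                cand[i] += 1
        joined = False
        for i in sorted(cand, key=lambda i: -cand[i]):
            if _identity(seq, reps[i][1]) >= identity:
                joined = True
                break
        if not joined:
            eid = f"ref{len(reps):05d}_{taxon}"
            reps.append((eid, seq, taxon))
            i = len(reps) - 1
            for p in range(len(seq) - k + 1):
                idx[seq[p : p + k]].add(i)
    return ReferenceDB(entries=reps, k=k, identity=identity)


def write_reference_fasta(db: ReferenceDB, path) -> None:
    """Serialize the reference as FASTA with ``source=`` tags in headers."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=eid, description=f"source={src}")
        for eid, seq, src in db.entries
    ]
    seqio_write(records, str(path), "fasta")


def read_reference_fasta(path, k: int = 15, identity: float = 0.95) -> ReferenceDB:
    """Load a reference written by :func:`write_reference_fasta` (entries
    are taken as already de-replicated)."""
    from Bio.SeqIO import parse as seqio_parse

    entries = []
    for rec in seqio_parse(str(path), "fasta"):
        src = "unknown"
        for tok in rec.description.split():
            if tok.startswith("source="):
                src = tok.removeprefix("source=")
        entries.append((rec.id, str(rec.seq).upper(), src))
    if not entries:
        raise ValueError(f"no sequences in {path}")
    return ReferenceDB(entries=entries, k=k, identity=identity)


@dataclass
class ClassificationSummary:
    """Per-library, per-stage category counts."""

    library_id: str
    stage: str  # "reads", "assembled", or "final"
    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.counts)
        for c in missing:
            self.counts[c] = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, category: str) -> float:
        return self.counts[category] / self.total if self.total else float("nan")


def classify(
    seqs: list[str],
    truth_taxon: str,
    db: ReferenceDB,
    min_identity: float = 0.85,
    min_fraction_aligned: float = 0.5,
    *,
    library_id: str = "",
    stage: str = "assembled",
) -> ClassificationSummary:
    """Best-hit classification of sequences against the reference.

    Candidates come from shared k-mers; each is scored by alignment
    identity.  For queries much shorter than the entry (reads vs loci)
    an infix alignment is used, requiring the aligned span to cover at
    least ``min_fraction_aligned`` of the query; for comparable lengths
    the alignment is global.  Ties break toward ``truth_taxon`` then
    lexicographic entry id.
    """
    counts = {c: 0 for c in CATEGORIES}
    for seq in seqs:
        seq = seq.upper().replace("-", "")
        best_key = best_eid = best_src = None
        for i in db.candidates(seq):
            eid, ref_seq, src = db.entries[i]
            if len(seq) < 0.8 * len(ref_seq):
                # short query vs long entry: infix alignment, full query aligned
                res = edlib.align(seq, ref_seq, mode="HW", task="distance")
                ident = 1.0 - res["editDistance"] / len(seq)
            else:
                ident = _identity(seq, ref_seq)
            frac = 1.0  # both modes align the whole query
            if ident < min_identity or frac < min_fraction_aligned:
                continue
            key = (ident, 1 if src == truth_taxon else 0)
            if (
                best_key is None
                or key > best_key
                or (key == best_key and eid < best_eid)
            ):
                best_key, best_eid, best_src = key, eid, src
        if best_key is None:
            counts["no_match"] += 1
        elif best_src == "human":
            counts["human"] += 1
        elif best_src == truth_taxon:
            counts["correct"] += 1
        else:
            counts["incorrect"] += 1
    return ClassificationSummary(library_id=library_id, stage=stage, counts=counts)


def stage_report(
    datasets: dict[str, LociDataset],
    db: ReferenceDB,
    policy: FilterPolicy | None = None,
    stages: tuple[str, ...] = ("assembled", "final"),
    extra_stage_seqs: dict[tuple[str, str], list[str]] | None = None,
) -> pd.DataFrame:
    """Classify every library at the requested pipeline stages.

    ``assembled`` uses each library's sequences over all loci of its
    dataset; ``final`` restricts to sharing-filtered loci.  ``reads``
    (real data only) is supplied through ``extra_stage_seqs`` keyed by
    ``(library_id, "reads")``.  Returns a tidy table with counts,
    proportions, and per-sample paired MDA-gDNA differences of the
    incorrect proportion merged in where both libraries exist.
    """
    policy = policy or FilterPolicy()
    rows = []
    for taxon, ds in datasets.items():
        stage_loci = {"assembled": ds.loci}
        if "final" in stages:
            stage_loci["final"] = final_dataset(ds, policy).loci
        for m in ds.libraries:
            for stage in stages:
                if stage == "reads":
                    seqs = (extra_stage_seqs or {}).get((m.library_id, "reads"))
                    if seqs is None:
                        continue
                else:
                    seqs = [
                        loc.members[m.library_id]
                        for loc in stage_loci[stage]
                        if m.library_id in loc.members
                    ]
                summ = classify(seqs, taxon, db, library_id=m.library_id, stage=stage)
                row = dict(library_id=m.library_id, sample_id=m.sample_id,
                           taxon=taxon, method=m.method, stage=stage,
                           total=summ.total, **summ.counts)
                for c in CATEGORIES:
                    row[f"p_{c}"] = summ.proportion(c)
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # paired MDA - gDNA difference of incorrect proportions
    diffs = []
    for (sid, stage), grp in table.groupby(["sample_id", "stage"]):
        methods = dict(zip(grp["method"], grp["p_incorrect"]))
        if "MDA" in methods and "gDNA" in methods:
            diffs.append(dict(sample_id=sid, stage=stage,
                              incorrect_diff=methods["MDA"] - methods["gDNA"]))
    if diffs:
        table = table.merge(pd.DataFrame(diffs), on=["sample_id", "stage"], how="left")
    return table
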