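"""Reading and writing of RAD locus alignments and companion tables.

The central on-disk format is the ``.loci`` dialect produced by de novo
RAD assemblers: blocks of ``name<whitespace>sequence`` lines, one block per
locus, each block closed by a separator line starting with ``//`` whose
characters mark variable (``-``) and phylogenetically informative (``*``)
alignment columns, optionally followed by a ``|N|`` locus identifier token.

Sequences are stored uppercase; ``-`` is an alignment gap and ``N`` an
uncalled base.  Heterozygous genotype calls are encoded with the standard
IUPAC two-allele ambiguity letters (R, Y, S, W, K, M).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ALPHABET",
    "HET_CODES",
    "IUPAC_ALLELES",
    "LibraryMeta",
    "Locus",
    "LociDataset",
    "FilterPolicy",
    "LociParseError",
    "read_loci",
    "write_loci",
    "read_metadata",
    "write_metadata",
    "presence_matrix",
    "final_dataset",
    "read_snp_phylip",
    "write_snp_phylip",
]

HET_CODES = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: Map from every accepted base to its (unordered) diploid allele pair.
#: Homozygotes map to two copies of the same base; N and '-' are uncalled.
IUPAC_ALLELES = {b: (b, b) for b in "ACGT"} | HET_CODES

ALPHABET = frozenset("ACGTRYSWKMN-")

# snp_flags codes
INVARIANT, VARIABLE, INFORMATIVE = 0, 1, 2


class LociParseError(ValueError):
    """Raised when a ``.loci`` or SNP matrix file is malformed."""


@dataclass(frozen=True)
class LibraryMeta:
    """Covariates for one sequencing library.

    ``method`` is ``"gDNA"`` for libraries prepared directly from genomic
    DNA and ``"MDA"`` for libraries whose template went through multiple
    displacement amplification; MDA libraries must record the nanograms of
    genomic DNA put into the amplification reaction.
    """

    library_id: str
    sample_id: str
    taxon: str
    population: str
    pool: str
    method: str
    input_dna_ng: float | None = None
    n_reads: int = 0
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("gDNA", "MDA"):
            raise ValueError(f"method must be gDNA or MDA, got {self.method!r}")
        if self.method == "MDA" and self.input_dna_ng is None:
            raise ValueError(f"MDA library {self.library_id} lacks input_dna_ng")
        if self.input_dna_ng is not None and self.input_dna_ng < 0:
            raise ValueError("input_dna_ng must be non-negative")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass
class Locus:
    """One assembled locus: an alignment of member-library sequences."""

    locus_id: str
    members: dict[str, str]
    snp_flags: np.ndarray  # int8 per column: 0 invariant, 1 variable, 2 informative
    depth: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"locus {self.locus_id} has no members")
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) != 1:
            raise LociParseError(
                f"ragged alignment in locus {self.locus_id}: lengths {sorted(lengths)}"
            )
        self.snp_flags = np.asarray(self.snp_flags, dtype=np.int8)
        if len(self.snp_flags) != lengths.pop():
            raise LociParseError(
                f"snp_flags length mismatch in locus {self.locus_id}"
            )

    @property
    def length(self) -> int:
        return len(self.snp_flags)

    def variable_columns(self) -> np.ndarray:
        """Indices of columns flagged variable or informative."""
        return np.flatnonzero(self.snp_flags != INVARIANT)


@dataclass
class LociDataset:
    """A per-taxon collection of loci plus the library metadata table."""

    taxon: str
    loci: list[Locus]
    libraries: list[LibraryMeta]

    def __post_init__(self) -> None:
        ids = [m.library_id for m in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate library_id in metadata")
        known = set(ids)
        unknown = sorted(
            {n for loc in self.loci for n in loc.members if n not in known}
        )
        if unknown:
            raise ValueError(f"locus members absent from metadata: {unknown}")

    @property
    def library_ids(self) -> list[str]:
        return [m.library_id for m in self.libraries]

    def meta(self, library_id: str) -> LibraryMeta:
        for m in self.libraries:
            if m.library_id == library_id:
                return m
        raise KeyError(library_id)


@dataclass(frozen=True)
class FilterPolicy:
    """Dataset-assembly filters.

    ``min_coverage`` is the per-library read depth below which a locus does
    not count as assembled; ``min_samples_per_locus`` is the sharing filter
    defining the final dataset; ``min_shared_for_distance`` is the minimum
    number of shared final loci for a pairwise genetic distance to be
    reported; ``n_exclude_lowest`` optionally drops that many MDA libraries
    with the fewest final loci before paired comparisons.
    """

    min_coverage: int = 7
    min_samples_per_locus: int = 4
    min_final_loci: int = 100
    min_shared_for_distance: int = 35
    n_exclude_lowest: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_coverage",
            "min_samples_per_locus",
            "min_final_loci",
            "min_shared_for_distance",
            "n_exclude_lowest",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_LOCUS_ID_RE = re.compile(r"\|(\S+?)\|\s*$")


def read_loci(path, metadata: list[LibraryMeta] | None = None) -> LociDataset:
    """Parse a ``.loci`` file into a :class:`LociDataset`.

    Parameters
    ----------
    path
        File in the block dialect described in the module docstring.
    metadata
        Library metadata. When given, member names not present in it raise
        an error; when omitted, minimal gDNA metadata is synthesized from
        the member names (useful for ad hoc inspection).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    loci: list[Locus] = []
    block: list[str] = []
    for line in lines:
        if line.startswith("//"):
            loci.append(_parse_block(block, line, ordinal=len(loci)))
            block = []
        elif line.strip():
            block.append(line)
    if block:
        raise LociParseError("trailing locus block without '//' separator")

    if metadata is None:
        names = sorted({n for loc in loci for n in loc.members})
        metadata = [
            LibraryMeta(n, n, taxon="unknown", population="", pool="", method="gDNA")
            for n in names
        ]
    return LociDataset(taxon=metadata[0].taxon if metadata else "unknown",
                       loci=loci, libraries=metadata)


def _parse_block(block: list[str], sep_line: str, ordinal: int) -> Locus:
    m = _LOCUS_ID_RE.search(sep_line)
    locus_id = m.group(1) if m else str(ordinal)
    if not block:
        raise LociParseError(f"empty locus block before separator (locus {locus_id})")
    members: dict[str, str] = {}
    offset = None
    for line in block:
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise LociParseError(f"malformed sample line in locus {locus_id}: {line!r}")
        name, seq = parts[0], parts[1].strip().upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise LociParseError(
                f"invalid characters {sorted(bad)} in locus {locus_id}, sample {name}"
            )
        members[name] = seq
        offset = len(line) - len(line.split(None, 1)[1].strip())  # column where seq starts
    lengths = {len(s) for s in members.values()}
    if len(lengths) != 1:
        raise LociParseError(
            f"ragged alignment in locus {locus_id}: lengths {sorted(lengths)}"
        )
    length = lengths.pop()

    flag_field = sep_line[2:]
    if m:
        flag_field = flag_field[: m.start() - 2]
    # Flags are column-aligned with the sequences; sequence starts at `offset`.
    flag_field = flag_field.ljust(offset - 2 + length)[offset - 2 : offset - 2 + length]
    flags = np.zeros(length, dtype=np.int8)
    for i, ch in enumerate(flag_field):
        if ch == "-":
            flags[i] = VARIABLE
        elif ch == "*":
            flags[i] = INFORMATIVE
    return Locus(locus_id=locus_id, members=members, snp_flags=flags)


def write_loci(ds: LociDataset, path) -> None:
    """Write ``ds`` in the dialect :func:`read_loci` accepts (round-trip stable)."""
    name_w = max((len(n) for loc in ds.loci for n in loc.members), default=2)
    name_w = max(name_w, 2) + 4
    with open(path, "w") as fh:
        for loc in ds.loci:
            for name in sorted(loc.members):
                fh.write(name.ljust(name_w) + loc.members[name] + "\n")
            flag_chars = "".join(
                "-" if f == VARIABLE else "*" if f == INFORMATIVE else " "
                for f in loc.snp_flags
            )
            fh.write("//".ljust(name_w) + flag_chars + f"|{loc.locus_id}|\n")


_META_FIELDS = [
    "library_id",
    "sample_id",
    "taxon",
    "population",
    "pool",
    "method",
    "input_dna_ng",
    "n_reads",
    "latitude",
    "longitude",
]


def _opt_float(v: str) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_metadata(path) -> list[LibraryMeta]:
    """Read the library metadata table (CSV with a header naming the fields)."""
    out: list[LibraryMeta] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_META_FIELDS[:6]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"metadata missing required columns: {sorted(missing)}")
        for row in reader:
            out.append(
                LibraryMeta(
                    library_id=row["library_id"],
                    sample_id=row["sample_id"],
                    taxon=row["taxon"],
                    population=row["population"],
                    pool=row["pool"],
                    method=row["method"],
                    input_dna_ng=_opt_float(row.get("input_dna_ng")),
                    n_reads=int(row.get("n_reads") or 0),
                    latitude=_opt_float(row.get("latitude")),
                    longitude=_opt_float(row.get("longitude")),
                )
            )
    seen: dict[tuple[str, str], str] = {}
    for m in out:
        key = (m.sample_id, m.method)
        if key in seen:
            raise ValueError(f"duplicate (sample_id, method) pair {key}")
        seen[key] = m.library_id
    return out


def write_metadata(metadata: list[LibraryMeta], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_FIELDS)
        for m in metadata:
            writer.writerow(
                [
                    m.library_id,
                    m.sample_id,
                    m.taxon,
                    m.population,
                    m.pool,
                    m.method,
                    "" if m.input_dna_ng is None else repr(m.input_dna_ng),
                    m.n_reads,
                    "" if m.latitude is None else repr(m.latitude),
                    "" if m.longitude is None else repr(m.longitude),
                ]
            )


def presence_matrix(ds: LociDataset) -> pd.DataFrame:
    """Boolean library x locus membership matrix with explicit labels."""
    lib_ids = ds.library_ids
    idx = {l: i for i, l in enumerate(lib_ids)}
    mat = np.zeros((len(lib_ids), len(ds.loci)), dtype=bool)
    cols = []
    for j, loc in enumerate(ds.loci):
        cols.append(loc.locus_id)
        for name in loc.members:
            mat[idx[name], j] = True
    return pd.DataFrame(mat, index=pd.Index(lib_ids, name="library_id"),
                        columns=pd.Index(cols, name="locus_id"))


def final_dataset(ds: LociDataset, policy: FilterPolicy) -> LociDataset:
    """Apply the sharing filter: keep loci with enough member libraries.

    The library list is unchanged; the operation is idempotent.
    """
    kept = [loc for loc in ds.loci if len(loc.members) >= policy.min_samples_per_locus]
    return LociDataset(taxon=ds.taxon, loci=kept, libraries=list(ds.libraries))


_SNP_ALPHABET = frozenset("ACGTRYSWKMN-")


def read_snp_phylip(path) -> pd.DataFrame:
    """Read a relaxed-PHYLIP matrix of unlinked SNP genotypes.

    Returns a DataFrame of single-character IUPAC genotype calls, one row
    per library and one column per SNP site.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise LociParseError("phylip header must give n_rows n_cols")
        n, m = int(header[0]), int(header[1])
        rows: dict[str, list[str]] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip().upper()
            bad = set(seq) - _SNP_ALPHABET
            if bad:
                raise LociParseError(f"invalid genotype characters {sorted(bad)}")
            if len(seq) != m:
                raise LociParseError(
                    f"row {name} has {len(seq)} sites, header says {m}"
                )
            rows[name] = list(seq)
    if len(rows) != n:
        raise LociParseError(f"found {len(rows)} rows, header says {n}")
    return pd.DataFrame.from_dict(rows, orient="index")


def write_snp_phylip(snps: pd.DataFrame, path) -> None:
    name_w = max((len(str(i)) for i in snps.index), default=2) + 2
    with open(path, "w") as fh:
        fh.write(f"{snps.shape[0]} {snps.shape[1]}\n")
        for name, row in snps.iterrows():
            fh.write(str(name).ljust(name_w) + "".join(row) + "\n")
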