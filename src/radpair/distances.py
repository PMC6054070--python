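"""Inter-library distance matrices and the problematic-sample rule.

Two distances are computed between libraries of one taxon:

* **Locus-overlap dissimilarity** ``1 - p`` where ``p`` is the Jaccard
  proportion of final-dataset loci shared by the two libraries
  (``|A ∩ B| / |A ∪ B|``; ``shared/min`` is available as an option).
* **Genetic distance**: the average pairwise difference between the
  alleles of the two libraries at final-dataset SNP sites, ignoring N
  and gaps.  Each IUPAC call expands to its two alleles and a site
  contributes the mean of the four cross-library allele comparisons, so
  values are per-site and lie in [0, 1].

A sample whose gDNA and MDA libraries are genetically farther apart than
the gDNA library is from its nearest conspecific gDNA library is flagged
as problematic (likely contaminated or otherwise biased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loci_io import IUPAC_ALLELES, FilterPolicy, LibraryMeta, LociDataset, final_dataset

__all__ = [
    "DistanceMatrix",
    "locus_overlap_dissimilarity",
    "genetic_distance",
    "flag_problematic_samples",
    "neighbor_joining",
]

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance matrix with shared-locus support counts.

    Undefined pairs (insufficient shared loci, or no qualifying sites)
    are NaN; the diagonal is 0 by convention.
    """

    labels: list[str]
    values: np.ndarray
    kind: str  # "locus_overlap" or "genetic"
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        with np.errstate(invalid="ignore"):
            if not np.allclose(self.values, self.values.T, equal_nan=True):
                raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        sup = self.support[np.ix_(idx, idx)] if self.support is not None else None
        return DistanceMatrix(list(labels), sub, self.kind, sup)

    def complete_labels(self) -> list[str]:
        """Largest label set with no missing pairwise values (greedy removal
        of the label with most missing entries)."""
        vals = self.values.copy()
        keep = list(range(len(self.labels)))
        while True:
            sub = vals[np.ix_(keep, keep)]
            miss = np.isnan(sub).sum(axis=1)
            if miss.max(initial=0) == 0:
                break
            keep.pop(int(np.argmax(miss)))
        return [self.labels[i] for i in keep]


def locus_overlap_dissimilarity(
    pm: pd.DataFrame, *, denominator: str = "union"
) -> DistanceMatrix:
    """1 - (proportion of loci shared) from a boolean presence matrix.

    ``denominator="union"`` gives Jaccard dissimilarity;
    ``denominator="min"`` divides shared counts by the smaller locus set.
    Pairs where both libraries have empty locus sets are NaN.
    """
    if pm.shape[0] < 2:
        raise ValueError("need at least two libraries")
    x = pm.to_numpy(dtype=float)
    inter = x @ x.T
    row = x.sum(axis=1)
    if denominator == "union":
        denom = row[:, None] + row[None, :] - inter
    elif denominator == "min":
        denom = np.minimum(row[:, None], row[None, :])
    else:
        raise ValueError("denominator must be 'union' or 'min'")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / denom
    d[denom == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry despite float noise
    return DistanceMatrix(list(pm.index), d, "locus_overlap",
                          support=inter.astype(int))


def _allele_arrays(ds: LociDataset, policy: FilterPolicy):
    """Stack per-site allele codes over final-dataset SNP sites.

    Returns (a1, a2) int arrays of shape (n_libraries, n_sites) with -1
    for uncalled (absent member, N, or gap), plus the per-library final
    locus presence matrix used for support counts.
    """
    fds = final_dataset(ds, policy)
    lib_ids = ds.library_ids
    idx = {l: i for i, l in enumerate(lib_ids)}
    cols_a1, cols_a2 = [], []
    presence = np.zeros((len(lib_ids), len(fds.loci)), dtype=bool)
    site_locus = []
    for j, loc in enumerate(fds.loci):
        for name in loc.members:
            presence[idx[name], j] = True
        var_cols = loc.variable_columns()
        for c in var_cols:
            a1 = np.full(len(lib_ids), -1, dtype=np.int8)
            a2 = np.full(len(lib_ids), -1, dtype=np.int8)
            for name, seq in loc.members.items():
                ch = seq[c]
                pair = IUPAC_ALLELES.get(ch)
                if pair is None:  # N or gap
                    continue
                a1[idx[name]] = _BASE_CODE[pair[0]]
                a2[idx[name]] = _BASE_CODE[pair[1]]
            cols_a1.append(a1)
            cols_a2.append(a2)
            site_locus.append(j)
    if cols_a1:
        A1 = np.stack(cols_a1, axis=1)
        A2 = np.stack(cols_a2, axis=1)
    else:
        A1 = A2 = np.zeros((len(lib_ids), 0), dtype=np.int8)
    return A1, A2, presence


def genetic_distance(ds: LociDataset, policy: FilterPolicy | None = None) -> DistanceMatrix:
    """Average per-site allele difference between library pairs at SNP sites.

    At each final-dataset SNP site where both libraries carry a called
    base, each genotype expands to two alleles and the site score is the
    mean of the four cross-library allele comparisons (1 when the alleles
    differ).  The distance is the mean score over qualifying sites.
    Pairs sharing fewer than ``policy.min_shared_for_distance`` final loci
    (or with no qualifying site) are NaN.
    """
    policy = policy or FilterPolicy()
    A1, A2, presence = _allele_arrays(ds, policy)
    n = A1.shape[0]
    called = A1 >= 0
    # score_ij per site = 1 - (eq(a1,b1)+eq(a1,b2)+eq(a2,b1)+eq(a2,b2))/4
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for s in range(A1.shape[1]):
        a1, a2, m = A1[:, s], A2[:, s], called[:, s]
        e = (
            (a1[:, None] == a1[None, :]).astype(np.int8)
            + (a1[:, None] == a2[None, :])
            + (a2[:, None] == a1[None, :])
            + (a2[:, None] == a2[None, :])
        )
        valid = m[:, None] & m[None, :]
        sums += np.where(valid, 1.0 - e / 4.0, 0.0)
        counts += valid
    with np.errstate(invalid="ignore"):
        d = sums / counts
    shared = presence.astype(int) @ presence.astype(int).T
    d[shared < policy.min_shared_for_distance] = np.nan
    d[counts == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = np.where(np.isnan(d) | np.isnan(d.T), np.nan, (d + np.transpose(d)) / 2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ds.library_ids, d, "genetic", support=shared)


def flag_problematic_samples(
    gd: DistanceMatrix, metadata: list[LibraryMeta]
) -> pd.DataFrame:
    """Margins Δ for each paired sample; Δ ≤ 0 flags the sample.

    Δ = (distance from the sample's gDNA library to its nearest
    conspecific gDNA library) − (distance between the sample's own gDNA
    and MDA libraries).  A sample whose own pair is at least as distant
    as the nearest other individual (Δ ≤ 0) likely suffered
    contamination or strong genotyping bias in the MDA library.
    Samples lacking a defined own-pair distance or any conspecific
    comparator are excluded with a warning.
    """
    if gd.kind != "genetic":
        raise ValueError("flag_problematic_samples requires a genetic DistanceMatrix")
    by_sample: dict[str, dict[str, LibraryMeta]] = {}
    for m in metadata:
        by_sample.setdefault(m.sample_id, {})[m.method] = m
    rows = []
    labels = set(gd.labels)
    for sid, pair in sorted(by_sample.items()):
        if "gDNA" not in pair or "MDA" not in pair:
            continue
        g, mda = pair["gDNA"], pair["MDA"]
        if g.library_id not in labels or mda.library_id not in labels:
            continue
        d_own = gd.get(g.library_id, mda.library_id)
        comps = [
            gd.get(g.library_id, other["gDNA"].library_id)
            for osid, other in by_sample.items()
            if osid != sid
            and "gDNA" in other
            and other["gDNA"].taxon == g.taxon
            and other["gDNA"].library_id in labels
        ]
        comps = [c for c in comps if not np.isnan(c)]
        if np.isnan(d_own) or not comps:
            warnings.warn(
                f"sample {sid} excluded from problematic-sample test: "
                "no defined own-pair distance or conspecific comparator"
            )
            continue
        delta = min(comps) - d_own
        rows.append(dict(sample_id=sid, taxon=g.taxon, d_own=d_own,
                         d_nearest_conspecific=min(comps), margin=delta,
                         flagged=delta <= 0))
    return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["taxon", "d_own", "d_nearest_conspecific", "margin", "flagged"]
    )


def neighbor_joining(dm: DistanceMatrix):
    """Saitou-Nei neighbor joining; returns a scikit-bio TreeNode.

    Labels with missing pairwise values are dropped (with a warning) to
    obtain a complete submatrix; fewer than three remaining leaves is an
    error.  Serialize with ``tree.write(path)`` or ``str(tree)`` (newick).
    """
    import skbio

    keep = dm.complete_labels()
    if len(keep) < len(dm.labels):
        dropped = sorted(set(dm.labels) - set(keep))
        warnings.warn(f"dropping labels with missing distances: {dropped}")
    if len(keep) < 3:
        raise ValueError("neighbor joining needs at least 3 leaves with complete distances")
    sub = dm.subset(keep)
    sk = skbio.DistanceMatrix(sub.values, ids=keep)
    return skbio.tree.nj(sk)
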