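"""Population-genetics endpoints and missing-data condensing.

Covers: the greedy matrix condenser (joint sample/locus filtering to
bound per-sample missing data), PCA + k-means clustering with BIC model
selection, the Weir-Cockerham (1984) F_ST estimator combined across loci
as a ratio of summed variance components, Mantel tests, great-circle
distances, and isolation-by-distance analysis on linearized F_ST.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loci_io import IUPAC_ALLELES

__all__ = [
    "CondenserPolicy",
    "CondenseResult",
    "FstResult",
    "condense",
    "encode_dosage",
    "pca_kmeans",
    "wc_fst",
    "wc_components",
    "mantel",
    "great_circle_km",
    "ibd_analysis",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class CondenserPolicy:
    """Constraints for missing-data condensing.

    ``max_missing_per_sample`` bounds the per-sample missing fraction
    over retained loci; ``min_samples_grid`` is the set of candidate
    min-samples-per-locus thresholds to search (default: 2..n_samples).
    The objective keeps as many samples as possible, then as many loci.
    """

    max_missing_per_sample: float = 0.5
    min_samples_grid: tuple[int, ...] | None = None
    exact_max_samples: int = 15  # exhaustive search below this; greedy above

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_per_sample <= 1:
            raise ValueError("max_missing_per_sample must be in (0, 1]")


@dataclass
class CondenseResult:
    kept_samples: list[str]
    kept_loci: list[str]
    min_samples: int
    n_samples: int
    n_loci: int


def _condense_at(pm: pd.DataFrame, min_samples: int, max_missing: float):
    """Greedy removal of the worst sample until the constraint holds."""
    samples = list(pm.index)
    x = pm.to_numpy(dtype=bool)
    active = np.ones(len(samples), dtype=bool)
    while active.sum() >= 2:
        sub = x[active]
        locus_ok = sub.sum(axis=0) >= min_samples
        if locus_ok.sum() == 0:
            missing = np.ones(active.sum())
        else:
            missing = 1.0 - sub[:, locus_ok].mean(axis=1)
        if missing.max() <= max_missing:
            kept = [s for s, a in zip(samples, active) if a]
            kept_loci = [c for c, ok in zip(pm.columns, locus_ok) if ok]
            return kept, kept_loci
        # worst sample: highest missingness; ties -> fewer total loci, then id
        idx_active = np.flatnonzero(active)
        order = sorted(
            range(len(idx_active)),
            key=lambda i: (-missing[i], x[idx_active[i]].sum(), samples[idx_active[i]]),
        )
        active[idx_active[order[0]]] = False
    return None, None


def _condense_at_exact(pm: pd.DataFrame, min_samples: int, max_missing: float):
    """Exhaustive search over sample subsets (vectorized over all 2^n masks).

    Returns the feasible subset maximizing (n samples, n loci); among
    ties, the one whose kept-sample id list is lexicographically first.
    """
    samples = list(pm.index)
    x = pm.to_numpy(dtype=bool)
    n, L = x.shape
    masks = np.arange(1 << n, dtype=np.uint32)
    member = ((masks[:, None] >> np.arange(n)) & 1).astype(bool)  # (2^n, n)
    sizes = member.sum(axis=1)
    ok_subsets = sizes >= 2
    counts = member.astype(np.int32) @ x.astype(np.int32)  # (2^n, L)
    locus_ok = counts >= min_samples
    n_loci = locus_ok.sum(axis=1)
    # per-subset per-sample presence over passing loci
    present = np.einsum("sl,nl->sn", locus_ok.astype(np.int32), x.astype(np.int32))
    with np.errstate(invalid="ignore", divide="ignore"):
        miss = 1.0 - present / n_loci[:, None]
    viol = member & ((miss > max_missing) | (n_loci[:, None] == 0))
    feasible = ok_subsets & ~viol.any(axis=1) & (n_loci > 0)
    if not feasible.any():
        return None, None
    idx = np.flatnonzero(feasible)
    order = sorted(idx, key=lambda i: (-sizes[i], -n_loci[i],
                                       [s for s, m in zip(samples, member[i]) if m]))
    i = order[0]
    kept = [s for s, m in zip(samples, member[i]) if m]
    kept_loci = [c for c, ok in zip(pm.columns, locus_ok[i]) if ok]
    return kept, kept_loci


def condense(pm: pd.DataFrame, policy: CondenserPolicy | None = None) -> CondenseResult:
    """Search min-samples thresholds for the best feasible filtering.

    For each candidate threshold the best feasible sample subset is
    found — exactly (exhaustive, vectorized) when the matrix has at most
    ``exact_max_samples`` samples, else greedily by repeatedly removing
    the sample with most missing data.  Selection is by missingness
    alone (never identity or method).  The threshold maximizing (samples
    kept, then loci kept) wins; no feasible solution with >= 2 samples
    is an error.
    """
    policy = policy or CondenserPolicy()
    if pm.size == 0:
        raise ValueError("empty presence matrix")
    grid = policy.min_samples_grid or tuple(range(2, pm.shape[0] + 1))
    exact = pm.shape[0] <= policy.exact_max_samples
    best = None
    for m in grid:
        if exact:
            kept, kept_loci = _condense_at_exact(pm, m, policy.max_missing_per_sample)
        else:
            kept, kept_loci = _condense_at(pm, m, policy.max_missing_per_sample)
        if kept is None:
            continue
        key = (len(kept), len(kept_loci), -m)
        if best is None or key > best[0]:
            best = (key, kept, kept_loci, m)
    if best is None:
        raise ValueError("no feasible condensing with at least 2 samples")
    _key, kept, kept_loci, m = best
    return CondenseResult(kept_samples=kept, kept_loci=kept_loci, min_samples=m,
                          n_samples=len(kept), n_loci=len(kept_loci))


def encode_dosage(snps: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """IUPAC genotype matrix -> alt-allele dosage (0/1/2), NaN missing.

    The reference allele at each site is the most frequent allele; sites
    with more than two alleles across the dataset are dropped and their
    count returned alongside the dosage frame.
    """
    n_dropped = 0
    cols = {}
    for c in snps.columns:
        alleles: dict[str, int] = {}
        pairs = []
        for ch in snps[c]:
            pair = IUPAC_ALLELES.get(ch)
            pairs.append(pair)
            if pair:
                for a in pair:
                    alleles[a] = alleles.get(a, 0) + 1
        if len(alleles) > 2:
            n_dropped += 1
            continue
        if not alleles:
            continue
        ranked = sorted(alleles, key=lambda a: (-alleles[a], a))
        ref = ranked[0]
        col = np.array(
            [math.nan if p is None else (p[0] != ref) + (p[1] != ref) for p in pairs],
            dtype=float,
        )
        cols[c] = col
    return pd.DataFrame(cols, index=snps.index), n_dropped


def pca_kmeans(
    snps: pd.DataFrame,
    k_range: range | tuple[int, ...] = range(1, 7),
    seed: int = 0,
    var_threshold: float = 0.90,
    max_pcs: int = 20,
    n_restarts: int = 10,
):
    """PCA of centered dosages then k-means with BIC model selection.

    ``snps`` may be IUPAC characters (encoded internally) or numeric
    dosages.  Missing genotypes are mean-imputed before PCA.  K-means
    runs on the PCs explaining ``var_threshold`` of the variance (capped
    at ``max_pcs``), for each k in ``k_range`` with seeded restarts; k is
    chosen by minimum BIC = n·ln(WSS/n) + k·ln(n).

    Returns a dict with ``assignments`` (Series), ``scores`` (DataFrame of
    retained PCs), ``k``, and ``bic`` (Series over k).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if snps.dtypes.apply(lambda t: t.kind not in "fiu").any():
        dosage, _ = encode_dosage(snps)
    else:
        dosage = snps.astype(float)
    X = dosage.to_numpy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X = X - X.mean(axis=0)

    n = X.shape[0]
    n_comp = min(n - 1, X.shape[1], max(max_pcs, 1))
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_threshold) + 1)
    n_keep = min(max(n_keep, 1), scores.shape[1])
    S = scores[:, :n_keep]

    bics = {}
    labels_by_k = {}
    for k in k_range:
        if k > n:
            continue
        if k == 1:
            wss = float(((S - S.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            labels = km.fit_predict(S)
            wss = float(km.inertia_)
        bics[k] = n * math.log(max(wss, 1e-12) / n) + k * math.log(n)
        labels_by_k[k] = labels
    if not bics:
        raise ValueError("k_range has no feasible k for this sample size")
    k_best = min(bics, key=lambda k: (bics[k], k))
    return dict(
        assignments=pd.Series(labels_by_k[k_best], index=dosage.index, name="cluster"),
        scores=pd.DataFrame(S, index=dosage.index,
                            columns=[f"PC{i+1}" for i in range(n_keep)]),
        k=k_best,
        bic=pd.Series(bics).sort_index(),
    )


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    linearized: float
    n_loci: int


def wc_components(dosage_by_pop: list[np.ndarray]) -> np.ndarray:
    """Weir-Cockerham (1984) per-site variance components a, b, c.

    Each element of ``dosage_by_pop`` is an (individuals x sites) matrix
    of alt-allele dosages with NaN for missing genotypes.  Returns an
    array (sites, 3); monomorphic sites get all-zero components.
    """
    r = len(dosage_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    n_sites = dosage_by_pop[0].shape[1]
    n_i = np.stack([np.sum(~np.isnan(g), axis=0) for g in dosage_by_pop])  # (r, sites)
    with np.errstate(invalid="ignore"):
        p_i = np.stack([np.nanmean(g, axis=0) / 2 for g in dosage_by_pop])
    # heterozygote proportion among genotyped individuals only
    h_i = np.stack([
        np.where(n > 0, np.sum(g == 1, axis=0) / np.maximum(n, 1), 0.0)
        for g, n in zip(dosage_by_pop, n_i)
    ])
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    comp = np.stack([a, b, c], axis=1)
    mono = (pbar <= 0) | (pbar >= 1) | ~np.isfinite(pbar)
    comp[mono] = 0.0
    comp[nbar <= 1] = 0.0
    return comp


def wc_fst(
    dosage: pd.DataFrame, populations: pd.Series, pairs: bool = True
) -> list[FstResult]:
    """Combined Weir-Cockerham theta per population pair (ratio of sums).

    ``dosage`` is individuals x sites (NaN missing); ``populations`` maps
    each individual to its population.  All-monomorphic input raises.
    """
    pops = sorted(populations.unique())
    results = []
    pop_mats = {p: dosage.loc[populations[populations == p].index].to_numpy()
                for p in pops}
    pair_list = (
        [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
        if pairs
        else [(None, None)]
    )
    for a_pop, b_pop in pair_list:
        if a_pop is None:
            mats = [pop_mats[p] for p in pops]
            a_pop, b_pop = "all", "all"
        else:
            mats = [pop_mats[a_pop], pop_mats[b_pop]]
        comp = wc_components(mats)
        poly = comp.any(axis=1)
        num = comp[:, 0].sum()
        den = comp.sum()
        if not poly.any() or den == 0:
            raise ValueError(f"no polymorphic sites for pair ({a_pop}, {b_pop})")
        theta = float(num / den)
        lin = theta / (1 - theta) if theta < 1 else math.inf
        results.append(FstResult(a_pop, b_pop, theta, lin, int(poly.sum())))
    return results


def mantel(
    dm1, dm2, n_permutations: int = 999, seed: int = 0, alternative: str = "greater"
) -> tuple[float, float]:
    """Mantel test: Pearson r of off-diagonal upper triangles, permutation p.

    ``dm1`` and ``dm2`` are square arrays/DataFrames or DistanceMatrix
    objects over the same labels.  One-tailed (r >= observed) by default;
    ``alternative="two-sided"`` uses \\|r\\|.
    """
    a = _as_array(dm1)
    b = _as_array(dm2)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("mantel requires complete matrices")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        vp = b[np.ix_(p, p)][iu]
        r = float(np.corrcoef(va, vp)[0, 1])
        if alternative == "greater":
            ge += r >= r_obs - 1e-12
        else:
            ge += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, (1 + ge) / (1 + n_permutations)


def _as_array(dm) -> np.ndarray:
    if hasattr(dm, "values") and hasattr(dm, "labels"):
        return np.asarray(dm.values, dtype=float)
    if isinstance(dm, pd.DataFrame):
        return dm.to_numpy(dtype=float)
    return np.asarray(dm, dtype=float)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in kilometers on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude out of range: {lon}")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def ibd_analysis(
    dosage: pd.DataFrame,
    populations: pd.Series,
    coordinates: pd.DataFrame,
    subset_mask: pd.Series | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Isolation by distance: Mantel test of linearized F_ST vs km.

    ``coordinates`` is indexed by population with columns latitude /
    longitude.  ``subset_mask`` (boolean over individuals) restricts the
    analysis, e.g. to gDNA or MDA libraries; populations left with no
    individual are dropped.  Needs >= 3 populations after subsetting.
    """
    if subset_mask is not None:
        dosage = dosage.loc[subset_mask[subset_mask].index.intersection(dosage.index)]
        populations = populations.loc[dosage.index]
    pops = sorted(populations.unique())
    if len(pops) < 3:
        raise ValueError("isolation by distance needs at least 3 populations")
    fst = wc_fst(dosage, populations)
    n = len(pops)
    gen = np.zeros((n, n))
    geo = np.zeros((n, n))
    for res in fst:
        i, j = pops.index(res.pop_a), pops.index(res.pop_b)
        gen[i, j] = gen[j, i] = res.linearized
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i < j:
                d = great_circle_km(
                    coordinates.loc[a, "latitude"], coordinates.loc[a, "longitude"],
                    coordinates.loc[b, "latitude"], coordinates.loc[b, "longitude"],
                )
                geo[i, j] = geo[j, i] = d
    r, p = mantel(gen, geo, n_permutations=n_permutations, seed=seed)
    return dict(r=r, p=p, populations=pops,
                fst=pd.DataFrame([vars(f) for f in fst]),
                linearized_fst=pd.DataFrame(gen, index=pops, columns=pops),
                distance_km=pd.DataFrame(geo, index=pops, columns=pops))
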