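"""Population-structure analyses on multilocus microsatellite genotypes.

Between-group differentiation (Weir-Cockerham theta with a permutation test),
individual-based allele-sharing distances with an unrooted neighbor-joining
tree, PCA on allele-count indicators, genetic dissimilarity versus geographic
distance (with a Mantel-type permutation test), and a Gibbs sampler for the
standard Bayesian admixture model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .locus_stats import wc_locus_components
from .model import MultilocusGenotype, SampleRecord

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters between two WGS84 points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(h))


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over labeled individuals.

    Undefined pairs (no shared scored loci) are ``nan`` and listed in
    ``undefined_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")


def _pairwise_shared(
    genotypes: Sequence[MultilocusGenotype],
) -> tuple[np.ndarray, np.ndarray]:
    """(sum of per-locus shared-allele counts, number of shared loci) per pair."""
    n = len(genotypes)
    loci = genotypes[0].loci
    shared_sum = np.zeros((n, n))
    n_shared = np.zeros((n, n))
    for name in loci:
        calls = [g[name] for g in genotypes]
        alleles = sorted({a for c in calls if not c.is_missing for a in c.alleles})
        index = {a: i for i, a in enumerate(alleles)}
        counts = np.zeros((n, len(alleles) or 1))
        present = np.zeros(n, dtype=bool)
        for i, c in enumerate(calls):
            if not c.is_missing:
                present[i] = True
                counts[i, index[c.alleles[0]]] += 1
                counts[i, index[c.alleles[1]]] += 1
        s = np.minimum(counts[:, None, :], counts[None, :, :]).sum(axis=2)
        both = np.outer(present, present)
        shared_sum += np.where(both, s, 0.0)
        n_shared += both
    return shared_sum, n_shared


def shared_allele_distance(
    genotypes: Sequence[MultilocusGenotype], labels: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """Allele-sharing distance D = 1 - sum(shared_l) / (2 * L_shared)."""
    if len(genotypes) < 2:
        raise ValueError("need >= 2 individuals")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(genotypes))]
    shared_sum, n_shared = _pairwise_shared(genotypes)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared_sum / (2.0 * n_shared)
    np.fill_diagonal(d, 0.0)
    undefined = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if n_shared[i, j] == 0
    ]
    return DistanceMatrix(labels, d, undefined)


def kosman_dissimilarity(
    genotypes: Sequence[MultilocusGenotype], labels: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """Kosman-Leonard dissimilarity: mean over shared loci of d_l = 1 - shared_l/2.

    For diploid data this coincides exactly with
    :func:`shared_allele_distance`; both are exposed because they are distinct
    statistics in the literature.
    """
    if len(genotypes) < 2:
        raise ValueError("need >= 2 individuals")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(genotypes))]
    n = len(genotypes)
    loci = genotypes[0].loci
    d_sum = np.zeros((n, n))
    n_shared = np.zeros((n, n))
    for name in loci:
        calls = [g[name] for g in genotypes]
        for i in range(n):
            if calls[i].is_missing:
                continue
            for j in range(i + 1, n):
                if calls[j].is_missing:
                    continue
                d_l = 1.0 - calls[i].shared_count(calls[j]) / 2.0
                d_sum[i, j] += d_l
                d_sum[j, i] += d_l
                n_shared[i, j] += 1
                n_shared[j, i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        d = d_sum / n_shared
    np.fill_diagonal(d, 0.0)
    undefined = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if n_shared[i, j] == 0
    ]
    return DistanceMatrix(labels, d, undefined)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta with permutation test
# ---------------------------------------------------------------------------

def _locus_index_arrays(genotypes: Sequence[MultilocusGenotype]):
    """Per-locus allele-count matrices for the vectorized theta engine."""
    loci = genotypes[0].loci
    out = []
    for name in loci:
        calls = [g[name] for g in genotypes]
        alleles = sorted({a for c in calls if not c.is_missing for a in c.alleles})
        if len(alleles) < 2:
            continue
        index = {a: i for i, a in enumerate(alleles)}
        n = len(calls)
        counts = np.zeros((n, len(alleles)))
        nonmiss = np.zeros(n)
        for i, c in enumerate(calls):
            if c.is_missing:
                continue
            nonmiss[i] = 1.0
            counts[i, index[c.alleles[0]]] += 1
            counts[i, index[c.alleles[1]]] += 1
        het = (counts == 1).astype(float)
        out.append({"counts": counts, "het": het, "nonmiss": nonmiss})
    return out


def _theta_for_masks(locus_arrays, masks: np.ndarray) -> np.ndarray:
    """Weir-Cockerham theta for each boolean group-1 mask (vectorized, r=2).

    The overall allele frequencies and heterozygote frequencies are invariant
    under permutation of individuals; only group sizes and the among-group
    variance component move.
    """
    B = masks.shape[0]
    num = np.zeros(B)
    den = np.zeros(B)
    M = masks.astype(float)
    for arr in locus_arrays:
        m = arr["nonmiss"]
        counts_m = arr["counts"] * m[:, None]
        het_m = arr["het"] * m[:, None]
        n_tot = m.sum()
        S_tot = counts_m.sum(axis=0)
        H_tot = het_m.sum(axis=0)
        p_bar = S_tot / (2 * n_tot)
        h_bar = H_tot / n_tot
        c = h_bar / 2

        n1 = M @ m
        n2 = n_tot - n1
        valid = (n1 >= 2) & (n2 >= 2)
        n1s = np.where(valid, n1, 2.0)
        n2s = np.where(valid, n2, 2.0)
        S1 = M @ counts_m
        p1 = S1 / (2 * n1s[:, None])
        p2 = (S_tot - S1) / (2 * n2s[:, None])
        n_bar = (n1s + n2s) / 2
        n_c = (n1s + n2s) - (n1s**2 + n2s**2) / (n1s + n2s)
        s2 = (
            n1s[:, None] * (p1 - p_bar) ** 2 + n2s[:, None] * (p2 - p_bar) ** 2
        ) / n_bar[:, None]
        pq = p_bar * (1 - p_bar)
        a = (n_bar / n_c)[:, None] * (
            s2 - (pq - s2 / 2 - h_bar / 4) / (n_bar - 1)[:, None]
        )
        b = (n_bar / (n_bar - 1))[:, None] * (
            pq - s2 / 2 - ((2 * n_bar - 1) / (4 * n_bar))[:, None] * h_bar
        )
        contrib_num = np.where(valid[:, None], a, 0.0).sum(axis=1)
        contrib_den = np.where(valid[:, None], a + b + c, 0.0).sum(axis=1)
        num += contrib_num
        den += contrib_den
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def weir_cockerham_theta(
    group_a: Sequence[MultilocusGenotype], group_b: Sequence[MultilocusGenotype]
) -> float:
    """Multilocus Weir-Cockerham F_ST estimate between two genotype sets."""
    pooled = list(group_a) + list(group_b)
    arrays = _locus_index_arrays(pooled)
    mask = np.zeros((1, len(pooled)), dtype=bool)
    mask[0, : len(group_a)] = True
    return float(_theta_for_masks(arrays, mask)[0])


def pairwise_fst(
    group_a: Sequence[MultilocusGenotype],
    group_b: Sequence[MultilocusGenotype],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """(theta, p): Weir-Cockerham theta and its permutation p-value.

    Significance is assessed by permuting individuals between the two groups
    (group sizes fixed); ``p = (1 + #{theta_perm >= theta_obs}) /
    (n_permutations + 1)``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 individuals")
    pooled = list(group_a) + list(group_b)
    arrays = _locus_index_arrays(pooled)
    n = len(pooled)
    base = np.zeros(n, dtype=bool)
    base[: len(group_a)] = True
    theta = float(_theta_for_masks(arrays, base[None, :])[0])

    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n))
    order = np.argsort(keys, axis=1)
    masks = np.take_along_axis(np.broadcast_to(base, (n_permutations, n)), order, axis=1)
    perm_thetas = _theta_for_masks(arrays, masks)
    p = (1 + int(np.nansum(perm_thetas >= theta - 1e-15))) / (n_permutations + 1)
    return theta, p


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Negative branch lengths are clamped to zero with the excess transferred to
    the sister branch, preserving the pair's summed length.
    """
    if len(dm.labels) < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix has undefined entries")

    d = dm.values.astype(float).copy()
    nodes: list[str] = [f"'{l}'" if any(ch in l for ch in " (),:;") else l for l in dm.labels]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    if len(nodes) == 3:
        d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
        x = max(0.0, (d01 + d02 - d12) / 2)
        y = max(0.0, (d01 + d12 - d02) / 2)
        z = max(0.0, (d02 + d12 - d01) / 2)
        return f"({nodes[0]}:{x:.10g},{nodes[1]}:{y:.10g},{nodes[2]}:{z:.10g});"
    # exactly 2 nodes can only happen for the trivial input n == 2, guarded above
    return f"({nodes[0]}:{d[0,1]/2:.10g},{nodes[1]}:{d[0,1]/2:.10g});"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    labels: list[str]
    coordinates: np.ndarray  # individuals x components
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray


def pca_genotypes(
    genotypes: Sequence[MultilocusGenotype], labels: Optional[Sequence[str]] = None
) -> PCAResult:
    """PCA on the individuals x allele-indicator matrix.

    Entries are per-allele dosages (0/1/2); missing loci are imputed with the
    allele's mean dosage; columns are centered and the covariance matrix
    eigendecomposed (via SVD).
    """
    if len(genotypes) < 3:
        raise ValueError("need >= 3 individuals")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(genotypes))]
    cols = []
    loci = genotypes[0].loci
    for name in loci:
        calls = [g[name] for g in genotypes]
        alleles = sorted({a for c in calls if not c.is_missing for a in c.alleles})
        for allele in alleles:
            col = np.array(
                [
                    np.nan if c.is_missing else float(c.alleles.count(allele))
                    for c in calls
                ]
            )
            cols.append(col)
    X = np.column_stack(cols)
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    X -= X.mean(axis=0)
    if np.allclose(X, 0.0):
        raise ValueError("zero-variance genotype matrix")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (X.shape[0] - 1)
    coords = X @ vt.T
    return PCAResult(labels, coords, eigenvalues, eigenvalues / eigenvalues.sum())


# ---------------------------------------------------------------------------
# Genetic dissimilarity versus geographic distance
# ---------------------------------------------------------------------------

@dataclass
class DissimilarityDistanceResult:
    distances_m: np.ndarray
    dissimilarities: np.ndarray
    running_distance: np.ndarray
    running_mean: np.ndarray
    mantel_r: float
    mantel_p: float
    n_pairs_skipped: int


def dissimilarity_vs_distance(
    samples: Sequence[SampleRecord],
    window_m: float = 20_000.0,
    n_permutations: int = 999,
    seed: int = 0,
) -> DissimilarityDistanceResult:
    """Pair genetic dissimilarity with geographic distance across *samples*.

    Operates on all genotyped samples rather than unique individuals so that
    resampling of the same animal at different sites shows up as
    zero-dissimilarity points at nonzero distance.  The running average is the
    mean dissimilarity within a sliding window of width ``window_m`` centered
    on each observed distance.  A Mantel-type correlation (Pearson, one-sided
    for positive association) is computed by permuting sample identities.
    """
    usable = [
        s
        for s in samples
        if s.consensus is not None and s.lat is not None and s.lon is not None
    ]
    skipped = len([s for s in samples if s.consensus is not None]) - len(usable)
    if len(usable) < 3:
        raise ValueError("need >= 3 samples with coordinates and genotypes")
    gen = kosman_dissimilarity([s.consensus for s in usable], [s.sample_id for s in usable])
    n = len(usable)
    geo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = haversine_m(usable[i].lat, usable[i].lon, usable[j].lat, usable[j].lon)
            geo[i, j] = geo[j, i] = dist

    iu = np.triu_indices(n, k=1)
    gvec = gen.values[iu]
    dvec = geo[iu]
    defined = ~np.isnan(gvec)
    skipped_pairs = int((~defined).sum())
    gvec, dvec = gvec[defined], dvec[defined]

    order = np.argsort(dvec)
    dvec_sorted, gvec_sorted = dvec[order], gvec[order]
    half = window_m / 2
    lo = np.searchsorted(dvec_sorted, dvec_sorted - half, side="left")
    hi = np.searchsorted(dvec_sorted, dvec_sorted + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(gvec_sorted)])
    running = (csum[hi] - csum[lo]) / (hi - lo)

    # Mantel: permute sample identities of the genetic matrix
    def corr(gm: np.ndarray) -> float:
        v = gm[iu]
        mask = ~np.isnan(v)
        return float(np.corrcoef(v[mask], geo[iu][mask])[0, 1])

    r_obs = corr(gen.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        count += corr(gen.values[np.ix_(perm, perm)]) >= r_obs - 1e-15
    p = (1 + count) / (n_permutations + 1)
    return DissimilarityDistanceResult(
        dvec, gvec, dvec_sorted, running, r_obs, p, skipped + skipped_pairs
    )


# ---------------------------------------------------------------------------
# Bayesian admixture clustering (Gibbs sampler)
# ---------------------------------------------------------------------------

@dataclass
class ClusterPosterior:
    """Posterior summary of the admixture model at one K."""

    K: int
    labels: list[str]
    q_matrix: np.ndarray  # individuals x K, posterior mean membership
    log_likelihood_trace: np.ndarray
    lnp_estimate: float


def admixture_cluster(
    genotypes: Sequence[MultilocusGenotype],
    K: int,
    sweeps: int = 6_000,
    burn_in: int = 2_000,
    seed: int = 0,
    alpha: float = 1.0,
    labels: Optional[Sequence[str]] = None,
) -> ClusterPosterior:
    """Gibbs sampler for the standard (non-spatial) admixture model.

    Cluster allele frequencies carry a flat Dirichlet(1) prior; each
    individual's membership vector q_i a symmetric Dirichlet(``alpha``) prior
    with ``alpha`` fixed; each gene copy carries a latent cluster-of-origin
    updated by its conditional multinomial.  Missing gene copies are skipped.
    The per-sweep trace records the data log-likelihood conditional on the
    sampled origins, ``ln P(X | Z, P)``, and
    ``lnp_estimate = mean(lnL) - var(lnL)/2`` over post-burn-in sweeps — the
    usual model-choice score for picking K, which penalizes the extra latent
    freedom of larger K through the variance term.  K=1 reduces to sampling
    allele frequencies only, with every membership identically 1.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sweeps <= burn_in:
        raise ValueError("sweeps must exceed burn_in")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(genotypes))]
    N = len(genotypes)
    loci = genotypes[0].loci
    L = len(loci)

    ind_idx: list[int] = []
    loc_idx: list[int] = []
    all_idx: list[int] = []
    n_alleles = []
    for l, name in enumerate(loci):
        calls = [g[name] for g in genotypes]
        alleles = sorted({a for c in calls if not c.is_missing for a in c.alleles})
        index = {a: i for i, a in enumerate(alleles)}
        n_alleles.append(len(alleles))
        for i, c in enumerate(calls):
            if c.is_missing:
                continue
            for a in c.alleles:
                ind_idx.append(i)
                loc_idx.append(l)
                all_idx.append(index[a])
    ind_arr = np.array(ind_idx)
    loc_arr = np.array(loc_idx)
    all_arr = np.array(all_idx)
    M = ind_arr.size
    Amax = max(n_alleles)
    valid = np.zeros((L, Amax))
    for l, na in enumerate(n_alleles):
        valid[l, :na] = 1.0

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=M)
    q_sum = np.zeros((N, K))
    lnl_trace = np.zeros(sweeps)
    kept = 0
    for sweep in range(sweeps):
        # p | z : Dirichlet(1 + counts) per cluster x locus
        counts = np.zeros((K, L, Amax))
        np.add.at(counts, (z, loc_arr, all_arr), 1.0)
        shape = (counts + 1.0) * valid[None, :, :]
        gam = rng.gamma(np.maximum(shape, 1e-300)) * (shape > 0)
        p = gam / gam.sum(axis=2, keepdims=True)

        # q | z : Dirichlet(alpha + per-individual cluster counts)
        n_ik = np.zeros((N, K))
        np.add.at(n_ik, (ind_arr, z), 1.0)
        gam_q = rng.gamma(alpha + n_ik)
        q = gam_q / gam_q.sum(axis=1, keepdims=True)

        # z | p, q : conditional multinomial per gene copy
        w = q[ind_arr, :] * p[:, loc_arr, all_arr].T  # M x K
        tot = w.sum(axis=1, keepdims=True)
        # data log-likelihood conditional on the sampled origins,
        # ln P(X | Z, P); its mean - var/2 over the run scores K
        lnl_trace[sweep] = float(np.log(p[z, loc_arr, all_arr]).sum())
        if K > 1:
            cum = np.cumsum(w, axis=1)
            u = rng.random(M)[:, None] * tot
            z = (u >= cum).sum(axis=1)
        if sweep >= burn_in:
            q_sum += q
            kept += 1

    post = lnl_trace[burn_in:]
    lnp = float(post.mean() - post.var() / 2)
    return ClusterPosterior(K, labels, q_sum / kept, lnl_trace, lnp)


def best_label_permutation(q: np.ndarray, truth: np.ndarray) -> float:
    """Modal-assignment accuracy after resolving label switching.

    ``truth`` holds integer cluster ids; returns the best accuracy over all
    permutations of cluster labels.
    """
    from itertools import permutations

    K = q.shape[1]
    modal = q.argmax(axis=1)
    best = 0.0
    for perm in permutations(range(K)):
        remap = np.array(perm)[modal]
        best = max(best, float(np.mean(remap == truth)))
    return best
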