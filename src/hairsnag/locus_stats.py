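"""Per-locus diversity and genotyping-error statistics.

Covers allele frequencies, observed and unbiased expected heterozygosity, a
Monte-Carlo exact Hardy-Weinberg test, the Chakraborty null-allele estimator
r = (H_E - H_O)/(H_E + H_O), Weir-Cockerham (1984) variance-component
F-statistics, and the (unbiased) probability of identity P_ID and its
full-sib variant P_IDsib.  These are the quantities a noninvasive-sampling
study needs to decide whether a marker panel can distinguish individuals and
whether apparent homozygote excess signals null alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import LocusGenotype, MultilocusGenotype

NOT_TESTABLE = None


# ---------------------------------------------------------------------------
# Allele frequencies and heterozygosity
# ---------------------------------------------------------------------------

def allele_frequencies(
    genotypes: Sequence[LocusGenotype],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Observed allele frequencies at one locus.

    Returns ``(alleles, freqs, n_gene_copies)`` over non-missing genotypes.
    """
    sizes: list[int] = []
    for g in genotypes:
        if not g.is_missing:
            sizes.extend(g.alleles)
    if not sizes:
        raise ValueError("all genotypes missing at this locus")
    alleles, counts = np.unique(np.asarray(sizes), return_counts=True)
    return alleles, counts / counts.sum(), int(counts.sum())


def heterozygosities(genotypes: Sequence[LocusGenotype]) -> tuple[float, float]:
    """(H_O, H_E): observed heterozygosity and unbiased gene diversity.

    ``H_E = (2n/(2n-1)) * (1 - sum p_i^2)`` with ``n`` the number of
    individuals scored (the small-sample Levene/Nei correction).
    """
    present = [g for g in genotypes if not g.is_missing]
    n = len(present)
    if n < 2:
        raise ValueError("need at least 2 scored individuals")
    h_obs = sum(g.is_heterozygote for g in present) / n
    _, freqs, _ = allele_frequencies(present)
    h_exp = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(freqs**2)))
    return h_obs, h_exp


def gene_diversity_biased(freqs: np.ndarray) -> float:
    """Plain 1 - sum p_i^2, without the small-sample correction."""
    return 1.0 - float(np.sum(np.asarray(freqs) ** 2))


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    p_value: Optional[float]
    statistic: Optional[float]
    testable: bool
    method: str = "monte_carlo_exact"


def _genotype_class_counts(pairs: np.ndarray, k: int) -> np.ndarray:
    """Counts over the k*(k+1)/2 unordered genotype classes, coded i*k+j (i<=j)."""
    lo = pairs.min(axis=-1)
    hi = pairs.max(axis=-1)
    codes = lo * k + hi
    if codes.ndim == 1:
        return np.bincount(codes, minlength=k * k).astype(float)
    B = codes.shape[0]
    offset = (np.arange(B) * k * k)[:, None]
    flat = np.bincount((codes + offset).ravel(), minlength=B * k * k)
    return flat.reshape(B, k * k).astype(float)


def hwe_test(
    genotypes: Sequence[LocusGenotype],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> HWEResult:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    The statistic is the Pearson chi-square of observed genotype-class counts
    against HWE expectations at the observed allele frequencies.  Its null
    distribution is obtained by randomly re-pairing the observed gene copies
    ``n_permutations`` times (allele counts held fixed), and
    ``p = (1 + #{null >= observed}) / (n_permutations + 1)``.  Asymptotic
    chi-square would be invalid here: typical panels have 7-10 alleles scored
    on a few dozen individuals.
    """
    present = [g for g in genotypes if not g.is_missing]
    n = len(present)
    if n < 2:
        raise ValueError("need at least 2 scored individuals")
    alleles, freqs, _ = allele_frequencies(present)
    k = len(alleles)
    if k < 2:
        return HWEResult(NOT_TESTABLE, NOT_TESTABLE, testable=False)

    index = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[index[g.alleles[0]], index[g.alleles[1]]] for g in present])
    expected = np.zeros(k * k)
    for i in range(k):
        expected[i * k + i] = n * freqs[i] ** 2
        for j in range(i + 1, k):
            expected[i * k + j] = 2 * n * freqs[i] * freqs[j]
    valid = expected > 0

    def chi2(counts: np.ndarray) -> np.ndarray:
        diff = counts[..., valid] - expected[valid]
        return (diff**2 / expected[valid]).sum(axis=-1)

    observed_stat = float(chi2(_genotype_class_counts(pairs, k)))

    rng = np.random.default_rng(seed)
    copies = pairs.ravel()
    keys = rng.random((n_permutations, copies.size))
    order = np.argsort(keys, axis=1)
    shuffled = copies[order].reshape(n_permutations, n, 2)
    null_stats = chi2(_genotype_class_counts(shuffled, k))
    p = (1 + int(np.sum(null_stats >= observed_stat - 1e-12))) / (n_permutations + 1)
    return HWEResult(p, observed_stat, testable=True)


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------

def null_allele_chakraborty(h_obs: float, h_exp: float) -> Optional[float]:
    """Chakraborty-type null-allele frequency estimate (H_E-H_O)/(H_E+H_O).

    Negative values indicate heterozygote excess; returns ``None``
    (NOT_TESTABLE) when both heterozygosities are zero.
    """
    denom = h_exp + h_obs
    if denom == 0:
        return NOT_TESTABLE
    return (h_exp - h_obs) / denom


def homozygote_excess_test(
    genotypes: Sequence[LocusGenotype],
    n_simulations: int = 10_000,
    seed: int = 0,
) -> HWEResult:
    """One-sided Monte-Carlo test of homozygote excess (null-allele signal).

    Simulates HWE genotype draws at the observed allele frequencies and
    compares the observed homozygote count against the simulated distribution.
    """
    present = [g for g in genotypes if not g.is_missing]
    n = len(present)
    if n < 2:
        raise ValueError("need at least 2 scored individuals")
    alleles, freqs, _ = allele_frequencies(present)
    if len(alleles) < 2:
        return HWEResult(NOT_TESTABLE, NOT_TESTABLE, testable=False)
    observed_hom = sum(not g.is_heterozygote for g in present)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(alleles), size=(n_simulations, n, 2), p=freqs)
    sim_hom = (draws[..., 0] == draws[..., 1]).sum(axis=1)
    p = (1 + int(np.sum(sim_hom >= observed_hom))) / (n_simulations + 1)
    return HWEResult(p, float(observed_hom), testable=True, method="homozygote_excess")


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def wc_locus_components(
    pop_genotypes: Sequence[Sequence[LocusGenotype]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-allele components (a, b, c) at one locus.

    ``pop_genotypes`` is one genotype list per population sample; missing
    genotypes are excluded per population.  With a single population the
    among-population component ``a`` is identically zero and
    ``f = 1 - sum(c)/sum(b + c)`` estimates F_IS; with several populations
    ``theta = sum(a)/sum(a + b + c)`` estimates F_ST.
    """
    pops = [[g for g in pop if not g.is_missing] for pop in pop_genotypes]
    pops = [pop for pop in pops if pop]
    if not pops or any(len(pop) < 2 for pop in pops):
        raise ValueError("each population needs >= 2 scored individuals")
    alleles = sorted({a for pop in pops for g in pop for a in g.alleles})
    A = len(alleles)
    index = {a: i for i, a in enumerate(alleles)}
    r = len(pops)
    n_j = np.array([len(pop) for pop in pops], dtype=float)
    p_j = np.zeros((r, A))
    h_j = np.zeros((r, A))  # freq of individuals heterozygous for allele A
    for j, pop in enumerate(pops):
        for g in pop:
            i0, i1 = index[g.alleles[0]], index[g.alleles[1]]
            p_j[j, i0] += 1
            p_j[j, i1] += 1
            if i0 != i1:
                h_j[j, i0] += 1
                h_j[j, i1] += 1
        p_j[j] /= 2 * n_j[j]
        h_j[j] /= n_j[j]

    n_bar = n_j.mean()
    n_total = n_j.sum()
    p_bar = (n_j[:, None] * p_j).sum(axis=0) / n_total
    h_bar = (n_j[:, None] * h_j).sum(axis=0) / n_total
    c = h_bar / 2
    if r == 1:
        s2 = np.zeros(A)
        a = np.zeros(A)
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        return a, b, c
    n_c = (n_total - (n_j**2).sum() / n_total) / (r - 1)
    s2 = (n_j[:, None] * (p_j - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    frac = (r - 1) / r
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - frac * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - frac * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    return a, b, c


def fis_weir_cockerham(
    genotypes_by_locus: dict[str, Sequence[LocusGenotype]],
) -> tuple[dict[str, Optional[float]], Optional[float]]:
    """Per-locus and multilocus Weir-Cockerham F_IS for one population.

    Monomorphic loci are excluded (``None`` per locus) and noted by omission
    from the multilocus sums.
    """
    per_locus: dict[str, Optional[float]] = {}
    num = den = 0.0
    for name, gts in genotypes_by_locus.items():
        present = [g for g in gts if not g.is_missing]
        alleles = {a for g in present for a in g.alleles}
        if len(alleles) < 2:
            per_locus[name] = None
            continue
        _, b, c = wc_locus_components([present])
        bc = float((b + c).sum())
        per_locus[name] = 1.0 - float(c.sum()) / bc if bc != 0 else None
        num += float(c.sum())
        den += bc
    multilocus = 1.0 - num / den if den != 0 else None
    return per_locus, multilocus


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------

@dataclass
class PIDResult:
    per_locus_unbiased: dict[str, Optional[float]]
    per_locus_sib: dict[str, float]
    per_locus_biased: dict[str, float]
    cumulative_unbiased: Optional[float]
    cumulative_sib: float
    cumulative_biased: float


def pid_biased(freqs: np.ndarray) -> float:
    """Match probability of two random genotypes at known frequencies: 2*a2^2 - a4."""
    p = np.asarray(freqs, dtype=float)
    a2, a4 = float(np.sum(p**2)), float(np.sum(p**4))
    return 2 * a2**2 - a4


def pid_sib(freqs: np.ndarray) -> float:
    """Probability of identity for full sibs: 0.25 + 0.5*a2 + 0.5*a2^2 - 0.25*a4."""
    p = np.asarray(freqs, dtype=float)
    a2, a4 = float(np.sum(p**2)), float(np.sum(p**4))
    return 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4


def pid_unbiased(freqs: np.ndarray, n_gene_copies: int) -> Optional[float]:
    """Small-sample unbiased estimator of P_ID from estimated frequencies.

    With ``a_k = sum p_i^k`` and ``N`` gene copies::

        (N^3 (2 a2^2 - a4) - 2 N^2 (a3 + 2 a2) + N (9 a2 + 2) - 6)
        / ((N - 1)(N - 2)(N - 3))

    Returns ``None`` (NOT_TESTABLE) for N <= 3; the result is clipped to
    (0, 1].
    """
    N = n_gene_copies
    if N <= 3:
        return NOT_TESTABLE
    p = np.asarray(freqs, dtype=float)
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    num = N**3 * (2 * a2**2 - a4) - 2 * N**2 * (a3 + 2 * a2) + N * (9 * a2 + 2) - 6
    value = num / ((N - 1) * (N - 2) * (N - 3))
    return float(min(1.0, max(value, np.finfo(float).tiny)))


def probability_of_identity(
    freqs_by_locus: dict[str, np.ndarray],
    n_copies_by_locus: dict[str, int],
) -> PIDResult:
    """Per-locus and cumulative P_ID (unbiased) and P_IDsib.

    Cumulative values are products over loci; loci whose unbiased form is not
    testable (N <= 3 gene copies) are excluded from the unbiased product and
    the cumulative unbiased value is ``None`` if no locus is testable.
    """
    unb: dict[str, Optional[float]] = {}
    sib: dict[str, float] = {}
    biased: dict[str, float] = {}
    for name, freqs in freqs_by_locus.items():
        unb[name] = pid_unbiased(freqs, n_copies_by_locus[name])
        sib[name] = min(1.0, pid_sib(freqs))
        biased[name] = min(1.0, pid_biased(freqs))
    testable = [v for v in unb.values() if v is not None]
    cum_unb = float(np.prod(testable)) if testable else None
    return PIDResult(
        per_locus_unbiased=unb,
        per_locus_sib=sib,
        per_locus_biased=biased,
        cumulative_unbiased=cum_unb,
        cumulative_sib=float(np.prod(list(sib.values()))),
        cumulative_biased=float(np.prod(list(biased.values()))),
    )


# ---------------------------------------------------------------------------
# Summary table (one row per locus, Table-2 style)
# ---------------------------------------------------------------------------

def locus_summary(
    genotypes: Sequence[MultilocusGenotype],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus summary: N_allele, H_O, H_E, HWE p, Null_ch (+ its one-sided
    homozygote-excess p), F_IS, P_IDunb and P_IDsib, one row per locus, plus
    multilocus F_IS and cumulative P_ID products in ``DataFrame.attrs``."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    loci = genotypes[0].loci
    by_locus = {name: [g[name] for g in genotypes] for name in loci}
    fis_per_locus, fis_multi = fis_weir_cockerham(by_locus)
    freqs_by_locus: dict[str, np.ndarray] = {}
    n_by_locus: dict[str, int] = {}
    rows = []
    for i, name in enumerate(loci):
        gts = by_locus[name]
        alleles, freqs, n_copies = allele_frequencies(gts)
        freqs_by_locus[name] = freqs
        n_by_locus[name] = n_copies
        h_obs, h_exp = heterozygosities(gts)
        hwe = hwe_test(gts, n_permutations=n_permutations, seed=seed + i)
        null_p = homozygote_excess_test(
            gts, n_simulations=n_permutations, seed=seed + 1000 + i
        )
        rows.append(
            {
                "locus": name,
                "n_alleles": len(alleles),
                "h_obs": h_obs,
                "h_exp": h_exp,
                "hwe_p": hwe.p_value,
                "null_ch": null_allele_chakraborty(h_obs, h_exp),
                "null_excess_p": null_p.p_value,
                "f_is": fis_per_locus[name],
            }
        )
    pid = probability_of_identity(freqs_by_locus, n_by_locus)
    for row in rows:
        row["pid_unb"] = pid.per_locus_unbiased[row["locus"]]
        row["pid_sib"] = pid.per_locus_sib[row["locus"]]
    table = pd.DataFrame(rows)
    table.attrs["multilocus_fis"] = fis_multi
    table.attrs["cumulative_pid_unb"] = pid.cumulative_unbiased
    table.attrs["cumulative_pid_sib"] = pid.cumulative_sib
    return table
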