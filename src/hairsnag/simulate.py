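"""Synthetic noninvasive-sampling datasets with a known truth table.

The generator emulates the data structure of a hair-snag microsatellite
study: a mountain population split over two weakly differentiated provinces
(Balding-Nichols divergence at a target F_ST), ten multiallelic loci,
individuals resampled a variable number of times from sources with very
different DNA quality, and per-replicate genotyping errors (allelic dropout,
false alleles, one-repeat stutter shifts, whole-locus amplification failure
at source-specific rates).  Every emitted sample is linked to its generating
individual in a :class:`TruthTable`, so downstream consensus, identification
and estimation stages can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .consensus import _round_has_mismatch
from .model import (
    Dataset,
    Locus,
    LocusGenotype,
    MISSING,
    MultilocusGenotype,
    SampleRecord,
    Sex,
    Source,
)

#: Published per-source genotyping success rates used as generator defaults
#: (fraction of hair samples yielding >= 8 of 10 loci).
SOURCE_SUCCESS = {
    Source.POLE: 0.2639,
    Source.TREE: 0.5472,
    Source.BARBED_WIRE: 0.8333,
    Source.HAIR_TRAP: 0.4286,
    Source.CAPTURE_HAIR: 0.95,
    Source.TISSUE: 1.0,
}

#: Noninvasive source counts of the emulated study (sums to 144).
SOURCE_COUNTS = {
    Source.POLE: 72,
    Source.TREE: 53,
    Source.BARBED_WIRE: 12,
    Source.HAIR_TRAP: 7,
}

#: Hair-sample counts per collection year (sums to 147, capture hair included).
YEAR_COUNTS = {2008: 34, 2009: 15, 2010: 27, 2011: 30, 2012: 32, 2014: 9}

PROVINCES = ("Artvin", "Bayburt")
PROVINCE_CENTERS = {"Artvin": (41.18, 41.82), "Bayburt": (40.26, 40.22)}


def locus_failure_rate_for_success(
    target_success: float, n_loci: int = 10, min_loci: int = 8
) -> float:
    """Per-replicate per-locus failure rate q reproducing a sample success rate.

    A consensus locus is missing when both replicates fail (probability q^2),
    and a sample succeeds when at most ``n_loci - min_loci`` loci are missing;
    q solves ``P(Binom(n_loci, q^2) <= n_loci - min_loci) = target``.
    """
    if target_success >= 1.0:
        return 0.0
    k = n_loci - min_loci

    def gap(m: float) -> float:
        return stats.binom.cdf(k, n_loci, m) - target_success

    m = optimize.brentq(gap, 1e-9, 1 - 1e-9)
    return float(np.sqrt(m))


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic population and error process.

    Defaults reproduce the emulated study's conditions: 10 loci with 7-10
    alleles, ~55 animals across two provinces at F_ST ~= 0.005, strongly
    male-biased detection at rub objects, and per-source locus-failure rates
    inverted from the published success table.
    """

    n_individuals: int = 55
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (7, 10)
    dirichlet_concentration: float = 1.0
    inbreeding_f: float = 0.0
    n_subpops: int = 2
    subpop_weights: Optional[tuple[float, ...]] = (47 / 55, 8 / 55)
    target_fst: float = 0.005
    sex_ratio_male: float = 0.833
    samples_per_individual: float = 1.67  # Poisson mean; each animal yields 1 + Poisson
    source_mix: dict = field(
        default_factory=lambda: {s: c / 144 for s, c in SOURCE_COUNTS.items()}
    )
    dropout_rate: float = 0.05
    small_allele_dropout_ratio: float = 1 / 3  # shorter fragments amplify better
    false_allele_rate: float = 0.01
    stutter_shift_rate: float = 0.005
    locus_failure_rate: Optional[dict] = None  # per source; derived if None
    sry_error_rate: float = 0.01
    repeat_unit: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_allele_rate", "stutter_shift_rate", "sry_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix must sum to 1")
        if not 0.0 <= self.target_fst < 0.5:
            raise ValueError("target_fst must be in [0, 0.5)")
        if self.locus_failure_rate is None:
            min_loci = max(1, self.n_loci - 2)  # the 8-of-10 rule, scaled
            self.locus_failure_rate = {
                src: locus_failure_rate_for_success(rate, self.n_loci, min_loci)
                for src, rate in SOURCE_SUCCESS.items()
            }


@dataclass
class TrueIndividual:
    genotype: MultilocusGenotype
    sex: Sex
    subpop: int


@dataclass
class TruthTable:
    """Ground truth behind a simulated dataset."""

    individuals: dict[str, TrueIndividual]
    sample_to_individual: dict[str, str] = field(default_factory=dict)
    injected_errors: dict[str, list[dict]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Allele frequencies and true genotypes
# ---------------------------------------------------------------------------

def simulate_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[Locus], list[np.ndarray], list[np.ndarray]]:
    """Draw ancestral and per-subpopulation allele frequencies.

    Ancestral frequencies at each locus are Dirichlet(concentration);
    subpopulation frequencies follow the Balding-Nichols construction
    (Dirichlet around the ancestral vector with scale ``(1-F)/F``), which has
    expected Weir-Cockerham differentiation equal to ``target_fst``.  Returns
    ``(loci, allele_size_arrays, subpop_freqs)`` where each frequency array is
    ``n_subpops x n_alleles`` and rows sum to one.
    """
    loci: list[Locus] = []
    sizes: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    lo, hi = config.alleles_per_locus
    for l in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        base = 90 + 30 * l
        sizes.append(base + config.repeat_unit * np.arange(k))
        loci.append(Locus(f"L{l+1:02d}", config.repeat_unit))
        ancestral = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        ancestral = np.maximum(ancestral, 1e-6)
        ancestral /= ancestral.sum()
        F = config.target_fst
        if F <= 0:
            sub = np.tile(ancestral, (config.n_subpops, 1))
        else:
            scale = (1 - F) / F
            sub = np.vstack(
                [rng.dirichlet(ancestral * scale) for _ in range(config.n_subpops)]
            )
        freqs.append(sub)
    return loci, sizes, freqs


def simulate_individuals(
    loci: Sequence[Locus],
    sizes: Sequence[np.ndarray],
    freqs: Sequence[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TruthTable:
    """Draw true genotypes, sexes and subpopulation labels.

    At each locus an individual is identical-by-descent with probability
    ``inbreeding_f`` (one allele drawn and duplicated); otherwise two alleles
    are drawn independently from its subpopulation's frequencies, i.e. the
    population is in Hardy-Weinberg proportions when ``inbreeding_f = 0``.
    """
    weights = config.subpop_weights or tuple(
        1 / config.n_subpops for _ in range(config.n_subpops)
    )
    counts = [int(round(w * config.n_individuals)) for w in weights]
    counts[0] += config.n_individuals - sum(counts)
    individuals: dict[str, TrueIndividual] = {}
    idx = 0
    for subpop, n_sub in enumerate(counts):
        for _ in range(n_sub):
            idx += 1
            calls = {}
            for locus, size_arr, freq in zip(loci, sizes, freqs):
                p = freq[subpop]
                if rng.random() < config.inbreeding_f:
                    a = b = size_arr[rng.choice(len(p), p=p)]
                else:
                    a = size_arr[rng.choice(len(p), p=p)]
                    b = size_arr[rng.choice(len(p), p=p)]
                calls[locus.name] = LocusGenotype(int(a), int(b))
            sex = Sex.MALE if rng.random() < config.sex_ratio_male else Sex.FEMALE
            individuals[f"T{idx:03d}"] = TrueIndividual(
                MultilocusGenotype(calls), sex, subpop
            )
    return TruthTable(individuals=individuals)


# ---------------------------------------------------------------------------
# Error injection and sampling
# ---------------------------------------------------------------------------

def _mutate_call(
    true_call: LocusGenotype,
    size_arr: np.ndarray,
    repeat_unit: int,
    source: Source,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[LocusGenotype, list[str]]:
    """One replicate's observed call at one locus, with the error kinds injected."""
    errors: list[str] = []
    if rng.random() < config.locus_failure_rate[source]:
        return MISSING, ["locus_failure"]
    alleles = list(true_call.alleles)
    for i in range(2):
        if rng.random() < config.stutter_shift_rate:
            alleles[i] += repeat_unit * (1 if rng.random() < 0.5 else -1)
            errors.append("stutter")
    if rng.random() < config.false_allele_rate:
        i = int(rng.integers(2))
        others = [int(s) for s in size_arr if s != alleles[i]]
        if others:
            alleles[i] = others[int(rng.integers(len(others)))]
            errors.append("false_allele")
    # length-dependent dropout: the larger allele of a heterozygote drops at
    # the full rate, the smaller at a reduced rate
    if alleles[0] == alleles[1]:
        drop_p = [config.dropout_rate, config.dropout_rate]
    else:
        small_rate = config.dropout_rate * config.small_allele_dropout_ratio
        drop_p = [
            small_rate if a == min(alleles) else config.dropout_rate for a in alleles
        ]
    surviving = [a for a, p in zip(alleles, drop_p) if rng.random() >= p]
    if not surviving:
        return MISSING, errors + ["dropout_both"]
    if len(surviving) == 1 and len(set(alleles)) == 2:
        errors.append("dropout")
        return LocusGenotype(surviving[0], None), errors
    return LocusGenotype(min(alleles), max(alleles)), errors


def _make_sample(
    sample_id: str,
    ind_id: str,
    truth: TruthTable,
    source: Source,
    year: int,
    lat: float,
    lon: float,
    province: str,
    loci: Sequence[Locus],
    sizes: Sequence[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SampleRecord:
    ind = truth.individuals[ind_id]
    errors: list[dict] = []

    def one_replicate(ridx: int) -> tuple[MultilocusGenotype, bool]:
        calls = {}
        for locus, size_arr in zip(loci, sizes):
            call, kinds = _mutate_call(
                ind.genotype[locus.name], size_arr, locus.repeat_unit, source, config, rng
            )
            calls[locus.name] = call
            for kind in kinds:
                errors.append({"replicate": ridx, "locus": locus.name, "kind": kind})
        is_male = ind.sex is Sex.MALE
        flag = is_male != (rng.random() < config.sry_error_rate)
        return MultilocusGenotype(calls), flag

    if source is Source.TISSUE:
        mlg, flag = one_replicate(0)
        # tissue extracts are clean: take the true genotype, keep the SRY draw
        reps = [MultilocusGenotype(dict(ind.genotype.calls))]
        flags = [flag]
    else:
        r1, f1 = one_replicate(0)
        r2, f2 = one_replicate(1)
        reps, flags = [r1, r2], [f1, f2]
        if _round_has_mismatch([r1, r2]):  # lab repeats on a fresh extraction
            r3, f3 = one_replicate(2)
            r4, f4 = one_replicate(3)
            reps += [r3, r4]
            flags += [f3, f4]

    truth.sample_to_individual[sample_id] = ind_id
    truth.injected_errors[sample_id] = errors
    return SampleRecord(
        sample_id=sample_id,
        province=province,
        source=source,
        year=year,
        lat=lat,
        lon=lon,
        replicates=reps,
        sry_positive=flags,
    )


def simulate_sampling(
    loci: Sequence[Locus],
    sizes: Sequence[np.ndarray],
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Dataset:
    """Generic sampling stage: each individual yields ``1 + Poisson(mean)``
    samples with sources from ``source_mix`` and jittered coordinates."""
    sources = list(config.source_mix)
    probs = np.array([config.source_mix[s] for s in sources])
    samples: list[SampleRecord] = []
    sid = 0
    homes = {}
    for ind_id, ind in truth.individuals.items():
        prov = PROVINCES[ind.subpop % len(PROVINCES)]
        c_lat, c_lon = PROVINCE_CENTERS[prov]
        homes[ind_id] = (c_lat + rng.normal(0, 0.15), c_lon + rng.normal(0, 0.15))
        n_samples = 1 + int(rng.poisson(config.samples_per_individual))
        for _ in range(n_samples):
            sid += 1
            source = sources[int(rng.choice(len(sources), p=probs))]
            year = int(rng.integers(2008, 2015))
            lat = homes[ind_id][0] + rng.normal(0, 0.02)
            lon = homes[ind_id][1] + rng.normal(0, 0.02)
            samples.append(
                _make_sample(
                    f"S{sid:03d}", ind_id, truth, source, year, lat, lon, prov,
                    loci, sizes, config, rng,
                )
            )
    return Dataset(samples=samples, loci=list(loci))


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Full generic pipeline: frequencies -> individuals -> sampling."""
    rng = np.random.default_rng(config.seed)
    loci, sizes, freqs = simulate_allele_frequencies(config, rng)
    truth = simulate_individuals(loci, sizes, freqs, config, rng)
    dataset = simulate_sampling(loci, sizes, truth, config, rng)
    return dataset, truth


# ---------------------------------------------------------------------------
# Study-like dataset with exact sample accounting
# ---------------------------------------------------------------------------

def _allocate_counts(
    n_items: int, n_bins: int, mean_extra: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-bin counts, each >= 1, drawn 1 + Poisson then adjusted to the exact total."""
    counts = 1 + rng.poisson(mean_extra, size=n_bins)
    while counts.sum() > n_items:
        eligible = np.flatnonzero(counts > 1)
        counts[rng.choice(eligible)] -= 1
    while counts.sum() < n_items:
        counts[int(rng.integers(n_bins))] += 1
    return counts


def generate_study_like_dataset(
    seed: int = 0, config: Optional[SimulationConfig] = None
) -> tuple[Dataset, TruthTable]:
    """A dataset with the emulated study's exact sample accounting.

    154 samples: 7 tissue samples from captured animals, 3 invasive capture
    hairs from a subset of those animals, and 144 noninvasive hairs with
    source counts 72 poles / 53 rubbing trees / 12 barbed wire / 7 hair traps.
    127 hair samples come from the larger eastern province, 20 (one season,
    2012, trees and poles only) from the smaller southwestern one.  Collection
    years follow the published per-year totals.
    """
    config = replace(config, seed=seed) if config else SimulationConfig(seed=seed)
    rng = np.random.default_rng(config.seed)
    loci, sizes, freqs = simulate_allele_frequencies(config, rng)
    truth = simulate_individuals(loci, sizes, freqs, config, rng)

    ids = list(truth.individuals)
    artvin_ids = [i for i in ids if truth.individuals[i].subpop == 0]
    bayburt_ids = [i for i in ids if truth.individuals[i].subpop == 1]

    # source labels for the 125 tree/pole samples, split 105 / 20 by province
    tree_pole = [Source.POLE] * SOURCE_COUNTS[Source.POLE] + [Source.TREE] * SOURCE_COUNTS[Source.TREE]
    tree_pole = [tree_pole[i] for i in rng.permutation(len(tree_pole))]
    artvin_sources = (
        tree_pole[:105]
        + [Source.BARBED_WIRE] * SOURCE_COUNTS[Source.BARBED_WIRE]
        + [Source.HAIR_TRAP] * SOURCE_COUNTS[Source.HAIR_TRAP]
        + [Source.CAPTURE_HAIR] * 3
    )
    artvin_sources = [artvin_sources[i] for i in rng.permutation(len(artvin_sources))]
    bayburt_sources = tree_pole[105:]

    # collection years: the smaller province was sampled in 2012 only
    year_pool = [y for y, c in YEAR_COUNTS.items() for _ in range(c)]
    artvin_years = [y for y in year_pool if True]
    for _ in range(20):
        artvin_years.remove(2012)
    artvin_years = [artvin_years[i] for i in rng.permutation(len(artvin_years))]

    samples: list[SampleRecord] = []
    homes: dict[str, tuple[float, float]] = {}
    sid = 0

    def home(ind_id: str) -> tuple[float, float]:
        if ind_id not in homes:
            prov = PROVINCES[truth.individuals[ind_id].subpop]
            c_lat, c_lon = PROVINCE_CENTERS[prov]
            homes[ind_id] = (c_lat + rng.normal(0, 0.15), c_lon + rng.normal(0, 0.15))
        return homes[ind_id]

    def emit(ind_id: str, source: Source, year: int, province: str) -> None:
        nonlocal sid
        sid += 1
        h_lat, h_lon = home(ind_id)
        samples.append(
            _make_sample(
                f"S{sid:03d}", ind_id, truth, source, year,
                h_lat + rng.normal(0, 0.02), h_lon + rng.normal(0, 0.02),
                province, loci, sizes, config, rng,
            )
        )

    # captured animals: 7 tissue samples, 3 of them also yield capture hair
    captured = [artvin_ids[i] for i in rng.choice(len(artvin_ids), size=7, replace=False)]
    for ind_id in captured:
        emit(ind_id, Source.TISSUE, int(rng.integers(2010, 2012)), "Artvin")

    hair_counts_artvin = _allocate_counts(127, len(artvin_ids), 1.7, rng)
    hair_counts_bayburt = _allocate_counts(20, len(bayburt_ids), 1.5, rng)
    capture_hair_owners = iter(captured[:3])
    artvin_iter = iter(artvin_years)
    queue = [
        (ind_id, int(c))
        for ind_id, c in zip(artvin_ids, hair_counts_artvin)
    ]
    src_iter = iter(artvin_sources)
    for ind_id, c in queue:
        for _ in range(c):
            source = next(src_iter)
            if source is Source.CAPTURE_HAIR:
                owner = next(capture_hair_owners, ind_id)
                emit(owner, source, next(artvin_iter), "Artvin")
            else:
                emit(ind_id, source, next(artvin_iter), "Artvin")
    src_iter = iter(bayburt_sources)
    for ind_id, c in zip(bayburt_ids, hair_counts_bayburt):
        for _ in range(int(c)):
            emit(ind_id, next(src_iter), 2012, "Bayburt")

    return Dataset(samples=samples, loci=list(loci)), truth


# ---------------------------------------------------------------------------
# Scoring identification output against the truth table
# ---------------------------------------------------------------------------

@dataclass
class IdentificationScore:
    n_truth_detected: int  # truth individuals with >= 1 clustered sample
    n_recovered: int  # detected truth individuals forming exactly one pure cluster
    n_splits: int  # truth individuals spread over > 1 cluster
    n_lumps: int  # clusters mixing > 1 truth individual

    @property
    def recovered_fraction(self) -> float:
        return self.n_recovered / self.n_truth_detected if self.n_truth_detected else 1.0


def compare_to_truth(individuals, truth: TruthTable) -> IdentificationScore:
    """Score inferred individuals against the truth table (splits and lumps)."""
    cluster_of = {}
    for ind in individuals:
        for sid in ind.member_sample_ids:
            cluster_of[sid] = ind.individual_id
    truth_clusters: dict[str, set[str]] = {}
    cluster_truths: dict[str, set[str]] = {}
    for sid, cid in cluster_of.items():
        tid = truth.sample_to_individual[sid]
        truth_clusters.setdefault(tid, set()).add(cid)
        cluster_truths.setdefault(cid, set()).add(tid)
    n_lump_clusters = sum(1 for tids in cluster_truths.values() if len(tids) > 1)
    lumped_truths = {
        tid for tids in cluster_truths.values() if len(tids) > 1 for tid in tids
    }
    n_split = sum(1 for cids in truth_clusters.values() if len(cids) > 1)
    n_recovered = sum(
        1
        for tid, cids in truth_clusters.items()
        if len(cids) == 1 and tid not in lumped_truths
    )
    return IdentificationScore(
        n_truth_detected=len(truth_clusters),
        n_recovered=n_recovered,
        n_splits=n_split,
        n_lumps=n_lump_clusters,
    )
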