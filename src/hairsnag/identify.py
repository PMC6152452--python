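"""Individual identification from consensus genotypes.

Two consensus genotypes are attributed to the same animal when they match at
every compared locus, or when their allele differences (at most two, the
``alleleMismatch=2`` convention) can each be explained by a known genotyping
artifact: large-allele dropout (a heterozygote scored elsewhere as a
homozygote for its *smaller* allele — long fragments amplify worse), an
allele-size shift of exactly one repeat unit (PCR stutter), or, for the
two-difference case, missing data at a locus.  Samples are clustered by these
pairwise verdicts; each connected component is one individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import networkx as nx

from .model import (
    Individual,
    LocusGenotype,
    MultilocusGenotype,
    SampleRecord,
    Sex,
    consolidate_calls,
)


class Attribution(str, Enum):
    DROPOUT = "dropout"
    SIZE_SHIFT = "size_shift"
    MISSING_DATA = "missing_data"
    UNEXPLAINED = "unexplained"


@dataclass
class LocusMismatch:
    locus: str
    n_mismatch: int  # 0 for missing-overlap loci
    attribution: Optional[Attribution] = None


@dataclass
class PairClassification:
    """Outcome of comparing two multilocus genotypes.

    ``verdict == "same"`` requires at most two allele mismatches in total and
    no unexplained attribution at any differing locus.
    """

    n_mismatch_alleles: int
    details: list[LocusMismatch] = field(default_factory=list)
    verdict: str = "distinct"

    @property
    def attributions(self) -> list[Attribution]:
        return [d.attribution for d in self.details if d.attribution is not None]


def genotype_mismatch_count(
    g1: MultilocusGenotype, g2: MultilocusGenotype
) -> tuple[int, list[LocusMismatch]]:
    """Total allele mismatches over shared loci, with per-locus detail.

    Per locus the mismatch count is ``2 - |multiset intersection|`` of the two
    allele pairs.  Loci missing in either genotype contribute zero mismatches
    but are recorded as missing-overlap.
    """
    shared = [n for n in g1.loci if n in set(g2.loci)]
    if not shared:
        raise ValueError("genotypes share no loci")
    total = 0
    details: list[LocusMismatch] = []
    for name in shared:
        a, b = g1[name], g2[name]
        if a.is_missing or b.is_missing:
            if a.is_missing != b.is_missing:
                details.append(LocusMismatch(name, 0, Attribution.MISSING_DATA))
            continue
        n_mm = 2 - a.shared_count(b)
        if n_mm:
            details.append(LocusMismatch(name, n_mm))
            total += n_mm
    return total, details


def _attribute_locus(
    a: LocusGenotype, b: LocusGenotype, repeat_unit: int, n_mm: int
) -> Attribution:
    # dropout: one call heterozygous, the other homozygous for the smaller
    # allele (large fragments amplify worse) -- or for either allele when the
    # homozygote carries the low-confidence flag marking it a single-allele
    # observation, i.e. an already-documented dropout suspect
    if n_mm == 1:
        het, hom = (a, b) if a.is_heterozygote and not b.is_heterozygote else (b, a)
        if het.is_heterozygote and not hom.is_heterozygote:
            if hom.alleles[0] == min(het.alleles):
                return Attribution.DROPOUT
            if hom.low_confidence and hom.alleles[0] in het.alleles:
                return Attribution.DROPOUT
    # size shift: leftover alleles pair up at exactly one repeat unit apart
    rest_a, rest_b = list(a.alleles), list(b.alleles)
    for x in a.alleles:
        if x in rest_b:
            rest_a.remove(x)
            rest_b.remove(x)
    if rest_a and len(rest_a) == len(rest_b):
        if all(
            abs(x - y) == repeat_unit
            for x, y in zip(sorted(rest_a), sorted(rest_b))
        ):
            return Attribution.SIZE_SHIFT
    return Attribution.UNEXPLAINED


def classify_pair(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    repeat_units: Mapping[str, int],
    max_mismatch: int = 2,
) -> PairClassification:
    """Classify a genotype pair as same individual or distinct."""
    total, details = genotype_mismatch_count(g1, g2)
    for d in details:
        if d.n_mismatch == 0:
            continue  # already attributed missing_data
        d.attribution = _attribute_locus(
            g1[d.locus], g2[d.locus], repeat_units.get(d.locus, 2), d.n_mismatch
        )
    ok = total <= max_mismatch and all(
        d.attribution is not Attribution.UNEXPLAINED for d in details
    )
    return PairClassification(
        n_mismatch_alleles=total, details=details, verdict="same" if ok else "distinct"
    )


def assign_sex(sry_flags: Sequence[bool]) -> Sex:
    """Sex from the SRY amplification flags of an individual's member samples.

    All positive -> male; all negative -> female.  Mixed evidence: a positive
    majority is called male (SRY dropout in degraded hair is expected), but a
    positive among a majority of negatives is a genuine conflict and is
    reported as such rather than silently resolved.
    """
    if not sry_flags:
        raise ValueError("at least one member sample required")
    pos = sum(bool(f) for f in sry_flags)
    if pos == len(sry_flags):
        return Sex.MALE
    if pos == 0:
        return Sex.FEMALE
    return Sex.MALE if pos > len(sry_flags) - pos else Sex.CONFLICT


def cluster_samples(
    samples: Sequence[SampleRecord],
    repeat_units: Mapping[str, int],
    max_mismatch: int = 2,
) -> list[Individual]:
    """Cluster consensus samples into individuals.

    Builds a graph with an edge for every pair whose verdict is ``same`` and
    takes connected components.  A component containing a pair that conflicts
    (verdict ``distinct``) arises from non-transitive chaining; it is flagged
    and split at its weakest edge (the ``same`` edge with the most allele
    mismatches) until internally consistent.  Output is deterministic and
    invariant to input order: individuals are numbered by their first member
    sample id.
    """
    recs = sorted(
        (r for r in samples if r.consensus is not None), key=lambda r: r.sample_id
    )
    by_id = {r.sample_id: r for r in recs}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    verdicts: dict[tuple[str, str], PairClassification] = {}
    for i, r1 in enumerate(recs):
        for r2 in recs[i + 1 :]:
            cls = classify_pair(r1.consensus, r2.consensus, repeat_units, max_mismatch)
            verdicts[(r1.sample_id, r2.sample_id)] = cls
            if cls.verdict == "same":
                graph.add_edge(
                    r1.sample_id, r2.sample_id, weight=cls.n_mismatch_alleles
                )

    def component_conflicts(nodes: list[str]) -> bool:
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                key = (u, v) if (u, v) in verdicts else (v, u)
                if verdicts[key].verdict == "distinct":
                    return True
        return False

    flagged: set[str] = set()
    while True:
        bad = None
        for comp in nx.connected_components(graph):
            nodes = sorted(comp)
            if len(nodes) > 1 and component_conflicts(nodes):
                bad = nodes
                break
        if bad is None:
            break
        flagged.update(bad)
        edges = sorted(
            graph.subgraph(bad).edges(data="weight"),
            key=lambda e: (-e[2], e[0], e[1]),
        )
        graph.remove_edge(edges[0][0], edges[0][1])

    individuals: list[Individual] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for idx, comp in enumerate(components, start=1):
        members = sorted(comp)
        member_recs = [by_id[m] for m in members]
        loci = member_recs[0].consensus.loci
        calls = {
            name: consolidate_calls(r.consensus[name] for r in member_recs)
            for name in loci
        }
        flags = ["nontransitive_chain"] if any(m in flagged for m in members) else []
        individuals.append(
            Individual(
                individual_id=f"IND{idx:03d}",
                member_sample_ids=members,
                consolidated_genotype=MultilocusGenotype(calls),
                sex=assign_sex([r.sry_any_positive for r in member_recs]),
                provinces_seen={r.province for r in member_recs},
                flags=flags,
            )
        )
    return individuals


def filter_for_analysis(
    individuals: Sequence[Individual], max_missing_loci: int = 1
) -> list[Individual]:
    """Retain individuals whose consolidated genotype misses at most
    ``max_missing_loci`` loci (default 1 of 10)."""
    return [
        ind
        for ind in individuals
        if ind.consolidated_genotype.n_missing_loci <= max_missing_loci
    ]
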