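"""Replicate-consensus genotyping.

Noninvasive extracts are genotyped twice in parallel; if any locus mismatches
between the two replicates, the whole sample is re-extracted and genotyped
twice again, and a mismatch in that second round discards the sample.  The
consensus is built from the accepted round; a locus that amplified in only one
replicate of the round is accepted but flagged low-confidence, and a locus
that failed in both replicates is missing.
"""

from __future__ import annotations

import copy
from enum import Enum
from typing import Sequence

from .model import Dataset, LocusGenotype, MISSING, MultilocusGenotype, SampleRecord


class LocusConsensusStatus(str, Enum):
    CONFIRMED = "confirmed"
    CONFIRMED_SINGLE = "confirmed_single"  # one replicate amplified
    MISMATCH = "mismatch"
    FAILED = "failed"  # no replicate amplified


ACCEPTED = "accepted"
DISCARDED = "discarded"
MISMATCH_UNRESOLVED = "mismatch_unresolved"


def consensus_locus(
    replicate_calls: Sequence[LocusGenotype],
) -> tuple[LocusGenotype, LocusConsensusStatus]:
    """Collapse replicate calls at one locus.

    All non-missing full calls identical -> that call (``confirmed``, or
    ``confirmed_single`` with a low-confidence flag if only one replicate
    amplified); any disagreement -> missing (``mismatch``); all missing ->
    missing (``failed``).

    A provisional homozygote (single-allele observation, the signature of
    allelic dropout) is *compatible* with any call containing its observed
    allele and is resolved to the more informative call rather than scored as
    a mismatch: e.g. one replicate showing only allele 100 agrees with a
    (100, 102) heterozygote seen in the other replicate.  Two full calls that
    differ — including a confirmed homozygote against a heterozygote — remain
    a mismatch.
    """
    if not replicate_calls:
        raise ValueError("consensus_locus requires at least one call")
    present = [g for g in replicate_calls if not g.is_missing]
    if not present:
        return MISSING, LocusConsensusStatus.FAILED
    full = [g for g in present if not g.low_confidence]
    provisional = [g for g in present if g.low_confidence]

    if full:
        first = full[0]
        if any(not g.same_call(first) for g in full[1:]):
            return MISSING, LocusConsensusStatus.MISMATCH
        if any(p.allele_a not in first.alleles for p in provisional):
            return MISSING, LocusConsensusStatus.MISMATCH
        if len(full) >= 2:
            return LocusGenotype(first.allele_a, first.allele_b), LocusConsensusStatus.CONFIRMED
        flagged = LocusGenotype(first.allele_a, first.allele_b, low_confidence=True)
        return flagged, LocusConsensusStatus.CONFIRMED_SINGLE
    # only single-allele observations
    first = provisional[0]
    if any(not g.same_call(first) for g in provisional[1:]):
        return MISSING, LocusConsensusStatus.MISMATCH
    status = (
        LocusConsensusStatus.CONFIRMED
        if len(provisional) == len(replicate_calls) and len(provisional) >= 2
        else LocusConsensusStatus.CONFIRMED_SINGLE
    )
    return first, status


def _round_has_mismatch(round_reps: Sequence[MultilocusGenotype]) -> bool:
    for name in round_reps[0].loci:
        _, status = consensus_locus([r[name] for r in round_reps])
        if status is LocusConsensusStatus.MISMATCH:
            return True
    return False


def consensus_sample(record: SampleRecord) -> SampleRecord:
    """Apply the two-round repeat-then-discard rule to one sample.

    Returns a copy with ``consensus`` and ``consensus_status`` filled in.
    Tissue samples pass through: their single replicate is the consensus.
    Round 1 is replicates 1-2; a locus mismatch there demands round 2
    (replicates 3-4); a mismatch in round 2 discards the sample.  A
    two-replicate sample whose round 1 mismatches has no second extraction on
    fixed data and is reported ``mismatch_unresolved`` (treated as discarded).
    """
    rec = copy.deepcopy(record)
    if rec.is_tissue:
        if len(rec.replicates) != 1:
            raise ValueError("tissue samples carry exactly one replicate")
        rec.consensus = rec.replicates[0]
        rec.consensus_status = ACCEPTED
        return rec
    if len(rec.replicates) not in (2, 4):
        raise ValueError(
            f"{rec.sample_id}: expected 2 or 4 replicates, got {len(rec.replicates)}"
        )

    round1 = rec.replicates[:2]
    if not _round_has_mismatch(round1):
        accepted = round1
    elif len(rec.replicates) == 2:
        rec.consensus = None
        rec.consensus_status = MISMATCH_UNRESOLVED
        return rec
    else:
        round2 = rec.replicates[2:4]
        if _round_has_mismatch(round2):
            rec.consensus = None
            rec.consensus_status = DISCARDED
            return rec
        accepted = round2

    calls = {}
    for name in accepted[0].loci:
        call, status = consensus_locus([r[name] for r in accepted])
        calls[name] = call
        if status is LocusConsensusStatus.CONFIRMED_SINGLE:
            rec.qc_flags.append(f"single_replicate:{name}")
    rec.consensus = MultilocusGenotype(calls)
    rec.consensus_status = ACCEPTED
    return rec


def consensus_dataset(dataset: Dataset) -> Dataset:
    """Run :func:`consensus_sample` over every sample; returns a new Dataset."""
    return Dataset(
        samples=[consensus_sample(rec) for rec in dataset.samples],
        loci=list(dataset.loci),
    )


def filter_by_locus_coverage(
    dataset: Dataset, min_loci: int = 8
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition samples into (retained, failed) by scored-locus count.

    A sample is retained iff it has an accepted consensus scored at
    ``min_loci`` or more loci; discarded samples count as failed.
    """
    n_loci = len(dataset.loci)
    if min_loci > n_loci:
        raise ValueError(f"min_loci={min_loci} exceeds the {n_loci} dataset loci")
    retained, failed = [], []
    for rec in dataset.samples:
        ok = rec.consensus is not None and rec.consensus.n_scored_loci >= min_loci
        (retained if ok else failed).append(rec)
    return retained, failed
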