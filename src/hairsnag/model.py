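"""Core data types for noninvasive multilocus microsatellite datasets.

A diploid microsatellite call is an unordered pair of integer allele sizes
(fragment lengths in base pairs) or missing.  Field samples (hair pulled from
rubbing trees, creosote power poles, barbed wire or corral hair traps) carry
2-4 replicate PCR genotypes plus a Y-chromosome (SRY) amplification flag per
replicate; tissue samples from captured animals carry a single replicate that
is taken at face value.  Individuals are clusters of samples whose consensus
genotypes match under the rules in :mod:`hairsnag.identify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence


class Source(str, Enum):
    """Provenance of a field sample."""

    POLE = "pole"
    TREE = "tree"
    BARBED_WIRE = "barbed_wire"
    HAIR_TRAP = "hair_trap"
    TISSUE = "tissue"
    CAPTURE_HAIR = "capture_hair"


#: Sources collected without handling the animal; the source-success analysis
#: is restricted to these.
NONINVASIVE_SOURCES = frozenset(
    {Source.POLE, Source.TREE, Source.BARBED_WIRE, Source.HAIR_TRAP}
)

#: Hair sources (everything except tissue); the per-year success analysis uses
#: all hair samples, invasively collected capture hair included.
HAIR_SOURCES = NONINVASIVE_SOURCES | {Source.CAPTURE_HAIR}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    CONFLICT = "conflict"


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered diploid call at one microsatellite locus.

    Stored in canonical sorted order (``allele_a <= allele_b``).  A replicate
    in which only one allele amplified is stored as a *provisional homozygote*
    of the observed allele with ``low_confidence=True``: this mirrors how
    allelic dropout manifests and lets the matching rules reason about it.
    Both alleles are ``None`` for a missing call.
    """

    allele_a: Optional[int] = None
    allele_b: Optional[int] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if a is None and b is None:
            return
        if a is None or b is None:
            observed = a if a is not None else b
            object.__setattr__(self, "allele_a", observed)
            object.__setattr__(self, "allele_b", observed)
            object.__setattr__(self, "low_confidence", True)
            return
        if b < a:
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    # -- predicates ---------------------------------------------------------
    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygote(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @property
    def alleles(self) -> tuple[int, int]:
        """The canonical allele pair; raises on a missing call."""
        if self.is_missing:
            raise ValueError("missing genotype has no alleles")
        return (self.allele_a, self.allele_b)  # type: ignore[return-value]

    def same_call(self, other: "LocusGenotype") -> bool:
        """Allele-pair equality, ignoring the confidence flag."""
        return (self.allele_a, self.allele_b) == (other.allele_a, other.allele_b)

    def shared_count(self, other: "LocusGenotype") -> int:
        """Size of the maximal multiset intersection of the two pairs (0-2)."""
        if self.is_missing or other.is_missing:
            raise ValueError("shared_count undefined for missing calls")
        a = sorted(self.alleles)
        b = list(other.alleles)
        shared = 0
        for x in a:
            if x in b:
                b.remove(x)
                shared += 1
        return shared


MISSING = LocusGenotype()


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its repeat-unit size in bp."""

    name: str
    repeat_unit: int = 2

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError("repeat_unit must be >= 1")


@dataclass
class MultilocusGenotype:
    """Ordered map locus name -> :class:`LocusGenotype` over a fixed locus set."""

    calls: dict[str, LocusGenotype]

    @classmethod
    def from_mapping(
        cls, calls: Mapping[str, LocusGenotype], loci: Sequence[str]
    ) -> "MultilocusGenotype":
        """Build over the dataset's full locus list, filling absent loci as missing."""
        return cls({name: calls.get(name, MISSING) for name in loci})

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    @property
    def n_missing_loci(self) -> int:
        return sum(1 for g in self.calls.values() if g.is_missing)

    @property
    def n_scored_loci(self) -> int:
        return len(self.calls) - self.n_missing_loci

    def __getitem__(self, locus: str) -> LocusGenotype:
        return self.calls[locus]

    def same_calls(self, other: "MultilocusGenotype") -> bool:
        return all(
            self.calls[name].same_call(other.calls[name]) for name in self.calls
        )


@dataclass
class SampleRecord:
    """One field sample: metadata, replicate genotypes and (later) a consensus.

    ``sry_positive`` holds one boolean per replicate.  ``consensus`` is filled
    by :func:`hairsnag.consensus.consensus_sample`; ``consensus_status`` is one
    of ``accepted`` / ``discarded`` / ``mismatch_unresolved`` (2 replicates
    only, round-1 mismatch with no second extraction available).
    """

    sample_id: str
    province: str
    source: Source
    year: int
    lat: Optional[float] = None
    lon: Optional[float] = None
    replicates: list[MultilocusGenotype] = field(default_factory=list)
    sry_positive: list[bool] = field(default_factory=list)
    consensus: Optional[MultilocusGenotype] = None
    consensus_status: Optional[str] = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def is_tissue(self) -> bool:
        return self.source is Source.TISSUE

    @property
    def sry_any_positive(self) -> bool:
        return any(self.sry_positive)


@dataclass
class Individual:
    """A cluster of samples attributed to one animal."""

    individual_id: str
    member_sample_ids: list[str]
    consolidated_genotype: MultilocusGenotype
    sex: Sex
    provinces_seen: set[str]
    flags: list[str] = field(default_factory=list)


@dataclass
class Dataset:
    """Samples + locus definitions (+ individuals after identification)."""

    samples: list[SampleRecord]
    loci: list[Locus]
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def repeat_units(self) -> dict[str, int]:
        return {l.name: l.repeat_unit for l in self.loci}

    def samples_with_consensus(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.consensus is not None]


def consolidate_calls(calls: Iterable[LocusGenotype]) -> LocusGenotype:
    """Resolve several concordant-or-dropout calls at one locus into one.

    Preference order: confirmed heterozygote > any heterozygote >
    high-confidence homozygote > provisional homozygote > missing.  Ties are
    broken by allele pair (sorted), making the result order-invariant.
    """
    present = [g for g in calls if not g.is_missing]
    if not present:
        return MISSING

    def rank(g: LocusGenotype) -> tuple:
        return (
            0 if (g.is_heterozygote and not g.low_confidence) else
            1 if g.is_heterozygote else
            2 if not g.low_confidence else 3,
            g.alleles,
        )

    return min(present, key=rank)
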