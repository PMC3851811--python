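"""Core domain objects for the small-RNA transcriptome ("miRnome") pipeline.

The pipeline works on collapsed small-RNA reads (one record per distinct
sequence, carrying a multiplicity), a reference set of pre-miRNA hairpins with
mature miRNAs located on them, per-class sequence databases for the other RNA
species, and genomic intergenic/intronic regions backed by a genome.

Conventions used throughout the package:

* all sequences are uppercase DNA (``U`` is converted to ``T`` on ingestion);
* coordinates are 0-based, half-open;
* ``N`` is a valid read character but never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "RNA_CLASSES",
    "ALL_CLASS_LABELS",
    "ParseError",
    "AmbiguousLocationError",
    "ConfigurationError",
    "revcomp",
    "normalize_sequence",
    "SmallRNARead",
    "ReadLibrary",
    "MatureMiRNA",
    "Hairpin",
    "RNAClassDB",
    "GenomicRegion",
    "GenomicRegionSet",
    "ReferenceSet",
]

#: Fixed ordered vocabulary of annotatable RNA classes (elimination priority).
RNA_CLASSES: tuple[str, ...] = (
    "miRNA",
    "sn_sno",
    "lincRNA",
    "tRNA",
    "rRNA",
    "mRNA",
    "misc",
)

#: Every label a read can end up with after annotation.
ALL_CLASS_LABELS: tuple[str, ...] = RNA_CLASSES + ("unannotated_genomic", "unmatched")

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A file did not parse under the named standard."""


class AmbiguousLocationError(ValueError):
    """A mature miRNA locates at more than one position on its hairpin."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase DNA sequence (``N`` maps to ``N``)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase a sequence and convert RNA (``U``) to DNA (``T``)."""
    return sequence.upper().replace("U", "T")


def _validate_dna(sequence: str, context: str) -> None:
    if not sequence:
        raise ValueError(f"{context}: empty sequence")
    bad = set(sequence) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)!r}")


@dataclass(frozen=True)
class SmallRNARead:
    """One collapsed small-RNA read: a distinct sequence with a multiplicity."""

    read_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        _validate_dna(self.sequence, f"read {self.read_id!r}")
        if self.count < 1:
            raise ValueError(f"read {self.read_id!r}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadLibrary:
    """A sample's collapsed reads.  Sequences are unique within a library."""

    sample_id: str
    reads: list[SmallRNARead] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.reads]
        if len(seqs) != len(set(seqs)):
            raise ValueError(
                f"library {self.sample_id!r}: duplicate sequences after collapsing"
            )

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def counts(self) -> dict[str, int]:
        """Mapping sequence -> count."""
        return {r.sequence: r.count for r in self.reads}

    @classmethod
    def from_counts(cls, sample_id: str, counts: Mapping[str, int]) -> "ReadLibrary":
        reads = [
            SmallRNARead(f"{sample_id}_r{i + 1}", seq, n)
            for i, (seq, n) in enumerate(counts.items())
            if n > 0
        ]
        return cls(sample_id, reads)

    @classmethod
    def collapse(
        cls, sample_id: str, records: Iterable[tuple[str, str, int]]
    ) -> "ReadLibrary":
        """Collapse ``(read_id, sequence, count)`` records by identical sequence.

        Counts of identical sequences are summed; the first id seen is kept.
        Total read mass is conserved.
        """
        merged: dict[str, list] = {}
        for read_id, seq, count in records:
            entry = merged.get(seq)
            if entry is None:
                merged[seq] = [read_id, count]
            else:
                entry[1] += count
        reads = [SmallRNARead(rid, seq, n) for seq, (rid, n) in merged.items()]
        return cls(sample_id, reads)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA located on its hairpin precursor.

    ``hairpin[start:end] == sequence``; ``arm`` is ``"5p"`` or ``"3p"``
    depending on which precursor arm the locus lies on.
    """

    name: str
    sequence: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        _validate_dna(self.sequence, f"mature {self.name!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"mature {self.name!r}: coordinates/length mismatch")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"mature {self.name!r}: arm must be 5p or 3p")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Hairpin:
    """A pre-miRNA stem-loop precursor with 0-2 mature loci."""

    hairpin_id: str
    sequence: str
    mature_loci: list[MatureMiRNA] = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_dna(self.sequence, f"hairpin {self.hairpin_id!r}")
        if len(self.mature_loci) > 2:
            raise ValueError(f"hairpin {self.hairpin_id!r}: more than 2 mature loci")
        loci = sorted(self.mature_loci, key=lambda m: m.start)
        for a, b in zip(loci, loci[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"hairpin {self.hairpin_id!r}: overlapping mature loci"
                )
        for m in self.mature_loci:
            if self.sequence[m.start : m.end] != m.sequence:
                raise ValueError(
                    f"hairpin {self.hairpin_id!r}: locus {m.name!r} does not match"
                )


@dataclass
class RNAClassDB:
    """Named sequences of one RNA class (the annotation target of one stage)."""

    class_name: str
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_name not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.class_name!r}")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval (0-based half-open) of type intergenic or intronic."""

    chrom: str
    start: int
    end: int
    region_type: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self}: start must be < end")
        if self.region_type not in ("intergenic", "intronic"):
            raise ValueError(f"region {self}: bad region_type")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.region_type})"


@dataclass
class GenomicRegionSet:
    """Intergenic/intronic intervals plus the genome sequences backing them."""

    regions: list[GenomicRegion] = field(default_factory=list)
    genome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.chrom not in self.genome:
                raise ValueError(f"region {r.name}: chromosome not in genome")
            if r.end > len(self.genome[r.chrom]):
                raise ValueError(f"region {r.name}: end beyond chromosome length")

    def region_sequence(self, region: GenomicRegion) -> str:
        return self.genome[region.chrom][region.start : region.end]


@dataclass
class ReferenceSet:
    """Hairpins, located matures, unlocated matures and other class databases."""

    hairpins: dict[str, Hairpin] = field(default_factory=dict)
    class_dbs: dict[str, RNAClassDB] = field(default_factory=dict)
    #: mature name -> sequence, for matures that could not be placed on a hairpin.
    unlocated_matures: dict[str, str] = field(default_factory=dict)

    @property
    def matures(self) -> list[MatureMiRNA]:
        out: list[MatureMiRNA] = []
        for hp in self.hairpins.values():
            out.extend(hp.mature_loci)
        return out

    def mature_sequences(self) -> dict[str, str]:
        """Mapping of mature name -> sequence over located *and* unlocated matures.

        Raises ``ValueError`` if one name maps to two different sequences.
        """
        out: dict[str, str] = {}
        for m in self.matures:
            if m.name in out and out[m.name] != m.sequence:
                raise ValueError(f"duplicate mature name {m.name!r} with differing sequences")
            out[m.name] = m.sequence
        for name, seq in self.unlocated_matures.items():
            if name in out and out[name] != seq:
                raise ValueError(f"duplicate mature name {name!r} with differing sequences")
            out.setdefault(name, seq)
        return out
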