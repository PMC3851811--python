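"""Length filtering, length-distribution diagnostics and elimination annotation.

The elimination pipeline assigns each read to the first RNA class it hits,
trying classes in a fixed priority order (miRNA, sn/snoRNA, lincRNA, tRNA,
rRNA, mRNA, misc); a read assigned to a class is removed from the pool, so
priority dominates mismatch count.  Survivors are matched exactly against
genomic intergenic/intronic regions (both strands) and labelled
``unannotated_genomic``; whatever remains is ``unmatched``.

The miRNA stage matches reads against the hairpin precursors (plus any
matures that could not be located on a hairpin): isomiRs are shifted or
trimmed relative to the canonical mature, so only the precursor contains them
end-to-end.  Class databases are matched in transcript sense only; genomic
matching is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .core import (
    ALL_CLASS_LABELS,
    GenomicRegionSet,
    ReadLibrary,
    ReferenceSet,
    RNAClassDB,
    SmallRNARead,
    revcomp,
)
from .matching import Hit, best_hit

__all__ = [
    "LengthDistribution",
    "ReadAssignment",
    "AnnotationResult",
    "filter_by_length",
    "length_distribution",
    "match_with_mismatches",
    "eliminate",
]


@dataclass
class LengthDistribution:
    """Read-length histogram weighted by collapsed counts."""

    sample_id: str
    histogram: dict[int, int]
    modal_length: int | None

    @property
    def total(self) -> int:
        return sum(self.histogram.values())


def filter_by_length(lib: ReadLibrary, min_len: int) -> ReadLibrary:
    """Retain reads of length >= ``min_len`` (the input is not modified)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return ReadLibrary(lib.sample_id, [r for r in lib.reads if len(r) >= min_len])


def length_distribution(lib: ReadLibrary) -> LengthDistribution:
    """Histogram of read lengths; the smallest length wins modal ties.

    An empty library yields an empty histogram with ``modal_length`` None.
    """
    hist: dict[int, int] = {}
    for r in lib.reads:
        hist[len(r)] = hist.get(len(r), 0) + r.count
    mode = None
    if hist:
        mode = min(hist, key=lambda l: (-hist[l], l))
    return LengthDistribution(lib.sample_id, dict(sorted(hist.items())), mode)


def match_with_mismatches(
    read: SmallRNARead | str,
    db: RNAClassDB,
    max_mm: int,
    both_strands: bool = False,
) -> Hit | None:
    """Best ungapped end-to-end hit of a read in one class database.

    The minimum-mismatch hit is returned (ties by record name, then offset);
    None when nothing aligns within ``max_mm`` substitutions.  By default the
    read is matched in transcript sense only; ``both_strands`` additionally
    tries the reverse complement.
    """
    seq = read.sequence if isinstance(read, SmallRNARead) else read
    hit = best_hit(seq, db.records, max_mm)
    if both_strands:
        rc_hit = best_hit(revcomp(seq), db.records, max_mm)
        if rc_hit is not None and (
            hit is None
            or (rc_hit.mismatches, rc_hit.name, rc_hit.offset)
            < (hit.mismatches, hit.name, hit.offset)
        ):
            hit = rc_hit
    return hit


@dataclass(frozen=True)
class ReadAssignment:
    sequence: str
    count: int
    label: str
    mismatches: int | None = None
    hit_name: str | None = None


@dataclass
class AnnotationResult:
    """Per-read class assignments plus the class-mass apportionment."""

    sample_id: str
    assignments: dict[str, ReadAssignment] = field(default_factory=dict)

    @property
    def class_mass(self) -> dict[str, int]:
        mass = {label: 0 for label in ALL_CLASS_LABELS}
        for a in self.assignments.values():
            mass[a.label] += a.count
        return mass

    @property
    def total(self) -> int:
        return sum(a.count for a in self.assignments.values())

    @property
    def apportionment(self) -> dict[str, float]:
        """Read-mass fraction per class (sums to 1 over a non-empty library)."""
        total = self.total
        if total == 0:
            return {}
        return {label: mass / total for label, mass in self.class_mass.items()}

    def reads_with_label(self, label: str) -> ReadLibrary:
        return ReadLibrary.from_counts(
            f"{self.sample_id}_{label}",
            {a.sequence: a.count for a in self.assignments.values() if a.label == label},
        )


def _mirna_records(ref: ReferenceSet) -> dict[str, str]:
    records = {hid: hp.sequence for hid, hp in ref.hairpins.items()}
    records.update(ref.unlocated_matures)
    return records


def eliminate(
    lib: ReadLibrary,
    ref: ReferenceSet,
    regions: GenomicRegionSet | None,
    cfg: PipelineConfig | None = None,
) -> AnnotationResult:
    """Hierarchically annotate a (length-filtered) library into RNA classes.

    Classes are tried in ``cfg.class_order``; a read is assigned to the first
    class in which it hits within ``cfg.max_mismatches`` and eliminated from
    the pool.  Survivors matching a genomic region exactly (either strand)
    become ``unannotated_genomic``; the rest are ``unmatched``.  Empty or
    missing databases simply never match.
    """
    cfg = cfg or PipelineConfig()
    dbs: list[tuple[str, dict[str, str]]] = []
    for cls in cfg.class_order:
        if cls == "miRNA":
            dbs.append((cls, _mirna_records(ref)))
        elif cls in ref.class_dbs:
            dbs.append((cls, ref.class_dbs[cls].records))
        else:
            dbs.append((cls, {}))

    region_seqs: list[tuple[str, str]] = []
    blob_parts: list[str] = []
    if regions is not None:
        for r in regions.regions:
            seq = regions.region_sequence(r)
            region_seqs.append((r.name, seq))
            blob_parts.append(seq)
    blob = "#".join(blob_parts)

    result = AnnotationResult(lib.sample_id)
    for read in lib.reads:
        assignment = None
        for cls, records in dbs:
            hit = best_hit(read.sequence, records, cfg.max_mismatches)
            if hit is not None:
                assignment = ReadAssignment(
                    read.sequence, read.count, cls, hit.mismatches, hit.name
                )
                break
        if assignment is None and blob:
            seq, rc = read.sequence, revcomp(read.sequence)
            if ("N" not in seq) and (seq in blob or rc in blob):
                hit_name = next(
                    (name for name, rseq in region_seqs if seq in rseq or rc in rseq),
                    None,
                )
                assignment = ReadAssignment(
                    read.sequence, read.count, "unannotated_genomic", 0, hit_name
                )
        if assignment is None:
            assignment = ReadAssignment(read.sequence, read.count, "unmatched")
        result.assignments[read.sequence] = assignment
    return result
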