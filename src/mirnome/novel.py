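"""Novel miRNA discovery from unannotated reads.

The track mirrors how small-RNA pipelines mine intergenic/intronic loci for
new miRNA genes:

1. keep unannotated reads with frequency >= 5 (configurable);
2. place them by exact match (both strands) inside the intergenic/intronic
   intervals;
3. extend each placement by 70 nt on both sides to a precursor-sized window
   (reverse-complemented for minus-strand placements so the read stays in
   sense);
4. fold the window with the pluggable engine (default: best single stem-loop,
   see :mod:`mirnome.fold`) and reject windows without a miRNA-like hairpin;
5. require the seeding sRNA to lie in a stem arm (hard gate; loop-spanning
   reads are prediction errors) and record isomiR and opposite-arm
   counterpart evidence as flags;
6. pool candidates across samples, merge families from common precursors,
   designate the most abundant member as the mature arm, deduplicate and name
   the survivors ``jnu-pat-hsa-1..N`` in descending total-count order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import PipelineConfig
from .core import (
    GenomicRegion,
    GenomicRegionSet,
    ReadLibrary,
    SmallRNARead,
    revcomp,
)
from .fold import FoldEngine, FoldResult, HairpinStructure, fold_hairpin

__all__ = [
    "Placement",
    "PrecursorWindow",
    "FilterFlags",
    "NovelCandidate",
    "select_candidate_reads",
    "map_exact_to_regions",
    "extend_flanks",
    "apply_structural_filters",
    "find_sample_candidates",
    "group_name_dedupe",
    "predict_novel",
]

NAME_PREFIX = "jnu-pat-hsa"


@dataclass(frozen=True)
class Placement:
    """Exact genomic placement of a candidate read (0-based half-open)."""

    read: SmallRNARead
    chrom: str
    start: int
    end: int
    strand: str
    region_type: str


@dataclass(frozen=True)
class PrecursorWindow:
    """A flank-extended precursor window, oriented so the read is in sense."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    #: seeding read interval in window-local (oriented) coordinates
    read_local: tuple[int, int]
    clipped: bool


@dataclass(frozen=True)
class FilterFlags:
    in_stem: bool
    has_isomir: bool
    has_counterpart: bool


@dataclass
class NovelCandidate:
    """A putative novel precursor with its sRNA family and filter evidence."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    structure: HairpinStructure
    mature_sequence: str
    mature_count: int
    #: sequence -> summed count over samples, for every family member
    members: dict[str, int]
    flags: FilterFlags
    sample_ids: list[str]
    name: str | None = None
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


def select_candidate_reads(
    reads: ReadLibrary | Sequence[SmallRNARead], min_freq: int
) -> list[SmallRNARead]:
    """Reads with collapsed count >= ``min_freq`` (candidate novel sRNAs)."""
    pool = reads.reads if isinstance(reads, ReadLibrary) else list(reads)
    return [r for r in pool if r.count >= min_freq]


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_exact_to_regions(
    reads: Sequence[SmallRNARead], regions: GenomicRegionSet
) -> list[Placement]:
    """All exact placements of each read within the region intervals.

    Both strands are searched: a minus-strand placement means the genomic
    window equals the reverse complement of the read.  Reads with no
    placement are dropped from this track.
    """
    placements: list[Placement] = []
    seen: set[tuple[str, str, int, str]] = set()
    for region in regions.regions:
        if region.chrom not in regions.genome:
            raise ValueError(f"region {region.name}: missing chromosome")
        seq = regions.region_sequence(region)
        for read in reads:
            if "N" in read.sequence:
                continue
            for strand, needle in (("+", read.sequence), ("-", revcomp(read.sequence))):
                for i in _find_all(seq, needle):
                    start = region.start + i
                    key = (read.sequence, region.chrom, start, strand)
                    if key in seen:
                        continue  # overlapping intervals: one placement per locus
                    seen.add(key)
                    placements.append(
                        Placement(
                            read,
                            region.chrom,
                            start,
                            start + len(read),
                            strand,
                            region.region_type,
                        )
                    )
    placements.sort(key=lambda p: (p.chrom, p.start, p.strand, p.read.sequence))
    return placements


def extend_flanks(
    placement: Placement, flank: int, genome: Mapping[str, str]
) -> PrecursorWindow:
    """Extend a placement by ``flank`` nt both sides, clipped to the chromosome.

    Minus-strand windows are reverse-complemented so the returned precursor
    contains the read verbatim; ``read_local`` gives the read's interval on
    the returned (oriented) sequence.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    chrom_seq = genome[placement.chrom]
    ws = max(0, placement.start - flank)
    we = min(len(chrom_seq), placement.end + flank)
    clipped = ws != placement.start - flank or we != placement.end + flank
    seq = chrom_seq[ws:we]
    if placement.strand == "-":
        seq = revcomp(seq)
        local = (we - placement.end, we - placement.start)
    else:
        local = (placement.start - ws, placement.end - ws)
    return PrecursorWindow(placement.chrom, ws, we, placement.strand, seq, local, clipped)


def _arm_fraction(interval: tuple[int, int], arm: tuple[int, int]) -> float:
    length = interval[1] - interval[0]
    if length <= 0:
        return 0.0
    ov = max(0, min(interval[1], arm[1]) - max(interval[0], arm[0]))
    return ov / length


def apply_structural_filters(
    window: PrecursorWindow,
    structure: HairpinStructure,
    family_occurrences: Sequence[tuple[SmallRNARead, int, int]],
    seed_read: SmallRNARead,
    isomir_window: int = 3,
) -> FilterFlags:
    """Evaluate the three miRNA-likeness filters for one accepted window.

    ``in_stem``: >= 90% of the seeding sRNA's positions lie within one stem
    arm and none in the loop (loop-spanning reads are prediction errors).
    ``has_isomir``: another read starts and ends within ``isomir_window`` nt
    of the seed.  ``has_counterpart``: another read lies (majority of its
    positions) in the opposite arm.
    """
    seed = window.read_local
    loop_ov = max(0, min(seed[1], structure.loop[1]) - max(seed[0], structure.loop[0]))
    f5 = _arm_fraction(seed, structure.arm5)
    f3 = _arm_fraction(seed, structure.arm3)
    in_stem = loop_ov == 0 and max(f5, f3) >= 0.9
    my_arm, other_arm = (
        (structure.arm5, structure.arm3) if f5 >= f3 else (structure.arm3, structure.arm5)
    )
    has_isomir = False
    has_counterpart = False
    for read, lstart, lend in family_occurrences:
        same_position = lstart == seed[0] and lend == seed[1]
        if read.sequence != seed_read.sequence or not same_position:
            if (
                abs(lstart - seed[0]) <= isomir_window
                and abs(lend - seed[1]) <= isomir_window
            ):
                has_isomir = True
            if _arm_fraction((lstart, lend), other_arm) >= 0.5:
                has_counterpart = True
    return FilterFlags(in_stem, has_isomir, has_counterpart)


def find_sample_candidates(
    sample_id: str,
    unannotated: ReadLibrary,
    regions: GenomicRegionSet,
    cfg: PipelineConfig | None = None,
    engine: FoldEngine | None = None,
) -> list[NovelCandidate]:
    """Run steps 1-5 (selection through filtering) for one sample."""
    cfg = cfg or PipelineConfig()
    candidates = select_candidate_reads(unannotated, cfg.novel_min_freq)
    if not candidates:
        return []
    placements = map_exact_to_regions(candidates, regions)
    out: list[NovelCandidate] = []
    folded: dict[tuple, FoldResult] = {}
    for placement in placements:
        window = extend_flanks(placement, cfg.flank_length, regions.genome)
        key = (window.chrom, window.start, window.end, window.strand)
        if key not in folded:
            folded[key] = fold_hairpin(window.sequence, cfg.fold, engine)
        result = folded[key]
        if not result.accepted or result.structure is None:
            continue
        occurrences = [
            (read, i, i + len(read))
            for read in candidates
            for i in _find_all(window.sequence, read.sequence)
        ]
        flags = apply_structural_filters(
            window, result.structure, occurrences, placement.read, cfg.isomir_window
        )
        if not flags.in_stem:
            continue
        if cfg.strict_filters and not (flags.has_isomir and flags.has_counterpart):
            continue
        members: dict[str, int] = {}
        for read, _s, _e in occurrences:
            members[read.sequence] = read.count
        out.append(
            NovelCandidate(
                chrom=window.chrom,
                start=window.start,
                end=window.end,
                strand=window.strand,
                precursor=window.sequence,
                structure=result.structure,
                mature_sequence=placement.read.sequence,
                mature_count=placement.read.count,
                members=members,
                flags=flags,
                sample_ids=[sample_id],
                scores=dict(result.scores),
            )
        )
    return out


def group_name_dedupe(
    per_sample: Sequence[Sequence[NovelCandidate]],
) -> list[NovelCandidate]:
    """Pool candidates over samples, merge common precursors, dedupe and name.

    Candidates whose precursor windows overlap on the same strand are one
    family; member counts are summed across samples and the most abundant
    member becomes the mature arm.  Sequence-identical precursors at distinct
    loci are deduplicated (highest total count survives).  Survivors are named
    ``jnu-pat-hsa-1..N`` in descending total-count order, ties broken
    lexicographically by precursor sequence.
    """
    pool = [c for sample in per_sample for c in sample]
    if not pool:
        return []
    pool.sort(key=lambda c: (c.chrom, c.strand, c.start, c.end))
    clusters: list[list[NovelCandidate]] = []
    for cand in pool:
        placed = False
        for cluster in clusters:
            last = cluster[-1]
            if (
                cand.chrom == last.chrom
                and cand.strand == last.strand
                and cand.start < max(c.end for c in cluster)
            ):
                cluster.append(cand)
                placed = True
                break
        if not placed:
            clusters.append([cand])

    merged: list[NovelCandidate] = []
    for cluster in clusters:
        members: dict[str, int] = {}
        samples: set[str] = set()
        for c in cluster:
            samples.update(c.sample_ids)
            for seq, count in c.members.items():
                members[seq] = members.get(seq, 0) + count
        mature_seq = sorted(members, key=lambda s: (-members[s], s))[0]
        rep = next(
            c for c in sorted(cluster, key=lambda c: (c.start, c.end))
            if mature_seq in c.members
        )
        flags = FilterFlags(
            in_stem=any(c.flags.in_stem for c in cluster),
            has_isomir=any(c.flags.has_isomir for c in cluster),
            has_counterpart=any(c.flags.has_counterpart for c in cluster),
        )
        merged.append(
            NovelCandidate(
                chrom=rep.chrom,
                start=min(c.start for c in cluster),
                end=max(c.end for c in cluster),
                strand=rep.strand,
                precursor=rep.precursor,
                structure=rep.structure,
                mature_sequence=mature_seq,
                mature_count=members[mature_seq],
                members=members,
                flags=flags,
                sample_ids=sorted(samples),
                scores=dict(rep.scores),
            )
        )

    by_precursor: dict[str, NovelCandidate] = {}
    for cand in merged:
        prev = by_precursor.get(cand.precursor)
        if prev is None or cand.total_count > prev.total_count:
            by_precursor[cand.precursor] = cand
    final = sorted(
        by_precursor.values(), key=lambda c: (-c.total_count, c.precursor)
    )
    for i, cand in enumerate(final, 1):
        cand.name = f"{NAME_PREFIX}-{i}"
    return final


def predict_novel(
    unannotated_by_sample: Mapping[str, ReadLibrary],
    regions: GenomicRegionSet,
    cfg: PipelineConfig | None = None,
    engine: FoldEngine | None = None,
) -> list[NovelCandidate]:
    """Full novel-miRNA track over a set of samples (steps 1-6)."""
    per_sample = [
        find_sample_candidates(sid, lib, regions, cfg, engine)
        for sid, lib in sorted(unannotated_by_sample.items())
    ]
    return group_name_dedupe(per_sample)
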