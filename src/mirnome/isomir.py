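"""IsomiR families: hairpin alignment, dominant calling and YES/NO comparison.

Reads are aligned ungapped, end-to-end, to the pre-miRNA hairpins (sense
strand, at most ``max_mm`` substitutions, best-mismatch stratum per read,
multi-mapping retained).  Each alignment is assigned to the mature locus on
its hairpin with which it overlaps most, provided the overlap covers at least
half of the shorter of read and mature; the resulting positional cluster is
the miRNA's isomiR family.  Members are keyed by read sequence and carry 5'
and 3' end offsets relative to the canonical mature locus.

The family member with the highest count is the dominant (most abundant)
isomiR — operationally, the miRNA's active form.  Comparing the dominant
sequence with the canonical reference sequence per sample, and requiring
unanimity across the samples of a group, yields the YES/NO classification:
YES when the dominant isomiR *is* the reference sequence in every sample,
NO when it is a different isomiR in every sample; miRNAs below the detection
threshold in any sample are ``low_expression`` and expressed-but-disagreeing
miRNAs are ``non_uniform`` (together: "not considered").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import MatureMiRNA, ReadLibrary, ReferenceSet, SmallRNARead
from .matching import placements
from .profiles import ExpressionProfile, ProfileRow, tpm

__all__ = [
    "HairpinAlignment",
    "FamilyMember",
    "IsomiRFamily",
    "ComparisonRecord",
    "GroupTally",
    "SampleIsomirProfile",
    "align_to_hairpins",
    "build_families",
    "select_dominant",
    "abundant_profile",
    "compare_profiles",
    "isomir_count_distribution",
]


@dataclass(frozen=True)
class HairpinAlignment:
    """Ungapped placement of one read on one hairpin (0-based half-open)."""

    read: SmallRNARead
    hairpin_id: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class FamilyMember:
    """One isomiR: a distinct read sequence at an offset from the mature locus."""

    sequence: str
    count: int
    offset5: int
    offset3: int
    mismatches: int


@dataclass
class IsomiRFamily:
    """Positional cluster of read variants assigned to one mature miRNA."""

    mature: MatureMiRNA
    members: list[FamilyMember] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.members)


def align_to_hairpins(
    lib: ReadLibrary, ref: ReferenceSet, max_mm: int
) -> list[HairpinAlignment]:
    """All best-stratum ungapped placements of each read on the hairpins.

    For each read, every placement with the read's minimum mismatch count is
    reported (a read may align to several hairpins); placements needing more
    mismatches than that minimum are dropped.
    """
    hairpin_items = sorted(ref.hairpins.items())
    out: list[HairpinAlignment] = []
    for read in lib.reads:
        hits: list[tuple[str, int, int]] = []
        best_mm = max_mm + 1
        for hid, hp in hairpin_items:
            for off, mm in placements(read.sequence, hp.sequence, max_mm):
                hits.append((hid, off, mm))
                if mm < best_mm:
                    best_mm = mm
        for hid, off, mm in hits:
            if mm == best_mm:
                out.append(
                    HairpinAlignment(read, hid, off, off + len(read), mm)
                )
    return out


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def build_families(
    alignments: Sequence[HairpinAlignment],
    ref: ReferenceSet,
    overlap_fraction: float = 0.5,
) -> tuple[dict[str, IsomiRFamily], list[HairpinAlignment]]:
    """Cluster alignments into per-mature isomiR families.

    Each alignment joins the mature locus (on the same hairpin) with which its
    overlap is maximal, provided the overlap is at least ``overlap_fraction``
    of min(read length, mature length); ties go to the leftmost locus.
    Alignments overlapping no mature sufficiently are returned separately as
    "hairpin-other" (reported, not familied).  Multi-mapped reads contribute
    their full count to each family they enter.
    """
    raw: dict[str, dict[str, FamilyMember]] = {}
    matures: dict[str, MatureMiRNA] = {}
    hairpin_other: list[HairpinAlignment] = []
    for aln in alignments:
        hp = ref.hairpins[aln.hairpin_id]
        best_locus = None
        best_ov = 0
        for locus in sorted(hp.mature_loci, key=lambda m: m.start):
            ov = _overlap(aln.start, aln.end, locus.start, locus.end)
            need = overlap_fraction * min(aln.end - aln.start, len(locus))
            if ov >= need and ov > best_ov:
                best_locus, best_ov = locus, ov
        if best_locus is None:
            hairpin_other.append(aln)
            continue
        matures[best_locus.name] = best_locus
        members = raw.setdefault(best_locus.name, {})
        seq = aln.read.sequence
        prev = members.get(seq)
        count = aln.read.count + (prev.count if prev else 0)
        members[seq] = FamilyMember(
            seq,
            count,
            aln.start - best_locus.start,
            aln.end - best_locus.end,
            aln.mismatches,
        )
    families = {
        name: IsomiRFamily(matures[name], sorted(members.values(), key=lambda m: m.sequence))
        for name, members in sorted(raw.items())
    }
    return families, hairpin_other


def select_dominant(family: IsomiRFamily) -> FamilyMember:
    """The highest-count member; ties prefer smaller |5' offset|, then smaller
    |3' offset|, then the lexicographically smallest sequence."""
    if not family.members:
        raise ValueError(f"family {family.mature.name!r} is empty")
    return sorted(
        family.members,
        key=lambda m: (-m.count, abs(m.offset5), abs(m.offset3), m.sequence),
    )[0]


def abundant_profile(
    families: Mapping[str, IsomiRFamily], library_total: int, sample_id: str
) -> ExpressionProfile:
    """Most-abundant-isomiR expression profile (one row per familied miRNA)."""
    rows = {}
    for name, family in sorted(families.items()):
        dom = select_dominant(family)
        rows[name] = ProfileRow(dom.count, tpm(dom.count, library_total))
    return ExpressionProfile(sample_id, "abundant_isomir", rows, library_total)


@dataclass
class SampleIsomirProfile:
    """Everything the group comparison needs from one sample."""

    sample_id: str
    reference: ExpressionProfile
    abundant: ExpressionProfile
    #: miRNA name -> dominant isomiR sequence
    dominants: dict[str, str]


@dataclass(frozen=True)
class ComparisonRecord:
    name: str
    group_id: str
    #: sample -> (reference count, abundant count, dominant sequence or None)
    per_sample: tuple
    status: str


@dataclass
class GroupTally:
    n_yes: int = 0
    n_no: int = 0
    n_low: int = 0
    n_nonuniform: int = 0

    @property
    def not_considered(self) -> int:
        return self.n_low + self.n_nonuniform


def compare_profiles(
    samples: Sequence[SampleIsomirProfile],
    canonical: Mapping[str, str],
    group_id: str = "group",
    detection_threshold: int = 1,
) -> tuple[list[ComparisonRecord], GroupTally]:
    """Classify every canonical miRNA as YES / NO / low / non-uniform in a group.

    A miRNA is *expressed* in a sample when its dominant isomiR count reaches
    ``detection_threshold``.  Group status: YES (dominant equals the canonical
    sequence in every sample), NO (a different isomiR dominates in every
    sample), ``non_uniform`` (expressed everywhere but disagreeing),
    ``low_expression`` (not expressed in at least one sample).
    """
    if not samples:
        raise ValueError("group must contain at least one sample")
    records: list[ComparisonRecord] = []
    tally = GroupTally()
    for name in sorted(canonical):
        per_sample = []
        verdicts: list[bool] = []
        expressed_everywhere = True
        for s in samples:
            abundant = s.abundant.rows.get(name)
            refrow = s.reference.rows.get(name)
            dom = s.dominants.get(name)
            count = abundant.raw if abundant else 0
            per_sample.append(
                (s.sample_id, refrow.raw if refrow else 0, count, dom)
            )
            if count >= detection_threshold and dom is not None:
                verdicts.append(dom == canonical[name])
            else:
                expressed_everywhere = False
        if not expressed_everywhere:
            status = "low_expression"
            tally.n_low += 1
        elif all(verdicts):
            status = "YES"
            tally.n_yes += 1
        elif not any(verdicts):
            status = "NO"
            tally.n_no += 1
        else:
            status = "non_uniform"
            tally.n_nonuniform += 1
        records.append(ComparisonRecord(name, group_id, tuple(per_sample), status))
    return records, tally


def isomir_count_distribution(
    families_by_sample: Mapping[str, Mapping[str, IsomiRFamily]],
    names: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Distinct isomiR-member counts per named miRNA per sample.

    Unknown names are reported as 0 and returned in the warnings list.
    """
    warnings = []
    sample_ids = sorted(families_by_sample)
    known = set().union(*(set(f) for f in families_by_sample.values())) if families_by_sample else set()
    data = {}
    for sid in sample_ids:
        fams = families_by_sample[sid]
        data[sid] = [fams[n].n_members if n in fams else 0 for n in names]
    for n in names:
        if n not in known:
            warnings.append(f"unknown miRNA name {n!r}")
    frame = pd.DataFrame(data, index=list(names))
    frame.index.name = "miRNA"
    return frame, warnings
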