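"""Synthetic small-RNA study generator with planted ground truth.

Everything downstream of sequencing is testable without real data: this
module builds a reference set (stem-loop hairpins with one mature per arm,
plus random databases for the other RNA classes), a genome with
intergenic/intronic intervals, and per-sample read libraries in which every
read's class, every isomiR family's member counts and dominant member, every
YES/NO label and every novel precursor is planted and recorded in a
:class:`TruthTable`.

The generator's defaults emulate the study conditions the pipeline targets:

* read-length mode 22 nt for normal-like libraries; a degraded mode whose
  modal length is 17 nt, modelled as a 3' truncation down to a target length
  drawn from a mode-17 table for a configurable fraction of reads;
* RNA-class proportions dominated by miRNA (74%), with small sn/snoRNA,
  lincRNA, tRNA, rRNA, mRNA and miscellaneous fractions, ~5% unannotated
  genomic reads and ~7% reads matching nothing;
* isomiR families with 5'/3' end offsets drawn uniformly from [-2, +2]^2, a
  planted dominant member with a >= 2x count margin, and a 32% probability
  that the dominant member is the canonical (reference) sequence;
* more distinct isomiRs for more highly expressed miRNAs.

Counts are sampled multinomially by default; in *fixture mode*
(``fixed_counts=True``) the planned integer counts are written exactly, which
is what margin-guarantee tests use.  Identical spec + seed gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    GenomicRegion,
    GenomicRegionSet,
    Hairpin,
    MatureMiRNA,
    ReadLibrary,
    ReferenceSet,
    RNAClassDB,
    revcomp,
)
from .fold import FoldParams, fold_hairpin

__all__ = [
    "SimulationSpec",
    "FamilyPlan",
    "PlantedFamily",
    "PlantedNovel",
    "TruthTable",
    "generate_reference",
    "generate_regions",
    "generate_reads",
    "plant_novel_hairpins",
    "generate_cohort",
    "Cohort",
    "CohortSample",
    "simulate_sample",
]

_BASES = np.array(list("ACGT"))

#: read-length distribution of an intact size-selected library (mode 22 nt)
_LENGTH_TABLE: dict[int, float] = {
    18: 0.04, 19: 0.06, 20: 0.10, 21: 0.18, 22: 0.30,
    23: 0.14, 24: 0.08, 25: 0.04, 26: 0.03, 27: 0.02, 28: 0.01,
}

_MATURE_LENGTH_TABLE: dict[int, float] = {20: 0.1, 21: 0.2, 22: 0.4, 23: 0.2, 24: 0.1}

_DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "miRNA": 0.74,
    "sn_sno": 0.02,
    "lincRNA": 0.02,
    "tRNA": 0.03,
    "rRNA": 0.01,
    "mRNA": 0.04,
    "misc": 0.02,
    "unannotated_genomic": 0.05,
    "unmatched": 0.07,
}

#: per-class (n_records, min_len, max_len) for the random databases
_DB_SHAPES: dict[str, tuple[int, int, int]] = {
    "sn_sno": (25, 60, 300),
    "lincRNA": (10, 200, 1000),
    "tRNA": (15, 70, 90),
    "rRNA": (4, 1000, 2000),
    "mRNA": (15, 500, 1500),
    "misc": (15, 80, 400),
}


def _uniform_offsets(radius: int = 2) -> dict[tuple[int, int], float]:
    pairs = [
        (o5, o3)
        for o5 in range(-radius, radius + 1)
        for o3 in range(-radius, radius + 1)
    ]
    return {p: 1.0 / len(pairs) for p in pairs}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic sample (and its shared reference)."""

    n_hairpins: int = 40
    mature_length_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_MATURE_LENGTH_TABLE)
    )
    loop_length_range: tuple[int, int] = (8, 15)
    #: substitution rate applied to the 3' arm (reverse complement of the 5' arm)
    stem_mutation_rate: float = 0.05
    isomir_offset_probs: Mapping[tuple[int, int], float] = field(
        default_factory=_uniform_offsets
    )
    dominant_is_reference_prob: float = 0.32
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROPORTIONS)
    )
    length_mode: str = "normal_like_22"  # or "degraded_17"
    degraded_fraction: float = 0.7
    #: 3' truncation target lengths for degraded reads (mode 17 nt)
    degraded_target_probs: Mapping[int, float] = field(
        default_factory=lambda: {
            14: 0.05, 15: 0.08, 16: 0.13, 17: 0.36, 18: 0.14,
            19: 0.09, 20: 0.06, 21: 0.05, 22: 0.04,
        }
    )
    total_reads: int = 100_000
    expressed_fraction: float = 0.85
    expression_log10_range: tuple[float, float] = (0.3, 3.8)
    #: dominant member's count margin over every other member (strict in fixture mode)
    dominant_margin: float = 2.0
    fixed_counts: bool = False
    n_chromosomes: int = 2
    chromosome_length: int = 15_000
    seed: int = 0

    def __post_init__(self) -> None:
        for table, what in (
            (self.isomir_offset_probs, "isomir_offset_probs"),
            (self.class_proportions, "class_proportions"),
            (self.mature_length_probs, "mature_length_probs"),
            (self.degraded_target_probs, "degraded_target_probs"),
        ):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{what} must sum to 1 (got {total})")
        if self.length_mode not in ("normal_like_22", "degraded_17"):
            raise ConfigurationError(f"unknown length_mode {self.length_mode!r}")
        if self.n_hairpins < 0 or self.total_reads < 0:
            raise ConfigurationError("n_hairpins and total_reads must be >= 0")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            options = [b for b in "ACGT" if b != chars[i]]
            chars[i] = options[rng.integers(0, 3)]
    return "".join(chars)


def _mutate_interior(
    rng: np.random.Generator, seq: str, rate: float, min_muts: int, margin: int = 4
) -> str:
    """Substitutions confined to interior positions, at least ``min_muts`` of them.

    Interior mismatches keep a planted stem from being a perfect palindrome
    (whose reads would map on both strands at once) while leaving both stem
    ends intact, so the stem detector recovers the planted register exactly.
    """
    chars = list(seq)
    interior = list(range(margin, len(seq) - margin))
    diffs = []
    for i in interior:
        if rng.random() < rate:
            options = [b for b in "ACGT" if b != seq[i]]
            chars[i] = options[int(rng.integers(0, 3))]
            diffs.append(i)
    while len(diffs) < min_muts and len(diffs) < len(interior):
        pos = interior[int(rng.integers(0, len(interior)))]
        if chars[pos] != seq[pos]:
            continue
        options = [b for b in "ACGT" if b != seq[pos]]
        chars[pos] = options[int(rng.integers(0, 3))]
        diffs.append(pos)
    return "".join(chars)


def _choice_from_table(rng: np.random.Generator, table: Mapping) -> object:
    keys = list(table.keys())
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_reference(spec: SimulationSpec) -> ReferenceSet:
    """Build hairpins (one mature per arm) and the other class databases.

    Each hairpin is a stem-loop: a random 5' arm, a loop of 8-15 nt and the
    mutated reverse complement of the arm as the 3' arm, padded by a few
    context nucleotides on each side.  Construction is rejection-sampled so
    every hairpin is accepted by the default fold engine and every mature
    locates uniquely on its hairpin.  Deterministic under the simulation seed.
    """
    rng = np.random.default_rng(spec.seed)
    fold_params = FoldParams()
    hairpins: dict[str, Hairpin] = {}
    used: set[str] = set()
    for i in range(spec.n_hairpins):
        hid = f"sim-mir-{i + 1}"
        for _attempt in range(100):
            arm_len = int(_choice_from_table(rng, spec.mature_length_probs))
            arm5 = _random_seq(rng, arm_len)
            loop = _random_seq(rng, int(rng.integers(*spec.loop_length_range)))
            arm3 = _mutate(rng, revcomp(arm5), spec.stem_mutation_rate)
            pad5 = _random_seq(rng, int(rng.integers(4, 7)))
            pad3 = _random_seq(rng, int(rng.integers(4, 7)))
            seq = pad5 + arm5 + loop + arm3 + pad3
            if not fold_hairpin(seq, fold_params).accepted:
                continue
            if seq.count(arm5) != 1 or seq.count(arm3) != 1:
                continue
            if arm5 in used or arm3 in used or arm5 == arm3:
                continue
            s5 = len(pad5)
            s3 = len(seq) - len(pad3) - arm_len
            hairpins[hid] = Hairpin(
                hid,
                seq,
                [
                    MatureMiRNA(f"sim-miR-{i + 1}-5p", arm5, hid, s5, s5 + arm_len, "5p"),
                    MatureMiRNA(f"sim-miR-{i + 1}-3p", arm3, hid, s3, s3 + arm_len, "3p"),
                ],
            )
            used.update((arm5, arm3))
            break
        else:  # pragma: no cover - overwhelmingly unlikely
            raise RuntimeError(f"could not build a folding hairpin for {hid}")
    class_dbs = {}
    for cls, (n, lo, hi) in _DB_SHAPES.items():
        records = {
            f"{cls}-{j + 1}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
            for j in range(n)
        }
        class_dbs[cls] = RNAClassDB(cls, records)
    return ReferenceSet(hairpins=hairpins, class_dbs=class_dbs)


def generate_regions(spec: SimulationSpec) -> GenomicRegionSet:
    """Random genome with alternating intronic/intergenic intervals."""
    rng = np.random.default_rng(spec.seed + 101)
    genome: dict[str, str] = {}
    regions: list[GenomicRegion] = []
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        genome[chrom] = _random_seq(rng, spec.chromosome_length)
        pos, toggle = 300, c % 2
        while pos + 2500 < spec.chromosome_length:
            rtype = "intronic" if toggle % 2 == 0 else "intergenic"
            end = min(pos + int(rng.integers(2500, 4500)), spec.chromosome_length - 100)
            if end - pos >= 500:
                regions.append(GenomicRegion(chrom, pos, end, rtype))
            pos = end + int(rng.integers(200, 500))
            toggle += 1
    return GenomicRegionSet(regions, genome)


# ---------------------------------------------------------------------------
# read planting


@dataclass(frozen=True)
class FamilyPlan:
    """Planned isomiR family for one mature miRNA in one sample."""

    mature_name: str
    weight: float
    member_offsets: tuple[tuple[int, int], ...]
    dominant: tuple[int, int]
    expressed: bool = True

    @property
    def dominant_is_reference(self) -> bool:
        return self.dominant == (0, 0)


@dataclass
class PlantedFamily:
    """Realized truth for one miRNA family."""

    mature_name: str
    canonical: str
    members: dict[str, int]
    offsets: dict[str, tuple[int, int]]
    dominant_seq: str
    label: str  # YES iff dominant_seq == canonical


@dataclass
class PlantedNovel:
    novel_id: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    mature_seq: str
    isomir_seqs: list[str]
    counterpart_seq: str
    is_decoy: bool
    read_counts: dict[str, int]


@dataclass
class TruthTable:
    """Everything planted: per-read labels, families, novel loci."""

    read_classes: dict[str, str] = field(default_factory=dict)
    families: dict[str, PlantedFamily] = field(default_factory=dict)
    canonical: dict[str, str] = field(default_factory=dict)
    novel: list[PlantedNovel] = field(default_factory=list)
    ambiguous: set[str] = field(default_factory=set)
    total_reads: int = 0

    def class_mass_of(self, lib: ReadLibrary) -> dict[str, int]:
        mass: dict[str, int] = {}
        for read in lib.reads:
            label = self.read_classes[read.sequence]
            mass[label] = mass.get(label, 0) + read.count
        return mass


@dataclass(frozen=True)
class _Entry:
    sequence: str
    weight: float
    label: str
    mature_name: Optional[str] = None
    offsets: Optional[tuple[int, int]] = None
    novel_id: Optional[str] = None
    fixed: bool = False  # exempt from multinomial resampling and truncation


def _valid_offsets(
    mature: MatureMiRNA, hairpin: Hairpin, table: Mapping[tuple[int, int], float]
) -> dict[tuple[int, int], float]:
    out = {}
    for (o5, o3), p in table.items():
        start, end = mature.start + o5, mature.end + o3
        if 0 <= start < end <= len(hairpin.sequence) and end - start >= 14:
            out[(o5, o3)] = p
    return out


def _sample_offsets(
    rng: np.random.Generator,
    valid: dict[tuple[int, int], float],
    k: int,
    required: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    chosen = list(dict.fromkeys(required))
    remaining = [o for o in valid if o not in chosen]
    probs = np.array([valid[o] for o in remaining], dtype=float)
    k_extra = min(max(k - len(chosen), 0), len(remaining))
    if k_extra and probs.sum() > 0:
        idx = rng.choice(len(remaining), size=k_extra, replace=False, p=probs / probs.sum())
        chosen.extend(remaining[int(i)] for i in sorted(idx))
    return chosen


def plan_families(
    spec: SimulationSpec, ref: ReferenceSet, rng: np.random.Generator
) -> list[FamilyPlan]:
    """Default single-sample family plan: expression, members and dominants."""
    plans = []
    for mature in sorted(ref.matures, key=lambda m: m.name):
        if rng.random() > spec.expressed_fraction:
            continue
        hairpin = ref.hairpins[mature.hairpin_id]
        valid = _valid_offsets(mature, hairpin, spec.isomir_offset_probs)
        if (0, 0) not in valid:
            continue
        weight = 10.0 ** rng.uniform(*spec.expression_log10_range)
        # highly expressed miRNAs carry more distinct isomiRs
        k = int(np.clip(2 + round(2 * math.log10(max(weight, 1.0))), 2, len(valid)))
        if rng.random() < spec.dominant_is_reference_prob:
            dominant = (0, 0)
        else:
            others = [o for o in valid if o != (0, 0)]
            dominant = others[int(rng.integers(0, len(others)))]
        offsets = _sample_offsets(rng, valid, k, [dominant])
        plans.append(FamilyPlan(mature.name, weight, tuple(offsets), dominant))
    return plans


def _family_entries(
    spec: SimulationSpec,
    ref: ReferenceSet,
    plans: Sequence[FamilyPlan],
    rng: np.random.Generator,
    used: set[str],
) -> list[_Entry]:
    matures = {m.name: m for m in ref.matures}
    entries: list[_Entry] = []
    for plan in plans:
        if not plan.expressed:
            continue
        mature = matures[plan.mature_name]
        hairpin = ref.hairpins[mature.hairpin_id]
        member_seqs: dict[tuple[int, int], str] = {}
        for o5, o3 in plan.member_offsets:
            seq = hairpin.sequence[mature.start + o5 : mature.end + o3]
            if seq in used:
                continue
            member_seqs[(o5, o3)] = seq
        if plan.dominant not in member_seqs:
            continue  # dominant collided with an existing sequence: drop family
        fractions = {
            o: float(rng.uniform(0.05, 1.0 / spec.dominant_margin * 0.9))
            for o in member_seqs
            if o != plan.dominant
        }
        denom = 1.0 + sum(fractions.values())
        dom_weight = plan.weight / denom
        for o, seq in member_seqs.items():
            w = dom_weight if o == plan.dominant else dom_weight * fractions[o]
            entries.append(_Entry(seq, w, "miRNA", plan.mature_name, o))
            used.add(seq)
    return entries


def _length_from_table(rng: np.random.Generator, max_len: int) -> int:
    table = {l: p for l, p in _LENGTH_TABLE.items() if l <= max_len}
    if not table:
        return max_len
    return int(_choice_from_table(rng, table))


def _contaminant_entries(
    spec: SimulationSpec,
    ref: ReferenceSet,
    rng: np.random.Generator,
    used: set[str],
    targets: Mapping[str, float],
) -> list[_Entry]:
    entries: list[_Entry] = []
    for cls in ("sn_sno", "lincRNA", "tRNA", "rRNA", "mRNA", "misc"):
        target = targets.get(cls, 0.0)
        if target <= 0:
            continue
        db = ref.class_dbs.get(cls)
        if db is None or not db.records:
            raise ConfigurationError(f"class {cls} requested but its database is empty")
        names = sorted(db.records)
        n_reads = max(8, int(round(target / 30.0)))
        weights, seqs = [], []
        attempts = 0
        while len(seqs) < n_reads and attempts < n_reads * 20:
            attempts += 1
            record = db.records[names[int(rng.integers(0, len(names)))]]
            length = _length_from_table(rng, len(record))
            start = int(rng.integers(0, len(record) - length + 1))
            seq = record[start : start + length]
            n_mm = int(rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1]))
            if n_mm:
                chars = list(seq)
                for pos in rng.choice(length, size=n_mm, replace=False):
                    options = [b for b in "ACGT" if b != chars[pos]]
                    chars[int(pos)] = options[int(rng.integers(0, 3))]
                seq = "".join(chars)
            if seq in used:
                continue
            used.add(seq)
            seqs.append(seq)
            weights.append(10.0 ** rng.uniform(0.0, 1.5))
        scale = target / sum(weights)
        entries.extend(
            _Entry(s, w * scale, cls) for s, w in zip(seqs, weights)
        )
    return entries


def _genomic_entries(
    spec: SimulationSpec,
    regions: Optional[GenomicRegionSet],
    rng: np.random.Generator,
    used: set[str],
    target: float,
    db_blob: str,
    count_factor: float,
    flank: int = 70,
    min_freq_gate: int = 5,
) -> list[_Entry]:
    """Unannotated-genomic background: a few screened loci plus low-count debris.

    The background must never masquerade as a novel miRNA locus, so it is
    built in two tiers: "hub" reads with moderate expected counts whose
    flank-extended windows are rejection-sampled to NOT fold (mirroring the
    planted decoys), and many "debris" reads whose expected counts sit well
    below the novel-candidate frequency gate.  ``count_factor`` converts
    weight units into expected read counts, so the tiering is stable across
    library sizes.
    """
    if target <= 0:
        return []
    if regions is None or not regions.regions:
        raise ConfigurationError(
            "unannotated_genomic proportion > 0 but no genomic regions supplied"
        )
    fold_params = FoldParams()
    expected_mass = target * count_factor
    n_hub = max(1, int(round(0.4 * expected_mass / 27.0)))
    n_debris = max(5, int(round(0.6 * expected_mass / 0.7)))

    def draw(length_cap: int = 28) -> tuple[GenomicRegion, int, str] | None:
        region = regions.regions[int(rng.integers(0, len(regions.regions)))]
        seq_region = regions.region_sequence(region)
        length = _length_from_table(rng, min(length_cap, len(seq_region)))
        start = int(rng.integers(0, len(seq_region) - length + 1))
        seq = seq_region[start : start + length]
        if seq in used or seq in db_blob:
            return None
        return region, start, seq

    entries: list[_Entry] = []
    attempts = 0
    while len(entries) < n_hub and attempts < n_hub * 50 + 200:
        attempts += 1
        drawn = draw()
        if drawn is None:
            continue
        region, start, seq = drawn
        chrom_seq = regions.genome[region.chrom]
        gstart = region.start + start
        window = chrom_seq[
            max(0, gstart - flank) : min(len(chrom_seq), gstart + len(seq) + flank)
        ]
        if fold_hairpin(window, fold_params).accepted:
            continue  # looks like a hairpin locus: not background
        used.add(seq)
        entries.append(
            _Entry(seq, float(rng.uniform(15.0, 40.0)) / count_factor,
                   "unannotated_genomic")
        )
    attempts = 0
    while len(entries) < n_hub + n_debris and attempts < n_debris * 20:
        attempts += 1
        drawn = draw()
        if drawn is None:
            continue
        region, start, seq = drawn
        used.add(seq)
        entries.append(
            _Entry(seq, float(rng.uniform(0.3, 1.1)) / count_factor,
                   "unannotated_genomic")
        )
    total = sum(e.weight for e in entries)
    return [replace(e, weight=e.weight * target / total) for e in entries]


def _unmatched_entries(
    spec: SimulationSpec,
    rng: np.random.Generator,
    used: set[str],
    target: float,
    forbidden_blob: str,
) -> list[_Entry]:
    if target <= 0:
        return []
    entries: list[_Entry] = []
    n_reads = max(5, int(round(target / 2.0)))
    attempts = 0
    while len(entries) < n_reads and attempts < n_reads * 20:
        attempts += 1
        seq = _random_seq(rng, _length_from_table(rng, 28))
        if seq in used or seq in forbidden_blob or revcomp(seq) in forbidden_blob:
            continue
        used.add(seq)
        entries.append(_Entry(seq, float(rng.uniform(1.0, 3.0)), "unmatched"))
    total = sum(e.weight for e in entries)
    return [replace(e, weight=e.weight * target / total) for e in entries]


def _truncation_probs(
    spec: SimulationSpec, length: int
) -> tuple[list[int], np.ndarray]:
    """Distribution of 3' trim amounts for one read length in degraded mode.

    A degraded read is truncated down to a target length drawn from
    ``degraded_target_probs`` (mode 17 nt); targets at or above the read's
    own length leave it untouched, as does the intact fraction.
    """
    f = spec.degraded_fraction
    table = spec.degraded_target_probs
    p_no_trim = (1.0 - f) + f * sum(p for t, p in table.items() if t >= length)
    trims = [0]
    probs = [p_no_trim]
    for t in sorted(table):
        if t < length:
            trims.append(length - t)
            probs.append(f * table[t])
    arr = np.array(probs)
    return trims, arr / arr.sum()


def _apply_degradation(
    spec: SimulationSpec,
    realized: list[tuple[_Entry, int]],
    rng: np.random.Generator,
) -> list[tuple[_Entry, int]]:
    if spec.length_mode != "degraded_17":
        return realized
    out: list[tuple[_Entry, int]] = []
    for entry, count in realized:
        if entry.fixed or count == 0:
            out.append((entry, count))
            continue
        trims, probs = _truncation_probs(spec, len(entry.sequence))
        split = rng.multinomial(count, probs)
        for trim, n in zip(trims, split):
            if n == 0:
                continue
            if trim == 0:
                out.append((entry, int(n)))
            else:
                seq = entry.sequence[: len(entry.sequence) - trim]
                offs = entry.offsets
                if offs is not None:
                    offs = (offs[0], offs[1] - trim)
                out.append((replace(entry, sequence=seq, offsets=offs), int(n)))
    return out


def _dominant_of(members: dict[str, int], offsets: dict[str, tuple[int, int]]) -> str:
    return sorted(
        members,
        key=lambda s: (
            -members[s],
            abs(offsets[s][0]),
            abs(offsets[s][1]),
            s,
        ),
    )[0]


def generate_reads(
    spec: SimulationSpec,
    ref: ReferenceSet,
    regions: Optional[GenomicRegionSet] = None,
    extra_entries: Optional[Sequence[_Entry]] = None,
    plan: Optional[Sequence[FamilyPlan]] = None,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sim",
) -> tuple[ReadLibrary, TruthTable]:
    """Generate one sample's collapsed library plus its truth table.

    ``extra_entries`` (e.g. planted novel-locus reads) carry exact counts and
    are exempt from multinomial resampling and degradation.  ``plan`` overrides
    the default per-miRNA family plan (used by :func:`generate_cohort`).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    used: set[str] = set()
    extra = list(extra_entries or [])
    for e in extra:
        used.add(e.sequence)

    if plan is None:
        plan = plan_families(spec, ref, rng)
    entries = _family_entries(spec, ref, plan, rng, used)
    w_mirna = sum(e.weight for e in entries)
    p = dict(spec.class_proportions)
    p_mirna = p.get("miRNA", 0.0)
    if entries and p_mirna <= 0:
        raise ConfigurationError("miRNA families planned but miRNA proportion is 0")
    w_total = w_mirna / p_mirna if p_mirna > 0 else 1000.0
    targets = {cls: p.get(cls, 0.0) * w_total for cls in p}

    db_blob = "#".join(
        sorted(
            [hp.sequence for hp in ref.hairpins.values()]
            + [
                seq
                for db in ref.class_dbs.values()
                for seq in db.records.values()
            ]
        )
    )
    genome_blob = "#".join(
        regions.genome[c] for c in sorted(regions.genome)
    ) if regions is not None else ""

    count_factor = (
        1.0
        if spec.fixed_counts or spec.total_reads == 0
        else spec.total_reads / max(w_total, 1e-9)
    )
    entries += _contaminant_entries(spec, ref, rng, used, targets)
    entries += _genomic_entries(
        spec,
        regions,
        rng,
        used,
        targets.get("unannotated_genomic", 0.0),
        db_blob,
        count_factor,
    )
    entries += _unmatched_entries(
        spec, rng, used, targets.get("unmatched", 0.0), db_blob + "#" + genome_blob
    )

    # realize counts
    realized: list[tuple[_Entry, int]] = []
    if spec.fixed_counts:
        for e in entries:
            realized.append((e, max(1, int(round(e.weight)))))
    elif entries:
        weights = np.array([e.weight for e in entries], dtype=float)
        counts = rng.multinomial(spec.total_reads, weights / weights.sum())
        realized = [(e, int(n)) for e, n in zip(entries, counts)]
    if spec.fixed_counts:
        # enforce the planted dominant margin exactly
        by_family: dict[str, list[int]] = {}
        for i, (e, n) in enumerate(realized):
            if e.label == "miRNA" and e.mature_name:
                by_family.setdefault(e.mature_name, []).append(i)
        plan_by_name = {fp.mature_name: fp for fp in plan}
        for name, idxs in by_family.items():
            fp = plan_by_name[name]
            dom_idx = next(
                (i for i in idxs if realized[i][0].offsets == fp.dominant), None
            )
            if dom_idx is None:
                continue
            others = [realized[i][1] for i in idxs if i != dom_idx]
            if others:
                need = int(math.ceil(spec.dominant_margin * max(others)))
                e, n = realized[dom_idx]
                realized[dom_idx] = (e, max(n, need))

    realized += [(e, max(1, int(round(e.weight)))) for e in extra]
    realized = _apply_degradation(spec, realized, rng)

    # collapse
    counts: dict[str, int] = {}
    labels: dict[str, str] = {}
    family_members: dict[str, dict[str, int]] = {}
    family_offsets: dict[str, dict[str, tuple[int, int]]] = {}
    novel_ids: dict[str, str] = {}
    ambiguous: set[str] = set()
    for entry, n in realized:
        if n <= 0:
            continue
        seq = entry.sequence
        counts[seq] = counts.get(seq, 0) + n
        if seq in labels and labels[seq] != entry.label:
            ambiguous.add(seq)
        else:
            labels[seq] = entry.label
        if entry.label == "miRNA" and entry.mature_name is not None:
            fam = family_members.setdefault(entry.mature_name, {})
            fam[seq] = fam.get(seq, 0) + n
            family_offsets.setdefault(entry.mature_name, {}).setdefault(
                seq, entry.offsets or (0, 0)
            )
        if entry.novel_id is not None:
            novel_ids[seq] = entry.novel_id

    lib = ReadLibrary.from_counts(sample_id, counts)
    canonical = {
        m.name: m.sequence for m in ref.matures
    }
    truth = TruthTable(
        read_classes=labels,
        canonical=canonical,
        ambiguous=ambiguous,
        total_reads=lib.total_reads,
    )
    for name, members in sorted(family_members.items()):
        offsets = family_offsets[name]
        dom = _dominant_of(members, offsets)
        truth.families[name] = PlantedFamily(
            name,
            canonical[name],
            dict(members),
            dict(offsets),
            dom,
            "YES" if dom == canonical[name] else "NO",
        )
    return lib, truth


# ---------------------------------------------------------------------------
# novel-locus planting


def plant_novel_hairpins(
    spec: SimulationSpec,
    regions: GenomicRegionSet,
    n_novel: int,
    n_decoys: int = 0,
    flank: int = 70,
    seed: Optional[int] = None,
) -> tuple[GenomicRegionSet, list[_Entry], list[PlantedNovel]]:
    """Embed folding precursors (and non-folding decoy loci) into the genome.

    Each planted precursor sits inside an intronic/intergenic interval with
    room for the discovery flanks; its reads (mature arm, one 3'-trimmed
    isomiR, one opposite-arm counterpart) all meet the minimum-frequency gate.
    Decoy loci carry a high-count read whose flank-extended window is verified
    NOT to fold (rejection-sampled), so they exercise the negative path.
    Returns the updated regions, the read entries to plant, and the truth.
    """
    rng = np.random.default_rng(spec.seed + 7 if seed is None else seed)
    genome = dict(regions.genome)
    fold_params = FoldParams()
    occupied: list[tuple[str, int, int]] = []

    def free(chrom: str, start: int, end: int) -> bool:
        return all(
            not (chrom == c and start < e + 200 and end > s - 200)
            for c, s, e in occupied
        )

    entries: list[_Entry] = []
    truth: list[PlantedNovel] = []

    def pick_position(length: int) -> tuple[GenomicRegion, int]:
        suitable = [
            r for r in regions.regions if (r.end - r.start) >= length + 2 * flank + 20
        ]
        if not suitable:
            raise ConfigurationError(
                f"no region long enough for a precursor of {length} nt plus "
                f"{flank} nt flanks; longest is "
                f"{max((r.end - r.start) for r in regions.regions)} nt"
            )
        for _ in range(200):
            region = suitable[int(rng.integers(0, len(suitable)))]
            pos = int(
                rng.integers(region.start + flank, region.end - flank - length)
            )
            if free(region.chrom, pos, pos + length):
                return region, pos
        raise ConfigurationError("could not place a novel locus without overlap")

    for k in range(n_novel):
        for _attempt in range(100):
            arm_len = int(rng.integers(20, 24))
            arm5 = _random_seq(rng, arm_len)
            loop = _random_seq(rng, int(rng.integers(8, 14)))
            arm3 = _mutate_interior(rng, revcomp(arm5), spec.stem_mutation_rate, 2)
            precursor = arm5 + loop + arm3
            if not fold_hairpin(precursor, fold_params).accepted:
                continue
            region, pos = pick_position(len(precursor))
            chrom_seq = genome[region.chrom]
            genome[region.chrom] = (
                chrom_seq[:pos] + precursor + chrom_seq[pos + len(precursor) :]
            )
            # verify the discovery window itself folds
            window = genome[region.chrom][pos - flank : pos + len(precursor) + flank]
            if not fold_hairpin(window, fold_params).accepted:
                genome[region.chrom] = chrom_seq  # revert
                continue
            occupied.append((region.chrom, pos, pos + len(precursor)))
            mature_count = int(rng.integers(24, 61))
            isomir = arm5[: arm_len - 2]  # 3'-trimmed isomiR, still in the arm
            counterpart = precursor[arm_len + len(loop) + 1 : len(precursor) - 1]
            reads = {
                arm5: mature_count,
                isomir: int(rng.integers(6, max(7, mature_count // 3))),
                counterpart: int(rng.integers(5, max(6, mature_count // 4))),
            }
            nid = f"novel-{k + 1}"
            for seq, count in reads.items():
                entries.append(
                    _Entry(seq, float(count), "unannotated_genomic", novel_id=nid, fixed=True)
                )
            truth.append(
                PlantedNovel(
                    nid,
                    region.chrom,
                    pos,
                    pos + len(precursor),
                    "+",
                    precursor,
                    arm5,
                    [isomir],
                    counterpart,
                    False,
                    reads,
                )
            )
            break
        else:  # pragma: no cover
            raise RuntimeError("failed to plant a novel hairpin")

    updated = GenomicRegionSet(list(regions.regions), genome)
    for k in range(n_decoys):
        for _attempt in range(200):
            region, pos = pick_position(22)
            seq = updated.genome[region.chrom][pos : pos + 22]
            window = updated.genome[region.chrom][pos - flank : pos + 22 + flank]
            if fold_hairpin(window, fold_params).accepted:
                continue
            occupied.append((region.chrom, pos, pos + 22))
            count = int(rng.integers(5, 21))
            nid = f"decoy-{k + 1}"
            entries.append(
                _Entry(seq, float(count), "unannotated_genomic", novel_id=nid, fixed=True)
            )
            truth.append(
                PlantedNovel(
                    nid, region.chrom, pos, pos + 22, "+", window, seq, [], "", True,
                    {seq: count},
                )
            )
            break
        else:  # pragma: no cover
            raise RuntimeError("failed to plant a decoy locus")
    return updated, entries, truth


# ---------------------------------------------------------------------------
# cohorts (groups of samples sharing planted YES/NO structure)


@dataclass
class CohortSample:
    sample_id: str
    group_id: str
    library: ReadLibrary
    truth: TruthTable


@dataclass
class Cohort:
    samples: list[CohortSample]
    #: group -> miRNA name -> planned status (YES/NO/low_expression/non_uniform)
    group_status: dict[str, dict[str, str]]

    def libraries(self, group_id: Optional[str] = None) -> dict[str, ReadLibrary]:
        return {
            s.sample_id: s.library
            for s in self.samples
            if group_id is None or s.group_id == group_id
        }


_STATUS_PROBS = {"YES": 0.10, "NO": 0.20, "low_expression": 0.63, "non_uniform": 0.07}


def generate_cohort(
    spec: SimulationSpec,
    ref: ReferenceSet,
    regions: Optional[GenomicRegionSet] = None,
    n_groups: int = 2,
    samples_per_group: int = 2,
    status_probs: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> Cohort:
    """Samples in ``n_groups`` groups with planted group-level YES/NO structure.

    Within a group all samples share expression weights and family plans; the
    planted status of each miRNA (YES / NO / low_expression / non_uniform)
    drives per-sample dominants and presence.  Status priors default to the
    composition a whole-miRnome comparison shows: most miRNAs below the
    detection limit, a minority uniformly expressed, and about twice as many
    NO as YES among those.
    """
    if samples_per_group < 2:
        raise ConfigurationError("cohorts need >= 2 samples per group")
    probs = dict(status_probs or _STATUS_PROBS)
    base_seed = spec.seed if seed is None else seed
    statuses = list(probs)
    pvec = np.array([probs[s] for s in statuses], dtype=float)
    pvec = pvec / pvec.sum()
    matures = {m.name: m for m in sorted(ref.matures, key=lambda m: m.name)}

    samples: list[CohortSample] = []
    group_status: dict[str, dict[str, str]] = {}
    for g in range(n_groups):
        gid = f"group{g + 1}"
        rng_g = np.random.default_rng(base_seed + 7919 * (g + 1))
        status_of: dict[str, str] = {}
        plans_per_sample: list[list[FamilyPlan]] = [[] for _ in range(samples_per_group)]
        for name, mature in matures.items():
            status = statuses[int(rng_g.choice(len(statuses), p=pvec))]
            hairpin = ref.hairpins[mature.hairpin_id]
            valid = _valid_offsets(mature, hairpin, spec.isomir_offset_probs)
            if (0, 0) not in valid or len(valid) < 2:
                status = "low_expression"
                status_of[name] = status
                continue
            status_of[name] = status
            weight = 10.0 ** rng_g.uniform(1.5, 3.5)
            non_ref = [o for o in valid if o != (0, 0)]
            alt = non_ref[int(rng_g.integers(0, len(non_ref)))]
            k = int(np.clip(2 + round(2 * math.log10(weight)), 3, len(valid)))
            offsets = tuple(
                _sample_offsets(rng_g, valid, k, [(0, 0), alt])
            )
            if status == "low_expression":
                absent_everywhere = rng_g.random() < 0.5
                absent_in = (
                    set(range(samples_per_group))
                    if absent_everywhere
                    else {int(rng_g.integers(0, samples_per_group))}
                )
                for s in range(samples_per_group):
                    if s not in absent_in:
                        plans_per_sample[s].append(
                            FamilyPlan(name, weight, offsets, (0, 0))
                        )
            elif status == "YES":
                for s in range(samples_per_group):
                    plans_per_sample[s].append(FamilyPlan(name, weight, offsets, (0, 0)))
            elif status == "NO":
                for s in range(samples_per_group):
                    plans_per_sample[s].append(FamilyPlan(name, weight, offsets, alt))
            else:  # non_uniform: first sample dominated by the reference
                for s in range(samples_per_group):
                    dom = (0, 0) if s == 0 else alt
                    plans_per_sample[s].append(FamilyPlan(name, weight, offsets, dom))
        group_status[gid] = status_of
        for s in range(samples_per_group):
            sid = f"{gid}_s{s + 1}"
            lib, truth = generate_reads(
                spec,
                ref,
                regions=regions,
                plan=plans_per_sample[s],
                rng=np.random.default_rng(base_seed + 104729 * (g + 1) + s),
                sample_id=sid,
            )
            samples.append(CohortSample(sid, gid, lib, truth))
    return Cohort(samples, group_status)


def simulate_sample(
    spec: SimulationSpec,
    n_novel: int = 0,
    n_decoys: int = 0,
    sample_id: str = "sim",
) -> tuple[ReferenceSet, GenomicRegionSet, ReadLibrary, TruthTable]:
    """Convenience: reference + regions (+ planted novel loci) + one library."""
    ref = generate_reference(spec)
    regions = generate_regions(spec)
    extra: list[_Entry] = []
    novel_truth: list[PlantedNovel] = []
    if n_novel or n_decoys:
        regions, extra, novel_truth = plant_novel_hairpins(
            spec, regions, n_novel, n_decoys
        )
    lib, truth = generate_reads(
        spec, ref, regions=regions, extra_entries=extra, sample_id=sample_id
    )
    truth.novel = novel_truth
    return ref, regions, lib, truth
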