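"""End-to-end orchestration: one sample, then a whole study.

``run_sample`` chains length filtering, length diagnostics, elimination
annotation, the reference profile, hairpin alignment, isomiR familying and
the abundant-isomiR profile.  ``run_study`` adds the per-group YES/NO
comparison, sample clustering and the pooled novel-miRNA track.
``write_study_outputs`` emits every result as deterministic TSV/text, so two
runs from the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .annotate import (
    AnnotationResult,
    LengthDistribution,
    eliminate,
    filter_by_length,
    length_distribution,
)
from .config import PipelineConfig
from .core import GenomicRegionSet, ReadLibrary, ReferenceSet
from .fold import FoldEngine
from .io import write_profile_tsv
from .isomir import (
    ComparisonRecord,
    GroupTally,
    IsomiRFamily,
    SampleIsomirProfile,
    abundant_profile,
    align_to_hairpins,
    build_families,
    compare_profiles,
    select_dominant,
)
from .novel import NovelCandidate, predict_novel
from .profiles import ExpressionProfile, SampleLinkage, cluster_samples, reference_profile

__all__ = ["SampleResult", "StudyResult", "run_sample", "run_study", "write_study_outputs"]


@dataclass
class SampleResult:
    sample_id: str
    raw_total: int
    library: ReadLibrary  # length-filtered
    lengths: LengthDistribution
    annotation: AnnotationResult
    reference: ExpressionProfile
    families: dict[str, IsomiRFamily]
    hairpin_other_mass: int
    abundant: ExpressionProfile
    dominants: dict[str, str]

    @property
    def isomir_profile(self) -> SampleIsomirProfile:
        return SampleIsomirProfile(
            self.sample_id, self.reference, self.abundant, self.dominants
        )


@dataclass
class StudyResult:
    samples: dict[str, SampleResult]
    comparisons: dict[str, tuple[list[ComparisonRecord], GroupTally]]
    linkage: Optional[SampleLinkage]
    novel: list[NovelCandidate]


def run_sample(
    lib: ReadLibrary,
    ref: ReferenceSet,
    regions: Optional[GenomicRegionSet],
    cfg: PipelineConfig | None = None,
) -> SampleResult:
    cfg = cfg or PipelineConfig()
    raw_total = lib.total_reads
    lengths = length_distribution(lib)
    filtered = filter_by_length(lib, cfg.min_read_length)
    annotation = eliminate(filtered, ref, regions, cfg)
    ref_profile = reference_profile(filtered, ref)
    alignments = align_to_hairpins(filtered, ref, cfg.max_mismatches)
    families, hairpin_other = build_families(
        alignments, ref, cfg.family_overlap_fraction
    )
    abundant = abundant_profile(families, filtered.total_reads, lib.sample_id)
    dominants = {
        name: select_dominant(family).sequence for name, family in families.items()
    }
    return SampleResult(
        lib.sample_id,
        raw_total,
        filtered,
        lengths,
        annotation,
        ref_profile,
        families,
        sum(a.read.count for a in hairpin_other),
        abundant,
        dominants,
    )


def run_study(
    libraries: Mapping[str, ReadLibrary],
    groups: Mapping[str, Sequence[str]],
    ref: ReferenceSet,
    regions: Optional[GenomicRegionSet],
    cfg: PipelineConfig | None = None,
    engine: FoldEngine | None = None,
) -> StudyResult:
    """Run every sample, compare profiles per group, cluster and mine novels."""
    cfg = cfg or PipelineConfig()
    samples = {
        sid: run_sample(lib, ref, regions, cfg) for sid, lib in sorted(libraries.items())
    }
    canonical = ref.mature_sequences()
    comparisons = {}
    for gid, members in sorted(groups.items()):
        pairs = [samples[sid].isomir_profile for sid in members]
        comparisons[gid] = compare_profiles(
            pairs, canonical, gid, cfg.detection_threshold
        )
    linkage = None
    if len(samples) >= 2:
        try:
            linkage = cluster_samples([s.reference for s in samples.values()])
        except ValueError:
            linkage = None
    novel = []
    if regions is not None:
        unannotated = {
            sid: s.annotation.reads_with_label("unannotated_genomic")
            for sid, s in samples.items()
        }
        novel = predict_novel(unannotated, regions, cfg, engine)
    return StudyResult(samples, comparisons, linkage, novel)


def write_study_outputs(study: StudyResult, outdir: str | Path) -> list[Path]:
    """Write every study artefact as deterministic text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, lines: Sequence[str]) -> None:
        path = outdir / name
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    for sid, s in sorted(study.samples.items()):
        emit(
            f"{sid}.lengths.tsv",
            ["length\tcount"]
            + [f"{l}\t{n}" for l, n in sorted(s.lengths.histogram.items())],
        )
        emit(
            f"{sid}.apportionment.tsv",
            ["class\tmass\tfraction"]
            + [
                f"{cls}\t{s.annotation.class_mass[cls]}\t{frac:.6f}"
                for cls, frac in sorted(s.annotation.apportionment.items())
            ],
        )

    ref_path = outdir / "reference_profile.tsv"
    write_profile_tsv([s.reference for s in study.samples.values()], ref_path)
    written.append(ref_path)
    ab_path = outdir / "abundant_profile.tsv"
    write_profile_tsv([s.abundant for s in study.samples.values()], ab_path)
    written.append(ab_path)

    for gid, (records, tally) in sorted(study.comparisons.items()):
        lines = ["miRNA\tstatus"] + [f"{r.name}\t{r.status}" for r in records]
        lines.append(
            f"# YES={tally.n_yes} NO={tally.n_no} "
            f"not_considered={tally.not_considered}"
        )
        emit(f"{gid}.comparison.tsv", lines)

    if study.linkage is not None:
        emit("clustering.nwk", [study.linkage.to_newick()])

    lines = [
        "name\tchrom\tstart\tend\tstrand\ttotal_count\tmature\tn_members"
        "\thas_isomir\thas_counterpart\tsamples\tprecursor\tstructure"
    ]
    for c in study.novel:
        lines.append(
            f"{c.name}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.total_count}"
            f"\t{c.mature_sequence}\t{len(c.members)}"
            f"\t{int(c.flags.has_isomir)}\t{int(c.flags.has_counterpart)}"
            f"\t{','.join(c.sample_ids)}\t{c.precursor}"
            f"\t{c.structure.dot_bracket(len(c.precursor))}"
        )
    emit("novel_candidates.tsv", lines)
    return written
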