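"""Novel-miRNA discovery: mapping, flank extension, filters, naming."""

import numpy as np
import pytest

from mirnome.config import PipelineConfig
from mirnome.core import (
    GenomicRegion,
    GenomicRegionSet,
    ReadLibrary,
    SmallRNARead,
    revcomp,
)
from mirnome.novel import (
    Placement,
    extend_flanks,
    group_name_dedupe,
    map_exact_to_regions,
    predict_novel,
    select_candidate_reads,
)
from mirnome.simulate import SimulationSpec, simulate_sample
from mirnome.annotate import eliminate, filter_by_length
from oracle_utils import hamming_placements

BASES = np.array(list("ACGT"))


def _read(seq, count=10, rid="r"):
    return SmallRNARead(rid, seq, count)


class TestSelectCandidates:
    def test_minimum_frequency_boundary(self):
        reads = [_read("ACGT" * 5, 5, "a"), _read("TTTT" * 5, 4, "b")]
        kept = select_candidate_reads(reads, 5)
        assert [r.read_id for r in kept] == ["a"]

    def test_min_freq_one_is_identity(self):
        reads = [_read("ACGT" * 5, 1, "a"), _read("TTTT" * 5, 3, "b")]
        assert select_candidate_reads(reads, 1) == reads

    def test_empty_input(self):
        assert select_candidate_reads([], 5) == []


def _region_world(insert, left=120, right=120, seed=0):
    rng = np.random.default_rng(seed)
    chrom = (
        "".join(BASES[rng.integers(0, 4, left)])
        + insert
        + "".join(BASES[rng.integers(0, 4, right)])
    )
    genome = {"chr1": chrom}
    regions = [GenomicRegion("chr1", 0, len(chrom), "intronic")]
    return GenomicRegionSet(regions, genome), left


class TestMapExact:
    def test_single_planted_locus(self):
        read = "GATTACAGATTACAGATTACAG"
        world, offset = _region_world(read)
        placements = map_exact_to_regions([_read(read)], world)
        assert len(placements) == 1
        p = placements[0]
        assert (p.start, p.end, p.strand, p.region_type) == (
            offset,
            offset + len(read),
            "+",
            "intronic",
        )

    def test_reverse_strand_placement(self):
        read = "GATTACAGATTACAGATTACAG"
        world, offset = _region_world(revcomp(read))
        placements = map_exact_to_regions([_read(read)], world)
        assert len(placements) == 1
        p = placements[0]
        assert p.strand == "-"
        window = world.genome["chr1"][p.start : p.end]
        assert revcomp(window) == read

    def test_double_occurrence_matches_brute_force(self):
        read = "GATTACAGATTACAGATTACAG"
        world, offset = _region_world(read + "TTTTCCCC" + read)
        placements = map_exact_to_regions([_read(read)], world)
        region_seq = world.genome["chr1"]
        expected = [off for off, mm in hamming_placements(read, region_seq, 0)]
        assert [p.start for p in placements if p.strand == "+"] == expected
        assert len(expected) == 2

    def test_missing_chromosome_raises(self):
        region = GenomicRegion("chr1", 0, 10, "intronic")
        world = GenomicRegionSet([region], {"chr1": "A" * 10})
        world.genome = {}
        with pytest.raises(ValueError):
            map_exact_to_regions([_read("AAAA" * 5)], world)


class TestExtendFlanks:
    def _placement(self, start, end, strand="+"):
        return Placement(_read("A" * (end - start)), "chr1", start, end, strand, "intronic")

    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 300}
        w = extend_flanks(self._placement(100, 122), 70, genome)
        assert (w.start, w.end) == (30, 192)
        assert len(w.sequence) == 162 and not w.clipped
        assert w.read_local == (70, 92)

    def test_clipping_at_chromosome_start(self):
        genome = {"chr1": "A" * 300}
        w = extend_flanks(self._placement(10, 32), 70, genome)
        assert (w.start, w.end) == (0, 102) and w.clipped

    def test_minus_strand_contains_read_verbatim(self):
        rng = np.random.default_rng(2)
        chrom = "".join(BASES[rng.integers(0, 4, 400)])
        genome = {"chr1": chrom}
        read_seq = revcomp(chrom[150:172])
        p = Placement(_read(read_seq), "chr1", 150, 172, "-", "intronic")
        w = extend_flanks(p, 70, genome)
        s, e = w.read_local
        assert w.sequence[s:e] == read_seq


class TestGroupNameDedupe:
    def _candidate(self, chrom, start, end, members, sample, precursor="ACGT" * 40):
        from mirnome.fold import fold_hairpin
        from mirnome.novel import FilterFlags, NovelCandidate

        # structure content is irrelevant for grouping; reuse a stub stem
        structure = fold_hairpin(
            "GGGGGGGGGGGGGGGGGGGG" + "AAAA" + "CCCCCCCCCCCCCCCCCCCC",
            None,
        ).structure
        mature = max(members, key=members.get)
        return NovelCandidate(
            chrom, start, end, "+", precursor, structure, mature,
            members[mature], dict(members),
            FilterFlags(True, False, False), [sample],
        )

    def test_same_precursor_two_samples_merges(self):
        c1 = self._candidate("chr1", 100, 260, {"AAAA": 10}, "s1")
        c2 = self._candidate("chr1", 101, 261, {"AAAA": 4}, "s2")
        final = group_name_dedupe([[c1], [c2]])
        assert len(final) == 1
        assert final[0].sample_ids == ["s1", "s2"]
        assert final[0].members == {"AAAA": 14}

    def test_most_abundant_member_becomes_mature(self):
        c = self._candidate("chr1", 0, 160, {"AAAA": 12, "CCCC": 3}, "s1")
        final = group_name_dedupe([[c]])
        assert final[0].mature_sequence == "AAAA" and final[0].mature_count == 12

    def test_names_follow_descending_total_count(self):
        c1 = self._candidate("chr1", 0, 160, {"AAAA": 5}, "s1", precursor="A" * 160)
        c2 = self._candidate("chr2", 0, 160, {"CCCC": 50}, "s1", precursor="C" * 160)
        c3 = self._candidate("chr1", 500, 660, {"GGGG": 20}, "s1", precursor="G" * 160)
        final = group_name_dedupe([[c1, c2, c3]])
        assert [(c.name, c.total_count) for c in final] == [
            ("jnu-pat-hsa-1", 50),
            ("jnu-pat-hsa-2", 20),
            ("jnu-pat-hsa-3", 5),
        ]


class TestEndToEnd:
    def test_planted_recovery_with_decoys(self):
        spec = SimulationSpec(n_hairpins=10, total_reads=12_000, seed=31)
        ref, regions, lib, truth = simulate_sample(spec, n_novel=3, n_decoys=3)
        flt = filter_by_length(lib, 14)
        unann = eliminate(flt, ref, regions).reads_with_label("unannotated_genomic")
        final = predict_novel({"s1": unann}, regions)
        assert [c.name for c in final] == [
            "jnu-pat-hsa-1",
            "jnu-pat-hsa-2",
            "jnu-pat-hsa-3",
        ]
        planted = [n for n in truth.novel if not n.is_decoy]
        for n in planted:
            assert any(
                c.chrom == n.chrom and c.start < n.end and c.end > n.start
                for c in final
            )
        decoys = [n for n in truth.novel if n.is_decoy]
        for d in decoys:
            assert not any(
                c.chrom == d.chrom and c.start < d.end and c.end > d.start
                for c in final
            )

    def test_planted_family_has_isomir_and_counterpart_evidence(self):
        spec = SimulationSpec(n_hairpins=8, total_reads=8_000, seed=33)
        ref, regions, lib, truth = simulate_sample(spec, n_novel=1)
        flt = filter_by_length(lib, 14)
        unann = eliminate(flt, ref, regions).reads_with_label("unannotated_genomic")
        final = predict_novel({"s1": unann}, regions)
        assert len(final) == 1
        c = final[0]
        assert c.flags.in_stem and c.flags.has_isomir and c.flags.has_counterpart
        planted = truth.novel[0]
        assert c.mature_sequence == planted.mature_seq
        assert set(planted.read_counts) <= set(c.members)

    def test_raising_min_freq_never_increases_candidates(self):
        spec = SimulationSpec(n_hairpins=8, total_reads=8_000, seed=35)
        ref, regions, lib, truth = simulate_sample(spec, n_novel=2)
        flt = filter_by_length(lib, 14)
        unann = eliminate(flt, ref, regions).reads_with_label("unannotated_genomic")
        counts = []
        for mf in (1, 5, 40):
            cfg = PipelineConfig(novel_min_freq=mf)
            counts.append(len(predict_novel({"s1": unann}, regions, cfg)))
        assert counts == sorted(counts, reverse=True)
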