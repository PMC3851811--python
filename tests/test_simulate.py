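"""The synthetic-data generator: determinism, planted truth, study structure."""

import numpy as np
import pytest

from mirnome.annotate import length_distribution
from mirnome.core import ConfigurationError
from mirnome.fold import fold_hairpin
from mirnome.simulate import (
    SimulationSpec,
    generate_cohort,
    generate_reads,
    generate_reference,
    generate_regions,
    plant_novel_hairpins,
    simulate_sample,
)


class TestGenerateReference:
    def test_zero_hairpins_empty_reference(self):
        ref = generate_reference(SimulationSpec(n_hairpins=0, seed=1))
        assert ref.hairpins == {} and ref.matures == []

    def test_deterministic_under_seed(self):
        a = generate_reference(SimulationSpec(n_hairpins=6, seed=5))
        b = generate_reference(SimulationSpec(n_hairpins=6, seed=5))
        assert {h: hp.sequence for h, hp in a.hairpins.items()} == {
            h: hp.sequence for h, hp in b.hairpins.items()
        }
        assert {
            c: db.records for c, db in a.class_dbs.items()
        } == {c: db.records for c, db in b.class_dbs.items()}

    def test_hairpins_locate_matures_and_fold(self):
        ref = generate_reference(SimulationSpec(n_hairpins=10, seed=2))
        assert len(ref.hairpins) == 10 and len(ref.matures) == 20
        for hp in ref.hairpins.values():
            for m in hp.mature_loci:
                assert hp.sequence[m.start : m.end] == m.sequence
            assert fold_hairpin(hp.sequence).accepted


class TestGenerateReads:
    def test_zero_reads_empty_library(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=0, seed=7)
        lib, truth = generate_reads(spec, ref, regions=regions)
        assert lib.total_reads == 0 and len(lib) == 0

    def test_mass_conservation(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=20_000, seed=8)
        lib, truth = generate_reads(spec, ref, regions=regions)
        assert lib.total_reads == 20_000
        assert sum(truth.class_mass_of(lib).values()) == 20_000

    def test_dominant_is_reference_prob_one_forces_yes(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(
            n_hairpins=12,
            total_reads=15_000,
            seed=9,
            dominant_is_reference_prob=1.0,
            fixed_counts=True,
        )
        lib, truth = generate_reads(spec, ref, regions=regions)
        assert truth.families
        assert all(f.label == "YES" for f in truth.families.values())

    def test_class_proportions_recovered(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=100_000, seed=10)
        lib, truth = generate_reads(spec, ref, regions=regions)
        mass = truth.class_mass_of(lib)
        for cls, expected in spec.class_proportions.items():
            assert mass.get(cls, 0) / lib.total_reads == pytest.approx(
                expected, abs=0.01
            )

    def test_modal_lengths_by_mode(self, small_world):
        ref, regions = small_world
        normal = SimulationSpec(n_hairpins=12, total_reads=10_000, seed=11)
        degraded = SimulationSpec(
            n_hairpins=12, total_reads=10_000, seed=11, length_mode="degraded_17"
        )
        lib_n, _ = generate_reads(normal, ref, regions=regions)
        lib_d, _ = generate_reads(degraded, ref, regions=regions)
        assert length_distribution(lib_n).modal_length == 22
        assert length_distribution(lib_d).modal_length == 17

    def test_missing_regions_with_genomic_proportion_raises(self, small_world):
        ref, _ = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=1000, seed=12)
        with pytest.raises(ConfigurationError):
            generate_reads(spec, ref, regions=None)

    def test_determinism(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=5_000, seed=13)
        lib1, _ = generate_reads(spec, ref, regions=regions)
        lib2, _ = generate_reads(spec, ref, regions=regions)
        assert lib1.counts() == lib2.counts()

    def test_expression_drives_isomir_diversity(self, small_world):
        """Families of highly expressed miRNAs carry more distinct members."""
        from scipy.stats import spearmanr

        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, total_reads=50_000, seed=14)
        lib, truth = generate_reads(spec, ref, regions=regions)
        totals, sizes = [], []
        for fam in truth.families.values():
            totals.append(sum(fam.members.values()))
            sizes.append(len(fam.members))
        rho = spearmanr(totals, sizes).statistic
        assert rho > 0


class TestSpecValidation:
    def test_probability_tables_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationSpec(class_proportions={"miRNA": 0.5})

    def test_unknown_length_mode(self):
        with pytest.raises(ConfigurationError):
            SimulationSpec(length_mode="bimodal")


class TestPlantNovel:
    def test_zero_plants_leave_regions_unchanged(self, small_spec):
        regions = generate_regions(small_spec)
        updated, entries, truth = plant_novel_hairpins(small_spec, regions, 0)
        assert updated.genome == regions.genome and not entries and not truth

    def test_planted_reads_meet_frequency_gate(self, small_spec):
        regions = generate_regions(small_spec)
        _, entries, truth = plant_novel_hairpins(small_spec, regions, 2, 1)
        for rec in truth:
            for seq, count in rec.read_counts.items():
                assert count >= 5
        assert sum(1 for t in truth if t.is_decoy) == 1

    def test_planted_precursors_fold_and_decoys_do_not(self, small_spec):
        regions = generate_regions(small_spec)
        updated, _, truth = plant_novel_hairpins(small_spec, regions, 2, 2)
        for rec in truth:
            chrom = updated.genome[rec.chrom]
            if rec.is_decoy:
                window = chrom[rec.start - 70 : rec.end + 70]
                assert not fold_hairpin(window).accepted
            else:
                assert chrom[rec.start : rec.end] == rec.precursor
                window = chrom[rec.start - 70 : rec.end + 70]
                assert fold_hairpin(window).accepted

    def test_interval_too_short_is_reported(self, small_spec):
        # an interval that cannot host precursor + flanks must be rejected loudly
        from mirnome.core import GenomicRegion, GenomicRegionSet

        regions = generate_regions(small_spec)
        tiny = GenomicRegionSet(
            [GenomicRegion("chr1", 0, 100, "intronic")],
            {"chr1": regions.genome["chr1"]},
        )
        with pytest.raises(ConfigurationError, match="region"):
            plant_novel_hairpins(small_spec, tiny, 1)


class TestCohort:
    def test_group_statuses_cover_all_matures(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(
            n_hairpins=12, total_reads=10_000, seed=15, fixed_counts=True
        )
        cohort = generate_cohort(spec, ref, regions=regions)
        names = {m.name for m in ref.matures}
        for gid, status in cohort.group_status.items():
            assert set(status) == names
            assert set(status.values()) <= {
                "YES", "NO", "low_expression", "non_uniform"
            }
        assert len(cohort.samples) == 4

    def test_rejects_single_sample_groups(self, small_world):
        ref, regions = small_world
        spec = SimulationSpec(n_hairpins=12, seed=16)
        with pytest.raises(ConfigurationError):
            generate_cohort(spec, ref, regions=regions, samples_per_group=1)


def test_simulate_sample_convenience_is_deterministic():
    spec = SimulationSpec(n_hairpins=8, total_reads=5_000, seed=17)
    _, _, lib1, t1 = simulate_sample(spec, n_novel=1, n_decoys=1)
    _, _, lib2, t2 = simulate_sample(spec, n_novel=1, n_decoys=1)
    assert lib1.counts() == lib2.counts()
    assert [n.precursor for n in t1.novel] == [n.precursor for n in t2.novel]
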