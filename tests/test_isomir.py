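"""Hairpin alignment, isomiR families, dominants and the YES/NO comparison."""

import pytest

from mirnome.core import ReadLibrary, SmallRNARead
from mirnome.isomir import (
    FamilyMember,
    IsomiRFamily,
    SampleIsomirProfile,
    abundant_profile,
    align_to_hairpins,
    build_families,
    compare_profiles,
    isomir_count_distribution,
    select_dominant,
)
from mirnome.matching import placements
from mirnome.profiles import ExpressionProfile, ProfileRow, reference_profile
from oracle_utils import hamming_placements
from conftest import H1_ARM5, H1_LOOP, H1_ARM3


def _lib(counts):
    return ReadLibrary.from_counts("s", counts)


class TestAlignToHairpins:
    def test_interior_slice_aligns_once(self, tiny_ref):
        hp = tiny_ref.hairpins["mir-a"]
        read = hp.sequence[5:27]
        alns = align_to_hairpins(_lib({read: 1}), tiny_ref, 2)
        assert len(alns) == 1
        a = alns[0]
        assert (a.hairpin_id, a.start, a.end, a.mismatches) == ("mir-a", 5, 27, 0)

    def test_best_stratum_only(self, tiny_ref):
        # read exact on mir-a; 1-mm placements elsewhere are suppressed
        read = tiny_ref.hairpins["mir-a"].sequence[0:20]
        alns = align_to_hairpins(_lib({read: 1}), tiny_ref, 2)
        assert {a.mismatches for a in alns} == {0}

    def test_multi_mapping_retained_at_equal_stratum(self, tiny_ref):
        shared = "ACGTTACGGATCCATGCGTT"
        ha = tiny_ref.hairpins["mir-a"].sequence + shared
        hb = shared + tiny_ref.hairpins["mir-b"].sequence
        import mirnome.core as core

        ref = core.ReferenceSet(
            hairpins={
                "mir-a": core.Hairpin("mir-a", ha),
                "mir-b": core.Hairpin("mir-b", hb),
            }
        )
        alns = align_to_hairpins(_lib({shared: 3}), ref, 2)
        assert sorted(a.hairpin_id for a in alns) == ["mir-a", "mir-b"]

    def test_agrees_with_brute_force_scan(self, small_world):
        ref, _ = small_world
        import numpy as np

        rng = np.random.default_rng(3)
        hp_ids = sorted(ref.hairpins)
        for _ in range(30):
            hp = ref.hairpins[hp_ids[int(rng.integers(0, len(hp_ids)))]]
            start = int(rng.integers(0, max(1, len(hp.sequence) - 20)))
            read = hp.sequence[start : start + 20]
            if len(read) < 14:
                continue
            alns = align_to_hairpins(_lib({read: 1}), ref, 2)
            best = min(
                (
                    mm
                    for h in ref.hairpins.values()
                    for _, mm in hamming_placements(read, h.sequence, 2)
                ),
                default=None,
            )
            expected = [
                (hid, off, mm)
                for hid, h in sorted(ref.hairpins.items())
                for off, mm in hamming_placements(read, h.sequence, 2)
                if mm == best
            ]
            got = sorted((a.hairpin_id, a.start, a.mismatches) for a in alns)
            assert got == sorted(expected)


class TestBuildFamilies:
    def test_offsets_zero_for_canonical_read(self, tiny_ref):
        alns = align_to_hairpins(_lib({H1_ARM5: 4}), tiny_ref, 2)
        fams, other = build_families(alns, tiny_ref)
        assert not other
        member = fams["mir-a-5p"].members[0]
        assert (member.offset5, member.offset3, member.count) == (0, 0, 4)

    def test_offset_arithmetic_upstream_variant(self, tiny_ref):
        # family membership needs hairpin context upstream of the mature: use
        # the 3p mature, whose locus starts mid-hairpin
        hp = tiny_ref.hairpins["mir-a"]
        locus = hp.mature_loci[1]
        read = hp.sequence[locus.start - 2 : locus.end - 1]
        alns = align_to_hairpins(_lib({read: 1}), tiny_ref, 2)
        fams, _ = build_families(alns, tiny_ref)
        member = fams["mir-a-3p"].members[0]
        assert (member.offset5, member.offset3) == (-2, -1)

    def test_loop_centered_read_is_hairpin_other(self, tiny_ref):
        hp = tiny_ref.hairpins["mir-a"]
        loop_start = len(H1_ARM5)
        read = hp.sequence[loop_start - 2 : loop_start + len(H1_LOOP) + 2]
        alns = align_to_hairpins(_lib({read: 1}), tiny_ref, 2)
        fams, other = build_families(alns, tiny_ref)
        assert not fams and len(other) == 1

    def test_family_mass_conservation_unique_mapping(self, tiny_ref):
        hp = tiny_ref.hairpins["mir-a"]
        lib = _lib(
            {
                H1_ARM5: 10,
                hp.sequence[1:23]: 5,
                hp.sequence[20:36]: 2,  # straddles the loop: hairpin-other
            }
        )
        alns = align_to_hairpins(lib, tiny_ref, 2)
        fams, other = build_families(alns, tiny_ref)
        fam_mass = sum(m.count for f in fams.values() for m in f.members)
        other_mass = sum(a.read.count for a in other)
        assert fam_mass + other_mass == lib.total_reads


class TestSelectDominant:
    def _fam(self, members):
        import mirnome.core as core

        mature = core.MatureMiRNA("m-5p", H1_ARM5, "mir-a", 0, len(H1_ARM5), "5p")
        return IsomiRFamily(mature, members)

    def test_single_member(self):
        m = FamilyMember("ACGT" * 5, 3, 0, 0, 0)
        assert select_dominant(self._fam([m])) is m

    def test_highest_count_wins(self):
        ms = [
            FamilyMember("AAAA" * 5, 10, 1, 0, 0),
            FamilyMember("CCCC" * 5, 7, 0, 0, 0),
            FamilyMember("GGGG" * 5, 7, 0, 1, 0),
        ]
        assert select_dominant(self._fam(ms)).count == 10

    def test_tie_prefers_canonical_offsets(self):
        canonical = FamilyMember(H1_ARM5, 5, 0, 0, 0)
        variant = FamilyMember("T" + H1_ARM5[:-1], 5, -1, 0, 0)
        assert select_dominant(self._fam([variant, canonical])) is canonical

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            select_dominant(self._fam([]))


class TestAbundantProfile:
    def test_superset_of_reference_and_dominance(self, tiny_ref):
        hp = tiny_ref.hairpins["mir-a"]
        shifted = hp.sequence[1:24]  # isomiR of the 5p mature, no canonical read
        lib = _lib({shifted: 50, H1_ARM3: 8, "A" + H1_ARM3[1:]: 3})
        alns = align_to_hairpins(lib, tiny_ref, 2)
        fams, _ = build_families(alns, tiny_ref)
        ab = abundant_profile(fams, lib.total_reads, "s")
        rp = reference_profile(lib, tiny_ref)
        assert set(rp.rows) <= set(ab.rows)
        for name in rp.rows:
            assert ab.rows[name].raw >= rp.rows[name].raw
        # the 5p row exists only in the abundant profile
        assert "mir-a-5p" in ab.rows and "mir-a-5p" not in rp.rows

    def test_unaligned_mirna_absent(self, tiny_ref):
        ab = abundant_profile({}, 100, "s")
        assert ab.rows == {}


def _sample(sid, dominants, counts, canonical):
    rows_ab = {}
    rows_ref = {}
    for name, c in counts.items():
        rows_ab[name] = ProfileRow(c, float(c))
        if dominants.get(name) == canonical[name]:
            rows_ref[name] = ProfileRow(c, float(c))
    return SampleIsomirProfile(
        sid,
        ExpressionProfile(sid, "reference", rows_ref, 1000),
        ExpressionProfile(sid, "abundant_isomir", rows_ab, 1000),
        dominants,
    )


class TestCompareProfiles:
    CANON = {"m1": "AAAA", "m2": "CCCC", "m3": "GGGG"}

    def test_unanimous_yes_and_no(self):
        s1 = _sample("a", {"m1": "AAAA", "m2": "CCCT"}, {"m1": 5, "m2": 9}, self.CANON)
        s2 = _sample("b", {"m1": "AAAA", "m2": "CCCT"}, {"m1": 7, "m2": 2}, self.CANON)
        records, tally = compare_profiles([s1, s2], self.CANON, "g")
        status = {r.name: r.status for r in records}
        assert status == {"m1": "YES", "m2": "NO", "m3": "low_expression"}
        assert (tally.n_yes, tally.n_no, tally.n_low, tally.n_nonuniform) == (1, 1, 1, 0)
        assert tally.not_considered == 1

    def test_disagreement_is_non_uniform(self):
        s1 = _sample("a", {"m1": "AAAA"}, {"m1": 5}, self.CANON)
        s2 = _sample("b", {"m1": "AAAT"}, {"m1": 5}, self.CANON)
        records, tally = compare_profiles([s1, s2], self.CANON, "g")
        assert {r.name: r.status for r in records}["m1"] == "non_uniform"
        assert tally.n_nonuniform == 1

    def test_detection_threshold_marks_low(self):
        s1 = _sample("a", {"m1": "AAAA"}, {"m1": 2}, self.CANON)
        s2 = _sample("b", {"m1": "AAAA"}, {"m1": 9}, self.CANON)
        _, tally = compare_profiles([s1, s2], self.CANON, "g", detection_threshold=3)
        assert tally.n_low == 3 and tally.n_yes == 0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_profiles([], self.CANON)


class TestIsomirCountDistribution:
    def test_counts_and_unknown_names(self, tiny_ref):
        hp = tiny_ref.hairpins["mir-a"]
        lib = _lib({H1_ARM5: 5, hp.sequence[1:23]: 2, hp.sequence[0:21]: 1})
        alns = align_to_hairpins(lib, tiny_ref, 2)
        fams, _ = build_families(alns, tiny_ref)
        frame, warnings = isomir_count_distribution(
            {"s": fams}, ["mir-a-5p", "nope-5p"]
        )
        assert frame.loc["mir-a-5p", "s"] == 3
        assert frame.loc["nope-5p", "s"] == 0
        assert warnings == ["unknown miRNA name 'nope-5p'"]
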