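"""Shared fixtures: a tiny hand-built reference and a small simulated world."""

import pytest

from mirnome.core import Hairpin, MatureMiRNA, ReferenceSet, RNAClassDB
from mirnome.simulate import SimulationSpec, generate_reference, generate_regions

# two hairpins, one mature per arm, interior-mismatched stems
H1_ARM5 = "TAGCTTATCAGACTGATGTTGA"
H1_LOOP = "TTTGCCTA"
H1_ARM3 = "CAACACCAGTCGATGGGCTGT"
H2_ARM5 = "TGAGGTAGTAGGTTGTATAGTT"
H2_LOOP = "AGGGTC"
H2_ARM3 = "CTATACAATCTACTGTCTTTC"


def _hairpin(hid: str, arm5: str, loop: str, arm3: str) -> Hairpin:
    seq = arm5 + loop + arm3
    return Hairpin(
        hid,
        seq,
        [
            MatureMiRNA(f"{hid}-5p", arm5, hid, 0, len(arm5), "5p"),
            MatureMiRNA(
                f"{hid}-3p", arm3, hid, len(seq) - len(arm3), len(seq), "3p"
            ),
        ],
    )


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceSet:
    hp1 = _hairpin("mir-a", H1_ARM5, H1_LOOP, H1_ARM3)
    hp2 = _hairpin("mir-b", H2_ARM5, H2_LOOP, H2_ARM3)
    return ReferenceSet(hairpins={"mir-a": hp1, "mir-b": hp2})


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(n_hairpins=12, total_reads=10_000, seed=7)


@pytest.fixture(scope="session")
def small_world(small_spec):
    ref = generate_reference(small_spec)
    regions = generate_regions(small_spec)
    return ref, regions
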