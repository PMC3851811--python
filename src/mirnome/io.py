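"""Readers and writers for the sequence, interval and tabular formats used.

Sequence formats go through Biopython; collapsed-FASTA count dialects
(``>id_x25`` and ``>id count=25``) are handled here.  BED is 3+3 columns with
the region type carried in the name field.  Expression tables are TSV with one
count and one TPM column per sample, rows ordered lexicographically by miRNA
name and TPM printed with 6 decimals.

Every writer's output re-read by its reader yields an equal in-memory object;
the round-trip tests enforce this.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    AmbiguousLocationError,
    GenomicRegion,
    GenomicRegionSet,
    Hairpin,
    MatureMiRNA,
    ParseError,
    ReadLibrary,
    ReferenceSet,
    SmallRNARead,
    normalize_sequence,
)

__all__ = [
    "read_fastq_or_fasta",
    "write_collapsed_fasta",
    "write_fasta",
    "read_mirbase_fastas",
    "locate_mature",
    "read_bed",
    "write_bed",
    "read_genome_fasta",
    "read_regions",
    "write_profile_tsv",
    "read_profile_tsv",
]

_COLLAPSED_X = re.compile(r"^(?P<id>.+)_x(?P<count>\d+)$")
_COLLAPSED_EQ = re.compile(r"count=(?P<count>\d+)")


def _validated(read_id: str, seq: str, count: int, where: str) -> tuple[str, str, int]:
    seq = normalize_sequence(seq)
    if not seq or set(seq) - set("ACGTN"):
        raise ParseError(f"{where}: invalid sequence for record {read_id!r}")
    return read_id, seq, count


def read_fastq_or_fasta(path: str | Path, format: str = "fasta") -> ReadLibrary:
    """Read a small-RNA file into a collapsed :class:`ReadLibrary`.

    ``format`` is one of ``fastq``, ``fasta`` or ``fasta_collapsed``.  In the
    collapsed dialect the header carries a count as ``>id_xN`` or
    ``>id count=N``.  Identical sequences are merged with counts summed; U is
    converted to T.  An empty file yields an empty library.
    """
    path = Path(path)
    sample_id = path.stem
    records: list[tuple[str, str, int]] = []
    if format == "fastq":
        try:
            with open(path) as handle:
                for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                    if len(qual) != len(seq):
                        raise ValueError("quality/sequence length mismatch")
                    records.append(
                        _validated(title.split()[0], seq, 1, f"{path} line {4 * i + 1}")
                    )
        except ValueError as err:
            n = len(records)
            raise ParseError(f"{path}: near line {4 * n + 1}: {err}") from err
    elif format in ("fasta", "fasta_collapsed"):
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            count = 1
            read_id = rec.id
            if format == "fasta_collapsed":
                m = _COLLAPSED_X.match(rec.id)
                if m:
                    read_id, count = m.group("id"), int(m.group("count"))
                else:
                    m = _COLLAPSED_EQ.search(rec.description)
                    if not m:
                        raise ParseError(
                            f"{path}: record {i + 1} ({rec.id!r}) carries no count "
                            "(_xN or count=N)"
                        )
                    count = int(m.group("count"))
            records.append(
                _validated(read_id, str(rec.seq), count, f"{path} record {i + 1}")
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    return ReadLibrary.collapse(sample_id, records)


def write_collapsed_fasta(lib: ReadLibrary, path: str | Path) -> None:
    """Write a library in the ``>id_xN`` collapsed-FASTA dialect."""
    with open(path, "w") as out:
        for read in lib.reads:
            out.write(f">{read.read_id}_x{read.count}\n{read.sequence}\n")


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as out:
        for name, seq in items:
            out.write(f">{name}\n{seq}\n")


def _name_stem(mature_name: str) -> str:
    """Hairpin name stem of a mature name (``hsa-miR-21-5p`` -> ``hsa-mir-21``)."""
    stem = re.sub(r"-(5p|3p)$", "", mature_name, flags=re.IGNORECASE)
    return stem.lower()


def locate_mature(
    name: str, sequence: str, hairpin: Hairpin
) -> MatureMiRNA | None:
    """Place a mature sequence on a hairpin by exact substring search.

    Returns None when the sequence does not occur; raises
    :class:`AmbiguousLocationError` when it occurs more than once.  The arm is
    taken from a ``-5p``/``-3p`` name suffix when present, otherwise assigned
    by position: a locus wholly within the first half of the hairpin is 5p,
    wholly within the second half 3p, else by midpoint.
    """
    hits = []
    i = hairpin.sequence.find(sequence)
    while i != -1:
        hits.append(i)
        i = hairpin.sequence.find(sequence, i + 1)
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousLocationError(
            f"mature {name!r} occurs at positions {hits} on hairpin "
            f"{hairpin.hairpin_id!r}"
        )
    start = hits[0]
    end = start + len(sequence)
    lower = name.lower()
    if lower.endswith("-5p"):
        arm = "5p"
    elif lower.endswith("-3p"):
        arm = "3p"
    else:
        half = len(hairpin.sequence) / 2
        if end <= half:
            arm = "5p"
        elif start >= half:
            arm = "3p"
        else:
            arm = "5p" if (start + end) / 2 <= half else "3p"
    return MatureMiRNA(name, sequence, hairpin.hairpin_id, start, end, arm)


def read_mirbase_fastas(
    mature_path: str | Path, hairpin_path: str | Path
) -> ReferenceSet:
    """Load mature and hairpin FASTA files (miRBase-style headers).

    Matures are located on hairpins whose name shares their stem
    (``hsa-miR-21-5p`` on ``hsa-mir-21``; duplicated loci like
    ``hsa-mir-16-1``/``-2`` are matched by a trailing ``-<digits>`` suffix).
    RNA alphabet is converted to DNA.  Matures that locate on no hairpin are
    retained in ``unlocated_matures``, never dropped silently.
    """
    hairpins: dict[str, Hairpin] = {}
    for rec in SeqIO.parse(str(hairpin_path), "fasta"):
        hairpins[rec.id] = Hairpin(rec.id, normalize_sequence(str(rec.seq)))
    by_lower = {}
    for hid in hairpins:
        by_lower.setdefault(hid.lower(), []).append(hid)

    unlocated: dict[str, str] = {}
    for rec in SeqIO.parse(str(mature_path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        stem = _name_stem(rec.id)
        candidates: list[str] = []
        for lower, hids in by_lower.items():
            if lower == stem or (
                lower.startswith(stem + "-") and lower[len(stem) + 1 :].isdigit()
            ):
                candidates.extend(hids)
        placed = False
        for hid in sorted(candidates):
            mature = locate_mature(rec.id, seq, hairpins[hid])
            if mature is not None:
                hairpins[hid].mature_loci.append(mature)
                placed = True
        if not placed:
            unlocated[rec.id] = seq
    for hp in hairpins.values():
        hp.mature_loci.sort(key=lambda m: m.start)
    return ReferenceSet(hairpins=hairpins, unlocated_matures=unlocated)


def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read 3+3-column BED; the name column holds the region type."""
    regions = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {line_no}: expected >= 4 BED columns")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "+"
            regions.append(GenomicRegion(chrom, int(start), int(end), name, strand))
    return regions


def write_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in regions:
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_type}\t0\t{r.strand}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: normalize_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_regions(bed_path: str | Path, genome_path: str | Path) -> GenomicRegionSet:
    return GenomicRegionSet(read_bed(bed_path), read_genome_fasta(genome_path))


def profiles_to_frame(profiles: Sequence) -> pd.DataFrame:
    """Tabulate one or more :class:`ExpressionProfile` objects.

    Columns are ``miRNA`` then ``<sample>_count``/``<sample>_tpm`` per sample;
    rows are the union of miRNA names in lexicographic order, absent entries 0.
    """
    names = sorted(set().union(*(p.rows.keys() for p in profiles))) if profiles else []
    data: dict[str, list] = {"miRNA": names}
    for p in profiles:
        data[f"{p.sample_id}_count"] = [
            p.rows[n].raw if n in p.rows else 0 for n in names
        ]
        data[f"{p.sample_id}_tpm"] = [
            p.rows[n].tpm if n in p.rows else 0.0 for n in names
        ]
    return pd.DataFrame(data)


def write_profile_tsv(profiles: Sequence, path: str | Path) -> None:
    """Write expression profiles as TSV (counts and TPM per sample).

    TPM is printed with fixed 6-decimal precision; row order is deterministic
    (lexicographic by miRNA name).  An empty profile list or empty profiles
    yield a header-only file.
    """
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Re-read a profile TSV exactly as written (counts int, TPM float)."""
    return pd.read_csv(path, sep="\t")
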