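"""Ungapped, end-to-end read matching with a bounded substitution count.

This is the short-read matching primitive the whole pipeline is built on: a
read "hits" a subject sequence if it aligns ungapped, over its entire length,
at some offset within the subject with at most ``max_mm`` substitutions.
``N`` never matches anything (it always counts as a mismatch), so a read
containing ``N`` can only hit with a mismatch budget left to absorb it.

Exact placements use ``str.find`` (C speed); mismatch-tolerant placements use
a vectorised Hamming scan over all windows of the subject.  An exhaustive
pure-Python sliding-window oracle in the test suite checks equivalence.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Hit", "placements", "best_hit", "all_db_placements"]

_N = ord("N")


class Hit(NamedTuple):
    """Best accepted hit of a read in a database."""

    name: str
    offset: int
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def placements(read: str, subject: str, max_mm: int) -> list[tuple[int, int]]:
    """All ``(offset, mismatches)`` placements of ``read`` within ``subject``.

    Offsets are sorted ascending; only placements with ``mismatches <= max_mm``
    are returned.
    """
    L, M = len(read), len(subject)
    if L == 0 or L > M:
        return []
    has_n = "N" in read or "N" in subject
    if max_mm == 0:
        if "N" in read:
            return []  # N never matches, so an exact placement is impossible
        out = []
        i = subject.find(read)
        while i != -1:
            out.append((i, 0))
            i = subject.find(read, i + 1)
        return out
    r = _encode(read)
    s = _encode(subject)
    windows = sliding_window_view(s, L)
    neq = windows != r
    if has_n:
        neq = neq | (windows == _N) | (r == _N)
    mm = neq.sum(axis=1)
    idx = np.nonzero(mm <= max_mm)[0]
    return [(int(i), int(mm[i])) for i in idx]


def best_hit(read: str, records: Mapping[str, str], max_mm: int) -> Hit | None:
    """Minimum-mismatch hit of ``read`` in ``records``; None when nothing hits.

    Ties are broken by database record name (lexicographic), then by offset.
    """
    best: Hit | None = None
    for name in sorted(records):
        subject = records[name]
        if len(read) > len(subject) or not read:
            continue
        # exact fast path: any 0-mm hit beats everything at later names
        if "N" not in read:
            j = subject.find(read)
            if j != -1:
                return Hit(name, j, 0)
        if max_mm > 0:
            for off, mm in placements(read, subject, max_mm):
                if (
                    best is None
                    or (mm, name, off) < (best.mismatches, best.name, best.offset)
                ):
                    best = Hit(name, off, mm)
    return best


def all_db_placements(
    read: str, records: Mapping[str, str], max_mm: int
) -> list[tuple[str, int, int]]:
    """Every placement ``(record name, offset, mismatches)`` across a database."""
    out: list[tuple[str, int, int]] = []
    for name in sorted(records):
        for off, mm in placements(read, records[name], max_mm):
            out.append((name, off, mm))
    return out
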