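"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own matching/folding code paths:
plain Python sliding-window scans and exhaustive recursion over nested
pairings, kept simple enough to be obviously correct.
"""

import functools


def hamming_placements(read: str, subject: str, max_mm: int):
    """Exhaustive sliding-window scan; N never matches."""
    out = []
    L = len(read)
    for off in range(len(subject) - L + 1):
        mm = 0
        for a, b in zip(read, subject[off : off + L]):
            if a != b or a == "N" or b == "N":
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append((off, mm))
    return out


def brute_best_hit(read: str, records: dict, max_mm: int):
    """Minimum-mismatch hit with (mismatches, name, offset) tie-breaking."""
    best = None
    for name in sorted(records):
        for off, mm in hamming_placements(read, records[name], max_mm):
            cand = (mm, name, off)
            if best is None or cand < best:
                best = cand
    return best


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive maximum over all nested pairings (recursion, no DP table)."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in _PAIRS:
                left = rec(i, k - 1) if k > i else 0
                best = max(best, left + 1 + rec(k + 1, j - 1))
        return best

    return rec(0, len(seq) - 1) if seq else 0
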