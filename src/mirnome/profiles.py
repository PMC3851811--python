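"""Reference miRNA expression profiles, TPM, summaries and sample clustering.

The reference profile counts, for each canonical (reference) mature miRNA,
the reads whose sequence is *exactly* that mature sequence, and normalises to
TPM (counts per million of the library's post-filter total):

    TPM = raw count / library total * 10^6

Sample similarity is summarised by average-linkage hierarchical clustering on
1 - Spearman correlation of log2(TPM + 1) vectors over the union of miRNA
names.  Both the metric and the transform are chosen for robustness to the
profiles' multi-order-of-magnitude dynamic range; they are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .config import TPM_SCALE
from .core import ReadLibrary, ReferenceSet

__all__ = [
    "ProfileRow",
    "ExpressionProfile",
    "ExpressionSummary",
    "SampleLinkage",
    "tpm",
    "reference_profile",
    "expression_summary",
    "cluster_samples",
]


class ProfileRow(NamedTuple):
    raw: int
    tpm: float


def tpm(raw: int, library_total: int) -> float:
    """Transcripts per million: ``raw / library_total * 10^6``."""
    if library_total < 1:
        raise ValueError("library_total must be >= 1")
    if raw < 0 or raw > library_total:
        raise ValueError("raw count must be within [0, library_total]")
    return raw / library_total * TPM_SCALE


@dataclass
class ExpressionProfile:
    """Per-miRNA raw counts and TPM for one sample.

    ``kind`` is ``"reference"`` (exact canonical-sequence counts) or
    ``"abundant_isomir"`` (dominant family-member counts).  Absent miRNAs are
    unlisted; every listed row has raw >= 1.
    """

    sample_id: str
    kind: str
    rows: dict[str, ProfileRow] = field(default_factory=dict)
    library_total: int = 0
    #: groups of mature names sharing an identical sequence (double counting report)
    duplicate_name_groups: list[list[str]] = field(default_factory=list)

    @property
    def n_expressed(self) -> int:
        return len(self.rows)

    def raw_counts(self) -> dict[str, int]:
        return {name: row.raw for name, row in self.rows.items()}


def reference_profile(lib: ReadLibrary, ref: ReferenceSet) -> ExpressionProfile:
    """Exact-match expression of every canonical mature miRNA in a library.

    A read contributes only if its sequence equals the mature sequence
    exactly.  When several mature names share one sequence (database
    duplicates) each name receives the full count and the duplicated name
    groups are reported on the profile.  Duplicate names with *different*
    sequences raise (names are keys).
    """
    mature_seqs = ref.mature_sequences()  # raises on conflicting duplicates
    counts = lib.counts()
    rows: dict[str, ProfileRow] = {}
    total = lib.total_reads
    by_seq: dict[str, list[str]] = {}
    for name, seq in mature_seqs.items():
        by_seq.setdefault(seq, []).append(name)
        raw = counts.get(seq, 0)
        if raw > 0:
            rows[name] = ProfileRow(raw, tpm(raw, total))
    dup_groups = [sorted(names) for names in by_seq.values() if len(names) > 1]
    return ExpressionProfile(
        lib.sample_id,
        "reference",
        dict(sorted(rows.items())),
        total,
        sorted(dup_groups),
    )


@dataclass
class ExpressionSummary:
    """Expression-level summary of one profile."""

    n_expressed: int
    n_singletons: int
    highly_expressed: list[str]
    #: floor(log10(raw)) -> number of miRNAs (order-of-magnitude histogram)
    log10_histogram: dict[int, int]


def expression_summary(
    profile: ExpressionProfile, high_threshold: int = 10_000
) -> ExpressionSummary:
    """Count expressed miRNAs, singletons and highly expressed entries.

    "Highly expressed" is a strict raw-count threshold (raw > high_threshold).
    The histogram bins raw counts by order of magnitude.
    """
    hist: dict[int, int] = {}
    singletons = 0
    high: list[str] = []
    for name, row in profile.rows.items():
        if row.raw == 1:
            singletons += 1
        if row.raw > high_threshold:
            high.append(name)
        bin_ = int(np.floor(np.log10(row.raw)))
        hist[bin_] = hist.get(bin_, 0) + 1
    return ExpressionSummary(
        profile.n_expressed, singletons, sorted(high), dict(sorted(hist.items()))
    )


@dataclass
class SampleLinkage:
    """Dendrogram over samples: labels plus a scipy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray

    def merge_label_sets(self) -> list[frozenset]:
        """The leaf-label set of each internal node, in merge order."""
        n = len(self.labels)
        clusters: dict[int, frozenset] = {
            i: frozenset([label]) for i, label in enumerate(self.labels)
        }
        out = []
        for step, (a, b, _h, _n) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return fmt(tree, tree.dist) + ";"


def cluster_samples(
    profiles: Sequence[ExpressionProfile],
    metric: str = "spearman",
    method: str = "average",
) -> SampleLinkage:
    """Agglomerate samples on 1 - rank correlation of log2(TPM+1) vectors.

    Requires >= 2 profiles; the feature space is the union of miRNA names
    (absent entries are 0).  A profile with zero variance over that space has
    an undefined correlation and raises, naming the sample.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    labels = [p.sample_id for p in profiles]
    names = sorted(set().union(*(p.rows.keys() for p in profiles)))
    X = np.zeros((len(profiles), len(names)))
    for i, p in enumerate(profiles):
        for j, name in enumerate(names):
            if name in p.rows:
                X[i, j] = p.rows[name].tpm
    X = np.log2(X + 1.0)
    for i, label in enumerate(labels):
        if np.allclose(X[i], X[i][0]):
            raise ValueError(f"sample {label!r}: constant profile, correlation undefined")
    if metric == "spearman":
        if len(profiles) == 2:
            r = float(spearmanr(X[0], X[1]).statistic)
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = spearmanr(X, axis=1).statistic
    elif metric == "pearson":
        rho = np.corrcoef(X)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return SampleLinkage(labels, Z)
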