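"""Pipeline-wide configuration constants.

The defaults encode the analysis' printed operating points: a 14 nt minimum
read length, up to 2 mismatches in class annotation and hairpin alignment, a
minimum frequency of 5 for novel-candidate reads, 70 nt precursor flanks, a
strict >10,000 count threshold for "highly expressed", and TPM scaling to
10^6 (fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import RNA_CLASSES
from .fold import FoldParams

__all__ = ["PipelineConfig", "TPM_SCALE"]

#: TPM is counts per million by definition; this constant is not tunable.
TPM_SCALE: float = 1e6


@dataclass(frozen=True)
class PipelineConfig:
    min_read_length: int = 14
    max_mismatches: int = 2
    novel_min_freq: int = 5
    flank_length: int = 70
    high_expression_threshold: int = 10_000
    rng_seed: int = 0
    #: elimination priority; reorderable, defaults to the canonical class listing
    class_order: tuple[str, ...] = RNA_CLASSES
    #: a miRNA counts as expressed in a sample if its dominant isomiR count >= this
    detection_threshold: int = 1
    #: an aligned read joins a family if it overlaps the mature locus by at
    #: least this fraction of min(read length, mature length)
    family_overlap_fraction: float = 0.5
    #: positional window (nt) for the novel-candidate "has an isomiR" flag
    isomir_window: int = 3
    #: require isomiR and counterpart evidence (not just stem placement)
    strict_filters: bool = False
    fold: FoldParams = field(default_factory=FoldParams)

    @property
    def tpm_scale(self) -> float:
        return TPM_SCALE

    def __post_init__(self) -> None:
        for name in (
            "min_read_length",
            "max_mismatches",
            "novel_min_freq",
            "flank_length",
            "high_expression_threshold",
            "detection_threshold",
            "isomir_window",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.class_order) - set(RNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_order: {sorted(unknown)}")
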