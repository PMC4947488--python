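"""Mitochondrial inheritance from relative parental coverage.

Saccharomyces hybrids inherit mitochondria uniparentally (after a brief
heteroplasmic phase one parental mtDNA fixes), so reads map almost
exclusively to one parent's mitochondrial contig. The call is a simple
fold-change test on mean depth; anything short of a decisive ratio is
reported as unresolved rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

DEFAULT_MIN_RATIO = 4.0

MitoOrigin = Literal["Scer", "Seub", "unresolved"]


@dataclass(frozen=True)
class MitoDepths:
    """Mean read depth on each parental mitochondrial contig."""

    mean_depth_scer: float
    mean_depth_seub: float
    min_ratio: float = DEFAULT_MIN_RATIO

    def __post_init__(self) -> None:
        if self.mean_depth_scer < 0 or self.mean_depth_seub < 0:
            raise ValueError("mitochondrial depths must be >= 0")
        if self.min_ratio <= 1:
            raise ValueError(f"min_ratio must be > 1, got {self.min_ratio}")


def mito_inheritance(d: MitoDepths) -> MitoOrigin:
    """Call the retained parent when one contig out-covers the other
    by at least ``min_ratio``-fold; scale-invariant and symmetric."""
    if d.mean_depth_scer >= d.min_ratio * d.mean_depth_seub and d.mean_depth_scer > 0:
        return "Scer"
    if d.mean_depth_seub >= d.min_ratio * d.mean_depth_scer and d.mean_depth_seub > 0:
        return "Seub"
    return "unresolved"
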