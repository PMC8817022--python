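"""The ±15 expression score from small-RNA 5'-end and coverage tracks.

A candidate locus earns +15 when it is expressed (more than ``min_reads``
reads), shows a distinct 5' end (at least half of its 5'-end counts
within ±2 nt of the modal 5' position), and is not part of a longer
transcript (mean coverage just upstream of the modal 5' end at most a
tenth of the mean locus coverage). Anything else earns −15. All three
thresholds are configurable; the tracks are the interface — read
alignment happens upstream of this package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import Track


@dataclass(frozen=True)
class ExpressionParams:
    min_reads: int = 100
    sharp5_window: int = 2       # ± nt around the modal 5' end
    sharp5_min_fraction: float = 0.5
    upstream_window: int = 20    # nt upstream of the modal 5' end
    max_upstream_ratio: float = 0.1
    locus_slop: int = 150        # reads are gathered this far around the locus

    def __post_init__(self) -> None:
        if min(self.min_reads, self.sharp5_window, self.upstream_window) < 0:
            raise ValueError("parameters must be non-negative")
        if not 0 < self.sharp5_min_fraction <= 1:
            raise ValueError("sharp5_min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionDiagnostics:
    reads: int
    sharp5_fraction: float
    upstream_ratio: float
    modal_end5: int | None       # 1-based genomic position
    expressed: bool
    distinct_end: bool
    not_runthrough: bool

    @property
    def score(self) -> int:
        return 15 if self.expressed and self.distinct_end and self.not_runthrough else -15


def expression_score(locus_start: int, locus_end: int, strand: str,
                     end5: Track, coverage: Track,
                     params: ExpressionParams = ExpressionParams(),
                     ) -> ExpressionDiagnostics:
    """Score one locus (0-based half-open genomic interval, stranded).

    For minus-strand loci the 5' end is the right edge and "upstream"
    runs toward higher coordinates.
    """
    n = len(end5)
    if len(coverage) != n:
        raise ValueError("end5 and coverage tracks differ in length")
    if not 0 <= locus_start < locus_end <= n:
        raise ValueError(f"locus [{locus_start}, {locus_end}) outside track bounds")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")

    slop = params.locus_slop
    win_start = max(0, locus_start - slop)
    win_end = min(n, locus_end + slop)
    counts5 = end5.counts[win_start:win_end]
    reads = int(counts5.sum())
    expressed = reads > params.min_reads

    if reads > 0:
        mode_local = int(np.argmax(counts5))
        modal0 = win_start + mode_local
        w = params.sharp5_window
        near = counts5[max(0, mode_local - w): mode_local + w + 1].sum()
        sharp5_fraction = float(near / reads)
    else:
        modal0 = None
        sharp5_fraction = 0.0
    distinct = sharp5_fraction >= params.sharp5_min_fraction and reads > 0

    locus_cov = float(coverage.counts[locus_start:locus_end].mean())
    if modal0 is not None:
        if strand == "+":
            ua, ub = max(0, modal0 - params.upstream_window), modal0
        else:
            ua, ub = modal0 + 1, min(n, modal0 + 1 + params.upstream_window)
        upstream_cov = float(coverage.counts[ua:ub].mean()) if ub > ua else 0.0
    else:
        upstream_cov = 0.0
    upstream_ratio = upstream_cov / locus_cov if locus_cov > 0 else 0.0
    not_runthrough = upstream_ratio <= params.max_upstream_ratio

    return ExpressionDiagnostics(
        reads=reads, sharp5_fraction=sharp5_fraction,
        upstream_ratio=upstream_ratio,
        modal_end5=None if modal0 is None else modal0 + 1,
        expressed=expressed, distinct_end=distinct,
        not_runthrough=not_runthrough)
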