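"""Per-position count tracks (read 5'/3' ends, coverage).

Tracks are the unit of exchange between the simulator, the expression
scorer and the RiboMeth-seq scorer: one non-negative integer count per
1-based reference position, serialised as 3-column TSV
(reference, position, count). Positions with zero count may be omitted
on disk; in memory the track is dense.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Track:
    """Dense per-position counts over one reference sequence.

    ``counts[i]`` is the count at 1-based position ``i + 1``.
    """

    reference: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("track counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("track counts must be non-negative")

    def __len__(self) -> int:
        return int(self.counts.size)

    def __getitem__(self, position: int) -> int:
        """Count at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return int(self.counts[position - 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def padded(self, length: int) -> "Track":
        """Zero-extend to ``length`` (sparse files drop trailing zeros)."""
        if length < len(self):
            raise ValueError("cannot pad to a shorter length")
        counts = np.zeros(length, dtype=np.int64)
        counts[: len(self)] = self.counts
        return Track(self.reference, counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reference": self.reference,
            "position": np.arange(1, len(self) + 1),
            "count": self.counts,
        })


def write_track(track: Track, path: str | Path, sparse: bool = False) -> None:
    df = track.to_frame()
    if sparse:
        df = df[df["count"] > 0]
    df.to_csv(path, sep="\t", index=False)


def read_track(path: str | Path, length: int | None = None) -> Track:
    """Read a 3-column TSV track; missing positions are zero-filled.

    ``length`` sets the reference length; defaults to the largest
    position present in the file.
    """
    df = pd.read_csv(path, sep="\t")
    expected = {"reference", "position", "count"}
    if not expected.issubset(df.columns):
        raise ValueError(f"track file {path} lacks columns {sorted(expected)}")
    refs = df["reference"].unique()
    if len(refs) != 1:
        raise ValueError(f"track file {path} must hold exactly one reference, got {list(refs)}")
    n = int(df["position"].max()) if length is None else int(length)
    counts = np.zeros(n, dtype=np.int64)
    pos = df["position"].to_numpy(dtype=np.int64)
    if (pos < 1).any() or (pos > n).any():
        raise ValueError(f"track file {path} has positions outside 1..{n}")
    counts[pos - 1] = df["count"].to_numpy(dtype=np.int64)
    return Track(reference=str(refs[0]), counts=counts)
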