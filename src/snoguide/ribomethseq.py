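"""Score C computation and 2'-O-methylation site calling from end counts.

A 2'-O-methyl group on nucleotide p protects the linkage 3' of p from
alkaline cleavage, so cleavage evidence for linkage i (between nt i and
i+1) is the 5'-end count at nt i+1 plus the 3'-end count at nt i. The
RMS score ("score C", the estimated fraction methylated) compares a
linkage's combined count with a distance-weighted average of its k
flanking linkages on each side:

    score_c(i) = clip(1 - n_i / ((l_i + r_i) / 2), 0, 1)

with l_i, r_i the weighted means of n over d = 1..k linkages to the
left/right, weights w_d = (k + 1 - d) / k. Positions whose mean score
across replicates exceeds 0.75 are called methylated; calls below 0.9
are labelled fractional.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track


def _nanmean(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=axis)


def mean_profile(profiles: list["RmsProfile"]) -> np.ndarray:
    """Mean score per position over replicates (NaN where all undefined)."""
    return _nanmean(np.vstack([p.scores for p in profiles]), axis=0)


@dataclass(frozen=True)
class ScoreCParams:
    k: int = 6                       # flanking linkages per side
    call_threshold: float = 0.75
    full_threshold: float = 0.9      # mean >= this -> "full", else "fractional"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.call_threshold < 1:
            raise ValueError("call_threshold must be in (0, 1)")

    @property
    def weights(self) -> np.ndarray:
        """w_d = (k + 1 - d) / k for d = 1..k — strictly decreasing, positive."""
        d = np.arange(1, self.k + 1)
        return (self.k + 1 - d) / self.k


@dataclass
class RmsProfile:
    """Per-linkage combined counts and per-position scores, one replicate."""

    rrna_name: str
    counts: np.ndarray = field(repr=False)   # counts[i-1] = n_i, i = 1..L-1
    scores: np.ndarray = field(repr=False)   # scores[p-1] = score_c at nt p, NaN if undefined
    replicate: str = "rep1"

    @property
    def length(self) -> int:
        return self.counts.size + 1

    def score_at(self, position: int) -> float:
        return float(self.scores[position - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reference": self.rrna_name,
            "position": np.arange(1, self.length + 1),
            "score_c": self.scores,
            "replicate": self.replicate,
        })


@dataclass(frozen=True)
class MethylationCall:
    rrna_name: str
    position: int
    nucleotide: str
    mean_score: float
    sd: float
    label: str          # "full" or "fractional"


def combine_end_counts(end5: Track, end3: Track,
                       mask3: set[int] = frozenset()) -> np.ndarray:
    """Per-linkage cleavage evidence n_i = end5[i+1] + end3[i], i = 1..L-1.

    At masked positions the 3'-end evidence is excluded (it can carry a
    ligation artefact from heterogeneous adaptor oligos) and the 5'-end
    count doubled to stay on the same scale: n_i = 2 * end5[i+1].
    """
    if end5.reference != end3.reference:
        raise ValueError("end tracks belong to different references")
    if len(end5) != len(end3):
        raise ValueError("end tracks differ in length")
    length = len(end5)
    n = end5.counts[1:] + end3.counts[:-1]
    for pos in mask3:
        if not 1 <= pos <= length - 1:
            raise ValueError(f"masked position {pos} outside linkages 1..{length - 1}")
        n[pos - 1] = 2 * end5.counts[pos]      # end5 at nt pos+1
    return n.astype(np.int64)


def score_c(n: np.ndarray, position: int,
            params: ScoreCParams = ScoreCParams()) -> float:
    """Score C at one position (1-based nt); NaN at boundaries/zero denominators."""
    return float(score_c_all(n, params)[position - 1])


def score_c_all(n: np.ndarray, params: ScoreCParams = ScoreCParams()) -> np.ndarray:
    """Vectorised score C for every nt position 1..L (linkage count L-1).

    Undefined (NaN) for positions i <= k or i > L - 1 - k and where the
    flanking average is zero.
    """
    n = np.asarray(n, dtype=float)
    linkages = n.size                 # L - 1
    k = params.k
    w = params.weights
    wsum = w.sum()
    scores = np.full(linkages + 1, np.nan)
    if linkages < 2 * k + 1:
        return scores
    core = np.arange(k, linkages - k)             # 0-based linkage indices
    left = np.zeros(core.size)
    right = np.zeros(core.size)
    for d in range(1, k + 1):
        left += w[d - 1] * n[core - d]
        right += w[d - 1] * n[core + d]
    left /= wsum
    right /= wsum
    denom = (left + right) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        val = 1.0 - n[core] / denom
    val = np.clip(val, 0.0, 1.0)
    val[denom == 0] = np.nan
    scores[core] = val                # linkage index i-1 <-> position i
    return scores


def profile_from_tracks(end5: Track, end3: Track, mask3: set[int] = frozenset(),
                        params: ScoreCParams = ScoreCParams(),
                        replicate: str = "rep1") -> RmsProfile:
    counts = combine_end_counts(end5, end3, mask3)
    return RmsProfile(rrna_name=end5.reference, counts=counts,
                      scores=score_c_all(counts, params), replicate=replicate)


def call_sites(profiles: list[RmsProfile], rrna_sequence: str | None = None,
               params: ScoreCParams = ScoreCParams()) -> list[MethylationCall]:
    """Mean replicate score per position; call where mean > threshold."""
    if not profiles:
        raise ValueError("need at least one replicate profile")
    names = {p.rrna_name for p in profiles}
    lengths = {p.length for p in profiles}
    if len(names) != 1 or len(lengths) != 1:
        raise ValueError("replicates must share one reference")
    stack = np.vstack([p.scores for p in profiles])
    mean = _nanmean(stack, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(profiles) > 1 \
            else np.zeros(stack.shape[1])
    calls = []
    for idx in np.flatnonzero(np.nan_to_num(mean, nan=-1.0) > params.call_threshold):
        position = int(idx) + 1
        nt = rrna_sequence[idx] if rrna_sequence else "N"
        label = "full" if mean[idx] >= params.full_threshold else "fractional"
        calls.append(MethylationCall(
            rrna_name=profiles[0].rrna_name, position=position, nucleotide=nt,
            mean_score=float(mean[idx]), sd=float(np.nan_to_num(sd[idx])),
            label=label))
    return calls


def calls_to_frame(calls: list[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "reference": c.rrna_name, "position": c.position,
        "nucleotide": c.nucleotide, "mean_score": c.mean_score,
        "sd": c.sd, "label": c.label,
    } for c in calls], columns=["reference", "position", "nucleotide",
                                "mean_score", "sd", "label"])


def compare_profiles(profiles_a: list[RmsProfile], profiles_b: list[RmsProfile],
                     delta_min: float = 0.1,
                     params: ScoreCParams = ScoreCParams()) -> pd.DataFrame:
    """Per-site score difference between two conditions.

    Rows cover the union of positions called in either condition;
    ``changed`` flags |meanB − meanA| > delta_min where both means are
    defined.
    """
    calls_a = call_sites(profiles_a, params=params)
    calls_b = call_sites(profiles_b, params=params)
    mean_a = mean_profile(profiles_a)
    mean_b = mean_profile(profiles_b)
    union = sorted({c.position for c in calls_a} | {c.position for c in calls_b})
    rows = []
    for pos in union:
        a, b = float(mean_a[pos - 1]), float(mean_b[pos - 1])
        delta = b - a
        changed = (not np.isnan(a)) and (not np.isnan(b)) and abs(delta) > delta_min
        rows.append({"position": pos, "mean_a": a, "mean_b": b,
                     "delta": delta, "changed": changed})
    return pd.DataFrame(rows, columns=["position", "mean_a", "mean_b",
                                       "delta", "changed"])
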