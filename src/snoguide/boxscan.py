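"""Genome-wide box C/D snoRNA candidate scan and classifier scoring.

Boxes are modelled as log-odds position weight matrices (bits) for the
box C consensus RUGAUGA and the box D consensus CUGA. A candidate is a
(box C, box D) pair on one strand with both box scores positive, a
combined score above the gate, and a C–D distance of 50–100 nt. The
final classifier adds a terminal-stem score, a distance score and the
±15 expression score; candidates reaching 29 are called bona fide.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import encode, is_gu, is_wc, revcomp_dna, to_dna
from .synthetic_data import SyntheticGenome

BOX_C_CONSENSUS = "RUGAUGA"
BOX_D_CONSENSUS = "CUGA"
_ALPHABET = "ACGT"  # column order; U is scored as T


@dataclass(frozen=True)
class BoxMotifModel:
    """PWMs for boxes C and D plus the background base composition."""

    pwm_box_c: np.ndarray  # 7 x 4 probabilities, columns ACGT(U)
    pwm_box_d: np.ndarray  # 4 x 4
    background: np.ndarray  # 4

    def __post_init__(self) -> None:
        for m in (self.pwm_box_c, self.pwm_box_d):
            if not np.allclose(m.sum(axis=1), 1.0) or (m <= 0).any():
                raise ValueError("PWM rows must be positive and sum to 1")
        if not np.isclose(self.background.sum(), 1.0) or (self.background <= 0).any():
            raise ValueError("background must be positive and sum to 1")

    @property
    def logodds_box_c(self) -> np.ndarray:
        return np.log2(self.pwm_box_c / self.background)

    @property
    def logodds_box_d(self) -> np.ndarray:
        return np.log2(self.pwm_box_d / self.background)


@dataclass(frozen=True)
class ScanParams:
    min_cd_distance: int = 50
    max_cd_distance: int = 100
    min_box_score: float = 9.0      # combined C+D gate, bits
    classifier_threshold: float = 29.0
    expression_bonus: int = 15
    expression_penalty: int = -15

    def __post_init__(self) -> None:
        if self.min_cd_distance >= self.max_cd_distance:
            raise ValueError("min_cd_distance must be < max_cd_distance")


@dataclass
class SnoCandidate:
    """One (box C, box D) candidate on one strand.

    ``box_c_start``/``box_d_start`` are 0-based offsets on the scanned
    strand (the reverse complement for strand "-"); ``start``/``end``
    are the candidate span (box C through box D) in plus-strand BED
    coordinates.
    """

    id: str
    strand: str
    box_c_start: int
    box_d_start: int
    box_c_score: float
    box_d_score: float
    start: int
    end: int
    ts_score: int = 0
    distance_score: int = 0
    expression_score: int | None = None
    kturn_ok: bool = False
    sequence: str = field(default="", repr=False)  # scanned-strand candidate span

    @property
    def cd_distance(self) -> int:
        """First nt of box C to first nt of box D."""
        return self.box_d_start - self.box_c_start

    @property
    def combined_box_score(self) -> float:
        return self.box_c_score + self.box_d_score


def build_box_model(background: np.ndarray | None = None,
                    consensus_weight: float = 0.91) -> BoxMotifModel:
    """PWMs giving each consensus base ``consensus_weight`` probability.

    The degenerate R of RUGAUGA splits the consensus weight equally over
    A and G; non-consensus bases share the remaining mass uniformly.
    """
    if not 0.5 < consensus_weight < 1.0:
        raise ValueError("consensus_weight must be in (0.5, 1)")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)

    def pwm_for(consensus: str) -> np.ndarray:
        rows = []
        for sym in consensus:
            row = np.empty(4)
            if sym == "R":
                row[:] = (1.0 - consensus_weight) / 2.0
                row[_ALPHABET.index("A")] = consensus_weight / 2.0
                row[_ALPHABET.index("G")] = consensus_weight / 2.0
            else:
                row[:] = (1.0 - consensus_weight) / 3.0
                row[_ALPHABET.index(to_dna(sym))] = consensus_weight
            rows.append(row)
        return np.array(rows)

    return BoxMotifModel(pwm_box_c=pwm_for(BOX_C_CONSENSUS),
                         pwm_box_d=pwm_for(BOX_D_CONSENSUS),
                         background=background)


def pwm_score(logodds: np.ndarray, kmer: str) -> float:
    idx = encode(to_dna(kmer), _ALPHABET)
    if idx.size != logodds.shape[0]:
        raise ValueError("k-mer length does not match PWM")
    return float(logodds[np.arange(idx.size), idx].sum())


def scan_pwm(sequence: str, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score of the PWM at every start position of ``sequence``."""
    arr = encode(to_dna(sequence), _ALPHABET)
    k = logodds.shape[0]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for off in range(k):
        scores += logodds[off, arr[off:off + n]]
    return scores


def terminal_stem_score(sequence: str, box_c_start: int, box_d_start: int,
                        flank: int = 10) -> int:
    """Longest ungapped complementary run between the box flanks, minus 3.

    Pairs the ``flank`` nt 5' of box C against the reverse of the
    ``flank`` nt 3' of box D (WC and G·U count); runs shorter than 2
    score 0, so stems of >= 4 bp score positive.
    """
    up = sequence[max(0, box_c_start - flank): box_c_start]
    down_start = box_d_start + len(BOX_D_CONSENSUS)
    down = sequence[down_start: down_start + flank][::-1]
    best = 0
    for i in range(len(up)):
        for j in range(len(down)):
            run = 0
            while (i + run < len(up) and j + run < len(down)
                   and (is_wc(up[i + run], down[j + run])
                        or is_gu(up[i + run], down[j + run]))):
                run += 1
            best = max(best, run)
    return max(0, best - 3) if best >= 2 else 0


def kturn_check(box_c_seq: str, box_d_seq: str) -> bool:
    """GA dinucleotides at consensus positions 3–4 of both boxes.

    These form the trans Hoogsteen/sugar-edge A•G pairs of the k-turn;
    the AUGA box D variant retains them.
    """
    box_c = to_dna(box_c_seq.upper())
    box_d = to_dna(box_d_seq.upper())
    return len(box_c) >= 4 and len(box_d) >= 4 \
        and box_c[2:4] == "GA" and box_d[2:4] == "GA"


def scan_candidates(genome: SyntheticGenome | str, model: BoxMotifModel,
                    params: ScanParams = ScanParams()) -> list[SnoCandidate]:
    """Exhaustive PWM scan of both strands for box C/D candidates.

    Emits every (box C, box D) pair with positive individual scores,
    combined score above the gate and C–D distance inside the window,
    after resolving overlaps: each box C keeps its best box D partner
    (higher combined score, then 3'-most box D) and each box D its best
    box C (higher combined score, then 5'-most box C). Candidates are
    sorted by plus-strand coordinate.
    """
    seq = genome.sequence if isinstance(genome, SyntheticGenome) else str(genome)
    seq = to_dna(seq.upper())
    if not seq:
        raise ValueError("genome is empty")
    length = len(seq)
    out: list[SnoCandidate] = []
    for strand in ("+", "-"):
        scanned = seq if strand == "+" else revcomp_dna(seq)
        c_scores = scan_pwm(scanned, model.logodds_box_c)
        d_scores = scan_pwm(scanned, model.logodds_box_d)
        c_hits = np.flatnonzero(c_scores > 0)
        d_hits = np.flatnonzero(d_scores > 0)
        pairs_found: list[tuple[int, int, float]] = []
        for c in c_hits:
            lo = np.searchsorted(d_hits, c + params.min_cd_distance, side="left")
            hi = np.searchsorted(d_hits, c + params.max_cd_distance, side="right")
            for d in d_hits[lo:hi]:
                combined = c_scores[c] + d_scores[d]
                if combined > params.min_box_score:
                    pairs_found.append((int(c), int(d), float(combined)))
        # overlap resolution: best partner per box C, then per box D
        best_d: dict[int, tuple[int, int, float]] = {}
        for c, d, s in pairs_found:
            cur = best_d.get(c)
            if cur is None or (s, d) > (cur[2], cur[1]):
                best_d[c] = (c, d, s)
        best_c: dict[int, tuple[int, int, float]] = {}
        for c, d, s in best_d.values():
            cur = best_c.get(d)
            if cur is None or (s, -c) > (cur[2], -cur[0]):
                best_c[d] = (c, d, s)
        for c, d, _ in best_c.values():
            d_end = d + len(BOX_D_CONSENSUS)
            if strand == "+":
                start, end = c, d_end
            else:
                start, end = length - d_end, length - c
            cand = SnoCandidate(
                id="", strand=strand, box_c_start=c, box_d_start=d,
                box_c_score=float(c_scores[c]), box_d_score=float(d_scores[d]),
                start=start, end=end,
                sequence=scanned[c:d_end],
            )
            cand.ts_score = terminal_stem_score(scanned, c, d)
            cand.distance_score = 0
            cand.kturn_ok = kturn_check(scanned[c:c + 7], scanned[d:d_end])
            out.append(cand)
    out.sort(key=lambda cd: (cd.start, cd.end, cd.strand))
    for i, cand in enumerate(out, start=1):
        cand.id = f"cand{i}"
    return out


def total_classifier_score(candidate: SnoCandidate,
                           expression_score: int | None = None,
                           params: ScanParams = ScanParams(),
                           ) -> tuple[float, bool]:
    """Combined classifier score and the bona fide call (>= threshold)."""
    expr = candidate.expression_score if expression_score is None else expression_score
    if expr not in (params.expression_bonus, params.expression_penalty):
        raise ValueError("expression score must be set to +15 or -15 before scoring")
    score = (candidate.box_c_score + candidate.box_d_score
             + candidate.ts_score + candidate.distance_score + expr)
    return score, score >= params.classifier_threshold
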