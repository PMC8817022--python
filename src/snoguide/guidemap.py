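"""Assignment of box C/D snoRNA guides to methylated rRNA positions.

The methylated nucleotide must sit opposite the 5th nucleotide upstream
of a box D or D' (the +5 rule; +6 is tried only as a flagged fallback
when no +5 duplex explains a site). The antisense element is extended
around that anchor as an ungapped antiparallel duplex inside a ±10 nt
rRNA window: Watson-Crick and G·U both pair, at most one internal
mismatch is tolerated, terminal mismatches are trimmed, and duplexes
shorter than 7 bp are discarded. Duplex stability is summarised with a
nearest-neighbor stacking model. snoRNAs that explain at least one site
are labelled CDn, the remainder ORn (orphans).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxscan import BoxMotifModel, build_box_model, pwm_score
from .ribomethseq import MethylationCall
from .seqs import is_gu, pairs, transcribe


@dataclass(frozen=True)
class GuideParams:
    target_flank: int = 10     # nt each side of the methylated position
    min_duplex_len: int = 7
    max_mismatch: int = 1
    register: int = 5          # preferred anchor register
    fallback_register: int = 6

    def __post_init__(self) -> None:
        if self.target_flank < self.min_duplex_len - 1:
            raise ValueError("target_flank too small for min_duplex_len")


@dataclass(frozen=True)
class BoxPositions:
    """0-based start offsets of the boxes found in one snoRNA."""

    box_c: int
    box_d: int
    box_dprime: int | None = None
    box_cprime: int | None = None


@dataclass(frozen=True)
class GuideAssignment:
    snorna_id: str
    box_used: str              # "D" or "Dprime"
    register: int              # 5, or 6 for the flagged fallback
    rrna_name: str
    position: int              # 1-based methylated nt
    duplex_len: int
    n_mismatch: int
    n_gu: int
    mfe: float                 # kcal/mol under the stacking model
    sno_interval: tuple[int, int]   # 0-based half-open on the snoRNA
    rrna_interval: tuple[int, int]  # 1-based inclusive on the rRNA


# ---------------------------------------------------------------------------
# nearest-neighbor stacking model

# Watson-Crick/Watson-Crick RNA stack free energies (dG37, kcal/mol),
# keyed by the two vertical pairs read along the top strand 5'->3'
# (pair string = top base + bottom base).
_WC_STACKS = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24, ("UA", "GC"): -2.11, ("UA", "CG"): -2.35,
    ("CG", "CG"): -3.26, ("CG", "GC"): -2.36, ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}
_GU_TO_WC = {"GU": "GC", "UG": "CG"}


@dataclass(frozen=True)
class StackingModel:
    """Stacking energies with a uniform destabilisation per G·U wobble.

    A stack involving G·U takes the energy of the stack with the wobble
    replaced by G-C, shifted up by ``gu_penalty`` per wobble pair, which
    keeps every G·U-containing duplex weaker than its all-WC version of
    the same length.
    """

    initiation: float = 4.1
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.8
    wc_stacks: dict = field(default_factory=lambda: dict(_WC_STACKS))

    def stack_energy(self, pair1: str, pair2: str) -> float:
        penalty = self.gu_penalty * sum(p in _GU_TO_WC for p in (pair1, pair2))
        p1 = _GU_TO_WC.get(pair1, pair1)
        p2 = _GU_TO_WC.get(pair2, pair2)
        return self.wc_stacks[(p1, p2)] + penalty

    def duplex_energy(self, top: str, bottom: str, paired: list[bool]) -> float:
        """Energy of an ungapped duplex.

        ``top`` is the rRNA segment 5'->3'; ``bottom`` holds the aligned
        snoRNA bases (the snoRNA strand runs antiparallel); ``paired``
        marks pair columns, the rest are internal mismatches.
        """
        if len(top) != len(bottom) or len(top) != len(paired):
            raise ValueError("duplex strands must align")
        energy = self.initiation
        for i in range(len(top)):
            if not paired[i]:
                energy += self.mismatch_penalty
                continue
            if i + 1 < len(top) and paired[i + 1]:
                energy += self.stack_energy(top[i] + bottom[i],
                                            top[i + 1] + bottom[i + 1])
        return energy


# ---------------------------------------------------------------------------
# box location within a snoRNA


def _best_hit(seq: str, logodds: np.ndarray, starts: list[int],
              prefer_rightmost: bool) -> tuple[int, float] | None:
    best: tuple[int, float] | None = None
    for s in starts:
        kmer = seq[s:s + logodds.shape[0]]
        score = pwm_score(logodds, kmer)
        if best is None or score > best[1] + 1e-9 or (
                abs(score - best[1]) <= 1e-9 and prefer_rightmost):
            best = (s, score)
    return best


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def locate_boxes(snorna: str, model: BoxMotifModel | None = None) -> BoxPositions:
    """Find boxes C, D and (if present) D'/C' in a snoRNA sequence.

    Box C is the best RUGAUGA PWM hit in the 5' third (leftmost on
    ties), box D the best exact CUGA/AUGA occurrence in the 3' third
    (rightmost on ties), box D' the best 4-mer within one deviation of
    CUGA lying strictly between them with at least 12 nt to each.
    """
    seq = transcribe(snorna.upper())
    if len(seq) < 50:
        raise ValueError("snoRNA sequence must be >= 50 nt")
    if model is None:
        model = build_box_model()
    third = len(seq) // 3

    c_hit = _best_hit(seq, model.logodds_box_c,
                      list(range(0, max(1, third))), prefer_rightmost=False)
    if c_hit is None or c_hit[1] <= 0:
        raise ValueError("no box C found in the 5' third")
    c_start = c_hit[0]

    d_starts = [s for s in range(max(0, len(seq) - third), len(seq) - 3)
                if seq[s:s + 4] in ("CUGA", "AUGA")]
    d_hit = _best_hit(seq, model.logodds_box_d, d_starts, prefer_rightmost=True)
    if d_hit is None:
        raise ValueError("no box D (CUGA/AUGA) found in the 3' third")
    d_start = d_hit[0]

    dp_starts = [s for s in range(c_start + 7 + 12, d_start - 12 - 3)
                 if _hamming(seq[s:s + 4], "CUGA") <= 1]
    dp_hit = _best_hit(seq, model.logodds_box_d, dp_starts, prefer_rightmost=True)
    dprime = dp_hit[0] if dp_hit else None

    cprime = None
    if dprime is not None:
        cp_starts = [s for s in range(dprime + 4 + 2, d_start - 7)
                     if _hamming(seq[s:s + 7], "AUGAUGA") <= 2
                     or _hamming(seq[s:s + 7], "GUGAUGA") <= 2]
        cp_hit = _best_hit(seq, model.logodds_box_c, cp_starts, prefer_rightmost=False)
        cprime = cp_hit[0] if cp_hit else None
    return BoxPositions(box_c=c_start, box_d=d_start,
                        box_dprime=dprime, box_cprime=cprime)


# ---------------------------------------------------------------------------
# duplex search


def best_duplex(snorna: str, rrna: str, position: int, box_start: int,
                register: int = 5, params: GuideParams = GuideParams(),
                model: StackingModel = StackingModel(),
                snorna_id: str = "sno", rrna_name: str = "rRNA",
                box_used: str = "D") -> GuideAssignment | None:
    """Maximal anchored ungapped duplex, or None if the filters fail.

    The rRNA nt at ``position`` is anchored opposite the snoRNA nt
    ``register`` positions upstream of the box at ``box_start``
    (antiparallel: rRNA position+j pairs snoRNA box_start-register-j).
    The longest window around the anchor with paired endpoints, a paired
    anchor and at most ``max_mismatch`` internal mismatches is returned
    when it reaches ``min_duplex_len``; ties prefer lower stacking
    energy, then the 5'-most rRNA window.
    """
    sno = transcribe(snorna.upper())
    rna = transcribe(rrna.upper())
    a0 = box_start - register          # 0-based anchor index on the snoRNA
    flank = params.target_flank
    # bounds: rRNA window ±flank, snoRNA inside [0, box_start-1] (the
    # extension never crosses the guided box)
    j_lo = max(-flank, -(register - 1), 1 - position, a0 - (len(sno) - 1))
    j_hi = min(flank, a0, len(rna) - position)
    if a0 < 0 or not j_lo <= 0 <= j_hi:
        return None
    js = np.arange(j_lo, j_hi + 1)
    status = np.array([pairs(rna[position + j - 1], sno[a0 - j]) for j in js])
    anchor_idx = -j_lo                 # index of j = 0
    if not status[anchor_idx]:
        return None

    best: tuple | None = None
    for li in range(anchor_idx + 1):
        if not status[li]:
            continue
        for ri in range(anchor_idx, len(js)):
            if not status[ri]:
                continue
            mism = int((~status[li:ri + 1]).sum())
            if mism > params.max_mismatch:
                continue
            length = ri - li + 1
            if length < params.min_duplex_len:
                continue
            jl, jr = int(js[li]), int(js[ri])
            top = rna[position + jl - 1: position + jr]
            bottom = "".join(sno[a0 - j] for j in range(jl, jr + 1))
            mfe = model.duplex_energy(top, bottom, list(status[li:ri + 1]))
            key = (-length, mfe, jl)
            if best is None or key < best[0]:
                n_gu = sum(is_gu(t, b) for t, b, ok in
                           zip(top, bottom, status[li:ri + 1]) if ok)
                best = (key, GuideAssignment(
                    snorna_id=snorna_id, box_used=box_used, register=register,
                    rrna_name=rrna_name, position=position, duplex_len=length,
                    n_mismatch=mism, n_gu=int(n_gu), mfe=float(mfe),
                    sno_interval=(a0 - jr, a0 - jl + 1),
                    rrna_interval=(position + jl, position + jr)))
    return best[1] if best else None


def _site_best(assignment_d: GuideAssignment | None,
               assignment_dp: GuideAssignment | None) -> GuideAssignment | None:
    """Longest duplex, ties by lower MFE, then box D over D'."""
    cands = [a for a in (assignment_d, assignment_dp) if a is not None]
    if not cands:
        return None
    return min(cands, key=lambda a: (-a.duplex_len, a.mfe, a.box_used != "D"))


def assign_guides(snornas: list[tuple[str, str]],
                  calls: list[MethylationCall],
                  rrnas: dict[str, str],
                  params: GuideParams = GuideParams(),
                  model: StackingModel = StackingModel(),
                  box_model: BoxMotifModel | None = None,
                  ) -> tuple[list[GuideAssignment], dict[str, str], list[MethylationCall]]:
    """Map every snoRNA against every called site; label CD/OR.

    ``snornas`` is (id, sequence) in genomic order. Returns the accepted
    assignments, the id -> CDn/ORn label map, and the unguided calls.
    The +6 register is attempted for a site only when no snoRNA offers a
    +5 duplex there, and such assignments carry register=6.
    """
    if not snornas or not rrnas:
        raise ValueError("need snoRNAs and rRNAs")
    boxes: dict[str, BoxPositions | None] = {}
    for sid, seq in snornas:
        try:
            boxes[sid] = locate_boxes(seq, box_model)
        except ValueError:
            boxes[sid] = None

    assignments: list[GuideAssignment] = []
    unguided: list[MethylationCall] = []
    for call in calls:
        rna = rrnas[call.rrna_name]
        site_hits: list[GuideAssignment] = []
        for register, flagged in ((params.register, False),
                                  (params.fallback_register, True)):
            for sid, seq in snornas:
                bx = boxes[sid]
                if bx is None:
                    continue
                hit_d = best_duplex(seq, rna, call.position, bx.box_d, register,
                                    params, model, snorna_id=sid,
                                    rrna_name=call.rrna_name, box_used="D")
                hit_dp = None
                if bx.box_dprime is not None:
                    hit_dp = best_duplex(seq, rna, call.position, bx.box_dprime,
                                         register, params, model, snorna_id=sid,
                                         rrna_name=call.rrna_name, box_used="Dprime")
                hit = _site_best(hit_d, hit_dp)
                if hit is not None:
                    site_hits.append(hit)
            if site_hits:
                break                   # +6 only when +5 failed for every snoRNA
        if site_hits:
            assignments.extend(site_hits)
        else:
            unguided.append(call)

    guided_ids = {a.snorna_id for a in assignments}
    labels: dict[str, str] = {}
    n_cd = n_or = 0
    for sid, _ in snornas:
        if sid in guided_ids:
            n_cd += 1
            labels[sid] = f"CD{n_cd}"
        else:
            n_or += 1
            labels[sid] = f"OR{n_or}"
    return assignments, labels, unguided


def assignments_to_frame(assignments: list[GuideAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snorna_id": a.snorna_id, "box_used": a.box_used, "register": a.register,
        "rrna_name": a.rrna_name, "position": a.position,
        "duplex_len": a.duplex_len, "n_mismatch": a.n_mismatch, "n_gu": a.n_gu,
        "mfe": a.mfe,
        "sno_start": a.sno_interval[0], "sno_end": a.sno_interval[1],
        "rrna_start": a.rrna_interval[0], "rrna_end": a.rrna_interval[1],
    } for a in assignments], columns=[
        "snorna_id", "box_used", "register", "rrna_name", "position",
        "duplex_len", "n_mismatch", "n_gu", "mfe",
        "sno_start", "sno_end", "rrna_start", "rrna_end"])


def duplex_summary(assignments: list[GuideAssignment]) -> dict:
    """Cohort-level duplex feature summary (lengths, MFE, wobbles, box usage)."""
    if not assignments:
        raise ValueError("no assignments to summarise")
    lengths = np.array([a.duplex_len for a in assignments])
    mfes = np.array([a.mfe for a in assignments])
    n = len(assignments)
    n_dprime = sum(a.box_used == "Dprime" for a in assignments)
    hist = {int(k): int(v) for k, v in
            zip(*np.unique(lengths, return_counts=True))}
    return {
        "n_assignments": n,
        "mean_duplex_len": float(lengths.mean()),
        "min_duplex_len": int(lengths.min()),
        "max_duplex_len": int(lengths.max()),
        "length_histogram": hist,
        "mean_mfe": float(mfes.mean()),
        "n_gu_total": int(sum(a.n_gu for a in assignments)),
        "n_mismatch_total": int(sum(a.n_mismatch for a in assignments)),
        "frac_box_d": float((n - n_dprime) / n),
        "frac_box_dprime": float(n_dprime / n),
    }
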