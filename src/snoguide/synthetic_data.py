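"""Seeded generators for every input the pipeline consumes.

The generators emulate the study system at desk scale: an AT-rich genome
with planted box C/D snoRNA genes, a ribosomal RNA with planted
2'-O-methylation fractions, alkaline-fragmentation read-end tracks over
that rRNA, and small-RNA 5'-end/coverage tracks over the genome. Every
generator is a pure function of its seed, and every planted feature is
returned as ground truth so downstream stages can be scored against it.

Coordinate conventions: rRNA positions are 1-based nucleotide indices
(Am28-style labels); genome intervals are 0-based half-open with an
explicit strand, matching BED.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import (
    DNA_ALPHABET,
    RNA_ALPHABET,
    pairs,
    random_sequence,
    revcomp_dna,
    revcomp_rna,
    to_dna,
)
from .tracks import Track

#: box motifs in the gene orientation and their reverse complements;
#: random filler is scrubbed of all of these so planted boxes stay
#: unambiguous on either strand.
_BOX_MOTIFS = ("AUGAUGA", "GUGAUGA", "CUGA", "AUGA")
_BOX_MOTIFS_RC = tuple(revcomp_rna(m) for m in _BOX_MOTIFS)

DEFAULT_AT_FRACTION = 0.7
DEFAULT_CLEAVAGE_RATE = 1.0 / 30.0  # mean fragment length ~30 nt


class PlacementError(ValueError):
    """Requested geometry cannot be realised."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RrnaReference:
    """A (synthetic) ribosomal RNA sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 200:
            raise ValueError("rRNA must be at least 200 nt")
        if set(self.sequence) - set(RNA_ALPHABET):
            raise ValueError("rRNA sequence must be over {A,C,G,U}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MethylationTruth:
    """Planted per-position methylation fractions (simulation ground truth)."""

    rrna_name: str
    sites: tuple[tuple[int, float], ...]  # (1-based position, fraction)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("site positions must be unique and sorted")
        if any(not 0.0 <= f <= 1.0 for _, f in self.sites):
            raise ValueError("fractions must lie in [0, 1]")

    def fraction_at(self, position: int) -> float:
        for p, f in self.sites:
            if p == position:
                return f
        return 0.0


@dataclass(frozen=True)
class PlantedTarget:
    """One guided methylation target built into a snoRNA gene."""

    rrna_name: str
    position: int          # 1-based methylated nucleotide
    box: str               # "D" or "Dprime"
    duplex_len: int
    register: int = 5


@dataclass(frozen=True)
class SnoRnaGene:
    """A generated box C/D snoRNA gene with its annotation (RNA, 0-based offsets)."""

    id: str
    sequence: str
    box_c_start: int
    box_d_start: int
    box_dprime_start: int | None
    stem_len: int
    targets: tuple[PlantedTarget, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cd_distance(self) -> int:
        """First nt of box C to first nt of box D."""
        return self.box_d_start - self.box_c_start


@dataclass(frozen=True)
class TruthLocus:
    snorna_id: str
    start: int             # 0-based, half-open
    end: int
    strand: str            # "+" or "-"
    gene: SnoRnaGene


@dataclass
class SyntheticGenome:
    sequence: str          # DNA
    truth_loci: list[TruthLocus] = field(default_factory=list)
    at_fraction: float = DEFAULT_AT_FRACTION

    def __post_init__(self) -> None:
        for locus in self.truth_loci:
            if not (0 <= locus.start < locus.end <= len(self.sequence)):
                raise ValueError(f"locus {locus.snorna_id} outside genome bounds")
            planted = self.sequence[locus.start:locus.end]
            gene_dna = to_dna(locus.gene.sequence)
            expect = gene_dna if locus.strand == "+" else revcomp_dna(gene_dna)
            if planted != expect:
                raise ValueError(f"locus {locus.snorna_id} does not match its gene")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# rRNA and methylation truth


def generate_rrna(length: int = 2000, at_fraction: float = DEFAULT_AT_FRACTION,
                  seed: int = 0, name: str = "rRNA") -> RrnaReference:
    """I.i.d. rRNA with expected A+U frequency ``at_fraction``."""
    if length < 200:
        raise ValueError("length must be >= 200")
    if not 0.0 < at_fraction < 1.0:
        raise ValueError("at_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return RrnaReference(name=name, sequence=random_sequence(rng, length, at_fraction, RNA_ALPHABET))


def plant_methylation(rrna: RrnaReference, n_sites: int,
                      fractions: tuple[float, ...] = (1.0, 0.85, 0.5, 0.25, 0.0),
                      min_gap: int = 50, seed: int = 0,
                      margin: int = 60) -> MethylationTruth:
    """Place ``n_sites`` methylation sites with pairwise gaps >= ``min_gap``.

    Fractions are assigned cyclically from ``fractions``. ``margin`` keeps
    sites away from the molecule termini, where size selection of the
    fragmentation simulator depletes end counts; the hard floor of 8 nt
    (one score window) is always enforced.
    """
    if min_gap < 13:
        raise ValueError("min_gap must be >= 13 so score windows never share a site")
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if n_sites == 0:
        return MethylationTruth(rrna_name=rrna.name, sites=())
    if not fractions:
        raise ValueError("need at least one fraction")
    lo = max(8, margin)
    hi = min(rrna.length - 8, rrna.length - margin)
    span = hi - lo
    slack = span - (n_sites - 1) * min_gap
    if slack < 0:
        raise PlacementError(
            f"cannot place {n_sites} sites with gap {min_gap} in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.integers(0, slack + 1, size=n_sites))
    positions = lo + offsets + min_gap * np.arange(n_sites)
    sites = tuple((int(p), float(fractions[i % len(fractions)]))
                  for i, p in enumerate(positions))
    return MethylationTruth(rrna_name=rrna.name, sites=sites)


# ---------------------------------------------------------------------------
# RiboMeth-seq end-count simulation


def simulate_rms_endcounts(rrna: RrnaReference, truth: MethylationTruth,
                           n_fragments: int = 200_000,
                           size_range: tuple[int, int] = (20, 40),
                           seed: int = 0,
                           cleavage_rate: float = DEFAULT_CLEAVAGE_RATE,
                           ) -> tuple[Track, Track]:
    """Alkaline fragmentation + size selection as a Bernoulli cleavage process.

    Each of ``n_fragments`` full-length molecules is cleaved independently
    at every internucleotide linkage i (between nt i and i+1, 1-based)
    with probability ``cleavage_rate * (1 - f_i)``, where f_i is the
    planted methylation fraction of nt i — a 2'-O-methyl group protects
    the linkage 3' of it. Fragments bounded by two cleavage events whose
    length falls in ``size_range`` are retained: one with first nt s and
    last nt e increments End5Track[s] and End3Track[e]. Fragments abutting
    a molecule terminus are discarded, so the two track totals both equal
    the number of retained fragments.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid size_range")
    length = rrna.length
    if truth.rrna_name != rrna.name:
        raise ValueError("truth and rRNA reference names differ")
    frac = np.zeros(length + 1)
    for pos, f in truth.sites:
        if not 8 <= pos <= length - 8:
            raise ValueError(f"site {pos} too close to the rRNA ends")
        frac[pos] = f
    # per-linkage cleavage probability, linkage i in 1..L-1
    p_cut = cleavage_rate * (1.0 - frac[1:length])
    rng = np.random.default_rng(seed)
    end5 = np.zeros(length, dtype=np.int64)
    end3 = np.zeros(length, dtype=np.int64)
    chunk = max(1, min(n_fragments, 4000))
    done = 0
    while done < n_fragments:
        m = min(chunk, n_fragments - done)
        cut = rng.random((m, length - 1)) < p_cut[None, :]
        mol, link0 = np.nonzero(cut)          # row-major: sorted within molecule
        if link0.size >= 2:
            linkage = link0 + 1               # 1-based linkage index
            same = mol[1:] == mol[:-1]
            start_link = linkage[:-1][same]
            end_link = linkage[1:][same]
            flen = end_link - start_link      # fragment covers nt start+1 .. end
            keep = (flen >= lo) & (flen <= hi)
            end5 += np.bincount(start_link[keep] + 1, minlength=length + 1)[1:]
            end3 += np.bincount(end_link[keep], minlength=length + 1)[1:]
        done += m
    return Track(rrna.name, end5), Track(rrna.name, end3)


# ---------------------------------------------------------------------------
# snoRNA gene construction


def _nonpairing_bases(rrna_base: str) -> str:
    """Bases that form neither a WC nor a wobble pair with ``rrna_base``."""
    return "".join(b for b in RNA_ALPHABET if not pairs(b, rrna_base))


def _scrub(seq: list[str], mutable: np.ndarray, guards: dict[int, str],
           rng: np.random.Generator, motifs: tuple[str, ...] = _BOX_MOTIFS + _BOX_MOTIFS_RC,
           alphabet: str = RNA_ALPHABET, max_rounds: int = 2000) -> None:
    """Destroy box-like motifs that overlap any mutable position (in place).

    ``mutable`` marks freely mutable filler; ``guards`` maps positions to
    their allowed substitution alphabets (duplex-flank guards may only
    take bases that keep them non-pairing). Motifs fully inside protected
    sequence (planted boxes, antisense elements) are left alone.
    """
    max_k = max(len(m) for m in motifs)

    skipped: set[tuple[int, str]] = set()

    def open_occurrences_near(i: int) -> bool:
        """Any non-skipped motif occurrence with an editable position
        in the window around i?"""
        lo = max(0, i - max_k + 1)
        window = "".join(seq[lo: i + max_k])
        for m in motifs:
            s = window.find(m)
            while s != -1:
                span = range(lo + s, lo + s + len(m))
                if (lo + s, m) not in skipped and \
                        any(mutable[j] or j in guards for j in span):
                    return True
                s = window.find(m, s + 1)
        return False
    for _ in range(max_rounds):
        text = "".join(seq)
        hit = None
        for motif in motifs:
            start = text.find(motif)
            while start != -1:
                span = range(start, start + len(motif))
                editable = [i for i in span if mutable[i] or i in guards]
                if editable and (start, motif) not in skipped:
                    hit = (start, editable, motif)
                    break
                start = text.find(motif, start + 1)
            if hit:
                break
        if hit is None:
            return
        start, editable, motif = hit
        # try substitutions (inner positions first) until one destroys
        # the occurrence without seeding a new motif nearby
        fixed = False
        order = sorted(editable, key=lambda i: abs(i - (start + len(motif) // 2)))
        for i in order:
            allowed = [b for b in guards.get(i, alphabet) if b != seq[i]]
            rng.shuffle(allowed)
            original = seq[i]
            for base in allowed:
                seq[i] = base
                if not open_occurrences_near(i):
                    fixed = True
                    break
                seq[i] = original
            if fixed:
                break
        if not fixed:
            # every admissible base re-forms a motif (e.g. a duplex-flank
            # guard abutting an antisense element that starts UGAUGA);
            # leave it — overlap resolution handles equal-scoring copies
            skipped.add((start, motif))
    raise PlacementError("could not scrub box-like motifs from filler")


def generate_snorna_gene(target, box_usage: str = "D", duplex_len: int = 10,
                         seed: int = 0, cd_distance: int | None = None,
                         stem_len: int = 5,
                         at_fraction: float = DEFAULT_AT_FRACTION,
                         sno_id: str = "sno") -> SnoRnaGene:
    """Build a box C/D snoRNA gene guiding the given rRNA target(s).

    ``target`` is one ``(rrna, position)`` pair, or a sequence of two for
    ``box_usage="both"`` (first guided by D', second by D). The antisense
    element is laid immediately 5' of the used box so that the target
    nucleotide pairs with the 5th nt upstream of that box; two guard
    nucleotides past the element are set non-pairing so the planted
    duplex has exactly ``duplex_len`` base pairs.
    """
    if box_usage not in ("D", "Dprime", "both"):
        raise ValueError("box_usage must be 'D', 'Dprime' or 'both'")
    if not 7 <= duplex_len <= 15:
        raise ValueError("duplex_len must be in [7, 15]")
    if stem_len and not 4 <= stem_len <= 6:
        raise ValueError("stem_len must be 0 (no stem) or in [4, 6]")
    targets_in = list(target) if isinstance(target, (list, tuple)) and \
        not (len(target) == 2 and isinstance(target[1], (int, np.integer))) else [target]
    if box_usage == "both":
        if len(targets_in) != 2:
            raise PlacementError("box_usage='both' needs two (rrna, position) targets")
    elif len(targets_in) != 1:
        raise PlacementError(f"box_usage={box_usage!r} needs exactly one target")

    rng = np.random.default_rng(seed)
    v = duplex_len - 5  # downstream reach of the antisense window past the site
    for rrna, pos in targets_in:
        if not 11 <= pos <= rrna.length - 11:
            raise PlacementError(f"target {pos} leaves no room for a ±10 nt window")

    c0 = stem_len
    need_dprime = box_usage in ("Dprime", "both")
    dp0 = max(c0 + 7 + 12, c0 + 9 + duplex_len) if need_dprime else None
    min_cd = 7 + duplex_len + 2 + 5
    if need_dprime:
        min_cd = max(min_cd, dp0 - c0 + 4 + 12 + duplex_len + 2)
    if cd_distance is None:
        cd_distance = max(70, min_cd)
    if not 50 <= cd_distance <= 100 or cd_distance < min_cd:
        raise PlacementError(
            f"cd_distance {cd_distance} infeasible (needs [{max(50, min_cd)}, 100])")
    d0 = c0 + cd_distance
    total = d0 + 4 + stem_len

    seq = list(random_sequence(rng, total, at_fraction, RNA_ALPHABET))
    mutable = np.ones(total, dtype=bool)
    guards: dict[int, str] = {}

    def fix(start: int, text: str) -> None:
        for k, b in enumerate(text):
            seq[start + k] = b
            mutable[start + k] = False

    # terminal stem: 3' flank is the reverse complement of the 5' flank.
    # Stems are drawn from {C,G} only: a GC stem is stable in an AT-rich
    # genome and, containing neither A nor U, can neither hold nor
    # complete a box-like motif at the junctions.
    if stem_len:
        stem = "".join("CG"[int(b)] for b in rng.integers(0, 2, size=stem_len))
        fix(0, stem)
        fix(total - stem_len, revcomp_rna(stem))
    box_c = ("A" if rng.integers(2) else "G") + "UGAUGA"
    fix(c0, box_c)
    fix(d0, "CUGA")

    def plant_antisense(box_start: int, rrna: RrnaReference, pos: int) -> None:
        window = rrna.sequence[pos - 4 - 1: pos + v]  # rRNA [pos-4, pos+v], 1-based
        fix(box_start - duplex_len, revcomp_rna(window))
        for off in (1, 2):  # guard: extension past the element must not pair
            gpos = box_start - duplex_len - off
            rpos = pos + v + off
            allowed = _nonpairing_bases(rrna.sequence[rpos - 1]) if rpos <= rrna.length \
                else RNA_ALPHABET
            seq[gpos] = allowed[int(rng.integers(len(allowed)))]
            mutable[gpos] = False
            guards[gpos] = allowed

    targets: list[PlantedTarget] = []
    if box_usage in ("D", "both"):
        rrna, pos = targets_in[-1]
        plant_antisense(d0, rrna, int(pos))
        targets.append(PlantedTarget(rrna.name, int(pos), "D", duplex_len))
    if need_dprime:
        fix(dp0, "CUGA")
        rrna, pos = targets_in[0]
        plant_antisense(dp0, rrna, int(pos))
        targets.insert(0 if box_usage == "both" else 0,
                       PlantedTarget(rrna.name, int(pos), "Dprime", duplex_len))

    _scrub(seq, mutable, guards, rng)
    return SnoRnaGene(
        id=sno_id, sequence="".join(seq), box_c_start=c0, box_d_start=d0,
        box_dprime_start=dp0, stem_len=stem_len, targets=tuple(targets))


# ---------------------------------------------------------------------------
# genome assembly and small-RNA reads


def assemble_genome(genes: list[SnoRnaGene], n_decoys: int = 0,
                    spacer: int = 150, at_fraction: float = DEFAULT_AT_FRACTION,
                    seed: int = 0, strands: list[str] | None = None) -> SyntheticGenome:
    """Concatenate spacers, genes (optionally minus-strand) and decoy segments.

    Spacers and decoys are random AT-rich DNA scrubbed of box-like motifs
    on both strands, so every box the scanner can find belongs to a
    planted gene. ``strands`` gives one "+"/"-" per gene (default:
    alternating, starting on "+").
    """
    if spacer < 20:
        raise ValueError("spacer must be >= 20 nt")
    rng = np.random.default_rng(seed)
    if strands is None:
        strands = ["+" if i % 2 == 0 else "-" for i in range(len(genes))]
    if len(strands) != len(genes):
        raise ValueError("need one strand per gene")

    parts: list[str] = [random_sequence(rng, spacer, at_fraction, DNA_ALPHABET)]
    offset = spacer
    loci: list[TruthLocus] = []
    for gene, strand in zip(genes, strands):
        gene_dna = to_dna(gene.sequence)
        planted = gene_dna if strand == "+" else revcomp_dna(gene_dna)
        loci.append(TruthLocus(gene.id, offset, offset + len(planted), strand, gene))
        parts.append(planted)
        offset += len(planted)
        parts.append(random_sequence(rng, spacer, at_fraction, DNA_ALPHABET))
        offset += spacer
    for _ in range(n_decoys):
        decoy = random_sequence(rng, int(rng.integers(70, 110)), at_fraction,
                                DNA_ALPHABET)
        parts.append(decoy)
        offset += len(decoy)
        parts.append(random_sequence(rng, spacer, at_fraction, DNA_ALPHABET))
        offset += spacer
    # scrub spacers/decoys in the assembled genome so that no box-like
    # motif survives outside a planted locus, junctions included
    seq = list("".join(parts))
    mutable = np.ones(len(seq), dtype=bool)
    for locus in loci:
        mutable[locus.start:locus.end] = False
    _scrub(seq, mutable, {}, rng,
           motifs=tuple(to_dna(m) for m in _BOX_MOTIFS + _BOX_MOTIFS_RC),
           alphabet=DNA_ALPHABET)
    return SyntheticGenome(sequence="".join(seq), truth_loci=loci,
                           at_fraction=at_fraction)


def simulate_small_rna_reads(genome: SyntheticGenome, expressed: set[str],
                             depth: int = 500, sharp5: float = 0.9, seed: int = 0,
                             run_through: set[str] = frozenset(),
                             ) -> tuple[Track, Track]:
    """Small-RNA 5'-end and coverage tracks over the genome.

    Expressed loci receive ``depth`` reads of the locus length whose 5'
    ends sit exactly at the annotated 5' end with probability ``sharp5``
    and otherwise within ±3 nt. Loci in ``run_through`` additionally get
    reads entering from 100 nt upstream, mimicking a longer host
    transcript and defeating the distinct-5'-end test. 5' ends are
    genomic positions (for minus-strand loci: the right end).
    """
    if not 0.0 <= sharp5 <= 1.0:
        raise ValueError("sharp5 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genome)
    end5 = np.zeros(n, dtype=np.int64)
    covdiff = np.zeros(n + 1, dtype=np.int64)

    def add_read(start0: int, length: int, strand: str) -> None:
        start0 = max(0, min(n - 1, start0))
        stop0 = min(n, start0 + length)
        covdiff[start0] += 1
        covdiff[stop0] -= 1
        pos5 = start0 if strand == "+" else stop0 - 1
        end5[pos5] += 1

    for locus in genome.truth_loci:
        if locus.snorna_id not in expressed:
            continue
        length = locus.end - locus.start
        exact = rng.binomial(depth, sharp5)
        offsets = np.concatenate([
            np.zeros(exact, dtype=np.int64),
            rng.integers(-3, 4, size=depth - exact),
        ])
        for off in offsets:
            if locus.strand == "+":
                add_read(locus.start + int(off), length, "+")
            else:
                add_read(locus.end - length - int(off), length, "-")
        if locus.snorna_id in run_through:
            for _ in range(depth):
                ext = int(rng.integers(1, 101))
                if locus.strand == "+":
                    add_read(locus.start - ext, length + ext, "+")
                else:
                    add_read(locus.start, length + ext, "-")
    coverage = np.cumsum(covdiff[:-1])
    return Track("genome", end5), Track("genome", coverage)


# ---------------------------------------------------------------------------
# decoy genomes


def dinucleotide_shuffle(seq: str, seed: int = 0, max_tries: int = 1000) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul–Erikson).

    Treats the sequence as an Eulerian walk on the 1-mer graph: the last
    outgoing edge of every vertex (except the terminal one) is chosen so
    the resulting last-edge graph is connected to the terminal vertex,
    the remaining edges are permuted, and the walk is replayed.
    """
    if len(seq) < 3:
        return seq
    rng = np.random.default_rng(seed)
    bases = sorted(set(seq))
    edges: dict[str, list[str]] = {b: [] for b in bases}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    for _ in range(max_tries):
        chosen = {}
        for b in bases:
            if b != last and edges[b]:
                chosen[b] = edges[b][int(rng.integers(len(edges[b])))]
        # connectivity: every non-terminal vertex must reach `last` via chosen edges
        ok = True
        for b in chosen:
            node, seen = b, set()
            while node != last and node in chosen and node not in seen:
                seen.add(node)
                node = chosen[node]
            if node != last:
                ok = False
                break
        if not ok:
            continue
        pools = {}
        for b in bases:
            pool = list(edges[b])
            if b in chosen:
                pool.remove(chosen[b])
            rng.shuffle(pool)
            if b in chosen:
                pool.append(chosen[b])
            pools[b] = pool
        out = [seq[0]]
        counters = {b: 0 for b in bases}
        for _ in range(len(seq) - 1):
            b = out[-1]
            out.append(pools[b][counters[b]])
            counters[b] += 1
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")
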