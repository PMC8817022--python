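# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic data's relation to real data, and the numerical
and design choices that were genuinely open.

## Synthetic data as study conditions

The generators are not test fixtures but the package's definition of
its study conditions. Defaults: rRNA length 2,000 nt (a desk-scale
small-subunit rRNA), A+U fraction 0.7 (caricaturing the AT-rich
*D. discoideum* genome; configurable), planted methylation fractions
{1.0, 0.85, 0.5, 0.25, 0.0} cycling over five sites (fully methylated,
fractional, and three sub-threshold controls), minimum inter-site gap
50 nt (the hard floor is 13 nt so two score windows never share a
site), read depth 500 per expressed locus with 90 % of 5′ ends exactly
at the annotated start, and 2·10⁵ fragmented molecules per RMS
replicate, three replicates. Every generator is a pure function of its
seed; sequences are i.i.d. given the base composition.

What the simulation does **not** emulate: sequence-dependent cleavage
bias, ligation/barcode chemistry (beyond the 3′-end masking hook),
alignment ambiguity (tracks, not reads, are the unit of exchange),
transcription noise, and real rRNA secondary structure. Green tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real libraries.

### Fragmentation model

Alkaline fragmentation is a Bernoulli process over internucleotide
linkages: each of the `n_fragments` molecules is cut at linkage *i*
(between nt *i* and *i*+1) with probability `c·(1−f_i)`, where `f_i`
is the methylation fraction of nt *i* and `c = 1/30` targets a mean
fragment length of 30 nt, the middle of the 20–40 nt gel excision that
the library emulates. Only fragments bounded by two cleavage events
and sized 20–40 nt are retained; a fragment spanning nt *s..e*
increments End5[*s*] and End3[*e*]. Fragments touching a molecule
terminus are discarded, which makes the two track totals exactly equal
the retained-fragment count (a tested invariant). Under this model the
expected combined end count at a linkage is proportional to its
cleavage probability, so score C recovers *f* directly; the small
upward bias from fragments spanning a protected linkage (molecules cut
less often inside them survive longer) is bounded by ~`c·f` ≈ 3 % and
sits well inside the ±0.05 recovery tolerance. Site placement keeps a
60 nt margin from the molecule ends, where the size selection depletes
end counts and the local-average denominator would be biased.

### Gene construction

A generated gene is: GC-only terminal stem (default 5 bp; 0 disables
it), box C (RUGAUGA, R drawn uniformly), optional internal box D′
(CUGA) with its antisense element, the box D antisense element, box D
(CUGA), and the stem's reverse complement — box C–D distance 50–100 nt
(default 70, or the minimum the geometry needs). The antisense element
immediately 5′ of the used box is the reverse complement of the rRNA
window `[site−4, site+duplex_len−5]`, which places the methylated
nucleotide opposite the 5th nt upstream of that box. Two "guard"
nucleotides past the element are chosen non-pairing with their rRNA
counterparts so the planted duplex has exactly the requested length
(7–15 bp).

All random filler — and, at assembly time, the inter-gene spacers and
decoy segments, junctions included — is scrubbed of box-like motifs
(RUGAUGA, CUGA, AUGA and their reverse complements) so that every
full-scoring box the scanner can find belongs to a planted gene. Two
deliberate exceptions: antisense elements are never mutated (they
encode the duplex and may legitimately contain CUGA), and a guard
position whose every admissible base would re-form a motif (e.g. when
the antisense element starts UGAUGA) is left as is. Both cases are
harmless under the scan's tie-breaks (below). Stems are drawn from
{C,G} only: a GC stem is the realistic choice for a stable helix in an
AT-rich genome, and — containing neither A nor U — cannot hold or
complete a box motif at its junctions.

## Box scan and classifier

snoRNA boxes are modelled as log-odds PWMs in bits: consensus bases
carry probability 0.91 (the R of box C splits it over A/G), the rest
share the remainder uniformly, scored against the genome background.
With that calibration perfect boxes score 12.05 (C) + 7.46 (D) bits,
so genuine genes clear the combined > 9 gate with margin, and the
classifier arithmetic keeps the published semantics: candidates
inside the 50–100 nt distance window score distance 0 (outside, they
are dropped rather than penalised), the terminal stem contributes
`max(0, longest complementary run − 3)` between the 10 nt flanks (so
≥ 4 bp stems are positive and the stem is never a prerequisite), and
expression contributes ±15. The bound matters: without expression
evidence the maximum attainable total (≈ 19.5 + 7 − 15) stays below
29, so nothing is bona fide on sequence alone — specificity on decoy
genomes is structural, not statistical.

The scan emits every (box C, box D) pair on either strand with both
scores positive, combined score above the gate, and distance in
window, then resolves overlaps: each box C keeps its best box D
partner and each box D its best box C — by higher combined score, ties
broken toward the **3′-most box D** and the 5′-most box C. The 3′-most
rule (rather than leftmost) reflects the architecture: the mature box
D sits at the snoRNA's 3′ end, so when an equal-scoring CUGA occurs
inside the antisense element just upstream, the 3′ copy is the box.
Degenerate PWM hits with small positive scores do produce additional
overlapping candidate pairs; they fail the classifier and are
reported, not suppressed.

The k-turn check is intentionally minimal: the GA dinucleotides at
consensus positions 3–4 of both boxes (the trans Hoogsteen/sugar-edge
A•G pairs), which the AUGA box D variant retains. It is reported as a
flag, never used as a filter.

## Expression score

+15 requires all three of: more than 100 reads at the locus (strictly
greater), a distinct 5′ end, and no evidence of a longer host
transcript; otherwise −15. "Distinct 5′ end" is quantified as ≥ 50 %
of 5′-end counts within ±2 nt of the modal 5′ position, and "not part
of a longer transcript" as mean coverage over the 20 nt upstream of
the modal 5′ end at most 0.1× the mean locus coverage — both are
package quantifications of qualitative published criteria and are
config-exposed. Reads are gathered within ±150 nt of the candidate
span, matching the ±150 bp alignment window of the original analysis;
all computations are strand-aware (a minus-strand locus's 5′ end is
its right edge). Replicates are pooled before scoring.

## RiboMeth-seq scoring

Score C is computed per linkage with the k = 6 window and linearly
decaying weights given in the README; the linkage 3′ of nt *p* carries
*p*'s protection signal. Boundary positions (i ≤ k or i > L−1−k) and
zero-denominator positions are undefined (NaN), never exceptions. The
3′-end mask (for sites where adaptor heterogeneity corrupts 3′ counts)
excludes the 3′ evidence and doubles the 5′ evidence, keeping `n_i` on
scale rather than halving the denominator. Calls use the mean over
replicates where defined, threshold strictly > 0.75; the boundary
between "fractional" and "full" is set at 0.9 — the source material
never defines "fully methylated" numerically, so this is a package
decision, exposed in `ScoreCParams`.

## Guide assignment

For each (snoRNA, called site) pair the search anchors the site
opposite the 5th nt upstream of box D, then box D′, and extends an
ungapped antiparallel duplex inside the ±10 nt rRNA window and the
antisense region (never crossing the guided box): WC and G·U count as
pairs, at most one internal mismatch is absorbed, terminal mismatches
are trimmed, and duplexes shorter than 7 bp are discarded. The
implementation enumerates all windows around the anchor (≤ 21 nt, so
enumeration is exact) and is tested against an independent exhaustive
oracle. Arbitration where the source is silent: per (snoRNA, site) the
longest duplex wins, ties by lower stacking energy, then box D over
D′; the +6 register is attempted only for sites no snoRNA can explain
at +5, and is flagged. All passing guides of a site are reported
(multiple guides per site are real); snoRNAs with at least one
assignment are labelled CD*n* in genomic order, the rest OR*n*.
Because chance D′-like boxes (≤ 1 deviation from CUGA) exist, a
planted D-box target is occasionally explained by a longer duplex at a
D′ of the same snoRNA — recovery of planted truth is therefore judged
on (snoRNA, site).

Box location inside a snoRNA: box C is the best RUGAUGA PWM hit in the
5′ third (leftmost on ties), box D the best exact CUGA/AUGA in the 3′
third (3′-most on ties, matching the scan), box D′ the best ≤ 1-
deviation CUGA strictly between them with ≥ 12 nt clearance to each.

### Stacking model

Duplex energies use a Watson-Crick nearest-neighbor ΔG°37 table with
+4.1 kcal/mol duplex initiation and +1.0 kcal/mol per internal
mismatch (which also interrupts stacking). Stacks involving G·U take
the energy of the G·C-substituted stack plus 0.8 kcal/mol per wobble.
This construction makes two contracts hold exactly — appending a WC
pair never raises the energy, and a G·U-containing duplex is never
more stable than its all-WC counterpart of equal length — which is
what the pipeline relies on for ordering; absolute agreement with any
external folding tool is a non-goal, though planted cohorts average
≈ 11 bp and ≈ −13 kcal/mol.

## Site table and conservation

The packaged TSV transcribes the published table of 49 sites (17 SSU +
32 LSU). The loader enforces that shape so a transcription error fails
fast, parses site labels as base+position, and splits joint guide
entries (CD9/13). A site is *conserved* when an orthologous modified
position is listed for yeast, human or thale cress — including
positions methylated there by a stand-alone enzyme (Spb1) rather than
a snoRNA — and *guided* when its own guide cell is non-empty (a "+6"
annotation still counts as guided). Conserved/specific and
guided/unguided are exact partitions, order-independent by
construction.

## Problem sizes and tolerances

The shipped tests and the acceptance script use: 2 kb rRNA, five
planted sites, 3 × 2·10⁵ molecules for stoichiometry recovery
(tolerance ±0.05, comfortably above the observed ≤ 0.02 error at this
depth); 50 genomes × 10 genes for detection sensitivity and 20
shuffled 50 kb decoys for specificity; 10 cohorts × 13 planted targets
for guide recovery and 1,000 random instances for oracle agreement.
These sizes were chosen so the whole suite completes in about a minute
while keeping every stochastic margin several standard deviations
wide. Seeds are fixed in tests; the acceptance script derives all
randomness from its `--seed`.

## Known limitations

- The box scores are this package's PWM calibration, not the scores of
  any external scanner; only the gating logic and classifier semantics
  carry over, so absolute classifier values are not comparable.
- The cleavage model is memoryless per linkage; real alkaline
  hydrolysis has sequence context and the 3′-adaptor artefact that the
  mask emulates is not itself simulated.
- Guide search is ungapped by design (bulged duplexes are out of
  scope), and C′ box detection is heuristic and unused downstream.
- Expression scoring pools replicates and never normalises between
  samples; differential-expression analysis is out of scope.
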