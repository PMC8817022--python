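#!/usr/bin/env python
"""Generate every input of the study at desk scale.

Simulates (a) a 2 kb AT-rich rRNA with five planted 2'-O-methylation
sites at fractions {1.0, 0.85, 0.5, 0.25, 0.0}, (b) three replicates of
alkaline-fragmentation end-count tracks over it (2x10^5 molecules each),
(c) a genome with ten planted box C/D snoRNA genes — D-guided,
D'-guided and dual-box, on both strands — plus one silent gene, and
(d) small-RNA 5'-end/coverage tracks with sharp 5' ends at the
expressed loci. Writes everything under results/sim/.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from snoguide import synthetic_data as synth
from snoguide.io import write_bed6, write_fasta
from snoguide.tracks import write_track


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    seed = args.seed

    rrna = synth.generate_rrna(2000, 0.7, seed=seed)
    truth = synth.plant_methylation(rrna, 5, (1.0, 0.85, 0.5, 0.25, 0.0),
                                    min_gap=50, seed=seed + 1)
    write_fasta([(rrna.name, rrna.sequence)], out / "rrna.fa")
    pd.DataFrame({"reference": rrna.name,
                  "position": [p for p, _ in truth.sites],
                  "fraction": [f for _, f in truth.sites]},
                 ).to_csv(out / "methylation_truth.tsv", sep="\t", index=False)
    print(f"rRNA: {rrna.length} nt; planted sites: "
          + ", ".join(f"{p} (f={f})" for p, f in truth.sites))

    for rep in range(3):
        end5, end3 = synth.simulate_rms_endcounts(
            rrna, truth, n_fragments=200_000, seed=seed + 10 + rep)
        write_track(end5, out / f"rep{rep + 1}.end5.tsv", sparse=True)
        write_track(end3, out / f"rep{rep + 1}.end3.tsv", sparse=True)
        print(f"replicate {rep + 1}: {end5.total} retained fragments")

    # genes guiding the two high-fraction sites (D, D' and dual-box),
    # two genes whose targets are sub-threshold (destined orphans), and
    # one silent gene that must fail the expression test
    high = [p for p, f in truth.sites if f > 0.75]
    low = [p for p, f in truth.sites if f <= 0.5]
    genes = [
        synth.generate_snorna_gene((rrna, high[0]), box_usage="D",
                                   duplex_len=10, seed=seed + 100, sno_id="sno1"),
        synth.generate_snorna_gene((rrna, high[1]), box_usage="Dprime",
                                   duplex_len=11, seed=seed + 101, sno_id="sno2"),
        synth.generate_snorna_gene([(rrna, high[0]), (rrna, high[1])],
                                   box_usage="both", duplex_len=12,
                                   seed=seed + 102, sno_id="sno3"),
        synth.generate_snorna_gene((rrna, low[0]), box_usage="D",
                                   duplex_len=10, seed=seed + 103, sno_id="sno4"),
        synth.generate_snorna_gene((rrna, low[-1]), box_usage="D",
                                   duplex_len=10, seed=seed + 104, sno_id="sno5"),
    ]
    silent = synth.generate_snorna_gene((rrna, high[0]), box_usage="D",
                                        seed=seed + 300, sno_id="silent")
    genome = synth.assemble_genome(genes + [silent], n_decoys=2, seed=seed + 400)
    write_fasta([("genome", genome.sequence)], out / "genome.fa")
    write_bed6(pd.DataFrame([{
        "chrom": "genome", "start": l.start, "end": l.end,
        "name": l.snorna_id, "score": 0, "strand": l.strand,
    } for l in genome.truth_loci]), out / "truth_loci.bed")

    expressed = {g.id for g in genes}
    end5r, cov = synth.simulate_small_rna_reads(genome, expressed, depth=500,
                                                sharp5=0.9, seed=seed + 500)
    write_track(end5r, out / "smallrna.end5.tsv", sparse=True)
    write_track(cov, out / "smallrna.coverage.tsv", sparse=True)
    (out / "manifest.json").write_text(json.dumps({
        "seed": seed, "expressed": sorted(expressed),
        "planted_targets": [
            {"snorna": g.id, "position": t.position, "box": t.box,
             "duplex_len": t.duplex_len}
            for g in genes for t in g.targets]}, indent=2))
    print(f"genome: {len(genome)} bp, {len(genome.truth_loci)} planted loci "
          f"({len(expressed)} expressed, 1 silent); outputs in {out}")


if __name__ == "__main__":
    main()
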