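#!/usr/bin/env python
"""Assign bona fide snoRNAs to the called methylation sites (+5 rule).

Takes the bona fide candidates of the scan and the RMS calls, locates
boxes C/D/D' in each snoRNA, searches for anchored ungapped duplexes
(>= 7 bp, <= 1 mismatch, G·U allowed) in ±10 nt windows around each
site, labels guides CDn and orphans ORn, and summarises duplex
features. Writes results/assignments.tsv and results/duplex_summary.json.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from snoguide import guidemap
from snoguide.io import read_fasta
from snoguide.ribomethseq import MethylationCall


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--candidates", type=Path,
                        default=Path("results/candidates.tsv"))
    parser.add_argument("--calls", type=Path, default=Path("results/rms_calls.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cands = pd.read_csv(args.candidates, sep="\t")
    bona = cands[cands["bona_fide"]]
    snos = [(str(r.id), str(r.sequence)) for r in bona.itertuples(index=False)]
    calls_df = pd.read_csv(args.calls, sep="\t")
    calls = [MethylationCall(str(r.reference), int(r.position), str(r.nucleotide),
                             float(r.mean_score), float(r.sd), str(r.label))
             for r in calls_df.itertuples(index=False)]
    rrnas = read_fasta(args.sim / "rrna.fa")

    assignments, labels, unguided = guidemap.assign_guides(snos, calls, rrnas)
    frame = guidemap.assignments_to_frame(assignments)
    frame["label"] = frame["snorna_id"].map(labels)
    frame.to_csv(args.out_dir / "assignments.tsv", sep="\t", index=False,
                 float_format="%.2f")
    summary = guidemap.duplex_summary(assignments) if assignments else {}
    (args.out_dir / "duplex_summary.json").write_text(
        json.dumps(summary, indent=2))

    n_cd = sum(1 for v in labels.values() if v.startswith("CD"))
    n_or = len(labels) - n_cd
    print(f"{len(assignments)} assignments over {len(calls)} called sites; "
          f"{n_cd} guides (CD), {n_or} orphans (OR), "
          f"{len(unguided)} unguided sites")
    if summary:
        print(f"duplexes: mean {summary['mean_duplex_len']:.1f} bp "
              f"(range {summary['min_duplex_len']}-{summary['max_duplex_len']}), "
              f"mean MFE {summary['mean_mfe']:.1f} kcal/mol, "
              f"D {summary['frac_box_d']:.0%} / D' {summary['frac_box_dprime']:.0%}")
    print(f"wrote {args.out_dir / 'assignments.tsv'}")


if __name__ == "__main__":
    main()
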