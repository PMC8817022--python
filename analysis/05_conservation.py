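#!/usr/bin/env python
"""Conservation accounting over the packaged rRNA methylation site table.

Parses the shipped transcription of the published 49-site table
(17S/SSU and 26S/LSU sites with their CD guides and orthologous
positions in yeast, human and thale cress) and reports the conservation
and guidance tallies. Writes results/conservation_counts.json.
"""
import argparse
import json
from pathlib import Path

from snoguide import conservation


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", type=Path, default=None,
                        help="site table TSV (default: packaged)")
    parser.add_argument("--out", type=Path,
                        default=Path("results/conservation_counts.json"))
    args = parser.parse_args()

    records = conservation.load_site_table(args.table)
    counts = conservation.conservation_counts(records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(counts, indent=2) + "\n")

    print(f"{counts['total']} sites ({counts['ssu']} SSU + {counts['lsu']} LSU)")
    print(f"conserved in yeast/human/thale cress: {counts['conserved']}; "
          f"species-specific: {counts['specific']} "
          f"({counts['specific_lsu']} of them on the LSU)")
    print(f"guided: {counts['guided_sites']} sites by "
          f"{counts['distinct_guides']} distinct CD snoRNAs; "
          f"unguided: {counts['unguided_sites']}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
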