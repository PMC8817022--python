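"""The packaged rRNA 2'-O-methylation site table and conservation counts.

The shipped fixture is a hand transcription of the published table of
49 methylated positions in the Dictyostelium discoideum 17S (SSU) and
26S (LSU) rRNAs, each with its guiding CD snoRNA(s) (where assigned)
and the orthologous modified positions/guides in Saccharomyces
cerevisiae, Homo sapiens and Arabidopsis thaliana. A site counts as
conserved when an orthologous position is listed for any of the three
species — whether the ortholog is guided by a snoRNA or by a
stand-alone methyltransferase (e.g. yeast Spb1) — and as guided when
its own guide cell is non-empty. Joint guide entries (CD9/13) denote
two snoRNAs guiding the same position.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

EXPECTED_TOTAL = 49
EXPECTED_SSU = 17
EXPECTED_LSU = 32

_SITE_RE = re.compile(r"^([ACGU])m(\d+)$")
_GUIDE_RE = re.compile(r"^CD\d+$")

_COLUMNS = ["subunit", "dd_site", "dd_guides", "register_note",
            "sc_site", "sc_guide", "hs_site", "hs_guide", "at_site", "at_guide"]


@dataclass(frozen=True)
class SiteRecord:
    """One row of the site table."""

    subunit: str               # "SSU" or "LSU"
    site_label: str            # e.g. "Am28"
    base: str
    position: int
    guides: tuple[str, ...]    # own CD guides, possibly empty
    register_note: str | None  # e.g. "+6"
    sc_site: str | None
    sc_guide: str | None
    hs_site: str | None
    hs_guide: str | None
    at_site: str | None
    at_guide: str | None

    @property
    def conserved(self) -> bool:
        """An orthologous modified position exists in any other species."""
        return any(s is not None for s in (self.sc_site, self.hs_site, self.at_site))

    @property
    def guided(self) -> bool:
        return len(self.guides) > 0


def default_table_path() -> Path:
    return Path(resources.files("snoguide").joinpath("data/table1_sites.tsv"))


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().replace("–", "-").replace("−", "-")
    return text if text and text != "-" else None


def load_site_table(path: str | Path | None = None,
                    validate_shape: bool = True) -> list[SiteRecord]:
    """Parse the site table TSV into validated records.

    Site labels must parse as base+position ([ACGU]m<int>), guide cells
    as CD identifiers (joint CD9/13 entries are split). With
    ``validate_shape`` the published 49 = 17 SSU + 32 LSU shape is
    enforced so transcription errors fail fast.
    """
    if path is None:
        path = default_table_path()
    df = pd.read_csv(path, sep="\t", header=0, names=_COLUMNS, dtype=str)
    if list(df.columns) != _COLUMNS:
        raise ValueError("site table header does not match the expected schema")
    records: list[SiteRecord] = []
    for row in df.itertuples(index=False):
        subunit = _clean(row.subunit)
        if subunit not in ("SSU", "LSU"):
            raise ValueError(f"bad subunit {row.subunit!r}")
        label = _clean(row.dd_site)
        m = _SITE_RE.match(label or "")
        if not m:
            raise ValueError(f"unparseable site label {label!r}")
        guides: tuple[str, ...] = ()
        raw_guides = _clean(row.dd_guides)
        if raw_guides:
            prefixless = raw_guides.split("/")
            guides = tuple(g if g.startswith("CD") else f"CD{g}" for g in prefixless)
            for g in guides:
                if not _GUIDE_RE.match(g):
                    raise ValueError(f"bad guide id {g!r} in {raw_guides!r}")
        note = _clean(row.register_note)
        records.append(SiteRecord(
            subunit=subunit, site_label=label, base=m.group(1),
            position=int(m.group(2)), guides=guides, register_note=note,
            sc_site=_clean(row.sc_site), sc_guide=_clean(row.sc_guide),
            hs_site=_clean(row.hs_site), hs_guide=_clean(row.hs_guide),
            at_site=_clean(row.at_site), at_guide=_clean(row.at_guide)))
    if validate_shape:
        n_ssu = sum(r.subunit == "SSU" for r in records)
        n_lsu = sum(r.subunit == "LSU" for r in records)
        if (len(records), n_ssu, n_lsu) != (EXPECTED_TOTAL, EXPECTED_SSU, EXPECTED_LSU):
            raise ValueError(
                f"site table shape {len(records)} ({n_ssu} SSU + {n_lsu} LSU) "
                f"!= expected {EXPECTED_TOTAL} ({EXPECTED_SSU} + {EXPECTED_LSU})")
    return records


def conservation_counts(records: list[SiteRecord]) -> dict[str, int]:
    """Conservation and guidance tallies over the site records."""
    if not records:
        raise ValueError("no records")
    conserved = sum(r.conserved for r in records)
    guided = sum(r.guided for r in records)
    distinct = set()
    for r in records:
        distinct.update(r.guides)
    return {
        "total": len(records),
        "ssu": sum(r.subunit == "SSU" for r in records),
        "lsu": sum(r.subunit == "LSU" for r in records),
        "conserved": conserved,
        "specific": len(records) - conserved,
        "specific_lsu": sum(1 for r in records
                            if r.subunit == "LSU" and not r.conserved),
        "guided_sites": guided,
        "unguided_sites": len(records) - guided,
        "distinct_guides": len(distinct),
    }
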