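import numpy as np
import pytest

from snoguide import boxscan
from snoguide import synthetic_data as synth


@pytest.fixture(scope="session")
def rrna():
    return synth.generate_rrna(2000, 0.7, seed=1)


@pytest.fixture(scope="session")
def truth(rrna):
    return synth.plant_methylation(rrna, 5, (1.0, 0.85, 0.5, 0.25, 0.0),
                                   min_gap=50, seed=2)


@pytest.fixture(scope="session")
def box_model():
    return boxscan.build_box_model()


@pytest.fixture(scope="session")
def endcount_tracks(rrna, truth):
    """One deep replicate of simulated end counts (reused across tests)."""
    return synth.simulate_rms_endcounts(rrna, truth, n_fragments=200_000, seed=3)


def make_genes(rrna, seed, n=10):
    """A mixed cohort of planted genes: D-guided, D'-guided and dual."""
    genes = []
    for i in range(n):
        usage = ("D", "Dprime", "both")[i % 3]
        duplex_len = 7 + (seed + i) % 9
        pos = 100 + 170 * i
        target = [(rrna, pos), (rrna, pos + 80)] if usage == "both" else (rrna, pos)
        genes.append(synth.generate_snorna_gene(
            target, box_usage=usage, duplex_len=duplex_len,
            seed=seed * 1000 + i, sno_id=f"s{seed}_{i}"))
    return genes


def expected_scan_coords(genome, locus):
    """Scanned-strand coordinates of a planted locus's annotated boxes."""
    gene = locus.gene
    if locus.strand == "+":
        c = locus.start + gene.box_c_start
    else:
        c = (len(genome) - locus.end) + gene.box_c_start
    return c, c + gene.cd_distance
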