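import numpy as np
import pandas as pd
import pytest

from inlinebc import simulate as sim
from inlinebc.catalogue import BarcodeCatalogue, BarcodedPrimer
from inlinebc.demux import ReadPair


@pytest.fixture(scope="session")
def bacterial_catalogue():
    """8 forward x 17 reverse panel (V3-V4 primer pair)."""
    return sim.random_catalogue(
        8, 17, seed=11, forward_primer=sim.PRIMER_338F, reverse_primer=sim.PRIMER_785R
    )


@pytest.fixture(scope="session")
def archaeal_catalogue():
    """13 forward x 12 reverse panel (V4-V5 primer pair)."""
    return sim.random_catalogue(
        13, 12, seed=12, forward_primer=sim.PRIMER_519F, reverse_primer=sim.PRIMER_915R
    )


@pytest.fixture(scope="session")
def tiny_catalogue():
    """Hand-built 2x2 catalogue with maximally separated barcodes."""
    return BarcodeCatalogue(
        forwards=[
            BarcodedPrimer(id="Forward_T_1", direction="forward",
                           barcode="AAAACCCC", primer="ACGTACGT"),
            BarcodedPrimer(id="Forward_T_2", direction="forward",
                           barcode="GGGGTTTT", primer="ACGTACGT"),
        ],
        reverses=[
            BarcodedPrimer(id="Reverse_T_1", direction="reverse",
                           barcode="ACACACAC", primer="TTGGCCAA"),
            BarcodedPrimer(id="Reverse_T_2", direction="reverse",
                           barcode="GTGTGTGT", primer="TTGGCCAA"),
        ],
    )


def make_reads(cat, reads_per_pair=5, seed=0, **plan_kwargs):
    """Read pairs + truth for a catalogue, as demux-ready ReadPair tuples."""
    plan = sim.SimulationPlan(
        catalogue=cat, reads_per_pair=reads_per_pair, seed=seed, **plan_kwargs
    )
    r1, r2, truth = sim.generate_reads(plan)
    reads = [ReadPair(a[0], a[1], a[2], b[1], b[2]) for a, b in zip(r1, r2)]
    return reads, truth


@pytest.fixture(scope="session")
def clean_reads(tiny_catalogue):
    """Error-free read pairs over the tiny catalogue."""
    return make_reads(tiny_catalogue, reads_per_pair=10, seed=42)
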