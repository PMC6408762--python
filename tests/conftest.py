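from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the bruteforce oracle

from circas.events import call_sample
from circas.io import GenomeRef, read_alignments
from circas.simulate import SimParams, simulate_bundle

SMALL_PARAMS = SimParams(
    seed=7,
    n_circles=6,
    coverage=16.0,
    background_linear_reads=40,
    n_contigs=2,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated sample: 6 circles, <=1000 reads, with decoys."""
    return simulate_bundle(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_reads(small_bundle, tmp_path_factory):
    sam = tmp_path_factory.mktemp("sam") / "reads.sam"
    sam.write_text(small_bundle.sam_text)
    return read_alignments(sam)


@pytest.fixture(scope="session")
def small_run(small_bundle, small_reads):
    bsjs, events = call_sample(small_reads, small_bundle.genome, small_bundle.models)
    return bsjs, events


@pytest.fixture()
def toy_genome():
    """2 kb single-contig genome with a canonical GT..AG junction at 150/1151.

    Donor flank GT at 151-152 and acceptor flank AG at 1149-1150, i.e. the
    junction (donor=150, acceptor=1151) is canonical; everything else is A.
    """
    seq = list("A" * 2000)
    seq[150:152] = "GT"
    seq[1148:1150] = "AG"
    return GenomeRef({"chrT": "".join(seq)})
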