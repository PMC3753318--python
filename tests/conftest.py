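import numpy as np
import pytest

from hkascan.io import LocusAlignment, SampleSheet


def make_alignment(seqs, pools, locus_id="loc", sample_ids=None, cds=(), frame=0):
    """Build a LocusAlignment from plain strings."""
    if sample_ids is None:
        sample_ids = tuple(f"s{i}" for i in range(len(seqs)))
    residues = np.vstack([np.frombuffer(s.encode("ascii"), dtype="S1") for s in seqs])
    return LocusAlignment(
        locus_id=locus_id,
        sample_ids=tuple(sample_ids),
        pools=tuple(pools),
        residues=residues,
        cds_intervals=tuple(cds),
        frame=frame,
    )


@pytest.fixture
def panel_sheet():
    """The study-shaped sample sheet: 8 wild + 6 landrace + 6 improved + 1 outgroup."""
    rows = [(f"w{i}", "wild") for i in range(1, 9)]
    rows += [(f"l{i}", "landrace") for i in range(1, 7)]
    rows += [(f"i{i}", "improved") for i in range(1, 7)]
    rows += [("out1", "outgroup")]
    return SampleSheet(samples=tuple(rows))


@pytest.fixture
def tiny_alignment():
    """Three haplotypes used throughout the hand-computed examples."""
    return make_alignment(["AAAA", "AAAT", "AATT"], ["wild"] * 3)
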