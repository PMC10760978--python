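import numpy as np
import pytest

from barcodekit import alignio, simdata


@pytest.fixture
def small_genus():
    """Six species x four individuals, clear barcode gap, fixed seed."""
    cfg = simdata.SimConfig(
        n_species=6,
        seqs_per_species=4,
        seq_length=600,
        intra_divergence=0.005,
        inter_divergence=0.03,
        seed=11,
    )
    seqset, truth = simdata.simulate_genus(cfg)
    return seqset, truth


@pytest.fixture
def trimmed_alignment(small_genus):
    seqset, _ = small_genus
    return alignio.trim_and_degap(alignio.alignment_from_seqset(seqset))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_alignment(rows: dict[str, str], reference_id: str | None = None,
                   trimmed: bool = True) -> alignio.Alignment:
    """Hand-built alignment from literal rows (test convenience)."""
    ids = list(rows)
    ref = reference_id or ids[0]
    width = len(next(iter(rows.values())))
    return alignio.Alignment(
        reference_id=ref,
        ids=ids,
        rows=dict(rows),
        column_map=tuple(range(1, width + 1)),
        trimmed=trimmed,
    )
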