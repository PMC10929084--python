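import numpy as np
import pytest

import rpifusion as rf


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal dataset shared by selection/eval/CLI tests."""
    cfg = rf.SimulationConfig(
        n_rna=30,
        n_protein=30,
        n_positive=60,
        rna_length_range=(60, 120),
        protein_length_range=(50, 100),
        seed=11,
    )
    ds, pairs = rf.simulate_labeled_dataset(cfg)
    return cfg, ds, pairs


@pytest.fixture(scope="session")
def small_blocks(small_sim):
    """Encoded feature blocks + labels for the small dataset."""
    _, ds, pairs = small_sim
    blocks, labels = rf.encode_dataset(
        pairs,
        ds.rnas,
        ds.proteins,
        ds.rna_structures,
        ds.protein_structures,
        ds.ppi_edges,
    )
    return blocks, labels, pairs


def random_rna(rng: np.random.Generator, length: int) -> rf.SequenceRecord:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return rf.SequenceRecord(id=f"r{rng.integers(1e9)}", kind="rna", residues=seq)


def random_protein(rng: np.random.Generator, length: int) -> rf.SequenceRecord:
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return rf.SequenceRecord(
        id=f"p{rng.integers(1e9)}", kind="protein", residues=seq
    )
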