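import numpy as np
import pytest

from rpikit import (
    InteractionPair,
    PairDataset,
    SequenceRecord,
    SyntheticConfig,
    encode_dataset,
    generate,
)


def make_dataset(triples):
    """Build a PairDataset from (protein_seq, rna_seq, label) triples."""
    ds = PairDataset()
    for i, (prot, rna, label) in enumerate(triples, start=1):
        p = SequenceRecord(f"P{i}", prot, "protein")
        r = SequenceRecord(f"R{i}", rna, "rna")
        ds.add_sequence(p)
        ds.add_sequence(r)
        ds.add_pair(InteractionPair(p.id, r.id, label))
    return ds


def separable_triples(n_per_class, seed=42):
    """Separable pairs: the two classes draw from disjoint residue classes,
    so their k-mer compositions occupy disjoint feature blocks."""
    rng = np.random.default_rng(seed)

    def seq(alphabet, length):
        return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))

    triples = []
    for _ in range(n_per_class):
        triples.append((seq("AYH", 30), seq("AG", 20), "positive"))
    for _ in range(n_per_class):
        triples.append((seq("RDC", 30), seq("CU", 20), "negative"))
    return triples


@pytest.fixture
def toy_separable():
    """Trivially separable 20-pair set (disjoint compositional blocks)."""
    return make_dataset(separable_triples(10))


@pytest.fixture(scope="session")
def planted_small():
    """Planted-signal dataset (30 pairs/class) with its encoded matrix."""
    ds = generate(SyntheticConfig(n_pairs_per_class=30, seed=7))
    X, y, index = encode_dataset(ds)
    return ds, X, y


@pytest.fixture(scope="session")
def planted_medium():
    """Planted-signal dataset at the reference size (200 pairs/class)."""
    ds = generate(SyntheticConfig(n_pairs_per_class=200, seed=11))
    X, y, index = encode_dataset(ds)
    return ds, X, y
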