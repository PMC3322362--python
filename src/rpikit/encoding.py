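"""k-mer composition features for RNA-protein pairs.

A protein is encoded by its conjoint triad feature (CTF) vector: the 20
amino acids are collapsed into 7 classes by dipole moment and side-chain
volume, and the normalized frequencies of all 7x7x7 = 343 reduced-alphabet
3-mers are counted over a sliding window.  An RNA is encoded by the
normalized frequencies of all 4x4x4x4 = 256 ribonucleotide 4-mers.  A pair
is the 599-long concatenation (protein part first).

Normalization divides counts by the number of valid windows, so each part
sums to 1; windows containing a non-standard letter (ambiguity codes)
contribute to neither numerator nor denominator.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

from .sequences import PairDataset, SequenceRecord, canonicalize

# The 7 amino-acid classes, in their conventional printed order.  The
# class index of a residue is its position in this tuple; triad (g1,g2,g3)
# maps to feature index g1*49 + g2*7 + g3.
PROTEIN_GROUPS: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

GROUP_OF_RESIDUE: dict[str, int] = {
    aa: gi for gi, group in enumerate(PROTEIN_GROUPS) for aa in group
}

RNA_BASES = "ACGU"
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(RNA_BASES)}

N_PROTEIN_FEATURES = 7**3  # 343
N_RNA_FEATURES = 4**4  # 256
N_PAIR_FEATURES = N_PROTEIN_FEATURES + N_RNA_FEATURES  # 599

INVALID = -1  # flag for residues outside the 20-letter alphabet


class EncodingError(ValueError):
    """Raised when a sequence has no valid k-mer window to count."""


def reduce_protein(seq: str) -> list[int]:
    """Map each residue to its 7-class index; non-standard residues get -1.

    Output length always equals input length.
    """
    s = canonicalize(seq, "protein")
    return [GROUP_OF_RESIDUE.get(c, INVALID) for c in s]


def triad_index(g1: int, g2: int, g3: int) -> int:
    return g1 * 49 + g2 * 7 + g3


def tetrad_index(tetrad: str) -> int:
    b1, b2, b3, b4 = (BASE_INDEX[c] for c in tetrad)
    return b1 * 64 + b2 * 16 + b3 * 4 + b4


def _kmer_profile(codes: Sequence[int], k: int, n_symbols: int, label: str) -> np.ndarray:
    """Normalized k-mer counts over all windows free of invalid codes."""
    n = len(codes)
    counts = np.zeros(n_symbols**k, dtype=float)
    n_valid = 0
    for i in range(n - k + 1):
        window = codes[i : i + k]
        if any(c < 0 for c in window):
            continue
        idx = 0
        for c in window:
            idx = idx * n_symbols + c
        counts[idx] += 1.0
        n_valid += 1
    if n_valid == 0:
        raise EncodingError(f"no valid {k}-mer window in {label}")
    return counts / n_valid


def encode_protein(seq: str | SequenceRecord) -> np.ndarray:
    """343-long normalized conjoint-triad frequency vector."""
    if isinstance(seq, SequenceRecord):
        label, s = seq.id, seq.seq
    else:
        label, s = "protein sequence", seq
    return _kmer_profile(reduce_protein(s), 3, 7, label)


def encode_rna(seq: str | SequenceRecord) -> np.ndarray:
    """256-long normalized 4-mer frequency vector (A=0, C=1, G=2, U=3)."""
    if isinstance(seq, SequenceRecord):
        label, s = seq.id, seq.seq
    else:
        label, s = "rna sequence", canonicalize(seq, "rna")
    codes = [BASE_INDEX.get(c, INVALID) for c in s]
    return _kmer_profile(codes, 4, 4, label)


def encode_pair(protein: str | SequenceRecord, rna: str | SequenceRecord) -> np.ndarray:
    """599-long pair vector: protein part (343) then RNA part (256)."""
    return np.concatenate([encode_protein(protein), encode_rna(rna)])


def feature_names() -> list[str]:
    """Stable names for the 599 features: triads by class digits, tetrads by bases."""
    prot = [
        f"triad_{g1}{g2}{g3}"
        for g1 in range(7)
        for g2 in range(7)
        for g3 in range(7)
    ]
    rna = ["tetrad_" + "".join(t) for t in itertools.product(RNA_BASES, repeat=4)]
    return prot + rna


def enumerate_triplets(classes: Iterable[str | Iterable[str]]) -> list[str]:
    """Expand a triple of amino-acid classes into all residue triplets.

    Each class must be one of the 7 classes (given as a set/string of its
    residues in any order, e.g. ``"ILFP"``).  Returns the Cartesian
    product; e.g. the class triple ({I,L,F,P}, {A,G,V}, {R,K}) expands to
    24 amino-acid triplets such as IAR, IAK, IGR, IGK.
    """
    canonical = {frozenset(g): g for g in PROTEIN_GROUPS}
    groups: list[str] = []
    for cls in classes:
        key = frozenset(cls)
        if key not in canonical:
            raise ValueError(f"unknown amino-acid class {sorted(key)!r}")
        groups.append(canonical[key])
    if len(groups) != 3:
        raise ValueError("exactly three classes required")
    return ["".join(t) for t in itertools.product(*groups)]


def encode_dataset(dataset: PairDataset) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Encode every pair of a dataset.

    Returns ``(X, y, index)`` where X is (n_pairs, 599), y holds 1 for
    positive and 0 for negative (-1 for unlabeled), and index lists the
    (protein_id, rna_id) of each row.  Each distinct sequence is encoded
    once and reused across pairs.
    """
    cache: dict[str, np.ndarray] = {}

    def enc(rec: SequenceRecord) -> np.ndarray:
        if rec.id not in cache:
            cache[rec.id] = (
                encode_protein(rec) if rec.moltype == "protein" else encode_rna(rec)
            )
        return cache[rec.id]

    rows, labels, index = [], [], []
    for p in dataset.pairs:
        rows.append(
            np.concatenate([enc(dataset.protein(p)), enc(dataset.rna(p))])
        )
        labels.append({"positive": 1, "negative": 0, "unlabeled": -1}[p.label])
        index.append((p.protein_id, p.rna_id))
    X = np.array(rows, dtype=float).reshape(len(rows), N_PAIR_FEATURES)
    return X, np.array(labels, dtype=int), index
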