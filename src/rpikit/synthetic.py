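"""Synthetic RNA-protein pair data with planted compositional signal.

Generates balanced labeled datasets in which interacting pairs carry an
enrichment of chosen protein triads (reduced-alphabet 3-mers) and RNA
tetrads, at a tunable per-window planting probability.  Background
residues are uniform over the molecule's alphabet — deliberately free of
codon structure or biophysical realism, since the goal is a controlled
testbed for the encoding/classification pipeline, not biological
fidelity.

Planting works by overwrite: scanning start positions left to right,
each position independently with probability ``signal_strength`` has a
signal k-mer written over the next k letters (a random residue
realization of a signal triad for proteins; a signal tetrad verbatim for
RNA), after which the scan advances past the planted k-mer so that every
planted motif stays intact.  Overwrites keep the sequence length fixed.
At strength 0 positive and negative sequences are identically
distributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import PROTEIN_GROUPS, RNA_BASES
from .sequences import (
    InteractionPair,
    PairDataset,
    SequenceRecord,
    write_fasta,
    write_pairs,
)

AMINO_ACIDS = "".join(PROTEIN_GROUPS)  # 20 residues, class-major order

# Defaults mirror the feature classes most often implicated in real
# RNA-binding signatures: the conjoint triad class {I,L,F,P}{A,G,V}{R,K}
# (class indices 1, 0, 4) and the tetrads AUUC, AGUG, UUUU, UCAA.
DEFAULT_SIGNAL_TRIADS: tuple[tuple[int, int, int], ...] = ((1, 0, 4),)
DEFAULT_SIGNAL_TETRADS: tuple[str, ...] = ("AUUC", "AGUG", "UUUU", "UCAA")


@dataclass(frozen=True)
class SyntheticConfig:
    n_pairs_per_class: int = 200
    protein_length: int = 150
    rna_length: int = 100
    signal_strength: float = 0.5
    signal_protein_triads: tuple[tuple[int, int, int], ...] = DEFAULT_SIGNAL_TRIADS
    signal_rna_tetrads: tuple[str, ...] = DEFAULT_SIGNAL_TETRADS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_per_class < 1:
            raise ValueError("n_pairs_per_class must be >= 1")
        if self.protein_length < 3 or self.rna_length < 4:
            raise ValueError("lengths must allow at least one k-mer window")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        for triad in self.signal_protein_triads:
            if len(triad) != 3 or any(not (0 <= g < 7) for g in triad):
                raise ValueError(f"invalid signal triad {triad!r}")
        for tet in self.signal_rna_tetrads:
            if len(tet) != 4 or any(b not in RNA_BASES for b in tet):
                raise ValueError(f"invalid signal tetrad {tet!r}")


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> list[str]:
    return [alphabet[i] for i in rng.integers(len(alphabet), size=length)]


def _plant_protein(
    rng: np.random.Generator,
    seq: list[str],
    triads: tuple[tuple[int, int, int], ...],
    strength: float,
) -> None:
    i = 0
    while i <= len(seq) - 3:
        if rng.random() < strength:
            triad = triads[int(rng.integers(len(triads)))]
            for j, g in enumerate(triad):
                group = PROTEIN_GROUPS[g]
                seq[i + j] = group[int(rng.integers(len(group)))]
            i += 3
        else:
            i += 1


def _plant_rna(
    rng: np.random.Generator,
    seq: list[str],
    tetrads: tuple[str, ...],
    strength: float,
) -> None:
    i = 0
    while i <= len(seq) - 4:
        if rng.random() < strength:
            tet = tetrads[int(rng.integers(len(tetrads)))]
            for j, b in enumerate(tet):
                seq[i + j] = b
            i += 4
        else:
            i += 1


def generate(config: SyntheticConfig) -> PairDataset:
    """Balanced labeled dataset: n positives with planted signal, n background negatives.

    Deterministic given ``config.seed``; every pair gets its own fresh
    protein and RNA sequence.
    """
    rng = np.random.default_rng(config.seed)
    ds = PairDataset(
        metadata={
            "generator": "rpikit.synthetic",
            "seed": config.seed,
            "signal_strength": config.signal_strength,
        }
    )
    width = len(str(2 * config.n_pairs_per_class))
    for k in range(2 * config.n_pairs_per_class):
        positive = k < config.n_pairs_per_class
        prot = _random_seq(rng, AMINO_ACIDS, config.protein_length)
        rna = _random_seq(rng, RNA_BASES, config.rna_length)
        if positive:
            _plant_protein(
                rng, prot, config.signal_protein_triads, config.signal_strength
            )
            _plant_rna(rng, rna, config.signal_rna_tetrads, config.signal_strength)
        tag = f"{k + 1:0{width}d}"
        p_rec = SequenceRecord(f"P{tag}", "".join(prot), "protein")
        r_rec = SequenceRecord(f"R{tag}", "".join(rna), "rna")
        ds.add_sequence(p_rec)
        ds.add_sequence(r_rec)
        ds.add_pair(
            InteractionPair(p_rec.id, r_rec.id, "positive" if positive else "negative")
        )
    return ds


def generate_fixture_files(config: SyntheticConfig, directory: str | Path) -> dict[str, Path]:
    """Write a generated dataset as FASTA + labeled pair TSV.

    Produces ``proteins.fasta``, ``rnas.fasta`` and ``pairs.tsv`` under
    ``directory``; regenerating with the same config is byte-identical.
    Returns the paths keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds = generate(config)
    paths = {
        "proteins": directory / "proteins.fasta",
        "rnas": directory / "rnas.fasta",
        "pairs": directory / "pairs.tsv",
    }
    write_fasta(ds.records("protein"), paths["proteins"])
    write_fasta(ds.records("rna"), paths["rnas"])
    write_pairs(ds, paths["pairs"])
    return paths
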