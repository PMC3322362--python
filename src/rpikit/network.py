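"""Bipartite RNA-protein interaction networks from model predictions.

A trained classifier is applied to candidate protein x RNA pairs (an
explicit list, or the full cross product) and each scored pair becomes a
probability-weighted edge; edges at or above the decision threshold
(default 0.50) are the predicted interactions.  Evaluation against a
catalogue of known interactions measures *recall* only — interaction
databases list positives and carry no verified non-interacting pairs, so
the fraction of known pairs recovered is the only honest score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .encoding import EncodingError, encode_protein, encode_rna
from .models import TrainedModel, predict_proba
from .sequences import SequenceRecord


@dataclass(frozen=True)
class Edge:
    protein_id: str
    rna_id: str
    probability: float
    predicted_label: bool


@dataclass
class InteractionNetwork:
    """Scored bipartite graph over protein and RNA nodes."""

    proteins: list[str] = field(default_factory=list)
    rnas: list[str] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    threshold: float = 0.50
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def edge_map(self) -> dict[tuple[str, str], Edge]:
        return {(e.protein_id, e.rna_id): e for e in self.edges}

    def positive_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.predicted_label]

    def validate(self) -> None:
        prot, rna = set(self.proteins), set(self.rnas)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.protein_id not in prot or e.rna_id not in rna:
                raise ValueError(f"edge references unknown node: {e}")
            if not (0.0 <= e.probability <= 1.0):
                raise ValueError(f"edge probability out of range: {e}")
            key = (e.protein_id, e.rna_id)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)


def predict_network(
    proteins: Sequence[SequenceRecord],
    rnas: Sequence[SequenceRecord],
    model: TrainedModel,
    candidates: Iterable[tuple[str, str]] | Literal["all"] = "all",
    threshold: float = 0.50,
) -> InteractionNetwork:
    """Score candidate pairs and assemble the predicted network.

    ``candidates`` is a list of (protein_id, rna_id) or ``"all"`` for
    the full cross product.  A sequence that cannot be encoded (e.g. no
    valid k-mer window) causes its pairs to be skipped with a warning
    and recorded in ``network.skipped``; the run itself never fails on
    one bad sequence.  The result does not depend on candidate order
    beyond edge listing order.
    """
    prot_by_id = {r.id: r for r in proteins}
    rna_by_id = {r.id: r for r in rnas}
    if candidates == "all":
        cand = [(p, r) for p in prot_by_id for r in rna_by_id]
    else:
        cand = list(candidates)
    net = InteractionNetwork(
        proteins=list(prot_by_id), rnas=list(rna_by_id), threshold=threshold
    )
    vec_cache: dict[str, np.ndarray] = {}
    rows: list[np.ndarray] = []
    kept: list[tuple[str, str]] = []
    for pid, rid in cand:
        if pid not in prot_by_id:
            raise KeyError(f"unknown protein id {pid!r}")
        if rid not in rna_by_id:
            raise KeyError(f"unknown rna id {rid!r}")
        try:
            if pid not in vec_cache:
                vec_cache[pid] = encode_protein(prot_by_id[pid])
            if rid not in vec_cache:
                vec_cache[rid] = encode_rna(rna_by_id[rid])
            rows.append(np.concatenate([vec_cache[pid], vec_cache[rid]]))
            kept.append((pid, rid))
        except EncodingError as exc:
            warnings.warn(f"skipping pair ({pid}, {rid}): {exc}")
            net.skipped.append((pid, rid))
    if rows:
        probs = predict_proba(model, np.vstack(rows))
        for (pid, rid), p in zip(kept, probs):
            net.edges.append(Edge(pid, rid, float(p), bool(p >= threshold)))
    net.validate()
    return net


def recall_on_known(
    network: InteractionNetwork, known_pairs: Iterable[tuple[str, str]]
) -> tuple[float, dict[str, int]]:
    """Fraction of known interactions recovered, with probability bands.

    Returns (recall, bands) where bands counts known pairs predicted
    with probability >= 0.80 and in [threshold, 0.80).  Raises if a
    known pair was never scored in the network.
    """
    emap = network.edge_map()
    known = list(known_pairs)
    if not known:
        raise ValueError("known pair list is empty")
    missing = [k for k in known if k not in emap]
    if missing:
        raise KeyError(f"known pairs absent from network: {missing[:5]}")
    hits = [emap[k] for k in known]
    recovered = sum(e.predicted_label for e in hits)
    bands = {
        "ge_0.80": sum(e.probability >= 0.80 for e in hits),
        f"{network.threshold:.2f}_0.80": sum(
            network.threshold <= e.probability < 0.80 for e in hits
        ),
    }
    return recovered / len(known), bands


def hub_summary(
    network: InteractionNetwork, min_degree: int = 2
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Protein and RNA hubs: nodes with predicted-positive degree >= min_degree.

    Each side is sorted by degree descending, ties broken by id.
    """
    pdeg: dict[str, int] = {}
    rdeg: dict[str, int] = {}
    for e in network.positive_edges():
        pdeg[e.protein_id] = pdeg.get(e.protein_id, 0) + 1
        rdeg[e.rna_id] = rdeg.get(e.rna_id, 0) + 1

    def hubs(deg: dict[str, int]) -> list[tuple[str, int]]:
        return sorted(
            ((n, d) for n, d in deg.items() if d >= min_degree),
            key=lambda t: (-t[1], t[0]),
        )

    return hubs(pdeg), hubs(rdeg)


def to_networkx(network: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    for pid in network.proteins:
        g.add_node(pid, bipartite="protein")
    for rid in network.rnas:
        g.add_node(rid, bipartite="rna")
    for e in network.edges:
        g.add_edge(
            e.protein_id,
            e.rna_id,
            probability=e.probability,
            predicted_label=int(e.predicted_label),
        )
    return g


def export_network(
    network: InteractionNetwork,
    path: str | Path,
    format: Literal["tsv", "sif", "graphml"] = "tsv",
) -> None:
    """Write the edge list as TSV, SIF (relation "rpi"), or GraphML."""
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("protein_id\trna_id\tprobability\tlabel\n")
            for e in network.edges:
                fh.write(
                    f"{e.protein_id}\t{e.rna_id}\t{e.probability:.6f}\t"
                    f"{int(e.predicted_label)}\n"
                )
    elif format == "sif":
        with path.open("w") as fh:
            for e in network.positive_edges():
                fh.write(f"{e.protein_id}\trpi\t{e.rna_id}\n")
    elif format == "graphml":
        nx.write_graphml(to_networkx(network), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def load_network_tsv(path: str | Path, threshold: float = 0.50) -> InteractionNetwork:
    """Re-import a TSV edge table written by :func:`export_network`."""
    path = Path(path)
    net = InteractionNetwork(threshold=threshold)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "rna_id", "probability", "label"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            pid, rid, prob, label = line.rstrip("\n").split("\t")
            if pid not in net.proteins:
                net.proteins.append(pid)
            if rid not in net.rnas:
                net.rnas.append(rid)
            net.edges.append(Edge(pid, rid, float(prob), bool(int(label))))
    net.validate()
    return net
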