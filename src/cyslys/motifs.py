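"""Grouping proximal Cys-Lys pairs into motifs.

Proximal pairs within one protein form a bipartite graph (Cys nodes vs Lys
nodes, an edge per proximal pair). Its connected components are the motif
units; each component is classified by how many cysteines and lysines it
contains:

==============  ===========================
(|Cys|, |Lys|)  motif class
==============  ===========================
(1, 1)          Cys1:Lys1
(>1, 1)         Cysx:Lys1
(1, >1)         Cys1:Lysx
(>1, >1)        Cysx:Lysx
==============  ===========================

Connected components make the four classes mutually exclusive and exhaustive
over proximal pairs — any per-residue neighborhood convention would count a
pair in several motifs when neighborhoods overlap. The per-residue (ego
network) view is still available as a report via :func:`ego_degree_report`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .proximity import CysLysPair

__all__ = [
    "MotifComponent",
    "build_components",
    "classify_motif",
    "filter_modified_components",
    "motif_summary",
    "ego_degree_report",
]

MOTIF_CLASSES = ("Cys1:Lys1", "Cysx:Lys1", "Cys1:Lysx", "Cysx:Lysx")


@dataclass
class MotifComponent:
    """A connected set of mutually proximal Cys/Lys residues in one protein."""

    protein_id: str
    cys_indices: frozenset[int]
    lys_indices: frozenset[int]
    motif_class: str
    contains_modified: bool
    member_pairs: tuple[CysLysPair, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.member_pairs)


def classify_motif(n_cys: int, n_lys: int) -> str:
    """Motif class from the component's Cys and Lys counts."""
    if n_cys < 1 or n_lys < 1:
        raise ValueError("a motif component must contain >= 1 Cys and >= 1 Lys")
    if n_cys == 1 and n_lys == 1:
        return "Cys1:Lys1"
    if n_lys == 1:
        return "Cysx:Lys1"
    if n_cys == 1:
        return "Cys1:Lysx"
    return "Cysx:Lysx"


def build_components(pairs: Iterable[CysLysPair]) -> list[MotifComponent]:
    """Connected components of the proximal-pair bipartite graph, per protein.

    Only pairs with ``proximal=True`` contribute edges; every proximal pair
    ends up in exactly one component. ``contains_modified`` is true iff any
    member residue carries a significant modification (per the pair flags set
    by :func:`cyslys.proximity.mark_modified`). Output is sorted by
    (protein_id, min cys index, min lys index) so reruns are deterministic.
    """
    by_protein: dict[str, list[CysLysPair]] = {}
    for p in pairs:
        if p.proximal:
            by_protein.setdefault(p.protein_id, []).append(p)
    components: list[MotifComponent] = []
    for pid in sorted(by_protein):
        g = nx.Graph()
        edge_pairs: dict[tuple, CysLysPair] = {}
        for p in by_protein[pid]:
            u = ("C", p.cys.residue_index)
            v = ("K", p.lys.residue_index)
            g.add_edge(u, v)
            edge_pairs[(u, v)] = p
        for nodes in nx.connected_components(g):
            cys = frozenset(i for t, i in nodes if t == "C")
            lys = frozenset(i for t, i in nodes if t == "K")
            member = tuple(
                sorted(
                    (
                        p
                        for (u, v), p in edge_pairs.items()
                        if u in nodes and v in nodes
                    ),
                    key=lambda p: (p.cys.residue_index, p.lys.residue_index),
                )
            )
            components.append(
                MotifComponent(
                    protein_id=pid,
                    cys_indices=cys,
                    lys_indices=lys,
                    motif_class=classify_motif(len(cys), len(lys)),
                    contains_modified=any(
                        p.cys_modified or p.lys_modified for p in member
                    ),
                    member_pairs=member,
                )
            )
    components.sort(
        key=lambda c: (c.protein_id, min(c.cys_indices), min(c.lys_indices))
    )
    return components


def filter_modified_components(
    components: Iterable[MotifComponent],
) -> list[MotifComponent]:
    """Components containing >= 1 significantly modified residue."""
    return [c for c in components if c.contains_modified]


def motif_summary(components: Iterable[MotifComponent]) -> dict:
    """Per-class component and pair counts (the motif-table accounting)."""
    comps = Counter()
    pair_counts = Counter()
    for c in components:
        comps[c.motif_class] += 1
        pair_counts[c.motif_class] += c.n_pairs
    return {
        cls: {"n_components": comps[cls], "n_pairs": pair_counts[cls]}
        for cls in MOTIF_CLASSES
    }


def ego_degree_report(pairs: Iterable[CysLysPair]) -> dict:
    """Per-residue proximal-degree view (how many counterparts each residue
    has). Informational only — overlapping neighborhoods mean these counts
    double-count pairs, which is why classification uses components instead."""
    cys_deg: Counter = Counter()
    lys_deg: Counter = Counter()
    for p in pairs:
        if p.proximal:
            cys_deg[(p.protein_id, p.cys.residue_index)] += 1
            lys_deg[(p.protein_id, p.lys.residue_index)] += 1
    return {
        "cys_degree": {f"{pid}:C{idx}": n for (pid, idx), n in sorted(cys_deg.items())},
        "lys_degree": {f"{pid}:K{idx}": n for (pid, idx), n in sorted(lys_deg.items())},
    }
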