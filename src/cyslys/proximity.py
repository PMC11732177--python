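"""Cys-Lys pair enumeration, confidence filtering and distance stratification.

Within each monomeric structure every cysteine is paired with every lysine
(all-vs-all; protein chains at these sizes do not warrant a spatial index).
The pair distance is the Euclidean separation of the thiol sulfur (SG) and the
epsilon-amine nitrogen (NZ). Pairs are then filtered on model confidence:

* both residues need pLDDT >= 70 (strictly-below-70 residues are excluded);
* the pair's predicted aligned error must be <= 15 A. PAE is intrinsically
  pairwise, so the default filter uses the symmetrized PAE of the two residues;
  a per-residue mode (mean PAE of each residue against the whole chain) is
  available as an alternative interpretation.

A pair is *proximal* when it passes quality and its distance is <= 15 A
(inclusive) — the separation at which thiol-to-amine acetyl transfer is
considered geometrically feasible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .structure_io import PAEMatrix, ResidueSite

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityConfig",
    "CysLysPair",
    "enumerate_pairs",
    "apply_quality_filters",
    "mark_modified",
    "nearest_counterpart_histogram",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class ProximityConfig:
    """Thresholds for pairing and confidence filtering.

    distance_threshold and pae_max in Angstrom, plddt_min in percent.
    ``distance_bin_edges`` defines the nearest-counterpart histogram bins in
    2.5 A steps anchored at 5 A (the range where the Lys-proximity effect on
    Cys redox is strongest); distances past the last edge land in an overflow
    bin.
    """

    distance_threshold: float = 15.0
    plddt_min: float = 70.0
    pae_max: float = 15.0
    pae_mode: Literal["pair", "residue"] = "pair"
    distance_bin_edges: tuple[float, ...] = (0.0, 5.0, 7.5, 10.0, 12.5, 15.0)

    def __post_init__(self) -> None:
        if min(self.distance_threshold, self.plddt_min, self.pae_max) <= 0:
            raise ValueError("all thresholds must be positive")
        edges = self.distance_bin_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    def bin_labels(self) -> list[str]:
        edges = self.distance_bin_edges
        labels = [f"[{a:g}, {b:g})" for a, b in zip(edges, edges[1:])]
        labels.append(f"> {edges[-1]:g}")
        return labels


@dataclass(frozen=True)
class CysLysPair:
    """One intra-protein Cys-Lys pair with its geometry and confidence."""

    cys: ResidueSite
    lys: ResidueSite
    distance: float
    pair_pae: float
    residue_pae_max: float = float("nan")
    passes_quality: bool | None = None
    proximal: bool | None = None
    cys_modified: bool = False
    lys_modified: bool = False

    @property
    def protein_id(self) -> str:
        return self.cys.protein_id

    @property
    def min_plddt(self) -> float:
        return min(self.cys.plddt, self.lys.plddt)


def enumerate_pairs(
    cys_sites: Sequence[ResidueSite],
    lys_sites: Sequence[ResidueSite],
    pae: PAEMatrix | None = None,
) -> list[CysLysPair]:
    """All |cys| x |lys| pairs of one protein, with distances and PAE.

    Distance is the Euclidean SG-NZ separation. ``pair_pae`` is the symmetrized
    PAE at the two residue indices; ``residue_pae_max`` the larger of the two
    residues' whole-chain mean PAE (used by the per-residue filter mode). With
    no PAE matrix both are 0, i.e. the PAE filter passes trivially.
    """
    proteins = {s.protein_id for s in cys_sites} | {s.protein_id for s in lys_sites}
    if len(proteins) > 1:
        raise ValueError(f"sites span multiple proteins: {sorted(proteins)}")
    pairs = []
    for c in cys_sites:
        c_xyz = np.asarray(c.coord)
        for k in lys_sites:
            d = float(np.linalg.norm(c_xyz - np.asarray(k.coord)))
            if pae is not None:
                ppae = pae.sym(c.residue_index, k.residue_index)
                rpae = max(pae.row_mean(c.residue_index), pae.row_mean(k.residue_index))
            else:
                ppae, rpae = 0.0, 0.0
            pairs.append(
                CysLysPair(cys=c, lys=k, distance=d, pair_pae=ppae, residue_pae_max=rpae)
            )
    return pairs


def apply_quality_filters(
    pairs: Iterable[CysLysPair], config: ProximityConfig = ProximityConfig()
) -> tuple[list[CysLysPair], Counter]:
    """Set ``passes_quality`` / ``proximal`` on every pair; tally exclusions.

    A pair passes quality iff both residues have pLDDT >= plddt_min and the
    configured PAE statistic is <= pae_max. The tally counts pairs removed by
    low pLDDT, by high PAE, and by both (disjoint categories).
    """
    out, tally = [], Counter()
    for p in pairs:
        plddt_ok = p.min_plddt >= config.plddt_min
        pae_stat = p.pair_pae if config.pae_mode == "pair" else p.residue_pae_max
        pae_ok = pae_stat <= config.pae_max
        quality = plddt_ok and pae_ok
        if not plddt_ok and not pae_ok:
            tally["low_plddt_and_high_pae"] += 1
        elif not plddt_ok:
            tally["low_plddt"] += 1
        elif not pae_ok:
            tally["high_pae"] += 1
        out.append(
            replace(
                p,
                passes_quality=quality,
                proximal=quality and p.distance <= config.distance_threshold,
            )
        )
    tally["passing"] = sum(p.passes_quality for p in out)
    return out, tally


def mark_modified(
    pairs: Iterable[CysLysPair],
    significant_sites: Iterable,
) -> list[CysLysPair]:
    """Set cys_modified / lys_modified from significant PTM sites.

    ``significant_sites`` are ModSites (or anything with protein_id,
    residue_index, mod_class, significant); only sites with significant=True
    count. Redox sites mark cysteines, acetyl sites mark lysines.
    """
    redox = set()
    acetyl = set()
    for s in significant_sites:
        if not getattr(s, "significant", False):
            continue
        key = (s.protein_id, s.residue_index)
        (redox if s.mod_class == "redox" else acetyl).add(key)
    return [
        replace(
            p,
            cys_modified=(p.protein_id, p.cys.residue_index) in redox,
            lys_modified=(p.protein_id, p.lys.residue_index) in acetyl,
        )
        for p in pairs
    ]


@dataclass
class NearestCounterpartResult:
    """Binned nearest-counterpart distances per modification class."""

    counts: dict[str, dict[str, int]]
    fraction_within: dict[str, float]
    unpaired: list[tuple[str, str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "fraction_within_threshold": self.fraction_within,
            "sites_without_counterpart": [list(u) for u in self.unpaired],
        }


def nearest_counterpart_histogram(
    significant_sites: Iterable,
    pairs: Iterable[CysLysPair],
    config: ProximityConfig = ProximityConfig(),
) -> NearestCounterpartResult:
    """Distance from each significant site to its nearest counterpart residue.

    For every significant redox Cys, the minimum distance to ANY quality-passing
    Lys in the same protein (modified or not); symmetrically for every
    significant acetyl Lys vs any Cys. Distances are binned by the configured
    edges plus an overflow bin; sites in proteins with no quality-passing
    counterpart go to the overflow bin and are logged. Also reports, per class,
    the fraction of sites whose nearest counterpart is within the proximity
    threshold.
    """
    nearest_from_cys: dict[tuple[str, int], float] = {}
    nearest_from_lys: dict[tuple[str, int], float] = {}
    for p in pairs:
        if not p.passes_quality:
            continue
        ck = (p.protein_id, p.cys.residue_index)
        lk = (p.protein_id, p.lys.residue_index)
        nearest_from_cys[ck] = min(nearest_from_cys.get(ck, np.inf), p.distance)
        nearest_from_lys[lk] = min(nearest_from_lys.get(lk, np.inf), p.distance)

    labels = config.bin_labels()
    edges = config.distance_bin_edges
    counts = {
        "redox_cys": {lab: 0 for lab in labels},
        "acetyl_lys": {lab: 0 for lab in labels},
    }
    totals = Counter()
    within = Counter()
    unpaired = []

    def bin_label(d: float) -> str:
        for a, b, lab in zip(edges, edges[1:], labels):
            if a <= d < b:
                return lab
        return labels[-1]

    for s in significant_sites:
        if not getattr(s, "significant", False):
            continue
        key = (s.protein_id, s.residue_index)
        if s.mod_class == "redox":
            cls, lookup = "redox_cys", nearest_from_cys
        elif s.mod_class == "acetyl":
            cls, lookup = "acetyl_lys", nearest_from_lys
        else:
            continue
        totals[cls] += 1
        d = lookup.get(key, np.inf)
        if not np.isfinite(d):
            counts[cls][labels[-1]] += 1
            unpaired.append((s.protein_id, s.mod_class, s.residue_index))
            logger.info(
                "significant %s site %s:%d has no quality-passing counterpart",
                s.mod_class, s.protein_id, s.residue_index,
            )
            continue
        counts[cls][bin_label(d)] += 1
        if d <= config.distance_threshold:
            within[cls] += 1

    fraction = {
        cls: (within[cls] / totals[cls]) if totals[cls] else float("nan")
        for cls in counts
    }
    return NearestCounterpartResult(counts=counts, fraction_within=fraction, unpaired=unpaired)


def pairs_to_frame(pairs: Iterable[CysLysPair]):
    """Pairs as a tidy frame with the package's fixed column order."""
    import pandas as pd

    rows = [
        {
            "protein_id": p.protein_id,
            "cys_index": p.cys.residue_index,
            "lys_index": p.lys.residue_index,
            "distance": p.distance,
            "pair_pae": p.pair_pae,
            "min_plddt": p.min_plddt,
            "passes_quality": p.passes_quality,
            "proximal": p.proximal,
            "cys_modified": p.cys_modified,
            "lys_modified": p.lys_modified,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "cys_index", "lys_index", "distance", "pair_pae",
            "min_plddt", "passes_quality", "proximal", "cys_modified", "lys_modified",
        ],
    )
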