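"""Quantitative PTM site tables: parsing, peptide-to-site stratification,
significance calling, and offline ortholog cross-referencing.

The upstream quantitation produces peptide-level rows (one peptide may carry
several modified residues) with a signed log2 fold change (alcohol vs control)
and a multiple-testing-corrected p-value. Downstream structural analysis works
at single-residue resolution, so multi-site peptides are stratified into
individual sites: the fold changes of all peptides covering a site are
averaged, and the smallest corrected p-value among them is kept.

Significance uses the dual threshold |log2FC| >= 0.58 (~1.5-fold) and
p_corr <= 0.05, both comparisons inclusive.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModClass",
    "PeptideRecord",
    "ModSite",
    "SignificanceThresholds",
    "parse_site_table",
    "stratify_peptides",
    "call_significance",
    "ortholog_crossref",
    "sites_to_frame",
]

ModClass = Literal["acetyl", "redox"]

#: Residue type each modification class lives on.
MOD_RESIDUE = {"acetyl": "K", "redox": "C"}

DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "positions": "positions",
    "log2fc": "log2fc",
    "p_corr": "p_corr",
}

# Position tokens: "K229", "C63", or a bare integer; multiple sites separated
# by ';' or ','.
_POSITION_RE = re.compile(r"^[A-Za-z]?(\d+)$")


@dataclass(frozen=True)
class PeptideRecord:
    """One quantified peptide with >= 1 modified residue positions."""

    protein_id: str
    mod_positions: tuple[tuple[int, str], ...]
    log2fc: float
    p_corr: float

    def __post_init__(self) -> None:
        if not self.mod_positions:
            raise ValueError("peptide record needs at least one modified position")
        if not 0.0 <= self.p_corr <= 1.0:
            raise ValueError(f"p_corr out of [0, 1]: {self.p_corr}")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc: {self.log2fc}")


@dataclass(frozen=True)
class ModSite:
    """A single modified residue aggregated over its contributing peptides."""

    protein_id: str
    residue_index: int
    residue_type: str
    mod_class: str
    log2fc: float
    p_corr: float
    n_peptides: int = 1
    significant: bool | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        if MOD_RESIDUE[self.mod_class] != self.residue_type:
            raise ValueError(
                f"{self.mod_class} site on residue type {self.residue_type!r}"
            )


@dataclass(frozen=True)
class SignificanceThresholds:
    """Dual significance rule: p_corr <= p_threshold AND |log2FC| >= fc_threshold."""

    p_threshold: float = 0.05
    fc_threshold: float = 0.58

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass(frozen=True)
class RowRejection:
    row: int
    reason: str


def _parse_positions(token: str) -> tuple[int, ...]:
    token = str(token).strip()
    if not token or token.lower() == "nan":
        raise ValueError("empty position field")
    out = []
    for part in re.split(r"[;,]", token):
        part = part.strip()
        m = _POSITION_RE.match(part)
        if m is None:
            raise ValueError(f"unparseable position token {part!r}")
        out.append(int(m.group(1)))
    return tuple(out)


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def parse_site_table(
    path: str | Path,
    mod_class: ModClass,
    column_map: Mapping[str, str] | None = None,
    linear_fc: bool = False,
) -> tuple[list[PeptideRecord], list[RowRejection]]:
    """Parse a delimited peptide table into :class:`PeptideRecord` rows.

    ``column_map`` maps the logical names (protein_id, positions, log2fc,
    p_corr) onto the file's headers. Rows that cannot be parsed are returned
    as logged rejections, not silently dropped. With ``linear_fc=True`` the
    fold-change column is taken as a (signed) linear ratio and converted to
    log2: log2(|fc|) with the original sign.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_delimited(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise KeyError(
            f"{path.name}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )
    records: list[PeptideRecord] = []
    rejections: list[RowRejection] = []
    for i, row in df.iterrows():
        try:
            positions = _parse_positions(row[cols["positions"]])
            fc = float(row[cols["log2fc"]])
            if linear_fc:
                if fc == 0:
                    raise ValueError("zero linear fold change")
                fc = math.copysign(math.log2(abs(fc)), fc)
            rec = PeptideRecord(
                protein_id=str(row[cols["protein_id"]]).strip(),
                mod_positions=tuple((p, mod_class) for p in positions),
                log2fc=fc,
                p_corr=float(row[cols["p_corr"]]),
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(row=int(i), reason=str(exc)))
            logger.warning("%s row %d rejected: %s", path.name, i, exc)
            continue
        records.append(rec)
    return records, rejections


def stratify_peptides(records: Iterable[PeptideRecord]) -> list[ModSite]:
    """Stratify multi-site peptides into single-residue sites.

    Each (protein, residue, mod class) site aggregates every peptide that
    covers it: log2FC is the arithmetic mean of the contributing peptides'
    signed values and p_corr is their minimum. Output is sorted by
    (protein_id, mod_class, residue_index).
    """
    groups: dict[tuple[str, int, str], list[PeptideRecord]] = {}
    for rec in records:
        for pos, mod_class in rec.mod_positions:
            groups.setdefault((rec.protein_id, pos, mod_class), []).append(rec)
    sites = [
        ModSite(
            protein_id=pid,
            residue_index=pos,
            residue_type=MOD_RESIDUE[mod_class],
            mod_class=mod_class,
            log2fc=float(np.mean([r.log2fc for r in recs])),
            p_corr=float(min(r.p_corr for r in recs)),
            n_peptides=len(recs),
        )
        for (pid, pos, mod_class), recs in groups.items()
    ]
    sites.sort(key=lambda s: (s.protein_id, s.mod_class, s.residue_index))
    return sites


def call_significance(
    site: ModSite, thresholds: SignificanceThresholds = SignificanceThresholds()
) -> ModSite:
    """Return the site with ``significant`` and ``direction`` set.

    Both comparisons are inclusive: p_corr <= p_threshold and
    |log2FC| >= fc_threshold.
    """
    significant = (
        site.p_corr <= thresholds.p_threshold
        and abs(site.log2fc) >= thresholds.fc_threshold
    )
    direction = "up" if site.log2fc >= 0 else "down"
    return replace(site, significant=significant, direction=direction)


def ortholog_crossref(
    murine_sites: Iterable[ModSite],
    mapping: pd.DataFrame,
    human_acetylome: pd.DataFrame,
    mapping_cols: tuple[str, str] = ("mouse_protein_id", "human_protein_id"),
    human_cols: tuple[str, str] = ("human_protein_id", "direction"),
) -> pd.DataFrame:
    """Join murine sites to a human acetylome through an ortholog table.

    Inner join: murine site -> ortholog mapping -> human direction. Returns a
    frame with both species' protein ids plus the human acetylation direction
    (column ``human_direction``); murine
    proteins with no mapping are logged. Duplicate mappings of one mouse
    protein to conflicting human ids raise, listing the offenders.
    """
    mouse_col, human_col = mapping_cols
    h_id_col, h_dir_col = human_cols
    # one mouse id may map to several human paralogs (fan-out is legitimate);
    # only byte-identical duplicated rows are collapsed
    mapping = mapping.drop_duplicates([mouse_col, human_col])

    sites_df = sites_to_frame(murine_sites)
    if sites_df.empty:
        logger.warning("ortholog cross-reference: no murine sites supplied")
        return pd.DataFrame(
            columns=["protein_id", "residue_index", "mod_class", human_col, "human_direction"]
        )
    unmapped = set(sites_df["protein_id"]) - set(mapping[mouse_col])
    for pid in sorted(unmapped):
        logger.info("no ortholog mapping for %s", pid)
    if mapping.empty:
        logger.warning("ortholog mapping table is empty; join is empty")
    joined = sites_df.merge(
        mapping[[mouse_col, human_col]], left_on="protein_id", right_on=mouse_col
    )
    human = human_acetylome[[h_id_col, h_dir_col]].drop_duplicates()
    conflicts = human.groupby(h_id_col)[h_dir_col].nunique()
    bad = list(conflicts[conflicts > 1].index)
    if bad:
        raise ValueError(f"conflicting human directions for: {bad}")
    human = human.rename(columns={h_dir_col: "human_direction"})
    joined = joined.merge(human, left_on=human_col, right_on=h_id_col)
    drop = [c for c in (mouse_col,) if c != "protein_id"]
    if h_id_col != human_col:
        drop.append(h_id_col)
    return joined.drop(columns=drop).reset_index(drop=True)


def sites_to_frame(sites: Iterable[ModSite]) -> pd.DataFrame:
    """Site collection as a tidy frame with the package's fixed column order."""
    rows = [
        {
            "protein_id": s.protein_id,
            "residue_type": s.residue_type,
            "residue_index": s.residue_index,
            "mod_class": s.mod_class,
            "log2fc": s.log2fc,
            "p_corr": s.p_corr,
            "significant": s.significant,
            "direction": s.direction,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "residue_type",
            "residue_index",
            "mod_class",
            "log2fc",
            "p_corr",
            "significant",
            "direction",
        ],
    )
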