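"""Fisher's exact tests and odds ratios for Cys-redox / Lys-acetylation
crosstalk.

Two analyses share the machinery:

* **Protein level** — proteins are divided into four mutually exclusive
  groups (both modification types significant, acetyl only, redox only,
  neither); the induced 2x2 asks whether the two modification types co-occur
  on the same proteins more often than chance.
* **Pair level** — restricted to proximal Cys-Lys pairs; rows split pairs by
  whether the Cys carries a significant redox change, columns by whether the
  Lys is significantly acetylated/deacetylated, so the odds ratio quantifies
  enrichment of Lys acetylation next to a modified Cys.

The reported odds ratio is the sample (cross-product) OR ad/bc; when any cell
is zero the Haldane-Anscombe corrected form (each cell + 0.5) is reported and
flagged. The two-sided p-value is the classical Fisher convention: the sum of
hypergeometric probabilities, at fixed margins, of every table at most as
probable as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "ORResult",
    "build_protein_groups",
    "build_pair_contingency",
    "fisher_exact_or",
    "PROTEIN_GROUPS",
]

PROTEIN_GROUPS = ("both", "acetyl_only", "cys_only", "neither")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts with rows = exposure, columns = outcome.

    Layout: [[a, b], [c, d]] with a = exposed & outcome, b = exposed & no
    outcome, c = unexposed & outcome, d = unexposed & no outcome.
    """

    a: int
    b: int
    c: int
    d: int
    row_label: str = "exposure"
    col_label: str = "outcome"

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with exact two-sided p for one 2x2 table."""

    or_value: float
    p_two_sided: float
    table: ContingencyTable2x2
    correction_applied: bool


def build_protein_groups(
    protein_ids: Iterable[str], sites: Iterable
) -> tuple[dict[str, str], ContingencyTable2x2]:
    """Label every protein in the analyzed universe and build the 2x2.

    A protein is "both" if it has >= 1 significant acetyl site AND >= 1
    significant redox site, "acetyl_only"/"cys_only" with exactly one type,
    else "neither" (including proteins whose sites all failed significance).
    The 2x2 is [[both, acetyl_only], [cys_only, neither]].
    """
    universe = sorted(set(protein_ids))
    if not universe:
        raise ValueError("empty protein universe")
    has_acetyl, has_redox = set(), set()
    for s in sites:
        if not getattr(s, "significant", False):
            continue
        (has_acetyl if s.mod_class == "acetyl" else has_redox).add(s.protein_id)
    labels = {}
    for pid in universe:
        ac, rx = pid in has_acetyl, pid in has_redox
        labels[pid] = (
            "both" if ac and rx else "acetyl_only" if ac else "cys_only" if rx else "neither"
        )
    n = {g: sum(1 for v in labels.values() if v == g) for g in PROTEIN_GROUPS}
    table = ContingencyTable2x2(
        a=n["both"], b=n["acetyl_only"], c=n["cys_only"], d=n["neither"],
        row_label="significant acetyl-Lys on protein",
        col_label="significant redox Cys on protein",
    )
    return labels, table


def build_pair_contingency(pairs: Iterable) -> ContingencyTable2x2:
    """2x2 over proximal pairs: Cys modified (rows) x Lys acetylated (columns).

    Each proximal pair is counted exactly once. Raises on an empty proximal
    pair set (a degenerate run with nothing to test).
    """
    a = b = c = d = 0
    for p in pairs:
        if not p.proximal:
            continue
        if p.cys_modified:
            if p.lys_modified:
                a += 1
            else:
                b += 1
        else:
            if p.lys_modified:
                c += 1
            else:
                d += 1
    if a + b + c + d == 0:
        raise ValueError("no proximal pairs: cannot build pair-level contingency table")
    return ContingencyTable2x2(
        a=a, b=b, c=c, d=d,
        row_label="Cys redox-modified",
        col_label="Lys acetylated",
    )


def fisher_exact_or(table: ContingencyTable2x2) -> ORResult:
    """Fisher's exact two-sided test plus the sample odds ratio.

    OR = ad/bc; with any zero cell the Haldane-Anscombe corrected OR
    ((a+.5)(d+.5))/((b+.5)(c+.5)) is reported and ``correction_applied`` set.
    The p-value sums hypergeometric probabilities of all same-margin tables no
    more probable than the observed one (ties included up to a 1e-7 relative
    tolerance, the convention scipy implements).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        or_value = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        or_value = (a * d) / (b * c)
        corrected = False
    p = float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])
    return ORResult(
        or_value=float(or_value),
        p_two_sided=min(p, 1.0),
        table=table,
        correction_applied=corrected,
    )


def crosstalk_report(
    analyses: Mapping[str, tuple[ContingencyTable2x2, str]]
) -> dict:
    """JSON-ready report: analysis name -> table, OR, p, universe description."""
    out = {}
    for name, (table, universe) in analyses.items():
        res = fisher_exact_or(table)
        out[name] = {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d,
                      "rows": table.row_label, "cols": table.col_label},
            "odds_ratio": res.or_value,
            "p_two_sided": res.p_two_sided,
            "correction_applied": res.correction_applied,
            "universe": universe,
        }
    return out
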