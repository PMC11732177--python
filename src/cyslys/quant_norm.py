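"""Spike-in normalization cascade and differential testing for acetyl-peptide
abundances.

Three stages, in fixed order:

1. **Retention-time standard (Procal) stage** — per-sample scalar factors from
   the summed abundance of spiked retention-time standard peptides; corrects
   run-to-run instrument variability.
2. **Acetyl-BSA stage** — per-sample scalar factors from the summed abundance
   of spiked acetylated-BSA peptides, computed on the already standard-corrected
   table; corrects immunoprecipitation / sample-prep variability.
3. **GPQ stage** — per-(protein, sample) factors from a general protein
   quantitation (label-free protein abundance) table, anchored to a named
   reference sample; corrects protein-loading differences so acetyl-peptide
   changes reflect stoichiometry rather than protein abundance.

Differential testing is an unpaired two-sample t-test (pooled variance by
default, Welch optional) with Benjamini-Hochberg correction across features.

Tables are pandas DataFrames with features as rows and samples as columns;
missing abundances are NaN and are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "spike_in_factors",
    "gpq_adjust",
    "differential_test",
    "bh_correct",
    "normalize_cascade",
]


def spike_in_factors(
    table: pd.DataFrame, standard_ids: Iterable[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample scalar normalization from a set of spike-in standard features.

    factor_s = mean_over_samples(standard sum) / standard_sum(s). Every feature
    (standards included) in sample s is multiplied by factor_s, so after
    rescaling the standard sums are equal across samples. The cross-sample
    mean anchor only sets the absolute scale and cancels in all downstream
    ratios.
    """
    standard_ids = [s for s in standard_ids if s in table.index]
    if not standard_ids:
        raise ValueError("no spike-in standard features found in the table")
    sums = table.loc[standard_ids].sum(axis=0, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"zero spike-in standard sum in sample(s): {list(zero.index)}"
        )
    factors = sums.mean() / sums
    return factors, table.mul(factors, axis=1)


def gpq_adjust(
    acetyl_table: pd.DataFrame,
    feature_protein: Mapping[str, str],
    gpq_table: pd.DataFrame,
    reference_sample: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein/sample-specific loading adjustment of acetyl-peptide abundances.

    factor(p, s) = GPQ(p, reference) / GPQ(p, s); each acetyl feature mapped to
    protein p is multiplied by factor(p, s) in sample s. ``gpq_table`` must
    already be standard-corrected. Returns the adjusted table and a per-feature
    status frame: features whose protein has no GPQ value in a sample are left
    unadjusted there ("no_gpq"); a zero GPQ against nonzero acetyl signal
    flags the feature "zero_gpq" and its value is set to NaN (excluded from
    statistics).
    """
    if reference_sample not in gpq_table.columns:
        raise KeyError(f"reference sample {reference_sample!r} not in GPQ table")
    adjusted = acetyl_table.copy().astype(float)
    status_rows = []
    for feat in acetyl_table.index:
        protein = feature_protein.get(feat)
        status = {"feature": feat, "protein": protein}
        if protein is None or protein not in gpq_table.index:
            status["status"] = "no_gpq_protein"
            logger.info("feature %s left unadjusted: protein %s lacks GPQ", feat, protein)
            status_rows.append(status)
            continue
        ref = gpq_table.at[protein, reference_sample]
        flags = []
        for s in acetyl_table.columns:
            val = gpq_table.at[protein, s] if s in gpq_table.columns else np.nan
            if pd.isna(val):
                flags.append("no_gpq")
                continue
            if val == 0:
                if pd.notna(adjusted.at[feat, s]) and adjusted.at[feat, s] != 0:
                    adjusted.at[feat, s] = np.nan
                    flags.append("zero_gpq")
                continue
            adjusted.at[feat, s] *= ref / val
        status["status"] = ";".join(sorted(set(flags))) or "adjusted"
        status_rows.append(status)
    return adjusted, pd.DataFrame(status_rows)


@dataclass
class DifferentialResult:
    """Per-feature t-test results plus the features skipped and why."""

    table: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)


def differential_test(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str = "control",
    group_b: str = "alcohol",
    equal_var: bool = True,
) -> DifferentialResult:
    """Unpaired two-sample t-test per feature, group_b vs group_a.

    Pooled-variance form by default; ``equal_var=False`` gives Welch. Features
    with fewer than two non-missing values in either group are skipped and
    logged. Two groups with zero variance and equal means get p = 1 by
    convention. The result table carries t, df, p, log2fc (log2 of the group-b
    to group-a mean ratio) and BH-corrected p (see :func:`bh_correct`).
    """
    a_cols = [s for s, g in groups.items() if g == group_a and s in table.columns]
    b_cols = [s for s, g in groups.items() if g == group_b and s in table.columns]
    if not a_cols or not b_cols:
        raise ValueError(f"both groups need samples; got {len(a_cols)} vs {len(b_cols)}")
    rows, skipped = [], []
    for feat in table.index:
        a = table.loc[feat, a_cols].dropna().to_numpy(dtype=float)
        b = table.loc[feat, b_cols].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            skipped.append((feat, f"<2 values per group ({len(a)} vs {len(b)})"))
            logger.info("feature %s skipped: insufficient replication", feat)
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
            logger.info("feature %s: zero variance, equal means; p = 1", feat)
        else:
            res = stats.ttest_ind(b, a, equal_var=equal_var)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        with np.errstate(divide="ignore"):
            log2fc = (
                float(np.log2(b.mean() / a.mean()))
                if a.mean() > 0 and b.mean() > 0
                else np.nan
            )
        rows.append({"feature": feat, "t": t, "df": df, "p": p, "log2fc": log2fc})
    out = pd.DataFrame(rows, columns=["feature", "t", "df", "p", "log2fc"])
    if len(out):
        out["p_corr"] = bh_correct(out["p"].tolist())
    else:
        out["p_corr"] = []
    return DifferentialResult(table=out.set_index("feature"), skipped=skipped)


def bh_correct(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_cascade(
    acetyl_table: pd.DataFrame,
    procal_ids: Iterable[str],
    bsa_ids: Iterable[str],
    feature_protein: Mapping[str, str],
    gpq_table: pd.DataFrame,
    gpq_procal_ids: Iterable[str],
    reference_sample: str,
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade in its fixed order: standards -> acetyl-BSA -> GPQ.

    The GPQ table receives its own standard correction before protein factors
    are formed. Returns the adjusted biological-feature table (spike-in rows
    dropped) and a record of every factor applied.
    """
    procal_ids = list(procal_ids)
    bsa_ids = list(bsa_ids)
    procal_factors, stage1 = spike_in_factors(acetyl_table, procal_ids)
    bsa_factors, stage2 = spike_in_factors(stage1, bsa_ids)
    gpq_factors, gpq_corrected = spike_in_factors(gpq_table, list(gpq_procal_ids))
    gpq_biological = gpq_corrected.drop(index=list(gpq_procal_ids), errors="ignore")
    biological = stage2.drop(index=procal_ids + bsa_ids, errors="ignore")
    adjusted, gpq_status = gpq_adjust(
        biological, feature_protein, gpq_biological, reference_sample
    )
    record = {
        "procal_factors": procal_factors,
        "bsa_factors": bsa_factors,
        "gpq_procal_factors": gpq_factors,
        "gpq_status": gpq_status,
        "reference_sample": reference_sample,
    }
    return adjusted, record
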