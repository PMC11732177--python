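"""Synthetic structures, confidence tracks and PTM/abundance tables with known
ground truth.

The generator emulates the inputs of the real study — AlphaFold-DB-style
monomeric models with per-residue pLDDT and pairwise PAE, plus quantitative
acetylome / Cys-redox site tables — at desk scale, with every planted quantity
recorded in a truth ledger so each pipeline stage can be checked against its
design:

* **Geometry** — Cys/Lys residues sit on a jittered 3D lattice whose spacing
  is twice the proximity threshold, so no accidental sub-threshold contacts
  arise; designated pairs are planted at exact requested distances by placing
  the Lys NZ at an axis-aligned offset from the Cys SG (axis-aligned so the
  distance survives the 3-decimal mmCIF coordinate precision exactly).
* **Confidence** — pLDDT mixes a high-confidence component with a controlled
  low-confidence fraction below the 70 cutoff; PAE grows with sequence
  separation from a near-diagonal mean to a far mean that straddles the 15 A
  cutoff.
* **Crosstalk** — each Cys is redox-modified with a base rate; a Lys with at
  least one proximal modified Cys is acetylated with probability p1 where
  odds(p1) = true_or x odds(p0), otherwise with p0. Significant sites draw
  log2FC / corrected p beyond the dual threshold, null sites inside it, with
  optional label noise.
* **Abundances** — lognormal peptide tables with planted per-sample injection
  and prep distortions and per-protein loading distortions that the
  normalization cascade provably removes, plus planted differential peptides.

Everything is driven by one integer seed; identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (
    PAEMatrix,
    ProteinStructure,
    ResidueSite,
    read_alphafold_cif,
    read_pae_json,
    write_pae_json,
    write_structure_cif,
)
from .crosstalk_stats import build_pair_contingency, fisher_exact_or

__all__ = [
    "SimConfig",
    "simulate_structures",
    "simulate_ptm_sites",
    "simulate_quant_tables",
    "recover_or",
    "acetyl_prob_from_or",
]

_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the real study where it states values (significance
    thresholds via the pipeline, n = 5 animals per group, pair-level odds
    ratio near 1.9, 70/15 confidence cutoffs straddled) and proteome-realistic
    choices elsewhere (Cys ~2.5 % and Lys ~6.5 % of residues; pLDDT centred in
    the high-confidence band with a 15 % low-confidence tail).
    """

    seed: int = 0
    n_proteins: int = 20
    residues_per_protein: int = 80
    cys_fraction: float = 0.025
    lys_fraction: float = 0.065
    # geometry: fraction of lysines planted proximal to a random cysteine,
    # at distances uniform on [4, 14.5] A (3-decimal precision)
    planted_proximal_rate: float = 0.5
    plddt_mean: float = 88.0
    plddt_sd: float = 6.0
    plddt_low_fraction: float = 0.15
    pae_near_mean: float = 4.0
    pae_far_mean: float = 18.0
    pae_noise_sd: float = 1.0
    true_or: float = 1.9
    base_acetyl_rate: float = 0.3
    base_redox_rate: float = 0.5
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.6
    null_log2fc_sd: float = 0.2
    label_noise: float = 0.0
    n_control: int = 5
    n_alcohol: int = 5

    def __post_init__(self) -> None:
        for name in ("cys_fraction", "lys_fraction", "base_acetyl_rate", "base_redox_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")


def acetyl_prob_from_or(p0: float, true_or: float) -> float:
    """p1 such that odds(p1) = true_or * odds(p0)."""
    odds = true_or * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


@dataclass
class PlantedPair:
    cys_index: int
    lys_index: int
    distance: float


@dataclass
class StructureTruth:
    """Per-protein planted ground truth."""

    protein_id: str
    cys_indices: list[int]
    lys_indices: list[int]
    planted_pairs: list[PlantedPair]
    plddt: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "cys_indices": self.cys_indices,
            "lys_indices": self.lys_indices,
            "planted_pairs": [dataclasses.asdict(p) for p in self.planted_pairs],
            "plddt": {str(k): v for k, v in self.plddt.items()},
        }


def _plddt_draw(rng: np.random.Generator, config: SimConfig) -> float:
    if rng.random() < config.plddt_low_fraction:
        v = rng.uniform(40.0, 69.9)
    else:
        v = float(np.clip(rng.normal(config.plddt_mean, config.plddt_sd), 70.0, 100.0))
    # B-factor column precision is 2 decimals; fix it at generation time so the
    # 70 % cutoff is applied to exactly the value the parser will see
    return round(v, 2)


def _simulate_one_structure(
    protein_id: str,
    rng: np.random.Generator,
    config: SimConfig,
    planted: list[tuple[int, int, float]] | None,
) -> tuple[ProteinStructure, PAEMatrix, StructureTruth]:
    n = config.residues_per_protein
    n_cys = max(1, round(config.cys_fraction * n))
    n_lys = max(1, round(config.lys_fraction * n))
    indices = rng.choice(np.arange(1, n + 1), size=n_cys + n_lys, replace=False)
    cys_idx = sorted(int(i) for i in indices[:n_cys])
    lys_idx = sorted(int(i) for i in indices[n_cys:])

    plddt = {i: _plddt_draw(rng, config) for i in range(1, n + 1)}

    # lattice spacing = 2x proximity threshold + margin; jitter << spacing
    spacing = 32.0
    side = int(np.ceil((n_cys + n_lys) ** (1 / 3))) + 1
    cells = [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
    order = rng.permutation(len(cells))
    coords: dict[int, np.ndarray] = {}
    for slot, idx in enumerate(cys_idx + lys_idx):
        cx, cy, cz = cells[order[slot]]
        jitter = rng.uniform(-1.0, 1.0, size=3)
        pos = np.array([cx, cy, cz], float) * spacing + jitter
        coords[idx] = np.round(pos, 3)

    if planted is None:
        planted = []
        n_plant = round(config.planted_proximal_rate * n_lys)
        chosen_lys = rng.choice(lys_idx, size=min(n_plant, n_lys), replace=False)
        for k in sorted(int(x) for x in chosen_lys):
            c = int(rng.choice(cys_idx))
            d = round(float(rng.uniform(4.0, 14.5)), 3)
            planted.append((c, k, d))
    seen = set()
    planted_pairs = []
    for c, k, d in planted:
        if c not in cys_idx or k not in lys_idx:
            raise ValueError(f"planted pair ({c}, {k}) not among Cys/Lys indices")
        if k in seen:
            raise ValueError(f"Lys {k} planted twice; geometry would be inconsistent")
        seen.add(k)
        axis = _AXES[rng.integers(0, 6)]
        coords[k] = np.round(coords[c] + axis * d, 3)
        planted_pairs.append(PlantedPair(c, k, float(d)))

    residues = []
    for i in range(1, n + 1):
        if i in coords:
            aa = "C" if i in cys_idx else "K"
            residues.append((i, aa, tuple(float(x) for x in coords[i]), plddt[i]))
        else:
            residues.append((i, "A", None, plddt[i]))

    sites = [
        ResidueSite(
            protein_id=protein_id,
            residue_index=i,
            aa=aa,
            atom_name="SG" if aa == "C" else "NZ",
            coord=coord,
            plddt=pl,
        )
        for i, aa, coord, pl in residues
        if coord is not None
    ]
    structure = ProteinStructure(
        protein_id=protein_id,
        model_id=f"AF-{protein_id}-F1",
        sites=sites,
        plddt_track=plddt,
        length=n,
    )

    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) / max(n - 1, 1)
    pae_vals = (
        config.pae_near_mean
        + (config.pae_far_mean - config.pae_near_mean) * sep
        + rng.normal(0.0, config.pae_noise_sd, size=(n, n))
    )
    np.fill_diagonal(pae_vals, 0.0)
    pae = PAEMatrix(protein_id=protein_id, values=np.round(np.clip(pae_vals, 0.0, 31.75), 2))

    truth = StructureTruth(
        protein_id=protein_id,
        cys_indices=cys_idx,
        lys_indices=lys_idx,
        planted_pairs=planted_pairs,
        plddt=plddt,
    )
    return structure, pae, truth


def simulate_structures(
    config: SimConfig,
    out_dir: str | Path | None = None,
    planted: dict[str, list[tuple[int, int, float]]] | None = None,
) -> tuple[list[ProteinStructure], dict[str, PAEMatrix], list[StructureTruth]]:
    """Simulate a batch of monomeric structures with confidence tracks.

    With ``out_dir`` set, every model is written to mmCIF + PAE JSON and read
    back through the real parsers, so the returned objects have passed through
    the same file path the pipeline uses; otherwise in-memory objects are
    returned directly. ``planted`` optionally fixes the planted (cys, lys,
    distance) list per protein id (SYN0000, SYN0001, ...).
    """
    rng = np.random.default_rng(config.seed)
    structures: list[ProteinStructure] = []
    paes: dict[str, PAEMatrix] = {}
    truths: list[StructureTruth] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(config.n_proteins):
        pid = f"SYN{i:04d}"
        requested = planted.get(pid) if planted else None
        structure, pae, truth = _simulate_one_structure(pid, rng, config, requested)
        if out_path is not None:
            cif = out_path / f"AF-{pid}-F1-model.cif"
            pae_file = out_path / f"AF-{pid}-F1-pae.json"
            residues = [
                (
                    idx,
                    next((s.aa for s in structure.sites if s.residue_index == idx), "A"),
                    next(
                        (s.coord for s in structure.sites if s.residue_index == idx),
                        None,
                    ),
                    structure.plddt_track[idx],
                )
                for idx in sorted(structure.plddt_track)
            ]
            write_structure_cif(pid, residues, cif, model_id=structure.model_id)
            write_pae_json(pae, pae_file)
            structure = read_alphafold_cif(cif, protein_id=pid)
            pae = read_pae_json(pae_file, n_expected=structure.length, protein_id=pid)
        structures.append(structure)
        paes[pid] = pae
        truths.append(truth)
    if out_path is not None:
        ledger = {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "proteins": [t.to_dict() for t in truths],
        }
        (out_path / "truth_ledger.json").write_text(json.dumps(ledger, indent=1))
    return structures, paes, truths


def _exposed_lysines(
    truths: list[StructureTruth],
    paes: dict[str, PAEMatrix],
    redox_truth: dict[tuple[str, int], bool],
    config: SimConfig,
    distance_threshold: float = 15.0,
    plddt_min: float = 70.0,
    pae_max: float = 15.0,
) -> set[tuple[str, int]]:
    """Lysines with >= 1 quality-passing planted proximal modified Cys."""
    exposed = set()
    for t in truths:
        pae = paes[t.protein_id]
        for pp in t.planted_pairs:
            if pp.distance > distance_threshold:
                continue
            if not redox_truth.get((t.protein_id, pp.cys_index), False):
                continue
            if min(t.plddt[pp.cys_index], t.plddt[pp.lys_index]) < plddt_min:
                continue
            if pae.sym(pp.cys_index, pp.lys_index) > pae_max:
                continue
            exposed.add((t.protein_id, pp.lys_index))
    return exposed


def _draw_site_stats(
    rng: np.random.Generator, config: SimConfig, modified: bool, sign: float
) -> tuple[float, float]:
    if modified:
        mag = max(0.6, rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd))
        return round(sign * mag, 4), round(float(rng.uniform(0.0005, 0.045)), 5)
    return (
        round(float(rng.normal(0.0, config.null_log2fc_sd)), 4),
        round(float(rng.uniform(0.06, 0.95)), 5),
    )


def simulate_ptm_sites(
    truths: list[StructureTruth],
    paes: dict[str, PAEMatrix],
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Acetylome and Cys-redox site tables consistent with the planted geometry.

    Each Cys is redox-modified with ``base_redox_rate``. Each Lys with at
    least one quality-passing proximal modified Cys is acetylated with
    probability p1, where odds(p1) = true_or x odds(base_acetyl_rate);
    otherwise with the base rate. Modified sites draw significant log2FC and
    corrected p, null sites non-significant ones; ``label_noise`` flips a
    site's drawn statistics with that probability. Returns peptide-style
    tables (columns protein_id, positions, log2fc, p_corr) plus the truth map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    redox_truth: dict[tuple[str, int], bool] = {}
    for t in truths:
        for c in t.cys_indices:
            redox_truth[(t.protein_id, c)] = bool(rng.random() < config.base_redox_rate)
    exposed = _exposed_lysines(truths, paes, redox_truth, config)
    p1 = acetyl_prob_from_or(config.base_acetyl_rate, config.true_or)
    acetyl_truth: dict[tuple[str, int], bool] = {}
    for t in truths:
        for k in t.lys_indices:
            p = p1 if (t.protein_id, k) in exposed else config.base_acetyl_rate
            acetyl_truth[(t.protein_id, k)] = bool(rng.random() < p)

    redox_rows, acetyl_rows = [], []
    for t in truths:
        for c in t.cys_indices:
            modified = redox_truth[(t.protein_id, c)]
            observed = modified ^ (rng.random() < config.label_noise)
            fc, p = _draw_site_stats(rng, config, observed, sign=1.0)
            redox_rows.append(
                {"protein_id": t.protein_id, "positions": f"C{c}", "log2fc": fc, "p_corr": p}
            )
        for k in t.lys_indices:
            modified = acetyl_truth[(t.protein_id, k)]
            observed = modified ^ (rng.random() < config.label_noise)
            fc, p = _draw_site_stats(rng, config, observed, sign=1.0)
            acetyl_rows.append(
                {"protein_id": t.protein_id, "positions": f"K{k}", "log2fc": fc, "p_corr": p}
            )
    truth = {
        "redox": {f"{p}:{i}": v for (p, i), v in sorted(redox_truth.items())},
        "acetyl": {f"{p}:{i}": v for (p, i), v in sorted(acetyl_truth.items())},
        "exposed_lysines": sorted(f"{p}:{i}" for p, i in exposed),
        "p1": p1,
    }
    return pd.DataFrame(acetyl_rows), pd.DataFrame(redox_rows), truth


def simulate_quant_tables(
    config: SimConfig,
    n_peptides: int = 200,
    n_quant_proteins: int = 40,
    n_differential: int = 20,
    differential_log2fc: float = 1.5,
    injection_sd: float = 0.3,
    prep_sd: float = 0.3,
    loading_sd: float = 0.25,
    peptide_noise_sd: float = 0.1,
    n_standards: int = 10,
) -> dict:
    """Raw abundance matrices with spike-in standards and planted distortions.

    Returns a dict with the acetyl-peptide table (standards embedded), the GPQ
    protein table (with its own standard rows), the id sets, the
    feature->protein map, the sample->group map, the reference sample, and a
    truth ledger of every planted distortion and differential peptide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = [f"C{i+1}" for i in range(config.n_control)] + [
        f"E{i+1}" for i in range(config.n_alcohol)
    ]
    groups = {s: ("control" if s.startswith("C") else "alcohol") for s in samples}
    reference_sample = samples[-1]

    injection = {s: float(np.exp(rng.normal(0, injection_sd))) for s in samples}
    injection_gpq = {s: float(np.exp(rng.normal(0, injection_sd))) for s in samples}
    prep = {s: float(np.exp(rng.normal(0, prep_sd))) for s in samples}

    proteins = [f"QP{i:03d}" for i in range(n_quant_proteins)]
    loading = {
        (p, s): float(np.exp(rng.normal(0, loading_sd))) for p in proteins for s in samples
    }

    peptides = [f"pep{i:04d}" for i in range(n_peptides)]
    pep_protein = {f: proteins[i % n_quant_proteins] for i, f in enumerate(peptides)}
    differential = set(rng.choice(peptides, size=n_differential, replace=False).tolist())

    procal_ids = [f"PROCAL{i:02d}" for i in range(n_standards)]
    bsa_ids = [f"ACBSA{i:02d}" for i in range(n_standards)]
    base = {f: float(np.exp(rng.normal(np.log(1e6), 1.0))) for f in peptides}
    std_base = {f: float(np.exp(rng.normal(np.log(1e5), 0.2))) for f in procal_ids + bsa_ids}
    gbase = {p: float(np.exp(rng.normal(np.log(1e7), 0.8))) for p in proteins}

    acetyl = pd.DataFrame(index=procal_ids + bsa_ids + peptides, columns=samples, dtype=float)
    for s in samples:
        for f in procal_ids:
            acetyl.at[f, s] = std_base[f] * injection[s]
        for f in bsa_ids:
            acetyl.at[f, s] = std_base[f] * injection[s] * prep[s]
        for f in peptides:
            effect = (
                2.0**differential_log2fc
                if (f in differential and groups[s] == "alcohol")
                else 1.0
            )
            noise = float(np.exp(rng.normal(0, peptide_noise_sd))) if peptide_noise_sd else 1.0
            acetyl.at[f, s] = (
                base[f] * injection[s] * prep[s] * loading[(pep_protein[f], s)] * effect * noise
            )

    gpq_procal_ids = [f"GPQPROCAL{i:02d}" for i in range(n_standards)]
    gstd_base = {f: float(np.exp(rng.normal(np.log(1e5), 0.2))) for f in gpq_procal_ids}
    gpq = pd.DataFrame(index=gpq_procal_ids + proteins, columns=samples, dtype=float)
    for s in samples:
        for f in gpq_procal_ids:
            gpq.at[f, s] = gstd_base[f] * injection_gpq[s]
        for p in proteins:
            gpq.at[p, s] = gbase[p] * injection_gpq[s] * loading[(p, s)]

    return {
        "acetyl_table": acetyl,
        "gpq_table": gpq,
        "procal_ids": procal_ids,
        "bsa_ids": bsa_ids,
        "gpq_procal_ids": gpq_procal_ids,
        "feature_protein": pep_protein,
        "groups": groups,
        "reference_sample": reference_sample,
        "truth": {
            "injection": injection,
            "injection_gpq": injection_gpq,
            "prep": prep,
            "loading": {f"{p}|{s}": v for (p, s), v in loading.items()},
            "differential": sorted(differential),
            "differential_log2fc": differential_log2fc,
        },
    }


@dataclass(frozen=True)
class _SimplePair:
    """Minimal pair record for large-scale odds-ratio simulation (geometry
    bypassed; the statistical path downstream of pair construction is real)."""

    proximal: bool
    cys_modified: bool
    lys_modified: bool


def recover_or(
    n_pairs: int,
    true_or: float,
    p0: float,
    seed_list: list[int],
    base_redox_rate: float = 0.5,
) -> dict:
    """Monte-Carlo recovery of the pair-level odds ratio.

    Per seed: draw ``n_pairs`` independent proximal pairs (Cys modified with
    ``base_redox_rate``; Lys acetylated with p1 next to a modified Cys, p0
    otherwise), run the real contingency + Fisher machinery, and collect the
    estimated OR. Reports the estimates, their median and the central 95 %.
    """
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100 for a meaningful recovery check")
    p1 = acetyl_prob_from_or(p0, true_or)
    estimates = []
    for seed in seed_list:
        rng = np.random.default_rng(seed)
        cys_mod = rng.random(n_pairs) < base_redox_rate
        p_acetyl = np.where(cys_mod, p1, p0)
        lys_mod = rng.random(n_pairs) < p_acetyl
        pairs = [
            _SimplePair(True, bool(c), bool(k)) for c, k in zip(cys_mod, lys_mod)
        ]
        res = fisher_exact_or(build_pair_contingency(pairs))
        estimates.append(res.or_value)
    est = np.array(estimates)
    return {
        "estimates": est.tolist(),
        "median": float(np.median(est)),
        "ci95": [float(np.quantile(est, 0.025)), float(np.quantile(est, 0.975))],
        "true_or": true_or,
        "n_pairs": n_pairs,
    }
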