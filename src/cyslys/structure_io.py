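"""Reading AlphaFold-style structure models and PAE matrices.

AlphaFold DB distributes one mmCIF model per protein (single chain, per-atom
B-factor column carrying the per-residue pLDDT confidence) plus a JSON file
with the n x n predicted aligned error (PAE) matrix. This module parses both
into light in-memory records and pulls out the two functional atoms the
downstream proximity analysis needs: the cysteine thiol sulfur (SG) and the
lysine epsilon-amine nitrogen (NZ).

Residue numbering is the 1-based UniProt numbering AlphaFold DB models use;
all site labels elsewhere in the package (Cys63, Lys229, ...) live in this
frame. Only single-model, single-chain files are accepted — the analysis is
restricted to monomeric structures.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "ResidueSite",
    "ProteinStructure",
    "PAEMatrix",
    "StructureParseError",
    "UnsupportedInputError",
    "FUNCTIONAL_ATOMS",
    "read_alphafold_cif",
    "read_pae_json",
    "write_pae_json",
    "extract_cys_lys_sites",
    "write_structure_cif",
]

#: Functional atom per residue type: thiol sulfur for Cys, epsilon-amine
#: nitrogen for Lys.
FUNCTIONAL_ATOMS = {"C": "SG", "K": "NZ"}

_THREE_TO_ONE = {"CYS": "C", "LYS": "K"}


class StructureParseError(ValueError):
    """Malformed structure or PAE input; the message names the offending record."""


class UnsupportedInputError(ValueError):
    """Structurally valid input outside the supported scope (e.g. multi-chain)."""


@dataclass(frozen=True)
class ResidueSite:
    """One Cys or Lys residue reduced to its functional atom.

    ``plddt`` is AlphaFold's per-residue confidence in [0, 100], read from the
    B-factor column (constant across the atoms of a residue in AlphaFold DB
    models).
    """

    protein_id: str
    residue_index: int
    aa: str
    atom_name: str
    coord: tuple[float, float, float]
    plddt: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"plddt out of [0, 100]: {self.plddt}")
        expected = FUNCTIONAL_ATOMS.get(self.aa)
        if expected is None or self.atom_name != expected:
            raise ValueError(
                f"atom {self.atom_name!r} inconsistent with residue type {self.aa!r}"
            )
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinates: {self.coord}")


@dataclass(frozen=True)
class ExclusionRecord:
    """A residue that could not yield a ResidueSite, with the reason."""

    protein_id: str
    residue_index: int
    residue_name: str
    reason: str


@dataclass
class ProteinStructure:
    """A parsed single-chain model: Cys/Lys functional-atom sites plus the
    full-length pLDDT track."""

    protein_id: str
    model_id: str
    sites: list[ResidueSite]
    plddt_track: dict[int, float]
    length: int
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [s.residue_index for s in self.sites]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing and unique")
        if self.length != len(self.plddt_track):
            raise ValueError(
                f"length {self.length} != pLDDT track size {len(self.plddt_track)}"
            )

    @property
    def cys_sites(self) -> list[ResidueSite]:
        return [s for s in self.sites if s.aa == "C"]

    @property
    def lys_sites(self) -> list[ResidueSite]:
        return [s for s in self.sites if s.aa == "K"]


@dataclass
class PAEMatrix:
    """Predicted aligned error between residue pairs, in Angstrom.

    PAE is not symmetric as emitted by AlphaFold; :meth:`sym` exposes the
    symmetrized value (mean of the two orientations) used for pair filtering.
    Indices are 1-based residue numbers.
    """

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructureParseError(
                f"PAE matrix for {self.protein_id} is not square: {self.values.shape}"
            )
        if (self.values < 0).any():
            raise StructureParseError(f"negative PAE values for {self.protein_id}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def sym(self, i: int, j: int) -> float:
        """Symmetrized PAE between residues i and j (1-based)."""
        return 0.5 * (self.values[i - 1, j - 1] + self.values[j - 1, i - 1])

    def row_mean(self, i: int) -> float:
        """Mean PAE of residue i against all residues (1-based); a per-residue
        confidence summary used by the per-residue PAE filtering mode."""
        return float(self.values[i - 1].mean())


def _accession_from_model_id(model_id: str) -> str:
    m = re.match(r"AF-([A-Z0-9]+)-F\d+", model_id)
    return m.group(1) if m else model_id


def read_alphafold_cif(path: str | Path, protein_id: str | None = None) -> ProteinStructure:
    """Parse an AlphaFold-DB-style mmCIF file into a :class:`ProteinStructure`.

    One :class:`ResidueSite` is produced per Cys/Lys residue that carries its
    functional atom (SG / NZ); residues missing the atom are recorded in
    ``exclusions`` rather than silently dropped. pLDDT is read from the
    B-factor column. Multi-model or multi-chain files raise
    :class:`UnsupportedInputError`.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse mmCIF {path.name}: {exc}") from None
    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no model records")
    if len(st) > 1:
        raise UnsupportedInputError(f"{path.name}: {len(st)} models; expected 1")
    model = st[0]
    if len(model) != 1:
        raise UnsupportedInputError(
            f"{path.name}: {len(model)} chains; only single-chain monomers supported"
        )
    chain = model[0]

    model_id = st.name if st.name else path.stem
    if protein_id is None:
        protein_id = _accession_from_model_id(model_id)

    sites: list[ResidueSite] = []
    exclusions: list[ExclusionRecord] = []
    plddt_track: dict[int, float] = {}
    for residue in chain:
        seqid = residue.seqid.num
        if not residue:
            raise StructureParseError(
                f"{path.name}: residue {residue.name} {seqid} has no atoms"
            )
        plddt = float(residue[0].b_iso)
        if seqid in plddt_track:
            raise StructureParseError(
                f"{path.name}: duplicate residue index {seqid}"
            )
        plddt_track[seqid] = plddt
        aa = _THREE_TO_ONE.get(residue.name.upper())
        if aa is None:
            continue
        atom_name = FUNCTIONAL_ATOMS[aa]
        atom = residue.find_atom(atom_name, "*")
        if atom is None:
            exclusions.append(
                ExclusionRecord(protein_id, seqid, residue.name, f"missing {atom_name} atom")
            )
            continue
        sites.append(
            ResidueSite(
                protein_id=protein_id,
                residue_index=seqid,
                aa=aa,
                atom_name=atom_name,
                coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                plddt=plddt,
            )
        )
    return ProteinStructure(
        protein_id=protein_id,
        model_id=model_id,
        sites=sites,
        plddt_track=plddt_track,
        length=len(plddt_track),
        exclusions=exclusions,
    )


def read_pae_json(path: str | Path, n_expected: int | None = None,
                  protein_id: str = "") -> PAEMatrix:
    """Read a PAE matrix from the AlphaFold DB JSON dialect.

    Accepts either ``{"predicted_aligned_error": [[...]]}`` or the list-of-one
    wrapper AlphaFold DB v4 emits. A ``n_expected`` mismatch is a hard error:
    silent residue-index misalignment against the paired structure would
    corrupt every downstream distance/PAE lookup.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if len(payload) != 1:
            raise StructureParseError(f"{path.name}: expected a single PAE object")
        payload = payload[0]
    if "predicted_aligned_error" not in payload:
        raise StructureParseError(
            f"{path.name}: missing 'predicted_aligned_error' key"
        )
    mat = np.asarray(payload["predicted_aligned_error"], dtype=float)
    pae = PAEMatrix(protein_id=protein_id or path.stem, values=mat)
    if n_expected is not None and pae.n != n_expected:
        raise StructureParseError(
            f"{path.name}: PAE dimension {pae.n} != expected residue count {n_expected}"
        )
    return pae


def write_pae_json(pae: PAEMatrix, path: str | Path) -> None:
    """Write a PAE matrix in the AlphaFold DB v4 JSON dialect."""
    payload = [{"predicted_aligned_error": pae.values.tolist(),
                "max_predicted_aligned_error": float(pae.values.max(initial=0.0))}]
    Path(path).write_text(json.dumps(payload))


def extract_cys_lys_sites(
    structure: ProteinStructure,
) -> tuple[list[ResidueSite], list[ResidueSite]]:
    """Partition a structure's parsed sites into (cys_sites, lys_sites), each
    sorted by residue index. Empty partitions are allowed."""
    key = lambda s: s.residue_index
    return sorted(structure.cys_sites, key=key), sorted(structure.lys_sites, key=key)


_ONE_TO_THREE = {"C": "CYS", "K": "LYS", "A": "ALA", "G": "GLY"}


def write_structure_cif(
    protein_id: str,
    residues: Sequence[tuple[int, str, tuple[float, float, float] | None, float]],
    path: str | Path,
    model_id: str | None = None,
) -> None:
    """Write a minimal single-chain mmCIF model.

    ``residues`` is a sequence of (residue_index, one_letter_aa, functional_atom
    coord or None, plddt). Every residue gets a CA placeholder atom (offset from
    the functional atom, or standalone); Cys/Lys residues with a coordinate get
    their SG/NZ functional atom. B-factors carry pLDDT. Coordinates survive a
    round-trip to 3 decimal places (mmCIF precision). Used by the synthetic
    generator so that simulated structures exercise the real parser.
    """
    st = gemmi.Structure()
    st.name = model_id or f"AF-{protein_id}-F1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for index, aa, coord, plddt in residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "ALA")
        res.seqid = gemmi.SeqId(index, " ")
        if coord is None:
            base = (float(index), 0.0, 0.0)
        else:
            base = coord
        ca = gemmi.Atom()
        ca.name = "CA"
        ca.element = gemmi.Element("C")
        ca.pos = gemmi.Position(base[0] + 1.0, base[1] + 1.0, base[2])
        ca.b_iso = plddt
        ca.occ = 1.0
        res.add_atom(ca)
        if coord is not None and aa in FUNCTIONAL_ATOMS:
            atom = gemmi.Atom()
            atom.name = FUNCTIONAL_ATOMS[aa]
            atom.element = gemmi.Element("S" if aa == "C" else "N")
            atom.pos = gemmi.Position(*coord)
            atom.b_iso = plddt
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    doc.write_file(str(path))
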