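"""Shared fixtures: hand-written mmCIF texts and small object builders."""

from __future__ import annotations

import textwrap

import pytest

from cyslys.ptm_sites import ModSite
from cyslys.structure_io import ResidueSite

_CIF_HEADER = textwrap.dedent(
    """\
    data_{block}
    loop_
    _atom_site.group_PDB
    _atom_site.id
    _atom_site.type_symbol
    _atom_site.label_atom_id
    _atom_site.label_alt_id
    _atom_site.label_comp_id
    _atom_site.label_asym_id
    _atom_site.label_entity_id
    _atom_site.label_seq_id
    _atom_site.pdbx_PDB_ins_code
    _atom_site.Cartn_x
    _atom_site.Cartn_y
    _atom_site.Cartn_z
    _atom_site.occupancy
    _atom_site.B_iso_or_equiv
    _atom_site.auth_seq_id
    _atom_site.auth_asym_id
    _atom_site.pdbx_PDB_model_num
    """
)


def make_cif_text(block: str, atoms: list[tuple]) -> str:
    """atoms: (id, element, atom_name, comp, chain, seq, x, y, z, b)."""
    lines = [
        f"ATOM {i} {el} {name} . {comp} {ch} 1 {seq} ? "
        f"{x:.3f} {y:.3f} {z:.3f} 1.00 {b:.2f} {seq} {ch} 1"
        for (i, el, name, comp, ch, seq, x, y, z, b) in atoms
    ]
    return _CIF_HEADER.format(block=block) + "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_cif(tmp_path):
    """Cys1 (with SG), Ala2, Lys3 (with NZ): exactly two functional-atom sites."""
    text = make_cif_text(
        "AF-TEST1-F1",
        [
            (1, "C", "CA", "CYS", "A", 1, 0.0, 0.0, 0.0, 90.0),
            (2, "S", "SG", "CYS", "A", 1, 1.0, 1.0, 1.0, 90.0),
            (3, "C", "CA", "ALA", "A", 2, 5.0, 0.0, 0.0, 80.5),
            (4, "C", "CA", "LYS", "A", 3, 3.0, 4.0, 0.0, 95.25),
            (5, "N", "NZ", "LYS", "A", 3, 4.0, 5.0, 1.0, 95.25),
        ],
    )
    path = tmp_path / "AF-TEST1-F1-model.cif"
    path.write_text(text)
    return path


@pytest.fixture
def missing_sg_cif(tmp_path):
    """Cys1 lacks its SG atom; Lys2 is complete."""
    text = make_cif_text(
        "AF-TEST2-F1",
        [
            (1, "C", "CA", "CYS", "A", 1, 0.0, 0.0, 0.0, 88.0),
            (2, "C", "CA", "LYS", "A", 2, 3.0, 0.0, 0.0, 91.0),
            (3, "N", "NZ", "LYS", "A", 2, 3.0, 4.0, 0.0, 91.0),
        ],
    )
    path = tmp_path / "AF-TEST2-F1-model.cif"
    path.write_text(text)
    return path


@pytest.fixture
def two_chain_cif(tmp_path):
    text = make_cif_text(
        "AF-TEST3-F1",
        [
            (1, "C", "CA", "CYS", "A", 1, 0.0, 0.0, 0.0, 90.0),
            (2, "S", "SG", "CYS", "A", 1, 1.0, 0.0, 0.0, 90.0),
            (3, "C", "CA", "LYS", "B", 1, 9.0, 0.0, 0.0, 90.0),
            (4, "N", "NZ", "LYS", "B", 1, 9.0, 1.0, 0.0, 90.0),
        ],
    )
    path = tmp_path / "AF-TEST3-F1-model.cif"
    path.write_text(text)
    return path


def make_site(pid="P1", index=1, aa="C", coord=(0.0, 0.0, 0.0), plddt=90.0):
    return ResidueSite(
        protein_id=pid,
        residue_index=index,
        aa=aa,
        atom_name="SG" if aa == "C" else "NZ",
        coord=coord,
        plddt=plddt,
    )


def make_mod_site(pid="P1", index=1, mod_class="redox", log2fc=2.0, p_corr=0.01,
                  significant=True):
    return ModSite(
        protein_id=pid,
        residue_index=index,
        residue_type="C" if mod_class == "redox" else "K",
        mod_class=mod_class,
        log2fc=log2fc,
        p_corr=p_corr,
        significant=significant,
        direction="up" if log2fc >= 0 else "down",
    )
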