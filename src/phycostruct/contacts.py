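"""Chromophore-protein hydrogen bonds, hydrophobic contacts and pockets.

At the ~2.3 A resolution typical of phycobiliprotein crystal structures no
hydrogen positions exist, so hydrogen bonds are detected with the standard
heavy-atom criterion: a chromophore N/O/S within ``d_max`` of a protein
N/O/S.  Hydrophobic contacts pair apolar carbons (per-residue-type lists
shipped as data) and the binding pocket is the union of residues within a
cutoff of any chromophore atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .structure_io import (AtomRecord, Chromophore, LigandTable, Structure,
                           default_ligand_table)

POLAR_ELEMENTS = {"N", "O", "S"}
MAINCHAIN_ATOMS = {"N", "O", "C", "CA", "OXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class HBond:
    """One heavy-atom hydrogen bond between chromophore and protein."""

    chromophore_atom: str
    partner_chain: str
    partner_residue_number: int
    partner_residue_name: str
    partner_atom: str
    distance: float
    classification: str  # "mainchain" / "sidechain"

    @property
    def partner_label(self) -> str:
        return f"{self.partner_chain}/{self.partner_residue_name}{self.partner_residue_number}"


@dataclass
class ResidueContact:
    """A protein residue in contact with a chromophore."""

    chain_id: str
    residue_number: int
    residue_name: str
    min_distance: float
    contact_type: str  # "hbond" / "hydrophobic" / "both" / "proximal"

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}"


def _protein_atoms(structure: Structure) -> list[AtomRecord]:
    return [a for a in structure.atoms
            if not a.is_hetero and not a.is_water and a.element != "H"]


def _attachment_exclusion(chromophore: Chromophore,
                          table: LigandTable) -> set[tuple]:
    """Atom-pair keys of the covalent thioether bond, excluded from contacts."""
    if chromophore.attachment is None:
        return set()
    chain, num, _ = chromophore.attachment
    att_atom = table.attachment_atom(chromophore.ligand_code)
    return {(att_atom, chain, num, "SG")}


def hydrogen_bonds(chromophore: Chromophore, structure: Structure,
                   d_max: float = 3.5,
                   ligand_table: LigandTable | None = None) -> list[HBond]:
    """All chromophore-protein N/O/S pairs within ``d_max`` (heavy-atom only).

    The covalent cysteine thioether pair is excluded; so is the attachment
    cysteine SG generally, since its proximity to the ring-A substituents is
    covalent geometry, not hydrogen bonding.
    """
    table = ligand_table or default_ligand_table()
    excluded = _attachment_exclusion(chromophore, table)
    chrom_polar = [a for a in chromophore.atoms if a.element in POLAR_ELEMENTS]
    out: list[HBond] = []
    for pa in _protein_atoms(structure):
        if pa.element not in POLAR_ELEMENTS:
            continue
        for ca in chrom_polar:
            if (ca.atom_name, pa.chain_id, pa.residue_number, pa.atom_name) in excluded:
                continue
            if (chromophore.attachment is not None and pa.atom_name == "SG"
                    and (pa.chain_id, pa.residue_number) == chromophore.attachment[:2]):
                continue
            d = float(np.linalg.norm(ca.position - pa.position))
            if d <= d_max:
                out.append(HBond(
                    chromophore_atom=ca.atom_name,
                    partner_chain=pa.chain_id,
                    partner_residue_number=pa.residue_number,
                    partner_residue_name=pa.residue_name,
                    partner_atom=pa.atom_name,
                    distance=d,
                    classification=("mainchain" if pa.atom_name in MAINCHAIN_ATOMS
                                    else "sidechain"),
                ))
    out.sort(key=lambda h: (h.partner_chain, h.partner_residue_number,
                            h.partner_atom, h.chromophore_atom))
    return out


def hydrophobic_contacts(chromophore: Chromophore, structure: Structure,
                         d_max: float = 4.5,
                         ligand_table: LigandTable | None = None
                         ) -> list[ResidueContact]:
    """Residues with at least one apolar-carbon pair within ``d_max``."""
    table = ligand_table or default_ligand_table()
    apolar_names = set(table.apolar_atoms(chromophore.ligand_code))
    chrom_apolar = np.array([a.position for a in chromophore.atoms
                             if a.atom_name in apolar_names])
    if chrom_apolar.size == 0:
        return []
    tree = cKDTree(chrom_apolar)
    per_residue: dict[tuple, float] = {}
    names: dict[tuple, str] = {}
    for pa in _protein_atoms(structure):
        if pa.atom_name not in chemdata.apolar_atoms(pa.residue_name):
            continue
        d, _ = tree.query(pa.position)
        if d <= d_max:
            key = (pa.chain_id, pa.residue_number)
            per_residue[key] = min(per_residue.get(key, np.inf), float(d))
            names[key] = pa.residue_name
    return [ResidueContact(chain_id=k[0], residue_number=k[1],
                           residue_name=names[k], min_distance=v,
                           contact_type="hydrophobic")
            for k, v in sorted(per_residue.items())]


def binding_pocket(chromophore: Chromophore, structure: Structure,
                   d_max: float = 4.5,
                   hbond_d_max: float = 3.5,
                   ligand_table: LigandTable | None = None
                   ) -> list[ResidueContact]:
    """Union of residues within ``d_max`` of any chromophore atom.

    Each residue is annotated with its nearest approach and the contact
    type: hydrogen-bonding, hydrophobic, both, or merely proximal.
    """
    chrom_pts = np.array([a.position for a in chromophore.atoms])
    tree = cKDTree(chrom_pts)
    per_residue: dict[tuple, float] = {}
    names: dict[tuple, str] = {}
    for pa in _protein_atoms(structure):
        d, _ = tree.query(pa.position)
        if d <= d_max:
            key = (pa.chain_id, pa.residue_number)
            per_residue[key] = min(per_residue.get(key, np.inf), float(d))
            names[key] = pa.residue_name

    hb_keys = {(h.partner_chain, h.partner_residue_number)
               for h in hydrogen_bonds(chromophore, structure, hbond_d_max,
                                       ligand_table)}
    hp_keys = {(c.chain_id, c.residue_number)
               for c in hydrophobic_contacts(chromophore, structure, d_max,
                                             ligand_table)}
    out = []
    for key, dist in sorted(per_residue.items()):
        is_hb, is_hp = key in hb_keys, key in hp_keys
        ctype = ("both" if is_hb and is_hp else "hbond" if is_hb
                 else "hydrophobic" if is_hp else "proximal")
        out.append(ResidueContact(chain_id=key[0], residue_number=key[1],
                                  residue_name=names[key], min_distance=dist,
                                  contact_type=ctype))
    return out
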