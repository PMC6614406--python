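"""Coordinate-file I/O and bilin chromophore extraction.

This module builds a light, typed view of a crystal structure (atoms grouped
by chain, unit cell, space group) from PDB or mmCIF input, and locates the
covalently attached open-chain tetrapyrrole chromophores (phycocyanobilin and
relatives) together with their named pyrrole-ring and methine-bridge atom
groups.  Parsing and serialisation are delegated to :mod:`gemmi`; the typed
model keeps author chain/residue numbering so that positions quoted in the
phycobiliprotein literature (e.g. the conserved attachment cysteines at
alpha-84, beta-82 and beta-153) match directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: Conventional attachment-site class labels keyed by cysteine residue number.
ATTACHMENT_CLASSES = {84: "alpha84", 82: "beta82", 153: "beta153"}

#: Covalent-bond cutoff (Angstrom) for the thioether link between the
#: attachment cysteine SG and the ring-A substituent carbon.
ATTACHMENT_CUTOFF = 2.1


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed or serialised."""


# ---------------------------------------------------------------------------
# Typed model
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One non-hydrogen-aware atom record with author numbering."""

    atom_name: str
    element: str
    position: np.ndarray          # shape (3,), Angstrom
    chain_id: str
    residue_number: int           # author numbering
    residue_name: str
    is_hetero: bool = False
    occupancy: float = 1.0
    b_factor: float = 0.0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.atom_name}: empty element")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES


@dataclass
class CellParams:
    """Unit-cell parameters with space group and ASU multiplicity."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    z_asu_per_cell: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        """Unit-cell volume (Angstrom^3), general triclinic formula."""
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma).volume

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell, space_group: str) -> "CellParams":
        sg = gemmi.find_spacegroup_by_name(space_group) if space_group else None
        z = len(sg.operations()) if sg is not None else 1
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma,
                   space_group=space_group or "P 1", z_asu_per_cell=z)


@dataclass
class Structure:
    """Ordered atom collection with chain grouping and optional cell."""

    atoms: list[AtomRecord]
    entry_id: str = ""
    cell: CellParams | None = None

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.chain_id, []).append(atom)
        return out

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id)
        return list(seen)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by (chain, author residue number, insertion code)."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue_key, []).append(atom)
        return out

    def coordinates(self, atoms: Sequence[AtomRecord] | None = None) -> np.ndarray:
        pool = self.atoms if atoms is None else atoms
        if not pool:
            return np.zeros((0, 3))
        return np.stack([a.position for a in pool])

    def protein_atoms(self, chain_id: str | None = None) -> list[AtomRecord]:
        return [a for a in self.atoms
                if not a.is_hetero and (chain_id is None or a.chain_id == chain_id)]

    def hetero_atoms(self, include_water: bool = False) -> list[AtomRecord]:
        return [a for a in self.atoms
                if a.is_hetero and (include_water or not a.is_water)]


@dataclass
class Chromophore:
    """One covalently attached bilin with named ring/bridge atom groups.

    ``ring_atoms`` maps ring labels A-D to the five pyrrole atoms
    (N + 4 ring carbons); ``bridge_atoms`` maps AB/BC/CD to the methine
    carbon.  ``attachment`` records the cysteine the ring-A substituent
    carbon is bonded to, or ``None`` when no SG lies within covalent range.
    """

    ligand_code: str
    chain_id: str
    ligand_number: int
    atoms: list[AtomRecord]
    ring_atoms: dict[str, list[AtomRecord]] = field(default_factory=dict)
    bridge_atoms: dict[str, AtomRecord] = field(default_factory=dict)
    conjugated_atoms: list[AtomRecord] = field(default_factory=list)
    attachment: tuple[str, int, str] | None = None
    missing_atoms: list[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.chain_id}/{self.ligand_code}{self.ligand_number}"

    @property
    def is_complete(self) -> bool:
        return not self.missing_atoms

    @property
    def site_class(self) -> str:
        """Attachment-site class (alpha84 / beta82 / beta153 / cysN / unattached)."""
        if self.attachment is None:
            return "unattached"
        num = self.attachment[1]
        return ATTACHMENT_CLASSES.get(num, f"cys{num}")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


# ---------------------------------------------------------------------------
# Ligand naming table
# ---------------------------------------------------------------------------

class LigandTable:
    """Ring/bridge/torsion atom-name tables for bilin chemical components.

    The default table ships with the package; ``overrides`` (a mapping with
    the same shape, e.g. loaded from a user YAML file) take precedence per
    ligand code.
    """

    def __init__(self, overrides: Mapping | None = None) -> None:
        with resources.files("phycostruct._data").joinpath("ligands.yaml").open() as fh:
            self._table: dict = yaml.safe_load(fh)
        if overrides:
            for code, entry in overrides.items():
                self._table.setdefault(code, {}).update(entry)

    @classmethod
    def from_file(cls, path: str | Path) -> "LigandTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def codes(self) -> set[str]:
        return set(self._table)

    def entry(self, code: str) -> dict:
        try:
            return self._table[code]
        except KeyError:
            raise KeyError(f"no ring-naming table for ligand code {code!r}") from None

    def rings(self, code: str) -> dict[str, list[str]]:
        return self.entry(code)["rings"]

    def bridges(self, code: str) -> dict[str, str]:
        return self.entry(code)["bridges"]

    def conjugated(self, code: str) -> list[str]:
        return self.entry(code)["conjugated"]

    def attachment_atom(self, code: str) -> str:
        return self.entry(code)["attachment_atom"]

    def torsions(self, code: str) -> dict[str, dict[str, list[str]]]:
        return self.entry(code)["torsions"]

    def apolar_atoms(self, code: str) -> list[str]:
        return self.entry(code).get("apolar_atoms", [])


_DEFAULT_TABLE: LigandTable | None = None


def default_ligand_table() -> LigandTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = LigandTable()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {fmt!r} (expected pdb, mmcif or auto)")


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB/mmCIF file into a :class:`Structure`.

    Alternate conformations are reduced to the highest-occupancy conformer.
    A missing unit cell is not an error: ``cell`` is simply ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise StructureFormatError(f"{path.name}: no models present")
    model = st[0]
    for chain in model:
        for residue in chain:
            # keep one conformer per atom name: highest occupancy wins
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            het = residue.het_flag == "H"
            for atom in residue:
                if best[atom.name] is not atom:
                    continue
                atoms.append(AtomRecord(
                    atom_name=atom.name,
                    element=atom.element.name.upper() or "X",
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    is_hetero=het,
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=atom.b_iso,
                    insertion_code=(residue.seqid.icode or "").strip(),
                ))

    cell = None
    if st.cell is not None and st.cell.a > 1.0:  # gemmi uses a dummy 1 A cell when absent
        cell = CellParams.from_gemmi(st.cell, st.spacegroup_hm or "P 1")
    return Structure(atoms=atoms, entry_id=st.name or path.stem, cell=cell)


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Serialise to PDB (fixed-column v3.3; serials beyond 99999 in hybrid-36)."""
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if not structure.atoms:
        raise ValueError("refusing to write an empty structure")
    for atom in structure.atoms:
        if len(atom.atom_name) > 4:
            raise StructureFormatError(
                f"atom name {atom.atom_name!r} exceeds the 4-character PDB field")

    st = gemmi.Structure()
    st.name = structure.entry_id or "XXXX"
    if structure.cell is not None:
        c = structure.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        st.spacegroup_hm = c.space_group
    # gemmi's add_residue/add_chain/add_model copy their argument, so every
    # container must be fully populated before being added to its parent
    model = gemmi.Model("1")
    for chain_id, chain_atoms in Structure(structure.atoms).chains.items():
        chain = gemmi.Chain(chain_id)
        groups: list[tuple[tuple, list[AtomRecord]]] = []
        for a in chain_atoms:
            key = (a.residue_number, a.insertion_code, a.residue_name)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        for (num, icode, resname), group in groups:
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(num, icode or " ")
            residue.het_flag = "H" if group[0].is_hetero else "A"
            for a in group:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Chromophore extraction
# ---------------------------------------------------------------------------

def _nearest_cysteine_sg(structure: Structure, point: np.ndarray,
                         cutoff: float = ATTACHMENT_CUTOFF
                         ) -> tuple[str, int, str] | None:
    best = None
    best_d = cutoff
    for atom in structure.atoms:
        if atom.residue_name == "CYS" and atom.atom_name == "SG":
            d = float(np.linalg.norm(atom.position - point))
            if d <= best_d:
                best_d = d
                best = (atom.chain_id, atom.residue_number, atom.residue_name)
    return best


def extract_chromophores(structure: Structure,
                         ligand_codes: Iterable[str] = ("CYC",),
                         ligand_table: LigandTable | None = None,
                         ) -> list[Chromophore]:
    """Locate bilin heteroresidues and resolve their named atom groups.

    A chromophore with a missing named ring atom is returned flagged
    incomplete (``missing_atoms`` non-empty) so geometry stages can exclude
    it; a chromophore whose ring-A substituent carbon has no cysteine SG
    within covalent range gets ``attachment=None``.
    """
    table = ligand_table or default_ligand_table()
    codes = set(ligand_codes)
    out: list[Chromophore] = []
    for key, res_atoms in structure.residues().items():
        name = res_atoms[0].residue_name
        if name not in codes or not res_atoms[0].is_hetero:
            continue
        by_name = {a.atom_name: a for a in res_atoms}
        missing: list[str] = []
        ring_atoms: dict[str, list[AtomRecord]] = {}
        for ring, names in table.rings(name).items():
            got = [by_name[n] for n in names if n in by_name]
            if len(got) == len(names):
                ring_atoms[ring] = got
            else:
                missing.extend(n for n in names if n not in by_name)
        bridge_atoms = {}
        for bridge, bname in table.bridges(name).items():
            if bname in by_name:
                bridge_atoms[bridge] = by_name[bname]
            else:
                missing.append(bname)
        conj = [by_name[n] for n in table.conjugated(name) if n in by_name]

        attachment = None
        att_name = table.attachment_atom(name)
        if att_name in by_name:
            attachment = _nearest_cysteine_sg(structure, by_name[att_name].position)
        chrom = Chromophore(
            ligand_code=name,
            chain_id=key[0],
            ligand_number=key[1],
            atoms=list(res_atoms),
            ring_atoms=ring_atoms,
            bridge_atoms=bridge_atoms,
            conjugated_atoms=conj,
            attachment=attachment,
            missing_atoms=sorted(set(missing)),
        )
        if chrom.missing_atoms:
            logger.warning("chromophore %s incomplete: missing %s",
                           chrom.key, ", ".join(chrom.missing_atoms))
        out.append(chrom)
    out.sort(key=lambda c: (c.chain_id, c.ligand_number))
    return out
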