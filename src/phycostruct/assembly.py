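"""Assembly partitioning, inter-chromophore distances, burial and packing.

Phycocyanin assembles hierarchically — alpha-beta heterodimer ("monomer"),
(alpha-beta)3 trimer, (alpha-beta)6 hexamer — and excitation-energy transfer
between bilins only becomes efficient once oligomerisation brings
chromophores of neighbouring monomers within ~20-25 A.  This module infers
the assembly hierarchy from inter-chain contacts, tabulates the closest
centre-centre chromophore distances per assembly level and chromophore-pair
class, measures interface burial with a sphere-sampling solvent-accessible
surface (Shrake-Rupley-style), and computes the Matthews coefficient /
crystal solvent content from the unit cell and asymmetric-unit mass.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemdata
from .structure_io import AtomRecord, CellParams, Chromophore, Structure

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 4.5     # Angstrom, heavy-atom inter-chain contact
DISTANCE_CAP = 51.0      # Angstrom, reporting cap for the distance table
PROTEIN_VM_CONSTANT = 1.230  # A^3/Da, protein partial-specific volume constant

SITE_CLASSES = ("alpha84", "beta82", "beta153")
PAIR_CLASSES = (
    ("alpha84", "beta82"),
    ("beta82", "beta153"),
    ("beta153", "alpha84"),
    ("alpha84", "alpha84"),
    ("beta82", "beta82"),
    ("beta153", "beta153"),
)


def pair_class_label(a: str, b: str) -> str:
    return f"inter-{a}" if a == b else f"{a}-{b}"


# ---------------------------------------------------------------------------
# Assembly map
# ---------------------------------------------------------------------------

@dataclass
class AssemblyMap:
    """Chain grouping into alpha-beta monomers, trimers and the hexamer."""

    monomers: list[tuple[str, str]]          # (alpha chain, beta chain)
    trimers: list[list[int]] = field(default_factory=list)
    hexamer: list[int] = field(default_factory=list)

    def monomer_of_chain(self) -> dict[str, int]:
        out = {}
        for i, (a, b) in enumerate(self.monomers):
            out[a] = i
            out[b] = i
        return out


def _chain_contact_counts(structure: Structure, cutoff: float = CONTACT_CUTOFF
                          ) -> dict[tuple[str, str], int]:
    """Heavy-atom contact-pair counts for every chain pair (waters excluded)."""
    chains = {}
    for cid, atoms in structure.chains.items():
        pts = np.stack([a.position for a in atoms
                        if a.element != "H" and not a.is_water])
        chains[cid] = cKDTree(pts)
    counts = {}
    ids = sorted(chains)
    for a, b in itertools.combinations(ids, 2):
        counts[(a, b)] = int(chains[a].count_neighbors(chains[b], cutoff))
    return counts


def build_assembly_map(structure: Structure,
                       chromophores: list[Chromophore],
                       cutoff: float = CONTACT_CUTOFF) -> AssemblyMap:
    """Pair alpha and beta chains into monomers and group them into trimers.

    Chain type is inferred from the chromophore census (one bilin = alpha,
    two = beta; chains without bilins are ignored).  Monomers are paired by
    maximal inter-chain heavy-atom contact count; six-monomer structures are
    split into the two trimers maximising intra-trimer contacts (exhaustive
    over the 10 partitions).  All orderings and tie-breaks are lexicographic.
    """
    per_chain: dict[str, int] = {}
    for c in chromophores:
        per_chain[c.chain_id] = per_chain.get(c.chain_id, 0) + 1
    alphas = sorted(cid for cid, n in per_chain.items() if n == 1)
    betas = sorted(cid for cid, n in per_chain.items() if n == 2)
    if not alphas or not betas:
        raise ValueError("need at least one alpha-type and one beta-type chain")

    counts = _chain_contact_counts(structure, cutoff)

    def contact(a: str, b: str) -> int:
        return counts.get((min(a, b), max(a, b)), 0)

    # greedy maximum pairing, deterministic tie-break
    monomers: list[tuple[str, str]] = []
    free_a, free_b = list(alphas), list(betas)
    while free_a and free_b:
        best = max(((contact(a, b), a, b) for a in free_a for b in free_b),
                   key=lambda t: (t[0], [-ord(ch) for ch in t[1] + t[2]]))
        n, a, b = best
        ties = [(x, y) for x in free_a for y in free_b
                if contact(x, y) == n and (x, y) != (a, b)]
        if ties:
            logger.info("monomer pairing tie at %d contacts; chose (%s, %s) "
                        "lexicographically", n, a, b)
        monomers.append((a, b))
        free_a.remove(a)
        free_b.remove(b)
    monomers.sort()

    n_mono = len(monomers)
    trimers: list[list[int]] = []
    hexamer: list[int] = []
    if n_mono >= 3:
        def mono_contact(i: int, j: int) -> int:
            return sum(contact(x, y) for x in monomers[i] for y in monomers[j])

        if n_mono == 3:
            trimers = [[0, 1, 2]]
        elif n_mono == 6:
            best_part = None
            for combo in itertools.combinations(range(1, 6), 2):
                g1 = [0, *combo]
                g2 = [i for i in range(6) if i not in g1]
                score = (sum(mono_contact(i, j) for i, j in itertools.combinations(g1, 2))
                         + sum(mono_contact(i, j) for i, j in itertools.combinations(g2, 2)))
                key = (score, [-i for i in g1])
                if best_part is None or key > best_part[0]:
                    best_part = (key, [sorted(g1), sorted(g2)])
            trimers = sorted(best_part[1])
            hexamer = list(range(6))
        else:
            logger.warning("unsupported monomer count %d; no trimer grouping", n_mono)
    return AssemblyMap(monomers=monomers, trimers=trimers, hexamer=hexamer)


# ---------------------------------------------------------------------------
# Chromophore centres and the distance table
# ---------------------------------------------------------------------------

def chromophore_center(chromophore: Chromophore, mode: str = "conjugated") -> np.ndarray:
    """Unweighted centroid of the selected atom set (Angstrom)."""
    if mode == "conjugated":
        atoms = chromophore.conjugated_atoms
    elif mode == "all_atoms":
        atoms = chromophore.atoms
    elif mode == "ring_C":
        atoms = chromophore.ring_atoms.get("C", [])
    else:
        raise ValueError(f"unknown centre mode {mode!r}")
    if not atoms:
        raise ValueError(f"chromophore {chromophore.key}: empty atom selection "
                         f"for mode {mode!r}")
    return np.mean([a.position for a in atoms], axis=0)


def distance_table(structure: Structure,
                   assembly_map: AssemblyMap,
                   chromophores: list[Chromophore],
                   mode: str = "conjugated",
                   cap: float = DISTANCE_CAP) -> pd.DataFrame:
    """Closest centre-centre chromophore distances per level and pair class.

    For each assembly level the minimum is taken over every chromophore pair
    of the class present at that level (within one monomer at the monomer
    level; within one trimer at the trimer level; anywhere in the hexamer).
    Distances above ``cap`` — and classes with no pair at the level, such as
    the inter-site classes inside a single monomer — are reported as
    ``+inf`` (rendered ``>cap`` on output); a site class with no chromophore
    at all yields ``NaN``.
    """
    chain_to_mono = assembly_map.monomer_of_chain()
    entries = []  # (site_class, monomer index, centre)
    for c in chromophores:
        if c.chain_id not in chain_to_mono or c.site_class not in SITE_CLASSES:
            continue
        entries.append((c.site_class, chain_to_mono[c.chain_id],
                        chromophore_center(c, mode)))

    def level_min(cls_a: str, cls_b: str, monomer_sets: list[set[int]]) -> float:
        present_a = any(e[0] == cls_a for e in entries)
        present_b = any(e[0] == cls_b for e in entries)
        if not (present_a and present_b):
            return math.nan
        best = math.inf
        for members in monomer_sets:
            pool_a = [e for e in entries if e[0] == cls_a and e[1] in members]
            pool_b = [e for e in entries if e[0] == cls_b and e[1] in members]
            for i, (_, mi, pi) in enumerate(pool_a):
                for j, (_, mj, pj) in enumerate(pool_b):
                    if cls_a == cls_b and (mi, tuple(pi)) == (mj, tuple(pj)):
                        continue
                    d = float(np.linalg.norm(pi - pj))
                    if d < best:
                        best = d
        return best if best <= cap else math.inf

    levels: dict[str, list[set[int]]] = {
        "monomer": [{i} for i in range(len(assembly_map.monomers))]}
    if assembly_map.trimers:
        levels["trimer"] = [set(t) for t in assembly_map.trimers]
    if assembly_map.hexamer:
        levels["hexamer"] = [set(assembly_map.hexamer)]

    rows = {}
    for level, monomer_sets in levels.items():
        rows[level] = {pair_class_label(a, b): level_min(a, b, monomer_sets)
                       for a, b in PAIR_CLASSES}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[pair_class_label(a, b)
                                           for a, b in PAIR_CLASSES])


def format_distance_table(table: pd.DataFrame, cap: float = DISTANCE_CAP) -> pd.DataFrame:
    """Render a distance table with the conventional ``>cap`` marker."""
    def fmt(v: float) -> str:
        if isinstance(v, float) and math.isnan(v):
            return "absent"
        if math.isinf(v):
            return f">{cap:.1f}"
        return f"{v:.1f}"
    return table.map(fmt)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(atoms: list[AtomRecord],
         probe_radius: float = 1.4,
         n_points: int = 960,
         radii: dict[str, float] | None = None,
         default_radius: float | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area by uniform sphere sampling.

    Each atom's extended sphere (vdW + probe) is sampled with a deterministic
    golden-spiral point set; a point survives when it lies outside every
    neighbouring extended sphere.  Unknown elements fall back to the
    configurable default radius with a warning.
    """
    if not atoms:
        return np.zeros(0)
    chem = chemdata.chemistry()
    table = dict(chem["vdw_radii"])
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    fallback = default_radius if default_radius is not None else chem["default_radius"]

    rads = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in table:
            logger.warning("unknown element %r; using default vdW radius %.2f",
                           el, fallback)
        rads[i] = table.get(el, fallback) + probe_radius
    coords = np.stack([a.position for a in atoms])
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = rads.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        neigh = [j for j in tree.query_ball_point(coords[i], rads[i] + max_r)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < rads[i] + rads[j]]
        pts = coords[i] + rads[i] * sphere
        if neigh:
            diff = pts[:, None, :] - coords[neigh][None, :, :]
            inside = (np.einsum("pnd,pnd->pn", diff, diff)
                      < (rads[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - inside.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * rads[i] ** 2
    return areas


@dataclass
class InterfaceReport:
    """Buried area between two chain sets with the per-side ASA breakdown."""

    chains_a: tuple[str, ...]
    chains_b: tuple[str, ...]
    asa_a_alone: float
    asa_b_alone: float
    asa_complex: float

    @property
    def buried_area(self) -> float:
        return self.asa_a_alone + self.asa_b_alone - self.asa_complex

    def as_dict(self) -> dict:
        return {"chains_a": list(self.chains_a), "chains_b": list(self.chains_b),
                "asa_a_alone": self.asa_a_alone, "asa_b_alone": self.asa_b_alone,
                "asa_complex": self.asa_complex, "buried_area": self.buried_area}


def buried_area(structure: Structure,
                chain_set_a: set[str] | list[str],
                chain_set_b: set[str] | list[str],
                include_ligands: bool = True,
                probe_radius: float = 1.4,
                n_points: int = 960) -> InterfaceReport:
    """Interface burial: SASA(A) + SASA(B) - SASA(A u B), waters excluded."""
    set_a, set_b = set(chain_set_a), set(chain_set_b)
    if not set_a or not set_b:
        raise ValueError("both chain sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"chain sets overlap: {sorted(set_a & set_b)}")

    def select(chain_ids: set[str]) -> list[AtomRecord]:
        return [a for a in structure.atoms
                if a.chain_id in chain_ids and a.element != "H" and not a.is_water
                and (include_ligands or not a.is_hetero)]

    atoms_a, atoms_b = select(set_a), select(set_b)
    kw = dict(probe_radius=probe_radius, n_points=n_points)
    asa_a = float(sasa(atoms_a, **kw).sum())
    asa_b = float(sasa(atoms_b, **kw).sum())
    asa_ab = float(sasa(atoms_a + atoms_b, **kw).sum())
    return InterfaceReport(tuple(sorted(set_a)), tuple(sorted(set_b)),
                           asa_a, asa_b, asa_ab)


# ---------------------------------------------------------------------------
# Solvent content and census
# ---------------------------------------------------------------------------

@dataclass
class SolventContentReport:
    """Matthews coefficient and crystal solvent fraction."""

    matthews_vm: float       # A^3 / Da
    solvent_fraction: float  # percent
    asu_mass: float          # Da
    cell_volume: float       # A^3
    physical: bool = True

    def as_dict(self) -> dict:
        return {"matthews_vm": self.matthews_vm,
                "solvent_fraction": self.solvent_fraction,
                "asu_mass": self.asu_mass, "cell_volume": self.cell_volume,
                "physical": self.physical}


def solvent_content(cell: CellParams, asu_mass: float) -> SolventContentReport:
    """V_M = V_cell / (Z * M_asu); solvent % = (1 - 1.230 / V_M) * 100."""
    if asu_mass <= 0:
        raise ValueError("asu_mass must be positive")
    vm = cell.volume / (cell.z_asu_per_cell * asu_mass)
    solvent = (1.0 - PROTEIN_VM_CONSTANT / vm) * 100.0
    physical = vm > PROTEIN_VM_CONSTANT
    if not physical:
        logger.warning("Matthews coefficient %.3f A^3/Da is non-physical "
                       "(below the protein constant)", vm)
    return SolventContentReport(matthews_vm=vm, solvent_fraction=solvent,
                                asu_mass=asu_mass, cell_volume=cell.volume,
                                physical=physical)


def asu_mass_from_sequences(sequences: dict[str, tuple[str, int]],
                            ligands: dict[str, int] | None = None) -> float:
    """Asymmetric-unit mass from chain sequences and bound-ligand counts.

    ``sequences`` maps a label to (one-letter sequence, copy number);
    ``ligands`` maps a chemical-component code to its copy count.  Waters
    are deliberately excluded.
    """
    mass = sum(chemdata.sequence_mass(seq) * n for seq, n in sequences.values())
    for code, n in (ligands or {}).items():
        mass += chemdata.ligand_mass(code) * n
    return mass


def census(structure: Structure) -> dict:
    """Chain/residue/atom counts (hydrogens excluded from the atom count)."""
    ligand_counts: dict[str, int] = {}
    protein_res: set[tuple] = set()
    waters = 0
    for key, res_atoms in structure.residues().items():
        first = res_atoms[0]
        if first.is_water:
            waters += 1
        elif first.is_hetero:
            ligand_counts[first.residue_name] = ligand_counts.get(first.residue_name, 0) + 1
        else:
            protein_res.add(key)
    return {
        "chains": len(structure.chain_ids),
        "protein_residues": len(protein_res),
        "ligand_residues": ligand_counts,
        "waters": waters,
        "non_hydrogen_atoms": sum(1 for a in structure.atoms
                                  if a.element not in ("H", "D")),
        "atoms": len(structure.atoms),
    }
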