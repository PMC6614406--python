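"""Conserved-position substitutions, structural mapping, compensation.

A handful of positions that are invariant across reported phycocyanin
sequences differ in some organisms; mapped onto the structure such
substitutions often come in spatially adjacent pairs whose combined steric
or hydrogen-bonding changes preserve local packing ("compensatory"
substitutions, e.g. a Phe->Tyr rescued by a neighbouring Glu->Asp).  This
module finds the substitutions from a multiple sequence alignment, maps
them onto chains of a structure with a hard guard against numbering drift,
and pairs them by side-chain proximity with steric/H-bond evidence labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from . import chemdata
from .assembly import AssemblyMap
from .contacts import POLAR_ELEMENTS, THREE_TO_ONE
from .structure_io import AtomRecord, Structure

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Net volume change window (A^3) within which a substitution pair counts
#: as sterically complementary.
VOLUME_WINDOW = 40.0


class AlignmentFormatError(ValueError):
    pass


class NumberingMismatchError(ValueError):
    """Alignment-derived residue does not match the structure at that position."""


@dataclass
class SubstitutionRecord:
    """A query residue differing from an otherwise conserved column."""

    subunit: str            # "alpha" / "beta" (or caller-defined label)
    position: int           # ungapped query position, 1-based
    conserved_residue: str  # one-letter consensus
    query_residue: str      # one-letter query
    conservation: float     # fraction of non-query rows carrying the consensus

    @property
    def label(self) -> str:
        return f"{self.subunit}{self.position}{self.conserved_residue}->{self.query_residue}"


@dataclass
class MappedSubstitution:
    """A substitution located on one or more chain copies of the model."""

    record: SubstitutionRecord
    sites: list[tuple[str, int, list[AtomRecord]]] = field(default_factory=list)
    unmapped_chains: list[str] = field(default_factory=list)

    @property
    def is_mapped(self) -> bool:
        return bool(self.sites)


@dataclass
class CompensatoryPair:
    """Two spatially adjacent substitutions with compensation evidence."""

    record_a: SubstitutionRecord
    record_b: SubstitutionRecord
    site_a: tuple[str, int]
    site_b: tuple[str, int]
    min_distance: float
    net_volume_change: float
    evidence: str  # "gained_hbond" / "volume_complementary" / "proximity_only"

    @property
    def labels(self) -> tuple[str, str]:
        return (self.record_a.label, self.record_b.label)


# ---------------------------------------------------------------------------


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleSeqAlignment:
    """Read a FASTA or Clustal alignment, validating equal row lengths."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"{Path(path).name}: {exc}") from exc
    if len(aln) < 2:
        raise AlignmentFormatError("alignment must contain at least 2 sequences")
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise AlignmentFormatError("duplicate sequence ids in alignment")
    return aln


def find_substitutions(alignment: MultipleSeqAlignment,
                       query_id: str,
                       conservation_threshold: float = 0.9,
                       subunit: str = "") -> list[SubstitutionRecord]:
    """Columns where the query deviates from a conserved consensus.

    A column qualifies when at least ``conservation_threshold`` of the
    non-query, non-gap residues agree on one residue and the (non-gap)
    query residue differs.  Positions are reported in ungapped query
    numbering, so they can be compared directly with author residue
    numbers.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in alignment}
    if query_id not in rows:
        raise KeyError(f"query id {query_id!r} not in alignment")
    query = rows.pop(query_id)

    records = []
    qpos = 0
    for col in range(alignment.get_alignment_length()):
        q = query[col]
        if q == "-":
            continue
        qpos += 1
        others = [row[col] for row in rows.values() if row[col] != "-"]
        if not others:
            continue
        values, counts = np.unique(others, return_counts=True)
        top = int(np.argmax(counts))
        consensus, frac = str(values[top]), counts[top] / len(others)
        if frac >= conservation_threshold and q != consensus:
            records.append(SubstitutionRecord(
                subunit=subunit, position=qpos, conserved_residue=consensus,
                query_residue=q, conservation=float(frac)))
    return records


def map_to_structure(records: list[SubstitutionRecord],
                     structure: Structure,
                     chain_assignment: dict[str, list[str]]
                     ) -> list[MappedSubstitution]:
    """Locate each substitution on every assigned chain copy.

    ``chain_assignment`` maps a subunit label to the chain ids carrying
    that subunit.  The residue found in the model must match the record's
    query residue — a mismatch raises :class:`NumberingMismatchError`
    rather than silently shifting numbering.  A residue missing from the
    model (disordered terminus) flags that chain as unmapped.
    """
    residues = structure.residues()
    out = []
    for rec in records:
        mapped = MappedSubstitution(record=rec)
        for chain_id in chain_assignment.get(rec.subunit, []):
            res_atoms = residues.get((chain_id, rec.position, ""))
            if res_atoms is None:
                mapped.unmapped_chains.append(chain_id)
                continue
            found = THREE_TO_ONE.get(res_atoms[0].residue_name, "X")
            if found != rec.query_residue:
                raise NumberingMismatchError(
                    f"{rec.label}: chain {chain_id} residue {rec.position} is "
                    f"{res_atoms[0].residue_name} ({found}), expected "
                    f"{rec.query_residue} — author numbering differs from "
                    f"alignment numbering")
            side = [a for a in res_atoms if a.atom_name not in BACKBONE_ATOMS
                    and a.element != "H"]
            if not side:  # glycine: fall back to CA for distance work
                side = [a for a in res_atoms if a.atom_name == "CA"]
            mapped.sites.append((chain_id, rec.position, side))
        out.append(mapped)
    return out


def _volume_change(rec: SubstitutionRecord) -> float:
    return (chemdata.residue_volume(rec.query_residue)
            - chemdata.residue_volume(rec.conserved_residue))


def compensatory_pairs(mapped: list[MappedSubstitution],
                       structure: Structure,
                       assembly_map: AssemblyMap | None = None,
                       d_max: float = 6.0,
                       hbond_d_max: float = 3.5,
                       volume_window: float = VOLUME_WINDOW
                       ) -> list[CompensatoryPair]:
    """Substitution pairs whose side chains approach within ``d_max``.

    All chain-copy combinations are searched (the assembly map, when given,
    restricts partners to the same or a contacting monomer).  Evidence:
    ``gained_hbond`` when the two substituted side chains share a polar
    heavy-atom pair within ``hbond_d_max``; otherwise
    ``volume_complementary`` when the summed residue-volume change lies
    within ``+/- volume_window`` of zero; else ``proximity_only``.
    """
    chain_mono = assembly_map.monomer_of_chain() if assembly_map else None

    def monomers_compatible(ch_a: str, ch_b: str) -> bool:
        if chain_mono is None:
            return True
        ma, mb = chain_mono.get(ch_a), chain_mono.get(ch_b)
        if ma is None or mb is None:
            return True
        if ma == mb:
            return True
        if assembly_map.trimers:
            same_trimer = any(ma in t and mb in t for t in assembly_map.trimers)
            if same_trimer:
                return True
        return bool(assembly_map.hexamer) and ma in assembly_map.hexamer \
            and mb in assembly_map.hexamer

    pairs = []
    for i in range(len(mapped)):
        for j in range(i + 1, len(mapped)):
            ma, mb = mapped[i], mapped[j]
            if not (ma.is_mapped and mb.is_mapped):
                continue
            best = None
            for ch_a, pos_a, atoms_a in ma.sites:
                for ch_b, pos_b, atoms_b in mb.sites:
                    if (ch_a, pos_a) == (ch_b, pos_b):
                        continue
                    if not monomers_compatible(ch_a, ch_b):
                        continue
                    pa = np.stack([a.position for a in atoms_a])
                    pb = np.stack([a.position for a in atoms_b])
                    dmat = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
                    d = float(dmat.min())
                    if best is None or d < best[0]:
                        best = (d, (ch_a, pos_a), (ch_b, pos_b), atoms_a, atoms_b)
            if best is None or best[0] > d_max:
                continue
            d, site_a, site_b, atoms_a, atoms_b = best
            polar_a = np.array([a.position for a in atoms_a
                                if a.element in POLAR_ELEMENTS])
            polar_b = np.array([a.position for a in atoms_b
                                if a.element in POLAR_ELEMENTS])
            gained = (polar_a.size and polar_b.size and
                      np.linalg.norm(polar_a[:, None] - polar_b[None, :],
                                     axis=-1).min() <= hbond_d_max)
            net = _volume_change(ma.record) + _volume_change(mb.record)
            if gained:
                evidence = "gained_hbond"
            elif abs(net) <= volume_window:
                evidence = "volume_complementary"
            else:
                evidence = "proximity_only"
            pairs.append(CompensatoryPair(
                record_a=ma.record, record_b=mb.record,
                site_a=site_a, site_b=site_b, min_distance=d,
                net_volume_change=net, evidence=evidence))
    pairs.sort(key=lambda p: (p.record_a.subunit, p.record_a.position,
                              p.record_b.subunit, p.record_b.position))
    return pairs
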