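"""Pyrrole ring-plane geometry and methine-bridge conformation.

The absorption maximum of a protein-bound bilin tracks the effective length
of its pi-conjugated system, which in turn depends on how coplanar the B, C
and D pyrrole rings stay.  This module quantifies that geometry: total
least-squares planes through each five-membered ring, the acute deviation
angle between adjacent ring planes, and the Z/E (configuration) and syn/anti
(conformation) classification of each methine bridge from its two torsions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Chromophore, LigandTable, default_ligand_table

RING_ORDER = ("A", "B", "C", "D")
BRIDGE_ORDER = ("AB", "BC", "CD")
_REF_AXES = np.eye(3)[::-1]  # z, then y, then x for sign tie-breaking


class DegenerateGeometryError(ValueError):
    """Raised when a plane fit is requested for degenerate input."""


@dataclass(frozen=True)
class PlaneFit:
    """Total least-squares plane: unit normal, centroid and residual RMS."""

    unit_normal: np.ndarray
    centroid: np.ndarray
    rms_deviation: float
    n_points: int


@dataclass
class RingAngleReport:
    """Adjacent ring-plane deviation angles (degrees, acute convention)."""

    chromophore_key: str
    angle_AB: float | None
    angle_BC: float | None
    angle_CD: float | None
    ring_rms: dict[str, float]

    def as_dict(self) -> dict:
        return {"chromophore": self.chromophore_key, "angle_AB": self.angle_AB,
                "angle_BC": self.angle_BC, "angle_CD": self.angle_CD}


@dataclass
class BridgeConformation:
    """Per-bridge Z/E isomer and syn/anti rotamer, plus the A->D summary."""

    chromophore_key: str
    config: dict[str, str]    # bridge -> "Z" / "E" / "unknown"
    rotamer: dict[str, str]   # bridge -> "syn" / "anti" / "unknown"

    @property
    def summary(self) -> str:
        return "-".join(self.rotamer.get(b, "unknown") for b in BRIDGE_ORDER)


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Fit the orthogonal-distance least-squares plane through ``points``.

    The plane through the centroid whose normal is the smallest-singular-
    vector of the centred coordinates minimises the sum of squared
    orthogonal distances.  The normal sign is fixed deterministically:
    positive component along +z, falling back to +y then +x for normals
    perpendicular to the earlier axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, sing, vt = np.linalg.svd(centred, full_matrices=False)
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = vt[2]
    for axis in _REF_AXES:
        d = float(normal @ axis)
        if abs(d) > 1e-12:
            if d < 0:
                normal = -normal
            break
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(unit_normal=normal / np.linalg.norm(normal),
                    centroid=centroid, rms_deviation=rms, n_points=len(pts))


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle (degrees) between two plane normals: arccos(|n1.n2|)."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180] (IUPAC)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    ang = np.degrees(np.arctan2(np.cross(b1n, v) @ w, v @ w))
    return float(ang) if ang > -180.0 else 180.0


def ring_plane_angles(chromophore: Chromophore) -> RingAngleReport:
    """Deviation-from-coplanarity angles between adjacent pyrrole rings.

    Each ring plane is fitted to exactly its five ring atoms (pyrrole N +
    four carbons).  An incomplete ring leaves the angles involving it as
    ``None`` while the remaining angles are still reported.
    """
    fits: dict[str, PlaneFit] = {}
    for ring in RING_ORDER:
        atoms = chromophore.ring_atoms.get(ring)
        if atoms is not None and len(atoms) == 5:
            fits[ring] = fit_plane(np.stack([a.position for a in atoms]))

    def angle(x: str, y: str) -> float | None:
        if x in fits and y in fits:
            return plane_angle(fits[x].unit_normal, fits[y].unit_normal)
        return None

    return RingAngleReport(
        chromophore_key=chromophore.key,
        angle_AB=angle("A", "B"),
        angle_BC=angle("B", "C"),
        angle_CD=angle("C", "D"),
        ring_rms={r: f.rms_deviation for r, f in fits.items()},
    )


def bridge_conformations(chromophore: Chromophore,
                         ligand_table: LigandTable | None = None,
                         ) -> BridgeConformation:
    """Classify each methine bridge from its double- and single-bond torsions.

    The atom quadruples for the configuration (double-bond) and rotamer
    (single-bond) torsions are fixed data shipped with the ligand table.
    ``|torsion| <= 90`` maps to Z / syn, otherwise E / anti; a missing atom
    leaves that bridge labelled ``unknown``.
    """
    table = ligand_table or default_ligand_table()
    quads = table.torsions(chromophore.ligand_code)
    config: dict[str, str] = {}
    rotamer: dict[str, str] = {}
    for bridge in BRIDGE_ORDER:
        spec = quads.get(bridge)
        if spec is None:
            config[bridge] = rotamer[bridge] = "unknown"
            continue
        for kind, labels in (("config", ("Z", "E")), ("rotamer", ("syn", "anti"))):
            atoms = [chromophore.atom(n) for n in spec[kind]]
            if any(a is None for a in atoms):
                value = "unknown"
            else:
                t = dihedral(*(a.position for a in atoms))
                value = labels[0] if abs(t) <= 90.0 else labels[1]
            (config if kind == "config" else rotamer)[bridge] = value
    return BridgeConformation(chromophore_key=chromophore.key,
                              config=config, rotamer=rotamer)
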