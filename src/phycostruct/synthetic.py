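"""Synthetic fixtures with machine-readable ground truth.

Every generator here emulates one input class of the analysis pipeline —
tetrapyrrole chromophores with prescribed ring-plane angles and bridge
torsions, toy multi-chain assemblies with chromophore centroids planted at
prescribed positions, alignments with planted substitutions, and spectra
that are sums of Gaussians plus seeded noise — and returns a
:class:`FixtureManifest` recording the exact planted values.  The manifest
is the oracle for the closure tests: generator output fed to its analysis
counterpart must recover the manifest within stated tolerance.

All generators are deterministic functions of (parameters, seed): the same
call produces byte-identical files.

Geometric note on the tetrapyrrole builder: each ring is attached to the
previous one through the methine bridge, and the only rotational degree of
freedom of a rigid planar ring about the bridge single bond simultaneously
sets the single-bond torsion and the inter-ring-plane angle.  A planted
torsion of 0 or 180 degrees therefore selects the coplanar base rotamer
(syn or anti) and the planted plane angle is applied as a tilt about the
bridge bond; the achieved torsion is ``base +/- angle``.  Requests where a
non-trivial torsion disagrees with the plane angle are geometrically
impossible for a rigid planar ring and raise ``ValueError``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AtomRecord, Structure, write_structure

PENTAGON_BOND = 1.38  # Angstrom, aromatic-like ring bond
PENTAGON_RADIUS = PENTAGON_BOND / (2.0 * math.sin(math.pi / 5.0))
RING_ORDER = ("A", "B", "C", "D")
BRIDGE_ORDER = ("AB", "BC", "CD")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: The twelve conserved-position substitutions of a blue-shifted Nostoc-clade
#: phycocyanin relative to the consensus of reported sequences:
#: (ungapped position, consensus residue, query residue).
TABLE1_SUBSTITUTIONS = {
    "alpha": [(18, "F", "Y"), (88, "I", "V"), (98, "C", "A")],
    "beta": [(56, "A", "V"), (60, "F", "W"), (79, "M", "A"), (83, "L", "I"),
             (86, "M", "L"), (87, "E", "D"), (109, "C", "A"), (134, "M", "L"),
             (138, "A", "S")],
}
#: Variant resolving the beta Glu->Asp position as 187 instead of 87; both
#: readings circulate in the literature and both are provided.
TABLE1_SUBSTITUTIONS_B187 = {
    "alpha": TABLE1_SUBSTITUTIONS["alpha"],
    "beta": [(p if p != 87 else 187, c, q) for p, c, q in TABLE1_SUBSTITUTIONS["beta"]],
}

#: Default planted B-C ring-plane deviation angles per attachment class:
#: the beta-153 chromophore of the emulated protein adopts the distorted
#: high-energy state (31.71 deg); the alpha-84/beta-82 sites stay near-coplanar.
CLASS_BC_ANGLES = {"alpha84": 12.0, "beta82": 12.0, "beta153": 31.71}


@dataclass
class FixtureManifest:
    """Ground truth of one generated fixture."""

    generator: str
    seed: int
    planted: dict
    files: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        payload = {"generator": self.generator, "seed": self.seed,
                   "planted": self.planted, "files": self.files}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Tetrapyrrole generator
# ---------------------------------------------------------------------------

def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _pentagon(c1: np.ndarray, inward: np.ndarray, normal: np.ndarray,
              clockwise: bool) -> list[np.ndarray]:
    """Regular pentagon C1,C2,C3,C4,N with C1 at ``c1``.

    ``inward`` is the in-plane unit vector from C1 toward the ring centroid;
    ``clockwise`` selects on which side of C1 the nitrogen sits.
    """
    centroid = c1 + PENTAGON_RADIUS * inward
    step = -72.0 if clockwise else 72.0
    pts = []
    v0 = c1 - centroid
    for k in range(5):
        pts.append(centroid + _rotation(normal, step * k) @ v0)
    return pts  # order C1, C2, C3, C4, N


def _torsion(p0, p1, p2, p3) -> float:
    """Signed torsion, IUPAC convention (same as geometry.dihedral)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return math.degrees(math.atan2(np.cross(b1n, v) @ w, v @ w))


def make_tetrapyrrole(ring_angles: dict[str, float] | None = None,
                      bridge_torsions: dict[str, float] | None = None,
                      seed: int = 0,
                      noise_sd: float = 0.0,
                      chain_id: str = "X",
                      ligand_number: int = 201,
                      attachment_residue: int = 84,
                      with_cysteine: bool = True,
                      path: str | Path | None = None,
                      ) -> tuple[Structure, FixtureManifest]:
    """Build an idealised bilin: four planar pyrrole rings joined by methines.

    Parameters
    ----------
    ring_angles
        Planted inter-ring-plane deviation angles in degrees for bridges
        AB/BC/CD, each in [0, 90].  Default all 0 (fully coplanar).
    bridge_torsions
        Planted methine single-bond torsions in (-180, 180].  0 selects the
        syn base rotamer, 180 the anti base (defaults 180, 0, 180: the
        extended anti-syn-anti conformation of protein-bound bilins).  A
        torsion not consistent with the requested plane angle raises
        ``ValueError``.
    noise_sd
        Isotropic Gaussian coordinate noise, Angstrom.
    with_cysteine
        Append a cysteine stub whose SG sits at thioether distance from the
        ring-A substituent carbon, so attachment detection has a target.
    """
    angles = {b: 0.0 for b in BRIDGE_ORDER}
    angles.update(ring_angles or {})
    torsions = {"AB": 180.0, "BC": 0.0, "CD": 180.0}
    torsions.update(bridge_torsions or {})
    for b in BRIDGE_ORDER:
        if not 0.0 <= angles[b] <= 90.0:
            raise ValueError(f"ring angle {b} must lie in [0, 90] degrees")
        if not -180.0 < torsions[b] <= 180.0:
            raise ValueError(f"bridge torsion {b} must lie in (-180, 180]")

    # resolve the planted torsion against the plane-angle tilt
    achieved: dict[str, float] = {}
    tilts: dict[str, float] = {}
    for b in BRIDGE_ORDER:
        t, phi = torsions[b], angles[b]
        base = 0.0 if abs(t) <= 90.0 else 180.0
        if math.isclose(abs(((t - base) + 180.0) % 360.0 - 180.0), phi, abs_tol=1e-9):
            tilt = ((t - base) + 180.0) % 360.0 - 180.0
        elif math.isclose(t, base, abs_tol=1e-9):
            tilt = phi
        else:
            raise ValueError(
                f"bridge {b}: torsion {t} deg inconsistent with plane angle "
                f"{phi} deg for a rigid planar ring (need torsion = base +/- angle)")
        tilts[b] = tilt
        a = base + tilt
        achieved[b] = a if a > -180.0 else a + 360.0
        if a > 180.0:
            achieved[b] = a - 360.0

    # ring A in the xy-plane
    normal = np.array([0.0, 0.0, 1.0])
    ringA = _pentagon(np.zeros(3), np.array([1.0, 0.0, 0.0]), normal, clockwise=False)
    rings = {"A": ringA}
    normals = {"A": normal.copy()}
    bridges: dict[str, np.ndarray] = {}

    for b in BRIDGE_ORDER:
        x, y = b[0], b[1]
        c1x, c2x, c3x, c4x, _nx = rings[x]
        cen_x = np.mean(rings[x], axis=0)
        nX = normals[x]
        # methine carbon: radial from ring X through C4X, in ring X's plane
        out = c4x - cen_x
        out = out / np.linalg.norm(out)
        ch = c4x + PENTAGON_BOND * out
        bridges[b] = ch
        # next ring's C1 at a 120-degree methine bond angle, staying in ring
        # X's plane (Z configuration about the formal double bond)
        u = ch - c4x
        u = u / np.linalg.norm(u)
        c1y = ch + PENTAGON_BOND * (_rotation(nX, 120.0) @ (-u))
        bond = c1y - ch
        bond = bond / np.linalg.norm(bond)
        # base ring Y: coplanar with ring X; pick the pentagon orientation
        # (nitrogen side) whose single-bond torsion equals the base rotamer
        base = 0.0 if abs(torsions[b]) <= 90.0 else 180.0
        best = None
        for clockwise in (False, True):
            cand = _pentagon(c1y, bond, nX, clockwise)
            t0 = _torsion(c4x, ch, c1y, cand[4])
            err = abs(((t0 - base) + 180.0) % 360.0 - 180.0)
            if best is None or err < best[0]:
                best = (err, cand, t0)
        _, ringY, t0 = best
        # tilt about the bridge single bond (axis through CH and C1Y) to
        # plant the plane angle; this shifts the torsion by the same amount
        delta = tilts[b] - (((t0 - base) + 180.0) % 360.0 - 180.0)
        rot = _rotation(bond, delta)
        rings[y] = [ch + rot @ (p - ch) for p in ringY]
        normals[y] = rot @ nX

    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []

    def add(name: str, element: str, pos: np.ndarray, *, hetero: bool = True,
            resnum: int = ligand_number, resname: str = "CYC") -> None:
        p = np.asarray(pos, float)
        if noise_sd > 0:
            p = p + rng.normal(0.0, noise_sd, size=3)
        atoms.append(AtomRecord(atom_name=name, element=element, position=p,
                                chain_id=chain_id, residue_number=resnum,
                                residue_name=resname, is_hetero=hetero))

    for ring in RING_ORDER:
        c1, c2, c3, c4, n = rings[ring]
        add(f"C1{ring}", "C", c1)
        add(f"C2{ring}", "C", c2)
        add(f"C3{ring}", "C", c3)
        add(f"C4{ring}", "C", c4)
        add(f"N{ring}", "N", n)
    for b in BRIDGE_ORDER:
        add(f"CH{b[1]}", "C", bridges[b])
    # ring-A thioether substituent carbon, radial from C3A
    c3a = rings["A"][2]
    cen_a = np.mean(rings["A"], axis=0)
    caa_dir = (c3a - cen_a) / np.linalg.norm(c3a - cen_a)
    caa = c3a + 1.50 * caa_dir
    add("CAA", "C", caa)

    if with_cysteine:
        sg = caa + 1.80 * caa_dir
        cb = sg + 1.80 * caa_dir
        ca = cb + 1.53 * np.array([0.0, 0.0, 1.0])
        nb = ca + 1.46 * np.array([0.0, 1.0, 0.0])
        for name, el, pos in (("N", "N", nb), ("CA", "C", ca),
                              ("CB", "C", cb), ("SG", "S", sg)):
            add(name, el, pos, hetero=False, resnum=attachment_residue,
                resname="CYS")

    structure = Structure(atoms=atoms, entry_id="SYNTHPYR")
    manifest = FixtureManifest(
        generator="make_tetrapyrrole",
        seed=seed,
        planted={
            "ring_angles": {b: angles[b] for b in BRIDGE_ORDER},
            "bridge_torsions": {b: torsions[b] for b in BRIDGE_ORDER},
            "achieved_torsions": {b: round(achieved[b], 6) for b in BRIDGE_ORDER},
            "rotamers": {b: ("syn" if abs(achieved[b]) <= 90 else "anti")
                         for b in BRIDGE_ORDER},
            "noise_sd": noise_sd,
            "attachment_residue": attachment_residue if with_cysteine else None,
        },
    )
    if path is not None:
        write_structure(structure, path)
        manifest.files.append(str(path))
    return structure, manifest


# ---------------------------------------------------------------------------
# Toy assembly generator
# ---------------------------------------------------------------------------

#: Default planted within-monomer centroid-centroid distances (Angstrom):
#: alpha84-beta82, beta82-beta153, beta153-alpha84.
DEFAULT_MONOMER_TRIANGLE = (50.9, 38.7, 50.0)

#: Frozen monomer-local chromophore centroids (rows: alpha84, beta82,
#: beta153) and trimer stacking parameters.  The layout was solved once so
#: that the doughnut-shaped hexamer built from it (3-fold symmetry within a
#: trimer; second trimer mirrored, twisted and stacked) reproduces the
#: published closest-distance table of the emulated phycocyanin: monomer row
#: 50.9 / 38.7 / 50.0, trimer minima 20.2 / 38.7 / 38.0 / >51 / 33.3 / >51,
#: hexamer inter-site minima 26.8 / 33.3 / 27.5 A (the published hexamer
#: inter-beta82 cell, 33.1 A, is matched to within 0.2 A; the remaining
#: cells are exact to the printed precision).
TABLE_LAYOUT_LOCAL = np.array([
    [37.7357, -7.8610, -0.9010],
    [-12.3602, -14.7260, -6.7386],
    [7.3407, -47.5610, -1.1326],
])
TABLE_LAYOUT_TWIST = 7.2815    # degrees, second-trimer twist about the 3-fold axis
TABLE_LAYOUT_ZSEP = 24.5471    # Angstrom, second-trimer axial shift

_ALPHA_CHAINS = "ACEGIK"
_BETA_CHAINS = "BDFHJL"


def _monomer_triangle(d_ab: float, d_bc: float, d_ca: float) -> np.ndarray:
    """Planar triangle with the three planted side lengths."""
    if not (d_ab < d_bc + d_ca and d_bc < d_ab + d_ca and d_ca < d_ab + d_bc):
        raise ValueError("planted chromophore distances violate the triangle inequality")
    x = (d_ab ** 2 + d_ca ** 2 - d_bc ** 2) / (2.0 * d_ab)
    y2 = d_ca ** 2 - x ** 2
    y = math.sqrt(max(y2, 0.0))
    return np.array([[0.0, 0.0, 0.0], [d_ab, 0.0, 0.0], [x, y, 0.0]])


def make_toy_assembly(n_monomers: int = 6,
                      center_distances: tuple[float, float, float] | None = None,
                      seed: int = 0,
                      ring_angles_by_class: dict[str, float] | None = None,
                      noise_sd: float = 0.0,
                      path: str | Path | None = None,
                      ) -> tuple[Structure, FixtureManifest]:
    """Toy phycocyanin assembly with chromophore centroids planted exactly.

    Each monomer is an alpha-chain stub carrying one chromophore (attached
    at Cys84) and a beta-chain stub carrying two (Cys82 and Cys153).  With
    the default ``center_distances=None`` the frozen layout emulating the
    published distance table is used (see ``TABLE_LAYOUT_LOCAL``); passing
    an explicit (alpha84-beta82, beta82-beta153, beta153-alpha84) triangle
    plants exactly those within-monomer distances in a generic 3-fold
    arrangement instead.  The manifest records every centroid and the full
    pairwise distance matrix — the oracle for distance-table closure tests.

    Chromophores carry planted B-C ring-plane angles per attachment class
    (default: the distorted beta-153 value 31.71 deg, near-coplanar 12 deg
    elsewhere) so geometry statistics can be exercised on the same fixture.
    """
    if n_monomers not in (1, 3, 6):
        raise ValueError("n_monomers must be 1, 3 or 6")
    bc_angles = dict(CLASS_BC_ANGLES)
    bc_angles.update(ring_angles_by_class or {})

    if center_distances is None:
        local = TABLE_LAYOUT_LOCAL.copy()
    else:
        local = _monomer_triangle(*center_distances)
    planted_triangle = tuple(float(np.linalg.norm(local[i] - local[j]))
                             for i, j in ((0, 1), (1, 2), (2, 0)))
    twist, zsep = TABLE_LAYOUT_TWIST, TABLE_LAYOUT_ZSEP
    rng = np.random.default_rng(seed)

    z_axis = np.array([0.0, 0.0, 1.0])
    monomers = []
    for i in range(n_monomers):
        trimer = i // 3
        j = i % 3
        loc = local.copy()
        if trimer == 1:
            loc = loc @ np.diag([1.0, 1.0, -1.0])  # face-to-face mirror
            loc[:, 2] += zsep
        rot = _rotation(z_axis, 120.0 * j + twist * trimer)
        centers = (rot @ loc.T).T
        anchor = centers.mean(axis=0)
        hub = np.array([0.0, 0.0, float(loc[:, 2].mean())])
        monomers.append({
            "alpha_chain": _ALPHA_CHAINS[i],
            "beta_chain": _BETA_CHAINS[i],
            "centers": centers,          # rows: alpha84, beta82, beta153
            "anchor": anchor,
            "hub": hub,
        })

    atoms: list[AtomRecord] = []
    chrom_records = []
    site_specs = (("alpha", 84, 301), ("beta", 82, 301), ("beta", 153, 302))
    for i, mono in enumerate(monomers):
        for k, (sub, cys, lignum) in enumerate(site_specs):
            chain = mono["alpha_chain"] if sub == "alpha" else mono["beta_chain"]
            site = {84: "alpha84", 82: "beta82", 153: "beta153"}[cys]
            sub_structure, _ = make_tetrapyrrole(
                ring_angles={"AB": 15.0, "BC": bc_angles[site], "CD": 25.0},
                seed=seed * 97 + i * 7 + k,
                noise_sd=noise_sd,
                chain_id=chain,
                ligand_number=lignum,
                attachment_residue=cys,
                with_cysteine=True,
            )
            # random orientation, then translate conjugated centroid to target
            conj_names = {f"{a}{r}" for r in "BCD" for a in ("C1", "C2", "C3", "C4", "N")}
            conj_names |= {"CHC", "CHD"}
            rot = _random_rotation(rng)
            pts = np.stack([a.position for a in sub_structure.atoms])
            pts = (rot @ pts.T).T
            conj_idx = [idx for idx, a in enumerate(sub_structure.atoms)
                        if a.atom_name in conj_names]
            centroid = pts[conj_idx].mean(axis=0)
            pts = pts - centroid + mono["centers"][k]
            for a, p in zip(sub_structure.atoms, pts):
                atoms.append(AtomRecord(atom_name=a.atom_name, element=a.element,
                                        position=p, chain_id=chain,
                                        residue_number=a.residue_number,
                                        residue_name=a.residue_name,
                                        is_hetero=a.is_hetero))
            chrom_records.append({"monomer": i, "chain": chain, "site": site,
                                  "center": mono["centers"][k].tolist()})
        # interface stubs driving assembly-map contacts: a tight alpha-beta
        # pair at the monomer anchor and an alpha atom at the shared trimer hub
        anchor = mono["anchor"]
        _add_gly(atoms, mono["alpha_chain"], 10, anchor + np.array([0, 0, 5.0]))
        _add_gly(atoms, mono["beta_chain"], 10, anchor + np.array([3.0, 0, 5.0]))
        _add_gly(atoms, mono["alpha_chain"], 11, mono["hub"] + 0.4 * _unit(i))

    structure = Structure(atoms=atoms, entry_id="SYNTHASM")
    centers = np.array([c["center"] for c in chrom_records])
    dmat = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    manifest = FixtureManifest(
        generator="make_toy_assembly",
        seed=seed,
        planted={
            "n_monomers": n_monomers,
            "center_distances": list(planted_triangle),
            "chromophores": chrom_records,
            "distance_matrix": np.round(dmat, 6).tolist(),
            "bc_angles_by_class": bc_angles,
            "monomer_pairs": [[m["alpha_chain"], m["beta_chain"]] for m in monomers],
            "trimers": [list(range(min(3, n_monomers)))] +
                       ([list(range(3, 6))] if n_monomers == 6 else []),
        },
    )
    if path is not None:
        write_structure(structure, path)
        manifest.files.append(str(path))
    return structure, manifest


def _unit(i: int) -> np.ndarray:
    ang = 2.399963 * i  # golden-angle spread keeps hub atoms distinct
    return np.array([math.cos(ang), math.sin(ang), 0.0])


def _add_gly(atoms: list[AtomRecord], chain: str, resnum: int, pos: np.ndarray) -> None:
    for name, el, off in (("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
                          ("C", "C", (2.2, 1.2, 0.0)), ("O", "O", (2.2, 2.43, 0.0))):
        atoms.append(AtomRecord(atom_name=name, element=el,
                                position=np.asarray(pos) + np.asarray(off),
                                chain_id=chain, residue_number=resnum,
                                residue_name="GLY"))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# Alignment generator
# ---------------------------------------------------------------------------

def make_alignment(n_refs: int = 8,
                   length: int = 162,
                   planted_substitutions: list[tuple[int, str, str]] | None = None,
                   seed: int = 0,
                   query_id: str = "query",
                   path: str | Path | None = None,
                   ) -> tuple[dict[str, str], FixtureManifest]:
    """Reference rows plus one query differing exactly at planted positions.

    ``planted_substitutions`` is a list of (ungapped 1-based position,
    consensus residue, query residue).  Returns an id -> gapped-row mapping
    (the query has no gaps, so column index equals position).
    """
    plants = planted_substitutions or []
    positions = [p for p, _, _ in plants]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate planted positions")
    if positions and max(positions) > length:
        raise ValueError("planted position beyond alignment length")

    rng = np.random.default_rng(seed)
    background = [AA_ALPHABET[k] for k in rng.integers(0, len(AA_ALPHABET), size=length)]
    for pos, cons, _ in plants:
        background[pos - 1] = cons
    query = list(background)
    for pos, cons, sub in plants:
        if cons == sub:
            raise ValueError(f"position {pos}: consensus and query residue identical")
        query[pos - 1] = sub

    rows = {f"ref{k + 1}": "".join(background) for k in range(n_refs)}
    rows[query_id] = "".join(query)
    manifest = FixtureManifest(
        generator="make_alignment", seed=seed,
        planted={"length": length, "n_refs": n_refs, "query_id": query_id,
                 "substitutions": [[p, c, q] for p, c, q in plants]},
    )
    if path is not None:
        with open(path, "w") as fh:
            for sid, row in rows.items():
                fh.write(f">{sid}\n{row}\n")
        manifest.files.append(str(path))
    return rows, manifest


def table1_alignments(seed: int = 0, variant_b187: bool = False,
                      outdir: str | Path | None = None,
                      ) -> dict[str, tuple[dict[str, str], FixtureManifest]]:
    """The packaged preset of the twelve conserved-position substitutions.

    Two alignments (alpha and beta subunit) whose query differs from an
    otherwise invariant consensus at exactly the twelve listed positions
    (3 alpha + 9 beta).
    """
    table = TABLE1_SUBSTITUTIONS_B187 if variant_b187 else TABLE1_SUBSTITUTIONS
    lengths = {"alpha": 162, "beta": 192 if variant_b187 else 172}
    out = {}
    for subunit in ("alpha", "beta"):
        p = Path(outdir) / f"{subunit}.fasta" if outdir is not None else None
        out[subunit] = make_alignment(
            n_refs=8, length=lengths[subunit],
            planted_substitutions=table[subunit],
            seed=seed + (0 if subunit == "alpha" else 1),
            query_id=f"NPC_{subunit}", path=p)
    return out


# ---------------------------------------------------------------------------
# Spectrum generator
# ---------------------------------------------------------------------------

#: Spectral study conditions: three Gaussian components with the published
#: absorbance maxima (nm) and plausible phycocyanin band widths/amplitudes.
DEFAULT_SPECTRUM_COMPONENTS = ((578.0, 18.0, 0.60), (607.0, 14.0, 0.90),
                               (626.0, 12.0, 0.75))
ML_PC_CENTERS = (598.0, 618.0, 625.0)


def make_spectrum(components=DEFAULT_SPECTRUM_COMPONENTS,
                  noise_sd: float = 0.005,
                  grid: tuple[float, float, float] = (450.0, 750.0, 1.0),
                  baseline: float = 0.0,
                  seed: int = 0,
                  path: str | Path | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, FixtureManifest]:
    """Sample a sum of Gaussians plus seeded noise on a wavelength grid.

    ``components`` is a sequence of (center nm, width-sd nm, amplitude);
    ``noise_sd`` is expressed as a fraction of the noiseless maximum.  The
    grid must cover every center +/- 3 widths so the fit window sees the
    full band shape.
    """
    comps = [tuple(map(float, c)) for c in components]
    if not comps:
        raise ValueError("need at least one Gaussian component")
    lo, hi, step = grid
    for c, w, a in comps:
        if w <= 0 or a <= 0:
            raise ValueError("component widths and amplitudes must be positive")
        if c - 3 * w < lo or c + 3 * w > hi:
            raise ValueError(f"grid [{lo}, {hi}] does not cover component at {c} nm +/- 3 sd")
    wavelengths = np.arange(lo, hi + 0.5 * step, step)
    signal = np.full_like(wavelengths, baseline, dtype=float)
    for c, w, a in comps:
        signal += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
    rng = np.random.default_rng(seed)
    noisy = signal + rng.normal(0.0, noise_sd * signal.max(), size=signal.shape)

    manifest = FixtureManifest(
        generator="make_spectrum", seed=seed,
        planted={"components": [list(c) for c in comps], "baseline": baseline,
                 "noise_sd": noise_sd, "grid": list(grid)},
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,absorbance\n")
            for wl, ab in zip(wavelengths, noisy):
                fh.write(f"{wl:.2f},{ab:.6f}\n")
        manifest.files.append(str(path))
    return wavelengths, noisy, manifest


# ---------------------------------------------------------------------------
# Compensation-geometry fixture
# ---------------------------------------------------------------------------

def make_compensation_structure(seed: int = 0,
                                path: str | Path | None = None,
                                ) -> tuple[Structure, FixtureManifest]:
    """Two-chain structure carrying the twelve substituted residues in 3-D.

    The residues of the substitution preset are placed so that the three
    published compensation groupings are reproduced geometrically: the
    alpha-18 tyrosine hydroxyl donates to the beta-87 aspartate carboxylate
    (2.9 A), the beta-60 tryptophan packs against the beta-79 alanine, and
    the beta-56 valine sits between the beta-83 isoleucine and beta-86
    leucine.  The remaining substituted positions are isolated (> 20 A from
    any other substituted side chain).  The manifest records the expected
    pairings, which drive the compensatory-pair closure tests.
    """
    rng = np.random.default_rng(seed)  # reserved for future coordinate noise

    def residue(chain, num, name, side_specs, origin):
        origin = np.asarray(origin, float)
        specs = [("N", "N", (-2.4, 1.2, 0.0)), ("CA", "C", (-1.5, 0.0, 0.0)),
                 ("C", "C", (-2.2, -1.3, 0.0)), ("O", "O", (-3.4, -1.4, 0.0))]
        specs += side_specs
        return [AtomRecord(atom_name=n, element=e,
                           position=origin + np.asarray(p, float),
                           chain_id=chain, residue_number=num, residue_name=name)
                for n, e, p in specs]

    atoms: list[AtomRecord] = []
    # grouping 1: alpha Tyr18 -- beta Asp87 hydrogen bond
    atoms += residue("A", 18, "TYR",
                     [("CB", "C", (0, 0, 0)), ("CG", "C", (1.4, 0, 0)),
                      ("CD1", "C", (2.1, 1.2, 0)), ("CD2", "C", (2.1, -1.2, 0)),
                      ("CE1", "C", (3.5, 1.2, 0)), ("CE2", "C", (3.5, -1.2, 0)),
                      ("CZ", "C", (4.2, 0, 0)), ("OH", "O", (5.6, 0, 0))],
                     (0, 0, 0))
    atoms += residue("B", 87, "ASP",
                     [("CB", "C", (0, 0, 0)), ("CG", "C", (-1.0, 1.0, 0)),
                      ("OD1", "O", (-2.2, 0.75, 0)), ("OD2", "O", (-0.6, 2.2, 0))],
                     (10.7, -0.75, 0))  # OH...OD1 = 2.9 A
    # grouping 2: beta Trp60 packs into the beta Ala79 void
    atoms += residue("B", 60, "TRP",
                     [("CB", "C", (0, 0, 0)), ("CG", "C", (1.4, 0.4, 0)),
                      ("CD1", "C", (1.8, 1.7, 0)), ("CD2", "C", (2.6, -0.5, 0)),
                      ("NE1", "N", (3.2, 1.8, 0)), ("CE2", "C", (3.7, 0.6, 0)),
                      ("CE3", "C", (2.9, -1.9, 0)), ("CZ2", "C", (5.0, 0.3, 0)),
                      ("CZ3", "C", (4.2, -2.2, 0)), ("CH2", "C", (5.3, -1.1, 0))],
                     (30, 0, 0))
    atoms += residue("B", 79, "ALA", [("CB", "C", (0, 0, 0))], (38.8, -1.1, 0))
    # grouping 3: beta Val56 between beta Ile83 and beta Leu86
    atoms += residue("B", 56, "VAL",
                     [("CB", "C", (0, 0, 0)), ("CG1", "C", (0.8, 1.2, 0)),
                      ("CG2", "C", (0.8, -1.2, 0))], (60, 0, 0))
    atoms += residue("B", 83, "ILE",
                     [("CB", "C", (0, 0, 0)), ("CG1", "C", (-1.0, 1.0, 0)),
                      ("CG2", "C", (1.2, 0.8, 0)), ("CD1", "C", (-2.2, 1.6, 0))],
                     (64.9, 1.0, 0))
    atoms += residue("B", 86, "LEU",
                     [("CB", "C", (0, 0, 0)), ("CG", "C", (1.1, 1.0, 0)),
                      ("CD1", "C", (2.4, 0.6, 0)), ("CD2", "C", (1.0, 2.4, 0))],
                     (64.6, -3.2, 0))
    # isolated substituted positions
    atoms += residue("A", 88, "VAL",
                     [("CB", "C", (0, 0, 0)), ("CG1", "C", (0.8, 1.2, 0)),
                      ("CG2", "C", (0.8, -1.2, 0))], (0, 40, 0))
    atoms += residue("A", 98, "ALA", [("CB", "C", (0, 0, 0))], (0, 80, 0))
    atoms += residue("B", 109, "ALA", [("CB", "C", (0, 0, 0))], (30, 40, 0))
    atoms += residue("B", 134, "LEU",
                     [("CB", "C", (0, 0, 0)), ("CG", "C", (1.1, 1.0, 0)),
                      ("CD1", "C", (2.4, 0.6, 0)), ("CD2", "C", (1.0, 2.4, 0))],
                     (30, 80, 0))
    atoms += residue("B", 138, "SER",
                     [("CB", "C", (0, 0, 0)), ("OG", "O", (0.7, 1.2, 0))],
                     (60, 40, 0))

    structure = Structure(atoms=atoms, entry_id="SYNTHCMP")
    manifest = FixtureManifest(
        generator="make_compensation_structure", seed=seed,
        planted={
            "expected_pairings": [
                {"a": ["alpha", 18], "b": ["beta", 87], "evidence": "gained_hbond"},
                {"a": ["beta", 60], "b": ["beta", 79],
                 "evidence": "volume_complementary"},
                {"a": ["beta", 56], "b": ["beta", 83]},
                {"a": ["beta", 56], "b": ["beta", 86]},
            ],
            "chain_assignment": {"alpha": ["A"], "beta": ["B"]},
        },
    )
    if path is not None:
        write_structure(structure, path)
        manifest.files.append(str(path))
    return structure, manifest


# ---------------------------------------------------------------------------
# Small building block shared by contact/substitution test fixtures
# ---------------------------------------------------------------------------

def make_residue(chain_id: str, resnum: int, resname: str,
                 atom_specs: list[tuple[str, str, tuple[float, float, float]]],
                 ) -> list[AtomRecord]:
    """Ad-hoc residue from explicit (atom name, element, position) triples."""
    return [AtomRecord(atom_name=n, element=e, position=np.asarray(p, float),
                       chain_id=chain_id, residue_number=resnum, residue_name=resname)
            for n, e, p in atom_specs]
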