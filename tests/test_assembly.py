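"""Assembly mapping, distance tables, SASA, burial, solvent content, census."""

import itertools
import math

import numpy as np
import pytest

from phycostruct.assembly import (DISTANCE_CAP, PAIR_CLASSES, SITE_CLASSES,
                                  build_assembly_map, buried_area, census,
                                  chromophore_center, distance_table,
                                  pair_class_label, sasa, solvent_content,
                                  asu_mass_from_sequences)
from phycostruct.structure_io import (AtomRecord, CellParams, Structure,
                                      extract_chromophores)
from phycostruct.synthetic import make_tetrapyrrole, make_toy_assembly


def atom(name="CA", element="C", pos=(0, 0, 0), chain="A", resnum=1,
         resname="ALA", **kw):
    return AtomRecord(atom_name=name, element=element,
                      position=np.asarray(pos, float), chain_id=chain,
                      residue_number=resnum, residue_name=resname, **kw)


class TestAssemblyMap:
    def test_hexamer_partition(self, toy_hexamer, toy_hexamer_chromophores,
                               toy_hexamer_map):
        _, manifest = toy_hexamer
        amap = toy_hexamer_map
        assert [list(m) for m in amap.monomers] == manifest.planted["monomer_pairs"]
        assert amap.trimers == manifest.planted["trimers"]
        assert amap.hexamer == [0, 1, 2, 3, 4, 5]

    def test_single_monomer_degenerate_levels_empty(self):
        st, _ = make_toy_assembly(n_monomers=1, seed=3)
        chroms = extract_chromophores(st)
        amap = build_assembly_map(st, chroms)
        assert len(amap.monomers) == 1
        assert amap.trimers == [] and amap.hexamer == []

    def test_chain_typing_requires_both_subunits(self):
        st, _ = make_tetrapyrrole(seed=0)  # one chain, one chromophore
        chroms = extract_chromophores(st)
        with pytest.raises(ValueError):
            build_assembly_map(st, chroms)


class TestChromophoreCenter:
    def test_centroid_equals_arithmetic_mean(self, distorted_chromophore):
        chrom, _ = distorted_chromophore
        for mode, atoms in (("conjugated", chrom.conjugated_atoms),
                            ("all_atoms", chrom.atoms),
                            ("ring_C", chrom.ring_atoms["C"])):
            expected = np.mean([a.position for a in atoms], axis=0)
            np.testing.assert_allclose(chromophore_center(chrom, mode),
                                       expected, atol=1e-12)

    def test_ring_centroid_is_symmetry_center(self, distorted_chromophore):
        chrom, _ = distorted_chromophore
        center = chromophore_center(chrom, "ring_C")
        radii = [np.linalg.norm(a.position - center)
                 for a in chrom.ring_atoms["C"]]
        assert np.std(radii) < 1e-9  # regular pentagon

    def test_empty_selection_errors(self, distorted_chromophore):
        chrom, _ = distorted_chromophore
        with pytest.raises(ValueError):
            chromophore_center(chrom, "nonsense")


def exhaustive_table(manifest, amap):
    """Brute-force oracle over the manifest's planted centres."""
    recs = manifest.planted["chromophores"]
    centers = np.array([r["center"] for r in recs])
    levels = {"monomer": [{i} for i in range(len(amap.monomers))]}
    if amap.trimers:
        levels["trimer"] = [set(t) for t in amap.trimers]
    if amap.hexamer:
        levels["hexamer"] = [set(amap.hexamer)]
    out = {}
    for level, groups in levels.items():
        row = {}
        for ca, cb in PAIR_CLASSES:
            best = math.inf
            for grp in groups:
                ia = [i for i, r in enumerate(recs)
                      if r["site"] == ca and r["monomer"] in grp]
                ib = [i for i, r in enumerate(recs)
                      if r["site"] == cb and r["monomer"] in grp]
                for i, j in itertools.product(ia, ib):
                    if i == j:
                        continue
                    best = min(best, float(np.linalg.norm(centers[i] - centers[j])))
            row[pair_class_label(ca, cb)] = best
        out[level] = row
    return out


class TestDistanceTable:
    def test_matches_exhaustive_oracle(self, toy_hexamer,
                                       toy_hexamer_chromophores,
                                       toy_hexamer_map):
        st, manifest = toy_hexamer
        table = distance_table(st, toy_hexamer_map, toy_hexamer_chromophores)
        oracle = exhaustive_table(manifest, toy_hexamer_map)
        for level, row in oracle.items():
            for label, expected in row.items():
                got = table.loc[level, label]
                if expected > DISTANCE_CAP:
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_down_assembly_levels(self, toy_hexamer,
                                           toy_hexamer_chromophores,
                                           toy_hexamer_map):
        st, _ = toy_hexamer
        table = distance_table(st, toy_hexamer_map, toy_hexamer_chromophores)
        for col in table.columns:
            m, t, h = (table.loc["monomer", col], table.loc["trimer", col],
                       table.loc["hexamer", col])
            assert h <= t <= m or (math.isinf(m) and h <= t)

    def test_planted_monomer_triangle(self, toy_hexamer,
                                      toy_hexamer_chromophores,
                                      toy_hexamer_map):
        st, manifest = toy_hexamer
        table = distance_table(st, toy_hexamer_map, toy_hexamer_chromophores)
        d_ab, d_bc, d_ca = manifest.planted["center_distances"]
        assert table.loc["monomer", "alpha84-beta82"] == pytest.approx(d_ab, abs=1e-6)
        assert table.loc["monomer", "beta82-beta153"] == pytest.approx(d_bc, abs=1e-6)
        assert table.loc["monomer", "beta153-alpha84"] == pytest.approx(d_ca, abs=1e-6)

    def test_oligomerisation_brings_chromophores_closer(
            self, toy_hexamer, toy_hexamer_chromophores, toy_hexamer_map):
        st, _ = toy_hexamer
        table = distance_table(st, toy_hexamer_map, toy_hexamer_chromophores)
        assert table.loc["trimer", "alpha84-beta82"] < \
            table.loc["monomer", "alpha84-beta82"]
        assert np.isfinite(table.loc["hexamer", "inter-alpha84"])

    def test_missing_class_reported_absent(self):
        st, _ = make_toy_assembly(n_monomers=1, seed=0)
        chroms = [c for c in extract_chromophores(st)
                  if c.site_class != "beta153"]
        amap = build_assembly_map(st, extract_chromophores(st))
        table = distance_table(st, amap, chroms)
        assert math.isnan(table.loc["monomer", "beta82-beta153"])
        assert math.isnan(table.loc["monomer", "inter-beta153"])


class TestSasa:
    def test_single_atom_analytic(self):
        area = sasa([atom(element="C")])[0]
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert abs(area - exact) / exact <= 0.005

    def test_two_sphere_analytic(self):
        d = 2.5
        atoms = [atom(element="C"), atom("O1", "O", (d, 0, 0))]
        areas = sasa(atoms)
        R1, R2 = 1.70 + 1.4, 1.52 + 1.4

        def exposed(Ra, Rb):
            h = Ra - (d * d + Ra * Ra - Rb * Rb) / (2 * d)
            return 4 * math.pi * Ra ** 2 - 2 * math.pi * Ra * h

        assert abs(areas[0] - exposed(R1, R2)) / exposed(R1, R2) <= 0.01
        assert abs(areas[1] - exposed(R2, R1)) / exposed(R2, R1) <= 0.01

    def test_point_doubling_converges(self, rng):
        atoms = [atom(f"C{i}", "C", p) for i, p in
                 enumerate(rng.normal(0, 4, size=(100, 3)))]
        t1 = sasa(atoms, n_points=960).sum()
        t2 = sasa(atoms, n_points=1920).sum()
        assert abs(t1 - t2) / t2 < 0.005

    def test_against_independent_implementation(self, rng):
        """Cross-check the sphere sampler against biotite's Shrake-Rupley."""
        import biotite.structure as struc
        pts = rng.normal(0, 4, size=(80, 3))
        atoms = [atom(f"C{i}", "C", p, resnum=i + 1) for i, p in enumerate(pts)]
        ours = sasa(atoms, n_points=960).sum()
        arr = struc.AtomArray(len(pts))
        arr.coord = pts.astype(np.float32)
        arr.element = np.array(["C"] * len(pts))
        arr.atom_name = np.array([a.atom_name for a in atoms])
        arr.res_id = np.arange(1, len(pts) + 1)
        arr.res_name = np.array(["ALA"] * len(pts))
        arr.chain_id = np.array(["A"] * len(pts))
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii="Single").sum()
        assert abs(ours - theirs) / theirs < 0.02

    def test_unknown_element_uses_default_radius(self):
        area = sasa([atom(element="XX")])[0]
        exact = 4 * math.pi * (1.70 + 1.4) ** 2  # default radius = carbon
        assert area == pytest.approx(exact, rel=0.005)


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        st = Structure(atoms=[atom(chain="A"),
                              atom("CB", "C", (50, 0, 0), chain="B")])
        rep = buried_area(st, {"A"}, {"B"})
        assert rep.buried_area == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_and_additive(self, toy_hexamer):
        st, _ = toy_hexamer
        r1 = buried_area(st, {"A"}, {"B"}, n_points=240)
        r2 = buried_area(st, {"B"}, {"A"}, n_points=240)
        assert r1.buried_area == pytest.approx(r2.buried_area, rel=1e-9)
        assert r1.buried_area >= 0
        # additivity identity by definition of the report
        assert r1.buried_area == pytest.approx(
            r1.asa_a_alone + r1.asa_b_alone - r1.asa_complex, rel=1e-9)

    def test_contacting_chains_bury_positive_area(self):
        atoms = ([atom(f"C{i}", "C", (1.9 * i, 0, 0), chain="A", resnum=i + 1)
                  for i in range(6)] +
                 [atom(f"C{i}", "C", (1.9 * i, 3.5, 0), chain="B", resnum=i + 1)
                  for i in range(6)])
        rep = buried_area(Structure(atoms=atoms), {"A"}, {"B"})
        assert rep.buried_area > 50.0

    def test_overlapping_chain_sets_rejected(self, toy_hexamer):
        st, _ = toy_hexamer
        with pytest.raises(ValueError):
            buried_area(st, {"A"}, {"A", "B"})


class TestSolventContent:
    CELL = CellParams(67.14, 186.16, 85.53, 90.0, 94.33, 90.0,
                      space_group="P 1 21 1", z_asu_per_cell=2)

    def test_algebraic_identity_vm_2p46(self):
        cell = CellParams(100.0, 100.0, 100.0, 90.0, 90.0, 90.0,
                          space_group="P 1", z_asu_per_cell=1)
        mass = cell.volume / 2.46
        rep = solvent_content(cell, mass)
        assert rep.solvent_fraction == pytest.approx(50.0, abs=1e-9)

    def test_limit_small_mass_approaches_hundred_percent(self):
        rep = solvent_content(self.CELL, 1.0)
        assert rep.solvent_fraction > 99.999
        assert not rep.physical or rep.matthews_vm > 1.230

    def test_round_trip_mass(self):
        rep = solvent_content(self.CELL, 222454.0)
        implied = rep.cell_volume / (2 * rep.matthews_vm)
        rep2 = solvent_content(self.CELL, implied)
        assert rep2.solvent_fraction == pytest.approx(rep.solvent_fraction,
                                                      abs=1e-9)

    def test_solvent_fraction_consistent_with_vm(self):
        rep = solvent_content(self.CELL, 200000.0)
        assert rep.solvent_fraction == pytest.approx(
            (1 - 1.230 / rep.matthews_vm) * 100.0, abs=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            solvent_content(self.CELL, 0.0)

    def test_mass_from_sequences(self):
        # glycine dipeptide: 2 * 57.0519 + water
        mass = asu_mass_from_sequences({"x": ("GG", 1)})
        assert mass == pytest.approx(2 * 57.0519 + 18.01528, abs=1e-3)
        with_ligand = asu_mass_from_sequences({"x": ("GG", 2)}, {"CYC": 3})
        assert with_ligand == pytest.approx(2 * mass + 3 * 586.68, abs=1e-2)


class TestCensus:
    def test_empty_structure_all_zero(self):
        c = census(Structure(atoms=[]))
        assert c["chains"] == 0 and c["non_hydrogen_atoms"] == 0
        assert c["ligand_residues"] == {}

    def test_counts_match_independent_groupby(self, toy_hexamer):
        st, _ = toy_hexamer
        c = census(st)
        assert c["chains"] == len({a.chain_id for a in st.atoms})
        assert c["ligand_residues"]["CYC"] == len(
            {(a.chain_id, a.residue_number) for a in st.atoms
             if a.residue_name == "CYC"})
        assert c["non_hydrogen_atoms"] == sum(
            1 for a in st.atoms if a.element not in ("H", "D"))

    def test_waters_counted_separately(self):
        atoms = [atom(), atom("O", "O", (5, 0, 0), resnum=2, resname="HOH",
                             is_hetero=True)]
        c = census(Structure(atoms=atoms))
        assert c["waters"] == 1
        assert "HOH" not in c["ligand_residues"]
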