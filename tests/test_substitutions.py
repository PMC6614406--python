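"""Alignment-derived substitutions, structural mapping, compensation."""

import numpy as np
import pytest
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phycostruct.substitutions import (AlignmentFormatError,
                                       NumberingMismatchError,
                                       compensatory_pairs, find_substitutions,
                                       map_to_structure, read_alignment)
from phycostruct.synthetic import make_alignment


def as_msa(rows: dict[str, str]) -> MultipleSeqAlignment:
    return MultipleSeqAlignment([SeqRecord(Seq(s), id=i) for i, s in rows.items()])


class TestReadAlignment:
    def test_fasta_and_clustal_agree(self, tmp_path):
        rows, _ = make_alignment(n_refs=3, length=40,
                                 planted_substitutions=[(5, "A", "G")],
                                 seed=1, path=tmp_path / "a.fasta")
        aln = read_alignment(tmp_path / "a.fasta", "fasta")
        AlignIO.write(aln, tmp_path / "a.aln", "clustal")
        aln2 = read_alignment(tmp_path / "a.aln", "clustal")
        assert {r.id: str(r.seq) for r in aln} == {r.id: str(r.seq) for r in aln2}

    def test_ragged_rows_rejected(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(tmp_path / "bad.fasta")

    def test_single_sequence_rejected(self, tmp_path):
        (tmp_path / "one.fasta").write_text(">a\nACDE\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(tmp_path / "one.fasta")


class TestFindSubstitutions:
    def test_table_preset_census(self, table1_fixture):
        paths, produced = table1_fixture
        records = {}
        for subunit in ("alpha", "beta"):
            aln = read_alignment(paths[subunit])
            records[subunit] = find_substitutions(aln, f"NPC_{subunit}",
                                                  subunit=subunit)
        assert len(records["alpha"]) == 3
        assert len(records["beta"]) == 9
        for subunit in ("alpha", "beta"):
            planted = {(p, c, q) for p, c, q in
                       produced[subunit][1].planted["substitutions"]}
            got = {(r.position, r.conserved_residue, r.query_residue)
                   for r in records[subunit]}
            assert got == planted

    def test_query_identical_to_consensus_empty(self):
        rows, _ = make_alignment(n_refs=4, length=30,
                                 planted_substitutions=[], seed=2)
        assert find_substitutions(as_msa(rows), "query") == []

    def test_random_plants_recovered(self):
        plants = [(3, "W", "F"), (11, "D", "E"), (27, "K", "R")]
        rows, man = make_alignment(n_refs=6, length=30,
                                   planted_substitutions=plants, seed=7)
        got = {(r.position, r.conserved_residue, r.query_residue)
               for r in find_substitutions(as_msa(rows), "query")}
        assert got == {tuple(p) for p in man.planted["substitutions"]}

    def test_invariant_to_row_order(self):
        rows, _ = make_alignment(n_refs=5, length=25,
                                 planted_substitutions=[(4, "L", "I")], seed=3)
        forward = find_substitutions(as_msa(rows), "query")
        reordered = as_msa(dict(reversed(list(rows.items()))))
        backward = find_substitutions(reordered, "query")
        assert [(r.position, r.query_residue) for r in forward] == \
            [(r.position, r.query_residue) for r in backward]

    def test_invariant_to_gap_only_column(self):
        rows, _ = make_alignment(n_refs=5, length=25,
                                 planted_substitutions=[(10, "N", "S")], seed=4)
        # insert a column that is gap in every reference and in the query
        gapped = {i: s[:6] + "-" + s[6:] for i, s in rows.items()}
        plain = find_substitutions(as_msa(rows), "query")
        withgap = find_substitutions(as_msa(gapped), "query")
        assert [(r.position, r.query_residue) for r in plain] == \
            [(r.position, r.query_residue) for r in withgap]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        rows, _ = make_alignment(n_refs=8, length=60,
                                 planted_substitutions=[(7, "C", "A"),
                                                        (30, "F", "Y")],
                                 seed=5)
        # degrade conservation at one planted column in a minority of refs
        broken = {}
        for i, s in rows.items():
            if i.startswith("ref") and i in ("ref1", "ref2"):
                s = s[:6] + rng.choice(list("GHK")) + s[7:]
            broken[i] = s
        counts = [len(find_substitutions(as_msa(broken), "query",
                                         conservation_threshold=t))
                  for t in (0.5, 0.75, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_missing_query_id(self):
        rows, _ = make_alignment(n_refs=3, length=10, seed=0)
        with pytest.raises(KeyError):
            find_substitutions(as_msa(rows), "nope")


class TestMapping:
    def test_maps_onto_expected_residues(self, compensation_fixture,
                                         table1_fixture):
        structure, manifest = compensation_fixture
        _, produced = table1_fixture
        records = []
        for subunit in ("alpha", "beta"):
            rows, _ = produced[subunit]
            records += find_substitutions(as_msa(rows), f"NPC_{subunit}",
                                          subunit=subunit)
        mapped = map_to_structure(records, structure,
                                  manifest.planted["chain_assignment"])
        assert all(m.is_mapped for m in mapped)
        beta56 = next(m for m in mapped
                      if m.record.subunit == "beta" and m.record.position == 56)
        chain, resnum, atoms = beta56.sites[0]
        assert (chain, resnum) == ("B", 56)
        assert atoms[0].residue_name == "VAL"

    def test_position_beyond_chain_flagged_unmapped(self, compensation_fixture):
        structure, _ = compensation_fixture
        from phycostruct.substitutions import SubstitutionRecord
        rec = SubstitutionRecord("beta", 999, "A", "V", 1.0)
        (m,) = map_to_structure([rec], structure, {"beta": ["B"]})
        assert not m.is_mapped
        assert m.unmapped_chains == ["B"]

    def test_numbering_drift_is_hard_error(self, compensation_fixture):
        structure, _ = compensation_fixture
        from phycostruct.substitutions import SubstitutionRecord
        # residue B87 is ASP in the model; claiming it should be TRP must fail
        rec = SubstitutionRecord("beta", 87, "E", "W", 1.0)
        with pytest.raises(NumberingMismatchError):
            map_to_structure([rec], structure, {"beta": ["B"]})

    def test_mapping_order_independent(self, compensation_fixture, rng):
        from phycostruct.structure_io import Structure
        structure, manifest = compensation_fixture
        from phycostruct.substitutions import SubstitutionRecord
        rec = SubstitutionRecord("beta", 60, "F", "W", 1.0)
        shuffled = list(structure.atoms)
        rng.shuffle(shuffled)
        m1 = map_to_structure([rec], structure, {"beta": ["B"]})[0]
        m2 = map_to_structure([rec], Structure(atoms=shuffled), {"beta": ["B"]})[0]
        assert {a.atom_name for a in m1.sites[0][2]} == \
            {a.atom_name for a in m2.sites[0][2]}


class TestCompensatoryPairs:
    @pytest.fixture()
    def mapped_records(self, compensation_fixture, table1_fixture):
        structure, manifest = compensation_fixture
        _, produced = table1_fixture
        records = []
        for subunit in ("alpha", "beta"):
            rows, _ = produced[subunit]
            records += find_substitutions(as_msa(rows), f"NPC_{subunit}",
                                          subunit=subunit)
        return structure, map_to_structure(records, structure,
                                           manifest.planted["chain_assignment"])

    def test_published_pairings_recovered(self, mapped_records):
        structure, mapped = mapped_records
        pairs = compensatory_pairs(mapped, structure)
        keyed = {frozenset([(p.record_a.subunit, p.record_a.position),
                            (p.record_b.subunit, p.record_b.position)]): p
                 for p in pairs}
        assert frozenset([("alpha", 18), ("beta", 87)]) in keyed
        assert frozenset([("beta", 60), ("beta", 79)]) in keyed
        assert frozenset([("beta", 56), ("beta", 83)]) in keyed
        assert frozenset([("beta", 56), ("beta", 86)]) in keyed
        assert keyed[frozenset([("alpha", 18), ("beta", 87)])].evidence == \
            "gained_hbond"
        assert keyed[frozenset([("beta", 60), ("beta", 79)])].evidence == \
            "volume_complementary"

    def test_pair_members_exist_in_input(self, mapped_records):
        structure, mapped = mapped_records
        inputs = {(m.record.subunit, m.record.position) for m in mapped}
        for p in compensatory_pairs(mapped, structure):
            assert (p.record_a.subunit, p.record_a.position) in inputs
            assert (p.record_b.subunit, p.record_b.position) in inputs

    def test_single_substitution_yields_nothing(self, mapped_records):
        structure, mapped = mapped_records
        assert compensatory_pairs(mapped[:1], structure) == []

    def test_volume_complementary_construction(self):
        """Two substituted residues 5 A apart with opposing volume changes."""
        from phycostruct.structure_io import Structure
        from phycostruct.substitutions import SubstitutionRecord
        from phycostruct.synthetic import make_residue
        atoms = make_residue("A", 10, "TRP", [
            ("N", "N", (-2, 1, 0)), ("CA", "C", (-1, 0, 0)),
            ("C", "C", (-2, -1, 0)), ("O", "O", (-3, -1, 0)),
            ("CB", "C", (0, 0, 0))])
        atoms += make_residue("A", 40, "ALA", [
            ("N", "N", (3, 1, 0)), ("CA", "C", (4, 0, 0)),
            ("C", "C", (3, -1, 0)), ("O", "O", (2, -1, 0)),
            ("CB", "C", (5, 0, 0))])
        st = Structure(atoms=atoms)
        recs = [SubstitutionRecord("beta", 10, "F", "W", 1.0),   # +37.9
                SubstitutionRecord("beta", 40, "M", "A", 1.0)]   # -74.3
        mapped = map_to_structure(recs, st, {"beta": ["A"]})
        (pair,) = compensatory_pairs(mapped, st)
        assert pair.min_distance == pytest.approx(5.0)
        assert pair.evidence == "volume_complementary"
        assert pair.net_volume_change == pytest.approx(-36.4, abs=0.2)
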