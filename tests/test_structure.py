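"""Structure parsing, interaction detectors, ensemble frequencies, tethers."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from dcx.structure import (
    Atom,
    Chain,
    Residue,
    Structure,
    StructureFormatError,
    TetherAnnotation,
    classify_tethers,
    detect_chpi,
    detect_hbonds,
    detect_vdw,
    ensemble_frequency,
    read_structure,
)
from dcx.synthetic import generate_helix, write_pdb


def _structure(residues, structure_id="test"):
    return Structure(structure_id, {"A": Chain("A", residues)})


def _res(num, name, atoms):
    return Residue(num, name, {a.name: a for a in atoms})


class TestReadStructure:
    def test_minimal_fixture_exact_coordinates(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  N   GLY A   2       3.300   1.100   0.000  1.00  0.00           N\n"
            "ATOM      4  CA  SER A   3       6.000   2.000   1.000  1.00  0.00           C\n"
            "END\n"
        )
        s = read_structure(pdb)
        assert sorted(s.chains["A"].residues) == [1, 2, 3]
        assert s.residue("A", 1).atom("CA").pos == (1.458, 0.0, 0.0)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        s = read_structure(pdb)
        assert s.residue("A", 1).atom("CA").pos[0] == 1.0

    def test_multi_model_takes_first(self, tmp_path):
        pdb = tmp_path / "nmr.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       9.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "END\n"
        )
        assert read_structure(pdb).residue("A", 1).atom("CA").pos[0] == 1.0

    def test_waters_and_ligands_dropped(self, tmp_path):
        pdb = tmp_path / "het.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = read_structure(pdb)
        assert list(s.chains["A"].residues) == [1]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureFormatError):
            read_structure(p)

    def test_helix_pdb_round_trip(self, helix12, tmp_path):
        s, truth = helix12
        p = tmp_path / "helix.pdb"
        write_pdb(s, p)
        s2 = read_structure(p)
        hb = sorted(
            (i.partner_a.number, i.partner_b.number) for i in detect_hbonds(s2)
        )
        assert tuple(hb) == truth.hbond_pairs


class TestHBonds:
    def test_close_pair_detected(self):
        # Bare N donor (no antecedents) and O acceptor at 2.9 A.
        s = _structure(
            {
                1: _res(1, "ALA", [Atom("N", "N", (0, 0, 0))]),
                5: _res(5, "ALA", [Atom("O", "O", (2.9, 0, 0))]),
            }
        )
        hb = detect_hbonds(s)
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9)

    def test_distant_pair_ignored(self):
        s = _structure(
            {
                1: _res(1, "ALA", [Atom("N", "N", (0, 0, 0))]),
                5: _res(5, "ALA", [Atom("O", "O", (10.0, 0, 0))]),
            }
        )
        assert detect_hbonds(s) == []

    def test_ideal_helix_recovers_exactly_i_i4(self, helix12):
        s, truth = helix12
        hb = detect_hbonds(s)
        pairs = sorted((i.partner_a.number, i.partner_b.number) for i in hb)
        assert tuple(pairs) == truth.hbond_pairs
        for i in hb:  # donor N, acceptor O, i -> i+4
            assert {i.partner_a.atom, i.partner_b.atom} == {"N", "O"}
            assert i.partner_b.number - i.partner_a.number == 4

    def test_sidechain_sidechain_close_separation_allowed(self):
        # Ser OG -> Asp OD1 between adjacent residues: side-chain/side-chain,
        # so the 2-residue separation rule does not apply.
        s = _structure(
            {
                1: _res(
                    1,
                    "SER",
                    [Atom("CB", "C", (0, 0, 0)), Atom("OG", "O", (1.4, 0, 0))],
                ),
                2: _res(2, "ASP", [Atom("OD1", "O", (4.3, 0, 0))]),
            }
        )
        hb = detect_hbonds(s)
        assert [(i.partner_a.atom, i.partner_b.atom) for i in hb] == [("OG", "OD1")]

    def test_antecedent_angle_filters(self):
        # Acceptor placed behind the donor's antecedent: angle ~0 -> rejected.
        s = _structure(
            {
                1: _res(
                    1,
                    "SER",
                    [Atom("CB", "C", (1.4, 0, 0)), Atom("OG", "O", (0, 0, 0))],
                ),
                5: _res(5, "ALA", [Atom("O", "O", (3.0, 0, 0))]),
            }
        )
        assert detect_hbonds(s) == []


class TestVdw:
    def test_carbon_pair_window(self):
        def pair_at(d):
            return _structure(
                {
                    1: _res(1, "ALA", [Atom("CB", "C", (0, 0, 0))]),
                    5: _res(5, "ALA", [Atom("CB", "C", (d, 0, 0))]),
                }
            )

        assert len(detect_vdw(pair_at(3.6))) == 1  # 1.7+1.7+0.5 = 3.9
        assert detect_vdw(pair_at(4.1)) == []

    def test_constructed_contact_count(self):
        # Exactly 3 CB-CB contacts by construction: residues on a line at
        # 3.8 A spacing -> adjacent-in-space pairs only (7.6 A next-nearest).
        residues = {
            num: _res(num, "ALA", [Atom("CB", "C", (3.8 * k, 0, 0))])
            for k, num in enumerate((1, 3, 5, 7))
        }
        assert len(detect_vdw(_structure(residues))) == 3

    def test_hbond_pairs_excluded(self):
        s = _structure(
            {
                1: _res(1, "ALA", [Atom("N", "N", (0, 0, 0))]),
                5: _res(5, "ALA", [Atom("O", "O", (2.9, 0, 0))]),
            }
        )
        assert detect_hbonds(s) != []
        assert detect_vdw(s) == []


class TestChPi:
    @staticmethod
    def _phe_ring(center=(0.0, 0.0, 0.0)):
        # Regular hexagon of radius 1.39 A in the xy plane.
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        atoms = []
        for k, name in enumerate(names):
            ang = k * np.pi / 3
            atoms.append(
                Atom(
                    name,
                    "C",
                    (
                        center[0] + 1.39 * np.cos(ang),
                        center[1] + 1.39 * np.sin(ang),
                        center[2],
                    ),
                )
            )
        return _res(10, "PHE", atoms)

    def test_carbon_above_ring_detected(self):
        s = _structure(
            {
                10: self._phe_ring(),
                1: _res(1, "ALA", [Atom("CB", "C", (0, 0, 3.8))]),
            }
        )
        hits = detect_chpi(s)
        assert len(hits) == 1
        assert hits[0].angle == pytest.approx(90.0, abs=1e-6)

    def test_carbon_in_plane_rejected(self):
        s = _structure(
            {
                10: self._phe_ring(),
                1: _res(1, "ALA", [Atom("CB", "C", (3.8, 0, 0))]),
            }
        )
        assert detect_chpi(s) == []


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("trial", range(8))
    def test_all_detectors_invariant(self, helix12, trial):
        s, _ = helix12
        rng = np.random.default_rng(trial)
        R = special_ortho_group.rvs(3, random_state=trial)
        t = rng.normal(scale=30.0, size=3)
        moved = s.transformed(R, t)
        for detect in (detect_hbonds, detect_vdw, detect_chpi):
            a = {
                (i.kind, i.partner_a.key(), i.partner_b.key()) for i in detect(s)
            }
            b = {
                (i.kind, i.partner_a.key(), i.partner_b.key())
                for i in detect(moved)
            }
            assert a == b


class TestEnsembleFrequency:
    def test_single_structure_all_frequencies_one(self, helix12):
        s, _ = helix12
        table = ensemble_frequency([s], range(1, 13), kinds=("hbond",))
        assert (table.rows["frequency"] == 1.0).all()

    def test_three_of_four(self, helix12):
        s, _ = helix12
        variants = []
        for k in range(4):
            v = s.transformed(np.eye(3), np.zeros(3))
            v.structure_id = f"s{k}"
            if k == 3:  # break the 1->5 bond by removing residue 1's O
                del v.chains["A"].residues[1].atoms["O"]
            variants.append(v)
        table = ensemble_frequency(variants, range(1, 13), kinds=("hbond",))
        row = table.rows.query("pos_a == 1 and pos_b == 5").iloc[0]
        assert row["n_present"] == 3 and row["n_total"] == 4
        assert row["frequency"] == pytest.approx(0.75)

    def test_disordered_residues_reduce_denominator(self, helix12):
        # Pair (1,5) present in the 2 complete structures; residue 5 deleted
        # in the other 2 -> denominator 2, frequency 1.0, coverage notes 2.
        s, _ = helix12
        structures = []
        for k in range(4):
            v = s.transformed(np.eye(3), np.zeros(3))
            v.structure_id = f"s{k}"
            if k >= 2:
                del v.chains["A"].residues[5]
            structures.append(v)
        table = ensemble_frequency(structures, range(1, 13), kinds=("hbond",))
        row = table.rows.query("pos_a == 1 and pos_b == 5").iloc[0]
        assert row["n_present"] == 2 and row["n_total"] == 2
        assert row["frequency"] == 1.0
        cov = table.coverage.query("refpos == 5").iloc[0]
        assert cov["n_missing"] == 2
        assert set(cov["missing_in"].split(",")) == {"s2", "s3"}

    def test_state_stratification(self, helix12):
        s, _ = helix12
        structures = []
        for k in range(4):
            v = s.transformed(np.eye(3), np.zeros(3))
            v.structure_id = f"s{k}"
            v.state_label = "active" if k < 2 else "inactive"
            if k == 3:
                del v.chains["A"].residues[1].atoms["O"]
            structures.append(v)
        table = ensemble_frequency(structures, range(1, 13), kinds=("hbond",))
        row = table.rows.query("pos_a == 1 and pos_b == 5").iloc[0]
        assert row["freq_active"] == 1.0
        assert row["freq_inactive"] == pytest.approx(0.5)

    def test_numbering_offset(self, helix12):
        s, _ = helix12
        s.structure_id = "offset_struct"
        table = ensemble_frequency(
            [s], range(101, 113), seq_offsets={"offset_struct": 100},
            kinds=("hbond",),
        )
        assert table.rows["pos_a"].min() == 101


class TestTetherClassification:
    def test_join_with_annotation(self, benchmark_msa):
        from dcx.contrast import ContrastModel

        aln, part, _ = benchmark_msa
        model = ContrastModel(
            aln, part, reference_id=aln.ids[0], signal_peptide_offset=24
        )
        res = model.fit()
        selected = res.selected_refpos
        assert selected
        annot = TetherAnnotation(
            {selected[0]: ("C-helix", "NLT"), selected[-1]: ("C-tail", "CLT")}
        )
        df = classify_tethers(res, annot)
        assert set(df["refpos"]) == set(selected)
        assert df.loc[df["refpos"] == selected[0], "tether_class"].iloc[0] == "NLT"
        unannotated = df.loc[~df["refpos"].isin(list(annot.regions)), "tether_class"]
        assert (unannotated == "none").all()

    def test_empty_selection_empty_report(self):
        from dcx.alignment import Alignment
        from dcx.contrast import ContrastModel, PartitionSpec

        aln = Alignment.from_pairs(
            [("f1", "AC"), ("f2", "AC"), ("b1", "AC"), ("b2", "AC")]
        )
        part = PartitionSpec(
            {"f1": "fore", "f2": "fore", "b1": "back", "b2": "back"}
        )
        res = ContrastModel(aln, part, reference_id="f1").fit()
        df = classify_tethers(res, TetherAnnotation({}))
        assert df.empty

    def test_annotation_tsv(self, tmp_path):
        p = tmp_path / "annot.tsv"
        p.write_text("refpos\tregion\ttether_class\n791\tinter-lobe linker\tAST\n")
        annot = TetherAnnotation.from_tsv(p)
        assert annot.regions[791] == ("inter-lobe linker", "AST")
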