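"""Domain types, file I/O, interaction typing and superposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import linkerdock as ld
from linkerdock.structures import detect_rotatable_torsions


@pytest.fixture()
def toy_pdb(tmp_path, toy_ensemble):
    models, _ = toy_ensemble
    path = tmp_path / "toy.pdb"
    ld.write_pdb(models[0], path)
    return path


class TestPdbIO:
    def test_three_residue_handwritten_pdb(self, tmp_path):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N\n"
            "ATOM      5  CA  GLY A   2       4.700   1.600   0.100  1.00  0.00           C\n"
            "ATOM      6  C   GLY A   2       5.400   2.900   0.000  1.00  0.00           C\n"
            "ATOM      7  N   SER A   3       6.700   3.000   0.000  1.00  0.00           N\n"
            "ATOM      8  CA  SER A   3       8.100   3.100   0.100  1.00  0.00           C\n"
            "ATOM      9  C   SER A   3       8.800   4.400   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "three.pdb"
        path.write_text(text)
        model = ld.read_pdb(path)
        assert sum(1 for _ in model.residues()) == 3
        assert model.n_atoms() == 9
        assert [r.name for r in model.residues()] == ["ALA", "GLY", "SER"]

    def test_round_trip_preserves_coordinates_and_identity(self, tmp_path, toy_pdb):
        model = ld.read_pdb(toy_pdb)
        out = tmp_path / "rt.pdb"
        ld.write_pdb(model, out)
        again = ld.read_pdb(out)
        assert np.abs(model.coords() - again.coords()).max() < 1e-3
        assert [r.key for r in model.residues()] == [r.key for r in again.residues()]
        assert [r.name for r in model.residues()] == [r.name for r in again.residues()]

    def test_two_chain_file_agrees_with_independent_parser(self, tmp_path):
        lines = []
        serial = 0
        for chain, offset in (("A", 0.0), ("B", 20.0)):
            for i in range(3):
                serial += 1
                lines.append(
                    f"ATOM  {serial:5d}  CA  GLY {chain}{i + 1:4d}    "
                    f"{offset + i * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
        path = tmp_path / "two_chain.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        model = ld.read_pdb(path)
        assert list(model.chains) == ["A", "B"]

        from Bio.PDB import PDBParser

        ref = PDBParser(QUIET=True).get_structure("x", str(path))[0]
        ref_atoms = [(c.id, r.id[1], a.get_name(), tuple(a.coord))
                     for c in ref for r in c for a in r]
        ours = [(res.chain_id, res.seq_number, a.name, tuple(a.coords))
                for res in model.residues() for a in res.atoms]
        assert len(ours) == len(ref_atoms)
        for (c1, s1, n1, x1), (c2, s2, n2, x2) in zip(ours, ref_atoms):
            assert (c1, s1, n1) == (c2, s2, n2)
            assert np.allclose(x1, x2, atol=1e-3)

    def test_missing_and_empty_files_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ld.read_pdb(tmp_path / "absent.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(ValueError):
            ld.read_pdb(empty)


class TestLigandIO:
    @pytest.mark.parametrize("name, expected_n_rot", [
        ("ethane", 0),       # terminal methyls excluded by the neighbour rule
        ("butane", 1),       # only the central C2–C3 bond
        ("cyclohexane", 0),  # ring bonds never rotatable
    ])
    def test_rotatable_bond_counts(self, sdf_dir, name, expected_n_rot):
        lig = ld.read_ligand(sdf_dir / f"{name}.sdf")
        assert lig.n_rot == expected_n_rot

    def test_butane_torsion_is_central_bond(self, sdf_dir):
        lig = ld.read_ligand(sdf_dir / "butane.sdf")
        (a, b, c, d) = lig.rotatable_torsions[0]
        assert {b, c} == {1, 2}

    def test_detection_matches_exhaustive_rule(self, sdf_dir, pyranose):
        # re-apply the rule bond by bond, independently of the implementation
        for lig in [ld.read_ligand(sdf_dir / "butane.sdf"), pyranose]:
            g = lig.bond_graph()
            import networkx as nx

            ring_atoms = set().union(*nx.cycle_basis(g)) if nx.cycle_basis(g) else set()
            expected = set()
            for (i, j, order) in lig.bonds:
                if order != 1:
                    continue
                in_ring = any(frozenset((i, j)) <= frozenset(cyc_pair)
                              for cyc in nx.cycle_basis(g)
                              for cyc_pair in zip(cyc, cyc[1:] + cyc[:1]))
                if in_ring:
                    continue
                heavy = lambda k: lig.atoms[k].element != "H"
                if not (heavy(i) and heavy(j)):
                    continue
                if any(heavy(n) for n in g.neighbors(i) if n != j) and \
                   any(heavy(n) for n in g.neighbors(j) if n != i):
                    expected.add(frozenset((i, j)))
            got = {frozenset((b, c)) for (_, b, c, _) in detect_rotatable_torsions(lig)}
            assert got == expected

    def test_unknown_format_errors(self, sdf_dir):
        with pytest.raises(ValueError):
            ld.read_ligand(sdf_dir / "ethane.sdf", fmt="pdbqt")


class TestInteractionClasses:
    def test_standard_protein_typing(self, toy_ensemble):
        models, _ = toy_ensemble
        model = models[0]
        ser = next(r for r in model.residues() if r.name == "SER")
        assert ser.atom("OG").interaction_class == "donor_acceptor"
        assert ser.atom("O").interaction_class == "acceptor"
        assert ser.atom("N").interaction_class == "donor"
        ala = next(r for r in model.residues() if r.name == "ALA")
        assert ala.atom("CB").interaction_class == "hydrophobic"

    def test_apolar_sidechain_carbon_is_hydrophobic(self):
        res = ld.Residue(chain_id="A", seq_number=1, name="LEU")
        atom = ld.Atom(serial=1, name="CD1", element="C", coords=(0, 0, 0), residue_ref=res.key)
        res.atoms.append(atom)
        model = ld.ProteinModel(model_id="m", chains={"A": [res]})
        ld.assign_interaction_classes(model)
        assert atom.interaction_class == "hydrophobic"

    def test_every_atom_classified(self, toy_ensemble, pyranose):
        models, _ = toy_ensemble
        for atom in models[0].atoms():
            assert atom.interaction_class is not None
        for atom in pyranose.atoms:
            assert atom.interaction_class is not None


class TestKabsch:
    def test_identity_and_halved_segment(self):
        P = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert ld.kabsch_rmsd(P, P) == 0.0
        Q = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert ld.kabsch_rmsd(P, Q) == pytest.approx(0.5, abs=1e-12)

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError):
            ld.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(7, 3))
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        t = rng.normal(size=3) * 10
        Q = P @ R.T + t
        assert ld.kabsch_rmsd(P, Q) < 1e-8
        A, B = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert ld.kabsch_rmsd(A, B) == pytest.approx(ld.kabsch_rmsd(B, A), abs=1e-8)
        assert ld.kabsch_rmsd(A @ R.T + t, B) == pytest.approx(ld.kabsch_rmsd(A, B), abs=1e-8)


class TestRmsdProfile:
    def test_identical_ensemble_is_all_zero(self, toy_ensemble):
        models, _ = toy_ensemble
        clones = [models[0]] * 4
        profile = ld.rmsd_profile(clones, 0)
        assert len(profile) == 4
        assert all(r == pytest.approx(0.0, abs=1e-8) for _, r in profile)

    def test_translation_is_removed(self, toy_ensemble):
        import copy

        models, _ = toy_ensemble
        shifted = copy.deepcopy(models[0])
        for atom in shifted.atoms():
            atom.coords = atom.coords + np.array([5.0, -3.0, 2.0])
        profile = ld.rmsd_profile([models[0], shifted], 0)
        assert profile[1][1] == pytest.approx(0.0, abs=1e-8)

    def test_profile_matches_per_frame_kabsch_oracle(self, toy_ensemble):
        models, _ = toy_ensemble
        profile = ld.rmsd_profile(models, 0)
        assert profile[0][1] == pytest.approx(0.0, abs=1e-10)
        ref_ca = np.array([r.atom("CA").coords for r in models[0].residues()])
        for (t, rmsd), model in zip(profile, models):
            ca = np.array([r.atom("CA").coords for r in model.residues()])
            assert rmsd == pytest.approx(ld.kabsch_rmsd(ca, ref_ca), abs=1e-10)
            assert t == model.time_label_ns


class TestRegionAnnotations:
    def test_span_parsing_round_trip(self, tmp_path):
        config = {"linker": ["A:15-24"], "pocket": ["A:31-35", "B:2"]}
        import yaml

        path = tmp_path / "regions.yaml"
        path.write_text(yaml.safe_dump(config))
        anns = ld.read_region_annotations(path)
        by_name = {a.region_name: a for a in anns}
        assert by_name["linker"].contains("A", 15)
        assert by_name["linker"].contains("A", 24)
        assert not by_name["linker"].contains("A", 25)
        assert by_name["pocket"].contains("B", 2)

        from linkerdock.structures import write_region_annotations

        out = tmp_path / "rt.yaml"
        write_region_annotations(anns, out)
        again = ld.read_region_annotations(out)
        assert {a.region_name: a.members for a in again} == {a.region_name: a.members for a in anns}

    def test_bad_span_errors(self):
        from linkerdock.structures import parse_region_spans

        with pytest.raises(ValueError):
            parse_region_spans({"linker": ["A15-24"]})
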