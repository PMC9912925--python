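"""Cluster selection, environment validation, capping and protonation."""

import numpy as np
import pytest

from qmrestraints.cluster import (build_ligand_cluster, cap_dangling_bonds,
                                  cluster_to_pdb, protonate_waters,
                                  validate_environment)
from qmrestraints.errors import SelectionError, ValidationError
from qmrestraints.fixtures import FixtureSpec, generate_fixture
from qmrestraints.geometry import bond_length, valence_angle
from qmrestraints.model import (Atom, Residue, ResidueKind, StructureModel,
                                UnitCell)
from qmrestraints.model_io import infer_connectivity

SEL = ("A", "LIG", 1)


def _ligand(position=(0.0, 0.0, 0.0)):
    residue = Residue("LIG", "A", 1, atoms=[
        Atom("C1", "C", np.asarray(position, float), serial=1)])
    residue.kind = ResidueKind.ligand
    return residue


def _water(position, seq=1, serial=10):
    residue = Residue("HOH", "W", seq, atoms=[
        Atom("O", "O", np.asarray(position, float), serial=serial)])
    residue.kind = ResidueKind.water
    return residue


def _model(residues, cell_edge=60.0):
    model = StructureModel(residues, UnitCell(cell_edge, cell_edge, cell_edge))
    model.renumber_serials()
    return model


class TestSelection:
    def test_threshold_includes_near_water_only(self):
        gly = Residue("GLY", "P", 1, atoms=[
            Atom("N", "N", [6.0, 0, 0], serial=0),
            Atom("CA", "C", [7.4, 0, 0], serial=0),
            Atom("C", "C", [8.0, 1.3, 0], serial=0),
            Atom("O", "O", [7.4, 2.3, 0], serial=0)])
        gly.kind = ResidueKind.amino_acid
        model = _model([_ligand(), _water([3.0, 0, 0]), gly])
        cluster = build_ligand_cluster(model, SEL, 3.5, include_symmetry=False)
        assert [r.comp_id for r in cluster.environment] == ["HOH"]

    @pytest.mark.parametrize("x,included", [(3.49, True), (3.51, False)])
    def test_cutoff_edge(self, x, included):
        model = _model([_ligand(), _water([x, 0, 0])])
        cluster = build_ligand_cluster(model, SEL, 3.5, include_symmetry=False)
        assert bool(cluster.environment) is included

    def test_whole_residue_rule(self):
        # only the carbonyl O is within the cutoff; the residue comes whole
        gly = Residue("GLY", "P", 1, atoms=[
            Atom("N", "N", [8.2, 0, 0], serial=0),
            Atom("CA", "C", [6.8, 0, 0], serial=0),
            Atom("C", "C", [4.6, 0.6, 0], serial=0),
            Atom("O", "O", [3.4, 0, 0], serial=0)])
        gly.kind = ResidueKind.amino_acid
        model = _model([_ligand(), gly])
        cluster = build_ligand_cluster(model, SEL, 3.5, include_symmetry=False)
        assert len(cluster.environment) == 1
        assert len(cluster.environment[0].atoms) == 4

    def test_radius_monotonicity_against_neighbor_oracle(self, rng):
        for _ in range(10):
            waters = [_water(rng.uniform(-8, 8, size=3), seq=i + 1)
                      for i in range(12)]
            model = _model([_ligand()] + waters)
            small = build_ligand_cluster(model, SEL, 3.5,
                                         include_symmetry=False)
            large = build_ligand_cluster(model, SEL, 5.0,
                                         include_symmetry=False)
            keys_small = {r.key for r in small.environment}
            keys_large = {r.key for r in large.environment}
            assert keys_small <= keys_large
            # plain neighbor-search oracle at 3.5
            expected = {w.key for w in waters
                        if np.linalg.norm(w.atoms[0].position) <= 3.5}
            assert keys_small == expected

    def test_selector_must_be_unique(self):
        model = _model([_ligand()])
        with pytest.raises(SelectionError):
            build_ligand_cluster(model, ("A", "LIG", 2))

    def test_symmetry_copies_have_provenance_and_fresh_serials(self):
        from qmrestraints.symcell import spacegroup_operators

        residue = _ligand([0.5, 0.5, 0.5])
        model = StructureModel([residue], UnitCell(4, 4, 4),
                               spacegroup_operators("P 1"), spacegroup="P 1")
        model.renumber_serials()
        cluster = build_ligand_cluster(model, SEL, 4.2)
        assert cluster.environment, "lattice copies expected in a 4 Å cell"
        serials = [a.serial for a in cluster.atoms()]
        assert len(serials) == len(set(serials))
        for copy in cluster.environment:
            assert copy.provenance[0] == "sym"


class TestValidation:
    def test_other_ligand_inside_radius(self):
        other = Residue("XYZ", "B", 1, atoms=[
            Atom("C1", "C", [4.9, 0, 0], serial=0)])
        other.kind = ResidueKind.ligand
        model = _model([_ligand(), other])
        report = validate_environment(model, SEL)
        assert report.other_ligand_within_5p5
        assert not report.clean

    def test_metal_outside_radius_is_ok(self):
        zinc = Residue("ZN", "M", 1, atoms=[
            Atom("ZN", "Zn", [6.0, 0, 0], serial=0)])
        model = _model([_ligand(), zinc])
        report = validate_environment(model, SEL)
        assert not report.metal_within_5p5
        near = Residue("ZN", "M", 2, atoms=[
            Atom("ZN", "Zn", [5.4, 0, 0], serial=0)])
        report2 = validate_environment(_model([_ligand(), near]), SEL)
        assert report2.metal_within_5p5

    def test_altloc_near_ligand_flagged(self):
        water = _water([4.0, 0, 0])
        water.atoms[0].altloc = "A"
        report = validate_environment(_model([_ligand(), water]), SEL)
        assert report.altloc_within_5p5 and not report.clean

    def test_missing_sidechain_atom_flagged(self):
        # SER missing its OG within 3.5 Å: flagged with the offender named
        ser = Residue("SER", "P", 1, atoms=[
            Atom("N", "N", [3.2, 2.2, 0], serial=0),
            Atom("CA", "C", [3.2, 0.8, 0], serial=0),
            Atom("C", "C", [4.4, 0.0, 0], serial=0),
            Atom("O", "O", [5.5, 0.5, 0], serial=0),
            Atom("CB", "C", [3.2, -0.7, 0], serial=0)])
        ser.kind = ResidueKind.amino_acid
        report = validate_environment(_model([_ligand(), ser]), SEL)
        assert report.missing_atoms_within_3p5
        (residue, absent), = report.missing_atom_offenders
        assert absent == ["OG"]

    def test_validation_radii_edges(self):
        for x, flagged in ((5.49, True), (5.51, False)):
            other = Residue("XYZ", "B", 1, atoms=[
                Atom("C1", "C", [x, 0, 0], serial=0)])
            other.kind = ResidueKind.ligand
            report = validate_environment(_model([_ligand(), other]), SEL)
            assert report.other_ligand_within_5p5 is flagged


def _cut_cluster():
    """Ligand covalently bonded to a residue straddling the cutoff."""
    lig = Residue("LIG", "A", 1, atoms=[
        Atom("C1", "C", [0, 0, 0], serial=1),
        Atom("O1", "O", [1.4, 0, 0], serial=2)])
    lig.kind = ResidueKind.ligand
    # two-residue peptide; res1 near the ligand, res2 outside the cutoff
    res1 = Residue("GLY", "P", 1, atoms=[
        Atom("N", "N", [0.0, 3.0, 0], serial=3),
        Atom("CA", "C", [1.4, 3.3, 0], serial=4),
        Atom("C", "C", [2.3, 4.4, 0], serial=5),
        Atom("O", "O", [1.9, 5.5, 0], serial=6)])
    res2 = Residue("GLY", "P", 2, atoms=[
        Atom("N", "N", [3.63, 4.2, 0], serial=7),
        Atom("CA", "C", [4.6, 5.2, 0], serial=8),
        Atom("C", "C", [6.0, 4.9, 0], serial=9),
        Atom("O", "O", [6.9, 5.7, 0], serial=10)])
    for r in (res1, res2):
        r.kind = ResidueKind.amino_acid
    model = StructureModel([lig, res1, res2], UnitCell(60, 60, 60))
    cluster = build_ligand_cluster(model, SEL, 3.5, include_symmetry=False)
    return model, cluster


class TestCapping:
    def test_peptide_cut_capped_along_bond_vector(self):
        model, cluster = _cut_cluster()
        assert len(cluster.environment) == 1
        assert len(cluster.cut_bonds) == 1
        cut = cluster.cut_bonds[0]
        assert (cut.inside_name, cut.outside_name) == ("C", "N")
        heavy_before = sum(1 for a in cluster.atoms() if not a.is_hydrogen)
        cap_dangling_bonds(cluster, "neutral")
        assert len(cluster.added_caps) == 1
        cap = cluster.added_caps[0].atom
        inside = cluster.atom_by_serial(cut.inside_serial)
        # placed along the former C->N vector at the C-H distance
        expected_dir = (cut.outside_position - cut.inside_position)
        expected_dir /= np.linalg.norm(expected_dir)
        assert np.allclose(cap.position,
                           inside.position + 1.09 * expected_dir, atol=1e-9)
        heavy_after = sum(1 for a in cluster.atoms() if not a.is_hydrogen)
        assert heavy_after == heavy_before

    def test_no_cut_bonds_is_identity(self):
        model = _model([_ligand(), _water([3.0, 0, 0])])
        cluster = build_ligand_cluster(model, SEL, 3.5,
                                       include_symmetry=False)
        before = [a.serial for a in cluster.atoms()]
        cap_dangling_bonds(cluster, "neutral")
        assert [a.serial for a in cluster.atoms()] == before
        assert not cluster.added_caps

    def test_zwitterion_carboxylate(self):
        model, cluster = _cut_cluster()
        cap_dangling_bonds(cluster, "zwitterion")
        cap = cluster.added_caps[0].atom
        assert cap.element == "O"
        inside = cluster.atom_by_serial(cluster.cut_bonds[0].inside_serial)
        assert bond_length(cap.position, inside.position) == pytest.approx(1.25)


class TestProtonation:
    def test_isolated_water_canonical_frame(self):
        model = _model([_ligand([30, 30, 30]), _water([0, 0, 0])])
        cluster = build_ligand_cluster(model, ("A", "LIG", 1), 200.0,
                                       include_symmetry=False)
        protonate_waters(cluster)
        water = next(r for r in cluster.environment
                     if r.kind is ResidueKind.water)
        hs = [a for a in water.atoms if a.is_hydrogen]
        assert len(hs) == 2
        o = water.get_atom("O")
        assert bond_length(o.position, hs[0].position) == pytest.approx(0.96)
        assert bond_length(o.position, hs[1].position) == pytest.approx(0.96)
        assert valence_angle(hs[0].position, o.position,
                             hs[1].position) == pytest.approx(104.5, abs=1e-6)

    def test_acceptor_directed_orientation(self):
        # water flanked by two carbonyl-like oxygens ~105° apart
        o1 = _water([2.9, 0, 0], seq=2, serial=20)   # acceptor 1 (a "water")
        o2 = _water([-0.75, 2.8, 0], seq=3, serial=30)
        target = _water([0, 0, 0], seq=1, serial=10)
        model = _model([_ligand([20, 20, 20]), target, o1, o2])
        cluster = build_ligand_cluster(model, ("A", "LIG", 1), 200.0,
                                       include_symmetry=False)
        protonate_waters(cluster)
        water = next(r for r in cluster.environment if r.seq_id == 1
                     and r.chain_id == "W")
        hs = [a for a in water.atoms if a.is_hydrogen]
        o = water.get_atom("O").position
        for h in hs:
            angles = [valence_angle(h.position, o, acc)
                      for acc in ([2.9, 0, 0], [-0.75, 2.8, 0])]
            assert min(angles) < 45.0

    def test_idempotent_and_deterministic(self):
        def build():
            model = _model([_ligand(), _water([3.0, 0, 0])])
            cluster = build_ligand_cluster(model, SEL, 3.5,
                                           include_symmetry=False)
            return protonate_waters(cluster)

        c1, c2 = build(), build()
        p1 = np.array([a.position for a in c1.atoms()])
        p2 = np.array([a.position for a in c2.atoms()])
        assert np.array_equal(p1, p2)
        # idempotence: a second pass changes nothing
        protonate_waters(c1)
        p3 = np.array([a.position for a in c1.atoms()])
        assert np.array_equal(p1, p3)

    def test_overprotonated_water_rejected(self):
        water = _water([3.0, 0, 0])
        for i, offset in enumerate(([0.9, 0, 0], [-0.3, 0.9, 0],
                                    [0, -0.9, 0.3])):
            water.atoms.append(Atom(f"H{i + 1}", "H",
                                    water.atoms[0].position + offset,
                                    serial=0))
        model = _model([_ligand(), water])
        cluster = build_ligand_cluster(model, SEL, 3.5,
                                       include_symmetry=False)
        with pytest.raises(ValidationError):
            protonate_waters(cluster)

    def test_half_protonated_water_completed(self):
        water = _water([3.0, 0, 0])
        water.atoms.append(Atom("H1", "H",
                                water.atoms[0].position + [0.96, 0, 0],
                                serial=0))
        model = _model([_ligand(), water])
        cluster = build_ligand_cluster(model, SEL, 3.5,
                                       include_symmetry=False)
        protonate_waters(cluster)
        hs = [a for a in cluster.environment[0].atoms if a.is_hydrogen]
        assert len(hs) == 2
        o = cluster.environment[0].get_atom("O").position
        assert valence_angle(hs[0].position, o,
                             hs[1].position) == pytest.approx(104.5, abs=1e-6)


class TestExport:
    def test_cluster_pdb_has_remarks_and_reparses(self, clean_fixture):
        from qmrestraints.model_io import parse_structure

        model, dictionary, _ = clean_fixture
        cluster = build_ligand_cluster(model, SEL, 3.5,
                                       dictionaries={"LIG": dictionary})
        protonate_waters(cap_dangling_bonds(cluster))
        text = cluster_to_pdb(cluster)
        assert "REMARK 350 LIGAND CLUSTER" in text
        assert "ADDED PROTON" in text
        back = parse_structure(text, "pdb")
        assert back.atom_count == sum(1 for _ in cluster.atoms())
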