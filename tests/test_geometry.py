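"""Internal-coordinate measurement and deviation arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmrestraints.errors import UndefinedTorsionError, ValidationError
from qmrestraints.geometry import (assign_bin, binned_summary, bond_length,
                                   geometry_report, resolution_bin_edges,
                                   signed_deviation, torsion_angle,
                                   valence_angle, wrap_angle)
from qmrestraints.restraints import (AngleRestraint, AtomSpec, BondRestraint,
                                     RestraintDictionary, TorsionRestraint)


def reference_torsion(p1, p2, p3, p4):
    """Independent formulation: angle between plane normals, signed by the
    projection of the 1→2 bond onto the second normal."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    cosphi = np.clip(np.dot(n1, n2), -1, 1)
    phi = math.degrees(math.acos(cosphi))
    if np.dot(n1, b3) < 0:
        phi = -phi
    return wrap_angle(phi)


class TestPrimitives:
    def test_planar_cis_square(self):
        corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
        assert torsion_angle(*corners) == pytest.approx(0.0, abs=1e-12)

    def test_trans_zigzag(self):
        zigzag = [(0, 1, 0), (1, 0, 0), (2, 0, 0), (3, -1, 0)]
        assert abs(torsion_angle(*zigzag)) == pytest.approx(180.0)

    def test_torsion_matches_independent_formula(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                ours = torsion_angle(*pts)
            except UndefinedTorsionError:
                continue
            assert ours == pytest.approx(reference_torsion(*pts), abs=1e-9)

    def test_collinear_torsion_is_undefined(self):
        with pytest.raises(UndefinedTorsionError):
            torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_angle_and_bond(self):
        assert bond_length((0, 0, 0), (0, 3, 4)) == pytest.approx(5.0)
        assert valence_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)


class TestSignedDeviation:
    # Δ = target − actual, checked against the published worked examples of
    # refined berberine (BER) and biotinylated pyrrolidine (EYW) geometries
    @pytest.mark.parametrize("kind,target,actual,expected,tol", [
        ("bond", 1.419, 1.394, 0.025, 1e-3),     # BER C20—O4
        ("bond", 1.430, 1.409, 0.021, 1e-3),     # BER C19—O3
        ("angle", 109.7, 117.3, -7.6, 0.1),      # BER C10—C7—N1
        ("angle", 109.0, 115.7, -6.7, 0.1),      # BER C4—C10—C7
        ("angle", 115.2, 121.3, -6.1, 0.1),      # BER C15—O3—C19
        ("torsion", 58.0, -18.7, 76.7, 0.1),     # BER C4—C10—C7—N1
        ("torsion", 43.0, -13.1, 56.1, 0.1),     # BER C1—C7—N1—C10
        ("torsion", 35.8, -12.4, 48.2, 0.1),     # BER C2—C10—C4—C7
        ("angle", 111.6, 118.8, -7.2, 0.1),      # EYW C15—C1—N12
        ("torsion", 210.9, 143.3, 67.6, 0.1),    # EYW C9—C10—C11—N12 (wraps)
        ("torsion", 37.2, -16.4, 53.6, 0.1),     # EYW C1—C15—N14—C13
        ("torsion", -6.5, 31.8, -38.4, 0.1),     # EYW C1—C12—C13—N14
    ])
    def test_published_outlier_rows(self, kind, target, actual, expected, tol):
        if kind == "torsion":
            target = wrap_angle(target)
        assert signed_deviation(kind, target, actual) == pytest.approx(
            expected, abs=tol)

    def test_methyl_propeller_periodicity(self):
        # period-3 well at 60° has equivalent minima at 180° and 300°;
        # an actual of 175° deviates 5° from the nearest minimum (180°)
        assert signed_deviation("torsion", 60.0, 175.0, periodicity=3) == \
            pytest.approx(5.0)

    def test_identity(self):
        for kind in ("bond", "angle", "torsion"):
            assert signed_deviation(kind, 1.5, 1.5) == 0.0

    def test_alternatives_pick_nearest(self):
        # ring-pucker style: explicit aperiodic alternative target
        delta = signed_deviation("torsion", 170.0, -70.0, alternatives=[-65.0])
        assert delta == pytest.approx(5.0)

    def test_invalid_periodicity(self):
        with pytest.raises(ValidationError):
            signed_deviation("torsion", 60.0, 0.0, periodicity=0)

    @given(target=st.floats(-180, 180, exclude_min=True),
           actual=st.floats(-180, 180, exclude_min=True),
           period=st.integers(1, 6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_periodicity_equals_bruteforce(self, target, actual, period):
        candidates = [wrap_angle(target + k * 360.0 / period)
                      for k in range(period)]
        brute = min((wrap_angle(c - actual) for c in candidates), key=abs)
        ours = signed_deviation("torsion", target, actual, period)
        assert abs(ours) == pytest.approx(abs(brute), abs=1e-9)
        assert abs(ours) <= 180.0 / period + 1e-9

    def test_bruteforce_agreement_bulk(self, rng):
        # dense randomized sweep incl. aperiodic alternatives
        for _ in range(10_000):
            target = float(rng.uniform(-180, 180))
            actual = float(rng.uniform(-180, 180))
            period = int(rng.integers(1, 7))
            alts = [float(a) for a in rng.uniform(-180, 180,
                                                  size=rng.integers(0, 3))]
            candidates = [wrap_angle(target + k * 360.0 / period)
                          for k in range(period)] + [wrap_angle(a)
                                                     for a in alts]
            brute = min((wrap_angle(c - actual) for c in candidates), key=abs)
            ours = signed_deviation("torsion", target, actual, period,
                                    alts or None)
            assert abs(abs(ours) - abs(brute)) < 1e-9


def _single_category_dictionary():
    atoms = [AtomSpec("A1", "C"), AtomSpec("A2", "C"), AtomSpec("A3", "C"),
             AtomSpec("A4", "C"), AtomSpec("H1", "H")]
    return RestraintDictionary(
        "TST", atoms,
        bonds=[BondRestraint(("A1", "A2"), 1.5, 0.02)],
        angles=[AngleRestraint(("A1", "A2", "A3"), 109.5, 2.0),
                AngleRestraint(("A1", "A2", "H1"), 109.5, 3.0)],
        torsions=[TorsionRestraint(("A1", "A2", "A3", "A4"), 60.0, 30.0)])


class TestGeometryReport:
    def test_exact_coordinates_give_zero(self, clean_fixture):
        model, dictionary, _ = clean_fixture
        ligand = model.find_residues("A", "LIG", 1)[0]
        report = geometry_report(ligand, dictionary)
        assert report.rmsd_bonds == pytest.approx(0.0, abs=1e-6)
        assert report.rmsd_angles == pytest.approx(0.0, abs=1e-3)
        assert report.rmsd_torsions == pytest.approx(0.0, abs=1e-3)
        assert not report.outliers()

    def test_single_angle_rmsd_is_absolute_deviation(self):
        d = _single_category_dictionary()
        coords = {
            "A1": np.array([1.0, 0.0, 0.0]),
            "A2": np.zeros(3),
            "A3": np.array([math.cos(math.radians(117.1)),
                            math.sin(math.radians(117.1)), 0.0]),
        }
        report = geometry_report(coords, d)
        assert report.rmsd_angles == pytest.approx(7.6, abs=1e-6)
        # the measurable bond is reported too; the torsion (A4 missing) is not
        assert len(report._category("bond")) == 1
        assert report.rmsd_torsions is None

    def test_rmsd_matches_hand_formula(self):
        # the three published GeoStd torsion outliers of berberine
        deltas = [76.7, 56.1, 48.2]
        expected = math.sqrt(sum(d * d for d in deltas) / 3)
        assert expected == pytest.approx(61.518, abs=0.001)

    def test_h_restraints_excluded_by_default(self):
        d = _single_category_dictionary()
        gen = np.random.default_rng(0)
        coords = {n: gen.normal(size=3) * 2
                  for n in ("A1", "A2", "A3", "A4", "H1")}
        rep = geometry_report(coords, d, include_h=False)
        assert all("H1" not in r.atoms for r in rep.records)
        rep_h = geometry_report(coords, d, include_h=True)
        assert any("H1" in r.atoms for r in rep_h.records)

    def test_empty_category_is_undefined_not_zero(self):
        d = _single_category_dictionary()
        coords = {"A1": np.zeros(3), "A2": np.array([1.5, 0, 0])}
        rep = geometry_report(coords, d)
        assert rep.rmsd_torsions is None
        assert rep.rmsd_bonds == pytest.approx(0.0)

    def test_rmsd_invariant_to_rigid_motion(self, clean_fixture, rng):
        model, dictionary, _ = clean_fixture
        ligand = model.find_residues("A", "LIG", 1)[0]
        coords = {a.name: a.position for a in ligand.atoms}
        base = geometry_report(coords, dictionary)
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        u, _, vt = np.linalg.svd(q)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        shift = rng.normal(size=3) * 10
        moved = {n: rot @ p + shift for n, p in coords.items()}
        rep = geometry_report(moved, dictionary)
        assert rep.rmsd_angles == pytest.approx(base.rmsd_angles, abs=1e-8)
        assert rep.rmsd_torsions == pytest.approx(base.rmsd_torsions, abs=1e-6)
        assert rep.rmsd_bonds == pytest.approx(base.rmsd_bonds, abs=1e-9)


class TestBinnedSummary:
    def test_bin_edges_and_assignment(self):
        edges = resolution_bin_edges()
        assert edges[0] == 0.8 and edges[1] == 1.4 and edges[-1] == 3.0
        assert assign_bin(1.39, edges) == 0
        assert assign_bin(1.41, edges) == 1
        assert assign_bin(1.4, edges) == 0

    def test_identical_values_have_zero_sem(self):
        summary = binned_summary({"a": [(1.0, 2.0)] * 5, "b": [(1.0, 2.5)] * 5})
        assert summary.mean["a"][0] == pytest.approx(2.0)
        assert summary.sem["a"][0] == pytest.approx(0.0)

    def test_small_bins_are_undefined(self):
        summary = binned_summary({"a": [(1.0, 2.0)], "b": [(1.0, 2.5)]})
        assert summary.sem["a"][0] is None
        assert summary.p_values[0] is None

    def test_null_pvalues_roughly_uniform(self):
        # both conditions drawn from one distribution: p should rarely be
        # small (this is the behavior of a well-calibrated Welch test)
        rng = np.random.default_rng(7)
        low = 0
        for _ in range(100):
            a = [(1.0, v) for v in rng.normal(2.0, 0.3, size=20)]
            b = [(1.0, v) for v in rng.normal(2.0, 0.3, size=20)]
            p = binned_summary({"a": a, "b": b}).p_values[0]
            if p <= 0.01:
                low += 1
        assert low <= 5

    def test_frame_roundtrip(self):
        summary = binned_summary({"a": [(1.0, 2.0)] * 3, "b": [(2.5, 1.0)] * 4})
        frame = summary.to_frame()
        assert frame["n_a"].sum() == 3
        assert frame["n_b"].sum() == 4
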