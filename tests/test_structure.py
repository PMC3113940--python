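"""Structure parsing and residue-descriptor computation."""

import math

import numpy as np
import pytest

from stabscan import constants as C
from stabscan.structure import (EmptyStructureError, StructureParseError,
                                classify_core_surface, compute_accessibility,
                                descriptor_table, load_structure,
                                parse_structure, pairwise_centroid_distances)
from stabscan.synthetic import make_toy_structure


def _drop_atom(pdb_text: str, resseq: int, atom: str) -> str:
    kept = []
    for line in pdb_text.splitlines():
        if (line.startswith("ATOM") and int(line[22:26]) == resseq
                and line[12:16].strip() == atom):
            continue
        kept.append(line)
    return "\n".join(kept) + "\n"


class TestParsing:
    def test_polyalanine_fixture(self, polyala_pdb):
        s = parse_structure(polyala_pdb, structure_id="polyA")
        assert len(s) == 5
        assert all(r.aa == "A" for r in s.residues)

    def test_repeated_parse_is_identical(self, polyala_pdb):
        s1 = load_structure(polyala_pdb, structure_id="x")
        s2 = load_structure(polyala_pdb, structure_id="x")
        for r1, r2 in zip(s1.residues, s2.residues):
            assert (r1.chain, r1.seq_number, r1.aa, r1.t_label) == \
                   (r2.chain, r2.seq_number, r2.aa, r2.t_label)
            assert r1.a == r2.a
            assert np.array_equal(r1.centroid, r2.centroid)
        assert s1.pairs == s2.pairs

    def test_residue_missing_backbone_atom_excluded(self, polyala_pdb):
        s = parse_structure(_drop_atom(polyala_pdb, 3, "CA"), structure_id="gap")
        assert len(s) == 4
        assert [r.resseq for r in s.residues] == [1, 2, 4, 5]

    def test_garbage_input_raises_parse_error(self):
        with pytest.raises(StructureParseError):
            parse_structure("this is not\na PDB file\n", structure_id="junk")

    def test_hetatm_and_water_ignored(self, polyala_pdb):
        extra = (
            "HETATM  999  O   HOH A 101      10.000  10.000  10.000"
            "  1.00  0.00           O\n")
        s = parse_structure(polyala_pdb + extra, structure_id="wet")
        assert len(s) == 5

    def test_altloc_resolved_to_highest_occupancy(self):
        base = make_toy_structure(4, "helix", seed=5, sequence="AAAA")
        lines = []
        for line in base.splitlines():
            if (line.startswith("ATOM") and int(line[22:26]) == 2
                    and line[12:16].strip() == "CB"):
                a = line[:16] + "A" + line[17:54] + "  0.30" + line[60:]
                moved = f"{float(line[30:38]) + 2.0:8.3f}"
                b = line[:16] + "B" + line[17:30] + moved + line[38:54] \
                    + "  0.70" + line[60:]
                lines += [a, b]
            else:
                lines.append(line)
        s = parse_structure("\n".join(lines) + "\n", structure_id="alt")
        cb_x = s.residues[1].centroid[0]
        base_s = parse_structure(base, structure_id="base")
        assert cb_x == pytest.approx(base_s.residues[1].centroid[0] + 2.0, abs=1e-3)

    def test_chain_filter_and_empty_error(self, polyala_pdb):
        with pytest.raises(EmptyStructureError):
            parse_structure(polyala_pdb, chain_filter=["Z"], structure_id="none")


class TestAccessibility:
    def test_isolated_residue_fully_exposed(self):
        # a single residue with nothing around it: everything the reference
        # tripeptide state exposes (and more) is accessible.  Alanine is the
        # one residue whose toy atom set (N, CA, C, O, CB) matches the real
        # one, so its reference area is meaningful for an isolated residue.
        text = make_toy_structure(3, "helix", seed=7, sequence="AAA")
        single = "\n".join(
            line for line in text.splitlines()
            if not (line.startswith("ATOM") and int(line[22:26]) != 2)) + "\n"
        s = load_structure(single, structure_id="iso")
        assert s.residues[0].a >= 95.0

    def test_caged_residue_buried(self):
        # surround one residue with a dense closed shell of atoms
        text = make_toy_structure(3, "helix", seed=7, sequence="AAA")
        lines = [l for l in text.splitlines()
                 if l.startswith("ATOM") and int(l[22:26]) == 2]
        coords = np.array([[float(l[30:38]), float(l[38:46]), float(l[46:54])]
                           for l in lines])
        center = coords.mean(axis=0)
        # Fibonacci sphere, 600 points at 6.0 Å: gaps far below probe size
        n = 600
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5 ** 0.5) * k
        shell = center + 6.0 * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
             np.cos(phi)])
        cage_lines = list(lines)
        serial = 100
        for g, i in enumerate(range(0, n - 2, 3)):
            for name, p in zip(("N", "CA", "C"), shell[i:i + 3]):
                cage_lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} GLY A{g + 10:4d}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}")
                serial += 1
        s = load_structure("\n".join(cage_lines) + "\n", structure_id="cage")
        target = next(r for r in s.residues if r.resseq == 2)
        assert target.a < 5.0

    def test_quadrature_convergence(self, polyala_pdb):
        s1 = parse_structure(polyala_pdb, structure_id="q")
        a1 = compute_accessibility(s1, n_points=960)
        s2 = parse_structure(polyala_pdb, structure_id="q")
        a2 = compute_accessibility(s2, n_points=1920)
        assert np.all(np.abs(a1 - a2) < 2.0)


class TestTorsion:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-57.0, -47.0, "helical"),
        (-120.0, 130.0, "extended"),
        (-75.0, 145.0, "polyproline"),
        (60.0, 45.0, "left_helical"),
        (75.0, 130.0, "epsilon"),
        (75.0, -130.0, "gamma"),
        (0.0, 0.0, "other"),
        (None, -47.0, "undefined"),
        (-57.0, None, "undefined"),
    ])
    def test_domain_partition(self, phi, psi, expected):
        assert C.torsion_domain(phi, psi) == expected

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        for phi, psi in rng.uniform(-180, 180, size=(500, 2)):
            assert C.torsion_domain(phi, psi) in C.TORSION_DOMAINS

    def test_termini_undefined(self, helix30):
        assert helix30.residues[0].t_label == C.TORSION_UNDEFINED
        assert helix30.residues[-1].t_label == C.TORSION_UNDEFINED
        interior = [r.t_label for r in helix30.residues[1:-1]]
        assert all(t != C.TORSION_UNDEFINED for t in interior)


class TestDistances:
    def test_three_four_five_triangle(self):
        # residues 1 and 3 (separation 2) with CB centroids 5 Å apart
        lines = []
        serial = 1
        positions = {
            1: {"N": (-30, 0, 0), "CA": (-29, 0, 0), "C": (-28, 0, 0),
                "CB": (0, 0, 0)},
            2: {"N": (40, 40, 0), "CA": (41, 40, 0), "C": (42, 40, 0),
                "CB": (43, 40, 0)},
            3: {"N": (30, 0, 0), "CA": (31, 0, 0), "C": (32, 0, 0),
                "CB": (3, 4, 0)},
        }
        for resseq, atoms in positions.items():
            for name, (x, y, z) in atoms.items():
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} ALA A{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}")
                serial += 1
        s = load_structure("\n".join(lines) + "\n", structure_id="tri")
        assert s.pairs == {(0, 2): pytest.approx(5.0, abs=1e-9)}

    def test_cutoff_excludes_far_pair(self, mixed20):
        pairwise_centroid_distances(mixed20, cutoff=8.0)
        assert all(d <= 8.0 for d in mixed20.pairs.values())
        far = pairwise_centroid_distances(mixed20, cutoff=6.0)
        assert all(d <= 6.0 for d in far.values())
        pairwise_centroid_distances(mixed20, cutoff=8.0)  # restore

    def test_matches_brute_force(self, mixed20):
        expected = {}
        for i in range(len(mixed20)):
            for j in range(i + 1, len(mixed20)):
                if abs(i - j) < C.MIN_SEQUENCE_SEPARATION:
                    continue
                d = float(np.linalg.norm(mixed20.residues[i].centroid
                                         - mixed20.residues[j].centroid))
                if d <= 8.0:
                    expected[(i, j)] = d
        assert set(mixed20.pairs) == set(expected)
        for k, d in expected.items():
            assert mixed20.pairs[k] == pytest.approx(d, abs=1e-9)


class TestCoreSurface:
    @pytest.mark.parametrize("a,expected", [
        (0.0, "core"), (9.99, "core"), (10.0, "surface"), (100.0, "surface"),
    ])
    def test_boundary_convention(self, helix30, a, expected):
        r = helix30.residues[5]
        saved = r.a
        r.a = a
        try:
            assert classify_core_surface(helix30)[5] == expected
        finally:
            r.a = saved

    def test_table_shape(self, helix30):
        df = descriptor_table(helix30)
        assert len(df) == len(helix30)
        assert set(df["burial"]) <= {"core", "surface"}


class TestRigidBodyInvariance:
    def test_descriptors_invariant_under_rotation(self):
        text = make_toy_structure(15, "mixed", seed=9)
        s0 = load_structure(text, structure_id="orig")
        # rotate + translate every coordinate, rewrite at PDB precision
        ang = 0.7
        R = np.array([[math.cos(ang), -math.sin(ang), 0],
                      [math.sin(ang), math.cos(ang), 0],
                      [0, 0, 1.0]])
        R2 = np.array([[1, 0, 0],
                       [0, math.cos(0.4), -math.sin(0.4)],
                       [0, math.sin(0.4), math.cos(0.4)]])
        M = R2 @ R
        shift = np.array([5.0, -3.0, 11.0])
        lines = []
        for line in text.splitlines():
            if line.startswith("ATOM"):
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                x, y, z = M @ xyz + shift
                line = line[:30] + f"{x:8.3f}{y:8.3f}{z:8.3f}" + line[54:]
            lines.append(line)
        s1 = load_structure("\n".join(lines) + "\n", structure_id="rot")
        # torsion labels are exact; distances match to coordinate precision;
        # accessibility to the resolution of the sphere quadrature
        assert [r.t_label for r in s0.residues] == [r.t_label for r in s1.residues]
        assert set(s0.pairs) == set(s1.pairs)
        for k in s0.pairs:
            assert s0.pairs[k] == pytest.approx(s1.pairs[k], abs=5e-3)
        for r0, r1 in zip(s0.residues, s1.residues):
            assert r0.a == pytest.approx(r1.a, abs=1.0)
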