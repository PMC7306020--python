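"""Tetrahedral element metrics and the mesh acceptance audit."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelvimech import (QualityCriteria, TetMesh, aspect_ratio, audit_mesh,
                       dihedral_angles, read_mesh, scaled_jacobian)
from pelvimech.mesh import edge_lengths

from conftest import regular_tet_with_edge

RIGHT_CORNER = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
COPLANAR = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)


def build_mesh_of_tets(tets):
    """Pack independent tetrahedra into one TetMesh (no shared nodes)."""
    nodes = np.vstack(tets)
    conn = np.arange(len(nodes)).reshape(-1, 4)
    return TetMesh(nodes, conn)


class TestElementMetrics:
    def test_regular_tet_closed_forms(self, regular_tet):
        assert aspect_ratio(regular_tet) == pytest.approx(np.sqrt(1.5), rel=1e-12)
        d = dihedral_angles(regular_tet)
        assert d == pytest.approx(np.degrees(np.arccos(1 / 3)), rel=1e-12)
        assert d.sum() == pytest.approx(6 * np.degrees(np.arccos(1 / 3)))
        assert scaled_jacobian(regular_tet) == pytest.approx(1.0, rel=1e-12)

    def test_right_corner_tet_has_three_right_dihedrals(self):
        d = np.sort(dihedral_angles(RIGHT_CORNER))
        assert d[-3:] == pytest.approx([90.0, 90.0, 90.0])

    def test_rigid_motion_invariance(self, regular_tet, rng):
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        shift = rng.normal(size=3) * 40
        moved = regular_tet @ rot.T + shift
        assert aspect_ratio(moved) == pytest.approx(aspect_ratio(regular_tet))
        assert np.sort(dihedral_angles(moved)) == pytest.approx(
            np.sort(dihedral_angles(regular_tet)))
        assert scaled_jacobian(moved) == pytest.approx(
            scaled_jacobian(regular_tet))

    @pytest.mark.parametrize("c", [0.1, 2.0, 37.5])
    def test_uniform_scaling(self, regular_tet, c):
        scaled = c * regular_tet
        assert aspect_ratio(scaled) == pytest.approx(aspect_ratio(regular_tet))
        assert scaled_jacobian(scaled) == pytest.approx(
            scaled_jacobian(regular_tet))
        assert edge_lengths(scaled) == pytest.approx(c * edge_lengths(regular_tet))

    def test_regular_tet_minimises_aspect_ratio(self, regular_tet, rng):
        base = aspect_ratio(regular_tet)
        for _ in range(50):
            perturbed = regular_tet + rng.normal(0, 0.25, (4, 3))
            if abs(np.linalg.det(perturbed[1:] - perturbed[0])) < 1e-9:
                continue
            assert aspect_ratio(perturbed) >= base - 1e-9

    def test_coplanar_degenerates(self):
        assert aspect_ratio(COPLANAR) == np.inf
        assert scaled_jacobian(COPLANAR) == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            dihedral_angles(COPLANAR)

    def test_vertex_swap_flips_jacobian_sign(self, regular_tet):
        swapped = regular_tet[[1, 0, 2, 3]]
        assert scaled_jacobian(swapped) == pytest.approx(
            -scaled_jacobian(regular_tet))

    def test_duplicated_vertices_rejected(self):
        bad = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        with pytest.raises(ValueError, match="duplicated"):
            aspect_ratio(bad)


class TestAudit:
    def test_two_mm_regular_tet_passes_everything(self):
        report = audit_mesh(build_mesh_of_tets([regular_tet_with_edge(2.0)]))
        assert report.pct_ar_gt_3 == 0.0
        assert not report.any_nonpositive_jacobian
        assert not report.any_jacobian_below_0_2
        assert not report.any_dihedral_outside_30_120
        assert not report.any_edge_outside_1_3mm
        assert report.passes_paper_criteria

    def test_five_mm_regular_tet_fails_only_edge_length(self):
        report = audit_mesh(build_mesh_of_tets([regular_tet_with_edge(5.0)]))
        assert report.any_edge_outside_1_3mm
        assert not report.passes_paper_criteria
        assert report.pct_ar_gt_3 == 0.0
        assert not report.any_nonpositive_jacobian
        assert not report.any_jacobian_below_0_2
        assert not report.any_dihedral_outside_30_120

    def test_hundred_element_mesh_with_six_violators(self):
        """6/100 elements stretched above AR 3 -> 6.0% and a failed audit."""
        good = regular_tet_with_edge(2.0)
        bad = good.copy()
        bad[:, 0] *= 12.0  # strong uniaxial stretch drives AR >> 3
        assert aspect_ratio(bad) > 3
        mesh = build_mesh_of_tets([bad] * 6 + [good] * 94)
        report = audit_mesh(mesh)
        assert report.n_elements == 100
        assert report.pct_ar_gt_3 == 6.0
        assert not report.passes_paper_criteria

    def test_percentage_threshold_is_exact_at_boundary(self):
        # exactly 5% violators must FAIL the strict '< 5%' criterion
        good = regular_tet_with_edge(2.0)
        bad = good.copy()
        bad[:, 0] *= 12.0
        report = audit_mesh(build_mesh_of_tets([bad] + [good] * 19))
        assert report.pct_ar_gt_3 == 5.0
        assert not report.passes_paper_criteria

    def test_criteria_overrides(self):
        report = audit_mesh(build_mesh_of_tets([regular_tet_with_edge(5.0)]),
                            QualityCriteria(edge_max_mm=6.0))
        assert report.passes_paper_criteria

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            audit_mesh(TetMesh(np.zeros((0, 3)), np.zeros((0, 4), dtype=int)))

    def test_degenerate_element_reported_not_raised(self):
        mesh = build_mesh_of_tets([regular_tet_with_edge(2.0), COPLANAR * 2.0])
        report = audit_mesh(mesh)
        assert report.any_nonpositive_jacobian
        assert not report.passes_paper_criteria
        assert np.isinf(report.per_element["aspect_ratio"]).any()


class TestReaders:
    def test_legacy_vtk_round_trip(self, tmp_path):
        tet = regular_tet_with_edge(2.0)
        vtk = tmp_path / "one.vtk"
        vtk.write_text(
            "# vtk DataFile Version 3.0\nsingle tet\nASCII\n"
            "DATASET UNSTRUCTURED_GRID\n"
            "POINTS 4 float\n"
            + "\n".join(" ".join(f"{x:.6f}" for x in row) for row in tet)
            + "\nCELLS 1 5\n4 0 1 2 3\nCELL_TYPES 1\n10\n")
        mesh = read_mesh(vtk)
        assert mesh.n_elements == 1
        assert scaled_jacobian(mesh.element_coords(0)) == pytest.approx(
            scaled_jacobian(tet))

    def test_gmsh_v2_round_trip(self, tmp_path):
        tet = regular_tet_with_edge(2.0)
        msh = tmp_path / "one.msh"
        nodes = "\n".join(f"{i + 1} " + " ".join(f"{x:.6f}" for x in row)
                          for i, row in enumerate(tet))
        msh.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            f"$Nodes\n4\n{nodes}\n$EndNodes\n"
            "$Elements\n1\n1 4 2 0 1 1 2 3 4\n$EndElements\n")
        mesh = read_mesh(msh)
        assert mesh.n_elements == 1
        assert aspect_ratio(mesh.element_coords(0)) == pytest.approx(
            np.sqrt(1.5))

    def test_non_tet_cells_rejected(self, tmp_path):
        msh = tmp_path / "tri.msh"
        msh.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n3\n1 0 0 0\n2 1 0 0\n3 0 1 0\n$EndNodes\n"
            "$Elements\n1\n1 2 2 0 1 1 2 3\n$EndElements\n")
        with pytest.raises(ValueError, match="tet4"):
            read_mesh(msh)
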