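"""Tetrahedral element quality metrics and mesh acceptance audits.

Metrics per four-node tetrahedron, coordinates in mm:

* aspect ratio — longest of the six edges over the smallest of the four
  vertex-to-opposite-face altitudes; sqrt(3/2) for the regular tet,
  +inf for a degenerate (coplanar) one;
* dihedral angles — the six interior angles between face planes along each
  edge, in degrees (arccos(1/3) ~ 70.53 deg for the regular tet);
* scaled Jacobian — the minimum over the four corners of the corner
  edge-vector determinant normalised by the edge-length product and a
  sqrt(2) factor, so the regular tet scores exactly 1; the sign encodes
  orientation (negative = inverted), 0 = degenerate.

The default audit criteria follow common finite-element preprocessing
practice for explicit tet meshes: fewer than 5% of aspect ratios above 3,
all dihedral angles inside [30 deg, 120 deg], all edges within 1-3 mm, every
scaled Jacobian positive and >= 0.2 with fewer than 5% below 0.7.
Pass/fail percentages are evaluated on integer element counts, so threshold
comparisons carry no floating-point drift.  Degenerate elements report
+inf aspect ratio and 0 Jacobian rather than raising, so an audit never
aborts on a bad mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TetMesh",
    "QualityCriteria",
    "MeshQualityReport",
    "aspect_ratio",
    "dihedral_angles",
    "scaled_jacobian",
    "edge_lengths",
    "audit_mesh",
    "read_mesh",
]

# Corner edge orderings chosen so every corner determinant equals +6V for a
# positively oriented tet (each is an even permutation of the vertex set).
_CORNER_EDGES = ((0, (1, 2, 3)), (1, (0, 3, 2)), (2, (0, 1, 3)), (3, (0, 2, 1)))

_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))  # face opposite vertex i

_EDGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class TetMesh:
    """Nodes (n, 3) in mm and tet connectivity (m, 4) into the node list."""

    nodes: np.ndarray
    tets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "tets", np.asarray(self.tets, dtype=int))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be an (m, 4) array")
        if self.tets.size and (self.tets.min() < 0
                               or self.tets.max() >= len(self.nodes)):
            raise ValueError("tet connectivity indexes outside the node list")
        for row in self.tets:
            if len(set(row.tolist())) != 4:
                raise ValueError(f"degenerate connectivity (repeated node): {row}")

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_coords(self, i: int) -> np.ndarray:
        return self.nodes[self.tets[i]]


def _validate_tet(tet: np.ndarray) -> np.ndarray:
    tet = np.asarray(tet, dtype=float)
    if tet.shape != (4, 3):
        raise ValueError("a tet is four 3D points")
    for i in range(4):
        for j in range(i + 1, 4):
            if np.allclose(tet[i], tet[j]):
                raise ValueError("duplicated vertices in tetrahedron")
    return tet


def edge_lengths(tet: np.ndarray) -> np.ndarray:
    """The six edge lengths (mm)."""
    tet = np.asarray(tet, dtype=float)
    return np.array([np.linalg.norm(tet[a] - tet[b]) for a, b in _EDGE_PAIRS])


def aspect_ratio(tet) -> float:
    """Longest edge over minimum vertex-to-opposite-face altitude.

    sqrt(3/2) for the regular tet; +inf when the four points are coplanar.
    """
    tet = _validate_tet(tet)
    longest = float(np.max(edge_lengths(tet)))
    vol6 = abs(float(np.linalg.det(tet[1:] - tet[0])))  # 6 * volume
    if vol6 == 0.0:
        return float("inf")
    min_alt = np.inf
    for i, face in enumerate(_FACES):
        a, b, c = tet[list(face)]
        area2 = float(np.linalg.norm(np.cross(b - a, c - a)))  # 2 * face area
        # altitude from vertex i = 3V / face_area = (vol6 / 2) / (area2 / 2)
        min_alt = min(min_alt, vol6 / area2)
    return longest / min_alt


def dihedral_angles(tet) -> np.ndarray:
    """The six interior dihedral angles in degrees, one per edge."""
    tet = _validate_tet(tet)
    vol6 = abs(float(np.linalg.det(tet[1:] - tet[0])))
    if vol6 == 0.0:
        raise ValueError("degenerate (coplanar) tetrahedron has no dihedrals")
    # inward face normals: normal of face opposite vertex i, oriented toward i
    normals = []
    for i, face in enumerate(_FACES):
        a, b, c = tet[list(face)]
        n = np.cross(b - a, c - a)
        if np.dot(n, tet[i] - a) < 0:
            n = -n
        normals.append(n / np.linalg.norm(n))
    angles = []
    for a, b in _EDGE_PAIRS:
        # the two faces meeting along edge (a, b) are those opposite the
        # other two vertices
        others = [k for k in range(4) if k not in (a, b)]
        cosang = -float(np.dot(normals[others[0]], normals[others[1]]))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.array(angles)


def scaled_jacobian(tet) -> float:
    """Corner-normalised signed Jacobian; 1 at the regular tet, 0 degenerate."""
    tet = np.asarray(tet, dtype=float)
    if tet.shape != (4, 3):
        raise ValueError("a tet is four 3D points")
    worst = np.inf
    for corner, (i, j, k) in _CORNER_EDGES:
        e = tet[[i, j, k]] - tet[corner]
        norms = np.linalg.norm(e, axis=1)
        denom = float(np.prod(norms))
        if denom == 0.0:
            return 0.0
        q = float(np.linalg.det(e)) * np.sqrt(2.0) / denom
        worst = min(worst, q)
    return worst


@dataclass(frozen=True)
class QualityCriteria:
    """Audit thresholds; the defaults are the explicit-FEM preprocessing set."""

    max_aspect_ratio: float = 3.0
    max_aspect_ratio_pct: float = 5.0       # % of elements allowed above
    dihedral_min_deg: float = 30.0
    dihedral_max_deg: float = 120.0
    edge_min_mm: float = 1.0
    edge_max_mm: float = 3.0
    jacobian_min: float = 0.2               # magnitude floor; sign must be +
    jacobian_soft: float = 0.7
    jacobian_soft_pct: float = 5.0          # % allowed below the soft floor


@dataclass(frozen=True)
class MeshQualityReport:
    """Per-element metrics plus the aggregate acceptance verdict."""

    per_element: pd.DataFrame
    criteria: QualityCriteria
    pct_ar_gt_3: float
    pct_jacobian_below_0_7: float
    any_nonpositive_jacobian: bool
    any_jacobian_below_0_2: bool
    any_dihedral_outside_30_120: bool
    any_edge_outside_1_3mm: bool
    passes_paper_criteria: bool

    @property
    def n_elements(self) -> int:
        return len(self.per_element)

    def to_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "pct_ar_gt_3": self.pct_ar_gt_3,
            "pct_jacobian_below_0_7": self.pct_jacobian_below_0_7,
            "any_nonpositive_jacobian": self.any_nonpositive_jacobian,
            "any_jacobian_below_0_2": self.any_jacobian_below_0_2,
            "any_dihedral_outside_30_120": self.any_dihedral_outside_30_120,
            "any_edge_outside_1_3mm": self.any_edge_outside_1_3mm,
            "passes_paper_criteria": self.passes_paper_criteria,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def write_element_csv(self, path: str | Path) -> None:
        self.per_element.to_csv(path, index=False)


def audit_mesh(mesh: TetMesh,
               criteria: QualityCriteria | None = None) -> MeshQualityReport:
    """Audit every element and aggregate the acceptance verdict.

    Percentage thresholds are checked as exact integer-count inequalities
    (count * 100 < pct * n), never through the float percentages themselves.
    """
    if mesh.n_elements == 0:
        raise ValueError("cannot audit an empty mesh")
    crit = criteria or QualityCriteria()

    rows = []
    for i in range(mesh.n_elements):
        coords = mesh.element_coords(i)
        sj = scaled_jacobian(coords)
        edges = edge_lengths(coords)
        vol6 = abs(float(np.linalg.det(coords[1:] - coords[0])))
        if vol6 == 0.0:
            dmin = dmax = float("nan")
            ar = float("inf")
        else:
            d = dihedral_angles(coords)
            dmin, dmax = float(d.min()), float(d.max())
            ar = aspect_ratio(coords)
        rows.append({
            "element_id": i,
            "aspect_ratio": ar,
            "min_dihedral_deg": dmin,
            "max_dihedral_deg": dmax,
            "min_edge_mm": float(edges.min()),
            "max_edge_mm": float(edges.max()),
            "scaled_jacobian": sj,
        })
    df = pd.DataFrame(rows)
    n = len(df)

    n_ar_bad = int(np.sum(df["aspect_ratio"].to_numpy() > crit.max_aspect_ratio))
    n_jac_soft = int(np.sum(np.abs(df["scaled_jacobian"].to_numpy())
                            < crit.jacobian_soft))
    any_nonpos = bool(np.any(df["scaled_jacobian"].to_numpy() <= 0.0))
    any_jac_low = bool(np.any(np.abs(df["scaled_jacobian"].to_numpy())
                              < crit.jacobian_min))
    dihedral_bad = (df["min_dihedral_deg"].isna()
                    | (df["min_dihedral_deg"] < crit.dihedral_min_deg)
                    | (df["max_dihedral_deg"] > crit.dihedral_max_deg))
    any_dih = bool(dihedral_bad.any())
    any_edge = bool(np.any((df["min_edge_mm"].to_numpy() < crit.edge_min_mm)
                           | (df["max_edge_mm"].to_numpy() > crit.edge_max_mm)))

    ar_ok = n_ar_bad * 100 < crit.max_aspect_ratio_pct * n
    jac_soft_ok = n_jac_soft * 100 < crit.jacobian_soft_pct * n
    passes = (ar_ok and not any_nonpos and not any_jac_low and jac_soft_ok
              and not any_dih and not any_edge)

    return MeshQualityReport(
        per_element=df, criteria=crit,
        pct_ar_gt_3=100.0 * n_ar_bad / n,
        pct_jacobian_below_0_7=100.0 * n_jac_soft / n,
        any_nonpositive_jacobian=any_nonpos,
        any_jacobian_below_0_2=any_jac_low,
        any_dihedral_outside_30_120=any_dih,
        any_edge_outside_1_3mm=any_edge,
        passes_paper_criteria=passes)


# ---------------------------------------------------------------------------
# Readers: legacy ASCII VTK unstructured grid and Gmsh MSH v2.2 ASCII,
# tet4 cells only.

def read_mesh(path: str | Path) -> TetMesh:
    """Load a tet4 mesh from legacy ASCII VTK (.vtk) or Gmsh MSH v2 (.msh)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".vtk" or "# vtk DataFile" in text[:200]:
        return _read_vtk_legacy(text)
    if path.suffix.lower() == ".msh" or text.lstrip().startswith("$MeshFormat"):
        return _read_gmsh2(text)
    raise ValueError(f"unrecognised mesh format: {path}")


def _read_vtk_legacy(text: str) -> TetMesh:
    tokens = []
    for line in text.splitlines():
        if line.startswith("#"):
            continue
        tokens.extend(line.split())
    it = iter(range(len(tokens)))

    def find(word: str) -> int:
        for i, t in enumerate(tokens):
            if t.upper() == word:
                return i
        raise ValueError(f"VTK file missing {word} section")

    i = find("DATASET")
    if tokens[i + 1].upper() != "UNSTRUCTURED_GRID":
        raise ValueError("only UNSTRUCTURED_GRID VTK datasets are supported")
    i = find("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)

    i = find("CELLS")
    n_cells = int(tokens[i + 1])
    total = int(tokens[i + 2])
    cell_data = [int(t) for t in tokens[i + 3:i + 3 + total]]
    j = find("CELL_TYPES")
    types = [int(t) for t in tokens[j + 2:j + 2 + n_cells]]

    tets = []
    pos = 0
    for ct in types:
        npts = cell_data[pos]
        conn = cell_data[pos + 1:pos + 1 + npts]
        pos += 1 + npts
        if ct != 10:
            raise ValueError(
                f"unsupported VTK cell type {ct}: only tet4 (type 10) meshes "
                "are audited")
        tets.append(conn)
    return TetMesh(coords, np.array(tets, dtype=int))


def _read_gmsh2(text: str) -> TetMesh:
    lines = [ln.strip() for ln in text.splitlines()]

    def section(name: str) -> list[str]:
        try:
            a = lines.index(f"${name}")
            b = lines.index(f"$End{name}")
        except ValueError as exc:
            raise ValueError(f"MSH file missing ${name} section") from exc
        return lines[a + 1:b]

    fmt = section("MeshFormat")[0].split()
    if not fmt[0].startswith("2"):
        raise ValueError(f"only MSH format 2.x ASCII is supported, got {fmt[0]}")

    node_lines = section("Nodes")
    n_nodes = int(node_lines[0])
    ids, coords = [], []
    for ln in node_lines[1:1 + n_nodes]:
        parts = ln.split()
        ids.append(int(parts[0]))
        coords.append([float(x) for x in parts[1:4]])
    id_map = {nid: k for k, nid in enumerate(ids)}

    elem_lines = section("Elements")
    n_elems = int(elem_lines[0])
    tets = []
    for ln in elem_lines[1:1 + n_elems]:
        parts = [int(x) for x in ln.split()]
        etype, ntags = parts[1], parts[2]
        conn = parts[3 + ntags:]
        if etype != 4:
            raise ValueError(
                f"unsupported Gmsh element type {etype}: only tet4 (type 4) "
                "meshes are audited")
        tets.append([id_map[c] for c in conn])
    return TetMesh(np.array(coords), np.array(tets, dtype=int))
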