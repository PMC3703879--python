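"""Conforming quadratic tetrahedral meshing of bone-implant scenarios.

The mesher is a deterministic structured-grid generator written on numpy:

* a body-fitted polar vertex grid is built around the implant axis whose
  innermost bone column follows the exact axisymmetric thread profile, whose
  top follows the morphology-adjusted bone surface, and whose outer boundary
  follows the bone segment walls;
* every (possibly degenerate) hexahedral cell is split with the Kuhn
  (Freudenthal) six-tetrahedra pattern, which is conforming on a structured
  grid when applied with the same axis order in every cell;
* corner tetrahedra are promoted to 10-node quadratic tetrahedra with
  mid-edge nodes at straight-edge midpoints (subparametric geometry).

Region tags are assigned by classifying element centroids against the
implicit scenario solid; cells falling outside any region are dropped, which
is how the free surface, the crater and the apposition collar acquire their
shape.  Tet10 local ordering follows the VTK convention: corners 0-3, then
mid-edge nodes on edges (0,1), (1,2), (2,0), (0,3), (1,3), (2,3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString

from . import geometry as G

TET_EDGES = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
TET_FACES = [(0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3)]


class MeshingError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# size field
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SizeField:
    """Two-zone target mesh size: ``hi`` near the implant, ``h0`` away."""

    h0_mm: float
    hi_mm: float
    transition_distance_mm: float

    def __post_init__(self):
        if not (0 < self.hi_mm <= self.h0_mm):
            raise MeshingError("size field requires 0 < hi <= h0")


def make_size_field(D_mm: float, h0_ratio: float = 0.1,
                    hi_ratio: float = 0.01,
                    transition_distance_mm: float | None = None) -> SizeField:
    if not (0 < hi_ratio <= h0_ratio):
        raise MeshingError("require 0 < hi_ratio <= h0_ratio")
    hi = hi_ratio * D_mm
    if transition_distance_mm is None:
        # keep the delta = 0.25 D control shell inside the fine zone
        transition_distance_mm = 2 * 0.25 * D_mm
    return SizeField(h0_ratio * D_mm, hi, transition_distance_mm)


# --------------------------------------------------------------------------- #
# mesh container
# --------------------------------------------------------------------------- #

@dataclass
class Tet10Mesh:
    nodes: np.ndarray                     # (N, 3) float
    elements: np.ndarray                  # (E, 10) int
    region: np.ndarray                    # (E,) int8, geometry.REGION_*
    face_groups: dict[str, np.ndarray] = field(default_factory=dict)
    n_corner_nodes: int = 0               # corner nodes come first

    # -- basic measures ------------------------------------------------------
    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]]

    def volumes(self) -> np.ndarray:
        x = self.corner_coords()
        a, b, c = x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def quality(self) -> np.ndarray:
        """Shape quality in (0, 1]: 6*sqrt(2)*V / l_max^3 (1 = regular tet)."""
        x = self.corner_coords()
        v = self.volumes()
        lmax = np.zeros(len(x))
        for i, j in TET_EDGES:
            lmax = np.maximum(lmax, np.linalg.norm(x[:, j] - x[:, i], axis=1))
        return 6 * np.sqrt(2.0) * v / lmax ** 3

    def region_volumes(self) -> dict[str, float]:
        v = self.volumes()
        return {G.REGION_NAMES[t]: float(v[self.region == t].sum())
                for t in np.unique(self.region)}

    # -- audits --------------------------------------------------------------
    def check(self, quality_floor: float = 0.0) -> None:
        v = self.volumes()
        if np.any(v <= 0):
            bad = int(np.argmin(v))
            raise MeshingError(f"non-positive Jacobian in element {bad}")
        if quality_floor > 0:
            q = self.quality()
            if q.min() < quality_floor:
                raise MeshingError(
                    f"element quality {q.min():.4f} below floor {quality_floor}"
                    f" (element {int(np.argmin(q))})")

    def face_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique corner faces and how many elements share each."""
        f = self.elements[:, :4][:, TET_FACES].reshape(-1, 3)
        f = np.sort(f, axis=1)
        uf, counts = np.unique(f, axis=0, return_counts=True)
        return uf, counts

    def is_conforming(self) -> bool:
        _, counts = self.face_counts()
        return bool(np.all((counts == 1) | (counts == 2)))

    # -- I/O -----------------------------------------------------------------
    def save(self, path: str) -> None:
        """Plain-text mesh format with exact (hex float) coordinates."""
        with open(path, "w") as fh:
            fh.write(f"perifem-tet10 1\n{len(self.nodes)} "
                     f"{len(self.elements)} {self.n_corner_nodes}\n")
            for p in self.nodes:
                fh.write(" ".join(x.hex() for x in p) + "\n")
            for el, rg in zip(self.elements, self.region):
                fh.write(" ".join(map(str, el)) + f" {rg}\n")
            fh.write(f"{len(self.face_groups)}\n")
            for name, faces in sorted(self.face_groups.items()):
                fh.write(f"{name} {len(faces)}\n")
                for f in faces:
                    fh.write(" ".join(map(str, f)) + "\n")

    @staticmethod
    def load(path: str) -> "Tet10Mesh":
        with open(path) as fh:
            header = fh.readline().split()
            assert header[0] == "perifem-tet10"
            nn, ne, nc = map(int, fh.readline().split())
            nodes = np.array([[float.fromhex(t) for t in fh.readline().split()]
                              for _ in range(nn)])
            rows = [fh.readline().split() for _ in range(ne)]
            elements = np.array([r[:10] for r in rows], int)
            region = np.array([r[10] for r in rows], np.int8)
            groups = {}
            ng = int(fh.readline())
            for _ in range(ng):
                name, nf = fh.readline().split()
                groups[name] = np.array(
                    [fh.readline().split() for _ in range(int(nf))], int)
        return Tet10Mesh(nodes, elements, region, groups, nc)

    def to_vtu(self, path: str, point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
        write_vtu(path, self, point_data, cell_data)


def write_vtu(path: str, mesh: Tet10Mesh, point_data=None, cell_data=None):
    """Minimal ASCII VTU (unstructured grid, quadratic tetra) writer."""
    n, e = mesh.nodes, mesh.elements

    def arr(a, name, ncomp):
        body = "\n".join(" ".join(f"{x:.9g}" for x in np.atleast_1d(row))
                         for row in np.asarray(a))
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n'
                '</DataArray>\n')

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n'
                 f'<Piece NumberOfPoints="{len(n)}" NumberOfCells="{len(e)}">\n')
        fh.write("<Points>\n" + arr(n, "Points", 3) + "</Points>\n")
        fh.write("<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n'
                 + "\n".join(" ".join(map(str, row)) for row in e)
                 + '\n</DataArray>\n')
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n'
                 + " ".join(str(10 * (i + 1)) for i in range(len(e)))
                 + '\n</DataArray>\n')
        fh.write('<DataArray type="UInt8" Name="types" format="ascii">\n'
                 + " ".join(["24"] * len(e)) + '\n</DataArray>\n</Cells>\n')
        fh.write("<PointData>\n")
        for name, a in (point_data or {}).items():
            a = np.asarray(a)
            fh.write(arr(a, name, a.shape[1] if a.ndim > 1 else 1))
        fh.write("</PointData>\n<CellData>\n")
        fh.write(arr(mesh.region, "region", 1))
        for name, a in (cell_data or {}).items():
            a = np.asarray(a)
            fh.write(arr(a, name, a.shape[1] if a.ndim > 1 else 1))
        fh.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


# --------------------------------------------------------------------------- #
# structured grid -> tet10
# --------------------------------------------------------------------------- #

_KUHN_PERMS = list(itertools.permutations(range(3)))


def _kuhn_tets(corner_ids: np.ndarray) -> np.ndarray:
    """Split hex cells (n, 2, 2, 2) of vertex ids into 6 tets each.

    The same axis-permutation pattern is used in every cell, which makes the
    triangulation of the whole structured grid conforming.
    """
    n = corner_ids.shape[0]
    tets = np.empty((n, 6, 4), dtype=corner_ids.dtype)
    for t, perm in enumerate(_KUHN_PERMS):
        idx = np.zeros(3, int)
        path = [tuple(idx)]
        for ax in perm:
            idx[ax] = 1
            path.append(tuple(idx))
        for c, (di, dj, dk) in enumerate(path):
            tets[:, t, c] = corner_ids[:, di, dj, dk]
    return tets.reshape(-1, 4)


def grid_to_tets(verts: np.ndarray, wrap_j: bool = False,
                 weld_tol: float = 1e-7):
    """Weld a structured vertex grid (I, J, K, 3) and emit corner tets.

    Returns (points, tets); degenerate tets produced by welded (collapsed)
    cells are removed and all tets are oriented to positive volume.
    """
    I, J, K, _ = verts.shape
    flat = verts.reshape(-1, 3)
    key = np.round(flat / weld_tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    points = flat[np.sort(first)]
    # renumber so point order is deterministic (by first occurrence)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    node_id = rank[inverse].reshape(I, J, K)

    jn = np.arange(J)
    j_next = np.roll(jn, -1) if wrap_j else jn[:-1] + 1
    j_base = jn if wrap_j else jn[:-1]
    ii, jj, kk = np.meshgrid(np.arange(I - 1), np.arange(len(j_base)),
                             np.arange(K - 1), indexing="ij")
    corners = np.empty(ii.shape + (2, 2, 2), dtype=np.int64)
    for di in range(2):
        for dj in range(2):
            for dk in range(2):
                jidx = (j_next if dj else j_base)[jj]
                corners[..., di, dj, dk] = node_id[ii + di, jidx, kk + dk]
    tets = _kuhn_tets(corners.reshape(-1, 2, 2, 2))
    # drop tets with repeated vertices
    s = np.sort(tets, axis=1)
    ok = np.all(np.diff(s, axis=1) != 0, axis=1)
    tets = tets[ok]
    x = points[tets]
    v6 = np.einsum("ij,ij->i",
                   np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                   x[:, 3] - x[:, 0])
    flip = v6 < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    keep = np.abs(v6) > 6e-7
    return points, tets[keep]


def tets_to_tet10(points: np.ndarray, tets: np.ndarray,
                  return_edges: bool = False):
    """Add mid-edge nodes (straight midpoints); returns (nodes, elements)."""
    edges = tets[:, TET_EDGES].reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    uedges, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (points[uedges[:, 0]] + points[uedges[:, 1]])
    nodes = np.vstack([points, mid])
    mid_ids = len(points) + inv.reshape(len(tets), 6)
    elements = np.hstack([tets, mid_ids])
    if return_edges:
        return nodes, elements, uedges
    return nodes, elements


# red (1:8) refinement children of a tet10, in parent-local node ids;
# the central octahedron is split along the (m02, m13) diagonal
_RED_CHILDREN = np.array([
    [0, 4, 6, 7], [4, 1, 5, 8], [6, 5, 2, 9], [7, 8, 9, 3],
    [4, 6, 7, 8], [4, 5, 6, 8], [6, 7, 8, 9], [5, 6, 8, 9]])
_FACE_CHILDREN = np.array([[0, 3, 5], [3, 1, 4], [5, 4, 2], [3, 4, 5]])


def refine_uniform(mesh: Tet10Mesh) -> Tet10Mesh:
    """Global red refinement: every tet10 into eight, geometry unchanged.

    Used by the convergence walk so that successive solves discretise the
    same geometry and error norms measure pure discretisation error.
    """
    tets = mesh.elements[:, _RED_CHILDREN].reshape(-1, 4)
    region = np.repeat(mesh.region, 8)
    # orient children positively
    x = mesh.nodes[tets]
    v6 = np.einsum("ij,ij->i", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                   x[:, 3] - x[:, 0])
    flip = v6 < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    nodes, elements, uedges = tets_to_tet10(mesh.nodes, tets,
                                            return_edges=True)
    edge_map = {(int(a), int(b)): len(mesh.nodes) + i
                for i, (a, b) in enumerate(uedges)}

    groups = {}
    for name, faces in mesh.face_groups.items():
        if len(faces) == 0:
            groups[name] = faces.reshape(0, 6)
            continue
        child_corners = faces[:, _FACE_CHILDREN].reshape(-1, 3)
        mids = np.empty_like(child_corners)
        for c, (a, b) in enumerate([(0, 1), (1, 2), (2, 0)]):
            key = np.sort(child_corners[:, [a, b]], axis=1)
            mids[:, c] = [edge_map[(int(p), int(q))] for p, q in key]
        groups[name] = np.hstack([child_corners, mids])
    return Tet10Mesh(nodes, elements, region, groups,
                     n_corner_nodes=len(mesh.nodes))


def _compact(nodes, elements, faces_list):
    used = np.unique(elements)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    elements = remap[elements]
    faces_list = {k: (remap[v] if len(v) else v.reshape(0, 6))
                  for k, v in faces_list.items()}
    return nodes[used], elements, faces_list


def _finish_mesh(points, tets, region_of, face_rules) -> Tet10Mesh:
    """Tag regions, drop outside cells, build tet10 and face groups."""
    cent = points[tets].mean(axis=1)
    region = region_of(cent).astype(np.int8)
    keep = region != G.REGION_OUTSIDE
    tets, region = tets[keep], region[keep]
    if len(tets) == 0:
        raise MeshingError("no elements remained after classification")
    nodes, elements = tets_to_tet10(points, tets)
    n_corner = len(points)

    # face bookkeeping: local faces of every tet with their mid nodes
    # (tri6: corners a,b,c then mids ab, bc, ca)
    face_mid_local = {(0, 1, 2): (4, 5, 6), (0, 1, 3): (4, 8, 7),
                      (1, 2, 3): (5, 9, 8), (0, 2, 3): (6, 9, 7)}
    f_corner = elements[:, TET_FACES].reshape(-1, 3)
    f_mid = np.stack([elements[:, face_mid_local[f]] for f in TET_FACES],
                     axis=1).reshape(-1, 3)
    owner = np.repeat(np.arange(len(elements)), 4)
    key = np.sort(f_corner, axis=1)
    uf, idx, inv, counts = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1

    groups: dict[str, list] = {name: [] for name in face_rules["order"]}
    tri6 = np.hstack([f_corner, f_mid])
    # interface faces: shared by one metal and one bone element.  Sort face
    # occurrences by unique-face id; count-2 faces then sit in adjacent pairs.
    metal = np.isin(region, (G.REGION_IMPLANT, G.REGION_ABUTMENT))
    order = np.argsort(inv, kind="stable")
    so_owner = owner[order]
    offs = np.cumsum(counts) - counts
    two = counts == 2
    o1, o2 = so_owner[offs[two]], so_owner[offs[two] + 1]
    iface = np.zeros(len(uf), dtype=bool)
    iface[two] = metal[o1] != metal[o2]
    groups["bone_implant_interface"] = tri6[idx[iface]]

    bfaces = tri6[boundary]
    bcent = nodes[f_corner[boundary]].mean(axis=1)
    assigned = np.zeros(len(bfaces), dtype=bool)
    for name, rule in face_rules["predicates"]:
        m = rule(bcent, nodes[f_corner[boundary]]) & ~assigned
        groups[name] = bfaces[m]
        assigned |= m
    groups["free_surface"] = bfaces[~assigned]
    groups = {k: np.asarray(v, dtype=np.int64).reshape(-1, 6)
              for k, v in groups.items()}
    nodes, elements, groups = _compact(nodes, elements, groups)
    return Tet10Mesh(nodes, elements, region, groups,
                     n_corner_nodes=int((elements[:, :4].max() + 1)))


# --------------------------------------------------------------------------- #
# benchmark meshes
# --------------------------------------------------------------------------- #

def divisions_for_size(lengths, h: float) -> tuple:
    """Grid divisions so the mean tetrahedron edge approximates ``h``.

    The Kuhn split mixes axis edges, face diagonals and body diagonals with
    mean length ~1.22x the grid spacing, hence the correction factor.
    """
    return tuple(max(1, round(l / (0.82 * h))) for l in lengths)


def build_box_mesh(lengths=(1.0, 1.0, 1.0), divisions=(4, 4, 4),
                   region_tag: int = G.REGION_CORTICAL) -> Tet10Mesh:
    """Uniform box mesh for benchmarks; boundary groups per face of the box."""
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    x = np.linspace(0, lx, nx + 1)
    y = np.linspace(0, ly, ny + 1)
    z = np.linspace(0, lz, nz + 1)
    Vx, Vy, Vz = np.meshgrid(x, y, z, indexing="ij")
    verts = np.stack([Vx, Vy, Vz], axis=-1)
    points, tets = grid_to_tets(verts)
    tol = 1e-9

    rules = {"order": ["xmin", "xmax", "ymin", "ymax", "zmin", "zmax",
                       "bone_implant_interface", "free_surface"],
             "predicates": [
                 ("xmin", lambda c, f: c[:, 0] < tol),
                 ("xmax", lambda c, f: c[:, 0] > lx - tol),
                 ("ymin", lambda c, f: c[:, 1] < tol),
                 ("ymax", lambda c, f: c[:, 1] > ly - tol),
                 ("zmin", lambda c, f: c[:, 2] < tol),
                 ("zmax", lambda c, f: c[:, 2] > lz - tol)]}
    mesh = _finish_mesh(points, tets,
                        lambda c: np.full(len(c), region_tag), rules)
    return mesh


def build_hollow_cylinder_mesh(r_in: float, r_out: float, height: float,
                               nr: int = 8, ntheta: int = 24, nz: int = 4,
                               grading: float = 1.0,
                               region_tag: int = G.REGION_CORTICAL) -> Tet10Mesh:
    """Full-annulus cylinder mesh (Lame benchmark)."""
    t = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
    w = np.linspace(0, 1, nr + 1) ** grading
    r = r_in + (r_out - r_in) * w
    z = np.linspace(0, height, nz + 1)
    R, T, Z = np.meshgrid(r, t, z, indexing="ij")
    verts = np.stack([R * np.cos(T), R * np.sin(T), Z], axis=-1)
    points, tets = grid_to_tets(verts, wrap_j=True)
    tol = 1e-9
    rules = {"order": ["inner", "outer", "zmin", "zmax",
                       "bone_implant_interface", "free_surface"],
             "predicates": [
                 ("zmin", lambda c, f: c[:, 2] < tol),
                 ("zmax", lambda c, f: c[:, 2] > height - tol),
                 ("inner", lambda c, f: np.hypot(c[:, 0], c[:, 1])
                  < r_in + 0.3 * (r_out - r_in) * (w[1])),
                 ("outer", lambda c, f: np.hypot(c[:, 0], c[:, 1])
                  > r[-2] + 0.7 * (r[-1] - r[-2]))]}
    return _finish_mesh(points, tets,
                        lambda c: np.full(len(c), region_tag), rules)


# --------------------------------------------------------------------------- #
# scenario mesher
# --------------------------------------------------------------------------- #

def _z_stations(sc: G.ScenarioSolid, size: SizeField) -> np.ndarray:
    """Master axial stations following the implant profile where it matters."""
    hi = size.hi_mm
    prof = sc.implant.profile.copy()
    prof[:, 1] += sc.platform_z                     # to global frame
    z_top_wall = float(sc.top_surface(np.array([sc.implant_spec.D_mm / 2]))[0])
    z_bot = -sc.bone_spec.crest_height_mm
    apex = sc.apex_z
    fine_lo = max(z_top_wall - (sc.bone_spec.cortical_thickness_mm + 1.5),
                  apex - 0.5)

    stations: list[float] = []
    # abutment span: coarse
    stations += list(np.linspace(sc.load_z, min(0.5, sc.load_z), 6))
    # crest span down to fine zone: profile breakpoints + fill
    brk = prof[:, 1]
    fine_hi = min(0.2, z_top_wall + 0.2) + 1e-9
    sel = brk[(brk <= fine_hi) & (brk >= fine_lo)]
    stations += list(sel)
    # companions just above horizontal steps so steps mesh as near-vertical
    zs = prof[:, 1]
    step = np.abs(np.diff(prof[:, 0])) > 0.04
    same_z = np.abs(np.diff(zs)) < 1e-9
    for i in np.where(step & same_z)[0]:
        stations.append(zs[i] + 0.7 * hi)
    stations += [z_top_wall, sc.platform_z, 0.0]
    if sc.morphology.kind is G.MorphologyKind.APPOSITION:
        stations += [sc.platform_z + sc.morphology.apposition_thickness_mm]
    # fill the fine zone to a max spacing
    fill = np.arange(fine_lo, fine_hi, max(1.6 * hi, 0.08))
    stations += list(fill)
    # below the fine zone: widen geometrically to the apex
    dz = max(3.0 * hi, 0.3)
    z = fine_lo
    while z - dz > apex + 0.3:
        z -= dz
        stations.append(z)
        dz = min(dz * 1.25, 0.8)
    stations += [apex + sc.implant_spec.apex_chamfer_mm, apex]
    # below the apex to the bone bottom
    for f in np.linspace(0, 1, 5)[1:] ** 1.3:
        stations.append(apex + f * (z_bot - apex))
    # dedupe with a minimum gap; protected stations always survive
    dome_h = G.dome_height(sc.implant_spec)
    protected = sorted({sc.load_z, 0.0, z_top_wall, sc.platform_z, apex,
                        apex + dome_h, z_bot,
                        -sc.bone_spec.cortical_thickness_mm}
                       | ({sc.platform_z + sc.morphology.apposition_thickness_mm}
                          if sc.morphology.kind is G.MorphologyKind.APPOSITION
                          else set()), reverse=True)
    # the crestal band (collar + cortical thread engagement) gets a denser
    # station budget than the rest of the fine zone: the thread profile
    # there drives the cortical peak stresses being compared
    crest_lo = z_top_wall - (sc.bone_spec.cortical_thickness_mm + 0.4)
    min_gap = max(0.8 * hi, 0.035)
    min_gap_crest = max(0.3 * hi, 0.035)
    kept = np.unique(np.round(np.array(protected), 9))
    for s in sorted(set(stations), reverse=True):
        gap = min_gap_crest if (crest_lo <= s <= 0.3) else min_gap
        if np.min(np.abs(kept - s)) >= gap:
            kept = np.append(kept, s)
    kept = kept[(kept <= sc.load_z + 1e-9) & (kept >= z_bot - 1e-9)]
    return np.array(sorted(kept, reverse=True))


def _effective_radius(sc: G.ScenarioSolid, z: np.ndarray,
                      window: float) -> np.ndarray:
    """Volume-equivalent smooth interface radius over an axial window."""
    zz = np.linspace(z.min() - window, z.max() + window, 2048)
    rr = sc.inner_radius(zz) ** 2
    n = max(3, int(window / (zz[1] - zz[0])))
    kern = np.ones(n) / n
    sm = np.convolve(rr, kern, mode="same")
    return np.sqrt(np.interp(z, zz, sm))


def mesh_scenario(sc: G.ScenarioSolid, size: SizeField, seed: int = 0,
                  symmetric: bool = True, quality_floor: float = 3e-5,
                  fin_exact_depth: float | None = None) -> Tet10Mesh:
    """Mesh a placed bone-implant scenario.

    ``symmetric=True`` meshes the y >= 0 half (the model is mirror-symmetric
    about the buccolingual loading plane); a ``symmetry`` face group is then
    emitted for the u_y = 0 constraint.  ``seed`` is accepted for interface
    uniformity; the generator is fully deterministic.

    The thread profile is honoured exactly down to ``fin_exact_depth`` below
    the local bone top (default: cortical thickness + 1.5 mm); deeper, the
    interface uses the volume-equivalent smooth radius of the thread band.
    """
    del seed  # deterministic generator
    hi = size.hi_mm
    D = sc.implant_spec.D_mm
    half_len = sc.bone_spec.mesiodistal_length_mm / 2

    zk = _z_stations(sc, size)
    K = len(zk)
    z_top_wall = float(sc.top_surface(np.array([D / 2]))[0])
    if fin_exact_depth is None:
        fin_exact_depth = sc.bone_spec.cortical_thickness_mm + 1.5
    fine_lo = max(z_top_wall - fin_exact_depth, sc.apex_z - 0.5)

    # interface radius per station: exact profile in the fine zone, smooth
    # volume-equivalent radius below, zero beyond the metal
    r_exact = sc.inner_radius(zk)
    r_smooth = _effective_radius(sc, zk, window=sc.implant_spec.thread.fin_spacing_mm)
    in_fine = zk >= fine_lo
    below_metal = zk < sc.apex_z + 1e-12
    r_if = np.where(in_fine, r_exact, r_smooth)
    r_if = np.where(below_metal, 0.0, r_if)
    r_if = np.where(zk > sc.load_z - 1e-9, r_exact, r_if)

    # theta sectors: uniform rays plus rays through the section corners so
    # the polar boundary reaches the far corners of the bone segment
    n_full = int(np.clip(np.round(2 * np.pi * (D / 2) / (4.5 * hi)), 10, 20))
    n_full += n_full % 2
    sect_mid = G._section_polygon(sc.bone_spec)
    cut = sect_mid.intersection(LineString(
        [(-50, -sc.bone_spec.crest_height_mm / 2),
         (50, -sc.bone_spec.crest_height_mm / 2)]))
    a_mid = cut.length / 2 if not cut.is_empty else sc.bone_spec.crest_width_mm / 2
    th_c = float(np.arctan2(half_len, a_mid))
    if symmetric:
        base = np.linspace(0.0, np.pi, n_full // 2 + 1)
        extra = [th_c, np.pi - th_c]
    else:
        base = np.linspace(0.0, 2 * np.pi, n_full, endpoint=False)
        extra = [th_c, np.pi - th_c, np.pi + th_c, 2 * np.pi - th_c]
    # corner rays replace the nearest interior ray so no slim sector appears
    dth = base[1] - base[0] if len(base) > 1 else 2 * np.pi
    for tc_ray in extra:
        i = int(np.argmin(np.abs(base - tc_ray)))
        if 0 < i < len(base) - 1 or not symmetric:
            base[i] = tc_ray
    thetas = np.unique(base)
    J = len(thetas)

    # radial ladders
    metal_fr = np.array([0.0, 0.45, 0.8])           # + interface ring
    g = 1.45
    n_near = max(3, int(np.ceil(np.log1p((size.transition_distance_mm / hi)
                                          * (g - 1)) / np.log(g))))
    near = hi * (g ** np.arange(1, n_near + 1) - 1) / (g - 1)
    n_far = 3
    far_fr = (1.9 ** np.arange(1, n_far + 1) - 1) / (1.9 ** n_far - 1)
    I = len(metal_fr) + 1 + n_near + n_far          # radial node count

    # bone section width vs height
    wz = np.linspace(-sc.bone_spec.crest_height_mm, 0.0, 256)
    sect = G._section_polygon(sc.bone_spec)
    widths = []
    for z in wz:
        cut = sect.intersection(LineString([(-50, z), (50, z)]))
        widths.append(cut.length if not cut.is_empty else 0.0)
    widths = np.array(widths)
    widths[-1] = widths[-2]

    def halfwidth(z):
        return 0.5 * np.interp(np.minimum(z, 0.0), wz, widths)

    # smooth reference for decaying the fin oscillation into the bone rings
    r_ref = np.where(in_fine & ~below_metal, r_smooth, r_if)
    decay = np.exp(-np.arange(1, n_near + 1) / 1.4)

    # far-field axial ladder: the thread-scale station clustering is only
    # needed near the interface; distant columns blend toward an evenly
    # graded ladder over the bone height to avoid sliver layers
    neg = zk < 0
    n_neg = int(neg.sum())
    z_far = zk.copy()
    z_bot = -sc.bone_spec.crest_height_mm
    z_far[neg] = zk[neg][0] + (z_bot - zk[neg][0]) \
        * (np.arange(n_neg) / max(n_neg - 1, 1)) ** 1.15
    w_axial = np.ones(I)
    nb0 = len(metal_fr) + 1
    # the delta = 0.25 D shell (first few bone rings) keeps the exact axial
    # stations; only distant columns blend to the smooth ladder
    w_axial[nb0 + 3:] = np.exp(-np.arange(1, I - nb0 - 2) / 2.0)

    verts = np.empty((I, J, K, 3))
    eps_gap = 0.25 * hi
    for k, z in enumerate(zk):
        a = max(halfwidth(z), 0.6)
        b = half_len
        ct, st = np.cos(thetas), np.sin(thetas)
        with np.errstate(divide="ignore"):
            R_out = np.minimum(np.where(np.abs(ct) > 1e-12, a / np.abs(ct),
                                        np.inf),
                               np.where(np.abs(st) > 1e-12, b / np.abs(st),
                                        np.inf))
        radii = np.empty((I, J))
        radii[:len(metal_fr)] = np.outer(metal_fr, np.full(J, r_if[k]))
        radii[len(metal_fr)] = r_if[k]
        base = r_ref[k] + near[:, None] + decay[:, None] * (r_if[k] - r_ref[k])
        radii[len(metal_fr) + 1: len(metal_fr) + 1 + n_near] = base
        start = radii[len(metal_fr) + n_near]
        rem = R_out[None, :] - start[None, :]
        radii[len(metal_fr) + 1 + n_near:] = start[None, :] \
            + far_fr[:, None] * rem
        # enforce monotone inside-out ordering (bone rings keep a minimum
        # gap so fin oscillation cannot create slivers); where the ladder
        # overshoots the outer wall, rescale the bone rings proportionally
        # into the available space instead of clipping (no sliver stacking)
        for i in range(nb0, I):
            radii[i] = np.maximum(radii[i], radii[i - 1] + eps_gap)
        radii = np.maximum.accumulate(radii, axis=0)
        span = radii[-1] - radii[nb0 - 1]
        avail = R_out - radii[nb0 - 1]
        scale = np.where((span > 1e-12) & (avail < span), avail / np.maximum(span, 1e-12), 1.0)
        radii[nb0:] = radii[nb0 - 1] + (radii[nb0:] - radii[nb0 - 1]) * scale
        radii[-1] = np.minimum(radii[-1], R_out)
        verts[:, :, k, 0] = radii * ct[None, :]
        verts[:, :, k, 1] = radii * st[None, :]
        verts[:, :, k, 2] = w_axial[:, None] * z + (1 - w_axial[:, None]) * z_far[k]

    # above the crest there is no bone: bone columns reuse the radii of the
    # first in-bone station so their clamped copies weld away exactly
    k0 = int(np.argmax(zk <= 0.0))
    above = zk > 0.0
    verts[nb0:, :, above, 0] = verts[nb0:, :, k0, 0][:, :, None]
    verts[nb0:, :, above, 1] = verts[nb0:, :, k0, 1][:, :, None]

    # clamp columns above their own top surface (bone) / load plane (metal);
    # nodes landing just under the cap snap onto it so the flattened cells
    # above degenerate cleanly and weld away
    rho = np.hypot(verts[..., 0], verts[..., 1])
    is_metal_col = np.arange(I)[:, None, None] <= len(metal_fr)
    ztop_col = sc.top_surface(rho.reshape(-1)).reshape(rho.shape)
    cap = np.where(is_metal_col, sc.load_z, ztop_col)
    zc = np.minimum(verts[..., 2], cap)
    snap_tol = 0.5 * max(0.8 * hi, 0.035)
    zc = np.where(cap - zc < snap_tol, cap, zc)

    # align one station per bone column with the cortical/trabecular
    # boundary surface (top surface minus shell thickness): a mesh-aligned
    # material interface avoids spurious stress spikes at a staircased
    # 27x stiffness jump
    tc = sc.bone_spec.cortical_thickness_mm
    target = np.full_like(ztop_col, -tc)         # pristine shell floor (I, J, K)
    miss = np.abs(zc - target)
    kstar = np.argmin(miss, axis=2)              # (I, J)
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    tgt = target[ii, jj, kstar]
    zs = zc[ii, jj, kstar]
    up = zc[ii, jj, np.maximum(kstar - 1, 0)]
    dn = zc[ii, jj, np.minimum(kstar + 1, K - 1)]
    room = np.minimum(np.abs(up - zs), np.abs(zs - dn))
    okm = (np.abs(tgt - zs) < 0.45 * np.maximum(room, 1e-9)) \
        & ~is_metal_col[:, :, 0]
    zc[ii[okm], jj[okm], kstar[okm]] = tgt[okm]
    verts[..., 2] = zc

    points, tets = grid_to_tets(verts, wrap_j=not symmetric)

    tol = 1e-6
    rules = {"order": ["coronal_cuts", "load_patch", "symmetry",
                       "bone_implant_interface", "free_surface"],
             "predicates": [
                 ("coronal_cuts",
                  lambda c, f: np.abs(f[..., 1]).max(axis=1) > half_len - 0.51),
                 ("load_patch", lambda c, f: c[:, 2] > sc.load_z - tol),
                 ("symmetry",
                  lambda c, f: (np.abs(f[..., 1]).max(axis=1) < tol)
                  if symmetric else np.zeros(len(c), bool))]}
    mesh = _finish_mesh(points, tets, sc.region_of, rules)
    mesh.check(quality_floor=quality_floor)
    if not len(mesh.face_groups["load_patch"]):
        raise MeshingError("empty load patch")
    if not len(mesh.face_groups["coronal_cuts"]):
        raise MeshingError("empty coronal cut face group")
    return mesh
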