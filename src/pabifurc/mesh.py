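"""Triangle surface meshes: representation, text I/O, clipping, volume.

A :class:`VesselSurface` is a plain indexed triangle mesh in millimetre
coordinates.  Only the operations the morphometry pipeline needs are
implemented: manifoldness / boundary-loop checks, half-space clipping
with optional planar capping, and signed enclosed volume via the
divergence theorem.  File formats are the ASCII variants of STL, PLY and
OBJ so that every artifact stays text.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VesselSurface",
    "MeshError",
    "clip_halfspace",
    "read_mesh",
]

_EPS = 1e-9


class MeshError(ValueError):
    """Raised for malformed or unsupported mesh input."""


@dataclass
class VesselSurface:
    """Indexed triangle mesh of a vessel wall (units: mm).

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Consistently oriented triangles (counter-clockwise seen from
        outside).
    opening_labels : dict, optional
        Maps an opening name (e.g. ``"MPA"``) to a boundary-loop index.
    """

    vertices: np.ndarray
    faces: np.ndarray
    opening_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # ---------------------------------------------------------------- topology

    def _edge_face_count(self) -> dict:
        counts: dict = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (a, b) if a < b else (b, a)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_manifold(self) -> bool:
        """Every edge borders at most two faces, with opposite winding."""
        directed: set = set()
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                if (a, b) in directed:
                    return False  # repeated directed edge -> inconsistent
                directed.add((a, b))
        # an undirected edge may appear once (boundary) or twice (opposed)
        counts = self._edge_face_count()
        return all(c <= 2 for c in counts.values())

    def boundary_edges(self) -> list:
        """Directed edges that belong to exactly one face."""
        counts = self._edge_face_count()
        out = []
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (a, b) if a < b else (b, a)
                if counts[key] == 1:
                    out.append((a, b))
        return out

    def boundary_loops(self) -> list:
        """Chained boundary loops, each a list of vertex indices."""
        nxt = {}
        for a, b in self.boundary_edges():
            nxt[a] = b
        loops = []
        seen: set = set()
        for start in list(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                if cur not in nxt:
                    raise MeshError("open boundary chain: mesh is not manifold")
                cur = nxt[cur]
            loops.append(loop)
        return loops

    def is_watertight(self) -> bool:
        return self.is_manifold() and not self.boundary_edges()

    # ---------------------------------------------------------------- geometry

    def volume(self) -> float:
        """Signed enclosed volume (mm^3) by the divergence theorem.

        Positive when faces are oriented outward.
        """
        v = self.vertices
        a = v[self.faces[:, 0]]
        b = v[self.faces[:, 1]]
        c = v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def compact(self) -> "VesselSurface":
        """Drop unreferenced vertices, re-indexing faces."""
        used = np.unique(self.faces)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return VesselSurface(self.vertices[used], remap[self.faces])

    def transformed(self, rotation=None, translation=None) -> "VesselSurface":
        """Rigidly transformed copy."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return VesselSurface(v, self.faces.copy(), dict(self.opening_labels))

    def scaled(self, k: float) -> "VesselSurface":
        return VesselSurface(self.vertices * k, self.faces.copy(), dict(self.opening_labels))

    # --------------------------------------------------------------------- I/O

    def write_stl(self, path) -> None:
        """ASCII STL (text deliverables only)."""
        v, f = self.vertices, self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1)
        n = n / np.where(norm > _EPS, norm, 1.0)[:, None]
        with open(path, "w") as fh:
            fh.write("solid vessel\n")
            for tri, nrm in zip(f, n):
                fh.write(f"facet normal {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}\n")
                fh.write(" outer loop\n")
                for idx in tri:
                    x, y, z = v[idx]
                    fh.write(f"  vertex {x:.9g} {y:.9g} {z:.9g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid vessel\n")

    def write_ply(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for x, y, z in self.vertices:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            for a, b, c in self.faces:
                fh.write(f"3 {a} {b} {c}\n")

    def write_obj(self, path) -> None:
        with open(path, "w") as fh:
            for x, y, z in self.vertices:
                fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
            for a, b, c in self.faces:
                fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


# ------------------------------------------------------------------ readers


def _read_stl_ascii(text: str) -> VesselSurface:
    verts, faces, vmap = [], [], {}
    cur = []
    for line in text.splitlines():
        parts = line.split()
        if parts[:1] == ["vertex"]:
            p = tuple(float(x) for x in parts[1:4])
            if p not in vmap:
                vmap[p] = len(verts)
                verts.append(p)
            cur.append(vmap[p])
            if len(cur) == 3:
                faces.append(cur)
                cur = []
    if not faces:
        raise MeshError("no facets found in STL")
    return VesselSurface(np.array(verts), np.array(faces))


def _read_stl_binary(data: bytes) -> VesselSurface:
    (ntri,) = struct.unpack("<I", data[80:84])
    verts, faces, vmap = [], [], {}
    off = 84
    for _ in range(ntri):
        rec = struct.unpack("<12fH", data[off : off + 50])
        tri = []
        for k in range(3):
            p = rec[3 + 3 * k : 6 + 3 * k]
            if p not in vmap:
                vmap[p] = len(verts)
                verts.append(p)
            tri.append(vmap[p])
        faces.append(tri)
        off += 50
    return VesselSurface(np.array(verts), np.array(faces))


def _read_ply_ascii(text: str) -> VesselSurface:
    lines = text.splitlines()
    nv = nf = None
    i = 0
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            nv = int(line.split()[-1])
        elif line.startswith("element face"):
            nf = int(line.split()[-1])
        elif line.strip() == "end_header":
            break
    if nv is None or nf is None:
        raise MeshError("PLY header missing vertex/face counts")
    body = lines[i + 1 :]
    verts = np.array([[float(x) for x in body[k].split()[:3]] for k in range(nv)])
    faces = []
    for k in range(nv, nv + nf):
        parts = body[k].split()
        if int(parts[0]) != 3:
            raise MeshError("only triangle PLY faces supported")
        faces.append([int(parts[1]), int(parts[2]), int(parts[3])])
    return VesselSurface(verts, np.array(faces))


def _read_obj(text: str) -> VesselSurface:
    verts, faces = [], []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            if len(idx) != 3:
                raise MeshError("only triangle OBJ faces supported")
            faces.append(idx)
    if not faces:
        raise MeshError("no faces found in OBJ")
    return VesselSurface(np.array(verts), np.array(faces))


def read_mesh(path) -> VesselSurface:
    """Read an STL / PLY / OBJ mesh, dispatching on extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        data = path.read_bytes()
        if data[:5].lower() == b"solid" and b"facet" in data[:500]:
            return _read_stl_ascii(data.decode("ascii", errors="replace"))
        return _read_stl_binary(data)
    if suffix == ".ply":
        return _read_ply_ascii(path.read_text())
    if suffix == ".obj":
        return _read_obj(path.read_text())
    raise MeshError(f"unsupported mesh format: {suffix!r}")


# ----------------------------------------------------------------- clipping


def clip_halfspace(
    surface: VesselSurface,
    origin,
    normal,
    cap: bool = False,
    tol: float = 1e-9,
) -> VesselSurface:
    """Keep the part of ``surface`` with ``dot(x - origin, normal) <= 0``.

    Triangles crossing the plane are split; cut vertices are shared
    between neighbouring triangles so the result stays manifold.  With
    ``cap=True`` every boundary loop lying in the cut plane is closed by
    a triangle fan around its centroid (valid for star-shaped sections,
    which vessel lumina are).
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    v = surface.vertices
    d = (v - origin) @ normal
    # snap near-plane vertices strictly to the kept side so every split
    # is clean (no zero-area faces, no duplicated cut vertices)
    d = np.where(np.abs(d) < tol, -tol, d)
    keep = d < 0.0

    new_verts = list(map(tuple, v))
    edge_cache: dict = {}

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key in edge_cache:
            return edge_cache[key]
        t = d[i] / (d[i] - d[j])
        p = v[i] + t * (v[j] - v[i])
        idx = len(new_verts)
        new_verts.append(tuple(p))
        edge_cache[key] = idx
        return idx

    out_faces = []
    for tri in surface.faces:
        k = keep[tri]
        nk = int(k.sum())
        if nk == 3:
            out_faces.append(list(tri))
            continue
        if nk == 0:
            continue
        # rotate so the pattern is canonical, preserving winding
        order = list(tri)
        kk = list(k)
        while not (kk[0] and (nk == 1 and not kk[1] or nk == 2 and kk[1])):
            order = order[1:] + order[:1]
            kk = kk[1:] + kk[:1]
        a, b, c = order
        if nk == 1:
            # a kept, b and c removed
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            out_faces.append([a, pab, pca])
        else:
            # a, b kept, c removed
            pbc = cut_point(b, c)
            pca = cut_point(c, a)
            out_faces.append([a, b, pbc])
            out_faces.append([a, pbc, pca])

    clipped = VesselSurface(np.array(new_verts), np.array(out_faces, dtype=np.int64))
    clipped = clipped.compact()

    if not cap:
        return clipped

    v2 = clipped.vertices
    faces = list(map(list, clipped.faces))
    for loop in clipped.boundary_loops():
        pts = v2[loop]
        if np.max(np.abs((pts - origin) @ normal)) > 1e-6 + 10 * tol:
            continue  # boundary not on the cut plane: leave open
        centroid = pts.mean(axis=0)
        cidx = len(v2)
        v2 = np.vstack([v2, centroid[None, :]])
        # cap triangles traverse each boundary edge in the opposite
        # direction, which keeps the mesh orientation consistent
        n_loop = len(loop)
        for i in range(n_loop):
            a, b = loop[i], loop[(i + 1) % n_loop]
            faces.append([cidx, b, a])
    return VesselSurface(v2, np.array(faces, dtype=np.int64))
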