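"""Triangulated structure surfaces: extraction, decimation, transforms.

Meshes are built from probability volumes by marching cubes (trilinear
edge interpolation), optionally on an upsampled grid, then decimated by a
quadric-error edge-collapse pass that removes a requested fraction of
vertices. All vertex coordinates are world mm.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

import nibabel as nib

from subparc.errors import ConfigError, DataError, GeometryError
from subparc.volume import ScalarVolume

__all__ = [
    "SurfaceMesh",
    "extract_surface",
    "apply_transform",
    "seed_spheres",
    "decimate_mesh",
]


@dataclass
class SurfaceMesh:
    """A triangulated closed surface in world mm.

    Attributes
    ----------
    vertices : (V, 3) float array, world mm.
    faces : (F, 3) int array of 0-based vertex indices.
    structure : structure tag, e.g. ``"SNc"``.
    hemisphere : ``"L"`` or ``"R"`` (or ``""`` when not applicable).
    vertex_labels : optional (V,) int array of subregion labels.
    provenance : construction parameters (threshold, upsampling, decimation).
    """

    vertices: np.ndarray
    faces: np.ndarray
    structure: str = ""
    hemisphere: str = ""
    vertex_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise DataError("face index exceeds vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- differential-geometry helpers --------------------------------------

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        """Total surface area (mm^2)."""
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (mm^3)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    # -- I/O ----------------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".ply":
            _write_ply(self, path)
        elif path.suffix == ".gii":
            _write_gifti(self, path)
        else:
            raise DataError(f"unknown mesh format {path.suffix!r}")

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        path = Path(path)
        if path.suffix == ".ply":
            return _read_ply(path)
        if path.suffix == ".gii":
            return _read_gifti(path)
        raise DataError(f"unknown mesh format {path.suffix!r}")


# ---------------------------------------------------------------------------
# extraction

def extract_surface(
    prob: ScalarVolume,
    threshold: float,
    upsample_pct: float = 100.0,
    decimate_fraction: float = 0.0,
    structure: str = "",
    hemisphere: str = "",
) -> SurfaceMesh:
    """Isosurface a probability volume and optionally decimate it.

    The volume is first trilinearly upsampled by ``upsample_pct / 100``
    (200 doubles the grid resolution), then marching cubes extracts the
    ``threshold`` isosurface, then ``decimate_fraction`` of vertices are
    removed by quadric edge collapse. Vertices are returned in world mm.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"threshold must be in (0, 1), got {threshold}")
    if not 0.0 <= decimate_fraction < 1.0:
        raise ConfigError(f"decimate_fraction must be in [0, 1), got {decimate_fraction}")
    if upsample_pct < 100.0:
        raise ConfigError(f"upsample_pct must be >= 100, got {upsample_pct}")

    data = np.asarray(prob.data, dtype=float)
    affine = prob.affine.copy()
    factor = upsample_pct / 100.0
    if factor != 1.0:
        data = ndimage.zoom(data, factor, order=1, grid_mode=False)
        # zoom keeps the voxel-centre span of the original grid:
        # new index i maps to old index i * (n_old - 1) / (n_new - 1)
        scale = np.ones(3)
        for ax in range(3):
            n_old, n_new = prob.data.shape[ax], data.shape[ax]
            scale[ax] = (n_old - 1) / (n_new - 1) if n_new > 1 else 1.0
        affine = affine @ np.diag([*scale, 1.0])

    if float(data.max(initial=0.0)) <= threshold:
        name = structure or "structure"
        raise GeometryError(f"empty structure: no voxel of {name} exceeds {threshold}")

    verts_vox, faces, _, _ = measure.marching_cubes(data, level=threshold)
    verts = verts_vox @ affine[:3, :3].T + affine[:3, 3]
    mesh = SurfaceMesh(
        verts,
        faces,
        structure=structure,
        hemisphere=hemisphere,
        provenance={
            "threshold": threshold,
            "upsample_pct": upsample_pct,
            "decimate_fraction": decimate_fraction,
        },
    )
    if decimate_fraction > 0.0:
        target = int(np.ceil((1.0 - decimate_fraction) * mesh.n_vertices))
        mesh = decimate_mesh(mesh, target)
    return mesh


# ---------------------------------------------------------------------------
# quadric edge-collapse decimation

def decimate_mesh(mesh: SurfaceMesh, target_vertices: int) -> SurfaceMesh:
    """Reduce the mesh to ``target_vertices`` by quadric edge collapse.

    Collapses are ordered by quadric error; a link-condition check keeps the
    surface manifold, so the Euler characteristic of a closed mesh is
    preserved. The collapsed vertex is placed at whichever of the two
    endpoints or the midpoint minimises the summed quadric.
    """
    if target_vertices >= mesh.n_vertices:
        return mesh
    if target_vertices < 4:
        raise ConfigError("cannot decimate below 4 vertices")

    verts = mesh.vertices.copy()
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set[int]] = {i: set() for i in range(len(verts))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)

    quadrics = np.zeros((len(verts), 4, 4))
    for f in faces.values():
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        plane = np.append(n, -n.dot(a))
        K = np.outer(plane, plane)
        for v in f:
            quadrics[v] += K

    def neighbours(v: int) -> set[int]:
        out: set[int] = set()
        for fi in vert_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def edge_cost(u: int, v: int) -> tuple[float, np.ndarray]:
        Q = quadrics[u] + quadrics[v]
        best_cost, best_p = np.inf, None
        for p in (verts[u], verts[v], 0.5 * (verts[u] + verts[v])):
            h = np.append(p, 1.0)
            c = float(h @ Q @ h)
            if c < best_cost:
                best_cost, best_p = c, p
        return best_cost, best_p  # type: ignore[return-value]

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    alive = np.ones(len(verts), dtype=bool)
    version = np.zeros(len(verts), dtype=int)

    def push(u: int, v: int) -> None:
        nonlocal counter
        if u > v:
            u, v = v, u
        cost, _ = edge_cost(u, v)
        heapq.heappush(heap, (cost, counter, u, v))
        counter += 1

    seen = set()
    for f in faces.values():
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                push(*key)
    del seen

    n_alive = len(verts)
    while n_alive > target_vertices and heap:
        cost, _, u, v = heapq.heappop(heap)
        if not (alive[u] and alive[v]):
            continue
        if v not in neighbours(u):
            continue
        # link condition: shared neighbours must be exactly the two opposite
        # vertices of the faces sharing edge (u, v)
        shared_faces = vert_faces[u] & vert_faces[v]
        opposite = set()
        for fi in shared_faces:
            opposite.update(faces[fi])
        opposite -= {u, v}
        if neighbours(u) & neighbours(v) != opposite or len(shared_faces) != 2:
            continue
        cur_cost, pos = edge_cost(u, v)
        if cur_cost > cost + 1e-12:
            push(u, v)
            continue
        # collapse v into u at pos
        verts[u] = pos
        quadrics[u] = quadrics[u] + quadrics[v]
        alive[v] = False
        n_alive -= 1
        for fi in list(shared_faces):
            for w in faces[fi]:
                vert_faces[w].discard(fi)
            del faces[fi]
        for fi in list(vert_faces[v]):
            f = faces[fi]
            faces[fi] = tuple(u if w == v else w for w in f)
            vert_faces[u].add(fi)
            vert_faces[v].discard(fi)
        vert_faces[v] = set()
        version[u] += 1
        for w in neighbours(u):
            push(u, w)

    keep = np.flatnonzero(alive)
    remap = -np.ones(len(verts), dtype=int)
    remap[keep] = np.arange(len(keep))
    new_faces = np.array([remap[list(f)] for f in faces.values()], dtype=int)
    out = replace(mesh, vertices=verts[keep], faces=new_faces)
    out.provenance = dict(mesh.provenance, decimated_to=len(keep))
    return out


# ---------------------------------------------------------------------------
# transforms and seeding

def apply_transform(mesh: SurfaceMesh, transform) -> SurfaceMesh:
    """Map vertices through a 4x4 affine or a callable displacement field.

    A callable receives (V, 3) world coordinates and returns per-vertex
    displacements to add. Faces are unchanged.
    """
    if callable(transform):
        disp = np.asarray(transform(mesh.vertices), dtype=float)
        if disp.shape != mesh.vertices.shape:
            raise GeometryError("displacement field shape mismatch")
        return replace(mesh, vertices=mesh.vertices + disp)
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise GeometryError(f"expected 4x4 affine, got {T.shape}")
    if abs(np.linalg.det(T[:3, :3])) < 1e-12:
        raise GeometryError("non-invertible affine")
    verts = mesh.vertices @ T[:3, :3].T + T[:3, 3]
    return replace(mesh, vertices=verts)


def seed_spheres(mesh: SurfaceMesh, radius_mm: float = 0.5) -> dict:
    """Per-vertex seeding spheres: one sphere of ``radius_mm`` per vertex."""
    if radius_mm <= 0:
        raise ConfigError(f"seed radius must be positive, got {radius_mm}")
    return {"centres": mesh.vertices.copy(), "radius_mm": float(radius_mm)}


# ---------------------------------------------------------------------------
# mesh file formats

def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment structure={mesh.structure} hemisphere={mesh.hemisphere}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise DataError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        structure = hemisphere = ""
        while True:
            line = fh.readline()
            if not line:
                raise DataError(f"truncated PLY header in {path}")
            line = line.strip()
            if line.startswith("comment structure="):
                parts = dict(p.split("=", 1) for p in line[8:].split())
                structure = parts.get("structure", "")
                hemisphere = parts.get("hemisphere", "")
            elif line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()] for _ in range(n_vert)]
        )
        faces = np.array(
            [[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)],
            dtype=int,
        ).reshape(-1, 3)
    return SurfaceMesh(verts, faces, structure=structure, hemisphere=hemisphere)


def _write_gifti(mesh: SurfaceMesh, path: Path) -> None:
    gii = nib.gifti.GiftiImage()
    gii.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    gii.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    nib.save(gii, str(path))


def _read_gifti(path: Path) -> SurfaceMesh:
    gii = nib.load(str(path))
    verts = gii.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = gii.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(verts, faces)
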