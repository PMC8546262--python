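"""Nested triangulated head geometries for boundary-element head modelling.

Synthetic heads are built from concentric geodesic spheres (scalp, skull,
CSF, brain) with an optional spherical lesion strictly inside the brain
compartment.  All coordinates are in millimetres; conductivities in S/m.
Surfaces are closed, consistently outward-oriented triangle meshes, which is
what the boundary-element solver in :mod:`lesioncond.bem` requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleSurface",
    "HeadModel",
    "LesionSpec",
    "LesionMetrics",
    "DEFAULT_RADII_MM",
    "DEFAULT_CONDUCTIVITIES",
    "make_icosphere",
    "make_geodesic_sphere",
    "make_sphere_head",
    "add_spherical_lesion",
    "lesion_metrics",
    "refine_near_points",
    "save_surface",
    "load_surface",
]

#: Default outer radii of the scalp, skull, CSF and brain surfaces (mm).
#: Adult-head scale, with a 6 mm scalp layer so that stimulation monopoles
#: placed 3 mm below the scalp stay inside the scalp compartment.
DEFAULT_RADII_MM = (92.0, 86.0, 80.0, 78.0)

#: Conductivities assigned inside scalp, skull, CSF and brain (S/m).
DEFAULT_CONDUCTIVITIES = (0.414, 0.016, 1.71, 0.37)


class GeometryError(ValueError):
    """Raised for invalid or non-nested geometry."""


@dataclass(frozen=True)
class TriangleSurface:
    """A closed, outward-oriented triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (m, 3) int array
        Vertex index triplets, wound counter-clockwise seen from outside.
    label : str
        Compartment name, e.g. ``"scalp"``.
    sphere : tuple or None
        ``(center, radius)`` when the surface discretizes an analytic
        sphere; refinement then re-projects new vertices onto it.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    label: str = ""
    sphere: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "triangles", np.asarray(self.triangles, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must be (m, 3)")

    # -- basic queries -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        m = self.as_trimesh()
        return bool(m.is_watertight and m.is_winding_consistent)

    def signed_volume_mm3(self) -> float:
        """Divergence-theorem volume; positive for outward orientation."""
        return float(self.as_trimesh().volume)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def validate(self) -> None:
        """Check closure, orientation and non-degeneracy; raise otherwise."""
        m = self.as_trimesh()
        if not m.is_watertight:
            raise GeometryError(f"surface {self.label!r} is not closed")
        if not m.is_winding_consistent:
            raise GeometryError(f"surface {self.label!r} has inconsistent winding")
        if m.volume <= 0:
            raise GeometryError(f"surface {self.label!r} is not outward oriented")
        if np.any(self.triangle_areas() <= 0):
            raise GeometryError(f"surface {self.label!r} has degenerate triangles")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: center (mm), radius (mm), conductivity (S/m)."""

    center: tuple
    radius: float
    conductivity: float

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.radius <= 0:
            raise GeometryError("lesion radius must be positive")
        if not (0.0 < self.conductivity <= 2.0):
            raise GeometryError("lesion conductivity must lie in (0, 2] S/m")

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3 / 1000.0


@dataclass(frozen=True)
class LesionMetrics:
    """Lesion volume (ml) and depth (mm: centroid to nearest scalp vertex)."""

    volume_ml: float
    depth_mm: float


@dataclass(frozen=True)
class HeadModel:
    """Nested closed surfaces, outermost first, with inside-conductivities.

    The conductivity outside the outermost (scalp) surface is zero (air).
    A four-surface model is scalp/skull/CSF/brain; a lesion surface may be
    appended as a fifth, strictly inside the brain.
    """

    surfaces: tuple
    conductivities: tuple  # S/m, inside each surface, same order

    def __post_init__(self):
        object.__setattr__(self, "surfaces", tuple(self.surfaces))
        object.__setattr__(self, "conductivities", tuple(float(c) for c in self.conductivities))
        if len(self.surfaces) != len(self.conductivities):
            raise GeometryError("one conductivity per surface required")
        if any(c <= 0 for c in self.conductivities):
            raise GeometryError("conductivities must be positive")

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.surfaces)

    @property
    def scalp(self) -> TriangleSurface:
        return self.surfaces[0]

    @property
    def has_lesion(self) -> bool:
        return "lesion" in self.labels

    @property
    def lesion(self) -> TriangleSurface:
        return self.surfaces[self.labels.index("lesion")]

    def conductivity_of(self, label: str) -> float:
        return self.conductivities[self.labels.index(label)]

    def outside_conductivity(self, i: int) -> float:
        """Conductivity just outside surface ``i``.

        For the nested chain this is the inside-conductivity of the previous
        surface (air, 0.0, outside the scalp); a lesion sits inside the
        brain compartment.
        """
        if i == 0:
            return 0.0
        if self.surfaces[i].label == "lesion":
            return self.conductivity_of("brain")
        return self.conductivities[i - 1]

    def with_conductivity(self, label: str, sigma: float) -> "HeadModel":
        """Return a copy with the conductivity inside ``label`` replaced."""
        idx = self.labels.index(label)
        cond = list(self.conductivities)
        cond[idx] = float(sigma)
        return replace(self, conductivities=tuple(cond))

    def without_lesion(self) -> "HeadModel":
        if not self.has_lesion:
            return self
        idx = self.labels.index("lesion")
        surfs = tuple(s for i, s in enumerate(self.surfaces) if i != idx)
        cond = tuple(c for i, c in enumerate(self.conductivities) if i != idx)
        return HeadModel(surfs, cond)


# ---------------------------------------------------------------------------
# Sphere construction
# ---------------------------------------------------------------------------

def make_icosphere(center, radius: float, subdivisions: int = 3, label: str = "") -> TriangleSurface:
    """Icosahedron-based sphere with ``20 * 4**subdivisions`` triangles."""
    if radius <= 0:
        raise GeometryError("radius must be positive")
    if subdivisions < 0:
        raise GeometryError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    vertices = np.asarray(m.vertices) + np.asarray(center, dtype=float)
    return TriangleSurface(vertices, np.asarray(m.faces), label=label,
                           sphere=(tuple(np.asarray(center, float)), float(radius)))


def make_geodesic_sphere(center, radius: float, frequency: int, label: str = "") -> TriangleSurface:
    """Geodesic icosahedral sphere with ``20 * frequency**2`` triangles.

    Each icosahedron face is split into a barycentric lattice of
    ``frequency**2`` triangles; lattice vertices are projected radially onto
    the sphere and welded exactly across shared edges.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    f = int(frequency)
    if f < 1:
        raise GeometryError("frequency must be >= 1")
    ico = trimesh.creation.icosahedron()
    base_v = np.asarray(ico.vertices)
    base_f = np.asarray(ico.faces)

    key_to_index: dict = {}
    vertices: list = []
    faces: list = []

    def vertex_index(face, i, j, k):
        # Canonical key: multiset of (icosahedron vertex id, lattice weight),
        # identical for lattice points shared across faces.
        key = frozenset((int(v), int(w)) for v, w in zip(face, (i, j, k)) if w > 0)
        idx = key_to_index.get(key)
        if idx is None:
            p = (i * base_v[face[0]] + j * base_v[face[1]] + k * base_v[face[2]]) / f
            p = p / np.linalg.norm(p)
            idx = len(vertices)
            vertices.append(p)
            key_to_index[key] = idx
        return idx

    for face in base_f:
        # lattice rows: i counts weight on vertex 0, descending
        grid = {}
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                grid[(i, j)] = vertex_index(face, i, j, k)
        for i in range(f):
            for j in range(f - i):
                a = grid[(i + 1, j)]
                b = grid[(i, j + 1)]
                c = grid[(i, j)]
                # upward triangle, same winding as parent face
                faces.append((a, b, c))
                if j < f - i - 1:
                    d = grid[(i + 1, j + 1)]
                    faces.append((a, d, b))

    v = np.asarray(vertices) * radius + np.asarray(center, dtype=float)
    surf = TriangleSurface(v, np.asarray(faces, dtype=np.int64), label=label,
                           sphere=(tuple(np.asarray(center, float)), float(radius)))
    if surf.signed_volume_mm3() < 0:  # flip winding if icosahedron was inward
        surf = replace(surf, triangles=surf.triangles[:, ::-1])
    return surf


def _frequency_for(elements: int) -> int:
    """Geodesic frequency whose triangle count best matches ``elements``.

    The count ``20 f**2`` is kept at or below twice the request.
    """
    if elements < 20:
        raise GeometryError("at least 20 elements required")
    f = max(1, int(round(np.sqrt(elements / 20.0))))
    while 20 * f * f > 2 * elements and f > 1:
        f -= 1
    return f


def make_sphere_head(
    radii=DEFAULT_RADII_MM,
    conductivities=DEFAULT_CONDUCTIVITIES,
    elements_per_surface: int = 3200,
    center=(0.0, 0.0, 0.0),
) -> HeadModel:
    """Four-shell concentric-sphere head model (scalp, skull, CSF, brain)."""
    radii = tuple(float(r) for r in radii)
    if len(radii) != 4 or len(tuple(conductivities)) != 4:
        raise GeometryError("four radii and four conductivities required")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise GeometryError("radii must be strictly decreasing (scalp to brain)")
    f = _frequency_for(elements_per_surface)
    labels = ("scalp", "skull", "csf", "brain")
    surfaces = tuple(
        make_geodesic_sphere(center, r, f, label=lab) for r, lab in zip(radii, labels)
    )
    return HeadModel(surfaces, tuple(conductivities))


def add_spherical_lesion(model: HeadModel, spec: LesionSpec, elements: int = 1280) -> HeadModel:
    """Return a five-surface model with a spherical lesion inside the brain.

    The lesion sphere plus a 1 mm margin must lie strictly inside the brain
    surface; boundary-element nesting forbids touching surfaces.
    """
    if model.has_lesion:
        raise GeometryError("model already has a lesion")
    brain = model.surfaces[-1]
    center = np.asarray(spec.center, dtype=float)
    margin = spec.radius + 1.0
    if brain.sphere is not None:
        bc, br = np.asarray(brain.sphere[0]), brain.sphere[1]
        inside = np.linalg.norm(center - bc) + margin < br
    else:
        sd = trimesh.proximity.signed_distance(brain.as_trimesh(), center[None, :])[0]
        inside = sd > margin
    if not inside:
        raise GeometryError(
            "lesion sphere (radius + 1 mm margin) must lie strictly inside the brain surface"
        )
    f = _frequency_for(elements)
    lesion = make_geodesic_sphere(center, spec.radius, f, label="lesion")
    return HeadModel(model.surfaces + (lesion,), model.conductivities + (spec.conductivity,))


def lesion_metrics(model: HeadModel) -> LesionMetrics:
    """Lesion volume (ml) and depth: centroid to nearest scalp *vertex* (mm)."""
    if not model.has_lesion:
        raise GeometryError("model has no lesion surface")
    lesion = model.lesion
    volume_ml = lesion.signed_volume_mm3() / 1000.0
    areas = lesion.triangle_areas()
    tri_centroids = lesion.vertices[lesion.triangles].mean(axis=1)
    centroid = (areas[:, None] * tri_centroids).sum(axis=0) / areas.sum()
    d = np.linalg.norm(model.scalp.vertices - centroid, axis=1)
    return LesionMetrics(volume_ml=float(volume_ml), depth_mm=float(d.min()))


# ---------------------------------------------------------------------------
# Local refinement
# ---------------------------------------------------------------------------

def refine_near_points(surface: TriangleSurface, points, radius: float = 25.0) -> TriangleSurface:
    """Conformingly subdivide triangles whose centroid lies near any point.

    Triangles with centroid within ``radius`` (mm) of a point are split
    4-way at edge midpoints; neighbours sharing split edges are split into
    two or three triangles so the mesh stays closed.  On sphere-derived
    surfaces new vertices are re-projected onto the analytic sphere.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise GeometryError("points must be nonempty")
    surface.validate()

    tris = surface.triangles
    verts = surface.vertices
    centroids = verts[tris].mean(axis=1)
    d = np.min(
        np.linalg.norm(centroids[:, None, :] - points[None, :, :], axis=2), axis=1
    )
    red = d <= radius
    if not red.any():
        return surface

    # mark all edges of red triangles for splitting
    def edge_key(a, b):
        return (a, b) if a < b else (b, a)

    split_edges = set()
    for t in tris[red]:
        split_edges.add(edge_key(t[0], t[1]))
        split_edges.add(edge_key(t[1], t[2]))
        split_edges.add(edge_key(t[2], t[0]))

    new_vertices = [verts]
    midpoint_index: dict = {}
    next_idx = len(verts)
    mids = []
    for e in split_edges:
        midpoint_index[e] = next_idx
        mids.append(0.5 * (verts[e[0]] + verts[e[1]]))
        next_idx += 1
    mids = np.asarray(mids) if mids else np.zeros((0, 3))
    if surface.sphere is not None and len(mids):
        c = np.asarray(surface.sphere[0])
        r = surface.sphere[1]
        u = mids - c
        mids = c + r * u / np.linalg.norm(u, axis=1, keepdims=True)
    new_vertices.append(mids)
    all_vertices = np.vstack(new_vertices)

    new_faces = []
    for t in tris:
        a, b, c = int(t[0]), int(t[1]), int(t[2])
        mab = midpoint_index.get(edge_key(a, b))
        mbc = midpoint_index.get(edge_key(b, c))
        mca = midpoint_index.get(edge_key(c, a))
        n_split = sum(m is not None for m in (mab, mbc, mca))
        if n_split == 0:
            new_faces.append((a, b, c))
        elif n_split == 3:
            new_faces += [(a, mab, mca), (mab, b, mbc), (mca, mbc, c), (mab, mbc, mca)]
        elif n_split == 1:
            if mab is not None:
                new_faces += [(a, mab, c), (mab, b, c)]
            elif mbc is not None:
                new_faces += [(b, mbc, a), (mbc, c, a)]
            else:
                new_faces += [(c, mca, b), (mca, a, b)]
        else:  # two split edges: rotate so the unsplit edge is (a, b)
            if mab is None:
                pass
            elif mbc is None:
                a, b, c = b, c, a
                mab, mbc, mca = mbc, mca, mab
            else:
                a, b, c = c, a, b
                mab, mbc, mca = mca, mab, mbc
            # edges (b,c) and (c,a) are split at mbc, mca
            new_faces += [(c, mca, mbc), (a, mbc, mca), (a, b, mbc)]
    out = TriangleSurface(
        all_vertices, np.asarray(new_faces, dtype=np.int64),
        label=surface.label, sphere=surface.sphere,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Mesh I/O (PLY / STL / OFF via trimesh)
# ---------------------------------------------------------------------------

_MESH_FORMATS = {".ply", ".stl", ".off"}


def save_surface(surface: TriangleSurface, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    surface.as_trimesh().export(path)


def load_surface(path, label: str = "") -> TriangleSurface:
    path = Path(path)
    if path.suffix.lower() not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    m = trimesh.load(path, force="mesh", process=False)
    return TriangleSurface(np.asarray(m.vertices), np.asarray(m.faces), label=label or path.stem)
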