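"""Boundary-element forward solver for nested piecewise-homogeneous heads.

The electric potential of current monopoles in a nested compartment model
satisfies the classical surface integral equation

    sigma_bar(r) phi(r) = g(r) + (1/4pi) sum_j (sigma_j^in - sigma_j^out)
                                  ∮_{S_j} phi(r') dOmega_r(r'),

where ``dOmega`` is the solid angle subtended at the observation point,
``sigma_bar`` the mean of the conductivities on both sides of the surface
at ``r``, and ``g`` the infinite-medium source term.  The equation is
discretized by linear collocation: vertex unknowns, hat-function
interpolation on triangles, and analytically integrated solid-angle
weights.  The rank-one constant-potential null space is removed by
deflation, fixing the area-weighted mean potential to zero.

Matrix blocks are pure geometry; conductivities only scale them.  For a
model with a lesion surface the dependence on the lesion conductivity is a
low-rank column update, so re-solving for a new lesion conductivity uses a
Woodbury correction of a single cached factorization -- this is what makes
the multi-start estimation loop tractable.

Geometry enters in millimetres (matching :mod:`lesioncond.geometry`); all
internal computation is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import trimesh

from .electrodes import ElectrodeLayout
from .geometry import HeadModel, TriangleSurface

__all__ = [
    "SourceConfig",
    "BEMSystem",
    "PotentialField",
    "ElectrodeRecording",
    "infinite_medium_potential",
    "stimulation_sources",
    "assemble_system",
    "solve_potentials",
    "record_at_electrodes",
]

MM = 1e-3  # mm -> m

#: Default stimulation current (A); 0.1 mA keeps the procedure comfortable
#: for a patient.
DEFAULT_CURRENT_A = 1e-4

#: Stimulation electrodes are modelled as current monopoles this far inside
#: the scalp surface (mm).
MONOPOLE_DEPTH_MM = 3.0


class BEMError(RuntimeError):
    pass


@dataclass(frozen=True)
class SourceConfig:
    """Current monopoles: positions (mm) and signed currents (A, sum 0)."""

    positions: np.ndarray
    currents: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions", np.atleast_2d(np.asarray(self.positions, float)))
        object.__setattr__(self, "currents", np.atleast_1d(np.asarray(self.currents, float)))
        if len(self.positions) != len(self.currents):
            raise ValueError("one current per monopole required")
        if abs(self.currents.sum()) > 1e-12 * np.abs(self.currents).max():
            raise ValueError("monopole currents must sum to zero")


def stimulation_sources(
    model: HeadModel,
    layout: ElectrodeLayout,
    pair,
    current: float = DEFAULT_CURRENT_A,
    depth_mm: float = MONOPOLE_DEPTH_MM,
) -> SourceConfig:
    """Anode/cathode monopoles ``depth_mm`` inside the scalp surface.

    The inward direction is radial for sphere-derived scalps and the local
    inward surface normal otherwise.
    """
    anode, cathode = pair
    positions = []
    scalp = model.scalp
    for label in (anode, cathode):
        p = layout.position_of(label)
        if scalp.sphere is not None:
            c = np.asarray(scalp.sphere[0])
            u = p - c
            u = u / np.linalg.norm(u)
            positions.append(p - depth_mm * u)
        else:
            mesh = scalp.as_trimesh()
            closest, _, tid = trimesh.proximity.closest_point(mesh, p[None, :])
            normal = mesh.face_normals[tid[0]]
            positions.append(closest[0] - depth_mm * normal)
    return SourceConfig(np.asarray(positions), np.array([current, -current]))


def infinite_medium_potential(sources: SourceConfig, points_mm, sigma: float) -> np.ndarray:
    """Potential (V) of monopoles in an unbounded medium of ``sigma`` S/m."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = np.atleast_2d(np.asarray(points_mm, float)) * MM
    src = sources.positions * MM
    d = np.linalg.norm(pts[:, None, :] - src[None, :, :], axis=2)
    if np.any(d < 1e-12):
        raise ValueError("evaluation point coincides with a source")
    phi = (sources.currents[None, :] / (4.0 * np.pi * sigma * d)).sum(axis=1)
    return phi if np.ndim(points_mm) == 2 else phi[0]


# ---------------------------------------------------------------------------
# Analytic linear-collocation solid-angle integrals
# ---------------------------------------------------------------------------

def _lin_solid_angle_chunk(obs, tri_xyz, tri_nn, tri_area):
    """Analytic integrals of hat functions against the solid-angle kernel.

    Returns (n_obs, n_tri, 3): the integral of each linear shape function
    over each triangle of ``dOmega`` as seen from each observation point
    (de Munck's analytically integrated elements).
    """
    v1 = tri_xyz[None, :, 0, :] - obs[:, None, :]
    v2 = tri_xyz[None, :, 1, :] - obs[:, None, :]
    v3 = tri_xyz[None, :, 2, :] - obs[:, None, :]
    l1 = np.linalg.norm(v1, axis=2)
    l2 = np.linalg.norm(v2, axis=2)
    l3 = np.linalg.norm(v3, axis=2)
    triple = np.einsum("otk,otk->ot", np.cross(v1, v2), v3)
    ss = l1 * l2 * l3
    ss += np.einsum("otk,otk->ot", v1, v2) * l3
    ss += np.einsum("otk,otk->ot", v1, v3) * l2
    ss += np.einsum("otk,otk->ot", v2, v3) * l1
    half_solid = np.arctan2(triple, ss)  # Omega / 2

    bad = np.abs(half_solid) < np.pi / 1e6  # observation in the triangle plane
    safe_l1 = np.where(bad, 1.0, l1)
    safe_l2 = np.where(bad, 1.0, l2)
    safe_l3 = np.where(bad, 1.0, l3)

    def beta(va, la, vb, lb):
        e = vb - va
        size = np.linalg.norm(e, axis=2)
        size = np.where(size < 1e-300, 1.0, size)
        eu = e / size[:, :, None]
        num = la + np.einsum("otk,otk->ot", va, eu)
        den = lb + np.einsum("otk,otk->ot", vb, eu)
        num = np.where(num <= 0, 1.0, num)
        den = np.where(den <= 0, 1.0, den)
        return np.log(num / den) / size

    b12 = beta(v1, safe_l1, v2, safe_l2)
    b23 = beta(v2, safe_l2, v3, safe_l3)
    b31 = beta(v3, safe_l3, v1, safe_l1)
    vec_omega = (
        (b31 - b12)[:, :, None] * v1
        + (b12 - b23)[:, :, None] * v2
        + (b23 - b31)[:, :, None] * v3
    )

    area2 = 2.0 * tri_area[None, :]
    n2 = 1.0 / (area2 * area2)
    out = np.empty(half_solid.shape + (3,))
    ys = (v1, v2, v3)
    for k in range(3):
        y_next = ys[(k + 1) % 3]
        y_prev = ys[(k + 2) % 3]
        diff = y_prev - y_next
        zdots = np.einsum("otk,otk->ot", np.cross(y_next, y_prev), tri_nn[None, :, :])
        out[:, :, k] = n2 * (
            area2 * zdots * 2.0 * half_solid
            - triple * np.einsum("otk,otk->ot", diff, vec_omega)
        )
    out[bad] = 0.0
    return out


def _lin_pot_block(obs, surface_v, surface_t, self_block: bool, chunk: int = 256):
    """(n_obs, n_verts) matrix of hat-function solid-angle integrals.

    For self blocks (observation points are the surface's own vertices)
    contributions of triangles containing the observation vertex vanish and
    the remaining row deficit against the flat-surface limit 2*pi is
    redistributed (half to the vertex itself, half to its neighbours).
    """
    tri_xyz = surface_v[surface_t]
    nrm = np.cross(tri_xyz[:, 1] - tri_xyz[:, 0], tri_xyz[:, 2] - tri_xyz[:, 0])
    tri_area = 0.5 * np.linalg.norm(nrm, axis=1)
    tri_nn = nrm / (2.0 * tri_area[:, None])

    n_tri = len(surface_t)
    n_obs = len(obs)
    cols = scipy.sparse.csr_matrix(
        (
            np.ones(3 * n_tri),
            (surface_t.reshape(-1), np.arange(3 * n_tri)),
        ),
        shape=(len(surface_v), 3 * n_tri),
    )
    out = np.empty((n_obs, len(surface_v)))
    for start in range(0, n_obs, chunk):
        sl = slice(start, min(start + chunk, n_obs))
        om = _lin_solid_angle_chunk(obs[sl], tri_xyz, tri_nn, tri_area)
        if self_block:
            ids = np.arange(start, sl.stop)
            mask = (surface_t[None, :, :] == ids[:, None, None]).any(axis=2)
            om[mask] = 0.0
        out[sl] = om.reshape(sl.stop - start, -1) @ cols.T
    if self_block:
        _redistribute_auto(surface_t, out)
    return out


def _redistribute_auto(tris, mat):
    """Fix self-block rows so each sums to the flat-surface limit 2*pi."""
    n = mat.shape[0]
    miss = 2.0 * np.pi - mat.sum(axis=1)
    neighbors = [[] for _ in range(n)]
    for t in tris:
        a, b, c = int(t[0]), int(t[1]), int(t[2])
        neighbors[a].append((b, c))
        neighbors[b].append((c, a))
        neighbors[c].append((a, b))
    for j in range(n):
        memb = neighbors[j]
        mat[j, j] += miss[j] / 2.0
        share = miss[j] / (4.0 * len(memb))
        for b, c in memb:
            mat[j, b] += share
            mat[j, c] += share


# ---------------------------------------------------------------------------
# System assembly and solution
# ---------------------------------------------------------------------------

@dataclass
class BEMSystem:
    """Assembled, deflated and factorized boundary-element operator."""

    model: HeadModel
    offsets: np.ndarray           # vertex offsets per surface
    vertices_m: np.ndarray        # all vertices, SI
    sigma_bar: np.ndarray         # per vertex
    lu: tuple = field(repr=False)
    lesion_update: np.ndarray | None = field(default=None, repr=False)  # N x n_les
    lesion_slice: slice | None = None
    sigma_lesion_ref: float | None = None
    _wood_X: np.ndarray | None = field(default=None, repr=False)
    _wood_W: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_unknowns(self) -> int:
        return len(self.vertices_m)

    def surface_slice(self, label: str) -> slice:
        i = self.model.labels.index(label)
        return slice(self.offsets[i], self.offsets[i + 1])

    def source_rhs(self, sources: SourceConfig) -> np.ndarray:
        src = sources.positions * MM
        d = np.linalg.norm(self.vertices_m[:, None, :] - src[None, :, :], axis=2)
        if np.any(d < 1e-9):
            raise BEMError("source coincides with a mesh vertex")
        return (sources.currents[None, :] / (4.0 * np.pi * d)).sum(axis=1)

    def solve(self, sources: SourceConfig) -> "PotentialField":
        rhs = self.source_rhs(sources)
        phi = scipy.linalg.lu_solve(self.lu, rhs)
        if not np.all(np.isfinite(phi)):
            raise BEMError("singular or ill-conditioned BEM system")
        return PotentialField(self, phi)

    # -- fast re-solve in the lesion conductivity --------------------------
    def _ensure_woodbury(self):
        if self.lesion_update is None:
            raise BEMError("model has no lesion surface")
        if self._wood_X is None:
            X = scipy.linalg.lu_solve(self.lu, self.lesion_update)
            self._wood_X = X
            self._wood_W = X[self.lesion_slice]

    def solve_lesion_sigma(self, sources_or_rhs, sigma_lesion: float) -> "PotentialField":
        """Solve with the lesion conductivity replaced by ``sigma_lesion``.

        Uses the Woodbury identity on the cached factorization; exact (up
        to round-off), not an approximation.
        """
        self._ensure_woodbury()
        if isinstance(sources_or_rhs, SourceConfig):
            rhs = self.source_rhs(sources_or_rhs)
        else:
            rhs = np.asarray(sources_or_rhs, float)
        y0 = scipy.linalg.lu_solve(self.lu, rhs)
        delta = float(sigma_lesion) - self.sigma_lesion_ref
        if delta == 0.0:
            return PotentialField(self, y0)
        nl = self._wood_W.shape[0]
        cap = np.eye(nl) + delta * self._wood_W
        z = np.linalg.solve(cap, y0[self.lesion_slice])
        phi = y0 - delta * (self._wood_X @ z)
        return PotentialField(self, phi)


@dataclass(frozen=True)
class PotentialField:
    """Per-vertex potentials (V) on every surface of a model."""

    system: BEMSystem
    values: np.ndarray

    def surface_values(self, label: str) -> np.ndarray:
        return self.values[self.system.surface_slice(label)]

    @property
    def model(self) -> HeadModel:
        return self.system.model


def _check_nesting(model: HeadModel) -> None:
    for i, surf in enumerate(model.surfaces[1:], start=1):
        if surf.label == "lesion":
            outer = model.surfaces[model.labels.index("brain")]
        else:
            outer = model.surfaces[i - 1]
        if surf.sphere is not None and outer.sphere is not None:
            ci, ri = np.asarray(surf.sphere[0]), surf.sphere[1]
            co, ro = np.asarray(outer.sphere[0]), outer.sphere[1]
            if np.linalg.norm(ci - co) + ri >= ro:
                raise BEMError(f"surface {surf.label!r} not strictly inside {outer.label!r}")
        else:
            if not outer.as_trimesh().contains(surf.vertices).all():
                raise BEMError(f"surface {surf.label!r} not strictly inside {outer.label!r}")


def _check_sources_in_scalp(model: HeadModel, sources: SourceConfig) -> None:
    scalp, skull = model.surfaces[0], model.surfaces[1]
    pts = sources.positions
    if scalp.sphere is not None and skull.sphere is not None:
        r = np.linalg.norm(pts - np.asarray(scalp.sphere[0]), axis=1)
        ok = np.all((r < scalp.sphere[1]) & (r > skull.sphere[1]))
    else:
        ok = scalp.as_trimesh().contains(pts).all() and not skull.as_trimesh().contains(pts).any()
    if not ok:
        raise BEMError("stimulation monopoles must lie inside the scalp compartment")


def assemble_system(
    model: HeadModel,
    sources: SourceConfig | None = None,
    sigma_lesion_ref: float | None = None,
    validate: bool = True,
) -> BEMSystem:
    """Assemble, deflate and factorize the linear-collocation operator.

    ``sources`` is optional (and only validated here): the operator depends
    on geometry and conductivities alone, so one assembled system serves
    any number of stimulation configurations.
    """
    if validate:
        for s in model.surfaces:
            s.validate()
        _check_nesting(model)
    if sources is not None:
        _check_sources_in_scalp(model, sources)

    n_surf = len(model.surfaces)
    nps = [s.n_vertices for s in model.surfaces]
    offsets = np.concatenate(([0], np.cumsum(nps)))
    n_tot = offsets[-1]
    verts_m = np.vstack([s.vertices for s in model.surfaces]) * MM

    sigma_in = np.asarray(model.conductivities)
    sigma_out = np.asarray([model.outside_conductivity(i) for i in range(n_surf)])
    contrast = sigma_in - sigma_out
    sigma_bar = np.concatenate(
        [np.full(nps[i], 0.5 * (sigma_in[i] + sigma_out[i])) for i in range(n_surf)]
    )

    lesion_idx = model.labels.index("lesion") if model.has_lesion else None
    if lesion_idx is not None:
        if sigma_lesion_ref is None:
            sigma_lesion_ref = model.conductivities[lesion_idx]
        sigma_brain = model.conductivity_of("brain")
        contrast = contrast.copy()
        contrast[lesion_idx] = sigma_lesion_ref - sigma_brain
        sigma_bar[offsets[lesion_idx]: offsets[lesion_idx + 1]] = 0.5 * (
            sigma_lesion_ref + sigma_brain
        )

    M = np.zeros((n_tot, n_tot))
    lesion_update = None
    for j, surf in enumerate(model.surfaces):
        sv = surf.vertices * MM
        st = surf.triangles
        col = slice(offsets[j], offsets[j + 1])
        block_rows = []
        for i in range(n_surf):
            row = slice(offsets[i], offsets[i + 1])
            obs = verts_m[row]
            if i == j:
                omega = _lin_pot_block(sv, sv, st, self_block=True)
            else:
                omega = _lin_pot_block(obs, sv, st, self_block=False)
            M[row, col] = -contrast[j] / (4.0 * np.pi) * omega
            block_rows.append(omega)
        if j == lesion_idx:
            omega_full = np.vstack(block_rows)
            lesion_update = -omega_full / (4.0 * np.pi)
            ids = np.arange(offsets[j], offsets[j + 1])
            lesion_update[ids, ids - offsets[j]] += 0.5
    M[np.arange(n_tot), np.arange(n_tot)] += sigma_bar

    # deflation: remove the constant null space, gauge area-weighted mean 0
    vertex_area = np.zeros(n_tot)
    for i, surf in enumerate(model.surfaces):
        a = surf.triangle_areas()
        va = np.zeros(surf.n_vertices)
        np.add.at(va, surf.triangles.reshape(-1), np.repeat(a / 3.0, 3))
        vertex_area[offsets[i]: offsets[i + 1]] = va
    p = vertex_area / vertex_area.sum()
    M += sigma_bar.mean() * p[None, :]

    lu = scipy.linalg.lu_factor(M, overwrite_a=True, check_finite=False)
    return BEMSystem(
        model=model,
        offsets=offsets,
        vertices_m=verts_m,
        sigma_bar=sigma_bar,
        lu=lu,
        lesion_update=lesion_update,
        lesion_slice=(
            slice(offsets[lesion_idx], offsets[lesion_idx + 1]) if lesion_idx is not None else None
        ),
        sigma_lesion_ref=sigma_lesion_ref,
    )


def solve_potentials(system: BEMSystem, sources: SourceConfig) -> PotentialField:
    """Solve for the potentials of ``sources`` on all surfaces."""
    return system.solve(sources)


# ---------------------------------------------------------------------------
# Electrode recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeRecording:
    """Potentials (V) at labelled electrodes, referenced to the reference.

    ``provenance`` distinguishes the potentials treated as measured in an
    experiment ("recorded", psi) from model-simulated ones ("simulated",
    phi(sigma)).
    """

    labels: tuple
    potentials: np.ndarray
    reference_label: str = "nasion"
    stim_pair: tuple | None = None
    provenance: str = "simulated"

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "potentials", np.asarray(self.potentials, float))
        if len(self.labels) != len(self.potentials):
            raise ValueError("labels/potentials length mismatch")
        if self.stim_pair is not None and set(self.stim_pair) & set(self.labels):
            raise ValueError("stimulation pair must be excluded from recordings")
        iref = self.labels.index(self.reference_label)
        if abs(self.potentials[iref]) > 1e-12:
            raise ValueError("reference potential must be zero after re-referencing")

    @property
    def measurement_labels(self) -> tuple:
        return tuple(l for l in self.labels if l != self.reference_label)

    def values_for(self, labels) -> np.ndarray:
        idx = [self.labels.index(l) for l in labels]
        return self.potentials[idx]


def _closest_point_on_mesh(surface: TriangleSurface, pts: np.ndarray):
    """Closest point, distance and triangle id on a mesh for each point.

    Candidate triangles are those incident to the few nearest vertices of
    each query point, which is exhaustive enough for points near the
    surface (the only supported use).
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(surface.vertices)
    _, near = tree.query(pts, k=min(12, surface.n_vertices))
    near = np.atleast_2d(near)
    vert_faces = [[] for _ in range(surface.n_vertices)]
    for fi, t in enumerate(surface.triangles):
        for v in t:
            vert_faces[v].append(fi)
    tri_xyz = surface.vertices[surface.triangles]
    closest = np.empty_like(pts)
    dist = np.empty(len(pts))
    tid = np.empty(len(pts), dtype=int)
    for i, p in enumerate(pts):
        cand = sorted({f for v in near[i] for f in vert_faces[v]})
        cp = trimesh.triangles.closest_point(tri_xyz[cand], np.tile(p, (len(cand), 1)))
        d = np.linalg.norm(cp - p, axis=1)
        k = int(np.argmin(d))
        closest[i], dist[i], tid[i] = cp[k], d[k], cand[k]
    return closest, dist, tid


def interpolation_operator(scalp: TriangleSurface, positions_mm, tolerance_mm: float = 2.0):
    """Barycentric interpolation matrix from scalp vertices to points.

    Points are projected to the closest point on the mesh; projection
    farther than ``tolerance_mm`` raises.
    """
    mesh = scalp.as_trimesh()
    pts = np.atleast_2d(np.asarray(positions_mm, float))
    closest, dist, tid = _closest_point_on_mesh(scalp, pts)
    if np.any(dist > tolerance_mm):
        worst = float(dist.max())
        raise ValueError(
            f"electrode {worst:.2f} mm from the scalp surface exceeds tolerance "
            f"{tolerance_mm} mm"
        )
    tri_xyz = mesh.triangles[tid]
    bary = trimesh.triangles.points_to_barycentric(tri_xyz, closest)
    W = np.zeros((len(pts), scalp.n_vertices))
    rows = np.repeat(np.arange(len(pts)), 3)
    cols = scalp.triangles[tid].reshape(-1)
    np.add.at(W, (rows, cols), bary.reshape(-1))
    return W


def record_at_electrodes(
    field: PotentialField,
    layout: ElectrodeLayout,
    exclude=(),
    tolerance_mm: float = 2.0,
    provenance: str = "simulated",
) -> ElectrodeRecording:
    """Interpolate scalp potentials at electrodes, re-referenced.

    ``exclude`` lists the stimulation pair; the result covers the remaining
    measurement electrodes plus the reference (value exactly zero).
    """
    exclude = tuple(exclude)
    keep = [l for l in layout.labels if l not in exclude]
    idx = [layout.labels.index(l) for l in keep]
    W = interpolation_operator(field.model.scalp, layout.positions[idx], tolerance_mm)
    vals = W @ field.surface_values("scalp")
    iref = keep.index(layout.reference_label)
    vals = vals - vals[iref]
    vals[iref] = 0.0
    return ElectrodeRecording(
        labels=tuple(keep),
        potentials=vals,
        reference_label=layout.reference_label,
        stim_pair=tuple(exclude) if exclude else None,
        provenance=provenance,
    )
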