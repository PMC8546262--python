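"""Closed-form potentials for concentric layered spheres.

A point current monopole inside the outermost layer of a concentric,
piecewise-homogeneous sphere has a Legendre-series solution: per harmonic
degree ``n`` the radial coefficients in each layer follow from continuity of
potential and normal current density at the interfaces and from the
insulating exterior boundary.  This module provides that series as the
ground-truth oracle for the boundary-element solver, together with the
standard RDM/MAG forward-solution error metrics.

Single-monopole fields are defined up to their spherically symmetric
(``n = 0``) component, which an insulated conductor cannot support for a net
current source; it cancels exactly when superposing an anode/cathode pair at
equal source radius, the only configuration used downstream.

Units are SI throughout (meters, volts, amperes, S/m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LayeredSphereModel",
    "SeriesConvergenceError",
    "layered_sphere_potential",
    "pair_potential",
    "rdm_mag",
]


class SeriesConvergenceError(RuntimeError):
    """The Legendre series did not reach the requested tail tolerance."""


@dataclass(frozen=True)
class LayeredSphereModel:
    """Concentric layered sphere: radii (m, strictly decreasing), sigmas (S/m)."""

    radii: tuple
    conductivities: tuple
    n_max: int = 200

    def __post_init__(self):
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))
        object.__setattr__(self, "conductivities", tuple(float(s) for s in self.conductivities))
        if len(self.radii) != len(self.conductivities):
            raise ValueError("one conductivity per layer required")
        if any(r2 >= r1 for r1, r2 in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly decreasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.radii)


def _radial_coefficients(model: LayeredSphereModel, source_radius: float, current: float, n_max: int):
    """Solve the per-degree interface conditions.

    Layer ``j`` (0-based, outermost first) occupies ``b[j+1] <= r <= b[j]``
    and carries ``phi_j = A_j (r/b_j)^n + B_j (c_j/r)^(n+1)`` with
    ``c_j = b[j+1]`` (innermost layer: A only).  The per-layer scaling keeps
    every matrix entry a power of a ratio of adjacent radii, which stays
    well-conditioned for large ``n``.

    Returns A (n_max, L) and B (n_max, L) with B[:, -1] = 0.
    """
    b = np.asarray(model.radii)
    sig = np.asarray(model.conductivities)
    L = model.n_layers
    r0 = source_radius
    # source layer index
    s = int(np.searchsorted(-b, -r0, side="right") - 1) if r0 < b[0] else 0
    s = min(max(s, 0), L - 1)
    q_over_r0 = current / (4.0 * np.pi * sig[s]) / r0

    n = np.arange(1, n_max + 1, dtype=float)[:, None]  # (N, 1)
    m = 2 * L - 1
    M = np.zeros((n_max, m, m))
    rhs = np.zeros((n_max, m))

    def col_A(j):
        return j

    def col_B(j):
        return L + j  # valid for j < L-1

    # source particular solution and r * derivative, scaled
    def S(r):
        if r >= r0:
            return q_over_r0 * (r0 / r) ** (n + 1)
        return q_over_r0 * (r / r0) ** n

    def rSp(r):
        if r >= r0:
            return -(n + 1) * q_over_r0 * (r0 / r) ** (n + 1)
        return n * q_over_r0 * (r / r0) ** n

    # exterior boundary (insulating) at b[0], layer 0
    row = 0
    M[:, row, col_A(0)] = n[:, 0]
    if L > 1:
        M[:, row, col_B(0)] = -(n[:, 0] + 1) * (b[1] / b[0]) ** (n[:, 0] + 1)
    if s == 0:
        rhs[:, row] = -rSp(b[0])[:, 0]
    row += 1

    for j in range(L - 1):
        bi = b[j + 1]
        fj = (bi / b[j]) ** n[:, 0]
        gj = np.ones(n_max)
        fj1 = np.ones(n_max)
        gj1 = (b[j + 2] / bi) ** (n[:, 0] + 1) if j + 1 < L - 1 else None
        # continuity of potential
        M[:, row, col_A(j)] = fj
        if j < L - 1:
            M[:, row, col_B(j)] = gj
        M[:, row, col_A(j + 1)] = -fj1
        if gj1 is not None:
            M[:, row, col_B(j + 1)] = -gj1
        src = np.zeros(n_max)
        if s == j:
            src -= S(bi)[:, 0]
        if s == j + 1:
            src += S(bi)[:, 0]
        rhs[:, row] = src
        row += 1
        # continuity of radial current density (times r)
        M[:, row, col_A(j)] = sig[j] * n[:, 0] * fj
        M[:, row, col_B(j)] = -sig[j] * (n[:, 0] + 1) * gj
        M[:, row, col_A(j + 1)] = -sig[j + 1] * n[:, 0] * fj1
        if gj1 is not None:
            M[:, row, col_B(j + 1)] = sig[j + 1] * (n[:, 0] + 1) * gj1
        src = np.zeros(n_max)
        if s == j:
            src -= sig[j] * rSp(bi)[:, 0]
        if s == j + 1:
            src += sig[j + 1] * rSp(bi)[:, 0]
        rhs[:, row] = src
        row += 1

    coef = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]  # (N, m)
    A = coef[:, :L]
    B = np.zeros((n_max, L))
    if L > 1:
        B[:, : L - 1] = coef[:, L:]
    return A, B, s, q_over_r0


def layered_sphere_potential(
    model: LayeredSphereModel,
    source_radius: float,
    source_direction,
    current: float,
    eval_points,
    n_max: int | None = None,
    tail_tol: float = 1e-8,
) -> np.ndarray:
    """Series potential (V) of one interior monopole at ``eval_points`` (m).

    ``source_direction`` is a unit vector; the source sits at
    ``source_radius * source_direction``.  Raises
    :class:`SeriesConvergenceError` when the last retained term exceeds
    ``tail_tol`` of the solution scale.
    """
    if n_max is None:
        n_max = model.n_max
    b = model.radii
    if not (0.0 < source_radius < b[0]):
        raise ValueError("source must be strictly inside the outer surface")
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    radii = np.linalg.norm(pts, axis=1)
    if np.any(radii > b[0] * (1 + 1e-9)):
        raise ValueError("evaluation points must lie on or inside the outer surface")
    sdir = np.asarray(source_direction, dtype=float)
    sdir = sdir / np.linalg.norm(sdir)

    A, B, s, q_over_r0 = _radial_coefficients(model, source_radius, current, n_max)
    n = np.arange(1, n_max + 1, dtype=float)[:, None]  # (N, 1)

    # layer index per evaluation point
    layer = np.zeros(len(pts), dtype=int)
    for j in range(1, model.n_layers):
        layer[radii < b[j] * (1 - 1e-12)] = j

    # radial part (N, P)
    rad = np.zeros((n_max, len(pts)))
    r = np.maximum(radii, 1e-12)[None, :]
    for j in range(model.n_layers):
        sel = layer == j
        if not sel.any():
            continue
        rj = r[:, sel]
        term = A[:, j : j + 1] * (rj / b[j]) ** n
        if j < model.n_layers - 1:
            term = term + B[:, j : j + 1] * (b[j + 1] / rj) ** (n + 1)
        if j == s:
            above = radii[sel] >= source_radius
            src = np.where(
                above[None, :],
                q_over_r0 * (source_radius / rj) ** (n + 1),
                q_over_r0 * (rj / source_radius) ** n,
            )
            term = term + src
        rad[:, sel] = term

    # Legendre P_n(cos gamma) by upward recurrence, n = 1..n_max
    unit = pts / np.maximum(radii, 1e-12)[:, None]
    x = np.clip(unit @ sdir, -1.0, 1.0)  # (P,)
    phi = np.zeros(len(pts))
    p_nm1 = np.ones_like(x)  # P_0
    p_n = x.copy()  # P_1
    for k in range(1, n_max + 1):
        phi += rad[k - 1] * p_n
        p_np1 = ((2 * k + 1) * x * p_n - k * p_nm1) / (k + 1)
        p_nm1, p_n = p_n, p_np1

    scale = np.max(np.abs(phi))
    tail = np.max(np.abs(rad[-1]))
    if scale > 0 and tail / scale > tail_tol:
        raise SeriesConvergenceError(
            f"series tail ratio {tail / scale:.2e} exceeds {tail_tol:.1e} at n_max={n_max}; "
            "increase n_max"
        )
    return phi if np.ndim(eval_points) == 2 else phi[0]


def pair_potential(
    model: LayeredSphereModel,
    source_radius: float,
    anode_direction,
    cathode_direction,
    current: float,
    eval_points,
    n_max: int | None = None,
    tail_tol: float = 1e-8,
) -> np.ndarray:
    """Superposed anode (+I) / cathode (-I) potential at equal source radius."""
    return layered_sphere_potential(
        model, source_radius, anode_direction, current, eval_points, n_max, tail_tol
    ) - layered_sphere_potential(
        model, source_radius, cathode_direction, current, eval_points, n_max, tail_tol
    )


def rdm_mag(reference, test):
    """Relative difference measure and magnitude ratio of two potential sets.

    ``RDM = || ref/||ref|| - test/||test|| ||`` (0 for identical topography,
    worst case 2); ``MAG = ||test|| / ||ref||``.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError("inputs must have equal shape")
    nr = np.linalg.norm(ref)
    nt = np.linalg.norm(tst)
    if nr == 0 or nt == 0:
        raise ValueError("zero-norm input")
    rdm = float(np.linalg.norm(ref / nr - tst / nt))
    mag = float(nt / nr)
    return rdm, mag
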