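"""Electrode coregistration error model and electrode subsets.

Systematic electrode-placement error is modelled as a rigid rotation of the
whole measurement layout about a head axis: "coronal" rotation is about the
left-right (interaural, x) axis and "sagittal" rotation about the
anterior-posterior (y) axis, in a head frame with x right, y anterior,
z superior.  Rotated positions are *not* re-projected onto the scalp;
recording tolerates the small off-surface displacement.

Subsets of 8/16/32/64/128 electrodes emulate sparser EEG caps: the
8-subset is the fixed set around the vertex; 16/32/64 are chosen by
deterministic farthest-point sampling seeded at Cz, giving uniform scalp
coverage and nested subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .electrodes import CENTRAL_8_LABELS, ElectrodeLayout

__all__ = [
    "RotationSpec",
    "SubsetSpec",
    "rotate_layout",
    "mean_displacement",
    "select_subset",
]

AXES = {"coronal": np.array([1.0, 0.0, 0.0]), "sagittal": np.array([0.0, 1.0, 0.0])}

SUBSET_SIZES = (8, 16, 32, 64, 128)


@dataclass(frozen=True)
class RotationSpec:
    """Rigid layout rotation: axis name, angle (deg, 0-5), center (mm)."""

    axis: str = "coronal"
    angle_deg: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError("axis must be 'coronal' or 'sagittal'")
        if not (0.0 <= self.angle_deg <= 5.0):
            raise ValueError("rotation angle must lie in [0, 5] degrees")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class SubsetSpec:
    """An electrode subset of size 8, 16, 32, 64 or 128."""

    size: int
    labels: tuple

    def __post_init__(self):
        if self.size not in SUBSET_SIZES:
            raise ValueError(f"subset size must be one of {SUBSET_SIZES}")
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != self.size:
            raise ValueError("label count must equal the subset size")
        if self.size == 8 and set(self.labels) != set(CENTRAL_8_LABELS):
            raise ValueError(f"the 8-subset is fixed to {CENTRAL_8_LABELS}")


def rotate_layout(layout: ElectrodeLayout, spec: RotationSpec) -> ElectrodeLayout:
    """Rigidly rotate all electrode positions (reference included)."""
    rot = Rotation.from_rotvec(np.radians(spec.angle_deg) * AXES[spec.axis])
    center = np.asarray(spec.center)
    return layout.with_positions(rot.apply(layout.positions - center) + center)


def mean_displacement(a: ElectrodeLayout, b: ElectrodeLayout) -> float:
    """Mean Euclidean distance (mm) between same-label electrodes."""
    if a.labels != b.labels:
        if set(a.labels) != set(b.labels):
            raise ValueError("layouts cover different electrodes")
        b = b.subset([l for l in a.labels if l != a.reference_label])
    return float(np.mean(np.linalg.norm(a.positions - b.positions, axis=1)))


def _farthest_point_order(layout: ElectrodeLayout, seed_label: str = "Cz"):
    """Greedy farthest-point ordering of measurement electrodes from Cz.

    Deterministic; ties broken by label order in the layout.  Prefixes of
    the ordering are nested, so size-16/32/64 subsets satisfy 16 ⊂ 32 ⊂ 64.
    """
    labels = list(layout.measurement_labels)
    pos = np.array([layout.position_of(l) for l in labels])
    order = [labels.index(seed_label)]
    dmin = np.linalg.norm(pos - pos[order[0]], axis=1)
    while len(order) < len(labels):
        nxt = int(np.argmax(dmin))
        order.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pos - pos[nxt], axis=1))
    return [labels[i] for i in order]


def select_subset(layout: ElectrodeLayout, size: int) -> ElectrodeLayout:
    """Restrict the layout to a standard subset (reference kept)."""
    if size not in SUBSET_SIZES:
        raise ValueError(f"subset size must be one of {SUBSET_SIZES}")
    n_meas = len(layout.measurement_labels)
    if size == n_meas:
        return layout
    if size > n_meas:
        raise ValueError(f"layout has only {n_meas} measurement electrodes")
    if size == 8:
        labels = list(CENTRAL_8_LABELS)
    else:
        labels = _farthest_point_order(layout)[:size]
    return layout.subset(labels)


def subset_spec(layout: ElectrodeLayout, size: int) -> SubsetSpec:
    sub = select_subset(layout, size)
    return SubsetSpec(size=size, labels=sub.measurement_labels)
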