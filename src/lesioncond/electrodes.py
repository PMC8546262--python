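"""Labelled 10/5 electrode layouts on the scalp surface.

The canonical layout ships as a static table of unit-sphere directions for
128 measurement labels plus a nasion reference; positions are obtained by
projecting each direction radially from the head center onto the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import trimesh

from .geometry import TriangleSurface

__all__ = [
    "ElectrodeLayout",
    "OUTER_EDGE_LABELS",
    "CENTRAL_8_LABELS",
    "canonical_directions",
    "place_electrodes_10_5",
    "save_layout_tsv",
    "load_layout_tsv",
]

#: The 20 outer-edge electrodes considered as stimulation candidates.
OUTER_EDGE_LABELS = (
    "Fp1", "Fp2", "F7", "F8", "FT9", "FT10", "FTT9h", "FTT10h", "T7", "T8",
    "TTP7h", "TTP8h", "TP7", "TP8", "TPP9h", "TPP10h", "P9", "P10", "I1", "I2",
)

#: The fixed eight-electrode subset around the vertex.
CENTRAL_8_LABELS = ("Cz", "FCz", "CPz", "C1", "C2", "FFC1h", "Fz", "AFF1")


class LayoutError(ValueError):
    """Raised for invalid electrode layouts."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Labelled electrode positions (mm) with a reference electrode.

    ``labels`` lists the measurement electrodes; the reference (default
    ``"nasion"``) is included in ``labels`` as well and identified by
    ``reference_label``.
    """

    labels: tuple
    positions: np.ndarray  # (n, 3) mm
    reference_label: str = "nasion"

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if len(self.labels) != len(self.positions):
            raise LayoutError("labels and positions must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise LayoutError("labels must be unique")
        if self.reference_label not in self.labels:
            raise LayoutError(f"reference {self.reference_label!r} not in layout")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def measurement_labels(self) -> tuple:
        return tuple(l for l in self.labels if l != self.reference_label)

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.labels.index(label)]

    def subset(self, labels) -> "ElectrodeLayout":
        """Restrict to ``labels`` (reference appended automatically)."""
        wanted = list(labels)
        if self.reference_label not in wanted:
            wanted.append(self.reference_label)
        missing = [l for l in wanted if l not in self.labels]
        if missing:
            raise LayoutError(f"labels not in layout: {missing}")
        idx = [self.labels.index(l) for l in wanted]
        return replace(self, labels=tuple(wanted), positions=self.positions[idx])

    def with_positions(self, positions) -> "ElectrodeLayout":
        return replace(self, positions=np.asarray(positions, dtype=float))


def canonical_directions():
    """Packaged canonical 10/5 unit directions: (labels, (n, 3) array)."""
    ref = resources.files("lesioncond").joinpath("data/layout_1005.tsv")
    labels, dirs = [], []
    with ref.open() as fh:
        header = fh.readline()
        assert header.split() == ["label", "x", "y", "z"]
        for line in fh:
            lab, x, y, z = line.split("\t")
            labels.append(lab)
            dirs.append([float(x), float(y), float(z)])
    return tuple(labels), np.asarray(dirs)


def place_electrodes_10_5(
    scalp: TriangleSurface,
    canonical=None,
    head_center=None,
    reference_label: str = "nasion",
) -> ElectrodeLayout:
    """Project canonical unit directions radially onto the scalp surface.

    On sphere-derived scalps each electrode is placed exactly on the
    analytic sphere; otherwise a ray from the head center is intersected
    with the mesh.
    """
    if canonical is None:
        labels, dirs = canonical_directions()
    else:
        labels, dirs = canonical
        labels = tuple(labels)
        dirs = np.asarray(dirs, dtype=float)
    required = set(OUTER_EDGE_LABELS) | set(CENTRAL_8_LABELS) | {reference_label}
    missing = required - set(labels)
    if missing:
        raise LayoutError(f"canonical layout is missing labels: {sorted(missing)}")

    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    if scalp.sphere is not None:
        center = np.asarray(scalp.sphere[0]) if head_center is None else np.asarray(head_center, float)
        radius = scalp.sphere[1]
        positions = center + radius * dirs
    else:
        center = (
            np.asarray(head_center, float)
            if head_center is not None
            else scalp.vertices.mean(axis=0)
        )
        mesh = scalp.as_trimesh()
        locations, ray_idx, _ = mesh.ray.intersects_location(
            np.tile(center, (len(dirs), 1)), dirs, multiple_hits=False
        )
        if len(ray_idx) != len(dirs):
            raise LayoutError("some electrode rays did not intersect the scalp")
        positions = np.empty_like(dirs)
        positions[ray_idx] = locations
    return ElectrodeLayout(labels, positions, reference_label=reference_label)


def save_layout_tsv(layout: ElectrodeLayout, path) -> None:
    """Write ``label<TAB>x<TAB>y<TAB>z`` (mm)."""
    with open(Path(path), "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, p in zip(layout.labels, layout.positions):
            fh.write(f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def load_layout_tsv(path, reference_label: str = "nasion") -> ElectrodeLayout:
    labels, pos = [], []
    with open(Path(path)) as fh:
        header = fh.readline()
        if header.split() != ["label", "x", "y", "z"]:
            raise LayoutError("expected header 'label\\tx\\ty\\tz'")
        for line in fh:
            lab, x, y, z = line.rstrip("\n").split("\t")
            labels.append(lab)
            pos.append([float(x), float(y), float(z)])
    return ElectrodeLayout(tuple(labels), np.asarray(pos), reference_label=reference_label)
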