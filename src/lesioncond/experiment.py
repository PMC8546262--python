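"""Full simulation study: sweep lesions, conductivities, rotations, subsets.

``run_study`` reproduces the study structure: per lesion, build the head
with and without the lesion, select the optimal stimulation pair by
exhaustive RMSD search, then for every (true conductivity, rotation axis,
rotation angle, electrode subset) simulate "recorded" potentials at the
perturbed electrodes and re-estimate the lesion conductivity against the
nominal electrode positions.  One row of the result table corresponds to
one estimation run; zero-degree rotation is axis-independent and evaluated
once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import bem
from .electrodes import ElectrodeLayout, place_electrodes_10_5
from .estimation import (
    EstimationConfig,
    NotConvergedError,
    error_metrics,
    estimate_lesion_conductivity,
    simulate_recorded,
)
from .geometry import (
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_RADII_MM,
    HeadModel,
    LesionSpec,
    add_spherical_lesion,
    lesion_metrics,
    make_sphere_head,
    refine_near_points,
)
from .montage import find_optimal_pair
from .perturbation import RotationSpec, mean_displacement, rotate_layout, select_subset

logger = logging.getLogger("lesioncond")

__all__ = ["StudyConfig", "StudyResultTable", "run_study", "summarize", "DEFAULT_LESION_RADII_MM"]

#: Synthetic lesion battery spanning the clinical volume range
#: (~0.1, 12, 51, 85 ml).
DEFAULT_LESION_RADII_MM = (2.9, 14.2, 23.0, 27.3)

#: Fixed left-temporal lesion center (mm); as superficial as the largest
#: battery lesion permits while staying strictly inside the brain surface.
DEFAULT_LESION_CENTER_MM = (-49.5, 0.0, 0.0)


@dataclass(frozen=True)
class StudyConfig:
    head_radii_mm: tuple = DEFAULT_RADII_MM
    tissue_conductivities: tuple = DEFAULT_CONDUCTIVITIES
    elements_per_surface: int = 3200
    lesion_center_mm: tuple = DEFAULT_LESION_CENTER_MM
    lesion_radii_mm: tuple = DEFAULT_LESION_RADII_MM
    lesion_conductivities: tuple = (0.74, 1.23, 1.71)
    rotation_axes: tuple = ("coronal", "sagittal")
    rotation_angles_deg: tuple = (0.0, 0.1, 0.5, 1.0, 5.0)
    subset_sizes: tuple = (8, 16, 32, 64, 128)
    current_A: float = bem.DEFAULT_CURRENT_A
    refine_search_per_pair: bool = False
    refine_radius_mm: float = 25.0
    n_starts: int = 10
    initial_interval: tuple = (0.033, 2.0)
    convergence_tol: float = 1e-3
    max_iterations: int = 100
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def n_rows(self) -> int:
        nonzero = sum(1 for a in self.rotation_angles_deg if a != 0.0)
        has_zero = any(a == 0.0 for a in self.rotation_angles_deg)
        per_sigma = (1 if has_zero else 0) + len(self.rotation_axes) * nonzero
        return (
            len(self.lesion_radii_mm)
            * len(self.lesion_conductivities)
            * per_sigma
            * len(self.subset_sizes)
        )


@dataclass
class StudyResultTable:
    """Machine twin of the study figure: one row per estimation run."""

    table: pd.DataFrame
    config: StudyConfig

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {"seed": self.config.seed, "config_hash": self.config.config_hash(),
                "config": asdict(self.config)}


def _build_lesion_model(cfg: StudyConfig, radius_mm: float, sigma: float) -> HeadModel:
    head = make_sphere_head(
        cfg.head_radii_mm, cfg.tissue_conductivities, cfg.elements_per_surface
    )
    spec = LesionSpec(center=cfg.lesion_center_mm, radius=radius_mm, conductivity=sigma)
    return add_spherical_lesion(head, spec, elements=cfg.elements_per_surface)


def _refine_for_pair(model: HeadModel, layout: ElectrodeLayout, pair, radius_mm: float):
    pts = np.array([layout.position_of(l) for l in pair])
    surfs = list(model.surfaces)
    for i in (0, 1):
        surfs[i] = refine_near_points(surfs[i], pts, radius_mm)
    return replace(model, surfaces=tuple(surfs))


def run_study(config: StudyConfig) -> StudyResultTable:
    """Run the complete sweep; failures are recorded per row, not raised."""
    rows = []
    row_seed = 0
    for li, radius in enumerate(config.lesion_radii_mm):
        # one pair search per lesion model (geometry + modeled conductivity)
        for sigma_true in config.lesion_conductivities:
            model = _build_lesion_model(config, radius, sigma_true)
            metrics = lesion_metrics(model)
            layout = place_electrodes_10_5(model.scalp)
            logger.info("lesion %.1f mm, sigma %.2f: searching optimal pair", radius, sigma_true)
            score = find_optimal_pair(
                model,
                None,
                layout,
                current=config.current_A,
                refine_per_pair=config.refine_search_per_pair,
                refine_radius_mm=config.refine_radius_mm,
            )
            pair = tuple(score.optimal)
            model_r = _refine_for_pair(model, layout, pair, config.refine_radius_mm)
            system = bem.assemble_system(model_r)
            logger.info("  optimal pair %s, system N=%d", pair, system.n_unknowns)

            conditions = [("none", 0.0)] if 0.0 in config.rotation_angles_deg else []
            conditions += [
                (ax, ang)
                for ax in config.rotation_axes
                for ang in config.rotation_angles_deg
                if ang != 0.0
            ]
            for axis, angle in conditions:
                rotation = (
                    None if angle == 0.0 else RotationSpec(axis=axis, angle_deg=angle)
                )
                for subset in config.subset_sizes:
                    row = {
                        "lesion_id": li,
                        "lesion_radius_mm": radius,
                        "volume_ml": metrics.volume_ml,
                        "depth_mm": metrics.depth_mm,
                        "sigma_true": sigma_true,
                        "axis": axis,
                        "angle_deg": angle,
                        "subset_size": subset,
                        "anode": pair[0],
                        "cathode": pair[1],
                        "pair_rmsd_V": score.optimal_rmsd,
                    }
                    try:
                        sub = select_subset(layout, subset)
                        disp = (
                            0.0
                            if rotation is None
                            else mean_displacement(sub, rotate_layout(sub, rotation))
                        )
                        psi = simulate_recorded(
                            model_r, pair, layout,
                            subset_size=subset, rotation=rotation,
                            current=config.current_A, system=system,
                        )
                        est_cfg = EstimationConfig(
                            n_starts=config.n_starts,
                            initial_interval=config.initial_interval,
                            convergence_tol=config.convergence_tol,
                            max_iterations=config.max_iterations,
                            seed=(config.seed * 100003 + row_seed) % (2**31),
                        )
                        result = estimate_lesion_conductivity(
                            psi, model_r, pair, layout, est_cfg,
                            current=config.current_A, system=system,
                        )
                        row["mean_displacement_mm"] = disp
                        row["converged"] = result.any_converged
                        if result.any_converged:
                            em = error_metrics(result, sigma_true)
                            row.update(
                                sigma_hat=result.sigma_hat,
                                abs_error=em.absolute_S_per_m,
                                rel_error=em.relative,
                            )
                        else:
                            row.update(sigma_hat=np.nan, abs_error=np.nan, rel_error=np.nan)
                        row["status"] = "ok"
                    except NotConvergedError:
                        row.update(
                            converged=False, sigma_hat=np.nan,
                            abs_error=np.nan, rel_error=np.nan, status="not_converged",
                        )
                    except Exception as exc:  # record and continue
                        logger.warning("row failed: %s", exc)
                        row.update(
                            converged=False, sigma_hat=np.nan,
                            abs_error=np.nan, rel_error=np.nan,
                            status=f"error: {exc}",
                        )
                    row_seed += 1
                    rows.append(row)
    table = pd.DataFrame(rows)
    return StudyResultTable(table=table, config=config)


def summarize(table, group_by=("sigma_true", "axis", "angle_deg")) -> pd.DataFrame:
    """Mean +/- sample sd of the errors per group over converged rows.

    Non-converged rows are excluded from the means and counted in
    ``n_nonconverged`` (mirroring runs marked as failed in the study).
    """
    df = table.table if isinstance(table, StudyResultTable) else table
    if len(df) == 0:
        raise ValueError("empty result table")
    group_by = list(group_by)

    def agg(g):
        conv = g[g.converged.astype(bool)]
        sd = lambda x: 0.0 if len(x) <= 1 else float(np.std(x, ddof=1))
        return pd.Series({
            "n": len(g),
            "n_nonconverged": int((~g.converged.astype(bool)).sum()),
            "abs_error_mean": float(conv.abs_error.mean()) if len(conv) else np.nan,
            "abs_error_sd": sd(conv.abs_error) if len(conv) else np.nan,
            "rel_error_mean": float(conv.rel_error.mean()) if len(conv) else np.nan,
            "rel_error_sd": sd(conv.rel_error) if len(conv) else np.nan,
        })

    out = df.groupby(group_by, dropna=False).apply(agg, include_groups=False).reset_index()
    if out.empty:
        raise ValueError("no groups formed")
    return out
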