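"""Conductivity estimation: recovery, oracle agreement, metrics, determinism."""

import numpy as np
import pytest

from lesioncond.estimation import (
    EstimationConfig,
    EstimationResult,
    NotConvergedError,
    error_metrics,
    estimate_lesion_conductivity,
    grid_search_conductivity,
    simulate_recorded,
)
from lesioncond.perturbation import RotationSpec


class TestSimulateRecorded:
    def test_zero_rotation_full_subset_equals_plain_recording(
        self, refined_lesioned, coarse_layout
    ):
        from lesioncond.bem import record_at_electrodes, stimulation_sources

        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, subset_size=128, system=system)
        src = stimulation_sources(model, coarse_layout, pair)
        plain = record_at_electrodes(system.solve(src), coarse_layout, exclude=pair)
        assert set(psi.labels) == set(plain.labels)
        assert np.allclose(psi.values_for(plain.labels), plain.potentials)
        assert psi.provenance == "recorded"

    def test_small_rotation_changes_recording(self, refined_lesioned, coarse_layout):
        model, pair, system = refined_lesioned
        a = simulate_recorded(model, pair, coarse_layout, 64, system=system)
        b = simulate_recorded(
            model, pair, coarse_layout, 64,
            rotation=RotationSpec("coronal", 0.1), system=system,
        )
        assert not np.allclose(a.potentials, b.values_for(a.labels))

    def test_linearity_in_current(self, refined_lesioned, coarse_layout):
        model, pair, system = refined_lesioned
        a = simulate_recorded(model, pair, coarse_layout, 64, system=system, current=1e-4)
        b = simulate_recorded(model, pair, coarse_layout, 64, system=system, current=2e-4)
        assert np.allclose(b.values_for(a.labels), 2 * a.potentials, rtol=1e-9)


class TestEstimate:
    def test_recovers_true_conductivity_without_rotation(
        self, refined_lesioned, coarse_layout, est_config
    ):
        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, 64, system=system)
        result = estimate_lesion_conductivity(
            psi, model, pair, coarse_layout, est_config, system=system
        )
        em = error_metrics(result, 1.23)
        assert em.relative < 0.01
        assert result.converged.all()

    def test_zero_contrast_self_consistency(self, refined_lesioned, coarse_layout, est_config):
        """psi generated at sigma_lesion = sigma_brain: the estimator must
        come back to 0.37 within 2%."""
        model, pair, system = refined_lesioned
        psi = simulate_recorded(
            model, pair, coarse_layout, 64, system=system, sigma_lesion=0.37
        )
        result = estimate_lesion_conductivity(
            psi, model, pair, coarse_layout, est_config, system=system
        )
        assert result.sigma_hat == pytest.approx(0.37, rel=0.02)

    def test_agrees_with_grid_search_oracle(self, refined_lesioned, coarse_layout, est_config):
        model, pair, system = refined_lesioned
        psi = simulate_recorded(
            model, pair, coarse_layout, 64, system=system,
            rotation=RotationSpec("sagittal", 0.1),
        )
        result = estimate_lesion_conductivity(
            psi, model, pair, coarse_layout, est_config, system=system
        )
        _, _, grid_best = grid_search_conductivity(
            psi, model, pair, coarse_layout, system=system
        )
        assert abs(result.sigma_hat - grid_best) / grid_best < 0.005

    def test_residual_unimodal_with_minimum_at_truth(
        self, refined_lesioned, coarse_layout
    ):
        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, 64, system=system)
        grid, res, best = grid_search_conductivity(
            psi, model, pair, coarse_layout,
            grid=np.arange(0.2, 2.0, 0.02), system=system,
        )
        assert best == pytest.approx(1.23, abs=0.02)
        # unimodal: residual decreases to the minimum then increases
        k = int(np.argmin(res))
        assert np.all(np.diff(res[: k + 1]) < 0)
        assert np.all(np.diff(res[k:]) > 0)

    def test_deterministic_given_seed(self, refined_lesioned, coarse_layout):
        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, 32, system=system)
        cfg = EstimationConfig(seed=123)
        r1 = estimate_lesion_conductivity(psi, model, pair, coarse_layout, cfg, system=system)
        r2 = estimate_lesion_conductivity(psi, model, pair, coarse_layout, cfg, system=system)
        assert r1.sigma_hat == r2.sigma_hat
        for a, b in zip(r1.traces, r2.traces):
            assert np.array_equal(a, b)

    def test_stopping_rule_inter_iterate_change(self, refined_lesioned, coarse_layout, est_config):
        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, 64, system=system)
        result = estimate_lesion_conductivity(
            psi, model, pair, coarse_layout, est_config, system=system
        )
        for trace, conv in zip(result.traces, result.converged):
            if conv:
                rel = abs(trace[-1] - trace[-2]) / trace[-2]
                assert rel <= est_config.convergence_tol

    def test_json_roundtrip(self, refined_lesioned, coarse_layout, est_config, tmp_path):
        import json

        model, pair, system = refined_lesioned
        psi = simulate_recorded(model, pair, coarse_layout, 8, system=system)
        result = estimate_lesion_conductivity(
            psi, model, pair, coarse_layout, est_config, system=system
        )
        path = tmp_path / "result.json"
        result.to_json(path)
        back = json.loads(path.read_text())
        assert back["sigma_hat"] == pytest.approx(result.sigma_hat)
        assert back["seed"] == est_config.seed


class TestErrorMetrics:
    def _result(self, sigma, converged=True):
        return EstimationResult(
            traces=[np.array([0.5, sigma])],
            residuals=np.array([1e-12]),
            converged=np.array([converged]),
            iterations=np.array([1]),
            initial_values=np.array([0.5]),
            seed=0,
            best_start=0 if converged else None,
        )

    def test_exact_estimate(self):
        em = error_metrics(self._result(0.74), 0.74)
        assert em.absolute_S_per_m == 0.0 and em.relative == 0.0

    def test_absolute_error_scale(self):
        em = error_metrics(self._result(0.86), 0.74)
        assert em.absolute_S_per_m == pytest.approx(0.12)

    def test_relative_error_doubling(self):
        em = error_metrics(self._result(1.48), 0.74)
        assert em.relative == pytest.approx(1.0)

    def test_non_converged_raises(self):
        with pytest.raises(NotConvergedError):
            error_metrics(self._result(1.0, converged=False), 1.0)
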