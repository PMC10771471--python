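"""Integrated gradients, trajectories, segmentation, and SDG calling."""

import numpy as np
import pytest
from scipy.integrate import quad

from stemst import (
    SpatialCoords,
    attribution_profile,
    fit_trajectory,
    identify_sdgs,
    integrated_gradients,
    segment_cells,
)
from stemst.attribution import SpatialTrajectory


class TestIntegratedGradients:
    def test_linear_model_exact_for_any_steps(self, rng):
        w = rng.normal(size=6)
        x = rng.normal(size=6)
        f = lambda v: float(w @ v)
        grad = lambda v: w
        for steps in (1, 3, 50):
            assert np.allclose(integrated_gradients(x, f, grad, steps), x * w)

    def test_zero_input_zero_attribution(self, rng):
        w = rng.normal(size=4)
        out = integrated_gradients(np.zeros(4), lambda v: float(w @ v), lambda v: w)
        assert np.array_equal(out, np.zeros(4))

    def test_completeness_on_smooth_nonlinear_function(self, rng):
        # f(x) = sigmoid(w.x): completeness gap shrinks with steps
        w = rng.normal(size=5)
        x = rng.normal(size=5) * 2
        sig = lambda t: 1.0 / (1.0 + np.exp(-t))
        f = lambda v: float(sig(w @ v))
        grad = lambda v: sig(w @ v) * (1 - sig(w @ v)) * w
        target = f(x) - f(np.zeros(5))
        gaps = [
            abs(integrated_gradients(x, f, grad, s).sum() - target)
            for s in (8, 32, 256)
        ]
        assert gaps[2] < gaps[0]
        assert gaps[2] < 1e-4

    def test_quadrature_oracle_on_toy_model(self, rng):
        # path integral computed by adaptive quadrature per gene
        w = rng.normal(size=5)
        u = rng.normal(size=5)
        x = rng.normal(size=5)
        f = lambda v: float(np.tanh(w @ v) + 0.5 * (u @ v) ** 2)
        grad = lambda v: (1 - np.tanh(w @ v) ** 2) * w + (u @ v) * u
        ig = integrated_gradients(x, f, grad, steps=400)
        for j in range(5):
            oracle = x[j] * quad(lambda a: grad(a * x)[j], 0, 1)[0]
            assert ig[j] == pytest.approx(oracle, abs=1e-3)

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            integrated_gradients(np.zeros(2), lambda v: 0.0, lambda v: np.zeros(2), 0)


class TestAttributionProfile:
    def test_identical_cells_identical_rows(self, trained_toy):
        _, _, sc_norm, result = trained_toy
        from stemst import ExpressionMatrix

        dup = ExpressionMatrix(
            np.vstack([sc_norm.values[:1], sc_norm.values[:1]]),
            sc_norm.gene_ids,
            ["c0", "c1"],
            "lognorm",
        )
        prof = attribution_profile(dup, result.encoder, result.z_st, steps=16)
        assert np.allclose(prof.scores[0], prof.scores[1])

    def test_absent_gene_zero_attribution(self, trained_toy):
        _, _, sc_norm, result = trained_toy
        from stemst import ExpressionMatrix

        values = sc_norm.values[:5].copy()
        values[:, 2] = 0.0
        x = ExpressionMatrix(values, sc_norm.gene_ids,
                             [f"c{i}" for i in range(5)], "lognorm")
        prof = attribution_profile(x, result.encoder, result.z_st, steps=16)
        assert np.allclose(prof.scores[:, 2], 0.0)

    def test_completeness_gap_small_on_trained_model(self, trained_toy):
        _, _, sc_norm, result = trained_toy
        from stemst import ExpressionMatrix

        x = ExpressionMatrix(sc_norm.values[:10], sc_norm.gene_ids,
                             [f"c{i}" for i in range(10)], "lognorm")
        prof = attribution_profile(x, result.encoder, result.z_st, steps=256)
        z, _ = result.encoder.forward(x.values)
        from stemst.model import _row_softmax

        c = _row_softmax(z @ result.z_st.vectors.T)
        f_x = c[np.arange(10), prof.target_spot]
        z0, _ = result.encoder.forward(np.zeros_like(x.values))
        c0 = _row_softmax(z0 @ result.z_st.vectors.T)
        f_0 = c0[np.arange(10), prof.target_spot]
        rel = prof.convergence_gap / np.maximum(np.abs(f_x - f_0), 1e-12)
        assert np.median(rel) < 0.01


class TestTrajectory:
    def test_line_pseudotime_equals_distance_from_start(self):
        x = np.linspace(0, 10, 12)
        coords = np.column_stack([x, 2 * x + 1])
        traj = fit_trajectory(coords, degree=1)
        start = traj.start_cell
        assert traj.pseudotime[start] == 0.0
        expected = np.linalg.norm(coords - coords[start], axis=1)
        assert np.allclose(traj.pseudotime, expected, atol=1e-6)

    def test_degree_five_interpolates_six_points(self, rng):
        x = np.arange(6, dtype=float)
        y = rng.normal(size=6)
        traj = fit_trajectory(np.column_stack([x, y]), degree=5)
        assert traj.residual == pytest.approx(0.0, abs=1e-12)

    def test_parabola_arc_length_matches_quadrature(self):
        x = np.linspace(0, 1, 40)
        coords = np.column_stack([x, x**2])
        traj = fit_trajectory(coords, degree=2)
        start_at_zero = np.argmin(x)
        oracle = quad(lambda t: np.sqrt(1 + 4 * t**2), 0, 1)[0]
        assert oracle == pytest.approx(1.4789, abs=1e-4)
        # pseudotime measured from the top-right start; the leftmost cell is
        # a full arc length away
        assert traj.pseudotime[start_at_zero] == pytest.approx(oracle, abs=1e-4)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="degree"):
            fit_trajectory(np.array([[0.0, 0.0], [1.0, 1.0]]), degree=5)

    def test_vertical_cloud_rejected(self):
        coords = np.column_stack([np.zeros(10), np.arange(10.0)])
        with pytest.raises(ValueError):
            fit_trajectory(coords, degree=2)


class TestSegmentation:
    def _traj(self, t):
        return SpatialTrajectory(np.zeros(2), 0, np.asarray(t, dtype=float), 0.0)

    def test_equal_width_bins(self):
        seg = segment_cells(self._traj([0.0, 0.49, 0.51, 1.0]), n_segments=2)
        assert list(seg) == [0, 0, 1, 1]

    def test_default_eleven_segments_partition(self, rng):
        t = rng.uniform(0, 5, size=300)
        seg = segment_cells(self._traj(t), n_segments=11)
        assert set(seg) == set(range(11))

    def test_degenerate_constant_pseudotime(self):
        with pytest.warns(UserWarning):
            seg = segment_cells(self._traj(np.ones(5)), n_segments=3)
        assert (seg == 0).all()

    def test_equal_count_option(self, rng):
        t = rng.exponential(1.0, size=200)
        seg = segment_cells(self._traj(t), n_segments=4, method="count")
        counts = np.bincount(seg)
        assert counts.max() - counts.min() <= 1


class TestSDGs:
    def test_complete_separation_gene_called(self, rng):
        n_per, n_genes = 25, 10
        segments = np.repeat([0, 1, 2], n_per)
        scores = rng.normal(size=(3 * n_per, n_genes))
        scores[segments == 1, 4] += 10.0  # complete separation in segment 1
        hits = identify_sdgs(scores, segments, fdr=0.05)
        assert ((hits["gene"] == "gene_4") & (hits["segment"] == 1)).any()

    def test_constant_attribution_never_significant(self):
        scores = np.ones((60, 5))
        segments = np.repeat([0, 1, 2], 20)
        hits = identify_sdgs(scores, segments, fdr=0.05)
        assert hits.empty

    def test_zero_fdr_empty(self, rng):
        scores = rng.normal(size=(40, 6))
        scores[:20, 0] += 5
        hits = identify_sdgs(scores, np.repeat([0, 1], 20), fdr=0.0)
        assert hits.empty

    def test_tiny_segment_excluded_with_warning(self, rng):
        scores = rng.normal(size=(41, 3))
        segments = np.array([0] * 20 + [1] * 20 + [2])
        with pytest.warns(UserWarning, match="segment 2"):
            hits = identify_sdgs(scores, segments, fdr=0.05)
        assert not (hits["segment"] == 2).any() if not hits.empty else True

    def test_permutation_calibration_false_positive_rate(self):
        # with segment labels shuffled, BH at level q should yield about
        # q * tests false positives on null data
        total_tests = 0
        total_hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            scores = g.normal(size=(90, 30))
            segments = g.permutation(np.repeat([0, 1, 2], 30))
            hits = identify_sdgs(scores, segments, fdr=0.05)
            total_hits += len(hits)
            total_tests += 3 * 30
        assert total_hits / total_tests <= 0.07
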