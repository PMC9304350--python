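"""Integrated gradients, smoothgrad, overlap assembly and top-k selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynamilc import (
    TimecourseRecord,
    assemble_subject_saliency,
    completeness_gap,
    integrated_gradients,
    random_importance,
    saliency_map,
    select_top_fraction,
    smoothgrad_ig,
)
from dynamilc.attribution import _ig_core


class TestIGCoreClosedForms:
    """The path integral against analytically differentiable surrogates."""

    def test_linear_model_recovers_w_times_x(self, rng):
        w = rng.standard_normal((3, 7))
        x = rng.standard_normal((3, 7))

        def grad_fn(pts):  # F(x) = sum(w * x): gradient is w everywhere
            return np.broadcast_to(w, pts.shape)

        attr = _ig_core(grad_fn, x, np.zeros_like(x), steps=16)
        np.testing.assert_allclose(attr, w * x, rtol=1e-6)

    def test_input_equal_to_baseline_gives_zero(self, rng):
        x = rng.standard_normal((2, 5))

        def grad_fn(pts):
            return np.ones_like(pts)

        attr = _ig_core(grad_fn, x, x.copy(), steps=16)
        np.testing.assert_array_equal(attr, 0.0)

    def test_quadratic_model_right_riemann_error_shrinks(self):
        # F(x) = x^2 / 2 with baseline 0: exact IG is x^2/2 per cell
        x = np.array([[2.0]])

        def grad_fn(pts):
            return pts

        errs = []
        for steps in [16, 64, 256]:
            attr = _ig_core(grad_fn, x, np.zeros_like(x), steps=steps)
            errs.append(abs(attr[0, 0] - 2.0))
        assert errs[0] > errs[1] > errs[2]

    def test_non_finite_gradient_raises(self):
        def grad_fn(pts):
            g = np.ones_like(pts)
            g[0] = np.nan
            return g

        with pytest.raises(FloatingPointError):
            _ig_core(grad_fn, np.ones((2, 2)), np.zeros((2, 2)), steps=16)


class TestModelIG:
    def test_step_floor_enforced(self, small_model, record):
        rec = TimecourseRecord("s", np.random.default_rng(0).standard_normal((8, 30)))
        with pytest.raises(ValueError):
            integrated_gradients(small_model, rec, steps=8)

    def test_completeness_gap_small_and_shrinking(self, small_model, rng):
        rec = TimecourseRecord("s", rng.standard_normal((8, 30)), label=1)
        gaps = []
        for steps in [16, 64, 256]:
            wa = integrated_gradients(small_model, rec, steps=steps)
            gaps.append(completeness_gap(small_model, rec, wa)["relative_gap"])
        assert gaps[-1] < 0.02
        assert gaps[0] >= gaps[-1]

    def test_smoothgrad_zero_noise_equals_plain_ig(self, small_model, rng):
        rec = TimecourseRecord("s", rng.standard_normal((8, 30)), label=0)
        ig = integrated_gradients(small_model, rec, steps=16)
        sg = smoothgrad_ig(small_model, rec, noise_sd=0.0, n_samples=5, steps=16)
        np.testing.assert_array_equal(ig.values, sg.values)
        assert sg.method == "SGIG"

    def test_smoothgrad_seeded_reproducibility(self, small_model, rng):
        rec = TimecourseRecord("s", rng.standard_normal((8, 30)))
        a = smoothgrad_ig(small_model, rec, noise_sd=0.05, n_samples=2, steps=16, seed=9)
        b = smoothgrad_ig(small_model, rec, noise_sd=0.05, n_samples=2, steps=16, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_smoothgrad_small_noise_tracks_ig(self, small_model, rng):
        rec = TimecourseRecord("s", rng.standard_normal((8, 30)))
        ig = integrated_gradients(small_model, rec, steps=16)
        sg = smoothgrad_ig(small_model, rec, noise_sd=0.01, n_samples=8, steps=16, seed=0)
        corr = np.corrcoef(ig.values.ravel(), sg.values.ravel())[0, 1]
        assert corr > 0.95

    def test_saliency_map_matches_record_shape(self, small_model, rng):
        rec = TimecourseRecord("s", rng.standard_normal((8, 31)))
        sal = saliency_map(small_model, rec, method="ig", steps=16)
        assert sal.values.shape == rec.data.shape
        assert sal.method == "IG"
        assert sal.predicted_class in (0, 1)


class TestAssembly:
    def test_disjoint_windows_pass_through(self, rng):
        wa = rng.standard_normal((3, 4, 10))
        sal = assemble_subject_saliency(wa, np.array([0, 10, 20]), 30)
        np.testing.assert_array_equal(sal.values, np.concatenate(list(wa), axis=1))

    def test_two_overlapping_windows_average(self, rng):
        wa = rng.standard_normal((2, 3, 20))
        sal = assemble_subject_saliency(wa, np.array([0, 10]), 30)
        # cell t=15 is covered by window 0 (offset 15) and window 1 (offset 5)
        expected = (wa[0, :, 15] + wa[1, :, 5]) / 2
        np.testing.assert_allclose(sal.values[:, 15], expected)

    def test_uncovered_tail_zeroed_and_flagged(self, rng):
        wa = rng.standard_normal((1, 2, 5))
        sal = assemble_subject_saliency(wa, np.array([0]), 9)
        np.testing.assert_array_equal(sal.values[:, 5:], 0.0)
        assert np.all(sal.coverage[5:] == 0)

    def test_coverage_counts_match_brute_force(self, rng):
        T, L, stride = 140, 20, 1
        starts = np.arange(0, T - L + 1, stride)
        wa = rng.standard_normal((len(starts), 3, L))
        sal = assemble_subject_saliency(wa, starts, T)
        brute = np.array([sum(s <= t < s + L for s in starts) for t in range(T)])
        np.testing.assert_array_equal(sal.coverage, brute)

    def test_disjoint_assembly_conserves_total(self, rng):
        wa = rng.standard_normal((4, 3, 5))
        sal = assemble_subject_saliency(wa, np.array([0, 5, 10, 15]), 20)
        assert sal.values.sum() == pytest.approx(wa.sum(), rel=1e-10)


class TestRandomImportance:
    def test_seeded_determinism_and_bijection(self):
        a = random_importance((3, 4), seed=5)
        b = random_importance((3, 4), seed=5)
        np.testing.assert_array_equal(a.permutation, b.permutation)
        assert sorted(a.permutation) == list(range(12))

    def test_rank_one_frequencies_are_uniform(self):
        counts = np.zeros(12)
        n = 10_000
        for s in range(n):
            counts[random_importance((3, 4), seed=s).permutation[0]] += 1
        freq = counts / n
        se = np.sqrt((1 / 12) * (11 / 12) / n)
        assert np.all(np.abs(freq - 1 / 12) < 4 * se)


class TestSelectTopFraction:
    def test_full_fraction_retains_everything(self, rng):
        mask = select_top_fraction(rng.standard_normal((6, 7)), p=1.0)
        assert mask.mask.all()

    def test_distinct_values_pick_the_largest(self, rng):
        vals = rng.permutation(100).reshape(10, 10).astype(float)
        mask = select_top_fraction(vals, p=0.05)
        assert mask.mask.sum() == 5
        assert set(vals[mask.mask]) == {95.0, 96.0, 97.0, 98.0, 99.0}

    def test_signed_ranking_never_prefers_negative_over_positive(self):
        vals = np.array([[-100.0, 1.0], [2.0, -50.0]])
        mask = select_top_fraction(vals, p=0.5)
        assert vals[mask.mask].min() > 0

    def test_all_tied_uses_component_then_time_order(self):
        mask = select_top_fraction(np.zeros((4, 5)), p=0.25)  # round(5)=5 cells
        expected = np.zeros((4, 5), dtype=bool)
        expected[0, :] = True  # first component row fills first
        np.testing.assert_array_equal(mask.mask, expected)

    def test_random_estimator_mask_uses_permutation_order(self):
        est = random_importance((3, 4), seed=0)
        mask = select_top_fraction(est, p=0.25)  # 3 cells
        expected = np.zeros(12, dtype=bool)
        expected[est.permutation[:3]] = True
        np.testing.assert_array_equal(mask.mask.reshape(-1), expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(2, 12),
           st.floats(0.01, 1.0, allow_nan=False), st.integers(0, 10**6))
    def test_cardinality_always_exact(self, C, T, p, seed):
        vals = np.random.default_rng(seed).standard_normal((C, T))
        mask = select_top_fraction(vals, p=p)
        assert mask.mask.sum() == int(round(p * C * T))

    def test_out_of_range_fraction_errors(self, rng):
        with pytest.raises(ValueError):
            select_top_fraction(rng.standard_normal((3, 3)), p=0.0)
        with pytest.raises(ValueError):
            select_top_fraction(rng.standard_normal((3, 3)), p=1.2)
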