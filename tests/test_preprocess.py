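"""Preprocessing: M/beta transforms, background, color bias, quantile
normalization, and the composed pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from bloodmeth.datamodel import DataValidationError, MethylationDataset, SampleSheet
from bloodmeth.preprocess import (
    PreprocessConfig,
    adjust_color_bias,
    beta_to_m,
    compute_m,
    m_to_beta,
    preprocess_pipeline,
    quantile_normalize,
    subtract_background,
)
from bloodmeth import synthetic


class TestMValue:
    def test_balanced_intensities_give_m_zero_half_methylated(self):
        assert compute_m(1000.0, 1000.0, 1e-9) == pytest.approx(0.0)
        assert m_to_beta(0.0) == pytest.approx(0.5)

    def test_known_ratios(self):
        assert compute_m(4000.0, 1000.0, 1e-9) == pytest.approx(2.0, abs=1e-8)
        assert compute_m(0.0, 0.0, 1.0) == 0.0
        assert m_to_beta(1.0) == pytest.approx(2.0 / 3.0)
        m, clamped = beta_to_m(0.9)
        assert m == pytest.approx(np.log2(9.0)) and not clamped

    @given(st.floats(min_value=1e-4, max_value=1 - 1e-4))
    @settings(derandomize=True, max_examples=200)
    def test_beta_m_round_trip(self, beta):
        # identity holds wherever |M| stays inside the +-15 clamp bound
        m, clamped = beta_to_m(beta)
        assert not clamped
        assert abs(m_to_beta(m) - beta) < 1e-12

    def test_beta_at_bounds_clamps_and_flags(self):
        with pytest.warns(UserWarning, match="clamped"):
            m, clamped = beta_to_m(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_array_equal(clamped, [True, False, True])
        np.testing.assert_array_equal(m, [-15.0, 0.0, 15.0])

    @given(
        st.floats(min_value=0, max_value=1e5),
        st.floats(min_value=0, max_value=1e5),
        st.floats(min_value=0.1, max_value=1e4),
    )
    @settings(derandomize=True, max_examples=100)
    def test_m_monotone_in_both_channels(self, meth, unmeth, delta):
        m0 = compute_m(meth, unmeth, 1.0)
        assert compute_m(meth + delta, unmeth, 1.0) > m0
        assert compute_m(meth, unmeth + delta, 1.0) < m0


def _dataset(meth, unmeth, channel=None):
    meth = np.asarray(meth, dtype=float)
    n, k = meth.shape
    sheet = SampleSheet(
        tuple(f"s{j}" for j in range(k)), tuple(f"d{j}" for j in range(k)), tuple("CD4T" for _ in range(k))
    )
    return MethylationDataset(
        np.array([f"cg{i}" for i in range(n)], dtype=object),
        meth,
        np.asarray(unmeth, dtype=float),
        np.array(channel if channel is not None else ["Both"] * n, dtype=object),
        sheet,
    )


class TestBackground:
    def test_constant_column_collapses_to_floor(self):
        ds = _dataset(np.full((10, 1), 100.0), np.full((10, 1), 100.0))
        out = subtract_background(ds, 0.05)
        assert (out.meth == 1.0).all() and (out.unmeth == 1.0).all()

    def test_shift_matches_quantile_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(-1, 1)
        ds = _dataset(vals, vals.copy())
        out = subtract_background(ds, 0.05)
        expected = np.clip(vals - np.quantile(vals, 0.05), 1.0, None)
        np.testing.assert_allclose(out.meth, expected)
        assert out.meth.min() == 1.0

    def test_zero_quantile_only_applies_floor(self):
        vals = np.array([[0.5, 10.0], [3.0, 20.0]])
        ds = _dataset(vals, vals.copy())
        out = subtract_background(ds, 0.0)
        np.testing.assert_allclose(out.meth, np.clip(vals, 1.0, None))


class TestColorBias:
    def test_identical_distributions_unchanged(self, rng):
        base = rng.gamma(4, 100, size=20)
        meth = np.concatenate([base, base]).reshape(-1, 1)
        ds = _dataset(meth, meth.copy(), channel=["Grn"] * 20 + ["Red"] * 20)
        out = adjust_color_bias(ds, "Grn")
        np.testing.assert_allclose(out.meth, ds.meth, rtol=1e-9)

    def test_doubled_red_mapped_onto_grn(self, rng):
        grn = np.sort(rng.gamma(4, 100, size=10))
        meth = np.concatenate([grn, 2 * grn]).reshape(-1, 1)
        ds = _dataset(meth, meth.copy(), channel=["Grn"] * 10 + ["Red"] * 10)
        out = adjust_color_bias(ds, "Grn")
        np.testing.assert_allclose(out.meth[10:, 0], grn, rtol=1e-6)
        np.testing.assert_allclose(out.meth[:10, 0], grn, rtol=1e-12)

    def test_midpoint_reference_averages_order_statistics(self):
        meth = np.array([1.0, 2, 3, 3, 4, 5]).reshape(-1, 1)
        ds = _dataset(meth, meth.copy(), channel=["Grn"] * 3 + ["Red"] * 3)
        out = adjust_color_bias(ds, "midpoint")
        np.testing.assert_allclose(out.meth[:3, 0], [2, 3, 4], rtol=1e-9)
        np.testing.assert_allclose(out.meth[3:, 0], [2, 3, 4], rtol=1e-9)

    def test_channel_with_too_few_probes_skipped(self):
        meth = np.array([[1.0], [2.0], [3.0]])
        ds = _dataset(meth, meth.copy(), channel=["Grn", "Grn", "Red"])
        with pytest.warns(UserWarning, match="skipped"):
            out = adjust_color_bias(ds, "Grn")
        np.testing.assert_array_equal(out.meth, ds.meth)


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        x = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(x)
        np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        np.testing.assert_array_equal(quantile_normalize(x), x)

    def test_sorted_columns_identical_and_ranks_preserved(self, rng):
        x = rng.gamma(2, 50, size=(100, 5))
        out = quantile_normalize(x)
        ref = np.sort(out[:, 0])
        for j in range(5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)
            rho = spearmanr(x[:, j], out[:, j]).statistic
            assert rho == pytest.approx(1.0)

    def test_single_sample_identity_with_warning(self):
        x = np.array([[5.0], [1.0]])
        with pytest.warns(UserWarning, match="single sample"):
            np.testing.assert_array_equal(quantile_normalize(x), x)


class TestPipeline:
    def test_noise_free_identical_samples_match_direct_m(self):
        truth = synthetic.make_truth(
            synthetic.GeneratorConfig(
                **{**synthetic.TINY_CONFIG, "donor_sigma": 0.0, "noise_sigma": 0.0,
                   "background": 0.0, "channel_bias": 1.0}
            ),
            seed=3,
        )
        ds = synthetic.simulate_samples(truth, seed=4)
        cfg = PreprocessConfig(do_background=False, do_color=False, do_quantile=False)
        m = preprocess_pipeline(ds, cfg)
        direct = compute_m(ds.meth, ds.unmeth, cfg.m_offset)
        np.testing.assert_allclose(m.values, direct, atol=1e-12)

    def test_single_sample_scaling_is_removed(self):
        # one sample's intensities scaled by a constant: after the rank-based
        # pipeline the effect is bounded by the target-distribution shift,
        # (c-1)/N relative, further damped by the log-ratio
        truth = synthetic.make_truth(
            synthetic.GeneratorConfig(**{**synthetic.TINY_CONFIG, "background": 0.0}), seed=5
        )
        ds = synthetic.simulate_samples(truth, seed=6)
        scaled = ds.copy()
        scaled.meth[:, 3] *= 2.0
        scaled.unmeth[:, 3] *= 2.0
        cfg = PreprocessConfig(background_quantile=0.0)
        m0 = preprocess_pipeline(ds, cfg)
        m1 = preprocess_pipeline(scaled, cfg)
        # the scaled column moves the shared mean-of-order-statistics target
        # by at most (c-1)/N times its own share of each rank
        n_samples = ds.n_samples
        stacked = np.vstack([ds.meth, ds.unmeth])
        target = np.sort(stacked, axis=0).mean(axis=1)
        share = np.sort(stacked[:, 3]) / np.maximum(target, 1e-12)
        bound = np.log2(1 + (2.0 - 1) * share.max() / n_samples) * 2
        assert np.abs(m1.values - m0.values).max() < bound
        assert bound < 0.25  # far below the log2(2)=1 scaling it removed

    def test_empty_probe_set_rejected(self):
        sheet = SampleSheet(("s0",), ("d0",), ("CD4T",))
        ds = MethylationDataset(
            np.array([], dtype=object), np.empty((0, 1)), np.empty((0, 1)),
            np.array([], dtype=object), sheet,
        )
        with pytest.raises(DataValidationError, match="empty"):
            preprocess_pipeline(ds)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(m_offset=0.0)
        with pytest.raises(ValueError):
            PreprocessConfig(background_quantile=0.6)
        with pytest.raises(ValueError):
            PreprocessConfig(color_reference="Blue")
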