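"""Connectivity core: taper, windowing, weighted correlation, dFC measures.

Oracle tests compare the vectorized implementations against independent
double-loop reference implementations frozen here.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfcpipe.connectivity import (
    SubnetworkSpec,
    WindowSpec,
    dfc_coefficient_of_variation,
    dfc_summed_difference,
    global_mean,
    static_fc,
    subnetwork_value,
    tapered_window_weights,
    weighted_correlation,
    window_start_indices,
    windowed_fc,
)
from dfcpipe.core import RegionTimeSeries
from dfcpipe.synthetic import simulate_stationary_series


def _ts(values, tr=2.2):
    values = np.asarray(values, dtype=float)
    return RegionTimeSeries(
        values=values, tr=tr, region_labels=[f"r{i}" for i in range(values.shape[0])]
    )


# ---------------------------------------------------------------- oracles


def loop_taper(length, sd):
    """Independent double-loop rectangular-window x Gaussian convolution."""
    radius = int(np.ceil(3 * sd))
    kernel = [np.exp(-0.5 * (k / sd) ** 2) for k in range(-radius, radius + 1)]
    ksum = sum(kernel)
    kernel = [k / ksum for k in kernel]
    out = []
    for i in range(length):  # full convolution evaluated at in-window points
        acc = 0.0
        for j in range(length):
            k = i - j + radius
            if 0 <= k < len(kernel):
                acc += kernel[k]
        out.append(acc)
    total = sum(out)
    return np.array([v / total for v in out])


def loop_weighted_corr(segment, weights):
    """Sum-loop weighted Pearson correlation."""
    w = np.asarray(weights) / np.sum(weights)
    n = segment.shape[0]
    out = np.eye(n)
    means = [sum(wk * xk for wk, xk in zip(w, segment[i])) for i in range(n)]
    for i in range(n):
        for j in range(n):
            cij = sum(
                wk * (xi - means[i]) * (xj - means[j])
                for wk, xi, xj in zip(w, segment[i], segment[j])
            )
            cii = sum(wk * (xi - means[i]) ** 2 for wk, xi in zip(w, segment[i]))
            cjj = sum(wk * (xj - means[j]) ** 2 for wk, xj in zip(w, segment[j]))
            out[i, j] = cij / np.sqrt(cii * cjj)
    return out


# ---------------------------------------------------------------- static FC


class TestStaticFc:
    def test_self_copy_and_sign_invariance(self):
        x = np.random.default_rng(0).standard_normal(50)
        ts = _ts(np.vstack([x, x, -x]))
        fc = static_fc(ts)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(1.0)  # absolute correlation

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((3, 10))
        fc = static_fc(_ts(vals))
        for i in range(3):
            for j in range(i + 1, 3):
                x, y = vals[i], vals[j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert fc.values[i, j] == pytest.approx(abs(num / den), abs=1e-12)

    def test_zero_variance_region_flagged(self):
        vals = np.vstack([np.ones(30), np.random.default_rng(1).standard_normal(30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            fc = static_fc(_ts(vals))
        assert np.isnan(fc.values[0, 1])


# ---------------------------------------------------------------- taper


class TestTaperedWindowWeights:
    def test_normalized_symmetric_peaked(self):
        w = tapered_window_weights(WindowSpec())
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, w[::-1])
        assert np.all(w > 0)
        assert np.argmax(w) in (13,)  # centre of a 27-volume window

    def test_flat_kernel_limit(self):
        w = tapered_window_weights(WindowSpec(taper_sd_volumes=1000))
        assert np.max(np.abs(w - 1 / 27)) < 1e-3

    def test_matches_convolution_loop_oracle(self):
        w = tapered_window_weights(WindowSpec(27, 5, 9))
        assert np.max(np.abs(w - loop_taper(27, 9.0))) < 1e-12


# ---------------------------------------------------------------- windows


class TestWindowStartIndices:
    def test_printed_protocol_counts(self):
        starts = window_start_indices(197, WindowSpec())
        assert len(starts) == 35
        assert starts[-1] == 170

    def test_single_window_and_boundary(self):
        spec = WindowSpec()
        assert list(window_start_indices(27, spec)) == [0]
        with pytest.raises(ValueError):
            window_start_indices(26, spec)

    @settings(derandomize=True, max_examples=60)
    @given(
        t=st.integers(2, 500),
        length=st.integers(2, 100),
        step=st.integers(1, 100),
    )
    def test_window_count_closed_form(self, t, length, step):
        step = min(step, length)
        if t < length:
            return
        starts = window_start_indices(t, WindowSpec(length, step, 9))
        assert len(starts) == (t - length) // step + 1
        assert starts[-1] + length <= t


# ---------------------------------------------------------------- weighted corr


class TestWeightedCorrelation:
    def test_uniform_weights_reduce_to_pearson(self, rng):
        seg = rng.standard_normal((4, 27))
        r = weighted_correlation(seg, np.ones(27))
        assert np.max(np.abs(r - np.corrcoef(seg))) < 1e-12

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(27)
        seg = np.vstack([x, 2 * x + 3])
        w = tapered_window_weights(WindowSpec())
        r = weighted_correlation(seg, w)
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_sum_loop_oracle(self, rng):
        seg = rng.standard_normal((3, 27))
        w = tapered_window_weights(WindowSpec())
        r = weighted_correlation(seg, w)
        assert np.max(np.abs(r - loop_weighted_corr(seg, w))) < 1e-12


# ---------------------------------------------------------------- windowed FC


class TestWindowedFc:
    def test_window_count_at_protocol_length(self, rng):
        ts = _ts(rng.standard_normal((4, 197)))
        wc = windowed_fc(ts)
        assert wc.stack.shape == (35, 4, 4)

    def test_single_window_equals_weighted_correlation(self, rng):
        vals = rng.standard_normal((3, 27))
        wc = windowed_fc(_ts(vals))
        w = tapered_window_weights(WindowSpec())
        assert np.allclose(wc.stack[0], weighted_correlation(vals, w), atol=1e-12)

    def test_strong_coupling_keeps_windows_high(self):
        profile = np.array([[1.0, 0.9], [0.9, 1.0]])
        ts = simulate_stationary_series(profile, 1970, 2.2, seed=21)
        wc = windowed_fc(ts)
        vals = wc.stack[:, 0, 1]
        assert vals.min() > 0.6
        assert vals.max() <= 1.0

    def test_slices_symmetric_unit_diagonal(self, stationary_ts):
        wc = windowed_fc(stationary_ts)
        assert np.allclose(wc.stack, wc.stack.swapaxes(1, 2), atol=1e-12)
        diags = np.diagonal(wc.stack, axis1=1, axis2=2)
        assert np.allclose(diags, 1.0)
        assert wc.stack.min() >= -1.0 and wc.stack.max() <= 1.0


# ---------------------------------------------------------------- dFC measures


def _wc_from_stack(stack):
    from dfcpipe.connectivity import WindowedConnectivity

    stack = np.asarray(stack, dtype=float)
    return WindowedConnectivity(
        stack=stack,
        window_starts=np.arange(stack.shape[0]),
        spec=WindowSpec(),
        region_labels=[f"r{i}" for i in range(stack.shape[1])],
        tr=2.2,
    )


def _random_stack(rng, n_windows=5, n_regions=4):
    stack = rng.uniform(-0.9, 0.9, size=(n_windows, n_regions, n_regions))
    stack = (stack + stack.swapaxes(1, 2)) / 2
    idx = np.arange(n_regions)
    stack[:, idx, idx] = 1.0
    return stack


class TestDfcMeasures:
    def test_constant_stack_gives_zero(self, rng):
        stack = np.repeat(_random_stack(rng, 1), 4, axis=0)
        assert np.nanmax(dfc_summed_difference(_wc_from_stack(stack)).matrix) == 0
        assert np.nanmax(
            dfc_coefficient_of_variation(_wc_from_stack(np.abs(stack))).matrix
        ) == pytest.approx(0.0, abs=1e-12)

    def test_summed_difference_hand_example(self):
        stack = np.ones((3, 2, 2))
        for w, v in enumerate([0.2, 0.5, 0.1]):
            stack[w, 0, 1] = stack[w, 1, 0] = v
        res = dfc_summed_difference(_wc_from_stack(stack))
        assert res.matrix[0, 1] == pytest.approx(0.7)

    def test_cv_hand_example_sample_sd(self):
        stack = np.ones((2, 2, 2))
        stack[0, 0, 1] = stack[0, 1, 0] = 0.2
        stack[1, 0, 1] = stack[1, 1, 0] = 0.4
        res = dfc_coefficient_of_variation(_wc_from_stack(stack))
        # mean 0.3, sample sd = 0.1414..., cv = 0.4714...
        assert res.matrix[0, 1] == pytest.approx(np.sqrt(0.02) / 0.3, abs=1e-12)

    def test_measures_match_loop_oracles(self, rng):
        stack = _random_stack(rng, 5, 4)
        wc = _wc_from_stack(stack)
        diff = dfc_summed_difference(wc).matrix
        cv = dfc_coefficient_of_variation(wc).matrix
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                series = stack[:, i, j]
                acc = sum(abs(series[w + 1] - series[w]) for w in range(4))
                assert diff[i, j] == pytest.approx(acc, abs=1e-12)
                a = np.abs(series)
                assert cv[i, j] == pytest.approx(
                    np.std(a, ddof=1) / np.mean(a), abs=1e-12
                )

    def test_permutation_invariance(self, rng):
        stack = _random_stack(rng, 6, 5)
        perm = rng.permutation(5)
        permuted = stack[:, perm][:, :, perm]
        d0 = dfc_summed_difference(_wc_from_stack(stack)).matrix
        d1 = dfc_summed_difference(_wc_from_stack(permuted)).matrix
        assert np.allclose(
            np.nan_to_num(d1), np.nan_to_num(d0[perm][:, perm]), atol=1e-12
        )
        c0 = dfc_coefficient_of_variation(_wc_from_stack(stack)).matrix
        c1 = dfc_coefficient_of_variation(_wc_from_stack(permuted)).matrix
        assert np.allclose(
            np.nan_to_num(c1), np.nan_to_num(c0[perm][:, perm]), atol=1e-12
        )

    def test_cv_scale_invariance_and_diff_linearity(self, rng):
        stack = np.abs(_random_stack(rng, 5, 3))
        base_cv = dfc_coefficient_of_variation(_wc_from_stack(stack)).matrix
        scaled_cv = dfc_coefficient_of_variation(_wc_from_stack(0.5 * stack)).matrix
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(base_cv[off], scaled_cv[off], atol=1e-12)
        d1 = dfc_summed_difference(_wc_from_stack(stack)).matrix
        d2 = dfc_summed_difference(_wc_from_stack(0.5 * stack)).matrix
        assert np.allclose(d2[off], 0.5 * d1[off], atol=1e-12)

    def test_fewer_than_two_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            dfc_summed_difference(_wc_from_stack(_random_stack(rng, 1)))

    def test_cv_shrinks_with_longer_windows_on_stationary_data(self, small_profile):
        lengths = (20, 27, 40)
        means = []
        for length in lengths:
            vals = []
            for seed in range(20):
                ts = simulate_stationary_series(small_profile, 400, 2.2, seed=seed)
                wc = windowed_fc(ts, WindowSpec(length_volumes=length))
                vals.append(global_mean(dfc_coefficient_of_variation(wc)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------- summaries


class TestSummaries:
    def test_global_mean_hand_example(self):
        mat = np.full((3, 3), np.nan)
        mat[0, 1] = mat[1, 0] = 0.1
        mat[0, 2] = mat[2, 0] = 0.2
        mat[1, 2] = mat[2, 1] = 0.3
        assert global_mean(mat) == pytest.approx(0.2)

    def test_global_mean_matches_pair_enumeration_at_full_scale(self, rng):
        n = 224
        mat = rng.uniform(0, 1, size=(n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, np.nan)
        acc = [mat[i, j] for i in range(n) for j in range(i + 1, n)]
        assert len(acc) == 24976
        assert global_mean(mat) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_subnetwork_value_hand_enumeration(self, rng):
        labels = ["a1", "a2", "b1", "b2"]
        mat = rng.uniform(0.1, 0.9, size=(4, 4))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, np.nan)
        from dfcpipe.connectivity import ConnectivityMatrix

        cm = ConnectivityMatrix(values=mat, measure="sFC", region_labels=labels)
        spec = SubnetworkSpec(("a1", "a2"), ("b1", "b2"))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        expected = np.mean([mat[i, j] for i, j in pairs])
        assert subnetwork_value(cm, spec) == pytest.approx(expected, abs=1e-12)
        between = SubnetworkSpec(("a1", "a2"), ("b1", "b2"), "between-sets-only")
        expected_b = np.mean([mat[i, j] for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]])
        assert subnetwork_value(cm, between) == pytest.approx(expected_b, abs=1e-12)

    def test_normalization_identity(self, rng):
        labels = ["a1", "a2", "b1", "b2", "c1"]
        mat = rng.uniform(0.1, 0.9, size=(5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, np.nan)
        from dfcpipe.connectivity import ConnectivityMatrix

        cm = ConnectivityMatrix(values=mat, measure="sFC", region_labels=labels)
        spec = SubnetworkSpec(("a1", "a2"), ("b1", "b2"))
        raw = subnetwork_value(cm, spec, normalize_by_global=False)
        norm = subnetwork_value(cm, spec, normalize_by_global=True)
        assert raw / norm == pytest.approx(global_mean(mat), abs=1e-12)

    def test_homogeneous_matrix_normalizes_to_one(self):
        mat = np.full((4, 4), 0.37)
        np.fill_diagonal(mat, np.nan)
        from dfcpipe.connectivity import ConnectivityMatrix

        cm = ConnectivityMatrix(
            values=mat, measure="sFC", region_labels=["a1", "a2", "b1", "b2"]
        )
        spec = SubnetworkSpec(("a1", "a2"), ("b1", "b2"))
        assert subnetwork_value(cm, spec, True) == pytest.approx(1.0, abs=1e-12)
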