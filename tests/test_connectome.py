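"""FC construction, edge indexing and atlas metadata."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memconn import connectome as cn


def _sine(freq_hz, tr, n_t):
    t = np.arange(n_t) * tr
    return np.sin(2 * np.pi * freq_hz * t)


def _fft_amplitude(x, freq_hz, tr):
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2 / n
    freqs = np.fft.rfftfreq(n, d=tr)
    return spec[np.argmin(np.abs(freqs - freq_hz))]


class TestDetrendBandpass:
    def test_linear_ramp_removed(self):
        series = np.outer([1.0, -2.0], np.arange(64.0)) + 5.0
        out = cn.detrend_and_bandpass(series, 0.01, 0.1, tr_seconds=2.0)
        assert np.abs(out).max() < 1e-8

    @pytest.mark.parametrize(
        "freq,check",
        [
            (0.05, lambda a0, a1: a1 > 0.95 * a0),   # pass band: within 5%
            (0.20, lambda a0, a1: a1 < 0.10 * a0),   # stop band: >= 90% removed
        ],
    )
    def test_band_edges(self, freq, check):
        tr = 2.0
        x = _sine(freq, tr, 512)
        out = cn.detrend_and_bandpass(x[None, :], 0.01, 0.1, tr_seconds=tr)[0]
        # measure away from the filter's edge transients
        mid = slice(64, 448)
        a0 = _fft_amplitude(x[mid], freq, tr)
        a1 = _fft_amplitude(out[mid], freq, tr)
        assert check(a0, a1)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            cn.detrend_and_bandpass(np.zeros((2, 64)), 0.01, 0.3, tr_seconds=2.0)
        with pytest.raises(ValueError):
            cn.detrend_and_bandpass(np.zeros((2, 64)), 0.1, 0.05, tr_seconds=2.0)


class TestRegressNuisance:
    def test_empty_regressors_mean_centre(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal((3, 40)) + 7.0
        out = cn.regress_nuisance(series, None)
        assert np.allclose(out, series - series.mean(axis=1, keepdims=True))

    def test_series_equal_to_regressor_vanishes(self):
        rng = np.random.default_rng(1)
        reg = rng.standard_normal(50)
        out = cn.regress_nuisance(reg[None, :], reg[:, None])
        assert np.abs(out).max() < 1e-10

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((5, 80))
        regs = rng.standard_normal((80, 4))
        out = cn.regress_nuisance(series, regs)
        unit = regs / np.linalg.norm(regs, axis=0)
        resid = out / np.linalg.norm(out, axis=1, keepdims=True)
        assert np.abs(resid @ unit).max() < 1e-8

    def test_rank_deficient_warns_and_succeeds(self):
        rng = np.random.default_rng(3)
        r = rng.standard_normal(30)
        regs = np.column_stack([r, 2 * r])
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            out = cn.regress_nuisance(rng.standard_normal((2, 30)), regs)
        assert np.all(np.isfinite(out))


class TestPearsonFC:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(30)
        series = np.vstack([base, base, -base])
        fc = cn.pearson_fc(series)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        assert fc.space == "r"

    def test_matches_direct_formula_on_small_vectors(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        expect = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        fc = cn.pearson_fc(np.vstack([x, y]))
        assert fc.values[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_constant_series_error_names_node(self):
        series = np.vstack([np.ones(20), np.arange(20.0)])
        with pytest.raises(cn.DegenerateInputError, match=r"\[0\]"):
            cn.pearson_fc(series)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((6, 50))
        scale = rng.uniform(0.5, 3.0, 6)[:, None]
        shift = rng.uniform(-5, 5, 6)[:, None]
        r1 = cn.pearson_fc(series).values
        r2 = cn.pearson_fc(series * scale + shift).values
        assert np.abs(r1 - r2).max() < 1e-10


class TestFisherZ:
    def test_known_values_and_clamp(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 1.0], [0.5, 1.0, 1.0]])
        cm = cn.ConnectivityMatrix(values=r, space="r")
        z = cn.fisher_z(cm)
        assert z.space == "z"
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(np.arctanh(0.5))
        assert np.all(np.isfinite(z.values))  # clamped r=1 stays finite
        assert np.all(np.diag(z.values) == 0.0)

    @given(st.floats(-0.999, 0.999))
    @settings(deadline=None)
    def test_odd_symmetry(self, r):
        m = np.array([[1.0, r], [r, 1.0]])
        z = cn.fisher_z(cn.ConnectivityMatrix(values=m, space="r")).values[0, 1]
        zneg = cn.fisher_z(
            cn.ConnectivityMatrix(values=-m + 2 * np.eye(2), space="r")
        ).values[0, 1]
        assert zneg == pytest.approx(-z, abs=1e-12)

    def test_strictly_increasing(self):
        rs = np.linspace(-0.99, 0.99, 101)
        zs = [
            cn.fisher_z(
                cn.ConnectivityMatrix(np.array([[1, r], [r, 1.0]]), space="r")
            ).values[0, 1]
            for r in rs
        ]
        assert np.all(np.diff(zs) > 0)


class TestVectorize:
    @pytest.mark.parametrize("n,m", [(90, 4005), (2, 1), (10, 45)])
    def test_edge_count(self, n, m):
        assert cn.n_edges(n) == m
        assert cn.edge_index(n).shape == (m, 2)

    def test_round_trip_exact(self):
        rng = np.random.default_rng(6)
        mat = rng.standard_normal((4, 4))
        mat = mat + mat.T
        np.fill_diagonal(mat, 0.0)
        fv = cn.vectorize(mat)
        back = cn.devectorize(fv.values, 4)
        assert np.array_equal(back, mat)

    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_round_trip_property(self, n, seed):
        rng = np.random.default_rng(seed)
        mat = rng.standard_normal((n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        assert np.array_equal(cn.devectorize(cn.vectorize(mat).values, n), mat)

    def test_asymmetry_rejected(self):
        mat = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            cn.vectorize(mat)

    def test_canonical_order_row_major(self):
        mat = cn.devectorize(np.arange(1.0, 7.0), 4)
        fv = cn.vectorize(mat)
        # edges (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) in order
        assert np.array_equal(fv.values, np.arange(1.0, 7.0))


class TestEdgeGeometry:
    def test_345_triangle_short_range(self, atlas10):
        atlas = cn.AtlasDefinition(
            labels=["a", "b"],
            modules=["m", "m"],
            centroids=np.array([[0.0, 0, 0], [3.0, 4.0, 0]]),
        )
        d = cn.edge_distance((0, 1), atlas)
        assert d == pytest.approx(5.0)
        assert not cn.is_long_range(d)

    def test_80mm_is_long_range(self):
        atlas = cn.AtlasDefinition(
            labels=["a", "b"],
            modules=["m", "m"],
            centroids=np.array([[0.0, 0, 0], [80.0, 0, 0]]),
        )
        assert cn.is_long_range(cn.edge_distance((0, 1), atlas))

    def test_all_edges_match_bruteforce(self, atlas90):
        dists = cn.edge_distances(atlas90)
        idx = cn.edge_index(90)
        for k in range(0, len(idx), 97):  # stride through all 4005
            i, j = idx[k]
            expect = float(np.sqrt(((atlas90.centroids[i] - atlas90.centroids[j]) ** 2).sum()))
            assert dists[k] == pytest.approx(expect, abs=1e-12)
            assert (dists[k] > 75.0) == cn.is_long_range(dists[k])

    def test_module_pairs(self, atlas10):
        a, b, within = cn.edge_module_pair((0, 1), atlas10)
        assert (a, b, within) == ("default mode", "default mode", True)
        a, b, within = cn.edge_module_pair((0, 7), atlas10)
        assert (a, b) == ("default mode", "limbic") and not within

    def test_single_module_always_within(self):
        atlas = cn.AtlasDefinition(
            labels=list("abc"),
            modules=["m"] * 3,
            centroids=np.zeros((3, 3)),
        )
        for e in [(0, 1), (0, 2), (1, 2)]:
            assert cn.edge_module_pair(e, atlas)[2]


def test_stack_features_appends_extras():
    rng = np.random.default_rng(7)
    mats = rng.standard_normal((3, 5, 5))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    extra = rng.standard_normal((3, 2))
    X = cn.stack_features(mats, extra)
    assert X.shape == (3, 12)
    assert np.array_equal(X[:, 10:], extra)
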