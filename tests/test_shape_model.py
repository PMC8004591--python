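"""PCA shape models, scores F and G, and the typical-leaf detection band."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafmorph import (
    InputError,
    ShapeModel,
    TraitVector,
    detect_typical,
    fit_shape_model,
    score_F,
    score_G,
)
from leafmorph.shape_model import variance_contribution_rates


def tv(s, c, l, w):
    return TraitVector(s=s, c=c, l=l, w=w)


def random_rows(rng, n=10, spread=0.1):
    rows = []
    for _ in range(n):
        f = rng.uniform(1 - spread, 1 + spread)
        rows.append(tv(1800 * f**2, 160 * f, 60 * f, 40 * f * rng.uniform(0.95, 1.05)))
    return rows


class TestFit:
    def test_identical_rows_degenerate_equal_weights(self):
        rows = [tv(100, 50, 10, 5)] * 8
        model = fit_shape_model(rows)
        assert model.degenerate
        assert np.allclose(model.a, 0.25)
        assert np.allclose(model.b, 1 / 6)

    def test_few_rows_fallback(self):
        model = fit_shape_model(random_rows(np.random.default_rng(0), n=3))
        assert model.degenerate and np.allclose(model.a, 0.25)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = fit_shape_model(random_rows(rng, n=12))
        assert model.a.sum() == pytest.approx(1.0, abs=1e-9)
        assert model.b.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.a >= 0).all() and (model.b >= 0).all()

    def test_two_informative_dimensions_spectrum(self):
        # two perfectly correlated pairs of uncorrelated factors ->
        # correlation spectrum (2, 2, 0, 0), contribution rates (.5, .5, 0, 0)
        rng = np.random.default_rng(2)
        z1, z2 = rng.normal(size=20), rng.normal(size=20)
        z2 = z2 - z1 * (z1 @ z2) / (z1 @ z1)  # exactly decorrelate
        z1, z2 = z1 - z1.mean(), z2 - z2.mean()
        z2 = z2 - z1 * (z1 @ z2) / (z1 @ z1)
        x = np.column_stack([z1, z1, z2, z2])
        w = variance_contribution_rates(x)
        assert np.allclose(w, [0.5, 0.5, 0.0, 0.0], atol=1e-9)

    def test_spectrum_matches_svd_oracle(self):
        # independent route: singular values of the standardized data matrix
        rng = np.random.default_rng(3)
        for p in (4, 6):
            x = rng.normal(size=(10, p)) @ rng.normal(size=(p, p))
            w = variance_contribution_rates(x)
            z = (x - x.mean(0)) / x.std(0, ddof=1)
            sv = np.linalg.svd(z, compute_uv=False)
            ev = sv**2 / (len(x) - 1)
            assert np.allclose(w, ev / ev.sum(), atol=1e-8)

    def test_non_positive_trait_rejected(self):
        rows = random_rows(np.random.default_rng(0))
        rows.append(tv(-1.0, 50, 10, 5))
        with pytest.raises(InputError):
            fit_shape_model(rows)

    def test_json_roundtrip(self, tmp_path):
        model = fit_shape_model(random_rows(np.random.default_rng(4)))
        p = tmp_path / "model.json"
        model.to_json(p)
        again = ShapeModel.from_json(p)
        assert np.allclose(again.a, model.a) and np.allclose(again.b, model.b)
        assert again.mean_g == pytest.approx(model.mean_g)


class TestScores:
    def make_model(self, a, means, mean_g=6.0, b=None, n_fit=10):
        return ShapeModel(
            a=np.asarray(a, float),
            b=np.full(6, 1 / 6) if b is None else np.asarray(b, float),
            mean_scale=np.asarray(means, float),
            mean_g=mean_g,
            n_fit=n_fit,
        )

    def test_f_zero_at_means(self):
        m = self.make_model([0.25] * 4, [100, 50, 10, 5])
        assert score_F(tv(100, 50, 10, 5), m) == pytest.approx(0.0)

    def test_f_one_at_doubled_traits(self):
        m = self.make_model([0.4, 0.3, 0.2, 0.1], [100, 50, 10, 5])
        assert score_F(tv(200, 100, 20, 10), m) == pytest.approx(1.0)

    def test_f_hand_example(self):
        m = self.make_model([0.5, 0.3, 0.1, 0.1], [100, 50, 10, 5])
        assert score_F(tv(110, 45, 10, 5), m) == pytest.approx(0.02)

    def test_f_invariant_under_common_unit_rescale(self):
        m = self.make_model([0.4, 0.3, 0.2, 0.1], [100, 50, 10, 5])
        k = 1000.0  # mm -> m style rescale of traits and means together
        m2 = self.make_model([0.4, 0.3, 0.2, 0.1], np.array([100, 50, 10, 5]) / k)
        t1, t2 = tv(110, 45, 12, 6), tv(110 / k, 45 / k, 12 / k, 6 / k)
        assert score_F(t1, m) == pytest.approx(score_F(t2, m2), rel=1e-12)

    def test_g_equal_weights_is_mean_of_ratios(self):
        # with b_i = 1/6, G is the plain mean of the six ratio traits
        t = tv(100, 50, 10, 5)
        m = self.make_model([0.25] * 4, [1, 1, 1, 1])
        assert score_G(t, m) == pytest.approx(np.mean(t.ratio_array()))

    def test_g_selector_weight(self):
        t = tv(100, 50, 10, 5)
        m = self.make_model([0.25] * 4, [1, 1, 1, 1], b=[1, 0, 0, 0, 0, 0])
        assert score_G(t, m) == pytest.approx(t.x11)

    def test_g_hand_example(self):
        b = [0.4, 0.3, 0.1, 0.1, 0.05, 0.05]
        # ratios (2, 10, 20, 5, 10, 2): s=100, c=50, l=10, w=5
        t = tv(100, 50, 10, 5)
        m = self.make_model([0.25] * 4, [1, 1, 1, 1], b=b)
        assert score_G(t, m) == pytest.approx(0.8 + 3 + 2 + 0.5 + 0.5 + 0.1)


class TestDetection:
    def test_mean_leaf_is_typical(self):
        rows = random_rows(np.random.default_rng(5), n=10, spread=0.03)
        model = fit_shape_model(rows)
        mean_tv = tv(*np.mean([r.scale_array() for r in rows], axis=0))
        res = detect_typical(mean_tv, model)
        assert res.is_typical and res.reason == "pass"

    def test_tiny_leaf_fails_size_band(self):
        rows = random_rows(np.random.default_rng(6), n=10, spread=0.03)
        model = fit_shape_model(rows)
        mean = np.mean([r.scale_array() for r in rows], axis=0)
        # 10% linear size: area 1%, others 10% -> 1 + F far below 0.25
        shrunk = tv(mean[0] * 0.01, mean[1] * 0.1, mean[2] * 0.1, mean[3] * 0.1)
        res = detect_typical(shrunk, model)
        assert not res.is_typical and res.reason == "size_out_of_band"

    def test_distorted_ratios_fail_shape_band(self):
        rows = random_rows(np.random.default_rng(7), n=10, spread=0.03)
        model = fit_shape_model(rows)
        mean = np.mean([r.scale_array() for r in rows], axis=0)
        # same area but absurd proportions (perimeter a third of normal)
        # -> G far off Gbar while the size score stays near the mean
        weird = tv(mean[0], mean[1] / 3.0, mean[2], mean[3])
        res = detect_typical(weird, model)
        assert not res.is_typical and res.reason == "shape_out_of_band"

    def test_degenerate_model_accepts_everything(self):
        model = fit_shape_model([tv(100, 50, 10, 5)])
        res = detect_typical(tv(1, 1, 1, 0.5), model)
        assert res.is_typical and res.reason == "degenerate_model"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fitting_rows_within_20pct_all_accepted(self, seed):
        # band containment: rows within +-20% of their means on every trait
        # always pass the (0.25, 1.25) bands because the weights sum to 1
        rng = np.random.default_rng(seed)
        rows = []
        base = np.array([2000.0, 180.0, 65.0, 41.0])
        for _ in range(8):
            f = rng.uniform(0.9, 1.1, size=4)  # each trait within +-10% of base
            rows.append(tv(*(base * f)))
        model = fit_shape_model(rows)
        mean = np.mean([r.as_array() for r in rows], axis=0)
        if (np.abs([r.as_array() / mean - 1 for r in rows]) < 0.2).all():
            for r in rows:
                assert detect_typical(r, model).is_typical
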