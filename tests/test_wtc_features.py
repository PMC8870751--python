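"""Area normalization, summary parameters, tail fractions and alpha selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneemorph import wtc_features as wtc
from kneemorph.mesh_core import TriSurface
from kneemorph.morphometry import ElementField


def _field_from(values, areas=None, kind="wall"):
    """Build an ElementField whose faces have prescribed areas."""
    values = np.asarray(values, float)
    m = len(values)
    if areas is None:
        areas = np.ones(m)
    verts, faces = [], []
    for i, a in enumerate(areas):
        # right triangle with legs (2a, 1) at z = i -> area a
        z = float(i)
        verts += [(0, 0, z), (2 * a, 0, z), (0, 1, z)]
        faces.append((3 * i, 3 * i + 1, 3 * i + 2))
    surf = TriSurface(np.array(verts), np.array(faces))
    return ElementField(surf, values, kind, np.ones(m, bool))


def _nf(values, kind="wall"):
    return wtc.NormalizedField(np.asarray(values, float), kind)


class TestNormalizeByArea:
    def test_direct_product(self):
        field = _field_from([2.0, 3.0], areas=[0.5, 1.0])
        nf = wtc.normalize_by_area(field)
        np.testing.assert_allclose(np.sort(nf.values), [1.0, 3.0])

    def test_uniform_areas_preserve_scale_free_stats(self, rng):
        x = rng.uniform(1, 3, size=50)
        field = _field_from(x, areas=np.full(50, 2.0))
        nf = wtc.normalize_by_area(field)
        raw = _nf(x)
        assert wtc.w_percent(nf, 0.7) == wtc.w_percent(raw, 0.7)

    def test_sum_matches_independent_accumulation(self, rng):
        x = rng.uniform(0.5, 4.0, size=200)
        a = rng.uniform(0.2, 2.0, size=200)
        field = _field_from(x, areas=a)
        nf = wtc.normalize_by_area(field)
        brute = 0.0
        for ai, xi in zip(field.surface.face_areas, field.values):
            brute += ai * xi
        assert nf.values.sum() == pytest.approx(brute, rel=1e-9)

    def test_invalid_elements_excluded(self):
        field = _field_from([1.0, 2.0, 3.0])
        field.valid[1] = False
        nf = wtc.normalize_by_area(field)
        assert nf.n_elements == 2

    def test_all_invalid_rejected(self):
        field = _field_from([1.0, 2.0])
        field.valid[:] = False
        with pytest.raises(ValueError):
            wtc.normalize_by_area(field)


class TestSummaryParams:
    def test_constant_field(self):
        mean, std, var, rms = wtc.summary_params(_nf([1, 1, 1, 1]))
        assert (mean, std, var, rms) == (1.0, 0.0, 0.0, 1.0)

    def test_hand_arithmetic(self):
        mean, std, var, rms = wtc.summary_params(_nf([0.0, 2.0]))
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(2.0)
        assert std == pytest.approx(np.sqrt(2))
        assert rms == pytest.approx(np.sqrt(2))

    def test_matches_two_pass_oracle(self, rng):
        y = rng.normal(5, 2, size=10_000)
        mean, std, var, rms = wtc.summary_params(_nf(y))
        mu = sum(y) / len(y)
        v = sum((yi - mu) ** 2 for yi in y) / (len(y) - 1)
        assert mean == pytest.approx(mu, rel=1e-10)
        assert var == pytest.approx(v, rel=1e-10)
        assert rms == pytest.approx(np.sqrt(sum(y * y) / len(y)), rel=1e-10)
        # the documented identity RMS^2 = mean^2 + VAR*(n-1)/n
        n = len(y)
        assert rms**2 == pytest.approx(mean**2 + var * (n - 1) / n, rel=1e-9)

    def test_single_element_rejected(self):
        with pytest.raises(ValueError):
            wtc.summary_params(_nf([1.0]))


class TestTailFractions:
    def test_constant_field_is_zero(self):
        assert wtc.w_percent(_nf([3, 3, 3]), 1.0) == 0.0
        assert wtc.c_percent(_nf([3, 3, 3], "curvature"), 1.0) == 0.0

    def test_hand_case_skewed(self):
        # mu = 2, sigma = sqrt(20) ~ 4.472, threshold ~ -0.236: nothing below
        assert wtc.w_percent(_nf([0, 0, 0, 0, 10]), 0.5) == 0.0

    def test_partition_at_alpha_zero(self, rng):
        y = rng.normal(size=501)
        nf = _nf(y)
        below = wtc.w_percent(nf, 0.0)
        at_or_above = np.mean(y >= y.mean())
        assert below + at_or_above == pytest.approx(1.0)

    def test_symmetric_field_mirrors(self):
        y = np.concatenate([np.arange(10), -np.arange(10)])
        assert wtc.w_percent(_nf(y), 0.0) == \
            wtc.c_percent(_nf(y, "curvature"), 0.0)

    def test_matches_exhaustive_count(self, rng):
        y = rng.standard_t(3, size=10_000)
        nf = _nf(y)
        for alpha in (0.0, 0.5, 2.0, 5.0):
            mu, sigma = y.mean(), y.std(ddof=1)
            below = sum(1 for v in y if v < mu - alpha * sigma) / len(y)
            above = sum(1 for v in y if v > mu + alpha * sigma) / len(y)
            assert wtc.w_percent(nf, alpha) == pytest.approx(below)
            assert wtc.c_percent(_nf(y, "curvature"), alpha) == \
                pytest.approx(above)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200),
        alpha=st.floats(0.0, 6.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance_and_bounds(self, data, alpha, scale):
        nf = _nf(data)
        w = wtc.w_percent(nf, alpha)
        c = wtc.c_percent(_nf(data, "curvature"), alpha)
        assert 0.0 <= w <= 1.0
        assert 0.0 <= c <= 1.0
        scaled = _nf(np.asarray(data) * scale)
        assert wtc.w_percent(scaled, alpha) == pytest.approx(w, abs=1e-12)

    def test_monotone_nonincreasing_in_alpha(self, rng):
        y = rng.normal(size=2000)
        nf = _nf(y)
        grid = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
        w = [wtc.w_percent(nf, a) for a in grid]
        c = [wtc.c_percent(_nf(y, "curvature"), a) for a in grid]
        assert all(w[i] >= w[i + 1] for i in range(len(w) - 1))
        assert all(c[i] >= c[i + 1] for i in range(len(c) - 1))


class TestSelectAlpha:
    def test_singleton_grid(self):
        fields = [_nf([1, 2, 3]), _nf([4, 5, 6])]
        assert wtc.select_alpha(fields, ["A", "B"], grid=[0.5]) == 0.5

    def test_constructed_separation_prefers_designed_alpha(self, rng):
        """Two groups whose shapes differ only in the lower tail beyond
        0.5 sigma: exhaustive search over the grid must find 0.5."""
        fields, labels = [], []
        for i in range(12):
            base = rng.normal(10, 1, size=400)
            if i < 6:  # group with extra mass just below mu - 0.5 sigma
                base[:120] = rng.normal(8.8, 0.05, size=120)
                labels.append("D")
            else:
                labels.append("C")
            fields.append(_nf(base))
        grid = (0.5, 3.0, 5.0)
        chosen = wtc.select_alpha(fields, labels, grid=grid)
        # independent exhaustive verification over the same grid
        from kneemorph.group_stats import kruskal_wallis

        hs = {}
        for alpha in grid:
            vals = np.array([wtc.w_percent(f, alpha) for f in fields])
            hs[alpha] = kruskal_wallis(
                [vals[np.array(labels) == g] for g in ("C", "D")]
            )[0]
        assert chosen == max(sorted(grid), key=lambda a: hs[a])
        assert chosen == 0.5

    def test_identical_fields_warn_and_return_smallest(self, caplog):
        fields = [_nf([1, 1, 1]) for _ in range(6)]
        labels = ["A"] * 3 + ["B"] * 3
        with caplog.at_level("WARNING"):
            alpha = wtc.select_alpha(fields, labels, grid=[0.3, 0.5])
        assert alpha == 0.3

    def test_default_alphas_match_config(self):
        assert wtc.DEFAULT_ALPHAS[("fem_cart", "wall")] == 0.5
        assert wtc.DEFAULT_ALPHAS[("tib_cart_lat", "wall")] == 0.3
        assert all(
            wtc.DEFAULT_ALPHAS[(c, "curvature")] == 5.0
            for c in ("fem_cart", "pat_cart", "tib_cart_lat", "tib_cart_med")
        )


class TestAssembleBlock:
    def _analyses(self, rng):
        out = {}
        for comp in ("fem_cart", "pat_cart", "tib_cart_lat", "tib_cart_med"):
            out[(comp, "wall")] = _nf(rng.uniform(1, 3, 100), "wall")
            out[(comp, "curvature")] = _nf(rng.normal(0, 0.01, 100),
                                           "curvature")
        return out

    def test_exactly_48_named_columns(self, rng):
        block = wtc.assemble_wtc_block(self._analyses(rng))
        assert len(block) == 48
        assert list(block) == wtc.wtc_column_names()
        for name in ("FemWallBelowSTDWeight", "PatWallVar", "LatWallMean",
                     "FemWallRMS", "FemCurvAboveSTDWeight"):
            assert name in block

    def test_alpha_columns_shared_across_subjects(self, rng):
        b1 = wtc.assemble_wtc_block(self._analyses(rng))
        b2 = wtc.assemble_wtc_block(self._analyses(rng))
        for name in wtc.wtc_column_names():
            if name.endswith("STDWeight") and not name.endswith(
                ("BelowSTDWeight", "AboveSTDWeight")
            ):
                assert b1[name] == b2[name]

    def test_missing_analysis_listed(self, rng):
        analyses = self._analyses(rng)
        del analyses[("pat_cart", "curvature")]
        with pytest.raises(ValueError, match="pat_cart"):
            wtc.assemble_wtc_block(analyses)

    def test_unstable_feature_rule(self):
        import pandas as pd

        table = pd.DataFrame({
            "steady": [1.0, 1.1, 0.9, 1.0],
            "wild": [0.001, 5.0, -4.0, 0.002],
        })
        assert wtc.unstable_features(table, threshold=5.0) == ["wild"]
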