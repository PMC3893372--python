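"""Medcouple, skew-adjusted fences, and thin-region flagging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcdmap.detection import (
    DysplasiaRegion,
    adjusted_fences,
    flag_thin_regions,
    flagged_fraction,
    mean_thickness_by_slide,
    medcouple,
    position_curvature_map,
)
from fcdmap.errors import InsufficientSampleError, UndefinedMedcoupleError
from fcdmap.ribbon import MidlineProfile


def brute_medcouple(x):
    """Independent O(n^2) kernel-median oracle (pure Python)."""
    x = np.sort(np.asarray(x, float))
    m = float(np.median(x))
    zero_i = [i for i, v in enumerate(x) if v == m]
    k = len(zero_i)
    vals = []
    for i, xi in enumerate(x):
        for j, xj in enumerate(x):
            if xi > m or xj < m:
                continue
            if xi == m and xj == m:
                vals.append(float(np.sign(zero_i.index(i) + zero_i.index(j) - (k - 1))))
            else:
                vals.append(((xj - m) - (m - xi)) / (xj - xi))
    return float(np.median(vals))


class TestMedcouple:
    def test_symmetric_sample_zero(self):
        assert medcouple([1, 2, 3, 4, 5]) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(3, 40))
            x = (
                rng.integers(0, 6, n).astype(float)
                if trial % 3 == 0
                else rng.lognormal(0, 1, n)
            )
            if x.min() == x.max():
                continue
            assert medcouple(x) == pytest.approx(brute_medcouple(x), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.stattools import medcouple as sm_medcouple

        rng = np.random.default_rng(3)
        for _ in range(40):
            x = rng.lognormal(0, 1, int(rng.integers(4, 200)))
            assert medcouple(x) == pytest.approx(float(sm_medcouple(x)), abs=1e-12)

    @given(
        st.lists(st.floats(1.0, 1e4, allow_nan=False), min_size=4, max_size=25).filter(
            lambda v: len(set(v)) > 1
        )
    )
    def test_antisymmetry(self, vals):
        x = np.asarray(vals)
        assert medcouple(x) + medcouple(-x) == pytest.approx(0.0, abs=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(UndefinedMedcoupleError):
            medcouple([2.0, 2.0, 2.0, 2.0])


class TestAdjustedFences:
    def test_symmetric_reduces_to_tukey(self):
        x = np.arange(1.0, 21.0)  # exactly symmetric
        f = adjusted_fences(x)
        assert f.medcouple == 0.0
        iqr = f.q3 - f.q1
        assert f.lower_fence == pytest.approx(f.q1 - 1.5 * iqr)
        assert f.upper_fence == pytest.approx(f.q3 + 1.5 * iqr)

    def test_right_skew_tightens_lower_widens_upper(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 500)
        adj = adjusted_fences(x)
        tuk = adjusted_fences(x, variant="tukey")
        assert adj.medcouple > 0
        assert adj.lower_fence > tuk.lower_fence  # closer to q1
        assert adj.upper_fence > tuk.upper_fence  # farther from q3

    def test_lognormal_outlier_fraction_below_2pc(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 0.8, 10_000)
        f = adjusted_fences(x)
        frac = np.mean((x < f.lower_fence) | (x > f.upper_fence))
        assert frac < 0.02

    @given(
        st.lists(st.floats(10.0, 1e3), min_size=12, max_size=40).filter(
            lambda v: len(set(v)) > 3
        ),
        st.floats(-50.0, 50.0),
        st.floats(0.1, 10.0),
    )
    def test_shift_scale_equivariance(self, vals, shift, scale):
        x = np.asarray(vals)
        f0 = adjusted_fences(x)
        f1 = adjusted_fences(x * scale + shift)
        assert f1.lower_fence == pytest.approx(f0.lower_fence * scale + shift, rel=1e-9, abs=1e-6)
        assert f1.upper_fence == pytest.approx(f0.upper_fence * scale + shift, rel=1e-9, abs=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            adjusted_fences([1.0, 2.0, 3.0])

    def test_quartile_ordering_invariants(self):
        rng = np.random.default_rng(9)
        f = adjusted_fences(rng.normal(300, 30, 200))
        assert f.q1 <= f.q2 <= f.q3
        assert f.lower_fence <= f.q1 and f.upper_fence >= f.q3
        assert -1.0 <= f.medcouple <= 1.0


def profile_from(t, step=100.0, slide="s", closed=False):
    t = np.asarray(t, float)
    s = np.arange(len(t)) * step
    pts = np.column_stack([s / 10.0, np.zeros_like(s)])
    return MidlineProfile(slide, pts, s, t, np.zeros_like(t), closed)


class TestFlagThinRegions:
    def fences(self, lower):
        return type("F", (), {"lower_fence": lower})()

    def test_no_thin_samples_empty(self):
        prof = profile_from(np.full(50, 300.0))
        assert flag_thin_regions(prof, self.fences(250.0)) == []

    def test_all_below_single_full_region(self):
        prof = profile_from(np.full(50, 200.0))
        regs = flag_thin_regions(prof, self.fences(250.0), min_len=100.0)
        assert len(regs) == 1
        assert regs[0].n_samples == 50
        assert flagged_fraction(regs, prof) == 1.0

    def test_short_runs_discarded(self):
        t = np.full(60, 300.0)
        t[10:12] = 200.0  # 100 um run
        t[30:45] = 200.0  # 1400 um run
        prof = profile_from(t)
        regs = flag_thin_regions(prof, self.fences(250.0), min_len=1000.0)
        assert len(regs) == 1
        assert regs[0].s_start == pytest.approx(3000.0)
        assert regs[0].s_end == pytest.approx(4400.0)

    def test_region_means_reported(self):
        t = np.full(40, 300.0)
        t[5:20] = 180.0
        prof = profile_from(t)
        (reg,) = flag_thin_regions(prof, self.fences(250.0), min_len=500.0)
        assert reg.mean_t == pytest.approx(180.0)
        assert reg.n_samples == 15

    def test_reversal_invariance(self):
        rng = np.random.default_rng(5)
        t = 300.0 + rng.normal(0, 40, 80)
        prof = profile_from(t)
        rev = profile_from(t[::-1])
        a = flag_thin_regions(prof, self.fences(260.0), min_len=300.0)
        b = flag_thin_regions(rev, self.fences(260.0), min_len=300.0)
        total = prof.arc_s[-1]
        spans_a = sorted((r.s_start, r.s_end) for r in a)
        spans_b = sorted((total - r.s_end, total - r.s_start) for r in b)
        assert np.allclose(spans_a, spans_b)

    def test_wraparound_merged_on_closed_midline(self):
        t = np.full(40, 300.0)
        t[:8] = 200.0
        t[-8:] = 200.0
        prof = profile_from(t, closed=True)
        regs = flag_thin_regions(prof, self.fences(250.0), min_len=500.0)
        assert len(regs) == 1
        assert regs[0].n_samples == 16


class TestCohortSummaries:
    def test_mean_thickness_is_arithmetic_mean(self):
        import pandas as pd

        p1 = profile_from([100.0, 200.0, 300.0], slide="a")
        p2 = profile_from([400.0, 500.0], slide="b")
        meta = pd.DataFrame(
            {"slide_id": ["a", "b"], "pair_id": [1, 1], "group": ["case", "control"],
             "y": [10.0, 10.0]}
        )
        df = mean_thickness_by_slide([p1, p2], meta)
        assert df.set_index("slide_id").loc["a", "mean_t"] == pytest.approx(200.0)
        assert df.set_index("slide_id").loc["b", "mean_t"] == pytest.approx(450.0)

    def test_identical_cohorts_zero_delta(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "y": rng.uniform(-100, 70, 500),
                "kappa": rng.normal(0, 0.3, 500),
                "t": rng.normal(2500, 200, 500),
            }
        )
        res = position_curvature_map(
            df, df.copy(), np.linspace(-106, 73, 7), np.array([-np.inf, 0, np.inf]), n_min=5
        )
        populated = ~np.isnan(res["delta_t"])
        assert populated.any()
        assert np.allclose(res["delta_t"][populated], 0.0)

    def test_crest_only_thinning_confined_to_positive_kappa_bins(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 4000
        base = pd.DataFrame(
            {
                "y": rng.uniform(-100, 70, n),
                "kappa": rng.normal(0, 0.3, n),
                "t": np.full(n, 2500.0),
            }
        )
        case = base.copy()
        case.loc[case.kappa > 0, "t"] -= 400.0
        res = position_curvature_map(
            case, base, np.linspace(-106, 73, 5), np.array([-np.inf, 0.0, np.inf]), n_min=10
        )
        assert np.nanmax(np.abs(res["delta_t"][:, 0])) < 1e-9  # kappa < 0 bins
        assert np.nanmin(res["delta_t"][:, 1]) < -390.0  # kappa > 0 bins

    def test_sparse_bins_masked_with_zero_count(self):
        import pandas as pd

        df = pd.DataFrame({"y": [0.0], "kappa": [0.1], "t": [2000.0]})
        res = position_curvature_map(
            df, df.copy(), np.array([-10.0, 10.0]), np.array([-1.0, 0.0, 1.0]), n_min=5
        )
        assert np.isnan(res["delta_t"][0, 0])
        assert res["n_case"][0, 0] == 0
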