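"""Parametric study: design sampling, statistics, correlations, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tonosim.study import (DEFAULT_RANGES, INPUT_COLUMNS, OUTPUT_COLUMNS,
                           StudyDesign, correlation_matrix, generate_design,
                           pearson_r, run_study, summarize,
                           synthesize_clinical, trace_rmse)


class TestDesign:
    def test_published_model_count(self):
        assert len(generate_design(StudyDesign(n=110, seed=3))) == 110

    def test_seeded_reproducibility(self):
        a = generate_design(StudyDesign(n=20, seed=11))
        b = generate_design(StudyDesign(n=20, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_samples_respect_bounds(self):
        d = generate_design(StudyDesign(n=64, seed=5))
        for col, (lo, hi) in DEFAULT_RANGES.items():
            assert d[col].between(lo, hi).all()

    def test_grid_scheme_and_validation(self):
        g = generate_design(StudyDesign(n=16, scheme="grid", seed=0))
        assert len(g) == 16
        with pytest.raises(ValueError):
            StudyDesign(n=2)
        with pytest.raises(ValueError):
            StudyDesign(n=10, ranges={"IOP (mmHg)": (25.0, 10.0)})


class TestPearson:
    def test_perfect_correlations(self):
        r, p, n = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and n == 3
        r, _, _ = pearson_r([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == -1.0

    def test_published_t_statistic(self):
        # r = 0.736 at n = 110 gives t = 11.30 and p far below 1e-4
        rng = np.random.default_rng(0)
        # construct data with exactly this sample correlation
        n = 110
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= np.polyval(np.polyfit(x, e, 1), x)
        target = 0.736
        y = target * (x - x.mean()) / x.std() + np.sqrt(1 - target**2) * (
            e / e.std())
        r, p, _ = pearson_r(x, y)
        assert r == pytest.approx(0.736, abs=1e-9)
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert t == pytest.approx(11.30, abs=0.01)
        assert p < 1e-4

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        r, p, _ = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_replication_keeps_r_shrinks_p(self):
        x = np.array([1.0, 2, 3, 4, 5, 7])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.4, 6.4])
        r1, p1, _ = pearson_r(x, y)
        r2, p2, _ = pearson_r(np.tile(x, 2), np.tile(y, 2))
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert p2 < p1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummarize:
    def test_hand_computed_two_row_table(self):
        t = pd.DataFrame({"IOP (mmHg)": [10.0, 20.0]})
        s = summarize(t)
        assert s.loc["IOP (mmHg)", "Mean"] == 15.0
        assert s.loc["IOP (mmHg)", "Std. Deviation"] == pytest.approx(
            np.sqrt(50.0))
        assert s.loc["IOP (mmHg)", "Minimum"] == 10.0
        assert s.loc["IOP (mmHg)", "Maximum"] == 20.0

    def test_constant_column_zero_sd(self):
        s = summarize(pd.DataFrame({"µ": [0.07, 0.07, 0.07]}))
        assert s.loc["µ", "Std. Deviation"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())


class TestSyntheticClinical:
    SPEC = {"CCT_um": (543.0, 31.5, 458.0, 635.0)}

    def test_moments_within_sampling_error(self):
        df = synthesize_clinical(self.SPEC, 225, seed=4)
        se = 31.5 / np.sqrt(225)
        assert abs(df["CCT_um"].mean() - 543.0) < 3 * se

    def test_all_samples_inside_printed_range(self):
        df = synthesize_clinical(self.SPEC, 500, seed=9)
        assert df["CCT_um"].between(458.0, 635.0).all()

    def test_seed_determinism(self):
        a = synthesize_clinical(self.SPEC, 50, seed=1)
        b = synthesize_clinical(self.SPEC, 50, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestTraceRMSE:
    def test_identical_traces(self):
        t = np.linspace(0, 30, 100)
        d = np.sin(t / 5)
        assert trace_rmse(t, d, t, d) == 0.0

    def test_constant_offset(self):
        t = np.linspace(0, 30, 100)
        d = np.sin(t / 5)
        assert trace_rmse(t, d, t, d + 0.25) == pytest.approx(0.25, rel=1e-12)

    def test_hand_built_three_point_value(self):
        rmse = trace_rmse([0, 1, 2], [0.0, 1.0, 2.0], [0, 1, 2], [0.1, 0.8, 2.3])
        assert rmse == pytest.approx(np.sqrt((0.01 + 0.04 + 0.09) / 3), rel=1e-12)

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError):
            trace_rmse([0, 1], [0, 0], [5, 6], [0, 0])


@pytest.fixture(scope="module")
def small_sweep():
    # the full 2^4 corner design exercising the whole pipeline
    design = StudyDesign(n=16, scheme="grid", seed=0)
    return run_study(design)


class TestRunStudy:
    def test_all_rows_complete(self, small_sweep):
        assert len(small_sweep) == 16
        assert not small_sweep["failed"].any()
        for c in OUTPUT_COLUMNS:
            assert np.isfinite(small_sweep[c]).all()

    def test_input_stats_equal_design_stats(self, small_sweep):
        design = generate_design(StudyDesign(n=16, scheme="grid", seed=0))
        for c in INPUT_COLUMNS:
            assert small_sweep[c].min() == design[c].min()
            assert small_sweep[c].max() == design[c].max()

    def test_higher_iop_lowers_hc_deformation(self, small_sweep):
        # grid corners share (CCT, mu, R) at min; compare IOP extremes
        lo = small_sweep[small_sweep["IOP (mmHg)"] == 10.0]
        hi = small_sweep[small_sweep["IOP (mmHg)"] == 25.0]
        assert hi["HC Def. Amp. (mm)"].mean() < lo["HC Def. Amp. (mm)"].mean()

    def test_correlation_requires_enough_rows(self, small_sweep):
        with pytest.raises(ValueError):
            correlation_matrix(small_sweep.head(4))


def test_correlation_matrix_matches_direct_formula():
    rng = np.random.default_rng(12)
    n = 40
    tab = pd.DataFrame(rng.uniform(size=(n, 4)), columns=INPUT_COLUMNS)
    for c in OUTPUT_COLUMNS:
        tab[c] = rng.uniform(size=n) + tab[INPUT_COLUMNS[0]]
    tab["failed"] = False
    ct = correlation_matrix(tab)
    # brute-force r from the definition sums
    x = tab[INPUT_COLUMNS[0]].to_numpy()
    y = tab[OUTPUT_COLUMNS[0]].to_numpy()
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2))
    assert ct.r.loc[INPUT_COLUMNS[0], OUTPUT_COLUMNS[0]] == pytest.approx(
        num / den, rel=1e-12)
    assert (ct.r.abs() <= 1.0).all().all()
    assert ((ct.p > 0) & (ct.p <= 1.0)).all().all()
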