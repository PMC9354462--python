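import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopls.transfer import (
    TransferDesign,
    ashman_d,
    ashman_d_params,
    confounder_score_correlation,
    histogram_match,
    run_transfer,
    separability_report,
)


class TestAshmanD:
    def test_identical_populations_give_zero(self, rng):
        a = rng.normal(size=50)
        assert ashman_d(a, a) == 0.0

    def test_analytic_unit_variance_separation(self):
        # means 0 and 2, unit SDs: sqrt(2)*2/sqrt(2) = 2, the
        # separability threshold
        assert ashman_d_params(0.0, 2.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_sample_statistic_converges_to_analytic(self):
        rng = np.random.default_rng(123)
        a = rng.normal(0.0, 1.0, size=200_000)
        b = rng.normal(2.0, 1.0, size=200_000)
        assert ashman_d(a, b) == pytest.approx(2.0, abs=0.01)

    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=20)
        b = rng.normal(1.0, 2.0, size=30)
        assert ashman_d(a, b) == pytest.approx(ashman_d(b, a))
        assert ashman_d(c * a, c * b) == pytest.approx(ashman_d(a, b),
                                                       rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ashman_d([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            ashman_d([1.0, 1.0], [2.0, 2.0])


class TestHistogramMatch:
    def test_forced_small_example(self):
        large = pd.DataFrame({"t": [1.0, 1.0, 2.0, 2.0, 2.0]},
                             index=[f"m{i}" for i in range(5)])
        small = pd.DataFrame({"t": [1.0, 2.0, 2.0]},
                             index=[f"f{i}" for i in range(3)])
        kept = histogram_match(large, small, "t", bin_width=1.0,
                               rng=np.random.default_rng(0))
        vals = large.loc[kept, "t"]
        assert (vals == 1.0).sum() == 1 and (vals == 2.0).sum() == 2

    def test_identical_distributions_keep_per_bin_counts(self, rng):
        v = rng.uniform(0, 100, size=40)
        large = pd.DataFrame({"t": v}, index=[f"m{i}" for i in range(40)])
        small = pd.DataFrame({"t": v}, index=[f"f{i}" for i in range(40)])
        kept = histogram_match(large, small, "t", bin_width=10.0, rng=rng)
        assert len(kept) == 40

    def test_per_bin_counts_match_binning_oracle(self, rng):
        large = pd.DataFrame({"t": rng.uniform(0, 60, size=120)},
                             index=[f"m{i}" for i in range(120)])
        small = pd.DataFrame({"t": rng.uniform(0, 60, size=50)},
                             index=[f"f{i}" for i in range(50)])
        bw = 7.5
        kept = histogram_match(large, small, "t", bin_width=bw, rng=rng)
        lo = min(large["t"].min(), small["t"].min())
        hi = max(large["t"].max(), small["t"].max())
        edges = np.arange(lo, hi + 2 * bw, bw)
        ck, _ = np.histogram(large.loc[kept, "t"], bins=edges)
        cl, _ = np.histogram(large["t"], bins=edges)
        cs, _ = np.histogram(small["t"], bins=edges)
        np.testing.assert_array_equal(ck, np.minimum(cl, cs))

    def test_disjoint_ranges_rejected(self):
        large = pd.DataFrame({"t": [1.0, 2.0]}, index=["a", "b"])
        small = pd.DataFrame({"t": [50.0, 60.0]}, index=["c", "d"])
        with pytest.raises(ValueError, match="overlap"):
            histogram_match(large, small, "t", bin_width=1.0)


class TestRunTransfer:
    def test_same_seed_identical_result(self, null_blocks):
        X, Y, meta = null_blocks
        td = TransferDesign(design="original", n_runs=5)
        a = run_transfer(X, Y, meta, td, seed=9)
        b = run_transfer(X, Y, meta, td, seed=9)
        for s in a.errors:
            np.testing.assert_array_equal(a.errors[s], b.errors[s])
        pd.testing.assert_series_equal(a.ashman, b.ashman)

    def test_null_mixed_design_centred_errors(self, null_blocks):
        """With identical male/female generative processes the mixed
        design yields near-zero error means and low Ashman's D."""
        X, Y, meta = null_blocks
        res = run_transfer(X, Y, meta,
                           TransferDesign(design="mixed", n_runs=60),
                           seed=5)
        s = res.error_summary()
        assert (s["mean_error"].abs() <= 2 * s["se_mean"]).all()
        assert (res.ashman < 1.0).all()

    def test_planted_effect_recovered_with_direction(self, panel):
        """A weakened repressive coupling in females raises female
        expression of the target; a male-trained model under-predicts it
        (negative prediction - actual) and flags it with the largest D."""
        from conftest import preprocess_cohort
        from cardiopls.simulate import SyntheticSpec

        spec = SyntheticSpec(seed=3, confounder_effect={})
        clr, meta, truth = preprocess_cohort(spec, panel)
        (target,) = truth.sex_delta
        res = run_transfer(clr.block(panel.modifier_genes),
                           clr.block(panel.ic_genes), meta,
                           TransferDesign(design="original", n_runs=60),
                           seed=7)
        s = res.error_summary()
        row = s[(s.gene == target) & (s.stratum == "female")].iloc[0]
        assert row.mean_error < -2 * row.se_mean
        assert res.ashman.idxmax() == target
        report = separability_report(res, threshold=1.0)
        flagged = set(report.loc[report.separable, "gene"])
        assert flagged == {target}

    def test_error_vector_sizes(self, null_blocks):
        X, Y, meta = null_blocks
        n_runs = 4
        td = TransferDesign(design="original", n_runs=n_runs)
        res = run_transfer(X, Y, meta, td, seed=1)
        n_female = int((meta["sex"] == "female").sum())
        n_hold = round(0.1 * td.n_train)
        assert res.errors["female"].shape == (n_runs * n_female, Y.shape[1])
        assert res.errors["male"].shape == (n_runs * n_hold, Y.shape[1])

    def test_insufficient_stratum_rejected(self, null_blocks):
        X, Y, meta = null_blocks
        td = TransferDesign(design="original", n_train=10_000)
        with pytest.raises(ValueError, match="n_train"):
            run_transfer(X, Y, meta, td, seed=0)


class TestSeparabilityReport:
    def test_threshold_zero_flags_everything(self, null_blocks):
        X, Y, meta = null_blocks
        res = run_transfer(X, Y, meta,
                           TransferDesign(design="original", n_runs=3),
                           seed=2)
        rep = separability_report(res, threshold=0.0)
        assert rep["separable"].all()
        rep2 = separability_report(res, threshold=np.inf)
        assert not rep2["separable"].any()


def test_confounder_score_correlation_detects_planted_covariate(
        panel, default_cohort):
    from cardiopls.pls import PLS

    clr, meta, truth = default_cohort
    res = PLS.from_clr(clr, panel, "modifier", "IC", n_components=4).fit()
    table = confounder_score_correlation(res.x_scores, meta)
    assert set(table.columns) >= {"age", "bmi", "ischemic_time"}
    assert table.shape[0] == 4
    assert np.isfinite(table.to_numpy()).all()
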