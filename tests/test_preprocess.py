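import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopls.matrixio import ExpressionMatrix
from cardiopls.preprocess import (
    clr_transform,
    filter_by_reference,
    geometric_mean,
    remove_score_outliers,
)
from cardiopls.simulate import SyntheticSpec, generate_cohort

positive_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1e6, allow_nan=False), min_size=1,
    max_size=20,
).map(np.array)


def _expr(values, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"s{i}" for i in range(values.shape[0])],
        columns=genes))


class TestReferenceFilter:
    def test_window_keeps_only_in_range_samples(self):
        expr = _expr([[300.0, 5.0], [1200.0, 5.0], [2600.0, 5.0]],
                     ["GAPDH", "GB"])
        kept, report = filter_by_reference(expr, "GAPDH")
        assert kept.sample_ids == ["s1"]
        assert report.reasons == {"s0": "reference_low",
                                  "s2": "reference_high"}

    def test_boundaries_are_inclusive(self):
        expr = _expr([[500.0, 1.0], [2500.0, 1.0]], ["GAPDH", "GB"])
        kept, report = filter_by_reference(expr, "GAPDH")
        assert kept.sample_ids == ["s0", "s1"]
        assert report.dropped_sample_ids == []

    def test_idempotent(self):
        expr = _expr([[700.0, 1.0], [90.0, 1.0], [1500.0, 1.0]],
                     ["GAPDH", "GB"])
        once, _ = filter_by_reference(expr, "GAPDH")
        twice, rep = filter_by_reference(once, "GAPDH")
        assert twice.sample_ids == once.sample_ids
        assert rep.dropped_sample_ids == []

    def test_errors(self):
        expr = _expr([[700.0, 1.0]], ["GAPDH", "GB"])
        with pytest.raises(KeyError):
            filter_by_reference(expr, "ACTB")
        with pytest.raises(ValueError, match="every sample"):
            filter_by_reference(expr, "GAPDH", low=100000, high=200000)


class TestGeometricMean:
    @pytest.mark.parametrize("x, expected", [
        ((1.0, 10.0, 100.0), 10.0),
        ((4.0, 4.0, 4.0), 4.0),
        ((2.0, 8.0), 4.0),
    ])
    def test_known_values(self, x, expected):
        assert geometric_mean(np.array(x)) == pytest.approx(expected)

    @given(x=positive_vectors, c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_positive_homogeneity(self, x, c):
        assert geometric_mean(c * x) == pytest.approx(
            c * geometric_mean(x), rel=1e-9)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            geometric_mean(np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            geometric_mean(np.array([-2.0, 1.0]))


class TestClrTransform:
    def test_single_sample_decades(self):
        clr = clr_transform(_expr([[1.0, 10.0, 100.0]]))
        np.testing.assert_allclose(clr.values, [[-1.0, 0.0, 1.0]],
                                   atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero_over_basis(self, seed):
        rng = np.random.default_rng(seed)
        clr = clr_transform(_expr(rng.uniform(0.01, 1e4, size=(5, 7))))
        assert np.abs(clr.values.sum(axis=1)).max() < 1e-9

    def test_invariant_to_per_sample_rescaling(self, rng):
        values = rng.uniform(0.1, 100, size=(4, 6))
        scaled = values * rng.uniform(0.5, 50, size=(4, 1))
        a = clr_transform(_expr(values))
        b = clr_transform(_expr(scaled))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_basis_subset_controls_denominator_only(self, rng):
        values = rng.uniform(0.1, 100, size=(3, 5))
        clr = clr_transform(_expr(values), basis=["G0", "G1"])
        assert clr.basis_gene_ids == ["G0", "G1"]
        # basis columns sum to zero; all columns still transformed
        assert np.abs(clr.values[:, :2].sum(axis=1)).max() < 1e-9
        assert clr.values.shape == (3, 5)

    def test_zero_policies(self):
        expr = _expr([[0.0, 10.0], [4.0, 10.0]])
        with pytest.raises(ValueError, match="s0.*G0"):
            clr_transform(expr, zero_policy="error")
        clr = clr_transform(expr, zero_policy="pseudocount")
        # zero replaced by half the smallest positive value of that gene (2.0)
        assert clr.values[0, 0] == pytest.approx(np.log10(2.0 / np.sqrt(20.0)))


class TestScoreOutliers:
    def test_planted_outlier_is_dropped_exactly(self, panel):
        spec = SyntheticSpec(seed=5, outlier_rate=1 / 242,
                             reference_out_rate=0.0)
        expr, _, truth = generate_cohort(spec, panel)
        assert len(truth.outlier_ids) == 1
        clr = clr_transform(expr, basis=list(panel.all_genes))
        kept, report = remove_score_outliers(clr, panel)
        assert report.dropped_sample_ids == truth.outlier_ids
        assert report.reasons[truth.outlier_ids[0]] == "score_outlier"

    def test_clean_cohort_untouched(self, panel):
        spec = SyntheticSpec(seed=6, outlier_rate=0.0,
                             reference_out_rate=0.0)
        expr, _, _ = generate_cohort(spec, panel)
        clr = clr_transform(expr, basis=list(panel.all_genes))
        _, report = remove_score_outliers(clr, panel)
        assert report.dropped_sample_ids == []

    def test_infinite_threshold_is_identity(self, default_cohort, panel):
        clr, _, _ = default_cohort
        kept, report = remove_score_outliers(clr, panel, k=np.inf)
        assert kept.sample_ids == clr.sample_ids
        assert report.dropped_sample_ids == []

    def test_too_few_samples(self, panel, rng):
        spec = SyntheticSpec(seed=7)
        expr, _, _ = generate_cohort(spec, panel)
        clr = clr_transform(expr, basis=list(panel.all_genes))
        tiny = clr.subset_samples(clr.sample_ids[:3])
        with pytest.raises(ValueError, match="at least"):
            remove_score_outliers(tiny, panel, n_components=2)
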