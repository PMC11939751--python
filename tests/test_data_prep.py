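"""Preparation contracts: reverse coding, filters, splits, binarization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brskit.data_prep import (
    DegenerateSplitWarning,
    binarize,
    dichotomize_outcome,
    discretize_levels,
    discretize_quantiles,
    filter_missing_variables,
    prepare,
    remove_outliers,
    reverse_code,
)
from brskit.survey import SurveyTable, VariableSpec
from brskit.synthetic_data import generate_survey

from conftest import small_specs


def _table(data: dict, specs: dict) -> SurveyTable:
    return SurveyTable(data=pd.DataFrame(data), specs=specs)


@pytest.fixture
def tiny_table():
    specs = {
        "Jobs": VariableSpec("Jobs", "ordinal", levels=(1, 2, 3, 4, 5), reverse_coded=True),
        "Sleepq": VariableSpec("Sleepq", "ordinal", levels=(1, 2, 3, 4), reverse_coded=True),
        "Selfd": VariableSpec("Selfd", "ordinal", levels=(1, 2, 3, 4), reverse_coded=True),
        "workt": VariableSpec("workt", "continuous", bounds=(0, 84)),
    }
    data = {
        "Jobs": [1, 2, 3, 4, 5, 2],
        "Sleepq": [1, 2, 3, 4, 1, 2],
        "Selfd": [2, 1, 4, 3, 2, 1],
        "workt": [10, 20, 30, 40, 50, 60],
    }
    return _table(data, specs)


class TestReverseCode:
    def test_four_point_scale_flips_one_to_four(self, tiny_table):
        out = reverse_code(tiny_table)
        # raw "very good" sleep (1) becomes the top of the construct scale (4)
        assert out.data["Sleepq"].tolist() == [4, 3, 2, 1, 4, 3]
        assert out.data["Selfd"].tolist() == [3, 4, 1, 2, 3, 4]

    def test_involution(self, tiny_table):
        twice = reverse_code(reverse_code(tiny_table))
        pd.testing.assert_frame_equal(twice.data, tiny_table.data, check_dtype=False)

    def test_non_reversed_columns_untouched(self, tiny_table):
        out = reverse_code(tiny_table)
        assert out.data["workt"].tolist() == tiny_table.data["workt"].tolist()

    def test_value_outside_levels_rejected(self, tiny_table):
        tiny_table.data.loc[0, "Sleepq"] = 9
        with pytest.raises(ValueError, match="outside declared level set"):
            reverse_code(tiny_table)


class TestFilterMissing:
    def _graded(self, n=200):
        """Fixture with per-variable missingness 0%, 7%, 12%."""
        specs = {
            "Jobs": VariableSpec("Jobs", "ordinal", levels=(1, 2, 3, 4, 5)),
            "a": VariableSpec("a", "continuous", bounds=(0, 1)),
            "b": VariableSpec("b", "continuous", bounds=(0, 1)),
        }
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "Jobs": rng.integers(1, 6, n).astype(float),
            "a": rng.random(n),
            "b": rng.random(n),
        })
        df.loc[: int(0.07 * n) - 1, "a"] = np.nan
        df.loc[: int(0.12 * n) - 1, "b"] = np.nan
        return SurveyTable(data=df, specs=specs)

    def test_no_missing_is_identity(self, tiny_table):
        out = filter_missing_variables(tiny_table, 0.10)
        pd.testing.assert_frame_equal(out.data, tiny_table.data)

    def test_variable_over_threshold_dropped_then_listwise(self):
        t = self._graded()
        out = filter_missing_variables(t, 0.10)
        assert "b" not in out.data.columns and "a" in out.data.columns
        assert not out.data.isna().any().any()

    def test_stricter_threshold_drops_superset(self):
        t = self._graded()
        kept_10 = set(filter_missing_variables(t, 0.10).data.columns)
        kept_05 = set(filter_missing_variables(t, 0.05).data.columns)
        assert kept_05 <= kept_10

    def test_outcome_over_threshold_is_fatal(self):
        t = self._graded()
        t.data.loc[: 50, "Jobs"] = np.nan
        with pytest.raises(ValueError, match="Jobs"):
            filter_missing_variables(t, 0.10)


class TestRemoveOutliers:
    def test_boundary_84_retained_85_removed(self):
        specs = {"workt": VariableSpec("workt", "continuous", bounds=(0, 200))}
        t = _table({"workt": [84.0, 85.0, 40.0]}, specs)
        out = remove_outliers(t)
        assert out.data["workt"].tolist() == [84.0, 40.0]

    def test_all_valid_is_identity(self, tiny_table):
        out = remove_outliers(tiny_table)
        pd.testing.assert_frame_equal(out.data, tiny_table.data)

    def test_transform_log_records_count(self):
        specs = {"workt": VariableSpec("workt", "continuous", bounds=(0, 200))}
        t = _table({"workt": [100.0, 90.0, 40.0]}, specs)
        out = remove_outliers(t)
        assert out.log[-1] == {"op": "remove_outliers", "rows_removed": 2}


class TestDichotomize:
    def test_hand_computed_example(self):
        labels, cutoff = dichotomize_outcome([1, 2, 2, 3, 5])
        v = np.array([1, 2, 2, 3, 5], dtype=float)
        assert cutoff == pytest.approx(v.mean() + v.std(ddof=1))
        assert labels.tolist() == [0, 0, 0, 0, 1]

    def test_constant_vector_all_zero_with_warning(self):
        with pytest.warns(DegenerateSplitWarning):
            labels, _ = dichotomize_outcome([3, 3, 3, 3])
        assert labels.tolist() == [0, 0, 0, 0]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=3, max_size=30),
        st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    def test_shift_invariance(self, values, c):
        base, _ = dichotomize_outcome(values)
        shifted, _ = dichotomize_outcome(np.asarray(values, dtype=float) + c)
        np.testing.assert_array_equal(base, shifted)


class TestDiscretize:
    def test_one_to_nine_cutpoints_and_bins(self):
        bins, (q1, q2) = discretize_quantiles(np.arange(1, 10))
        # type-7 quantiles of 1..9 at 1/3 and 2/3 are 3.67 and 6.33; the
        # resulting membership is {1,2,3} / {4,5,6} / {7,8,9}
        oracle = np.quantile(np.arange(1, 10), [1 / 3, 2 / 3], method="linear")
        assert (q1, q2) == pytest.approx(tuple(oracle))
        assert bins.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_constant_vector_warns_and_bins_bottom(self):
        with pytest.warns(DegenerateSplitWarning):
            bins, _ = discretize_quantiles(np.full(10, 7.0))
        assert (bins == 0).all()

    def test_monotone_transform_preserves_bins(self, rng):
        v = rng.normal(size=200)
        b1, _ = discretize_quantiles(v)
        b2, _ = discretize_quantiles(np.exp(v))
        np.testing.assert_array_equal(b1, b2)

    def test_ordinal_levels_split_into_contiguous_thirds(self):
        bins, parts = discretize_levels(np.array([1, 2, 3, 4, 5]), (1, 2, 3, 4, 5))
        assert parts == [[1, 2], [3, 4], [5]]
        assert bins.tolist() == [0, 0, 1, 1, 2]
        bins4, parts4 = discretize_levels(np.array([1, 2, 3, 4]), (1, 2, 3, 4))
        assert parts4 == [[1, 2], [3], [4]]
        assert bins4.tolist() == [0, 0, 1, 2]


class TestBinarize:
    @pytest.fixture
    def matrix(self, small_sim):
        table, _ = generate_survey(small_sim)
        _, m = prepare(table)
        return m

    def test_top_bin_row_has_overlapping_pattern(self, matrix):
        f = matrix.features
        top = f["workt_high"] == 1
        assert top.any()
        assert (f.loc[top, "workt_low"] == 0).all()
        assert (f.loc[top, "workt_low_or_med"] == 0).all()
        assert (f.loc[top, "workt_med_or_high"] == 1).all()

    def test_complement_identity_holds_columnwise(self, matrix):
        f = matrix.features
        for name in f.columns:
            if name.startswith("NOT_"):
                base = name[4:]
                assert ((f[name] + f[base]) == 1).all(), name

    def test_nesting_low_implies_low_or_med_high_implies_med_or_high(self, matrix):
        f = matrix.features
        for var in ("workt", "age", "Selfd", "health", "Sleepq"):
            assert (f[f"{var}_low"] <= f[f"{var}_low_or_med"]).all()
            assert (f[f"{var}_high"] <= f[f"{var}_med_or_high"]).all()

    def test_no_missing_entries_and_outcome_excluded(self, matrix):
        assert not matrix.features.isna().any().any()
        assert not any(c.startswith("Jobs") for c in matrix.features.columns)

    def test_binarize_requires_complete_table(self, tiny_table):
        tiny_table.data.loc[0, "workt"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            binarize(tiny_table, outcome_name="Jobs")


def test_filter_chain_is_idempotent():
    """Variable filter -> outlier removal -> listwise, run twice == once."""
    specs = small_specs()
    table, _ = generate_survey(
        __import__("brskit").SimulationConfig(n=300, seed=8, variables=specs)
    )
    from brskit.synthetic_data import inject_missingness, inject_outliers

    t = inject_outliers(inject_missingness(table, {"age": 0.15}, 1), 0.05, 2)

    def chain(x):
        x = filter_missing_variables(x, 0.10)
        return remove_outliers(x)

    once = chain(t)
    twice = chain(once)
    pd.testing.assert_frame_equal(once.data, twice.data)
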