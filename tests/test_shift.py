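import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirqc import (
    chi_square_independence,
    compare_methods_shift,
    migration_from_groups,
    migration_table,
)
from mirqc.errors import DegenerateTableError, ValidationError

# Published stratum counts (low, medium, high) per extraction method.
FFPE = [125, 141, 118]
MIRVANA = [96, 122, 166]
TRIZOL = [90, 122, 172]


def brute_force_chi2(table):
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestChiSquareIndependence:
    @pytest.mark.parametrize(
        "cols,expected",
        [
            ((TRIZOL, FFPE), 17.1255),
            ((MIRVANA, FFPE), 13.2907),
            ((TRIZOL, MIRVANA), 0.3001),
        ],
    )
    def test_extraction_method_tables(self, cols, expected):
        table = np.column_stack(cols)
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(expected, abs=1e-3)
        assert res.df == 2

    def test_identical_columns_give_zero_statistic(self):
        res = chi_square_independence(np.column_stack([TRIZOL, TRIZOL]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 50, size=(3, rng.integers(2, 4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = chi_square_independence(table)
        assert res.statistic == pytest.approx(brute_force_chi2(table), abs=1e-10)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_invariant_under_column_permutation_and_transpose(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(5, 60, size=(3, 3))
        base = chi_square_independence(table).statistic
        perm = table[:, rng.permutation(3)]
        assert chi_square_independence(perm).statistic == pytest.approx(base)
        assert chi_square_independence(table.T).statistic == pytest.approx(base)

    def test_p_monotone_decreasing_in_statistic(self):
        from mirqc.shift import chi_square_upper_tail

        ps = [chi_square_upper_tail(s, 2) for s in (0.1, 1.0, 5.0, 17.5, 40.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_upper_tail_matches_reference_implementation(self):
        from mirqc.shift import chi_square_upper_tail

        for df in (1, 2, 4, 6):
            for s in (0.0, 0.3, 3.3, 12.7, 17.5, 50.0):
                assert chi_square_upper_tail(s, df) == pytest.approx(
                    stats.chi2.sf(s, df), abs=1e-12
                )

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTableError):
            chi_square_independence(np.array([[0, 0], [5, 3], [2, 1]]))
        with pytest.raises(DegenerateTableError):
            chi_square_independence(np.array([[0, 5], [0, 3], [0, 1]]))

    def test_small_expected_counts_warn_not_abort(self):
        with pytest.warns(UserWarning, match="expected cell count"):
            res = chi_square_independence(np.array([[2, 1], [3, 2], [50, 60]]))
        assert res.n_small_expected > 0

    def test_agrees_with_scipy_contingency(self):
        table = np.column_stack([TRIZOL, FFPE])
        ours = chi_square_independence(table)
        ref = stats.chi2_contingency(table, correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestCompareMethodsShift:
    def test_identical_groups_show_no_shift(self, clinical_study):
        matrix, _ = clinical_study
        conds = [c.condition_id for c in matrix.conditions
                 if c.tissue_source == "frozen"]
        _, res = compare_methods_shift(matrix, conds, conds)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_low_input_loses_high_abundance_mirs(self, conc_study):
        matrix, _ = conc_study
        table, res = compare_methods_shift(
            matrix,
            ["conc10-r1", "conc10-r2"],
            ["conc200-r1", "conc200-r2"],
            labels=("10ng", "200ng"),
        )
        assert table.at["high", "200ng"] > table.at["high", "10ng"]
        assert res.p < 0.01

    def test_ffpe_counts_shift_toward_low_abundance(self, clinical_study):
        matrix, _ = clinical_study
        ffpe = [c.condition_id for c in matrix.conditions
                if c.tissue_source == "FFPE"]
        froz = [c.condition_id for c in matrix.conditions
                if c.tissue_source == "frozen"]
        table, res = compare_methods_shift(
            matrix, froz, ffpe, labels=("frozen", "FFPE")
        )
        assert res.df == 2
        assert table.at["low", "FFPE"] > table.at["low", "frozen"]
        assert table.at["high", "FFPE"] < table.at["high", "frozen"]
        assert res.statistic > 0


class TestMigrationTable:
    def test_identical_inputs_are_diagonal(self):
        cts = pd.Series([25.0, 32.0, 38.0], index=list("abc"))
        table = migration_table(cts, cts)
        assert table.to_numpy().sum() == 3
        assert np.trace(table.to_numpy()) == 3

    def test_uniform_upward_shift_moves_mass_to_lower_abundance(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.uniform(24, 33.9, 100),
                      index=[f"m{i}" for i in range(100)])
        table = migration_table(a, a + 6.0)
        arr = table.to_numpy()  # rows: stratum under A (low, medium, high)
        # no assay may become MORE abundant under B
        assert arr[0, 1] == 0 and arr[0, 2] == 0 and arr[1, 2] == 0
        assert arr[1, 0] + arr[2, 1] + arr[2, 0] > 0

    def test_grand_total_counts_shared_assays(self):
        a = pd.Series([25.0, 30.0], index=["x", "y"])
        b = pd.Series([26.0, 39.0, 20.0], index=["x", "y", "z"])
        table = migration_table(a, b)
        assert table.to_numpy().sum() == 2

    def test_no_shared_assays_raises(self):
        with pytest.raises(ValidationError):
            migration_table(
                pd.Series([25.0], index=["a"]), pd.Series([25.0], index=["b"])
            )

    def test_ffpe_migration_is_asymmetric_toward_low_abundance(self, clinical_study):
        matrix, _ = clinical_study
        ffpe = [c.condition_id for c in matrix.conditions
                if c.tissue_source == "FFPE"]
        froz = [c.condition_id for c in matrix.conditions
                if c.tissue_source == "frozen"]
        table = migration_from_groups(
            matrix, froz, ffpe, labels=("frozen", "FFPE")
        )
        # high in frozen but medium in FFPE must outnumber the reverse
        assert table.at["high", "medium"] > table.at["medium", "high"]
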