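"""Abundance-shift contingency analysis.

When a treatment (lower RNA input, FFPE fixation, a different extraction
chemistry) reduces effective template, microRNAs migrate between abundance
strata — fewer high-abundance, more low-abundance calls.  This module
builds stratum-count contingency tables across condition groups, tests
them with the Pearson chi-square test of independence, and cross-tabulates
per-assay stratum migration between two methods.

The statistic is the classic ``sum((O - E)^2 / E)`` with
``E = row_total * column_total / grand_total``, no continuity correction
(the tables here are 3x2 / 3x3; Yates' correction is a 2x2 device).  The
p-value is the chi-square upper tail, computed through the regularised
incomplete gamma function ``Q(df/2, x/2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import DegenerateTableError, ValidationError
from .io import CtMatrix
from .strata import STRATUM_ORDER, StratumCutoffs, assign_strata, stratum_counts

__all__ = [
    "ChiSquareResult",
    "chi_square_independence",
    "compare_methods_shift",
    "migration_table",
    "migration_from_groups",
]

EXPECTED_COUNT_WARN = 5.0


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    n_small_expected: int = 0  # cells with expected count < 5 (asymptotics weak)


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """P(Chi2_df >= statistic) via the regularised incomplete gamma function."""
    if statistic < 0 or df < 1:
        raise ValidationError("statistic must be >= 0 and df >= 1")
    return float(special.gammaincc(df / 2.0, statistic / 2.0))


def _as_table(table) -> tuple[np.ndarray, list, list]:
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        return arr, list(table.index), list(table.columns)
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on a counts table.

    Accepts a DataFrame (strata x groups) or any 2-D array of nonnegative
    counts with at least 2 rows and 2 columns.  A zero row or column total
    makes expected counts degenerate and raises; expected counts below 5
    only warn (asymptotic p-values weaken, they do not break).
    """
    arr, rows, cols = _as_table(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table")
    if (arr < 0).any() or np.isnan(arr).any():
        raise ValidationError("counts must be nonnegative and finite")
    row_tot = arr.sum(axis=1)
    col_tot = arr.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise DegenerateTableError(
            "zero row or column total: expected counts undefined"
        )
    grand = arr.sum()
    expected = np.outer(row_tot, col_tot) / grand
    stat = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    n_small = int((expected < EXPECTED_COUNT_WARN).sum())
    if n_small:
        warnings.warn(
            f"{n_small} expected cell count(s) below {EXPECTED_COUNT_WARN:g}; "
            "the asymptotic p-value may be inaccurate",
            stacklevel=2,
        )
    return ChiSquareResult(
        statistic=stat, df=df, p=chi_square_upper_tail(stat, df),
        n_small_expected=n_small,
    )


def compare_methods_shift(
    matrix: CtMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoffs: StratumCutoffs = StratumCutoffs(),
    aggregation: Literal["per_sample_average", "mean_ct"] = "per_sample_average",
    labels: tuple[str, str] = ("A", "B"),
    include_censored: bool = True,
) -> tuple[pd.DataFrame, ChiSquareResult]:
    """Stratum-count table for two condition groups plus its chi-square test."""
    table = stratum_counts(
        matrix,
        {labels[0]: list(group_a), labels[1]: list(group_b)},
        cutoffs=cutoffs,
        aggregation=aggregation,
        include_censored=include_censored,
    )
    return table, chi_square_independence(table)


def migration_table(
    mean_ct_a: pd.Series,
    mean_ct_b: pd.Series,
    cutoffs: StratumCutoffs = StratumCutoffs(),
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Cross-tabulate each assay's stratum under method A vs method B.

    Rows are strata under A, columns strata under B (low/medium/high
    order).  Off-diagonal cells count assays whose abundance call migrated;
    asymmetry between mirrored cells (e.g. high->medium vs medium->high)
    is the signature of a directional shift.  Assays lacking a mean Ct
    under either method are dropped.
    """
    shared = mean_ct_a.index.intersection(mean_ct_b.index)
    if len(shared) == 0:
        raise ValidationError("no shared assays between the two methods")
    sa = assign_strata(mean_ct_a.loc[shared], cutoffs)
    sb = assign_strata(mean_ct_b.loc[shared], cutoffs)
    keep = sa.notna() & sb.notna()
    out = pd.DataFrame(
        0,
        index=pd.Index(STRATUM_ORDER, name=labels[0]),
        columns=pd.Index(STRATUM_ORDER, name=labels[1]),
        dtype=int,
    )
    cross = pd.crosstab(sa[keep], sb[keep])
    for r in cross.index:
        for c in cross.columns:
            out.at[r, c] = int(cross.at[r, c])
    return out


def migration_from_groups(
    matrix: CtMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoffs: StratumCutoffs = StratumCutoffs(),
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Migration table from per-assay mean Cts of two condition groups
    (censored wells enter the means at 40)."""
    vals = matrix.mir_values()
    return migration_table(
        vals[list(group_a)].mean(axis=1),
        vals[list(group_b)].mean(axis=1),
        cutoffs=cutoffs,
        labels=labels,
    )
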