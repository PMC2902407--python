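"""Pearson concordance between conditions, overall and by abundance stratum.

Replicate concordance on qPCR arrays is dominated by template abundance:
duplicate plates correlate near-perfectly among high-abundance microRNAs
and poorly near the detection limit.  The central operation here therefore
stratifies each microRNA once — by its mean Ct across the compared
conditions — and reports all pairwise Pearson correlations within each
stratum.

p-values follow the asymptotic t-distribution:
``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom
(two-sided); |r| = 1 maps to p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyGroupError, UndefinedCorrelationError, ValidationError
from .io import CT_CEILING, CtMatrix
from .strata import STRATUM_ORDER, StratumCutoffs, assign_strata

__all__ = [
    "CorrelationResult",
    "StratifiedCorrelations",
    "CtSummary",
    "PairedDifference",
    "pearson_correlation",
    "stratified_pairwise_correlations",
    "summarize_ct",
    "paired_group_difference",
]

CensorPolicy = Literal["exclude_any_40", "include"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    n_dropped: int = 0
    stratum: str | None = None


def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_correlation(
    x,
    y,
    censor_policy: CensorPolicy = "exclude_any_40",
    stratum: str | None = None,
) -> CorrelationResult:
    """Pearson r between two paired Ct vectors.

    Pairs with a missing value are always dropped (pairwise-complete);
    under the default censor policy pairs where either value sits at the
    40-cycle ceiling are dropped too — a censored Ct is a detection bound,
    not a measurement.  ``include`` keeps them at 40.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if censor_policy == "exclude_any_40":
        keep &= (x < CT_CEILING) & (y < CT_CEILING)
    elif censor_policy != "include":
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    n_dropped = int((~keep).sum())
    xs, ys = x[keep], y[keep]
    n = len(xs)
    if n < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete pairs after filtering, got {n}"
        )
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("zero variance in a vector")
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(r=r, n=n, p=_pearson_p(r, n), n_dropped=n_dropped,
                             stratum=stratum)


@dataclass
class StratifiedCorrelations:
    """All pairwise correlations between conditions within each stratum.

    ``table`` has one row per (condition_a, condition_b, stratum);
    ``strata`` maps each microRNA to the single stratum it was assigned by
    its mean Ct across the compared conditions; ``skipped`` records strata
    (or stratum/pair combinations) that were not computable and why.
    """

    table: pd.DataFrame
    strata: pd.Series
    skipped: dict[str, str]

    def grid(self, stratum: str) -> pd.DataFrame:
        """Square condition x condition frame of r for one stratum."""
        sub = self.table[self.table["stratum"] == stratum]
        conds = sorted(set(sub["condition_a"]) | set(sub["condition_b"]))
        g = pd.DataFrame(np.nan, index=conds, columns=conds)
        for row in sub.itertuples(index=False):
            g.at[row.condition_a, row.condition_b] = row.r
            g.at[row.condition_b, row.condition_a] = row.r
        np.fill_diagonal(g.values, 1.0)
        return g


def stratified_pairwise_correlations(
    matrix: CtMatrix,
    conditions: Sequence[str],
    cutoffs: StratumCutoffs = StratumCutoffs(),
    censor_policy: CensorPolicy = "exclude_any_40",
    min_assays: int = 3,
) -> StratifiedCorrelations:
    """Stratify each microRNA by its mean Ct, then correlate within strata.

    Each assay is assigned exactly one stratum from its mean Ct across the
    listed conditions (censored wells entering at 40), so strata partition
    the assay set.  Strata retaining fewer than ``min_assays`` assays are
    flagged in ``skipped`` rather than aborting the rest.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise EmptyGroupError("need at least two conditions")
    vals = matrix.mir_values()[conditions]
    mean_ct = vals.mean(axis=1)
    strata = assign_strata(mean_ct, cutoffs)
    rows = []
    skipped: dict[str, str] = {}
    for stratum in STRATUM_ORDER:
        ids = strata.index[strata == stratum]
        if len(ids) < min_assays:
            skipped[stratum] = (
                f"only {len(ids)} assays assigned (need >= {min_assays})"
            )
            continue
        sub = vals.loc[ids]
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1:]:
                try:
                    res = pearson_correlation(
                        sub[ca], sub[cb], censor_policy, stratum=stratum
                    )
                except UndefinedCorrelationError as e:
                    skipped[f"{stratum}:{ca}|{cb}"] = str(e)
                    continue
                rows.append(
                    (ca, cb, stratum, res.r, res.n, res.p, res.n_dropped)
                )
    table = pd.DataFrame(
        rows,
        columns=["condition_a", "condition_b", "stratum", "r", "n", "p",
                 "n_dropped"],
    )
    return StratifiedCorrelations(table=table, strata=strata, skipped=skipped)


@dataclass(frozen=True)
class CtSummary:
    group: str
    n: int
    mean_ct: float
    sd_ct: float
    min_ct: float
    max_ct: float


def summarize_ct(
    matrix: CtMatrix,
    groups: Mapping[str, Sequence[str]],
    include_censored: bool = True,
) -> pd.DataFrame:
    """Mean/SD/range of raw Ct values per condition group.

    Censored wells enter at 40 by default (the raw score the instrument
    reports); ``include_censored=False`` drops them.  One row per group.
    """
    rows = []
    for label, conds in groups.items():
        conds = list(conds)
        if not conds:
            raise EmptyGroupError(f"group {label!r} is empty")
        sub = matrix.mir_values()[conds]
        if not include_censored:
            sub = sub.mask(matrix.mir_censored()[conds])
        flat = sub.to_numpy(float).ravel()
        flat = flat[~np.isnan(flat)]
        if flat.size == 0:
            raise EmptyGroupError(f"group {label!r} has no measurements")
        rows.append(
            CtSummary(
                group=label,
                n=int(flat.size),
                mean_ct=float(flat.mean()),
                sd_ct=float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                min_ct=float(flat.min()),
                max_ct=float(flat.max()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class PairedDifference:
    """Paired mean Ct difference (group_a - group_b) with a two-sided t-test.

    Computed on per-assay mean Cts within each group, paired by assay.
    """

    mean_difference: float
    t: float
    p: float
    n: int


def paired_group_difference(
    matrix: CtMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    include_censored: bool = True,
) -> PairedDifference:
    if not group_a or not group_b:
        raise EmptyGroupError("both groups must be nonempty")
    vals = matrix.mir_values()
    cen = matrix.mir_censored()
    a = vals[list(group_a)]
    b = vals[list(group_b)]
    if not include_censored:
        a = a.mask(cen[list(group_a)])
        b = b.mask(cen[list(group_b)])
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    keep = ma.notna() & mb.notna()
    d = (ma[keep] - mb[keep]).to_numpy(float)
    if d.size < 2:
        raise EmptyGroupError("fewer than 2 paired assays")
    if np.allclose(d.std(ddof=1), 0.0):
        t_stat, p = (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(ma[keep], mb[keep])
    return PairedDifference(
        mean_difference=float(d.mean()), t=float(t_stat), p=float(p), n=int(d.size)
    )
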