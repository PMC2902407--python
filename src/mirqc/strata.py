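"""Abundance stratification of Ct values and duplicate-agreement diagnostics.

Lower Ct means more template, and reproducibility of qPCR arrays is
strongly Ct-dependent: abundant targets replicate tightly while targets
near the detection limit are noisy.  Measurements are therefore divided
into three abundance strata::

    high    Ct < 30
    medium  30 <= Ct <= 35
    low     Ct > 35        (censored Ct = 40 wells fall here)

The cutoffs are configuration (:class:`StratumCutoffs`), not re-estimated
from data; the duplicate-agreement curve (:func:`duplicate_agreement` plus
:func:`fit_smoothing_spline`) is the diagnostic that motivates them — the
spread |Ct_a - Ct_b| between duplicate plates rises sharply above the
high-abundance zone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

from .errors import DomainError, EmptyGroupError, FitError, ValidationError
from .io import CT_CEILING, CtMatrix

__all__ = [
    "Stratum",
    "StratumCutoffs",
    "AgreementResult",
    "SplineFit",
    "assign_stratum",
    "assign_strata",
    "duplicate_agreement",
    "fit_smoothing_spline",
    "stratum_counts",
]

STRATUM_ORDER = ("low", "medium", "high")  # canonical row order for count tables


class Stratum(str, enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StratumCutoffs:
    """Boundaries of the abundance partition (cycles).

    ``high_below``: Ct strictly below this is high abundance (default 30).
    ``low_above``: Ct strictly above this is low abundance (default 35).
    The medium stratum is closed on both ends: [high_below, low_above].
    """

    high_below: float = 30.0
    low_above: float = 35.0

    def __post_init__(self):
        if not (0 < self.high_below < self.low_above < CT_CEILING):
            raise ValidationError(
                f"cutoffs must satisfy 0 < high_below < low_above < {CT_CEILING:g}"
            )


def assign_stratum(ct: float, cutoffs: StratumCutoffs = StratumCutoffs()) -> Stratum:
    """Stratum of a single Ct value; censored Ct = 40 lands in ``low``."""
    if not (0 < ct <= CT_CEILING):
        raise DomainError(f"Ct value {ct} outside (0, {CT_CEILING:g}]")
    if ct < cutoffs.high_below:
        return Stratum.HIGH
    if ct <= cutoffs.low_above:
        return Stratum.MEDIUM
    return Stratum.LOW


def assign_strata(
    values, cutoffs: StratumCutoffs = StratumCutoffs()
) -> pd.Series:
    """Vectorised :func:`assign_stratum`; NaN entries stay NaN.

    Accepts any array-like; returns a Series of {'high','medium','low'}
    aligned to the input index where one exists.
    """
    s = pd.Series(values, dtype=float)
    vals = s.to_numpy()
    ok = ~np.isnan(vals)
    if ok.any() and ((vals[ok] <= 0) | (vals[ok] > CT_CEILING)).any():
        raise DomainError(f"Ct values outside (0, {CT_CEILING:g}]")
    out = np.full(len(vals), None, dtype=object)
    out[ok & (vals < cutoffs.high_below)] = Stratum.HIGH.value
    out[ok & (vals >= cutoffs.high_below) & (vals <= cutoffs.low_above)] = (
        Stratum.MEDIUM.value
    )
    out[ok & (vals > cutoffs.low_above)] = Stratum.LOW.value
    return pd.Series(out, index=s.index, name="stratum")


@dataclass
class AgreementResult:
    """Duplicate-agreement points: one row per microRNA with both Ct < 40.

    ``points`` has columns ``assay_id``, ``mean_ct`` ((a+b)/2) and
    ``abs_diff`` (|a-b|); ``n_dropped`` counts pairs excluded because one
    or both wells were censored or missing.
    """

    points: pd.DataFrame
    n_dropped: int

    def __len__(self) -> int:
        return len(self.points)


def duplicate_agreement(
    matrix: CtMatrix, condition_a: str, condition_b: str
) -> AgreementResult:
    """Pair duplicate plates and compute |ΔCt| vs mean Ct per microRNA.

    Pairs where either duplicate sits at the 40-cycle ceiling are removed —
    a censored value is a bound, not a measurement, and would fabricate
    agreement at the ceiling.  Controls and blanks are excluded.
    """
    a = matrix.column(condition_a)
    b = matrix.column(condition_b)
    both = a.notna() & b.notna()
    uncensored = (a < CT_CEILING) & (b < CT_CEILING)
    keep = both & uncensored
    n_dropped = int((both & ~uncensored).sum())
    pts = pd.DataFrame(
        {
            "assay_id": a.index[keep],
            "mean_ct": (a[keep].to_numpy() + b[keep].to_numpy()) / 2.0,
            "abs_diff": np.abs(a[keep].to_numpy() - b[keep].to_numpy()),
        }
    ).reset_index(drop=True)
    return AgreementResult(points=pts, n_dropped=n_dropped)


@dataclass
class SplineFit:
    """A cubic smoothing spline of |ΔCt| on mean Ct.

    The roughness penalty ``lam`` is chosen by generalised cross-validation
    at fit time (``None`` means the fitter selected it internally without
    reporting the value); ``x_range`` is the observed mean-Ct span on which
    predictions are defined.
    """

    spline: BSpline
    lam: float | None
    x_range: tuple[float, float]
    rmse: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return np.asarray(self.spline(np.asarray(x, dtype=float)), dtype=float)

    def __call__(self, x) -> np.ndarray:
        return self.predict(x)


def fit_smoothing_spline(points: pd.DataFrame, min_points: int = 10) -> SplineFit:
    """Fit a cubic smoothing spline to duplicate-agreement points.

    ``points`` needs ``mean_ct`` and ``abs_diff`` columns (an
    :class:`AgreementResult`'s ``points`` frame works directly).  The
    roughness penalty is selected by generalised cross-validation.  Tied
    mean-Ct values are averaged before fitting.  Requires at least
    ``min_points`` distinct points spanning more than 2 cycles.
    """
    if isinstance(points, AgreementResult):
        points = points.points
    df = pd.DataFrame(points)[["mean_ct", "abs_diff"]].dropna()
    # collapse ties: smoothing-spline x must be strictly increasing
    grouped = df.groupby("mean_ct", sort=True)["abs_diff"].mean()
    x = grouped.index.to_numpy(float)
    y = grouped.to_numpy(float)
    if len(x) < min_points:
        raise FitError(f"need >= {min_points} distinct points, got {len(x)}")
    span = float(x.max() - x.min())
    if span <= 2.0:
        raise FitError(f"mean_ct span {span:.3g} cycles <= 2: too narrow to fit")
    spline = make_smoothing_spline(x, y, lam=None)  # lam=None -> GCV selection
    resid = y - spline(x)
    return SplineFit(
        spline=spline,
        lam=None,
        x_range=(float(x.min()), float(x.max())),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(x),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def stratum_counts(
    matrix: CtMatrix,
    groups: Mapping[str, Sequence[str]],
    cutoffs: StratumCutoffs = StratumCutoffs(),
    aggregation: Literal["per_sample_average", "mean_ct"] = "per_sample_average",
    include_censored: bool = True,
) -> pd.DataFrame:
    """Count microRNAs per abundance stratum for each condition group.

    ``groups`` maps a column label to the condition ids it pools.  Two
    aggregations:

    * ``per_sample_average`` — stratify every well, count per stratum per
      condition, average across the group's conditions and round half-up
      (what a per-sample-average column of a published count table shows).
    * ``mean_ct`` — average each assay's Ct across the group's conditions
      (censored wells enter at 40) and stratify the mean, so each assay
      contributes to exactly one cell.

    Censored wells count as low-abundance by default (the ceiling is the
    bottom of the detectable range); ``include_censored=False`` drops them.
    Returns a low/medium/high x group integer DataFrame.
    """
    if not groups:
        raise EmptyGroupError("no groups given")
    vals = matrix.mir_values()
    cen = matrix.mir_censored()
    out = {}
    for label, conds in groups.items():
        conds = list(conds)
        if not conds:
            raise EmptyGroupError(f"group {label!r} is empty")
        missing = [c for c in conds if c not in vals.columns]
        if missing:
            raise ValidationError(f"group {label!r}: unknown conditions {missing}")
        sub = vals[conds]
        subcen = cen[conds]
        if not include_censored:
            sub = sub.mask(subcen)
        if aggregation == "per_sample_average":
            per_cond = []
            for c in conds:
                strata = assign_strata(sub[c], cutoffs)
                counts = strata.value_counts()
                per_cond.append(
                    [float(counts.get(s, 0)) for s in STRATUM_ORDER]
                )
            avg = np.mean(np.asarray(per_cond), axis=0)
            out[label] = _round_half_up(avg)
        elif aggregation == "mean_ct":
            mean_ct = sub.mean(axis=1)  # NaN-skipping; all-missing stays NaN
            strata = assign_strata(mean_ct, cutoffs)
            counts = strata.value_counts()
            out[label] = np.array(
                [int(counts.get(s, 0)) for s in STRATUM_ORDER], dtype=int
            )
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return pd.DataFrame(out, index=list(STRATUM_ORDER))
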