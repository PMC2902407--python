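"""Well-failure classification and failure-rate statistics.

A *well failure* is an expected-positive well that never amplified within
the 40-cycle run (Ct recorded as 40).  With duplicate plates the call is
made per microRNA:

* one duplicate at 40, the other below 40  -> ``single_failure`` (1 well);
* both at 40, but the same assay amplified at another concentration of the
  same sample or in the Universal RNA positive control -> ``double_failure``
  (both wells charged, one to each plate);
* both at 40 with no reference evidence of expression -> ``not_expressed``
  (excluded from the expressed denominator — no failure charged);
* both below 40 -> ``ok``.

The summary statistic is::

    percent_failures = average well failures between duplicate plates
                       / number of microRNAs expressed * 100

For single plates (no duplicate run) a failure is any Ct = 40 among assays
known to be expressed in that sample from other runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyGroupError
from .io import CT_CEILING, CtMatrix

__all__ = [
    "FailureCall",
    "FailureSummary",
    "classify_well_failure",
    "summarize_duplicate_failures",
    "single_plate_failures",
]

CALL_OK = "ok"
CALL_SINGLE = "single_failure"
CALL_DOUBLE = "double_failure"
CALL_NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class FailureCall:
    assay_id: str
    call: str
    failure_count: int  # 0, 1 or 2 wells charged as failures


@dataclass(frozen=True)
class FailureSummary:
    """Per-condition(-pair) failure totals and the percentage statistic."""

    n_failures_plate_a: float
    n_failures_plate_b: float
    n_expressed: int
    n_skipped: int = 0  # assays with a missing well, left unclassified

    @property
    def average_failures(self) -> float:
        return (self.n_failures_plate_a + self.n_failures_plate_b) / 2.0

    @property
    def percent_failures(self) -> float:
        return self.average_failures / self.n_expressed * 100.0


def _check_ct(ct: float) -> None:
    if not (0 < ct <= CT_CEILING) or np.isnan(ct):
        raise DomainError(f"Ct value {ct} outside (0, {CT_CEILING:g}]")


def classify_well_failure(
    ct_a: float,
    ct_b: float,
    reference_cts: Iterable[float] = (),
    assay_id: str = "",
) -> FailureCall:
    """Classify one microRNA's duplicate wells.

    ``reference_cts`` are the same assay's Ct values at other concentrations
    of the same sample and in the Universal RNA positive control; they
    arbitrate the both-at-40 case.  With no references, both-at-40
    conservatively resolves to ``not_expressed``.  Symmetric in
    (ct_a, ct_b).
    """
    _check_ct(ct_a)
    _check_ct(ct_b)
    refs = [r for r in reference_cts if not (r is None or np.isnan(r))]
    for r in refs:
        _check_ct(r)
    a40 = ct_a == CT_CEILING
    b40 = ct_b == CT_CEILING
    if a40 and b40:
        if any(r < CT_CEILING for r in refs):
            return FailureCall(assay_id, CALL_DOUBLE, 2)
        return FailureCall(assay_id, CALL_NOT_EXPRESSED, 0)
    if a40 or b40:
        return FailureCall(assay_id, CALL_SINGLE, 1)
    return FailureCall(assay_id, CALL_OK, 0)


def summarize_duplicate_failures(
    matrix: CtMatrix,
    condition_a: str,
    condition_b: str,
    reference_conditions: Sequence[str] = (),
) -> tuple[FailureSummary, pd.DataFrame]:
    """Apply the duplicate failure rule across all microRNA assays.

    Returns the summary plus a per-assay report frame (``assay_id, ct_a,
    ct_b, call, failure_count``).  A ``double_failure`` charges one failure
    to each plate; blanks and endogenous controls never enter the counts.
    Assays with a missing well on either plate are skipped (counted in
    ``n_skipped``).
    """
    a = matrix.column(condition_a)
    b = matrix.column(condition_b)
    refs = {c: matrix.column(c) for c in reference_conditions}
    rows = []
    fail_a = fail_b = 0
    n_expressed = 0
    n_skipped = 0
    for aid in a.index:
        ca, cb = a[aid], b[aid]
        if np.isnan(ca) or np.isnan(cb):
            n_skipped += 1
            continue
        call = classify_well_failure(
            ca, cb, (r[aid] for r in refs.values()), assay_id=aid
        )
        rows.append((aid, ca, cb, call.call, call.failure_count))
        if call.call != CALL_NOT_EXPRESSED:
            n_expressed += 1
        if call.call == CALL_SINGLE:
            if ca == CT_CEILING:
                fail_a += 1
            else:
                fail_b += 1
        elif call.call == CALL_DOUBLE:
            fail_a += 1
            fail_b += 1
    if n_expressed == 0:
        raise EmptyGroupError(
            "no expressed microRNAs: percent failures is undefined"
        )
    report = pd.DataFrame(
        rows, columns=["assay_id", "ct_a", "ct_b", "call", "failure_count"]
    )
    return (
        FailureSummary(fail_a, fail_b, n_expressed, n_skipped),
        report,
    )


def single_plate_failures(
    matrix: CtMatrix, condition: str, expressed_assays: Iterable[str]
) -> FailureSummary:
    """Single-plate rule: a failure is Ct = 40 for any assay known expressed.

    ``expressed_assays`` comes from prior duplicate runs or other
    conditions of the same sample.  Both plate totals are set to the same
    count so ``average_failures`` equals the single-plate count.
    """
    expressed = [a for a in expressed_assays if a in set(matrix.mir_ids)]
    if not expressed:
        raise EmptyGroupError("expressed assay set is empty")
    col = matrix.column(condition)
    sub = col.loc[expressed]
    present = sub.notna()
    n_fail = int((sub[present] == CT_CEILING).sum())
    return FailureSummary(
        n_failures_plate_a=n_fail,
        n_failures_plate_b=n_fail,
        n_expressed=len(expressed),
        n_skipped=int((~present).sum()),
    )
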