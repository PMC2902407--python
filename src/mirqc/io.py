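"""Ct data containers and I/O for 384-well microfluidic qPCR arrays.

The central object is :class:`CtMatrix`: an assays x conditions grid of
cycle-threshold (Ct) values with a parallel censoring mask.  A Ct of 40 is
the instrument ceiling — the reaction ran 40 cycles without crossing the
fluorescence threshold — and is recorded as ``ct = 40, censored = True``
(the instrument software prints "Undetermined" for these wells).  Censored
values are detection bounds, not measurements, and downstream statistics
treat them accordingly.

Two CSV dialects are supported:

* ``long`` — one row per well: ``assay_id,condition_id,ct`` (canonical
  interchange format; matches instrument exports).
* ``wide`` — assays as rows, conditions as columns (spreadsheet review).

Sample metadata (tissue source, extraction method, RNA input concentration,
cDNA dilution, disease state, replicate) live in a separate CSV keyed by
``condition_id`` and attach to the matrix via :func:`read_metadata_table` /
:meth:`CtMatrix.attach_metadata`.
"""

from __future__ import annotations

import csv
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import (
    CtRangeError,
    DomainError,
    DuplicateEntryError,
    ParseError,
    ValidationError,
)

CT_CEILING = 40.0
UNDETERMINED_TOKEN = "Undetermined"

ROLE_MIR = "mir"
ROLE_CONTROL = "endogenous_control"
ROLE_BLANK = "blank"
_ROLES = (ROLE_MIR, ROLE_CONTROL, ROLE_BLANK)

TISSUE_SOURCES = ("FFPE", "frozen", "reference")
EXTRACTION_METHODS = ("RecoverAll", "mirVana", "TRIzol_Qiagen", "other")
DISEASE_STATES = ("normal", "tumour", "universal_control")

MIN_CDNA_DILUTION = 5.0


@dataclass(frozen=True)
class AssayDef:
    """One primer-probe set on the card."""

    assay_id: str
    role: str = ROLE_MIR

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValidationError(
                f"assay {self.assay_id!r}: role {self.role!r} not in {_ROLES}"
            )


@dataclass(frozen=True)
class SampleCondition:
    """One sample/condition: a plate run of a given RNA prep.

    ``input_rna_conc`` is the RNA concentration put into reverse
    transcription (ng/uL); ``cdna_dilution`` the fold-dilution of the RT
    product before PCR (the card requires at least 5x to reach loading
    volume).  ``subject_id`` links paired preparations (e.g. the FFPE and
    fresh-frozen halves of one resection specimen).
    """

    condition_id: str
    tissue_source: str = "reference"
    extraction_method: str = "other"
    disease_state: str = "universal_control"
    input_rna_conc: float = 200.0
    cdna_dilution: float = 15.0
    replicate_index: int = 1
    subject_id: str = ""

    def __post_init__(self):
        if self.tissue_source not in TISSUE_SOURCES:
            raise ValidationError(
                f"condition {self.condition_id!r}: tissue_source "
                f"{self.tissue_source!r} not in {TISSUE_SOURCES}"
            )
        if self.extraction_method not in EXTRACTION_METHODS:
            raise ValidationError(
                f"condition {self.condition_id!r}: extraction_method "
                f"{self.extraction_method!r} not in {EXTRACTION_METHODS}"
            )
        if self.disease_state not in DISEASE_STATES:
            raise ValidationError(
                f"condition {self.condition_id!r}: disease_state "
                f"{self.disease_state!r} not in {DISEASE_STATES}"
            )
        if not self.input_rna_conc > 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: input_rna_conc must be > 0"
            )
        if self.cdna_dilution < MIN_CDNA_DILUTION:
            raise ValidationError(
                f"condition {self.condition_id!r}: cdna_dilution must be "
                f">= {MIN_CDNA_DILUTION}"
            )
        if self.replicate_index < 1:
            raise ValidationError(
                f"condition {self.condition_id!r}: replicate_index must be >= 1"
            )


@dataclass(frozen=True)
class CtMeasurement:
    """A single well: Ct in (0, 40]; censored iff ct == 40."""

    assay_id: str
    condition_id: str
    ct: float
    censored: bool = False

    def __post_init__(self):
        _check_ct_range(self.ct)
        if self.censored != (self.ct == CT_CEILING):
            raise ValidationError(
                f"({self.assay_id}, {self.condition_id}): censored flag must be "
                f"True exactly when ct == {CT_CEILING:g} (got ct={self.ct}, "
                f"censored={self.censored})"
            )


def _check_ct_range(ct: float, line: int | None = None) -> None:
    if not (0 < ct <= CT_CEILING) or math.isnan(ct):
        raise CtRangeError(
            f"Ct value {ct} outside (0, {CT_CEILING:g}]"
            + (f" at line {line}" if line is not None else "")
        )


def default_layout(n_mirs: int = 365) -> list[AssayDef]:
    """The TaqMan microRNA card layout used throughout this package.

    ``n_mirs`` microRNA assays plus 3 endogenous small-nucleolar-RNA
    controls each present in two wells and two blank (no-template) wells.
    Duplicated control wells get ``-a``/``-b`` suffixes so assay ids stay
    unique.
    """
    width = len(str(n_mirs))
    assays = [AssayDef(f"miR-{i + 1:0{width}d}", ROLE_MIR) for i in range(n_mirs)]
    for ctrl in ("RNU44", "RNU48", "RNU6B"):
        assays.append(AssayDef(f"{ctrl}-a", ROLE_CONTROL))
        assays.append(AssayDef(f"{ctrl}-b", ROLE_CONTROL))
    assays.append(AssayDef("blank-a", ROLE_BLANK))
    assays.append(AssayDef("blank-b", ROLE_BLANK))
    return assays


def _infer_role(assay_id: str) -> str:
    low = assay_id.lower()
    if low.startswith("blank"):
        return ROLE_BLANK
    if low.startswith(("rnu", "sno", "u6")):
        return ROLE_CONTROL
    return ROLE_MIR


@dataclass
class CtMatrix:
    """Assays x conditions grid of Ct values with censoring flags.

    ``ct`` is a float DataFrame indexed by assay_id with condition_id
    columns; missing wells are NaN.  ``censored`` is a parallel boolean
    DataFrame (False where missing).  ``assays`` and ``conditions`` carry
    the layout roles and sample metadata in the same order as the frames.
    """

    assays: list[AssayDef]
    conditions: list[SampleCondition]
    ct: pd.DataFrame
    censored: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.censored is None:
            self.censored = self.ct == CT_CEILING
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        assay_ids = [a.assay_id for a in self.assays]
        cond_ids = [c.condition_id for c in self.conditions]
        if len(set(assay_ids)) != len(assay_ids):
            raise ValidationError("duplicate assay_id in layout")
        if len(set(cond_ids)) != len(cond_ids):
            raise ValidationError("duplicate condition_id in study")
        if list(self.ct.index) != assay_ids or list(self.ct.columns) != cond_ids:
            raise ValidationError("ct frame index/columns do not match layout")
        if self.censored.shape != self.ct.shape:
            raise ValidationError("censored mask shape mismatch")
        vals = self.ct.to_numpy(float)
        present = ~np.isnan(vals)
        if present.any():
            pv = vals[present]
            if (pv <= 0).any() or (pv > CT_CEILING).any():
                raise CtRangeError(
                    f"stored Ct values must lie in (0, {CT_CEILING:g}]"
                )
        cen = self.censored.to_numpy(bool)
        if (cen & ~present).any():
            raise ValidationError("censored flag set on a missing well")
        if ((vals == CT_CEILING) != (cen & present))[present].any():
            raise ValidationError(
                f"censored must be True exactly where ct == {CT_CEILING:g}"
            )

    # -- convenience views --------------------------------------------------
    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def mir_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays if a.role == ROLE_MIR]

    def roles(self) -> pd.Series:
        return pd.Series({a.assay_id: a.role for a in self.assays}, name="role")

    def condition(self, condition_id: str) -> SampleCondition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def column(self, condition_id: str, mir_only: bool = True) -> pd.Series:
        col = self.ct[condition_id]
        return col.loc[self.mir_ids] if mir_only else col

    def censored_column(self, condition_id: str, mir_only: bool = True) -> pd.Series:
        col = self.censored[condition_id]
        return col.loc[self.mir_ids] if mir_only else col

    def mir_values(self) -> pd.DataFrame:
        """Ct frame restricted to microRNA assays (controls/blanks dropped)."""
        return self.ct.loc[self.mir_ids]

    def mir_censored(self) -> pd.DataFrame:
        return self.censored.loc[self.mir_ids]

    def n_measurements(self) -> int:
        return int(self.ct.notna().to_numpy().sum())

    # -- construction -------------------------------------------------------
    @classmethod
    def from_measurements(
        cls,
        measurements: Iterable[CtMeasurement],
        assays: Sequence[AssayDef] | None = None,
        conditions: Sequence[SampleCondition] | None = None,
    ) -> "CtMatrix":
        ms = list(measurements)
        seen: set[tuple[str, str]] = set()
        for m in ms:
            key = (m.assay_id, m.condition_id)
            if key in seen:
                raise DuplicateEntryError(
                    f"duplicate measurement for assay {m.assay_id!r}, "
                    f"condition {m.condition_id!r}"
                )
            seen.add(key)
        if assays is None:
            order: dict[str, None] = {}
            for m in ms:
                order.setdefault(m.assay_id, None)
            assays = [AssayDef(a, _infer_role(a)) for a in order]
        if conditions is None:
            corder: dict[str, None] = {}
            for m in ms:
                corder.setdefault(m.condition_id, None)
            conditions = [SampleCondition(c) for c in corder]
        aidx = [a.assay_id for a in assays]
        cidx = [c.condition_id for c in conditions]
        ct = pd.DataFrame(np.nan, index=aidx, columns=cidx, dtype=float)
        cen = pd.DataFrame(False, index=aidx, columns=cidx, dtype=bool)
        for m in ms:
            if m.assay_id not in ct.index:
                raise ValidationError(f"measurement for unknown assay {m.assay_id!r}")
            if m.condition_id not in ct.columns:
                raise ValidationError(
                    f"measurement for unknown condition {m.condition_id!r}"
                )
            ct.at[m.assay_id, m.condition_id] = m.ct
            cen.at[m.assay_id, m.condition_id] = m.censored
        return cls(list(assays), list(conditions), ct, cen)

    def attach_metadata(self, conditions: Sequence[SampleCondition]) -> "CtMatrix":
        """Return a copy with sample metadata replacing the placeholders."""
        by_id = {c.condition_id: c for c in conditions}
        missing = [c for c in self.condition_ids if c not in by_id]
        if missing:
            raise ValidationError(f"metadata missing for conditions: {missing}")
        new = [by_id[c] for c in self.condition_ids]
        return CtMatrix(list(self.assays), new, self.ct.copy(), self.censored.copy())

    def subset_assays(self, assay_ids: Sequence[str]) -> "CtMatrix":
        keep = set(assay_ids)
        assays = [a for a in self.assays if a.assay_id in keep]
        ids = [a.assay_id for a in assays]
        return CtMatrix(
            assays,
            list(self.conditions),
            self.ct.loc[ids].copy(),
            self.censored.loc[ids].copy(),
        )

    def subset_conditions(self, condition_ids: Sequence[str]) -> "CtMatrix":
        keep = set(condition_ids)
        conds = [c for c in self.conditions if c.condition_id in keep]
        ids = [c.condition_id for c in conds]
        return CtMatrix(
            list(self.assays), conds, self.ct[ids].copy(), self.censored[ids].copy()
        )

    def equals(self, other: "CtMatrix") -> bool:
        return (
            self.assays == other.assays
            and self.conditions == other.conditions
            and self.ct.equals(other.ct)
            and self.censored.equals(other.censored)
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_ct_token(token: str, line: int) -> tuple[float, bool]:
    token = token.strip()
    if token.lower() == UNDETERMINED_TOKEN.lower():
        return CT_CEILING, True
    try:
        ct = float(token)
    except ValueError:
        raise ParseError(f"unparseable Ct value {token!r}", line) from None
    _check_ct_range(ct, line)
    return ct, ct == CT_CEILING


def _as_text_stream(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists() or isinstance(source, Path):
            return open(p, "r", newline="")
        return _io.StringIO(source)  # raw CSV text
    return source


def read_ct_table(
    source: str | Path | TextIO,
    dialect: Literal["long", "wide"] = "long",
    assays: Sequence[AssayDef] | None = None,
    conditions: Sequence[SampleCondition] | None = None,
) -> CtMatrix:
    """Read a Ct CSV in the ``long`` or ``wide`` dialect.

    ``source`` may be a path, an open text stream, or a raw CSV string.
    "Undetermined" (case-insensitive) and the literal value 40 both map to
    ``ct=40, censored=True``; values above 40 are a range error, never
    clamped.  Empty cells in the wide dialect are missing wells.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    stream = _as_text_stream(source)
    reader = csv.reader(stream)
    try:
        header = next(reader, None)
        if header is None:
            raise ParseError("empty input: no header row", 1)
        measurements: list[CtMeasurement] = []
        if dialect == "long":
            if len(header) < 3:
                raise ParseError(
                    "long dialect needs header assay_id,condition_id,ct", 1
                )
            for i, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != 3:
                    raise ParseError(f"expected 3 fields, got {len(row)}", i)
                assay_id, cond_id, token = (c.strip() for c in row)
                if not assay_id or not cond_id:
                    raise ParseError("empty assay_id or condition_id", i)
                ct, cen = _parse_ct_token(token, i)
                measurements.append(CtMeasurement(assay_id, cond_id, ct, cen))
            cond_order = None
        else:
            cond_ids = [c.strip() for c in header[1:]]
            if any(not c for c in cond_ids):
                raise ParseError("wide dialect header has an empty condition id", 1)
            for i, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != len(cond_ids) + 1:
                    raise ParseError(
                        f"expected {len(cond_ids) + 1} fields, got {len(row)}", i
                    )
                assay_id = row[0].strip()
                if not assay_id:
                    raise ParseError("empty assay_id", i)
                for cond_id, token in zip(cond_ids, row[1:]):
                    if not token.strip():
                        continue  # missing well
                    ct, cen = _parse_ct_token(token, i)
                    measurements.append(CtMeasurement(assay_id, cond_id, ct, cen))
            cond_order = cond_ids
    finally:
        if isinstance(source, (str, Path)) and stream is not None:
            stream.close()

    if conditions is None and cond_order is not None:
        conditions = [SampleCondition(c) for c in cond_order]
    return CtMatrix.from_measurements(measurements, assays, conditions)


def _format_ct(ct: float, censored: bool) -> str:
    if censored:
        return UNDETERMINED_TOKEN
    return repr(float(ct))


def write_ct_table(
    matrix: CtMatrix,
    dest: str | Path | TextIO | None = None,
    dialect: Literal["long", "wide"] = "long",
) -> str:
    """Serialise a matrix to CSV; returns the text (and writes to ``dest``).

    Round-trips exactly: ``read_ct_table(write_ct_table(m), d)`` reproduces
    ``m``'s values and censoring flags (censored wells become
    "Undetermined" in the long dialect; 40 in the wide dialect means the
    same thing on re-read).
    """
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    if dialect == "long":
        w.writerow(["assay_id", "condition_id", "ct"])
        for aid in matrix.assay_ids:
            for cid in matrix.condition_ids:
                v = matrix.ct.at[aid, cid]
                if pd.isna(v):
                    continue
                w.writerow([aid, cid, _format_ct(v, bool(matrix.censored.at[aid, cid]))])
    elif dialect == "wide":
        w.writerow(["assay_id", *matrix.condition_ids])
        for aid in matrix.assay_ids:
            row = [aid]
            for cid in matrix.condition_ids:
                v = matrix.ct.at[aid, cid]
                row.append("" if pd.isna(v) else repr(float(v)))
            w.writerow(row)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


_META_FIELDS = [
    "condition_id",
    "tissue_source",
    "extraction_method",
    "disease_state",
    "input_rna_conc",
    "cdna_dilution",
    "replicate_index",
    "subject_id",
]


def read_metadata_table(source: str | Path | TextIO) -> list[SampleCondition]:
    """Read the sample-metadata CSV (one row per condition)."""
    stream = _as_text_stream(source)
    try:
        df = pd.read_csv(stream, dtype=str).fillna("")
    finally:
        if isinstance(source, (str, Path)):
            stream.close()
    missing = [f for f in _META_FIELDS[:7] if f not in df.columns]
    if missing:
        raise ParseError(f"metadata missing columns: {missing}", 1)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                SampleCondition(
                    condition_id=d["condition_id"],
                    tissue_source=d["tissue_source"],
                    extraction_method=d["extraction_method"],
                    disease_state=d["disease_state"],
                    input_rna_conc=float(d["input_rna_conc"]),
                    cdna_dilution=float(d["cdna_dilution"]),
                    replicate_index=int(d["replicate_index"]),
                    subject_id=d.get("subject_id", ""),
                )
            )
        except (ValueError, ValidationError) as e:
            raise ParseError(str(e), i) from e
    return out


def write_metadata_table(
    conditions: Sequence[SampleCondition], dest: str | Path | TextIO | None = None
) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_META_FIELDS)
    for c in conditions:
        w.writerow(
            [
                c.condition_id,
                c.tissue_source,
                c.extraction_method,
                c.disease_state,
                repr(float(c.input_rna_conc)),
                repr(float(c.cdna_dilution)),
                c.replicate_index,
                c.subject_id,
            ]
        )
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# filtering and the equivalent-sample predicate
# ---------------------------------------------------------------------------

def prefilter_all_censored(matrix: CtMatrix) -> CtMatrix:
    """Drop microRNA assays censored (Ct = 40) in every condition.

    An assay with even one uncensored value — however close to the ceiling —
    is retained.  Endogenous controls and blanks are tracked, not filtered,
    so they always survive.  Idempotent.
    """
    mir = set(matrix.mir_ids)
    keep = []
    cen = matrix.censored
    present = matrix.ct.notna()
    for a in matrix.assay_ids:
        if a not in mir:
            keep.append(a)
            continue
        has_any = bool(present.loc[a].any())
        all_censored = bool((cen.loc[a] | ~present.loc[a]).all())
        if not has_any or not all_censored:
            keep.append(a)
    return matrix.subset_assays(keep)


def effective_template_concentration(c: SampleCondition) -> float:
    """Input RNA concentration divided by cDNA fold-dilution (ng/uL-equivalent).

    Conditions with (nearly) equal ratios — e.g. 200 ng/uL at 15x and
    66.7 ng/uL at 5x — deliver the same amount of template per well and are
    treated as equivalent samples.
    """
    if c.input_rna_conc <= 0 or c.cdna_dilution <= 0:
        raise DomainError("input_rna_conc and cdna_dilution must be positive")
    return c.input_rna_conc / c.cdna_dilution


def equivalent_samples(
    a: SampleCondition, b: SampleCondition, rel_tol: float = 0.01
) -> bool:
    """True when the effective template concentrations agree within ``rel_tol``."""
    return math.isclose(
        effective_template_concentration(a),
        effective_template_concentration(b),
        rel_tol=rel_tol,
    )
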