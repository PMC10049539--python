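"""Cohort data model and CSV I/O for the six-analyte serum L-arginine panel.

The panel comprises L-arginine, citrulline, ornithine and the three
methylarginines ADMA, MMA and SDMA, all in micromolar (µM).  Subjects carry a
clinical group (``long_covid`` or ``control``), a trial arm (``active`` =
L-arginine + vitamin C, ``placebo``, or ``none`` for controls) and a visit
timepoint (``baseline`` or ``day28``).  The :class:`CohortTable` is the single
container every downstream module consumes; its :meth:`CohortTable.matrix`
view fixes the metabolite column order used for all multivariate work.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical analyte order; every matrix view uses these columns in this order.
METABOLITES: tuple[str, ...] = (
    "arginine", "citrulline", "ornithine", "adma", "mma", "sdma",
)
#: CSV column names for the concentrations (µM).
METABOLITE_COLUMNS: tuple[str, ...] = tuple(f"{m}_uM" for m in METABOLITES)
#: Full CSV schema (label columns first, concentrations after).
SCHEMA_COLUMNS: tuple[str, ...] = (
    "subject_id", "group", "arm", "timepoint", *METABOLITE_COLUMNS,
)


class Group(str, Enum):
    LONG_COVID = "long_covid"
    CONTROL = "control"


class Arm(str, Enum):
    ACTIVE = "active"
    PLACEBO = "placebo"
    NONE = "none"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    DAY28 = "day28"


class SchemaError(ValueError):
    """A required CSV column is missing or mis-typed."""


class ValidationError(ValueError):
    """A row violates a data-model invariant (positivity, uniqueness, labels)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject-visit: labels plus the six concentrations in µM."""

    subject_id: str
    group: Group
    arm: Arm
    timepoint: Timepoint
    arginine: float
    citrulline: float
    ornithine: float
    adma: float
    mma: float
    sdma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        for name in METABOLITES:
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0.0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name} must be a finite "
                    f"positive concentration, got {v!r}"
                )
            object.__setattr__(self, name, v)
        if self.group is Group.CONTROL:
            if self.arm is not Arm.NONE or self.timepoint is not Timepoint.BASELINE:
                raise ValidationError(
                    f"subject {self.subject_id!r}: controls must have arm='none' "
                    f"and timepoint='baseline'"
                )

    @property
    def concentrations(self) -> np.ndarray:
        """The six concentrations as a vector in canonical order (µM)."""
        return np.array([getattr(self, m) for m in METABOLITES], dtype=float)


class CohortTable:
    """Ordered, validated collection of :class:`SubjectRecord` rows.

    Internally a pandas DataFrame with the CSV schema columns; row order is
    preserved from construction.  ``(subject_id, timepoint)`` pairs are unique.
    """

    def __init__(self, records: Sequence[SubjectRecord] = ()) -> None:
        rows = [
            {
                "subject_id": r.subject_id,
                "group": r.group.value,
                "arm": r.arm.value,
                "timepoint": r.timepoint.value,
                **{f"{m}_uM": getattr(r, m) for m in METABOLITES},
            }
            for r in records
        ]
        self._df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        self._check_unique()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        """Validate an arbitrary DataFrame against the schema, row by row."""
        missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
        if extra:
            log.warning("ignoring extra column(s): %s", ", ".join(extra))
        records = []
        for i, row in df.iterrows():
            vals = {}
            for m, col in zip(METABOLITES, METABOLITE_COLUMNS):
                try:
                    vals[m] = float(row[col])
                except (TypeError, ValueError) as exc:
                    raise ValidationError(
                        f"row {i} (subject {row['subject_id']!r}): "
                        f"non-numeric {col}={row[col]!r}"
                    ) from exc
            try:
                rec = SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=row["group"], arm=row["arm"], timepoint=row["timepoint"],
                    **vals,
                )
            except ValueError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
        return cls(records)

    def _check_unique(self) -> None:
        if len(self._df):
            dup = self._df.duplicated(subset=["subject_id", "timepoint"])
            if dup.any():
                pairs = self._df.loc[dup, ["subject_id", "timepoint"]]
                raise ValidationError(
                    "duplicate (subject_id, timepoint): "
                    + "; ".join(f"({r.subject_id}, {r.timepoint})"
                                for r in pairs.itertuples())
                )

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[SubjectRecord]:
        for row in self._df.itertuples(index=False):
            yield SubjectRecord(
                subject_id=row.subject_id, group=row.group, arm=row.arm,
                timepoint=row.timepoint,
                **{m: getattr(row, col)
                   for m, col in zip(METABOLITES, METABOLITE_COLUMNS)},
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def records(self) -> list[SubjectRecord]:
        return list(self)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    def matrix(self) -> np.ndarray:
        """n × 6 concentration matrix in canonical metabolite order (µM)."""
        return self._df[list(METABOLITE_COLUMNS)].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self._df["subject_id"].to_numpy()

    def labels(self, column: str) -> np.ndarray:
        if column not in ("group", "arm", "timepoint"):
            raise ValueError(f"not a label column: {column}")
        return self._df[column].to_numpy()

    # -- selection --------------------------------------------------------
    def partition(
        self,
        group: str | Group | None = None,
        arm: str | Arm | None = None,
        timepoint: str | Timepoint | None = None,
    ) -> "CohortTable":
        """Subset by any combination of labels, preserving row order."""
        mask = np.ones(len(self._df), dtype=bool)
        if group is not None:
            mask &= (self._df["group"] == Group(group).value).to_numpy()
        if arm is not None:
            mask &= (self._df["arm"] == Arm(arm).value).to_numpy()
        if timepoint is not None:
            mask &= (self._df["timepoint"] == Timepoint(timepoint).value).to_numpy()
        out = CohortTable.__new__(CohortTable)
        out._df = self._df.loc[mask].reset_index(drop=True)
        return out

    def concat(self, other: "CohortTable") -> "CohortTable":
        out = CohortTable.__new__(CohortTable)
        out._df = pd.concat([self._df, other._df], ignore_index=True)
        out._check_unique()
        return out


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read and validate a schema CSV (comma-separated, '.' decimal, UTF-8).

    Extra columns are ignored with a warning; any invariant violation raises
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    return CohortTable.from_dataframe(df)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a schema-conformant CSV; concentrations keep 12 significant digits
    so a write/read round trip is lossless well past 1e-9 relative."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.12g")
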