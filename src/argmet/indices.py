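"""NO-bioavailability indices and repeated-measures transforms.

Three dimensionless ratios summarise how much L-arginine is available for
nitric-oxide synthesis relative to its competitors and catabolic products:

* ``arg_adma`` — L-arginine / ADMA, the substrate-to-inhibitor balance at NOS;
* ``gabr``     — global arginine bioavailability ratio,
  L-arginine / (ornithine + citrulline);
* ``arg_orn``  — L-arginine / ornithine, an inverse marker of arginase flux.

For paired visits, concentrations are analysed as simple differences
(day 28 − baseline, µM) while the indices are analysed as base-10 log ratios
log10(day28 / baseline), which symmetrises relative changes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    METABOLITE_COLUMNS,
    METABOLITES,
    CohortTable,
    SubjectRecord,
    Timepoint,
)

#: Canonical index order used for all vector views.
INDEX_NAMES: tuple[str, ...] = ("arg_adma", "gabr", "arg_orn")


class PairingError(ValueError):
    """Baseline/day-28 records do not form a valid within-subject pair."""


@dataclass(frozen=True)
class DerivedIndices:
    """Per subject-visit NO-bioavailability ratios (dimensionless)."""

    arg_adma: float
    gabr: float
    arg_orn: float

    def as_array(self) -> np.ndarray:
        return np.array([self.arg_adma, self.gabr, self.arg_orn], dtype=float)


@dataclass(frozen=True)
class DeltaRecord:
    """Within-subject change over the intervention period.

    ``metabolite_deltas`` are day28 − baseline in µM (canonical analyte
    order); ``index_log_ratios`` are log10(day28/baseline) of the three
    indices (canonical index order).
    """

    subject_id: str
    metabolite_deltas: np.ndarray
    index_log_ratios: np.ndarray


def compute_indices(record: SubjectRecord) -> DerivedIndices:
    """Compute the three ratios for one subject-visit.

    All three are strictly positive and finite for any valid record, and
    ``gabr <= arg_orn`` always (the GABR denominator includes citrulline).
    """
    return DerivedIndices(
        arg_adma=record.arginine / record.adma,
        gabr=record.arginine / (record.ornithine + record.citrulline),
        arg_orn=record.arginine / record.ornithine,
    )


def indices_frame(table: CohortTable) -> pd.DataFrame:
    """Per-row index table (columns ``arg_adma``, ``gabr``, ``arg_orn``).

    Group-level summaries of these columns are means over per-subject ratios,
    never ratios of group means — the two differ for skewed panels.
    """
    X = table.matrix()
    arg, cit, orn, adma = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    return pd.DataFrame(
        {
            "arg_adma": arg / adma,
            "gabr": arg / (orn + cit),
            "arg_orn": arg / orn,
        }
    )


def add_indices(table: CohortTable) -> pd.DataFrame:
    """Schema DataFrame with the three index columns appended."""
    return pd.concat([table.to_dataframe(), indices_frame(table)], axis=1)


def compute_delta(baseline: SubjectRecord, day28: SubjectRecord) -> DeltaRecord:
    """Pair two visits of one subject into a :class:`DeltaRecord`.

    Concentration deltas are simple differences; index changes are base-10
    log ratios, so swapping the visit roles negates them exactly.
    """
    if baseline.subject_id != day28.subject_id:
        raise PairingError(
            f"subject mismatch: {baseline.subject_id!r} vs {day28.subject_id!r}"
        )
    if baseline.timepoint is not Timepoint.BASELINE:
        raise PairingError(f"first record of {baseline.subject_id!r} is not baseline")
    if day28.timepoint is not Timepoint.DAY28:
        raise PairingError(f"second record of {day28.subject_id!r} is not day28")
    i0 = compute_indices(baseline).as_array()
    i1 = compute_indices(day28).as_array()
    return DeltaRecord(
        subject_id=baseline.subject_id,
        metabolite_deltas=day28.concentrations - baseline.concentrations,
        index_log_ratios=np.log10(i1 / i0),
    )


def delta_table(table: CohortTable) -> pd.DataFrame:
    """Pair baseline/day-28 visits for every subject in ``table``.

    Returns one row per subject with columns ``subject_id``, ``arm``,
    ``d_<metabolite>_uM`` (µM differences) and ``lr_<index>`` (log10 ratios).
    Subjects lacking either visit are an error: the repeated-measures design
    requires complete pairs.
    """
    base = table.partition(timepoint=Timepoint.BASELINE)
    day28 = table.partition(timepoint=Timepoint.DAY28)
    b = {r.subject_id: r for r in base}
    d = {r.subject_id: r for r in day28}
    unpaired = sorted(set(b) ^ set(d))
    if unpaired:
        raise PairingError(
            "unpaired subject(s), both visits required: " + ", ".join(unpaired)
        )
    rows = []
    for rec in base:  # baseline row order defines output order
        delta = compute_delta(rec, d[rec.subject_id])
        row: dict[str, object] = {"subject_id": rec.subject_id, "arm": rec.arm.value}
        for m, v in zip(METABOLITES, delta.metabolite_deltas):
            row[f"d_{m}_uM"] = v
        for ix, v in zip(INDEX_NAMES, delta.index_log_ratios):
            row[f"lr_{ix}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def delta_matrix(table: CohortTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix of per-subject metabolite deltas.

    Returns ``(D, arms, subject_ids)`` where ``D`` is n × 6 (µM, canonical
    order) and ``arms`` the trial-arm label per subject.
    """
    df = delta_table(table)
    D = df[[f"d_{m}_uM" for m in METABOLITES]].to_numpy(dtype=float)
    return D, df["arm"].to_numpy(), df["subject_id"].tolist()
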