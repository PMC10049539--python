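"""Orchestration of the four PLS-DA analyses and the univariate battery.

The four analyses mirror the study design:

1. ``discriminate_lc_vs_hc`` — baseline six-metabolite profiles, long COVID
   (class 1) vs healthy controls (class 0);
2. ``treatment_vs_placebo_deltas`` — per-subject 28-day concentration
   changes, active supplementation (class 1) vs placebo (class 0);
3. ``arm_day28_vs_hc`` — day-28 profiles of one trial arm vs controls;
4. ``univariate_battery`` — the per-variable comparisons only.

Each multivariate analysis runs rDCV, the permutation test, and the
variable-significance summary, then attaches the univariate battery for the
matching variables (concentrations plus derived indices, or deltas plus
index log-ratios for the paired design).  Reports are plain JSON/CSV with a
provenance block; re-running with the same config and seed reproduces every
file byte for byte apart from the timestamp field.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import METABOLITE_COLUMNS, METABOLITES, CohortTable
from .indices import INDEX_NAMES, delta_table, indices_frame
from .rdcv import (
    FoldScheme,
    PermutationResult,
    RDCVResult,
    permutation_test,
    run_rdcv,
    variable_significance,
)
from .stats import UnivariateResult, compare_groups, results_to_frame

ANALYSES = (
    "discriminate_lc_vs_hc",
    "treatment_vs_placebo_deltas",
    "arm_day28_vs_hc",
    "univariate_battery",
)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    analysis: str
    input_path: str | None = None
    outer_k: int = 10
    inner_k: int = 8
    repetitions: int = 50
    permutations: int = 1000
    seed: int = 0
    scale: str = "autoscale"
    day28_arm: str = "active"
    include_index_log_ratios: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(
                f"unknown analysis {self.analysis!r}; choose from {ANALYSES}"
            )

    def scheme(self) -> FoldScheme:
        return FoldScheme(
            outer_k=self.outer_k, inner_k=self.inner_k,
            repetitions=self.repetitions, seed=self.seed, scale=self.scale,
        )


def build_feature_matrix(
    table: CohortTable, config: AnalysisConfig
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], list[str]]:
    """Assemble (X, y, feature_names, sample_ids) for a multivariate analysis."""
    a = config.analysis
    if a == "discriminate_lc_vs_hc":
        base = table.partition(timepoint="baseline")
        X = base.matrix()
        y = (base.labels("group") == "long_covid").astype(int)
        return X, y, METABOLITES, list(base.subject_ids)
    if a == "treatment_vs_placebo_deltas":
        lc = table.partition(group="long_covid")
        df = delta_table(lc)
        cols = [f"d_{m}_uM" for m in METABOLITES]
        names: tuple[str, ...] = tuple(f"d_{m}" for m in METABOLITES)
        if config.include_index_log_ratios:
            cols += [f"lr_{ix}" for ix in INDEX_NAMES]
            names += tuple(f"lr_{ix}" for ix in INDEX_NAMES)
        X = df[cols].to_numpy(dtype=float)
        y = (df["arm"] == "active").astype(int).to_numpy()
        return X, y, names, df["subject_id"].tolist()
    if a == "arm_day28_vs_hc":
        arm = table.partition(group="long_covid", arm=config.day28_arm,
                              timepoint="day28")
        hc = table.partition(group="control")
        both = arm.concat(hc)
        X = both.matrix()
        y = (both.labels("group") == "long_covid").astype(int)
        return X, y, METABOLITES, list(both.subject_ids)
    raise ValueError(f"{a!r} has no multivariate feature matrix")


def _univariate_battery(
    table: CohortTable, config: AnalysisConfig
) -> list[UnivariateResult]:
    """Per-variable comparisons matched to the analysis design."""
    a = config.analysis
    out: list[UnivariateResult] = []
    if a == "treatment_vs_placebo_deltas":
        df = delta_table(table.partition(group="long_covid"))
        act = df[df["arm"] == "active"]
        plc = df[df["arm"] == "placebo"]
        for m in METABOLITES:
            out.append(compare_groups(act[f"d_{m}_uM"], plc[f"d_{m}_uM"],
                                      variable=f"d_{m}_uM"))
        for ix in INDEX_NAMES:
            out.append(compare_groups(act[f"lr_{ix}"], plc[f"lr_{ix}"],
                                      variable=f"lr_{ix}"))
        return out
    if a == "arm_day28_vs_hc":
        g1 = table.partition(group="long_covid", arm=config.day28_arm,
                             timepoint="day28")
        g0 = table.partition(group="control")
    else:  # baseline long COVID vs controls
        base = table.partition(timepoint="baseline")
        g1 = base.partition(group="long_covid")
        g0 = base.partition(group="control")
    df1 = pd.concat([g1.to_dataframe(), indices_frame(g1)], axis=1)
    df0 = pd.concat([g0.to_dataframe(), indices_frame(g0)], axis=1)
    for col in (*METABOLITE_COLUMNS, *INDEX_NAMES):
        out.append(compare_groups(df1[col], df0[col], variable=col))
    return out


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _provenance(config: AnalysisConfig) -> dict:
    import scipy
    import sklearn

    return {
        "argmet_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "sklearn_version": sklearn.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": _config_hash(config),
    }


def _merit_block(res: RDCVResult, perm: PermutationResult | None) -> dict:
    block = res.summary()
    if perm is not None:
        block["permutation"] = {
            "n_permutations": perm.n_permutations,
            "observed_accuracy": perm.observed_accuracy,
            "p_value": perm.p_value,
            "null_mean": float(perm.null_accuracies.mean()),
            "null_sd": float(perm.null_accuracies.std(ddof=1)),
            "null_max": float(perm.null_accuracies.max()),
        }
    return block


def run_analysis(
    table: CohortTable, config: AnalysisConfig
) -> dict:
    """Run one configured analysis; return the report dict and, when
    ``config.out_dir`` is set, write report.json plus CSV side-tables."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "analysis": config.analysis,
        "provenance": _provenance(config),
    }
    univariate = _univariate_battery(table, config)
    uni_df = results_to_frame(univariate)
    report["univariate"] = uni_df.to_dict(orient="records")

    sig_df = scores_df = None
    if config.analysis != "univariate_battery":
        X, y, names, sample_ids = build_feature_matrix(table, config)
        scheme = config.scheme()
        perm = permutation_test(X, y, scheme, B=config.permutations)
        res = perm.observed
        res.feature_names = names
        sig_df = variable_significance(res)
        report["figures_of_merit"] = _merit_block(res, perm)
        report["variable_significance"] = sig_df.to_dict(orient="records")
        scores_df = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class": y,
                "score_mean": res.outer_scores.mean(axis=0),
                "score_sd": res.outer_scores.std(axis=0, ddof=1),
            }
        )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamped = dict(report)
        stamped["timestamp"] = datetime.now(timezone.utc).isoformat()
        (out / "report.json").write_text(
            json.dumps(stamped, sort_keys=True, indent=2) + "\n"
        )
        uni_df.to_csv(out / "univariate.csv", index=False)
        if sig_df is not None:
            sig_df.to_csv(out / "significance.csv", index=False)
        if scores_df is not None:
            scores_df.to_csv(out / "outer_scores.csv", index=False)
    return report
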