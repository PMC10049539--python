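"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators cover the two study designs:

* a cross-sectional draw — per group, concentrations are multivariate normal
  around the group means with the group SDs (independent across metabolites
  by default; a full correlation matrix can be supplied), rejection-resampled
  to keep every concentration positive;
* a paired intervention draw — a baseline visit per subject plus a day-28
  visit equal to baseline + a normally distributed per-metabolite change,
  optionally correlated with the baseline value.

The default parameterisations (:data:`BASELINE_GROUPS`,
:data:`INTERVENTION_EFFECTS`) are the published group summaries of the long-COVID
L-arginine + vitamin C trial this package analyses: two long-COVID arms of
n = 23 each and n = 11 healthy controls for the cross-sectional design, and
per-arm 28-day concentration changes for the intervention design.  Only
printed means and SDs are available, so the defaults assume independent,
normal margins; real panels are correlated and right-skewed, which these
defaults deliberately do not emulate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import METABOLITES, Arm, CohortTable, Group, SubjectRecord, Timepoint

_MAX_REDRAWS = 10_000


@dataclass(frozen=True)
class GroupSpec:
    """One group's size and per-metabolite mean/SD (µM, canonical order)."""

    label: str                       # Group value
    n: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    arm: str = "none"                # Arm value
    correlation: np.ndarray | None = None
    margins: str = "normal"          # "normal" | "lognormal"

    def __post_init__(self) -> None:
        if len(self.means) != 6 or len(self.sds) != 6:
            raise ValueError("means and sds must have 6 entries")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be strictly positive")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (6, 6) or not np.allclose(C, C.T):
                raise ValueError("correlation must be a symmetric 6x6 matrix")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("correlation must be positive definite")


@dataclass(frozen=True)
class EffectSpec:
    """Paired design: a baseline group plus per-metabolite 28-day changes."""

    baseline: GroupSpec
    delta_means: tuple[float, ...]
    delta_sds: tuple[float, ...]
    baseline_delta_corr: float = 0.0

    def __post_init__(self) -> None:
        if len(self.delta_means) != 6 or len(self.delta_sds) != 6:
            raise ValueError("delta means/sds must have 6 entries")
        if any(s < 0 for s in self.delta_sds):
            raise ValueError("delta sds must be non-negative")
        if not -1.0 < self.baseline_delta_corr < 1.0:
            raise ValueError("baseline_delta_corr must be in (-1, 1)")


# -- published group summaries (µM), canonical metabolite order:
#    arginine, citrulline, ornithine, ADMA, MMA, SDMA
BASELINE_ACTIVE = GroupSpec(
    label="long_covid", arm="active", n=23,
    means=(192.7, 41.4, 122.5, 0.60, 0.13, 0.71),
    sds=(74.1, 13.2, 43.6, 0.14, 0.05, 0.15),
)
BASELINE_PLACEBO = GroupSpec(
    label="long_covid", arm="placebo", n=23,
    means=(196.6, 41.6, 124.9, 0.64, 0.14, 0.77),
    sds=(80.6, 11.9, 56.6, 0.19, 0.06, 0.25),
)
BASELINE_CONTROL = GroupSpec(
    label="control", arm="none", n=11,
    means=(221.6, 30.1, 82.9, 0.48, 0.10, 0.53),
    sds=(31.3, 7.5, 12.5, 0.02, 0.02, 0.11),
)
#: Baseline cross-sectional design: 46 long-COVID (two arms) vs 11 controls.
BASELINE_GROUPS: tuple[GroupSpec, ...] = (BASELINE_ACTIVE, BASELINE_PLACEBO, BASELINE_CONTROL)

#: 28-day concentration changes per trial arm (µM).
INTERVENTION_ACTIVE = EffectSpec(
    baseline=BASELINE_ACTIVE,
    delta_means=(67.8, 4.0, 30.9, 0.07, 0.09, 0.02),
    delta_sds=(90.6, 10.2, 53.0, 0.10, 0.17, 0.04),
)
INTERVENTION_PLACEBO = EffectSpec(
    baseline=BASELINE_PLACEBO,
    delta_means=(5.3, 2.7, 8.8, 0.04, 0.03, 0.00),
    delta_sds=(81.7, 9.2, 44.8, 0.14, 0.15, 0.05),
)
INTERVENTION_EFFECTS: tuple[EffectSpec, EffectSpec] = (INTERVENTION_ACTIVE, INTERVENTION_PLACEBO)


def _cov(spec: GroupSpec) -> np.ndarray:
    sds = np.asarray(spec.sds, dtype=float)
    C = np.eye(6) if spec.correlation is None else np.asarray(spec.correlation)
    return np.outer(sds, sds) * C


def _draw_positive_mvn(
    mean: np.ndarray, cov: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Multivariate-normal rows, redrawing any row with a non-positive entry.

    At the default parameterisations the rejection rate is well below 1%, so
    truncation bias is negligible.
    """
    L = np.linalg.cholesky(cov)
    out = np.empty((n, mean.size))
    filled = 0
    for _ in range(_MAX_REDRAWS):
        need = n - filled
        if need == 0:
            return out
        draw = mean + rng.standard_normal((need, mean.size)) @ L.T
        good = draw[(draw > 0).all(axis=1)]
        out[filled:filled + good.shape[0]] = good
        filled += good.shape[0]
    raise RuntimeError("positivity rejection did not converge; check the group spec parameters")


def _draw_group(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(spec.means, dtype=float)
    if spec.margins == "lognormal":
        # moment-matched lognormal margins on the normal copula
        sds = np.asarray(spec.sds, dtype=float)
        sigma2 = np.log1p((sds / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        C = np.eye(6) if spec.correlation is None else np.asarray(spec.correlation)
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((spec.n, 6)) @ L.T
        return np.exp(mu + np.sqrt(sigma2) * z)
    if spec.margins != "normal":
        raise ValueError(f"unknown margins {spec.margins!r}")
    return _draw_positive_mvn(mean, _cov(spec), spec.n, rng)


def _records(
    X: np.ndarray, spec: GroupSpec, timepoint: Timepoint, start: int
) -> list[SubjectRecord]:
    prefix = f"{spec.label}-{spec.arm}" if spec.arm != "none" else spec.label
    return [
        SubjectRecord(
            subject_id=f"{prefix}-{start + i:03d}",
            group=Group(spec.label), arm=Arm(spec.arm), timepoint=timepoint,
            **dict(zip(METABOLITES, row)),
        )
        for i, row in enumerate(X)
    ]


def generate_cross_sectional(
    specs: tuple[GroupSpec, ...] | list[GroupSpec],
    seed: int | np.random.Generator = 0,
) -> CohortTable:
    """Baseline-only cohort, one group per spec, deterministic under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    start = 1
    for spec in specs:
        X = _draw_group(spec, rng)
        records.extend(_records(X, spec, Timepoint.BASELINE, start=start))
        start += spec.n
    return CohortTable(records)


def generate_intervention(
    spec_active: EffectSpec,
    spec_placebo: EffectSpec,
    seed: int | np.random.Generator = 0,
) -> CohortTable:
    """Paired two-visit cohort for the intervention design.

    Per subject the day-28 concentrations are baseline + delta, with
    delta_j | baseline_j bivariate-normal at correlation
    ``baseline_delta_corr`` (0 = independent changes); rows whose day-28
    value would be non-positive are redrawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    start = 1  # continuous numbering keeps ids unique if specs share an arm
    for spec in (spec_active, spec_placebo):
        base_spec = spec.baseline
        B = _draw_group(base_spec, rng)
        mu_b = np.asarray(base_spec.means, dtype=float)
        sd_b = np.asarray(base_spec.sds, dtype=float)
        mu_d = np.asarray(spec.delta_means, dtype=float)
        sd_d = np.asarray(spec.delta_sds, dtype=float)
        rho = spec.baseline_delta_corr
        cond_mean = mu_d + rho * (sd_d / sd_b) * (B - mu_b)
        cond_sd = np.sqrt(1.0 - rho**2) * sd_d
        D = np.empty_like(B)
        for i in range(B.shape[0]):
            for _ in range(_MAX_REDRAWS):
                d = cond_mean[i] + cond_sd * rng.standard_normal(6)
                if ((B[i] + d) > 0).all():
                    D[i] = d
                    break
            else:
                raise RuntimeError("day-28 positivity redraw did not converge")
        records.extend(_records(B, base_spec, Timepoint.BASELINE, start=start))
        records.extend(_records(B + D, base_spec, Timepoint.DAY28, start=start))
        start += base_spec.n
    return CohortTable(records)


def default_cross_sectional_cohort(seed: int = 0) -> CohortTable:
    """57-subject baseline cohort at the published parameterisation."""
    return generate_cross_sectional(BASELINE_GROUPS, seed)


def default_intervention_cohort(seed: int = 0) -> CohortTable:
    """46-subject paired cohort (23 active / 23 placebo) at the published
    baseline and 28-day-change parameterisations."""
    return generate_intervention(INTERVENTION_ACTIVE, INTERVENTION_PLACEBO, seed)
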