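"""Repeated double cross-validation (rDCV) of PLS-DA with permutation tests.

Two cross-validation loops are nested: the inner loop (default 8 cancelation
groups) selects the number of latent variables on each outer-training
portion; the outer loop (default 10 groups) provides predictions that mimic
an external test set.  The whole procedure is repeated (default 50 times)
with fresh random fold assignments, giving dispersions for every figure of
merit: overall accuracy, per-class correct-classification rates, selected
complexity, and the canonical-variate weights of every outer-loop model.

Statistical significance of the observed accuracy is assessed by permutation:
class labels are shuffled B times (default 1000) and one double-CV pass is
run per shuffle, yielding an empirical null distribution; the reported
p-value is (1 + #{null >= observed}) / (B + 1).  For imbalanced designs the
null concentrates near the majority-class rate, not 50% — the chance level
is established empirically, never assumed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsda import Preprocessor, fit_pls, predict_components

DEFAULT_CANDIDATE_LVS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class FoldScheme:
    """Cross-validation layout: outer/inner cancelation groups, repetitions."""

    outer_k: int = 10
    inner_k: int = 8
    repetitions: int = 50
    seed: int = 0
    candidate_lvs: tuple[int, ...] = DEFAULT_CANDIDATE_LVS
    scale: str = "autoscale"
    decision_threshold: float = 0.5


@dataclass
class RDCVResult:
    """Distributions of rDCV figures of merit over repetitions.

    Accuracies and per-class rates are on the percent scale.  The overall
    accuracy of each repetition is the class-size-weighted mean of its
    per-class rates by construction (pooled outer-fold predictions).
    """

    accuracies: np.ndarray            # (repetitions,) %
    class1_rates: np.ndarray          # (repetitions,) %
    class0_rates: np.ndarray          # (repetitions,) %
    n_lv_selected: np.ndarray         # (repetitions, outer_k)
    weight_samples: np.ndarray        # (repetitions*outer_k, p) sign-aligned
    outer_scores: np.ndarray          # (repetitions, n) canonical scores
    n_class1: int
    n_class0: int
    feature_names: tuple[str, ...] | None = None
    scheme: FoldScheme | None = None

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.accuracies.size > 1 else 0.0

    @property
    def per_class_rate_mean(self) -> dict[str, float]:
        return {
            "class1": float(self.class1_rates.mean()),
            "class0": float(self.class0_rates.mean()),
        }

    @property
    def per_class_rate_sd(self) -> dict[str, float]:
        if self.accuracies.size < 2:
            return {"class1": 0.0, "class0": 0.0}
        return {
            "class1": float(self.class1_rates.std(ddof=1)),
            "class0": float(self.class0_rates.std(ddof=1)),
        }

    @property
    def n_lv_mean(self) -> float:
        return float(self.n_lv_selected.mean())

    @property
    def n_lv_sd(self) -> float:
        return float(self.n_lv_selected.std(ddof=1))

    def summary(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "per_class_rate_mean": self.per_class_rate_mean,
            "per_class_rate_sd": self.per_class_rate_sd,
            "n_lv_mean": self.n_lv_mean,
            "n_lv_sd": self.n_lv_sd,
            "n_class1": self.n_class1,
            "n_class0": self.n_class0,
        }


@dataclass
class PermutationResult:
    """Empirical null of the rDCV accuracy under label shuffling."""

    n_permutations: int
    null_accuracies: np.ndarray       # (B,) %
    observed_accuracy: float          # %
    p_value: float
    observed: RDCVResult | None = field(default=None, repr=False)


def overall_from_per_class(rates: dict[str, float] | tuple[float, float],
                           ns: tuple[int, int]) -> float:
    """Class-size-weighted overall accuracy from per-class rates (%).

    overall = (r1·n1 + r0·n0) / (n1 + n0) — the identity linking pooled
    outer-fold accuracy to the per-class correct-classification rates.
    """
    if isinstance(rates, dict):
        r1, r0 = rates["class1"], rates["class0"]
    else:
        r1, r0 = rates
    n1, n0 = ns
    return (r1 * n1 + r0 * n0) / (n1 + n0)


def empirical_p(observed: float, nulls: np.ndarray) -> float:
    """p = (1 + #{null >= observed}) / (B + 1); floor 1/(B+1), cap 1."""
    nulls = np.asarray(nulls, dtype=float)
    return float((1 + int((nulls >= observed).sum())) / (nulls.size + 1))


def make_cancelation_groups(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified random partition into k folds (cancelation groups).

    Per class, fold sizes differ by at most one; which folds receive the
    remainder is randomised.  Returns a fold index per sample.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n={n}], got {k}")
    folds = np.empty(n, dtype=int)
    loads = np.zeros(k, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        base, rem = divmod(idx.size, k)
        sizes = np.full(k, base)
        if rem:
            # remainders go to the least-loaded folds (random tie-break), so
            # total fold sizes also stay within one of each other
            order = rng.permutation(k)
            extra = order[np.argsort(loads[order], kind="stable")[:rem]]
            sizes[extra] += 1
        loads += sizes
        folds[idx] = np.repeat(np.arange(k), sizes)
    return folds


def _cv_accuracy_per_nlv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    candidate_lvs: tuple[int, ...],
    rng: np.random.Generator,
    scale: str,
    threshold: float,
) -> np.ndarray:
    """Inner-CV accuracy for each candidate component count (one pass)."""
    a_max = max(candidate_lvs)
    folds = make_cancelation_groups(y, k, rng)
    correct = np.zeros(a_max)
    for f in range(k):
        te = folds == f
        tr = ~te
        ytr = y[tr]
        if np.unique(ytr).size < 2:
            raise SingleClassFoldError("inner training fold has a single class")
        pre = Preprocessor(mode=scale).fit(X[tr])
        model = fit_pls(pre.transform(X[tr]), ytr, a_max)
        model.preprocessor = pre
        yh = predict_components(model, X[te])          # n_te × a_eff
        if yh.shape[1] < a_max:                        # rank-limited: pad
            yh = np.hstack([yh, np.repeat(yh[:, -1:], a_max - yh.shape[1], axis=1)])
        correct += ((yh >= threshold).astype(int) == y[te][:, None]).sum(axis=0)
    return correct[np.asarray(candidate_lvs) - 1] / y.size


class SingleClassFoldError(RuntimeError):
    """A training fold lost one of the classes."""


def inner_select_nlv(
    X_train: np.ndarray,
    y_train: np.ndarray,
    inner_k: int,
    candidate_lvs: tuple[int, ...] = DEFAULT_CANDIDATE_LVS,
    rng: np.random.Generator | None = None,
    scale: str = "autoscale",
    threshold: float = 0.5,
) -> int:
    """Pick the component count maximising inner-CV accuracy (ties: smallest)."""
    if rng is None:
        rng = np.random.default_rng(0)
    if np.unique(y_train).size < 2:
        raise SingleClassFoldError("training set has a single class")
    candidate_lvs = tuple(sorted(candidate_lvs))
    if len(candidate_lvs) == 1:
        return candidate_lvs[0]
    acc = _cv_accuracy_per_nlv(
        X_train, y_train, inner_k, candidate_lvs, rng, scale, threshold
    )
    return candidate_lvs[int(np.argmax(acc))]  # argmax → first max → smallest


def _double_cv_pass(
    X: np.ndarray,
    y: np.ndarray,
    scheme: FoldScheme,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> tuple[float, float, float, np.ndarray, np.ndarray, np.ndarray]:
    """One repetition: outer split, per-fold inner selection, refit, predict.

    Returns (accuracy%, class1 rate%, class0 rate%, selected n_lv per fold,
    canonical weights per fold, canonical score per sample).
    """
    n = y.size
    for _ in range(max_resample):
        folds = make_cancelation_groups(y, scheme.outer_k, rng)
        ok = all(
            np.unique(y[folds != f]).size == 2 for f in range(scheme.outer_k)
        )
        if ok:
            break
    else:
        raise SingleClassFoldError(
            "could not build outer folds with both classes in every training "
            "portion; reduce outer_k"
        )
    pred = np.empty(n, dtype=int)
    scores = np.empty(n)
    nlvs = np.empty(scheme.outer_k, dtype=int)
    weights = np.empty((scheme.outer_k, X.shape[1]))
    for f in range(scheme.outer_k):
        te = folds == f
        tr = ~te
        nlv = inner_select_nlv(
            X[tr], y[tr], scheme.inner_k, scheme.candidate_lvs, rng,
            scheme.scale, scheme.decision_threshold,
        )
        pre = Preprocessor(mode=scheme.scale).fit(X[tr])
        model = fit_pls(pre.transform(X[tr]), y[tr], nlv)
        model.preprocessor = pre
        Xs_te = pre.transform(X[te])
        y_hat = Xs_te @ model.coef + model.y_mean
        pred[te] = (y_hat >= scheme.decision_threshold).astype(int)
        scores[te] = Xs_te @ model.cv_weights
        nlvs[f] = model.n_lv
        weights[f] = model.cv_weights
    hit = pred == y
    acc = 100.0 * hit.mean()
    r1 = 100.0 * hit[y == 1].mean()
    r0 = 100.0 * hit[y == 0].mean()
    return acc, r1, r0, nlvs, weights, scores


def run_rdcv(X: np.ndarray, y: np.ndarray, scheme: FoldScheme) -> RDCVResult:
    """Full repeated double cross-validation.

    Per repetition the outer predictions are pooled over folds before
    computing accuracy and per-class rates, so the weighted-rate identity
    holds exactly within each repetition.  Identical scheme (including seed)
    and inputs reproduce the result bit for bit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on n")
    if y.size < 20:
        raise ValueError("rDCV needs n >= 20; too few samples for nested CV")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    R = scheme.repetitions
    root = np.random.SeedSequence(scheme.seed)
    children = root.spawn(R)
    acc = np.empty(R)
    r1 = np.empty(R)
    r0 = np.empty(R)
    nlvs = np.empty((R, scheme.outer_k), dtype=int)
    weights = np.empty((R, scheme.outer_k, X.shape[1]))
    scores = np.empty((R, y.size))
    for rep in range(R):
        rng = np.random.default_rng(children[rep])
        acc[rep], r1[rep], r0[rep], nlvs[rep], weights[rep], scores[rep] = (
            _double_cv_pass(X, y, scheme, rng)
        )
    return RDCVResult(
        accuracies=acc, class1_rates=r1, class0_rates=r0,
        n_lv_selected=nlvs,
        weight_samples=weights.reshape(-1, X.shape[1]),
        outer_scores=scores,
        n_class1=int(counts[1]), n_class0=int(counts[0]),
        scheme=scheme,
    )


def variable_significance(
    result: RDCVResult, level: float = 0.95
) -> pd.DataFrame:
    """Flag variables whose canonical weights are stably non-zero.

    A variable contributes significantly when the central ``level`` percentile
    interval of its sign-aligned weights across all outer-loop models excludes
    zero; the direction is the sign of the median weight (positive = higher
    scores for class 1).
    """
    W = result.weight_samples
    if W.size == 0:
        raise ValueError("no weight samples collected")
    lo_q = 100.0 * (1 - level) / 2
    lo = np.percentile(W, lo_q, axis=0)
    hi = np.percentile(W, 100.0 - lo_q, axis=0)
    med = np.median(W, axis=0)
    names = result.feature_names or tuple(
        f"var{i}" for i in range(W.shape[1])
    )
    return pd.DataFrame(
        {
            "variable": list(names),
            "weight_median": med,
            "weight_lo": lo,
            "weight_hi": hi,
            "significant": (lo > 0) | (hi < 0),
            "direction": np.sign(med).astype(int),
        }
    )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    scheme: FoldScheme,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    full_rerun: bool = False,
) -> PermutationResult:
    """Permutation null for the rDCV accuracy.

    The observed accuracy comes from the full repeated run; each of the B
    label shuffles is scored by a single double-CV pass (set ``full_rerun``
    to repeat the whole rDCV per shuffle).  p = (1 + #{null >= observed}) /
    (B + 1), so the smallest attainable p is 1/(B+1).
    """
    if B < 20:
        raise ValueError("B < 20 permutations is non-informative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    observed = run_rdcv(X, y, scheme)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(scheme.seed).spawn(1)[0].entropy % (2**31)
        )
    nulls = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        if full_rerun:
            perm_scheme = FoldScheme(
                outer_k=scheme.outer_k, inner_k=scheme.inner_k,
                repetitions=scheme.repetitions,
                seed=int(rng.integers(2**31)),
                candidate_lvs=scheme.candidate_lvs, scale=scheme.scale,
                decision_threshold=scheme.decision_threshold,
            )
            nulls[b] = run_rdcv(X, y_perm, perm_scheme).accuracy_mean
        else:
            nulls[b] = _double_cv_pass(X, y_perm, scheme, rng)[0]
    obs_acc = observed.accuracy_mean
    return PermutationResult(
        n_permutations=B, null_accuracies=nulls,
        observed_accuracy=obs_acc,
        p_value=empirical_p(obs_acc, nulls),
        observed=observed,
    )
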