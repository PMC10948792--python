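"""Group-level model comparison against empirical joint-cue probabilities.

Each candidate model (Face-only, Situation-only, Bayes cue-integration) is
scored against the empirical joint-cue table by Pearson correlation and RMSE
over all stimulus x emotion cells, with percentile-bootstrap confidence
intervals.  Pairs of models are compared with the Hotelling-Williams test
for overlapping dependent correlations (both models are correlated with the
same empirical vector), and per emotion category with a bootstrap of the
difference in correlations across stimuli.

Resampling units follow the analyses being mirrored: the (stimulus, emotion)
cell for overall fits, the stimulus for per-emotion contrasts.  An optional
``unit="stimulus"`` resamples whole stimuli in the overall bootstrap
instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._stats import (
    bootstrap_correlation_differences,
    bootstrap_correlations,
    fisher_z,
    pearson_r,
    percentile_ci,
    rmse,
    t_from_r,
    williams_t,
    _row_pearson,
)
from .errors import DegenerateDataError
from .tables import ProbabilityTable, assert_aligned

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP = 10_000


@dataclass(frozen=True)
class ModelFit:
    """One model-vs-empirical comparison."""

    model_name: str
    n_pairs: int
    r: float
    z: float
    rmse: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    t: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.r <= self.ci_high):
            # Expected for almost all data; can fail for pathological inputs.
            logger.warning(
                "bootstrap CI [%.4f, %.4f] does not bracket r = %.4f for %s",
                self.ci_low, self.ci_high, self.r, self.model_name,
            )


@dataclass(frozen=True)
class CorrelationDifference:
    """Difference between two models' fits to the same empirical vector."""

    model_a: str
    model_b: str
    t_stat: float | None = None
    df: int | None = None
    df_conventional: int | None = None
    p: float | None = None
    delta_ci_low: float | None = None
    delta_ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    emotion: str | None = None
    n_redrawn: int = 0

    @property
    def significant(self) -> bool:
        """CI-based significance for bootstrap contrasts, p < 0.05 otherwise."""
        if self.delta_ci_low is not None:
            return not (self.delta_ci_low <= 0.0 <= self.delta_ci_high)
        return self.p is not None and self.p < 0.05


def flatten_pairs(
    empirical: ProbabilityTable,
    model: ProbabilityTable,
    emotion: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered (empirical, model) value pairs over matched cells.

    Without a filter, all stimulus x emotion cells in stimulus-major order
    (604 stimuli x 13 emotions -> 7852 pairs); with ``emotion`` set, one pair
    per stimulus for that category's column.
    """
    assert_aligned(empirical, model)
    if emotion is None:
        return empirical.values.ravel().copy(), model.values.ravel().copy()
    j = empirical.emotion_index(emotion)
    return empirical.values[:, j].copy(), model.values[:, j].copy()


def bootstrap_r_ci(
    x: np.ndarray,
    y: np.ndarray,
    *,
    seed: int,
    n_boot: int = DEFAULT_BOOTSTRAP,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the correlation of paired vectors.

    This is the interval :func:`fit_model` attaches to each model fit,
    exposed at the vector level.
    """
    rng = np.random.default_rng(seed)
    samples, redrawn = bootstrap_correlations(x, y, n_boot, rng)
    if redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", redrawn)
    return percentile_ci(samples, level=level)


def fit_model(
    empirical: ProbabilityTable,
    model: ProbabilityTable,
    *,
    seed: int,
    model_name: str = "model",
    n_boot: int = DEFAULT_BOOTSTRAP,
    emotion: str | None = None,
    unit: str = "cell",
    ci_level: float = 0.95,
) -> ModelFit:
    """Score one model against the empirical table.

    Pearson r by the product-moment formula, RMSE over cells, and a
    percentile bootstrap CI from ``n_boot`` resamples (of cells by default,
    of whole stimuli with ``unit="stimulus"``).  The seed is mandatory so
    every interval is reproducible.
    """
    x, y = flatten_pairs(empirical, model, emotion)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need at least 3 pairs, got {n}")
    r = pearson_r(x, y, x_name="empirical", y_name=model_name)
    rng = np.random.default_rng(seed)
    if unit == "cell" or emotion is not None:
        samples, redrawn = bootstrap_correlations(x, y, n_boot, rng)
    elif unit == "stimulus":
        samples, redrawn = _stimulus_bootstrap(empirical, model, n_boot, rng)
    else:
        raise ValueError(f"unknown resampling unit {unit!r}")
    if redrawn:
        logger.info("redrew %d degenerate bootstrap replicates for %s", redrawn, model_name)
    lo, hi = percentile_ci(samples, level=ci_level)
    return ModelFit(
        model_name=model_name,
        n_pairs=n,
        r=r,
        z=fisher_z(r),
        rmse=rmse(x, y),
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
        t=t_from_r(r, n),
    )


def _stimulus_bootstrap(
    empirical: ProbabilityTable,
    model: ProbabilityTable,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Resample whole stimuli (rows) rather than individual cells."""
    n_stim = empirical.n_stimuli
    out = np.empty(n_boot)
    filled = 0
    redrawn = 0
    chunk = max(1, 500_000 // (n_stim * empirical.n_emotions))
    while filled < n_boot:
        b = min(chunk, n_boot - filled)
        idx = rng.integers(0, n_stim, size=(b, n_stim))
        xs = empirical.values[idx].reshape(b, -1)
        ys = model.values[idx].reshape(b, -1)
        r = _row_pearson(xs, ys)
        ok = np.isfinite(r)
        k = int(ok.sum())
        redrawn += b - k
        out[filled : filled + k] = r[ok]
        filled += k
    return out, redrawn


def dependent_correlation_test(
    r_ae: float,
    r_be: float,
    r_ab: float,
    n: int,
    *,
    model_a: str = "A",
    model_b: str = "B",
) -> CorrelationDifference:
    """Two-tailed Hotelling-Williams test of r(A, E) vs r(B, E).

    ``df`` is reported as n - 2 (the convention used in the accompanying
    reports); the textbook n - 3 is stored as ``df_conventional``.
    """
    t, p, df_rep, df_conv = williams_t(r_ae, r_be, r_ab, n)
    return CorrelationDifference(
        model_a=model_a, model_b=model_b, t_stat=t, df=df_rep,
        df_conventional=df_conv, p=p,
    )


def per_emotion_bootstrap_difference(
    empirical: ProbabilityTable,
    model_a: ProbabilityTable,
    model_b: ProbabilityTable,
    emotion: str,
    *,
    seed: int,
    n_boot: int = DEFAULT_BOOTSTRAP,
    model_a_name: str = "A",
    model_b_name: str = "B",
    ci_level: float = 0.95,
) -> CorrelationDifference:
    """Bootstrap CI of r_a - r_b for one emotion category.

    Stimuli are resampled within the category's column; each replicate
    recomputes both correlations on the same resample.  The contrast is
    "significant" when the CI excludes zero.  Degenerate replicates are
    redrawn and counted in ``n_redrawn``.
    """
    x, a = flatten_pairs(empirical, model_a, emotion)
    _, b = flatten_pairs(empirical, model_b, emotion)
    if x.size < 3:
        raise DegenerateDataError(f"need at least 3 stimuli for emotion {emotion!r}")
    rng = np.random.default_rng(seed)
    deltas, redrawn = bootstrap_correlation_differences(x, a, b, n_boot, rng)
    if redrawn:
        logger.info(
            "redrew %d degenerate bootstrap replicates for emotion %s", redrawn, emotion
        )
    lo, hi = percentile_ci(deltas, level=ci_level)
    return CorrelationDifference(
        model_a=model_a_name,
        model_b=model_b_name,
        delta_ci_low=lo,
        delta_ci_high=hi,
        n_boot=n_boot,
        seed=seed,
        emotion=emotion,
        n_redrawn=redrawn,
    )


def compare_models(
    empirical: ProbabilityTable,
    models: Mapping[str, ProbabilityTable],
    *,
    seed: int,
    n_boot: int = DEFAULT_BOOTSTRAP,
    unit: str = "cell",
) -> dict:
    """Fit every model and test every model pair against the empirical table.

    Returns ``{"fits": {name: ModelFit}, "differences": [CorrelationDifference]}``
    with one Williams test per unordered model pair.  Child seeds for each
    model's bootstrap are derived deterministically from ``seed``.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(models)) % (2**31)
    fits = {
        name: fit_model(
            empirical, table, seed=int(s), model_name=name, n_boot=n_boot, unit=unit
        )
        for (name, table), s in zip(models.items(), child_seeds)
    }
    diffs = []
    for name_a, name_b in itertools.combinations(models, 2):
        xa, ya = flatten_pairs(empirical, models[name_a])
        _, yb = flatten_pairs(empirical, models[name_b])
        r_ab = pearson_r(ya, yb, x_name=name_a, y_name=name_b)
        diffs.append(
            dependent_correlation_test(
                fits[name_a].r, fits[name_b].r, r_ab, xa.size,
                model_a=name_a, model_b=name_b,
            )
        )
    return {"fits": fits, "differences": diffs}
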