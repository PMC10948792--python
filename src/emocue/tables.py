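"""Row-stochastic probability tables and prior vectors.

A :class:`ProbabilityTable` is a stimulus x emotion matrix in which every row
is a probability distribution over emotion categories (sums to 1 within
``ROW_SUM_TOL``).  It is the common currency of the package: the Face-only
table P(e|f), the Situation-only table P(e|s), the empirical joint-cue table
and the model P(e|s,f) are all instances.  A :class:`PriorVector` holds the
global emotion base rates P(e).

Rows whose raw content is all zero (every rater judged every emotion absent
for that stimulus) fall back to the uniform distribution and are flagged in
``degenerate_rows`` so the anomaly stays auditable downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AxisMismatchError, SchemaError

#: Tolerance on row sums for any normalized table or prior.
ROW_SUM_TOL = 1e-9

#: Default floor applied to prior probabilities before normalization so the
#: division in the cue-integration rule is always defined.
PRIOR_FLOOR = 1e-6


def _as_labels(values: Iterable, what: str) -> tuple[str, ...]:
    labels = tuple(str(v) for v in values)
    if not labels:
        raise SchemaError(f"empty {what} axis")
    if len(set(labels)) != len(labels):
        dupes = sorted({v for v in labels if labels.count(v) > 1})
        raise SchemaError(f"duplicate {what} labels: {dupes}")
    return labels


@dataclass(frozen=True)
class ProbabilityTable:
    """Stimulus x emotion matrix of probabilities; every row sums to 1."""

    stimulus_ids: tuple[str, ...]
    emotions: tuple[str, ...]
    values: np.ndarray
    degenerate_rows: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus_ids", _as_labels(self.stimulus_ids, "stimulus"))
        object.__setattr__(self, "emotions", _as_labels(self.emotions, "emotion"))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.stimulus_ids), len(self.emotions)):
            raise SchemaError(
                f"values shape {values.shape} does not match "
                f"{len(self.stimulus_ids)} stimuli x {len(self.emotions)} emotions"
            )
        if not np.all(np.isfinite(values)):
            raise SchemaError("non-finite probability entries")
        if values.min() < -ROW_SUM_TOL or values.max() > 1 + ROW_SUM_TOL:
            raise SchemaError("probability entries outside [0, 1]")
        row_sums = values.sum(axis=1)
        bad = np.flatnonzero(np.abs(row_sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise SchemaError(
                f"rows do not sum to 1 within {ROW_SUM_TOL:g}: "
                f"{[self.stimulus_ids[i] for i in bad[:5]]}"
            )
        values = np.clip(values, 0.0, 1.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "degenerate_rows", frozenset(self.degenerate_rows))

    # -- construction ----------------------------------------------------

    @classmethod
    def from_means(
        cls,
        stimulus_ids: Sequence,
        emotions: Sequence[str],
        means: np.ndarray,
        *,
        extra_degenerate: Iterable[str] = (),
    ) -> "ProbabilityTable":
        """Row-normalize a matrix of non-negative cell means.

        Rows with zero sum are replaced by the uniform distribution and
        recorded in ``degenerate_rows``.
        """
        stimulus_ids = _as_labels(stimulus_ids, "stimulus")
        emotions = _as_labels(emotions, "emotion")
        means = np.asarray(means, dtype=float)
        if not np.all(np.isfinite(means)):
            raise SchemaError("non-finite cell means")
        if means.min() < 0:
            raise SchemaError("negative cell means")
        row_sums = means.sum(axis=1, keepdims=True)
        zero = row_sums[:, 0] == 0.0
        degenerate = {stimulus_ids[i] for i in np.flatnonzero(zero)}
        safe = np.where(row_sums == 0.0, 1.0, row_sums)
        probs = means / safe
        probs[zero] = 1.0 / len(emotions)
        return cls(
            stimulus_ids,
            emotions,
            probs,
            degenerate_rows=frozenset(degenerate) | frozenset(extra_degenerate),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ProbabilityTable":
        """Build from a wide frame (index = stimulus_id, columns = emotions)."""
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                   df.to_numpy(dtype=float), **kwargs)

    # -- views -----------------------------------------------------------

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def n_emotions(self) -> int:
        return len(self.emotions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.stimulus_ids, name="stimulus_id"),
                            columns=list(self.emotions))

    def emotion_index(self, emotion: str) -> int:
        try:
            return self.emotions.index(emotion)
        except ValueError:
            raise KeyError(f"unknown emotion {emotion!r}; table has {list(self.emotions)}") from None

    def row(self, stimulus_id: str) -> np.ndarray:
        return self.values[self.stimulus_ids.index(str(stimulus_id))]

    def subset(self, stimulus_ids: Sequence[str]) -> "ProbabilityTable":
        """Restrict to the given stimuli, preserving the requested order."""
        wanted = [str(s) for s in stimulus_ids]
        missing = sorted(set(wanted) - set(self.stimulus_ids))
        if missing:
            raise AxisMismatchError(f"stimuli not in table: {missing[:10]}")
        pos = [self.stimulus_ids.index(s) for s in wanted]
        return dataclasses.replace(
            self,
            stimulus_ids=tuple(wanted),
            values=self.values[pos],
            degenerate_rows=self.degenerate_rows & set(wanted),
        )

    def with_degenerate(self, extra: Iterable[str]) -> "ProbabilityTable":
        return dataclasses.replace(self, degenerate_rows=self.degenerate_rows | frozenset(extra))


def assert_aligned(a: ProbabilityTable, b: ProbabilityTable) -> None:
    """Raise :class:`AxisMismatchError` unless both tables share identical axes."""
    if a.stimulus_ids != b.stimulus_ids:
        only_a = sorted(set(a.stimulus_ids) - set(b.stimulus_ids))
        only_b = sorted(set(b.stimulus_ids) - set(a.stimulus_ids))
        detail = (
            f"only in first: {only_a[:5]}; only in second: {only_b[:5]}"
            if only_a or only_b
            else "same stimuli, different order"
        )
        raise AxisMismatchError(f"stimulus axes differ ({detail})")
    if a.emotions != b.emotions:
        raise AxisMismatchError(
            f"emotion axes differ: {list(a.emotions)} vs {list(b.emotions)}"
        )


@dataclass(frozen=True)
class PriorVector:
    """Global emotion base rates P(e): strictly positive, sums to 1."""

    emotions: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "emotions", _as_labels(self.emotions, "emotion"))
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.shape != (len(self.emotions),):
            raise SchemaError(
                f"prior length {probs.shape} does not match {len(self.emotions)} emotions"
            )
        if not np.all(np.isfinite(probs)) or probs.min() <= 0:
            raise SchemaError(
                "prior entries must be strictly positive; apply the floor "
                "(PriorVector.from_means with floor > 0)"
            )
        if abs(probs.sum() - 1.0) > ROW_SUM_TOL:
            raise SchemaError(f"prior does not sum to 1 within {ROW_SUM_TOL:g}")
        probs = probs.copy()
        probs.flags.writeable = False
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def from_means(
        cls, emotions: Sequence[str], means: np.ndarray, *, floor: float = PRIOR_FLOOR
    ) -> "PriorVector":
        """Normalize per-emotion mean ratings into a prior.

        Entries below ``floor`` are raised to ``floor`` before normalization,
        so the cue-integration division never sees a zero.
        """
        if floor <= 0:
            raise ValueError("floor must be positive")
        means = np.asarray(means, dtype=float)
        if not np.all(np.isfinite(means)) or means.min() < 0:
            raise SchemaError("prior means must be finite and non-negative")
        floored = np.maximum(means, floor)
        return cls(emotions, floored / floored.sum())

    @classmethod
    def uniform(cls, emotions: Sequence[str]) -> "PriorVector":
        emotions = _as_labels(emotions, "emotion")
        k = len(emotions)
        return cls(emotions, np.full(k, 1.0 / k))

    def is_uniform(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.probabilities, 1.0 / len(self.emotions), atol=tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"emotion": list(self.emotions), "probability": self.probabilities}
        )
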