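"""Encoding, cleaning and aggregation of presence/intensity ratings.

Raters first judge whether an emotion is present (yes/no) and, only if
present, rate its intensity on a 4-point scale (slightly .. intensely).
Absence is coded as intensity 0 and *included* in cross-rater means, so a
cell mean is a frequency-weighted intensity — the quantity that the
probability-matching rationale converts into a probability by row
normalization.

Cleaning follows the deposited studies' rules:

* ``accidental`` trials (absent + slight intensity, the instructed marker for
  an accidental scale click) are corrected to "emotion absent";
* ``incorrect`` trials (absent + intensity above slight) are removed
  trial-by-trial, as are ``missing`` trials;
* participants whose accidental + incorrect + missing trials exceed 10% of
  their data (strictly) are excluded entirely.

Long-format rating frames carry the columns ``participant_id``,
``stimulus_id``, ``condition``, ``emotion``, ``presence``, ``intensity`` and
optionally ``session`` and ``quality``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import (
    CONDITIONS,
    EMOTIONS,
    INTENSITY_FROM_LABEL,
    INTENSITY_MAX,
    INTENSITY_MIN,
    PRIOR_LIKELIHOOD_MAX,
    PRIOR_LIKELIHOOD_MIN,
    QUALITIES,
)
from .errors import DegenerateDataError, SchemaError
from .tables import PriorVector, ProbabilityTable, PRIOR_FLOOR

logger = logging.getLogger(__name__)

_TRUTHY = {"yes", "true", "1", "y", "t"}
_FALSY = {"no", "false", "0", "n", "f"}


@dataclass(frozen=True)
class RatingRecord:
    """One participant x stimulus x emotion judgment."""

    participant_id: str
    stimulus_id: str
    condition: str
    emotion: str
    presence: bool
    intensity: int
    session: int | None = None
    quality: str = "valid"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SchemaError(f"unknown condition {self.condition!r}")
        if self.quality not in QUALITIES:
            raise SchemaError(f"unknown quality {self.quality!r}")
        if not INTENSITY_MIN <= self.intensity <= INTENSITY_MAX:
            raise SchemaError(f"intensity {self.intensity} outside 0..4")


@dataclass(frozen=True)
class PriorRatingRecord:
    """One participant x emotion likelihood rating on the 7-point scale."""

    participant_id: str
    emotion: str
    likelihood: int

    def __post_init__(self) -> None:
        if not PRIOR_LIKELIHOOD_MIN <= self.likelihood <= PRIOR_LIKELIHOOD_MAX:
            raise SchemaError(f"likelihood {self.likelihood} outside 1..7")


def parse_presence(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise SchemaError(f"cannot parse presence value {value!r}")


def encode_rating(presence, intensity_label: str) -> int:
    """Map a (presence, intensity label) response to the ordinal 0..4 scale.

    A "no" presence response always encodes as 0, regardless of the label.
    """
    present = parse_presence(presence)
    label = str(intensity_label).strip().lower()
    if label not in INTENSITY_FROM_LABEL:
        raise SchemaError(
            f"unknown intensity label {intensity_label!r}; "
            f"expected one of {sorted(INTENSITY_FROM_LABEL)}"
        )
    if not present:
        return 0
    return INTENSITY_FROM_LABEL[label]


def annotate_quality(records: pd.DataFrame) -> pd.DataFrame:
    """Derive the per-trial ``quality`` column from raw presence/intensity.

    absent + intensity 1 -> ``accidental`` (the instructed marker for an
    accidental click); absent + intensity > 1 -> ``incorrect``; missing
    presence or intensity -> ``missing``; everything else -> ``valid``.
    Existing non-null quality annotations are preserved.
    """
    out = records.copy()
    if "quality" not in out.columns:
        out["quality"] = pd.NA
    presence = out["presence"]
    intensity = pd.to_numeric(out["intensity"], errors="coerce")
    derived = pd.Series("valid", index=out.index, dtype=object)
    missing = presence.isna() | intensity.isna()
    derived[missing] = "missing"
    absent = presence.fillna(True).astype(bool) == False  # noqa: E712
    derived[absent & intensity.eq(1)] = "accidental"
    derived[absent & intensity.gt(1)] = "incorrect"
    out["quality"] = out["quality"].where(out["quality"].notna(), derived)
    unknown = set(out["quality"].unique()) - set(QUALITIES)
    if unknown:
        raise SchemaError(f"unknown quality labels: {sorted(unknown)}")
    return out


def correct_trials(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the trial-level cleaning rules.

    Accidental trials are retained as "emotion absent" (presence False,
    intensity 0, quality valid); incorrect and missing trials are dropped.
    Returns the cleaned frame and a report counting corrections per
    participant and category.
    """
    if "quality" not in records.columns or records["quality"].isna().any():
        records = annotate_quality(records)
    out = records.copy()

    per_participant: dict[str, dict[str, int]] = {}
    flagged = out[out["quality"] != "valid"]
    for (pid, quality), group in flagged.groupby(["participant_id", "quality"], sort=True):
        per_participant.setdefault(str(pid), {})[str(quality)] = int(len(group))

    accidental = out["quality"] == "accidental"
    out.loc[accidental, "presence"] = False
    out.loc[accidental, "intensity"] = 0
    out.loc[accidental, "quality"] = "valid"
    dropped = out["quality"].isin(("incorrect", "missing"))
    report = {
        "n_accidental_corrected": int(accidental.sum()),
        "n_incorrect_removed": int((records["quality"] == "incorrect").sum()),
        "n_missing_removed": int((records["quality"] == "missing").sum()),
        "per_participant": per_participant,
    }
    cleaned = out[~dropped].reset_index(drop=True)
    return cleaned, report


def exclude_participants(
    records: pd.DataFrame, max_bad_fraction: float = 0.10
) -> tuple[pd.DataFrame, dict]:
    """Remove participants whose bad-trial fraction strictly exceeds the cap.

    "Bad" trials are accidental + incorrect + missing, counted on the raw
    (pre-correction) records; exactly ``max_bad_fraction`` is retained.
    """
    if records.empty:
        logger.warning("exclude_participants called with no records")
        return records.copy(), {
            "max_bad_fraction": max_bad_fraction,
            "excluded": {},
            "n_participants_before": 0,
            "n_participants_after": 0,
        }
    if "quality" not in records.columns or records["quality"].isna().any():
        records = annotate_quality(records)
    bad = records["quality"].isin(("accidental", "incorrect", "missing"))
    frac = bad.groupby(records["participant_id"]).mean()
    excluded = frac[frac > max_bad_fraction]
    kept = records[~records["participant_id"].isin(excluded.index)].reset_index(drop=True)
    report = {
        "max_bad_fraction": max_bad_fraction,
        "excluded": {str(pid): float(f) for pid, f in excluded.items()},
        "n_participants_before": int(frac.size),
        "n_participants_after": int(frac.size - excluded.size),
    }
    return kept, report


def _pivot_mean_intensity(
    records: pd.DataFrame, emotions: Sequence[str]
) -> pd.DataFrame:
    unknown = set(records["emotion"].unique()) - set(emotions)
    if unknown:
        raise SchemaError(f"emotions not in the configured category list: {sorted(unknown)}")
    pivot = records.pivot_table(
        index="stimulus_id", columns="emotion", values="intensity", aggfunc="mean"
    )
    pivot = pivot.reindex(columns=list(emotions))
    if pivot.isna().any().any():
        ragged = []
        for sid, row in pivot.iterrows():
            miss = [e for e in emotions if pd.isna(row[e])]
            if miss:
                ragged.append((str(sid), miss))
            if len(ragged) >= 5:
                break
        raise SchemaError(f"ragged design; stimuli missing emotion cells: {ragged}")
    return pivot


def condition_probability_table(
    records: pd.DataFrame,
    condition: str,
    emotions: Sequence[str] = EMOTIONS,
) -> ProbabilityTable:
    """Aggregate one condition's ratings into a row-stochastic table.

    Cell means of ordinal intensities (absence = 0) are taken across raters
    for each stimulus x emotion, then each stimulus row is normalized across
    emotions.  Stimuli whose every emotion was judged absent by every rater
    fall back to the uniform row and are flagged degenerate.
    """
    if condition not in CONDITIONS:
        raise SchemaError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    sub = records[records["condition"] == condition]
    if sub.empty:
        raise DegenerateDataError(f"no records for condition {condition!r}")
    pivot = _pivot_mean_intensity(sub, emotions)
    return ProbabilityTable.from_means(
        [str(s) for s in pivot.index], emotions, pivot.to_numpy(dtype=float)
    )


def prior_vector(
    prior_records: pd.DataFrame,
    emotions: Sequence[str] = EMOTIONS,
    floor: float = PRIOR_FLOOR,
) -> PriorVector:
    """Aggregate priors-task likelihood ratings into a prior vector P(e).

    Per-emotion means of the 1..7 likelihood ratings are normalized to sum
    to 1, with ``floor`` applied first so no entry can be exactly zero.
    """
    required = {"participant_id", "emotion", "likelihood"}
    missing_cols = required - set(prior_records.columns)
    if missing_cols:
        raise SchemaError(f"priors table missing columns: {sorted(missing_cols)}")
    lik = pd.to_numeric(prior_records["likelihood"], errors="raise")
    if lik.min() < PRIOR_LIKELIHOOD_MIN or lik.max() > PRIOR_LIKELIHOOD_MAX:
        raise SchemaError("likelihood ratings outside the 1..7 scale")
    unknown = set(prior_records["emotion"].unique()) - set(emotions)
    if unknown:
        raise SchemaError(f"emotions not in the configured category list: {sorted(unknown)}")
    means = lik.groupby(prior_records["emotion"]).mean().reindex(list(emotions))
    absent = [e for e in emotions if pd.isna(means[e])]
    if absent:
        raise SchemaError(f"missing emotion categories in priors data: {absent}")
    return PriorVector.from_means(emotions, means.to_numpy(dtype=float), floor=floor)
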