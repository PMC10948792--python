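"""Individual-difference machinery: cue-reliance estimates, best-model
classification, outlier screening, covariate associations, and test-retest
reliability.

A participant's face-reliance, situation-reliance and cue-integration
estimates are the Pearson correlations between their own joint-cue
probability table and fixed group-level Face-only, Situation-only and
cue-integration tables (the group tables are inputs, never re-estimated from
the individual-level sample).  Estimates are Fisher r-to-z transformed
before any second-level statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import (
    bonferroni,
    fisher_z,
    pearson_r,
    r_confint_fisher,
    t_from_r,
)
from .categories import EMOTIONS, MODEL_NAMES
from .errors import AxisMismatchError, DegenerateDataError, SchemaError
from .tables import ProbabilityTable

logger = logging.getLogger(__name__)

#: Documented tie-break precedence for best-model classification.  The
#: simpler single-cue situation account wins exact ties, then integration,
#: then face.
TIE_PRECEDENCE: tuple[str, ...] = ("situation", "integration", "face")


@dataclass(frozen=True)
class ParticipantEstimates:
    participant_id: str
    r_face: float
    r_situation: float
    r_integration: float
    z_face: float
    z_situation: float
    z_integration: float
    n_pairs: int
    best_model: str
    session: int | None = None


@dataclass(frozen=True)
class ReliabilityResult:
    """Intraclass correlation across sessions with its F test and CI."""

    icc: float
    f_stat: float
    df1: int
    df2: int
    p: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_sessions: int
    form: str = "consistency"


@dataclass(frozen=True)
class CovariateAssociation:
    estimate_name: str
    covariate_name: str
    r: float
    t_stat: float
    df: int
    p_adjusted: float
    ci_low: float
    ci_high: float
    n: int
    n_tests: int


def participant_probability_table(
    records: pd.DataFrame,
    condition: str = "joint",
    emotions: Sequence[str] = EMOTIONS,
) -> ProbabilityTable:
    """Single-rater probability table from one participant's cleaned records.

    The participant's intensity ratings for each stimulus are normalized
    across emotions (mean first, should the participant have rated a
    stimulus more than once).  Stimuli with missing emotion cells are
    dropped with a warning so downstream comparisons stay pairwise-complete;
    all-absent stimuli fall back to the uniform row and are flagged.
    """
    participants = records["participant_id"].unique()
    if len(participants) != 1:
        raise SchemaError(
            f"expected records for exactly one participant, got {len(participants)}"
        )
    sub = records[records["condition"] == condition]
    if sub.empty:
        raise DegenerateDataError(
            f"participant {participants[0]!r} has no records for condition {condition!r}"
        )
    pivot = sub.pivot_table(
        index="stimulus_id", columns="emotion", values="intensity", aggfunc="mean"
    ).reindex(columns=list(emotions))
    incomplete = pivot.index[pivot.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "participant %s: dropping %d stimuli with missing emotion cells",
            participants[0], len(incomplete),
        )
        pivot = pivot.drop(index=incomplete)
    if pivot.empty:
        raise DegenerateDataError(f"participant {participants[0]!r} has no complete stimuli")
    return ProbabilityTable.from_means(
        [str(s) for s in pivot.index], emotions, pivot.to_numpy(dtype=float)
    )


def classify_best_model(r_face: float, r_situation: float, r_integration: float) -> str:
    """Argmax over the three reliance correlations with documented tie-break.

    Exact ties resolve by the fixed precedence situation > integration >
    face.  Non-finite inputs raise so callers can exclude the participant.
    """
    values = {"face": r_face, "situation": r_situation, "integration": r_integration}
    if not all(np.isfinite(v) for v in values.values()):
        raise DegenerateDataError(f"non-finite reliance estimates: {values}")
    best = max(values.values())
    for name in TIE_PRECEDENCE:
        if values[name] == best:
            return name
    raise AssertionError("unreachable")


def reliance_estimates(
    participant_table: ProbabilityTable,
    model_tables: Mapping[str, ProbabilityTable],
    *,
    participant_id: str = "participant",
    session: int | None = None,
) -> ParticipantEstimates:
    """Correlate one participant's joint-cue table with the three model tables.

    Correlations run over all shared stimulus x emotion cells (the full
    44-stimulus subset gives 44 x 13 = 572 pairs).  A participant whose cell
    vector has zero variance is unusable and raises
    :class:`DegenerateDataError`; cohort drivers catch this and exclude the
    participant from downstream statistics.
    """
    missing = set(MODEL_NAMES) - set(model_tables)
    if missing:
        raise SchemaError(f"model_tables missing entries: {sorted(missing)}")
    shared = [s for s in participant_table.stimulus_ids
              if all(s in model_tables[m].stimulus_ids for m in MODEL_NAMES)]
    if len(shared) < 3:
        raise DegenerateDataError(
            f"participant {participant_id!r} shares only {len(shared)} stimuli "
            "with the model tables (need >= 3)"
        )
    part = participant_table.subset(shared)
    x = part.values.ravel()
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"participant {participant_id!r} has zero variance; flagged unusable"
        )
    r = {}
    for name in MODEL_NAMES:
        model = model_tables[name].subset(shared)
        if model.emotions != part.emotions:
            raise AxisMismatchError(
                f"model {name!r} emotions differ from participant table"
            )
        r[name] = pearson_r(x, model.values.ravel(), x_name="participant", y_name=name)
    return ParticipantEstimates(
        participant_id=str(participant_id),
        r_face=r["face"],
        r_situation=r["situation"],
        r_integration=r["integration"],
        z_face=fisher_z(r["face"]),
        z_situation=fisher_z(r["situation"]),
        z_integration=fisher_z(r["integration"]),
        n_pairs=len(shared) * part.n_emotions,
        best_model=classify_best_model(r["face"], r["situation"], r["integration"]),
        session=session,
    )


def cohort_estimates(
    records: pd.DataFrame,
    model_tables: Mapping[str, ProbabilityTable],
    *,
    condition: str = "joint",
    emotions: Sequence[str] = EMOTIONS,
    session: int | None = None,
) -> tuple[list[ParticipantEstimates], list[str]]:
    """Reliance estimates for every participant in a long-format frame.

    Participants whose data are degenerate (zero variance, too few shared
    stimuli) are skipped with a log entry; their ids are returned second.
    """
    estimates: list[ParticipantEstimates] = []
    skipped: list[str] = []
    for pid, group in records.groupby("participant_id", sort=True):
        try:
            table = participant_probability_table(group, condition, emotions)
            estimates.append(
                reliance_estimates(
                    table, model_tables, participant_id=str(pid), session=session
                )
            )
        except DegenerateDataError as exc:
            logger.warning("skipping participant %s: %s", pid, exc)
            skipped.append(str(pid))
    return estimates, skipped


def estimates_frame(estimates: Sequence[ParticipantEstimates]) -> pd.DataFrame:
    """Wide frame of reliance estimates indexed by participant."""
    df = pd.DataFrame([vars(e) for e in estimates])
    return df.set_index("participant_id")


def group_shares(estimates: Sequence[ParticipantEstimates]) -> dict[str, float]:
    """Percentage of the cohort best fit by each model."""
    if not estimates:
        raise DegenerateDataError("no estimates to summarize")
    counts = {name: 0 for name in MODEL_NAMES}
    for e in estimates:
        counts[e.best_model] += 1
    total = len(estimates)
    return {name: 100.0 * c / total for name, c in counts.items()}


def mahalanobis_outliers(
    z_matrix,
    alpha: float = 0.001,
    *,
    return_distances: bool = False,
):
    """Classical Mahalanobis screening of a participants x estimates matrix.

    Squared distances from the column-mean vector under the sample
    covariance are compared with the chi-square quantile at 1 - ``alpha``
    (df = number of columns); rows beyond the cutoff are flagged.  Returns
    the flagged row labels (positions for plain arrays), optionally together
    with the full distance vector.
    """
    if isinstance(z_matrix, pd.DataFrame):
        labels = list(z_matrix.index)
        X = z_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(z_matrix, dtype=float)
        labels = list(range(X.shape[0]))
    if X.ndim != 2:
        raise SchemaError("z_matrix must be 2-D (participants x estimate columns)")
    n, p = X.shape
    if n <= p:
        raise DegenerateDataError(
            f"need more rows than columns for a covariance estimate ({n} x {p})"
        )
    if not np.all(np.isfinite(X)):
        raise SchemaError("non-finite entries in z_matrix")
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if np.linalg.cond(cov) > 1e12:
        raise DegenerateDataError(
            "singular covariance matrix; prune collinear estimate columns"
        )
    centered = X - X.mean(axis=0)
    d2 = np.einsum("ij,ij->i", centered @ np.linalg.inv(cov), centered)
    cutoff = stats.chi2.ppf(1.0 - alpha, df=p)
    flagged = [labels[i] for i in np.flatnonzero(d2 > cutoff)]
    if return_distances:
        return flagged, d2
    return flagged


def covariate_association(
    estimates,
    covariate,
    *,
    n_tests: int = 1,
    estimate_name: str = "estimate",
    covariate_name: str = "covariate",
) -> CovariateAssociation:
    """Pearson association between a reliance estimate and a covariate score.

    Two-tailed t test with df = n - 2, Bonferroni-multiplied p capped at 1,
    and an (unadjusted) 95% Fisher-z confidence interval.  Inputs are the
    already outlier-screened, paired observations.
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("estimate and covariate must be 1-D and aligned")
    n = x.size
    if n < 4:
        raise DegenerateDataError(f"need at least 4 paired observations, got {n}")
    r = pearson_r(x, y, x_name=estimate_name, y_name=covariate_name)
    t = t_from_r(r, n)
    p_raw = float(2.0 * stats.t.sf(abs(t), n - 2)) if np.isfinite(t) else 0.0
    lo, hi = r_confint_fisher(r, n)
    # A numerically perfect fit pins the interval endpoint at +/-1.
    if r >= 1.0:
        hi = 1.0
    if r <= -1.0:
        lo = -1.0
    return CovariateAssociation(
        estimate_name=estimate_name,
        covariate_name=covariate_name,
        r=r,
        t_stat=t,
        df=n - 2,
        p_adjusted=bonferroni(min(1.0, p_raw), n_tests),
        ci_low=lo,
        ci_high=hi,
        n=n,
        n_tests=n_tests,
    )


def _align_sessions(session1, session2) -> tuple[np.ndarray, np.ndarray, int]:
    if isinstance(session1, pd.Series) and isinstance(session2, pd.Series):
        only1 = sorted(set(session1.index) - set(session2.index))
        only2 = sorted(set(session2.index) - set(session1.index))
        if only1 or only2:
            raise AxisMismatchError(
                f"participant sets differ; only in session 1: {only1[:10]}, "
                f"only in session 2: {only2[:10]}"
            )
        session2 = session2.reindex(session1.index)
    y1 = np.asarray(session1, dtype=float)
    y2 = np.asarray(session2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise SchemaError("sessions must be 1-D and of equal length")
    if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))):
        raise SchemaError("non-finite session values")
    return y1, y2, y1.size


def icc_consistency(
    session1,
    session2,
    *,
    form: str = "consistency",
    ci_level: float = 0.95,
) -> ReliabilityResult:
    """Two-way, single-measure intraclass correlation across two sessions.

    The default ``consistency`` form is ICC(3,1): subjects are random rows,
    sessions fixed columns, and session main effects do not count against
    agreement.  F = MS_rows / MS_error with df (n - 1, (n - 1)(k - 1)) —
    (n - 1, n - 1) for two sessions — a two-tailed p, and the F-based
    confidence interval (which can dip below zero for weak reliability).
    ``form="agreement"`` returns the absolute-agreement point estimate
    ICC(2,1) with the same ANOVA F; its exact interval is not implemented
    (ci bounds are NaN).
    """
    if form not in ("consistency", "agreement"):
        raise ValueError(f"unknown ICC form {form!r}")
    y1, y2, n = _align_sessions(session1, session2)
    if n < 5:
        raise DegenerateDataError(f"need at least 5 subjects, got {n}")
    Y = np.column_stack([y1, y2])
    k = Y.shape[1]
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(0.0, ss_total - ss_rows - ss_cols)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_rows = ss_rows / df1
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / df2
    # Identical sessions leave only floating-point residue in the error
    # term; treat it as the exact zero it is mathematically.
    if ms_err <= 1e-12 * ms_rows:
        ms_err = 0.0

    if ms_err == 0.0:
        if form == "consistency":
            icc = 1.0 if ms_rows > 0 else 0.0
            ci_low = ci_high = icc
        else:
            denom = ms_rows + k / n * ms_cols
            icc = ms_rows / denom if denom > 0 else 0.0
            ci_low = ci_high = float("nan")
        return ReliabilityResult(
            icc=icc, f_stat=float("inf"), df1=df1, df2=df2, p=0.0,
            ci_low=ci_low, ci_high=ci_high, n_subjects=n, k_sessions=k, form=form,
        )

    f_obs = ms_rows / ms_err
    if form == "consistency":
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        alpha = 1.0 - ci_level
        f_lower = f_obs / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
        f_upper = f_obs * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
        ci_low = (f_lower - 1.0) / (f_lower + k - 1.0)
        ci_high = (f_upper - 1.0) / (f_upper + k - 1.0)
    else:
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
        )
        ci_low = ci_high = float("nan")
    p = min(1.0, 2.0 * min(stats.f.sf(f_obs, df1, df2), stats.f.cdf(f_obs, df1, df2)))
    return ReliabilityResult(
        icc=float(icc), f_stat=float(f_obs), df1=df1, df2=df2, p=float(p),
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_subjects=n, k_sessions=k, form=form,
    )
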