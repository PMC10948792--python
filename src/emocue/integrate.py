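"""Bayesian combination of situation and face cues under the lay theory.

The lay causal theory — situations cause emotions, emotions cause facial
expressions — implies that an observer who sees both cues should hold

    P(e | s, f)  proportional to  P(e | s) P(e | f) / P(e)

per emotion category e.  The proportionality constant is restored by
renormalizing each stimulus row to sum to 1.  Setting ``flat_prior=True``
replaces P(e) with the uniform distribution, the variant used to test
whether empirically measured priors are informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AxisMismatchError, SchemaError
from .tables import PriorVector, ProbabilityTable, assert_aligned


@dataclass(frozen=True)
class IntegrationResult:
    """Model P(e|s,f) table plus the prior actually used."""

    table: ProbabilityTable
    prior_used: PriorVector
    flat_prior: bool

    def __post_init__(self) -> None:
        if self.flat_prior and not self.prior_used.is_uniform(tol=1e-12):
            raise SchemaError("flat_prior result must carry a uniform prior")


def uniform_prior(emotions: Sequence[str]) -> PriorVector:
    """The uninformative prior: 1/K for each of the K categories."""
    if not list(emotions):
        raise SchemaError("empty emotion category list")
    return PriorVector.uniform(emotions)


def integrate(
    situation: ProbabilityTable,
    face: ProbabilityTable,
    prior: PriorVector,
    flat_prior: bool = False,
) -> IntegrationResult:
    """Combine single-cue tables with a prior into the cue-integration table.

    Cell-wise P(e|s) * P(e|f) / P(e), each stimulus row renormalized.  The
    two likelihood tables enter symmetrically.  Rows that are identically
    zero before renormalization (possible only with degenerate inputs) fall
    back to the uniform distribution and are flagged; degenerate flags from
    the inputs are propagated.
    """
    assert_aligned(situation, face)
    if flat_prior:
        prior = PriorVector.uniform(situation.emotions)
    if prior.emotions != situation.emotions:
        raise AxisMismatchError(
            f"prior emotions {list(prior.emotions)} do not match table "
            f"emotions {list(situation.emotions)}"
        )
    if np.any(prior.probabilities <= 0):
        raise SchemaError(
            "prior has a zero entry; rebuild it with PriorVector.from_means "
            "(floor > 0) before integrating"
        )
    ratio = situation.values * face.values / prior.probabilities[np.newaxis, :]
    table = ProbabilityTable.from_means(
        situation.stimulus_ids,
        situation.emotions,
        ratio,
        extra_degenerate=situation.degenerate_rows | face.degenerate_rows,
    )
    return IntegrationResult(table=table, prior_used=prior, flat_prior=flat_prior)
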