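"""Synthetic generative world for the rating pipeline.

The generator mirrors the causal lay theory: every stimulus has a latent
situation-conditional emotion distribution (a Dirichlet draw), and a
face-conditional distribution that is a ``face_informativeness``-weighted
mixture of the situation row with an independent Dirichlet draw.  At
``face_informativeness = 1`` the face is perfectly redundant with the
situation; at 0 it is an independent signal.  A per-category
``category_boost`` *reduces* the face-situation coupling for that emotion
column: in this world, face variance that is independent of the situation
is exactly the signal joint-cue raters can only pick up from the face, so a
boosted category is one whose facial cue carries extra information beyond
the situation (the happiness analog).

Synthetic raters hold one of the competing strategies — face-reliant,
situation-reliant, integrating, or a weighted mixture — and convert their
target distribution to ratings by probability matching: expected intensity
is 4 x target probability, perturbed by truncated Gaussian noise on the 0-4
scale and rounded to the ordinal grid (a multinomial sampling mode is
available as an alternative response process).  Presence is intensity > 0.

Seeds are mandatory everywhere; identical specs and seeds reproduce
bitwise-identical records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CONDITIONS, EMOTIONS
from .errors import SchemaError
from .integrate import integrate
from .tables import PriorVector, ProbabilityTable, assert_aligned

RATER_TYPES = ("face", "situation", "integrator", "mixed")

#: Dirichlet concentration for the global prior draw: mildly informative
#: base rates, never near zero.
_PRIOR_CONCENTRATION = 5.0


@dataclass(frozen=True)
class StimulusSpaceSpec:
    """Parameters of the generative stimulus world."""

    n_stimuli: int
    seed: int
    emotions: tuple[str, ...] = EMOTIONS
    concentration: float = 0.7
    face_informativeness: float = 0.9
    category_boost: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_stimuli < 1:
            raise SchemaError("n_stimuli must be >= 1")
        if self.concentration <= 0:
            raise SchemaError("concentration must be > 0")
        if not 0.0 <= self.face_informativeness <= 1.0:
            raise SchemaError("face_informativeness must lie in [0, 1]")
        for emo, boost in (self.category_boost or {}).items():
            if emo not in self.emotions:
                raise SchemaError(f"category_boost names unknown emotion {emo!r}")
            if not 0.0 <= boost <= 1.0:
                raise SchemaError(f"category_boost for {emo!r} must lie in [0, 1]")


@dataclass(frozen=True)
class RaterProfile:
    """A synthetic rater: strategy, response noise, retest stability, seed."""

    participant_id: str
    rater_type: str
    noise_sd: float
    seed: int
    stability: float = 1.0
    weights: tuple[float, float, float] | None = None  # (face, situation, integration)

    def __post_init__(self) -> None:
        if self.rater_type not in RATER_TYPES:
            raise SchemaError(f"unknown rater_type {self.rater_type!r}")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")
        if not 0.0 <= self.stability <= 1.0:
            raise SchemaError("stability must lie in [0, 1]")
        if self.rater_type == "mixed":
            if self.weights is None:
                raise SchemaError("mixed raters need explicit weights")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (3,) or w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
                raise SchemaError("weights must be 3 non-negative values summing to 1")

    def weight_vector(self) -> np.ndarray:
        """(face, situation, integration) mixture weights of the strategy."""
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return {
            "face": np.array([1.0, 0.0, 0.0]),
            "situation": np.array([0.0, 1.0, 0.0]),
            "integrator": np.array([0.0, 0.0, 1.0]),
        }[self.rater_type]


def simulate_stimulus_space(
    spec: StimulusSpaceSpec,
) -> tuple[ProbabilityTable, ProbabilityTable, PriorVector]:
    """Draw (situation table, face table, prior) for one synthetic world."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.emotions)
    alpha = np.full(k, spec.concentration)
    situation = rng.dirichlet(alpha, size=spec.n_stimuli)
    independent = rng.dirichlet(alpha, size=spec.n_stimuli)
    weights = np.full(k, spec.face_informativeness)
    for emo, boost in (spec.category_boost or {}).items():
        j = spec.emotions.index(emo)
        weights[j] = float(np.clip(spec.face_informativeness - boost, 0.0, 1.0))
    face_raw = situation * weights + independent * (1.0 - weights)
    prior_raw = rng.dirichlet(np.full(k, _PRIOR_CONCENTRATION))
    ids = [f"s{i:04d}" for i in range(spec.n_stimuli)]
    situation_table = ProbabilityTable.from_means(ids, spec.emotions, situation)
    face_table = ProbabilityTable.from_means(ids, spec.emotions, face_raw)
    prior = PriorVector.from_means(spec.emotions, prior_raw)
    return situation_table, face_table, prior


def make_profiles(
    n: int,
    rater_type: str,
    noise_sd,
    seed: int,
    *,
    prefix: str | None = None,
    stability: float = 1.0,
    weights_alpha: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[RaterProfile]:
    """Build a cohort of rater profiles with derived per-rater seeds.

    ``noise_sd`` may be a scalar (shared by the cohort) or a ``(low, high)``
    pair, in which case each rater's noise is drawn uniformly from that
    range — stable individual differences in reliability.  ``mixed`` cohorts
    draw per-rater strategy weights from a Dirichlet with ``weights_alpha``.
    """
    if n < 1:
        raise SchemaError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    if np.isscalar(noise_sd):
        noises = np.full(n, float(noise_sd))
    else:
        lo, hi = noise_sd
        noises = rng.uniform(float(lo), float(hi), size=n)
    weights = None
    if rater_type == "mixed":
        weights = rng.dirichlet(np.asarray(weights_alpha, dtype=float), size=n)
    prefix = prefix or rater_type
    return [
        RaterProfile(
            participant_id=f"{prefix}{i:03d}",
            rater_type=rater_type,
            noise_sd=float(noises[i]),
            seed=int(seeds[i]),
            stability=stability,
            weights=tuple(weights[i]) if weights is not None else None,
        )
        for i in range(n)
    ]


def _rate(target: np.ndarray, rng: np.random.Generator, noise_sd: float, mode: str) -> np.ndarray:
    """Ordinal 0..4 intensity responses for one rater across all stimuli."""
    if mode == "gaussian":
        mu = 4.0 * target
        x = mu + rng.normal(0.0, noise_sd, size=target.shape) if noise_sd > 0 else mu
        return np.rint(np.clip(x, 0.0, 4.0)).astype(np.int64)
    if mode == "multinomial":
        # Probability-matching responses: four independent category draws
        # per stimulus, the per-category count serving as its intensity.
        out = np.empty(target.shape, dtype=np.int64)
        for i in range(target.shape[0]):
            out[i] = rng.multinomial(4, target[i])
        return out
    raise SchemaError(f"unknown response mode {mode!r}")


def simulate_raters(
    situation: ProbabilityTable,
    face: ProbabilityTable,
    prior: PriorVector,
    profiles: Sequence[RaterProfile],
    conditions: Iterable[str] = ("joint",),
    *,
    mode: str = "gaussian",
    session: int | None = None,
) -> pd.DataFrame:
    """Long-format rating records for a cohort under the requested conditions.

    In ``face_only`` / ``situation_only`` conditions the rater's target is
    the shown cue's row regardless of strategy; in the ``joint`` condition
    it is the strategy's mixture of the face row, situation row, and the
    cue-integration row.
    """
    profiles = list(profiles)
    if not profiles:
        raise SchemaError("empty profile list")
    assert_aligned(situation, face)
    conditions = sorted(set(conditions), key=CONDITIONS.index)
    if not conditions:
        raise SchemaError("no conditions requested")
    bad = set(conditions) - set(CONDITIONS)
    if bad:
        raise SchemaError(f"unknown conditions: {sorted(bad)}")

    integration = None
    if "joint" in conditions:
        integration = integrate(situation, face, prior).table

    n_stim = situation.n_stimuli
    k = situation.n_emotions
    stim_col = np.repeat(np.asarray(situation.stimulus_ids, dtype=object), k)
    emo_col = np.tile(np.asarray(situation.emotions, dtype=object), n_stim)

    chunks: list[dict] = []
    for profile in profiles:
        rng = np.random.default_rng(profile.seed)
        for condition in conditions:
            if condition == "face_only":
                target = face.values
            elif condition == "situation_only":
                target = situation.values
            else:
                w = profile.weight_vector()
                target = (
                    w[0] * face.values + w[1] * situation.values + w[2] * integration.values
                )
            intensity = _rate(target, rng, profile.noise_sd, mode).ravel()
            chunks.append(
                {
                    "participant_id": np.full(n_stim * k, profile.participant_id, dtype=object),
                    "stimulus_id": stim_col,
                    "condition": np.full(n_stim * k, condition, dtype=object),
                    "emotion": emo_col,
                    "presence": intensity > 0,
                    "intensity": intensity,
                }
            )
    out = pd.DataFrame(
        {
            key: np.concatenate([c[key] for c in chunks])
            for key in ("participant_id", "stimulus_id", "condition", "emotion",
                        "presence", "intensity")
        }
    )
    out["quality"] = "valid"
    if session is not None:
        out["session"] = int(session)
    return out


def simulate_prior_ratings(
    prior: PriorVector, n_participants: int, seed: int, *, noise_sd: float = 1.0
) -> pd.DataFrame:
    """Synthetic priors-task responses on the 7-point likelihood scale.

    Each participant's expected rating is a monotone map of the true base
    rate onto 1..7 (the most likely category maps to 7), perturbed by
    Gaussian noise and rounded to the ordinal grid.
    """
    if n_participants < 1:
        raise SchemaError("need at least one participant")
    rng = np.random.default_rng(seed)
    p = prior.probabilities
    mu = 1.0 + 6.0 * p / p.max()
    ratings = np.rint(
        np.clip(mu + rng.normal(0.0, noise_sd, size=(n_participants, p.size)), 1.0, 7.0)
    ).astype(np.int64)
    k = p.size
    return pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"prior{i:03d}" for i in range(n_participants)], k
            ),
            "emotion": np.tile(np.asarray(prior.emotions, dtype=object), n_participants),
            "likelihood": ratings.ravel(),
        }
    )


def simulate_retest(
    situation: ProbabilityTable,
    face: ProbabilityTable,
    prior: PriorVector,
    profiles: Sequence[RaterProfile],
    stability: float,
    seed: int,
    *,
    mode: str = "gaussian",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-session joint-cue ratings with controllable rater persistence.

    Session-2 rater parameters are a ``stability``-weighted blend of the
    session-1 parameters with fresh draws (strategy weights blended on the
    simplex; noise levels blended with a permutation of the cohort's own
    noise values so the marginal distribution is preserved).  At
    ``stability = 1`` the session-1 profiles are reused verbatim — including
    their response-noise seeds — so the two sessions are identical: the
    idealized perfectly stable rater.  At ``stability = 0`` session-2
    parameters are independent redraws.
    """
    if not 0.0 <= stability <= 1.0:
        raise SchemaError("stability must lie in [0, 1]")
    profiles = list(profiles)
    session1 = simulate_raters(
        situation, face, prior, profiles, ("joint",), mode=mode, session=1
    )
    if stability == 1.0:
        profiles2 = profiles
    else:
        rng = np.random.default_rng(seed)
        fresh_weights = rng.dirichlet(np.ones(3), size=len(profiles))
        fresh_noise = rng.permutation([p.noise_sd for p in profiles])
        new_seeds = rng.integers(0, 2**31 - 1, size=len(profiles))
        profiles2 = []
        for i, p in enumerate(profiles):
            w1 = p.weight_vector()
            w2 = stability * w1 + (1.0 - stability) * fresh_weights[i]
            w2 = w2 / w2.sum()
            profiles2.append(
                dataclasses.replace(
                    p,
                    rater_type="mixed",
                    weights=tuple(w2),
                    noise_sd=float(stability * p.noise_sd + (1.0 - stability) * fresh_noise[i]),
                    seed=int(new_seeds[i]),
                    stability=stability,
                )
            )
    session2 = simulate_raters(
        situation, face, prior, profiles2, ("joint",), mode=mode, session=2
    )
    return session1, session2
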