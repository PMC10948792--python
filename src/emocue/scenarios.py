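"""Reference end-to-end simulation scenarios.

These functions wire the synthetic world through the *full* pipeline —
simulated ratings in, cleaned and aggregated tables, integration, model
comparison, individual estimates, retest reliability out — at the study
scale the package is designed around: 44 stimuli x 13 emotions for
individual-difference designs, a larger stimulus pool for the group-level
comparison.  They back both the validation suite and the reproduction
script, so the numbers those report are always produced by the same code
path a user of the library would run.

The default joint-cue cohort is heterogeneous: a majority of
situation-reliant raters with smaller integrating and face-reliant groups
(59 / 23 / 18 percent), emulating the predominantly situation-reliant
populations these rating tasks recruit.  In the group-comparison scenario
the face-only cohort rates with elevated noise: isolated facial portrayals
are the harder judgment, and that degraded face table is what leaves the
Face-only model the weakest while pulling the integration model's fit down
to the Situation-only model's level.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .compare import compare_models, per_emotion_bootstrap_difference
from .individuals import cohort_estimates, estimates_frame, group_shares, icc_consistency
from .integrate import integrate
from .ratings import condition_probability_table, prior_vector
from .simulate import (
    RaterProfile,
    StimulusSpaceSpec,
    make_profiles,
    simulate_prior_ratings,
    simulate_raters,
    simulate_retest,
    simulate_stimulus_space,
)

#: Default composition of a heterogeneous joint-cue cohort
#: (face, situation, integrator shares).
COHORT_SHARES: dict[str, float] = {"face": 0.18, "situation": 0.59, "integrator": 0.23}

#: Default response-noise levels (sd on the 0-4 intensity scale).  Face-only
#: raters are noisier: judging an isolated portrayal is the harder task, and
#: this is what leaves the estimated face table the weakest single-cue model.
NOISE_SD = 0.5
FACE_NOISE_SD = 1.2


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def heterogeneous_cohort(
    n: int,
    seed: int,
    *,
    noise_sd: float = NOISE_SD,
    shares: Mapping[str, float] = COHORT_SHARES,
    prefix: str = "joint",
) -> list[RaterProfile]:
    """Pure-strategy raters in the given proportions (largest remainders)."""
    counts = {t: int(np.floor(n * s)) for t, s in shares.items()}
    order = sorted(shares, key=lambda t: n * shares[t] - counts[t], reverse=True)
    i = 0
    while sum(counts.values()) < n:
        counts[order[i % len(order)]] += 1
        i += 1
    profiles: list[RaterProfile] = []
    for rater_type, s in zip(sorted(counts), _child_seeds(seed, len(counts))):
        if counts[rater_type]:
            profiles.extend(
                make_profiles(
                    counts[rater_type], rater_type, noise_sd, s,
                    prefix=f"{prefix}_{rater_type}",
                )
            )
    return profiles


def study_pipeline(
    seed: int,
    *,
    n_stimuli: int = 44,
    n_raters: int = 30,
    n_prior_raters: int = 45,
    noise_sd: float = NOISE_SD,
    face_noise_sd: float | None = None,
    category_boost: Mapping[str, float] | None = None,
) -> dict:
    """Simulate a world plus single-cue cohorts and estimate all model tables.

    ``face_noise_sd`` defaults to ``noise_sd``; the group-comparison scenario
    passes the elevated :data:`FACE_NOISE_SD` instead.

    Returns the generative truth (``situation_true`` etc.) alongside the
    pipeline estimates (``situation``, ``face``, ``prior``, ``integration``,
    ``integration_flat``) so recovery can be checked.
    """
    if face_noise_sd is None:
        face_noise_sd = noise_sd
    s_world, s_face, s_sit, s_prior = _child_seeds(seed, 4)
    spec = StimulusSpaceSpec(
        n_stimuli=n_stimuli, seed=s_world, category_boost=category_boost
    )
    situation_true, face_true, prior_true = simulate_stimulus_space(spec)

    face_raters = make_profiles(n_raters, "face", face_noise_sd, s_face, prefix="fc")
    sit_raters = make_profiles(n_raters, "situation", noise_sd, s_sit, prefix="sc")
    face_records = simulate_raters(
        situation_true, face_true, prior_true, face_raters, ("face_only",)
    )
    sit_records = simulate_raters(
        situation_true, face_true, prior_true, sit_raters, ("situation_only",)
    )
    prior_records = simulate_prior_ratings(prior_true, n_prior_raters, s_prior)

    face_table = condition_probability_table(face_records, "face_only", spec.emotions)
    situation_table = condition_probability_table(
        sit_records, "situation_only", spec.emotions
    )
    prior_est = prior_vector(prior_records, spec.emotions)
    integration_table = integrate(situation_table, face_table, prior_est).table
    integration_flat = integrate(
        situation_table, face_table, prior_est, flat_prior=True
    ).table
    return {
        "spec": spec,
        "situation_true": situation_true,
        "face_true": face_true,
        "prior_true": prior_true,
        "situation": situation_table,
        "face": face_table,
        "prior": prior_est,
        "integration": integration_table,
        "integration_flat": integration_flat,
    }


def group_comparison_run(
    seed: int,
    *,
    n_stimuli: int = 44,
    n_raters: int = 30,
    n_joint_raters: int = 25,
    noise_sd: float = NOISE_SD,
    face_noise_sd: float = FACE_NOISE_SD,
    n_boot: int = 2_000,
    category_boost: Mapping[str, float] | None = None,
) -> dict:
    """Group-level model comparison on one simulated study.

    A heterogeneous joint-cue cohort provides the empirical table; the three
    models (plus the flat-prior integration variant) come from
    :func:`study_pipeline`.  Returns the pipeline outputs together with
    ``fits`` and pairwise ``differences``.
    """
    world = study_pipeline(
        seed,
        n_stimuli=n_stimuli,
        n_raters=n_raters,
        noise_sd=noise_sd,
        face_noise_sd=face_noise_sd,
        category_boost=category_boost,
    )
    s_joint, s_boot = _child_seeds(seed + 1, 2)
    joint_cohort = heterogeneous_cohort(n_joint_raters, s_joint, noise_sd=noise_sd)
    joint_records = simulate_raters(
        world["situation_true"], world["face_true"], world["prior_true"],
        joint_cohort, ("joint",),
    )
    empirical = condition_probability_table(joint_records, "joint", world["spec"].emotions)
    models = {
        "situation": world["situation"],
        "integration": world["integration"],
        "face": world["face"],
        "integration_flat": world["integration_flat"],
    }
    comparison = compare_models(empirical, models, seed=s_boot, n_boot=n_boot)
    return {**world, "empirical": empirical, "models": models, **comparison}


def per_emotion_contrast(
    run: dict,
    emotion: str,
    *,
    seed: int,
    n_boot: int = 2_000,
):
    """Bootstrap contrast r(integration) - r(situation) for one category."""
    return per_emotion_bootstrap_difference(
        run["empirical"],
        run["integration"],
        run["situation"],
        emotion,
        seed=seed,
        n_boot=n_boot,
        model_a_name="integration",
        model_b_name="situation",
    )


def boosted_contrast_run(
    seed: int,
    *,
    boost_emotion: str = "happiness",
    boost: float = 0.8,
    n_stimuli: int = 120,
    n_joint_raters: int = 40,
    noise_sd: float = NOISE_SD,
    n_boot: int = 1_000,
):
    """Per-emotion contrast for a category with a selectively diagnostic face.

    The boosted category's facial cue carries strong information beyond the
    situation (``boost`` is subtracted from its face-situation coupling), and
    the joint-cue cohort *integrates* — a diagnostic cue can only surface in
    judgments if perceivers use it, so this demonstration pairs the stimulus
    manipulation with integrating raters and face raters at baseline noise.
    Returns the bootstrap contrast r(integration) - r(situation) for the
    boosted category.
    """
    world = study_pipeline(
        seed,
        n_stimuli=n_stimuli,
        noise_sd=noise_sd,
        face_noise_sd=noise_sd,
        category_boost={boost_emotion: boost},
    )
    s_joint, s_boot = _child_seeds(seed + 1, 2)
    cohort = make_profiles(n_joint_raters, "integrator", noise_sd, s_joint, prefix="jt")
    records = simulate_raters(
        world["situation_true"], world["face_true"], world["prior_true"],
        cohort, ("joint",),
    )
    empirical = condition_probability_table(records, "joint", world["spec"].emotions)
    return per_emotion_bootstrap_difference(
        empirical,
        world["integration"],
        world["situation"],
        boost_emotion,
        seed=s_boot,
        n_boot=n_boot,
        model_a_name="integration",
        model_b_name="situation",
    )


def classification_recovery_run(
    seed: int,
    noise_sd: float,
    *,
    n_per_type: int = 30,
    n_stimuli: int = 44,
) -> float:
    """Classification accuracy for cohorts of pure-strategy raters.

    Generates ``n_per_type`` raters of each strategy, estimates the group
    model tables through the full pipeline, classifies every rater by their
    best-fitting model, and returns the fraction classified as their
    generating type.
    """
    world = study_pipeline(seed, n_stimuli=n_stimuli)
    s_f, s_s, s_i = _child_seeds(seed + 1, 3)
    truth = {"face": "face", "situation": "situation", "integrator": "integration"}
    cohort: list[RaterProfile] = []
    for rater_type, s in zip(("face", "situation", "integrator"), (s_f, s_s, s_i)):
        cohort.extend(
            make_profiles(n_per_type, rater_type, noise_sd, s, prefix=f"r_{rater_type}")
        )
    records = simulate_raters(
        world["situation_true"], world["face_true"], world["prior_true"],
        cohort, ("joint",),
    )
    model_tables = {
        "face": world["face"],
        "situation": world["situation"],
        "integration": world["integration"],
    }
    estimates, _ = cohort_estimates(records, model_tables, emotions=world["spec"].emotions)
    by_id = {p.participant_id: truth[p.rater_type] for p in cohort}
    hits = sum(1 for e in estimates if e.best_model == by_id[e.participant_id])
    return hits / len(estimates)


def retest_run(
    seed: int,
    stability: float,
    *,
    n_participants: int = 110,
    n_stimuli: int = 44,
    noise_range: tuple[float, float] = (0.3, 1.2),
) -> dict:
    """Two-session reliability of the three reliance estimates.

    The cohort is heterogeneous in both strategy (Dirichlet(1,1,1) weights)
    and reliability (uniform noise range) — the stable individual
    differences whose persistence across sessions ``stability`` controls.
    Returns one :class:`~emocue.individuals.ReliabilityResult` per estimate.
    """
    world = study_pipeline(seed, n_stimuli=n_stimuli)
    s_cohort, s_retest = _child_seeds(seed + 1, 2)
    cohort = make_profiles(
        n_participants, "mixed", noise_range, s_cohort, prefix="rt"
    )
    records1, records2 = simulate_retest(
        world["situation_true"], world["face_true"], world["prior_true"],
        cohort, stability, s_retest,
    )
    model_tables = {
        "face": world["face"],
        "situation": world["situation"],
        "integration": world["integration"],
    }
    est1, skipped1 = cohort_estimates(
        records1, model_tables, emotions=world["spec"].emotions, session=1
    )
    est2, skipped2 = cohort_estimates(
        records2, model_tables, emotions=world["spec"].emotions, session=2
    )
    f1 = estimates_frame(est1)
    f2 = estimates_frame(est2)
    common = f1.index.intersection(f2.index)
    out = {}
    for name in ("face", "situation", "integration"):
        col = f"z_{name}"
        out[name] = icc_consistency(f1.loc[common, col], f2.loc[common, col])
    return out


def individual_differences_run(
    seed: int,
    *,
    n_participants: int = 130,
    n_stimuli: int = 44,
    noise_range: tuple[float, float] = (0.3, 1.2),
) -> dict:
    """Individual-difference study on one simulated cohort.

    A heterogeneous pure-strategy cohort rates the joint-cue condition; the
    run returns per-participant estimates and cohort best-model shares.
    """
    world = study_pipeline(seed, n_stimuli=n_stimuli)
    s_cohort = _child_seeds(seed + 1, 1)[0]
    cohort = heterogeneous_cohort(n_participants, s_cohort, noise_sd=NOISE_SD)
    records = simulate_raters(
        world["situation_true"], world["face_true"], world["prior_true"],
        cohort, ("joint",),
    )
    model_tables = {
        "face": world["face"],
        "situation": world["situation"],
        "integration": world["integration"],
    }
    estimates, skipped = cohort_estimates(
        records, model_tables, emotions=world["spec"].emotions
    )
    return {
        **world,
        "estimates": estimates,
        "skipped": skipped,
        "shares": group_shares(estimates),
    }
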