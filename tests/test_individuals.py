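import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emocue._stats import fisher_z
from emocue.errors import AxisMismatchError, DegenerateDataError, SchemaError
from emocue.individuals import (
    classify_best_model,
    cohort_estimates,
    covariate_association,
    icc_consistency,
    mahalanobis_outliers,
    participant_probability_table,
    reliance_estimates,
)
from emocue.ratings import condition_probability_table
from emocue.tables import ProbabilityTable

from conftest import THREE_EMOTIONS, make_ratings, random_table


def model_tables(rng, n=10):
    emp = random_table(rng, n)
    return {
        name: ProbabilityTable(
            emp.stimulus_ids, THREE_EMOTIONS, rng.dirichlet([0.8] * 3, size=n)
        )
        for name in ("face", "situation", "integration")
    }


class TestParticipantTable:
    def test_hand_example(self):
        rows = [
            ("p", "A", "joint", "anger", True, 2),
            ("p", "A", "joint", "fear", True, 2),
            ("p", "A", "joint", "happiness", False, 0),
        ]
        t = participant_probability_table(make_ratings(rows), emotions=THREE_EMOTIONS)
        np.testing.assert_allclose(t.row("A"), [0.5, 0.5, 0.0], atol=1e-12)

    def test_all_absent_stimulus_goes_uniform_and_flagged(self):
        rows = [("p", "A", "joint", e, False, 0) for e in THREE_EMOTIONS]
        t = participant_probability_table(make_ratings(rows), emotions=THREE_EMOTIONS)
        np.testing.assert_allclose(t.row("A"), 1 / 3)
        assert t.degenerate_rows == {"A"}

    def test_incomplete_stimulus_dropped_with_warning(self, caplog):
        rows = [
            ("p", "A", "joint", "anger", True, 2),
            ("p", "B", "joint", "anger", True, 2),
            ("p", "B", "joint", "fear", True, 1),
            ("p", "B", "joint", "happiness", False, 0),
        ]
        with caplog.at_level("WARNING"):
            t = participant_probability_table(
                make_ratings(rows), emotions=THREE_EMOTIONS
            )
        assert t.stimulus_ids == ("B",)

    def test_matches_group_aggregation_for_a_single_rater(self, rng):
        rows = []
        for s in range(6):
            for e, x in zip(THREE_EMOTIONS, rng.integers(0, 5, size=3)):
                rows.append(("p", f"s{s}", "joint", e, x > 0, int(x)))
        df = make_ratings(rows)
        t_ind = participant_probability_table(df, emotions=THREE_EMOTIONS)
        t_grp = condition_probability_table(df, "joint", THREE_EMOTIONS)
        np.testing.assert_allclose(t_ind.values, t_grp.values, atol=1e-12)

    def test_two_participants_rejected(self):
        rows = [("p", "A", "joint", "anger", True, 1),
                ("q", "A", "joint", "anger", True, 1)]
        with pytest.raises(SchemaError, match="one participant"):
            participant_probability_table(make_ratings(rows))


class TestRelianceEstimates:
    def test_perfect_match_to_one_model(self, rng):
        tables = model_tables(rng)
        participant = tables["situation"]
        est = reliance_estimates(participant, tables, participant_id="p1")
        assert est.r_situation == pytest.approx(1.0)
        assert est.best_model == "situation"
        assert est.n_pairs == 10 * 3
        assert est.z_situation == pytest.approx(fisher_z(1.0))

    def test_invariant_to_common_stimulus_reordering(self, rng):
        tables = model_tables(rng)
        participant = random_table(rng, 10)
        est1 = reliance_estimates(participant, tables)
        perm = list(participant.stimulus_ids[::-1])
        est2 = reliance_estimates(
            participant.subset(perm), {k: v.subset(perm) for k, v in tables.items()}
        )
        for attr in ("r_face", "r_situation", "r_integration", "best_model"):
            assert getattr(est1, attr) == pytest.approx(getattr(est2, attr))

    def test_zero_variance_participant_flagged_unusable(self, rng):
        tables = model_tables(rng)
        flat = ProbabilityTable(
            tables["face"].stimulus_ids, THREE_EMOTIONS, np.full((10, 3), 1 / 3)
        )
        with pytest.raises(DegenerateDataError, match="unusable"):
            reliance_estimates(flat, tables, participant_id="px")

    def test_too_few_shared_stimuli_rejected(self, rng):
        tables = model_tables(rng)
        lone = ProbabilityTable(["s000", "s001"], THREE_EMOTIONS,
                                np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]]))
        with pytest.raises(DegenerateDataError, match="shares only 2"):
            reliance_estimates(lone, tables)

    def test_cohort_driver_skips_degenerate_participants(self, rng):
        tables = model_tables(rng, n=4)
        rows = []
        for s in tables["face"].stimulus_ids:
            for e, x in zip(THREE_EMOTIONS, (3, 1, 0)):
                rows.append(("good", s, "joint", e, x > 0, x))
            for e in THREE_EMOTIONS:
                rows.append(("flat", s, "joint", e, False, 0))
        estimates, skipped = cohort_estimates(
            make_ratings(rows), tables, emotions=THREE_EMOTIONS
        )
        assert [e.participant_id for e in estimates] == ["good"]
        assert skipped == ["flat"]


class TestClassifyBestModel:
    @pytest.mark.parametrize(
        "rf, rs, ri, expected",
        [
            (0.3, 0.7, 0.5, "situation"),
            (0.9, 0.2, 0.3, "face"),
            (0.1, 0.5, 0.5, "situation"),  # tie: situation precedes integration
            (0.5, 0.2, 0.5, "integration"),  # tie: integration precedes face
        ],
    )
    def test_argmax_with_documented_tie_break(self, rf, rs, ri, expected):
        assert classify_best_model(rf, rs, ri) == expected

    def test_non_finite_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            classify_best_model(0.5, float("nan"), 0.2)


class TestMahalanobis:
    def test_planted_outlier_is_the_only_flag(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(100, 3))
        X[17] += 10.0
        flagged = mahalanobis_outliers(X, alpha=0.001)
        assert flagged == [17]

    def test_null_data_flags_about_alpha_fraction(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        flagged = mahalanobis_outliers(X, alpha=0.001)
        assert len(flagged) <= 1

    def test_dataframe_labels_are_returned(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.normal(size=(50, 2)), index=[f"p{i}" for i in range(50)]
        )
        df.iloc[5] += 12.0
        assert mahalanobis_outliers(df, alpha=0.001) == ["p5"]

    def test_underdetermined_covariance_rejected(self):
        with pytest.raises(DegenerateDataError, match="more rows than columns"):
            mahalanobis_outliers(np.zeros((2, 3)))

    def test_singular_covariance_advises_pruning(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        with pytest.raises(DegenerateDataError, match="prune"):
            mahalanobis_outliers(np.column_stack([x, 2 * x]))


class TestCovariateAssociation:
    def test_closed_form_t_for_r_half_n_thirty(self):
        # r = 0.5, n = 30 -> t = 0.5 * sqrt(28 / 0.75) = 3.0551
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            # project y to have exactly r = 0.5 with x
            xs = (x - x.mean()) / x.std()
            resid = y - np.polyval(np.polyfit(x, y, 1), x)
            ys = resid / resid.std()
            y_target = 0.5 * xs + np.sqrt(1 - 0.25) * ys
            assoc = covariate_association(x, y_target)
            assert assoc.r == pytest.approx(0.5, abs=1e-10)
            assert assoc.t_stat == pytest.approx(0.5 * np.sqrt(28 / 0.75), abs=1e-9)
            assert assoc.df == 28

    def test_perfectly_linear_covariate(self):
        x = np.linspace(0, 1, 25)
        assoc = covariate_association(x, 3 * x + 1)
        assert assoc.r == pytest.approx(1.0)
        assert assoc.ci_high == pytest.approx(1.0, abs=1e-6)
        assert assoc.p_adjusted == pytest.approx(0.0, abs=1e-12)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assoc = covariate_association(x, y, n_tests=50)
        assert assoc.p_adjusted == 1.0

    @given(
        p=st.floats(0, 1, allow_nan=False),
        m=st.integers(1, 30),
    )
    def test_bonferroni_never_lowers_and_is_exact_below_cap(self, p, m):
        from emocue._stats import bonferroni

        adj = bonferroni(p, m)
        assert adj >= min(1.0, p)
        if p * m < 1.0:
            assert adj == pytest.approx(p * m)


class TestIcc:
    def test_identical_sessions_give_exactly_one(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        result = icc_consistency(z, z.copy())
        assert result.icc == 1.0
        assert result.ci_low == result.ci_high == 1.0

    def test_df_structure_for_two_sessions(self):
        rng = np.random.default_rng(6)
        z1 = rng.normal(size=110)
        z2 = 0.5 * z1 + rng.normal(size=110)
        result = icc_consistency(z1, z2)
        assert (result.df1, result.df2) == (109, 109)
        assert result.n_subjects == 110 and result.k_sessions == 2

    def test_independent_sessions_give_near_zero_icc(self):
        rng = np.random.default_rng(42)
        result = icc_consistency(rng.normal(size=200), rng.normal(size=200))
        assert abs(result.icc) < 0.15

    def test_matches_pingouin_two_way_mixed_single_consistency(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(77)
        n = 60
        z1 = rng.normal(size=n)
        z2 = 0.7 * z1 + 0.6 * rng.normal(size=n)
        ours = icc_consistency(z1, z2)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), 2),
                "session": np.repeat([1, 2], n),
                "score": np.concatenate([z1, z2]),
            }
        )
        out = pingouin.intraclass_corr(
            data=df, targets="subject", raters="session", ratings="score"
        ).set_index("Type")
        ref = out.loc["ICC(C,1)"] if "ICC(C,1)" in out.index else out.loc["ICC3"]
        assert ours.icc == pytest.approx(ref["ICC"], abs=1e-10)
        assert ours.f_stat == pytest.approx(ref["F"], abs=1e-10)
        assert (ours.df1, ours.df2) == (ref["df1"], ref["df2"])
        ci_col = "CI95" if "CI95" in out.columns else "CI95%"
        # pingouin prints its interval rounded to two decimals
        assert (ours.ci_low, ours.ci_high) == pytest.approx(
            tuple(ref[ci_col]), abs=5e-3
        )

    def test_mismatched_participants_listed(self):
        s1 = pd.Series([0.1] * 6, index=[f"p{i}" for i in range(6)])
        s2 = pd.Series([0.1] * 6, index=[f"p{i}" for i in range(1, 7)])
        with pytest.raises(AxisMismatchError, match="p0"):
            icc_consistency(s1, s2)

    def test_agreement_form_point_estimate(self):
        rng = np.random.default_rng(13)
        z1 = rng.normal(size=40)
        z2 = z1 + 1.0  # constant session shift
        cons = icc_consistency(z1, z2, form="consistency")
        agree = icc_consistency(z1, z2, form="agreement")
        # a pure session shift leaves consistency at 1 but lowers agreement
        assert cons.icc == pytest.approx(1.0)
        assert agree.icc < cons.icc


class TestFisherTransform:
    @given(r=st.floats(-0.999, 0.999))
    def test_round_trip_and_monotonicity(self, r):
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)
        assert fisher_z(0.0) == 0.0
        eps = 1e-4
        if r + eps <= 0.999:
            assert fisher_z(r + eps) > fisher_z(r)

    def test_clamped_near_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))
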