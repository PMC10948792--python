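import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emocue.errors import DegenerateDataError, SchemaError
from emocue.ratings import (
    annotate_quality,
    condition_probability_table,
    correct_trials,
    encode_rating,
    exclude_participants,
    prior_vector,
)

from conftest import THREE_EMOTIONS, make_ratings


class TestEncodeRating:
    @pytest.mark.parametrize(
        "presence, label, expected",
        [
            ("no", "absent", 0),
            ("yes", "slightly", 1),
            ("yes", "moderately", 2),
            ("yes", "strongly", 3),
            ("yes", "intensely", 4),
            ("no", "intensely", 0),  # absence dominates
            (True, "slightly", 1),
            ("false", "slightly", 0),
        ],
    )
    def test_monotone_presence_gated_map(self, presence, label, expected):
        assert encode_rating(presence, label) == expected

    def test_unknown_label_names_the_token(self):
        with pytest.raises(SchemaError, match="'extremely'"):
            encode_rating("yes", "extremely")

    def test_unparseable_presence(self):
        with pytest.raises(SchemaError, match="presence"):
            encode_rating("maybe", "slightly")


class TestCleaning:
    @staticmethod
    def raw_frame():
        # p1: one accidental (absent + slight); p2: one incorrect (absent +
        # strong); p3: all valid; p4: one missing intensity.
        rows = [
            ("p1", "s1", "joint", "anger", False, 1),
            ("p1", "s1", "joint", "fear", True, 3),
            ("p2", "s1", "joint", "anger", False, 3),
            ("p2", "s1", "joint", "fear", True, 2),
            ("p3", "s1", "joint", "anger", True, 4),
            ("p3", "s1", "joint", "fear", False, 0),
            ("p4", "s1", "joint", "anger", True, np.nan),
            ("p4", "s1", "joint", "fear", True, 1),
        ]
        return make_ratings(rows)

    def test_annotate_quality_derives_categories(self):
        q = annotate_quality(self.raw_frame())["quality"]
        assert list(q) == [
            "accidental", "valid", "incorrect", "valid",
            "valid", "valid", "missing", "valid",
        ]

    def test_accidental_corrected_to_absent_and_kept(self):
        cleaned, report = correct_trials(self.raw_frame())
        p1 = cleaned[cleaned.participant_id == "p1"]
        row = p1[p1.emotion == "anger"].iloc[0]
        assert row.presence == False and row.intensity == 0  # noqa: E712
        assert row.quality == "valid"
        assert report["n_accidental_corrected"] == 1

    def test_incorrect_and_missing_removed_trialwise(self):
        cleaned, report = correct_trials(self.raw_frame())
        assert len(cleaned[cleaned.participant_id == "p2"]) == 1
        assert len(cleaned[cleaned.participant_id == "p4"]) == 1
        assert report["n_incorrect_removed"] == 1
        assert report["n_missing_removed"] == 1
        assert report["per_participant"]["p2"] == {"incorrect": 1}

    def test_all_valid_input_is_identity_with_empty_report(self):
        clean_rows = make_ratings(
            [("p", "s1", "joint", "anger", True, 2),
             ("p", "s1", "joint", "fear", False, 0)]
        )
        cleaned, report = correct_trials(clean_rows)
        pd.testing.assert_frame_equal(
            cleaned[clean_rows.columns], clean_rows, check_dtype=False
        )
        assert report["per_participant"] == {}

    @pytest.mark.parametrize(
        "n_bad, n_total, kept",
        [(0, 50, True), (5, 50, True), (6, 50, False)],  # 10% exact retained
    )
    def test_exclusion_boundary_is_strict(self, n_bad, n_total, kept):
        rows = []
        for i in range(n_total):
            bad = i < n_bad
            rows.append(
                ("p", f"s{i}", "joint", "anger", False if bad else True, 3)
            )
        # a clean companion participant so the frame is never empty
        rows += [("q", f"s{i}", "joint", "anger", True, 2) for i in range(n_total)]
        records, report = exclude_participants(make_ratings(rows))
        assert ("p" in set(records.participant_id)) == kept
        assert "q" in set(records.participant_id)
        if not kept:
            assert report["excluded"]["p"] == pytest.approx(n_bad / n_total)

    def test_empty_input_warns_and_returns_empty(self, caplog):
        records, report = exclude_participants(make_ratings([]))
        assert records.empty and report["excluded"] == {}


class TestConditionProbabilityTable:
    def test_two_rater_hand_example(self):
        # means (3, 1, 0) -> row (0.75, 0.25, 0)
        rows = [
            ("r1", "A", "joint", "anger", True, 4),
            ("r1", "A", "joint", "fear", True, 1),
            ("r1", "A", "joint", "happiness", False, 0),
            ("r2", "A", "joint", "anger", True, 2),
            ("r2", "A", "joint", "fear", True, 1),
            ("r2", "A", "joint", "happiness", False, 0),
        ]
        table = condition_probability_table(make_ratings(rows), "joint", THREE_EMOTIONS)
        np.testing.assert_allclose(table.row("A"), [0.75, 0.25, 0.0], atol=1e-12)

    def test_single_rater_hand_example(self):
        rows = [
            ("r1", "A", "joint", "anger", True, 2),
            ("r1", "A", "joint", "fear", True, 2),
            ("r1", "A", "joint", "happiness", False, 0),
        ]
        table = condition_probability_table(make_ratings(rows), "joint", THREE_EMOTIONS)
        np.testing.assert_allclose(table.row("A"), [0.5, 0.5, 0.0], atol=1e-12)

    def test_all_absent_stimulus_flagged_uniform(self):
        rows = [
            ("r1", "A", "joint", e, False, 0) for e in THREE_EMOTIONS
        ] + [
            ("r1", "B", "joint", e, True, 2) for e in THREE_EMOTIONS
        ]
        table = condition_probability_table(make_ratings(rows), "joint", THREE_EMOTIONS)
        np.testing.assert_allclose(table.row("A"), 1 / 3)
        assert table.degenerate_rows == {"A"}

    def test_empty_condition_is_an_error_naming_it(self):
        rows = [("r1", "A", "joint", "anger", True, 2)]
        with pytest.raises(DegenerateDataError, match="face_only"):
            condition_probability_table(make_ratings(rows), "face_only", THREE_EMOTIONS)

    def test_ragged_design_is_an_error(self):
        rows = [
            ("r1", "A", "joint", "anger", True, 2),
            ("r1", "A", "joint", "fear", True, 2),
        ]  # happiness never rated for A
        with pytest.raises(SchemaError, match="ragged"):
            condition_probability_table(make_ratings(rows), "joint", THREE_EMOTIONS)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 5),  # rater
                st.integers(0, 3),  # stimulus
                st.tuples(*[st.integers(0, 4)] * 3),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_rows_stochastic_and_invariant_to_order_and_duplication(self, data):
        rows = []
        for rater, stim, intensities in data:
            for emotion, x in zip(THREE_EMOTIONS, intensities):
                rows.append((f"r{rater}", f"s{stim}", "joint", emotion, x > 0, x))
        df = make_ratings(rows)
        table = condition_probability_table(df, "joint", THREE_EMOTIONS)
        np.testing.assert_allclose(table.values.sum(axis=1), 1.0, atol=1e-9)

        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        np.testing.assert_allclose(
            condition_probability_table(shuffled, "joint", THREE_EMOTIONS).values,
            table.values, atol=1e-12,
        )
        doubled = pd.concat(
            [df, df.assign(participant_id=df.participant_id + "_copy")],
            ignore_index=True,
        )
        np.testing.assert_allclose(
            condition_probability_table(doubled, "joint", THREE_EMOTIONS).values,
            table.values, atol=1e-12,
        )


class TestPriorVector:
    @staticmethod
    def priors_frame(ratings_by_participant):
        rows = []
        for pid, ratings in ratings_by_participant.items():
            for emotion, lik in zip(THREE_EMOTIONS, ratings):
                rows.append({"participant_id": pid, "emotion": emotion, "likelihood": lik})
        return pd.DataFrame(rows)

    def test_constant_ratings_give_uniform_prior(self):
        prior = prior_vector(
            self.priors_frame({"p1": (4, 4, 4), "p2": (4, 4, 4)}), THREE_EMOTIONS
        )
        np.testing.assert_allclose(prior.probabilities, 1 / 3, atol=1e-12)

    def test_two_emotion_hand_example(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2", "p2"],
                "emotion": ["anger", "fear", "anger", "fear"],
                "likelihood": [7, 3, 5, 1],  # means (6, 2) -> (0.75, 0.25)
            }
        )
        prior = prior_vector(df, ("anger", "fear"))
        np.testing.assert_allclose(prior.probabilities, [0.75, 0.25], atol=1e-12)

    def test_missing_category_errors_with_its_name(self):
        df = self.priors_frame({"p1": (4, 4, 4)})
        df = df[df.emotion != "fear"]
        with pytest.raises(SchemaError, match="fear"):
            prior_vector(df, THREE_EMOTIONS)

    def test_out_of_scale_rating_rejected(self):
        df = self.priors_frame({"p1": (4, 9, 4)})
        with pytest.raises(SchemaError, match="1..7"):
            prior_vector(df, THREE_EMOTIONS)
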