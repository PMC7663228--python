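"""Ballot cleaning, vote tallying and the per-school top-18% cutoff."""

import numpy as np
import pandas as pd
import pytest

from peerlca import nomination, synthetic
from peerlca.nomination import (clean_ballots, identify_supporters,
                                school_cutoff, tally_votes)


def ballot(nominator, school, question, nominee):
    return {"nominator_id": nominator, "school_id": school,
            "question": question, "nominee_name": nominee}


@pytest.fixture
def roster():
    return pd.DataFrame({
        "participant_id": ["a", "b", "c", "d", "e"],
        "school_id": [1, 1, 1, 2, 2],
        "name": ["a", "b", "c", "d", "e"],
    })


class TestClean:
    def test_cross_school_and_out_of_roster_removed(self, roster):
        ballots = pd.DataFrame([
            ballot("a", 1, "respect", "b"),
            ballot("a", 1, "respect", "d"),        # pupil of school 2
            ballot("b", 1, "trust", "nobody"),     # not on any roster
        ])
        out = clean_ballots(ballots, roster)
        assert out["nominee_name"].tolist() == ["b"]

    def test_self_nominations_dropped(self, roster):
        ballots = pd.DataFrame([ballot("a", 1, "respect", "a"),
                                ballot("a", 1, "respect", "b")])
        out = clean_ballots(ballots, roster)
        assert out["nominee_name"].tolist() == ["b"]

    def test_exact_duplicates_deduplicated(self, roster):
        ballots = pd.DataFrame([ballot("a", 1, "respect", "b")] * 3)
        assert len(clean_ballots(ballots, roster)) == 1

    def test_ambiguous_names_dropped_never_guessed(self, roster):
        roster = pd.concat([roster, pd.DataFrame([
            {"participant_id": "c2", "school_id": 1, "name": "c"}])],
            ignore_index=True)
        ballots = pd.DataFrame([ballot("a", 1, "respect", "c"),
                                ballot("a", 1, "respect", "b")])
        out = clean_ballots(ballots, roster)
        assert out["nominee_name"].tolist() == ["b"]

    def test_unknown_question_rejected(self, roster):
        with pytest.raises(ValueError, match="question"):
            clean_ballots(pd.DataFrame([ballot("a", 1, "bff", "b")]), roster)


class TestTally:
    def test_one_vote_per_nominator_regardless_of_questions(self, roster):
        ballots = pd.DataFrame([ballot("a", 1, q, "b")
                                for q in ("respect", "leader", "trust", "lookup")])
        tally = tally_votes(clean_ballots(ballots, roster), roster)
        assert tally.set_index("participant_id")["votes"]["b"] == 1

    def test_votes_from_distinct_nominators_add(self, roster):
        ballots = pd.DataFrame([
            ballot("a", 1, "respect", "b"),
            ballot("c", 1, "respect", "b"),
            ballot("c", 1, "trust", "b"),
        ])
        tally = tally_votes(clean_ballots(ballots, roster), roster)
        assert tally.set_index("participant_id")["votes"]["b"] == 2

    def test_empty_ballots_give_all_zero(self, roster):
        ballots = pd.DataFrame(
            columns=["nominator_id", "school_id", "question", "nominee_name"])
        tally = tally_votes(clean_ballots(ballots, roster), roster)
        assert (tally["votes"] == 0).all()
        assert len(tally) == len(roster)

    def test_question_duplication_invariance(self, small_cohort, small_cfg):
        ballots = synthetic.generate_ballots(small_cohort, small_cfg.nomination,
                                             seed=8)
        roster = synthetic.roster_from_cohort(small_cohort)
        t1 = tally_votes(clean_ballots(ballots, roster), roster)
        dup = []
        for q in ("respect", "leader", "trust", "lookup"):
            d = ballots.copy()
            d["question"] = q
            dup.append(d)
        t2 = tally_votes(clean_ballots(pd.concat(dup), roster), roster)
        pd.testing.assert_frame_equal(t1, t2)


def tally_frame(votes, school=1):
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(len(votes))],
        "school_id": school,
        "votes": votes,
    })


class TestCutoff:
    def test_worked_example_school_of_ten(self):
        tally = tally_frame([9, 7, 7, 5, 4, 3, 2, 1, 1, 0])
        cutoffs = school_cutoff(tally, 0.18)
        assert cutoffs[1] == 7
        flagged = identify_supporters(tally, cutoffs)
        assert flagged["supporter"].sum() == 3

    def test_school_of_31_uses_rank_six(self):
        votes = list(range(31, 0, -1))  # 31..1, all distinct
        cutoffs = school_cutoff(tally_frame(votes), 0.18)
        assert cutoffs[1] == sorted(votes, reverse=True)[5]  # rank ceil(5.58)=6

    def test_all_tied_at_one_vote_everyone_qualifies(self):
        tally = tally_frame([1] * 10)
        flagged = identify_supporters(tally, school_cutoff(tally, 0.18))
        assert flagged["supporter"].all()

    def test_zero_vote_pupils_never_qualify(self):
        tally = tally_frame([0] * 10)
        flagged = identify_supporters(tally, school_cutoff(tally, 0.18))
        assert not flagged["supporter"].any()

    def test_votes_equal_to_cutoff_qualify(self):
        tally = tally_frame([5, 5, 1, 1, 1, 1, 1, 1, 1, 1])
        cutoffs = school_cutoff(tally, 0.18)
        flagged = identify_supporters(tally, cutoffs)
        at_cut = flagged[flagged["votes"] == cutoffs[1]]
        assert at_cut["supporter"].all()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            school_cutoff(tally_frame([1, 2]), 0.0)


class TestEndToEnd:
    def test_supporter_fraction_at_least_the_cutoff_fraction(self, small_cohort,
                                                             small_cfg):
        ballots = synthetic.generate_ballots(small_cohort, small_cfg.nomination,
                                             seed=3)
        roster = synthetic.roster_from_cohort(small_cohort)
        tally = nomination.nominate(ballots, roster, fraction=0.18)
        per_school = tally.groupby("school_id")["supporter"].mean()
        assert (per_school >= 0.18 - 1e-12).all()

    def test_supporter_set_invariant_to_ballot_shuffling(self, small_cohort,
                                                         small_cfg):
        ballots = synthetic.generate_ballots(small_cohort, small_cfg.nomination,
                                             seed=4)
        roster = synthetic.roster_from_cohort(small_cohort)
        base = nomination.nominate(ballots, roster)
        shuffled = ballots.sample(frac=1.0, random_state=0).reset_index(drop=True)
        other = nomination.nominate(shuffled, roster)
        a = base.sort_values("participant_id")["supporter"].to_numpy()
        b = other.sort_values("participant_id")["supporter"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_default_cohort_share_in_plausible_band(self, cohort, default_cfg):
        ballots = synthetic.generate_ballots(cohort, default_cfg.nomination,
                                             seed=6)
        roster = synthetic.roster_from_cohort(cohort)
        tally = nomination.nominate(ballots, roster)
        assert 0.18 <= tally["supporter"].mean() <= 0.27
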