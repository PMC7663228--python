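"""Peer-nomination ballots: cleaning, tallying and supporter identification.

Pupils nominate up to five names for each of four questions (respect,
leader, trust, lookup). Nominations to names outside the nominator's school
roster are removed, a nominee receives at most one vote per nominator
regardless of how many questions named them, and each school's supporters
are the pupils whose vote count reaches the school's top-18% cutoff (rank
ceil(0.18 * n), ties included, zero-vote pupils never qualify).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import NOMINATION_QUESTIONS

log = logging.getLogger(__name__)


def clean_ballots(ballots: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Drop out-of-roster, cross-school, self and ambiguous nominations.

    ``roster`` maps (school_id, name) -> participant_id; a name occurring
    more than once within a school is ambiguous and nominations to it are
    dropped (never guessed). Exact duplicate records are de-duplicated.
    """
    required = {"nominator_id", "school_id", "question", "nominee_name"}
    if not required.issubset(ballots.columns):
        raise ValueError(f"ballots must have columns {sorted(required)}")
    bad_q = ~ballots["question"].isin(NOMINATION_QUESTIONS)
    if bad_q.any():
        raise ValueError(
            f"unknown questions: {sorted(ballots.loc[bad_q, 'question'].unique())}")

    n0 = len(ballots)
    out = ballots.drop_duplicates(
        subset=["nominator_id", "school_id", "question", "nominee_name"])
    n_dupes = n0 - len(out)

    counts = roster.groupby(["school_id", "name"]).size()
    ambiguous = set(counts[counts > 1].index)
    lookup = roster.set_index(["school_id", "name"])["participant_id"]
    lookup = lookup[~lookup.index.duplicated(keep=False)]

    keys = list(zip(out["school_id"], out["nominee_name"]))
    nominee_id = np.array(
        [lookup.get(k, None) if k not in ambiguous else None for k in keys],
        dtype=object)
    in_roster = np.array([v is not None for v in nominee_id], dtype=bool)
    n_ambiguous = sum(1 for k in keys if k in ambiguous)
    nominators = out["nominator_id"].to_numpy(dtype=object)
    self_nom = np.array(
        [(a is not None) and (i == a) for i, a in zip(nominators, nominee_id)],
        dtype=bool) if len(out) else np.zeros(0, dtype=bool)

    keep = in_roster & ~self_nom
    cleaned = out.loc[keep].copy()
    cleaned["nominee_id"] = nominee_id[keep]
    log.info(
        "clean_ballots: kept %d of %d (%d duplicates, %d out-of-roster/"
        "cross-school, %d ambiguous, %d self-nominations removed)",
        len(cleaned), n0, n_dupes, int((~in_roster).sum()) - n_ambiguous,
        n_ambiguous, int(self_nom.sum()))
    return cleaned


def tally_votes(ballots: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """One vote per (nominator, nominee) pair; zero-vote pupils included.

    ``ballots`` must be cleaned (carry a ``nominee_id`` column).
    """
    if "nominee_id" not in ballots.columns:
        raise ValueError("ballots must be cleaned first (no nominee_id)")
    pairs = ballots.drop_duplicates(subset=["nominator_id", "nominee_id"])
    votes = pairs.groupby("nominee_id").size()
    tally = roster[["participant_id", "school_id"]].copy()
    tally["votes"] = tally["participant_id"].map(votes).fillna(0).astype(int)
    return tally


def school_cutoff(tally: pd.DataFrame, fraction: float = 0.18) -> pd.Series:
    """Per-school cutoff: votes of the pupil at rank ceil(fraction * n).

    A floor of one vote is enforced so pupils nobody nominated never qualify.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cutoffs = {}
    for school, grp in tally.groupby("school_id"):
        votes = np.sort(grp["votes"].to_numpy())[::-1]
        rank = math.ceil(fraction * len(votes))
        cutoffs[school] = max(1, int(votes[rank - 1]))
    return pd.Series(cutoffs, name="cutoff_votes")


def identify_supporters(tally: pd.DataFrame, cutoffs: pd.Series) -> pd.DataFrame:
    """Flag pupils with votes >= their school's cutoff (ties included)."""
    out = tally.copy()
    out["cutoff_votes"] = out["school_id"].map(cutoffs)
    out["supporter"] = out["votes"] >= out["cutoff_votes"]
    out["rank"] = out.groupby("school_id")["votes"].rank(
        method="min", ascending=False).astype(int)
    return out


def nominate(ballots: pd.DataFrame, roster: pd.DataFrame,
             fraction: float = 0.18) -> pd.DataFrame:
    """Clean, tally, and flag supporters in one call."""
    cleaned = clean_ballots(ballots, roster)
    tally = tally_votes(cleaned, roster)
    cutoffs = school_cutoff(tally, fraction)
    return identify_supporters(tally, cutoffs)
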