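"""Synthetic cohort, ballot and count-stream generators."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from peerlca import synthetic
from peerlca.accelerometry import NONWEAR, detect_nonwear, process_series
from peerlca.config import (BINARY_COLUMNS, CONTINUOUS_COLUMNS, MVPA_INDEX,
                            SEDENTARY_INDEX, NominationModel,
                            SimulationConfig, default_config)
from peerlca.rng import child_rng


def big_config(n=20000, seed=3):
    d = default_config(seed=seed).to_dict()
    per = n // 100
    d["n_schools"] = 100
    d["school_sizes"] = (per,) * 100
    return SimulationConfig.from_dict(d)


def test_fixed_seed_is_bit_identical(default_cfg):
    a = synthetic.generate_cohort(default_cfg)
    b = synthetic.generate_cohort(default_cfg)
    pdt.assert_frame_equal(a, b)
    ba = synthetic.generate_ballots(a, default_cfg.nomination, seed=5)
    bb = synthetic.generate_ballots(b, default_cfg.nomination, seed=5)
    pdt.assert_frame_equal(ba, bb)


def test_class_assignment_matches_inverse_cdf_oracle(default_cfg):
    cohort = synthetic.generate_cohort(default_cfg)
    # independent re-draw of the same stream: inverse-CDF on the uniforms
    oracle_rng = child_rng(default_cfg.seed, "cohort")
    u = oracle_rng.random(len(cohort))
    cls = np.searchsorted(np.cumsum(default_cfg.mixing), u) + 1
    np.testing.assert_array_equal(cohort["true_class"].to_numpy(), cls)


def test_sample_moments_match_configuration_within_mc_error():
    cfg = big_config()
    cohort = synthetic.generate_cohort(cfg)
    n = len(cohort)
    mix = np.asarray(cfg.mixing)
    means = np.asarray(cfg.class_means)
    sds = np.asarray(cfg.class_sds)
    marg_mean = mix @ means
    marg_var = mix @ (sds ** 2) + mix @ (means - marg_mean) ** 2
    for j, col in enumerate(CONTINUOUS_COLUMNS):
        if col in ("self_esteem", "self_efficacy", "autonomous", "screen"):
            continue  # bounded columns have a small clipping bias by design
        se = np.sqrt(marg_var[j] / n)
        assert abs(cohort[col].mean() - marg_mean[j]) < 3 * se, col
    probs = mix @ np.asarray(cfg.binary_probs)
    for j, col in enumerate(BINARY_COLUMNS):
        se = np.sqrt(probs[j] * (1 - probs[j]) / n)
        assert abs(cohort[col].mean() - probs[j]) < 3 * se, col


def test_within_class_mvpa_sed_covariance_matches_shared_value():
    cfg = big_config(seed=9)
    cohort = synthetic.generate_cohort(cfg)
    covs, ws = [], []
    for k in range(1, 6):
        sub = cohort[cohort["true_class"] == k]
        covs.append(np.cov(sub["mvpa"], sub["sedentary"])[0, 1])
        ws.append(len(sub))
    pooled = np.average(covs, weights=ws)
    sds = np.asarray(cfg.class_sds)
    va = float(np.mean(sds[:, MVPA_INDEX] ** 2))
    vb = float(np.mean(sds[:, SEDENTARY_INDEX] ** 2))
    se = np.sqrt((va * vb + cfg.shared_mvpa_sed_cov ** 2) / len(cohort))
    assert abs(pooled - cfg.shared_mvpa_sed_cov) < 3 * se


def test_degenerate_mixture_yields_single_class():
    d = default_config(seed=2).to_dict()
    d["mixing"] = (1.0, 0.0, 0.0, 0.0, 0.0)
    cfg = SimulationConfig.from_dict(d)
    cohort = synthetic.generate_cohort(cfg)
    assert (cohort["true_class"] == 1).all()
    mu1 = np.asarray(cfg.class_means)[0]
    assert abs(cohort["mvpa"].mean() - mu1[MVPA_INDEX]) < 2.0


def test_default_clipping_is_rare(cohort):
    assert cohort.attrs["clip_fraction"] < 0.01


def test_nonpositive_definite_pa_block_rejected():
    d = default_config().to_dict()
    d["shared_mvpa_sed_cov"] = -1e9
    with pytest.raises(ValueError, match="positive definite"):
        SimulationConfig.from_dict(d)


# -- missingness ---------------------------------------------------------

def test_zero_rates_leave_cohort_unchanged(cohort):
    res = synthetic.inject_missingness(cohort, {"mvpa": 0.0}, seed=1)
    pdt.assert_frame_equal(res.data, cohort)


def test_masked_cells_reconstruct_original(cohort):
    rates = {"mvpa": 0.08, "sedentary": 0.08, "self_esteem": 0.04}
    res = synthetic.inject_missingness(cohort, rates, seed=1)
    rebuilt = res.data.copy()
    for col in rates:
        hit = res.mask[col]
        assert rebuilt.loc[hit, col].isna().all()
        rebuilt.loc[hit, col] = res.original.loc[hit, col]
    pdt.assert_frame_equal(rebuilt, res.original)


def test_realized_missingness_near_configured_rate(cohort):
    res = synthetic.inject_missingness(cohort, {"mvpa": 0.08}, seed=4)
    frac = res.data["mvpa"].isna().mean()
    assert abs(frac - 0.08) < 0.02


def test_mar_on_class_doubles_rate_in_flagged_class(cohort):
    res = synthetic.inject_missingness(
        cohort, {"mvpa": 0.10}, mechanism="mar-class",
        class_multipliers={5: 2.0}, seed=4)
    miss = res.data["mvpa"].isna()
    r5 = miss[cohort["true_class"] == 5].mean()
    rest = miss[cohort["true_class"] != 5].mean()
    assert r5 > rest * 1.4


def test_extreme_rate_refused(cohort):
    with pytest.raises(ValueError, match="0.95"):
        synthetic.inject_missingness(cohort, {"mvpa": 0.99})


# -- ballots -------------------------------------------------------------

def test_nominator_never_exceeds_twenty_slots(small_cohort, small_cfg):
    ballots = synthetic.generate_ballots(small_cohort, small_cfg.nomination,
                                         seed=2)
    per = ballots.groupby("nominator_id").size()
    model = small_cfg.nomination
    assert per.max() <= model.max_names_per_question * model.n_questions
    per_q = ballots.groupby(["nominator_id", "question"]).size()
    assert per_q.max() <= model.max_names_per_question


def test_mean_votes_monotone_in_class_propensity():
    d = default_config(seed=0).to_dict()
    d["n_schools"], d["school_sizes"] = 2, (100, 100)
    cfg = SimulationConfig.from_dict(d)
    model = NominationModel(class_propensity=(4.0, 2.0, 1.0, 1.0, 0.5),
                            individual_log_sd=0.0, out_of_roster_rate=0.0,
                            cross_school_rate=0.0,
                            n_nonconsenting_nominators=0)
    votes = {k: [] for k in range(1, 6)}
    for s in range(30):
        d["seed"] = s
        cohort = synthetic.generate_cohort(SimulationConfig.from_dict(d))
        ballots = synthetic.generate_ballots(cohort, model, seed=s)
        received = ballots.groupby("nominee_name").size()
        cohort = cohort.set_index("participant_id")
        for k in range(1, 6):
            ids = cohort.index[cohort["true_class"] == k]
            votes[k].append(received.reindex(ids).fillna(0).mean())
    means = [np.mean(votes[k]) for k in range(1, 6)]
    assert means[0] > means[1] > means[2] > means[4]
    assert abs(means[2] - means[3]) < 0.15 * means[2]  # equal propensities


def test_single_pupil_school_produces_no_ballots(caplog):
    cohort = pd.DataFrame({
        "participant_id": ["a"], "school_id": [1], "true_class": [1]})
    model = NominationModel(class_propensity=(1.0,),
                            n_nonconsenting_nominators=0)
    with caplog.at_level("WARNING"):
        ballots = synthetic.generate_ballots(cohort, model, seed=0)
    assert ballots.empty
    assert "no ballots" in caplog.text


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        synthetic.generate_ballots(pd.DataFrame(), NominationModel(), seed=0)


def test_out_of_roster_names_injected(small_cohort, small_cfg):
    model = NominationModel(out_of_roster_rate=0.2, cross_school_rate=0.0,
                            n_nonconsenting_nominators=0)
    ballots = synthetic.generate_ballots(small_cohort, model, seed=3)
    assert ballots["nominee_name"].str.startswith("ext_").any()


# -- count streams -------------------------------------------------------

def test_all_zero_day_is_one_nonwear_run():
    series = synthetic.generate_count_stream([], n_days=1, seed=0,
                                             native_epoch_s=10)
    assert (series.counts == 0).all()
    assert (series.truth == "nonwear").all()
    assert not detect_nonwear(series).any()


def test_short_zero_run_flanked_by_activity_is_wear_in_truth():
    profile = [(0, 600, "light"), (600, 59, "nonwear"), (659, 781, "light")]
    series = synthetic.generate_count_stream(profile, n_days=1, seed=0,
                                             native_epoch_s=10)
    zero_idx = slice(600 * 6, 659 * 6)
    assert (series.truth[zero_idx] == "sedentary").all()  # wear, zero counts
    assert detect_nonwear(series)[zero_idx].all()


def test_mvpa_minutes_recovered_exactly_on_valid_day():
    profile = [(360, 500, "sedentary"), (860, 70, "mvpa"), (930, 200, "light")]
    series = synthetic.generate_count_stream(profile, n_days=1, seed=1,
                                             native_epoch_s=10)
    res = process_series(series, min_valid_days=1)
    day = res["days"][0]
    assert day.valid
    assert day.mvpa_min == pytest.approx(70.0)
    assert day.sedentary_min == pytest.approx(500.0)


def test_overlapping_profile_blocks_rejected():
    with pytest.raises(ValueError, match="overlap"):
        synthetic.generate_count_stream(
            [(0, 100, "light"), (50, 100, "mvpa")], n_days=1, seed=0)
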