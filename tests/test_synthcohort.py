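"""Generator behaviour: determinism, calibration, design constraints."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dormantlink.outcomes import ScoreScale, grade_to_points, standardise_external
from dormantlink.synthcohort import (
    ErrorModel,
    OutcomeModel,
    corrupt_identifiers,
    generate_world,
    permuted_block_sequence,
    simulate_register,
    simulate_trials,
)
from dormantlink.trials import DEFAULT_TRIAL_SPECS


def test_register_deterministic_and_seed_sensitive():
    a = simulate_register(500, seed=3)
    b = simulate_register(500, seed=3)
    c = simulate_register(500, seed=4)
    pd.testing.assert_frame_equal(a.pupils, b.pupils)
    pd.testing.assert_frame_equal(a.census, b.census)
    assert not a.pupils.equals(c.pupils)


def test_world_deterministic():
    w1 = generate_world(seed=5, population_size=1000, trial_specs={"PALMT": DEFAULT_TRIAL_SPECS["PALMT"]})
    w2 = generate_world(seed=5, population_size=1000, trial_specs={"PALMT": DEFAULT_TRIAL_SPECS["PALMT"]})
    pd.testing.assert_frame_equal(w1[0].participants, w2[0].participants)
    pd.testing.assert_frame_equal(w1[0].contacts, w2[0].contacts)
    pd.testing.assert_frame_equal(w1[1].pupils, w2[1].pupils)


def test_register_grade_marginals_match_national_reference():
    """Mean external z-score of GCSE maths is ~0 by construction at n=10000."""
    model = OutcomeModel()
    reg = simulate_register(10_000, model, seed=5)
    pts = grade_to_points(reg.pupils["gcse_maths"])
    ok = ~np.isnan(pts)
    scale = ScoreScale.from_outcome_model(model)
    z = standardise_external(pts[ok], scale, reg.pupils.loc[ok, "gcse_year"])
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.std() < 1.1


def test_zero_error_model_identifiers_agree(zero_world):
    """With zero corruption each participant's transcription equals the register view."""
    cohort, register, truth = zero_world
    linked = cohort.participants.dropna(subset=["true_pupil_id"])
    merged = linked.merge(
        register.pupils[["pupil_id", "forename", "surname", "dob"]],
        left_on="true_pupil_id",
        right_on="pupil_id",
        suffixes=("", "_reg"),
    )
    assert (merged["forename"] == merged["forename_reg"]).all()
    assert (merged["surname"] == merged["surname_reg"]).all()
    assert (merged["dob"] == merged["dob_reg"]).all()
    # trial contacts never contradict the participant identity
    con = cohort.contacts.merge(
        cohort.participants[["participant_id", "surname"]],
        on="participant_id",
        suffixes=("", "_truth"),
    )
    assert (con["surname"] == con["surname_truth"]).all()


def test_randomised_totals_per_trial(small_world):
    cohort, _, _ = small_world
    counts = cohort.participants.groupby("trial_id").size().to_dict()
    assert counts == {
        "NEP": 229, "NETSGA": 299, "LCPUFAP": 196, "LCPUFAT": 309,
        "IRONT": 327, "PALMT": 203, "NUCLEOT": 200,
    }
    per_arm = cohort.participants.groupby(["trial_id", "arm"]).size()
    assert per_arm[("NEP", "modified")] == 113
    assert per_arm[("IRONT", "standard")] == 165


def test_permuted_blocks_of_length_two_alternate():
    rng = np.random.default_rng(0)
    seq = permuted_block_sequence(50, 50, (2,), rng)
    prefix = np.cumsum(2 * seq - 1)
    assert np.abs(prefix).max() <= 1
    assert seq.sum() == 50


def test_block_lengths_must_be_even():
    import dataclasses

    with pytest.raises(ValueError, match="even"):
        dataclasses.replace(DEFAULT_TRIAL_SPECS["NEP"], block_lengths=(3, 4))


def test_null_model_latent_balance(small_world):
    """With arm_effect=0 the latent-ability arm difference is ~0 per trial."""
    cohort, _, _ = small_world
    for trial_id, grp in cohort.participants.groupby("trial_id"):
        a = grp.loc[grp["arm"] == "modified", "latent_ability"]
        b = grp.loc[grp["arm"] == "standard", "latent_ability"]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3.5 * se, trial_id


def test_twins_share_dob_and_surname(small_world):
    cohort, _, _ = small_world
    twins = cohort.participants.dropna(subset=["twin_group"])
    assert len(twins) > 0
    for _, grp in twins.groupby("twin_group"):
        assert grp["dob"].nunique() == 1
        assert grp["surname"].nunique() == 1
        assert grp["trial_id"].nunique() == 1


def test_deceased_never_claim_a_pupil(small_world):
    cohort, _, truth = small_world
    dead = cohort.participants[cohort.participants["death"] == 1]
    assert len(dead) > 0
    assert dead["true_pupil_id"].isna().all()


def test_preterm_deficit_orders_raw_scores(small_world):
    """Preterm/SGA cohorts score lower in raw GCSE points than term cohorts."""
    cohort, register, _ = small_world
    merged = cohort.participants.dropna(subset=["true_pupil_id"]).merge(
        register.pupils[["pupil_id", "gcse_maths"]],
        left_on="true_pupil_id", right_on="pupil_id",
    )
    merged["pts"] = grade_to_points(merged["gcse_maths"])
    pop = {s.trial_id: s.population for s in DEFAULT_TRIAL_SPECS.values()}
    merged["population"] = merged["trial_id"].map(pop)
    means = merged.groupby("population")["pts"].mean()
    assert means["preterm"] < means["term"]
    assert means["term_sga"] < means["term"]


def test_corruption_zero_model_is_identity():
    specs = {"PALMT": DEFAULT_TRIAL_SPECS["PALMT"]}
    cohort, register, truth = generate_world(
        seed=9, population_size=1000, trial_specs=specs, error_model=ErrorModel.zero()
    )
    assert truth["pupil_id"].notna().sum() == (cohort.participants["death"] == 0).sum()
    con = cohort.contacts.merge(
        cohort.participants[["participant_id", "forename", "surname", "dob"]],
        on="participant_id", suffixes=("", "_t"),
    )
    assert (con["forename"] == con["forename_t"]).all()
    assert (con["dob"] == con["dob_t"]).all()


@pytest.mark.parametrize("p_typo,forced", [(1.0, True), (0.05, False)])
def test_name_typo_rates(p_typo, forced):
    """Typo corruption counts follow the configured binomial rate."""
    specs = {
        "IRONT": DEFAULT_TRIAL_SPECS["IRONT"],
        "LCPUFAT": DEFAULT_TRIAL_SPECS["LCPUFAT"],
        "NETSGA": DEFAULT_TRIAL_SPECS["NETSGA"],
    }  # ~935 participants
    em = ErrorModel(p_name_typo=p_typo, p_surname_change=0, p_postcode_move_unrecorded=0,
                    p_dob_error=0, p_missing_field=0, p_register_absent=0)
    cohort, register, truth = generate_world(
        seed=13, population_size=2000, trial_specs=specs, error_model=em
    )
    con = cohort.contacts.drop_duplicates("participant_id").merge(
        cohort.participants[["participant_id", "forename", "surname"]],
        on="participant_id", suffixes=("", "_t"),
    )
    edited = (
        (con["forename"].fillna("") != con["forename_t"])
        | (con["surname"].fillna("") != con["surname_t"])
    )
    n = len(con)
    if forced:
        assert edited.all()
    else:
        expect = n * p_typo
        bound = 3 * np.sqrt(n * p_typo * (1 - p_typo))
        assert abs(edited.sum() - expect) < bound


def test_register_too_small_raises():
    from dormantlink.synthcohort import simulate_register

    reg = simulate_register(100, seed=1)
    with pytest.raises(ValueError, match="too small"):
        simulate_trials({"IRONT": DEFAULT_TRIAL_SPECS["IRONT"]}, reg, seed=1)


def test_error_model_probabilities_validated():
    with pytest.raises(ValueError):
        ErrorModel(p_name_typo=1.5)
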