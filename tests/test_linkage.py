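"""Candidate generation, Fellegi-Sunter scoring and link selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dormantlink.linkage import (
    FIELDS,
    MatchWeights,
    evaluate_linkage,
    generate_candidates,
    score_candidate,
    score_candidates,
    select_best_links,
    threshold_sweep,
)
from dormantlink.namebank import build_postcode_lookup
from dormantlink.synthcohort import ErrorModel, generate_world
from dormantlink.trials import DEFAULT_TRIAL_SPECS

from conftest import link_world


def uniform_weights(m_exact=0.95, u_exact=0.05, m_dis=0.01, u_dis=0.9):
    """Weights with the same exact/disagree m/u in every field."""
    def dist(ex, dis, extra=()):
        others = ("partial", "missing", *extra)
        rest = (1.0 - ex - dis) / len(others)
        return {"exact": ex, "disagree": dis, **{k: rest for k in others}}

    m = {f: dist(m_exact, m_dis) for f in FIELDS}
    u = {f: dist(u_exact, u_dis) for f in FIELDS}
    m["postcode"] = dist(m_exact, m_dis, extra=("neighbouring_authority",))
    u["postcode"] = dist(u_exact, u_dis, extra=("neighbouring_authority",))
    return MatchWeights(m=m, u=u)


def test_all_exact_score_closed_form():
    """Four exact fields at m=0.95, u=0.05 give 4*log2(19) ~ 16.99."""
    w = uniform_weights()
    cand = {f"{f}_level": "exact" for f in FIELDS}
    assert score_candidate(cand, w) == pytest.approx(4 * np.log2(0.95 / 0.05), abs=1e-9)
    assert score_candidate(cand, w) == pytest.approx(16.99, abs=0.01)


def test_all_disagree_score_closed_form():
    """Four disagreeing fields at m=0.01, u=0.9 give 4*log2(1/90) ~ -25.97."""
    w = uniform_weights()
    cand = {f"{f}_level": "disagree" for f in FIELDS}
    assert score_candidate(cand, w) == pytest.approx(4 * np.log2(0.01 / 0.9), abs=1e-9)
    assert score_candidate(cand, w) == pytest.approx(-25.97, abs=0.01)


def test_m_equals_u_contributes_zero():
    w = uniform_weights()
    w.m["dob"] = {"exact": 0.3, "partial": 0.3, "disagree": 0.3, "missing": 0.1}
    w.u["dob"] = {"exact": 0.3, "partial": 0.3, "disagree": 0.3, "missing": 0.1}
    base = {f"{f}_level": "missing" for f in FIELDS}
    cand = dict(base, dob_level="exact")
    assert score_candidate(cand, w) == pytest.approx(0.0)


def test_missing_field_contributes_zero_and_score_decomposes():
    w = uniform_weights()
    per_field = {
        f: w.weight(f, lvl)
        for f, lvl in [("surname", "exact"), ("forename", "partial"),
                       ("dob", "missing"), ("postcode", "disagree")]
    }
    cand = {
        "surname_level": "exact", "forename_level": "partial",
        "dob_level": "missing", "postcode_level": "disagree",
    }
    assert per_field["dob"] == 0.0
    assert score_candidate(cand, w) == pytest.approx(sum(per_field.values()))


def test_unknown_level_raises():
    w = uniform_weights()
    with pytest.raises(KeyError):
        w.weight("surname", "sounds_like")


def test_weights_must_be_distributions():
    with pytest.raises(ValueError):
        MatchWeights(m={"surname": {"exact": 0.5, "disagree": 0.2}}, u={"surname": {"exact": 0.5, "disagree": 0.5}})


def _manual_canonical(rows, key):
    df = pd.DataFrame(rows)
    df["dob"] = pd.to_datetime(df["dob"])
    return df


def test_candidate_cap_at_four(lookup):
    """Six register pupils with identical identifiers: only four retained."""
    pc = lookup.postcodes[0]
    auth = lookup.authority(pc)
    trial = _manual_canonical(
        [dict(participant_id="T0", contact_date=1, surname="SMITH", forename="ANNA",
              dob="1994-01-01", postcode=pc, authority=auth, postcode_valid=True)],
        "participant_id",
    )
    register = _manual_canonical(
        [dict(pupil_id=f"P{i}", census_year=2000, surname="SMITH", forename="ANNA",
              dob="1994-01-01", postcode=pc, authority=auth, postcode_valid=True)
         for i in range(6)],
        "pupil_id",
    )
    cands = generate_candidates(trial, register, lookup, max_candidates=4)
    assert len(cands) == 4
    assert list(cands["pupil_id"]) == ["P0", "P1", "P2", "P3"]  # deterministic ties


def test_zero_corruption_candidate_recall_is_one(zero_world):
    cohort, register, truth = zero_world
    scored, _ = link_world(zero_world, error_model=ErrorModel.zero())
    pairs = set(zip(scored["participant_id"], scored["pupil_id"]))
    present = truth.dropna(subset=["pupil_id"])
    missing = [
        (a, b) for a, b in zip(present["participant_id"], present["pupil_id"])
        if (a, b) not in pairs
    ]
    assert missing == []


def test_register_absent_participant_has_no_true_candidate(small_world, small_world_links):
    cohort, _, truth = small_world
    scored, _ = small_world_links
    absent = set(truth.loc[truth["pupil_id"].isna(), "participant_id"]) - set(
        cohort.participants.loc[cohort.participants["death"] == 1, "participant_id"]
    )
    truth_map = dict(zip(truth["participant_id"], truth["pupil_id"]))
    for pid in list(absent)[:50]:
        cands = scored[scored["participant_id"] == pid]
        assert all(truth_map.get(pid) != p for p in cands["pupil_id"])


def test_deceased_participants_are_excluded(lookup):
    pc = lookup.postcodes[0]
    auth = lookup.authority(pc)
    trial = _manual_canonical(
        [dict(participant_id="T0", contact_date=1, surname="SMITH", forename="ANNA",
              dob="1994-01-01", postcode=pc, authority=auth, postcode_valid=True)],
        "participant_id",
    )
    register = _manual_canonical(
        [dict(pupil_id="P0", census_year=2000, surname="SMITH", forename="ANNA",
              dob="1994-01-01", postcode=pc, authority=auth, postcode_valid=True)],
        "pupil_id",
    )
    participants = pd.DataFrame(
        {"participant_id": ["T0"], "death": [1], "twin_group": [None]}
    )
    scored = score_candidates(
        generate_candidates(trial, register, lookup), MatchWeights.from_error_model()
    )
    decisions = select_best_links(scored, participants)
    assert decisions.loc[0, "status"] == "excluded_death"
    assert decisions.loc[0, "pupil_id"] is None


def test_twins_ceded_to_forename_match(lookup):
    """Co-twins with shared surname/dob/postcode each get their own pupil."""
    pc = lookup.postcodes[0]
    auth = lookup.authority(pc)

    def trial_row(pid, forename):
        return dict(participant_id=pid, contact_date=1, surname="SMITH",
                    forename=forename, dob="1994-01-01", postcode=pc,
                    authority=auth, postcode_valid=True)

    def reg_row(pid, forename):
        return dict(pupil_id=pid, census_year=2000, surname="SMITH",
                    forename=forename, dob="1994-01-01", postcode=pc,
                    authority=auth, postcode_valid=True)

    trial = _manual_canonical([trial_row("TA", "ANNA"), trial_row("TB", "BETH")], "participant_id")
    register = _manual_canonical([reg_row("P_ANNA", "ANNA"), reg_row("P_BETH", "BETH")], "pupil_id")
    participants = pd.DataFrame(
        {"participant_id": ["TA", "TB"], "death": [0, 0], "twin_group": ["G1", "G1"]}
    )
    scored = score_candidates(
        generate_candidates(trial, register, lookup), MatchWeights.from_error_model()
    )
    decisions = select_best_links(scored, participants).set_index("participant_id")
    assert decisions.loc["TA", "pupil_id"] == "P_ANNA"
    assert decisions.loc["TB", "pupil_id"] == "P_BETH"


def test_simulated_twins_not_cross_assigned(small_world, small_world_links):
    """Across all simulated twin pairs with distinct forenames: no swaps."""
    cohort, _, truth = small_world
    _, decisions = small_world_links
    twins = cohort.participants.dropna(subset=["twin_group"])
    truth_map = dict(zip(truth["participant_id"], truth["pupil_id"]))
    dec_map = dict(zip(decisions["participant_id"], decisions["pupil_id"]))
    crossed = 0
    for _, grp in twins.groupby("twin_group"):
        if grp["forename"].nunique() < len(grp):
            continue
        for pid in grp["participant_id"]:
            got, want = dec_map.get(pid), truth_map.get(pid)
            if got is not None and want is not None and got != want:
                crossed += 1
    assert crossed == 0


def test_one_to_one_assignment(small_world_links):
    _, decisions = small_world_links
    linked = decisions[decisions["status"] == "linked"]
    assert linked["pupil_id"].is_unique
    assert decisions["participant_id"].is_unique


def test_evaluate_conventions():
    decisions = pd.DataFrame(
        {"participant_id": ["A", "B"], "pupil_id": [None, None],
         "status": ["unlinked", "unlinked"], "score": [np.nan] * 2, "margin": [np.nan] * 2}
    )
    truth = pd.DataFrame({"participant_id": ["A", "B"], "pupil_id": ["P1", "P2"]})
    rep = evaluate_linkage(decisions, truth)
    assert rep["recall"] == 0.0
    assert rep["precision"] == 1.0 and rep["zero_links"]

    decisions2 = pd.DataFrame(
        {"participant_id": ["A", "B"], "pupil_id": ["P1", "P2"],
         "status": ["linked", "linked"], "score": [5.0, 5.0], "margin": [np.inf] * 2}
    )
    rep2 = evaluate_linkage(decisions2, truth)
    assert rep2["precision"] == rep2["recall"] == 1.0


def test_score_permutation_invariance(small_world_links):
    """Reordering candidate columns does not change scores."""
    scored, _ = small_world_links
    w = MatchWeights.from_error_model()
    sample = scored.head(200)
    rev = sample[list(sample.columns)[::-1]]
    s1 = [score_candidate(r, w) for _, r in sample.iterrows()]
    s2 = [score_candidate(r, w) for _, r in rev.iterrows()]
    assert np.allclose(s1, s2)
    assert np.allclose(s1, sample["score"])


def test_threshold_sweep_monotone(small_world, small_world_links):
    cohort, _, truth = small_world
    scored, _ = small_world_links
    sweep = threshold_sweep(
        scored, cohort.participants, truth, thresholds=np.linspace(-5, 30, 15)
    )
    assert (np.diff(sweep["recall"]) <= 1e-12).all()
    assert (np.diff(sweep["n_linked"]) <= 0).all()
    assert sweep["precision"].iloc[-1] >= sweep["precision"].iloc[0] - 1e-12


def test_recall_monotone_in_corruption():
    """More identifier corruption never helps recall (within MC error)."""
    specs = {"LCPUFAT": DEFAULT_TRIAL_SPECS["LCPUFAT"]}
    recalls = []
    for f in (0.0, 0.5, 1.0):
        em = ErrorModel(
            p_name_typo=0.4 * f, p_surname_change=0.3 * f,
            p_postcode_move_unrecorded=0.4 * f, p_dob_error=0.25 * f,
            p_missing_field=0.3 * f, p_register_absent=0.0,
        )
        world = generate_world(seed=21, population_size=1200, trial_specs=specs, error_model=em)
        _, decisions = link_world(world)
        recalls.append(evaluate_linkage(decisions, world[2])["recall"])
    assert recalls[1] <= recalls[0] + 0.02
    assert recalls[2] <= recalls[1] + 0.02
    assert recalls[2] < recalls[0]  # heavy corruption must actually bite
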