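"""Synthetic trial cohorts and pupil register with ground-truth links.

This module emulates the data world of a dormant-trial reactivation
study: seven infant-formula trials whose participants are later found (or
not) in a national pupil register carrying school-census identifier
histories and exam results at ages 11 (key stage 2) and 16 (GCSE).

The generative model is deliberately simple and fully declared:

* one standard-normal latent ability per child, plus linear covariate
  effects (sex, maternal education and smoking, birth weight, gestational
  age, centre), a non-negative population deficit for children born
  preterm or small for gestational age at term, and an injectable
  per-trial arm effect in SD units (zero by default: the null model);
* exam grades obtained by discretising a noisy copy of the latent score
  with year-specific thresholds (a per-year threshold drift stands in
  for grade inflation, and supplies the per-year national reference used
  for external standardisation);
* identifier histories on both sides (trial contact records, school
  census entries) drawn with recorded postcode moves, and an error model
  injecting typos, name changes, unrecorded moves, date-of-birth digit
  errors, missing fields, and register absence.

Trial participants are claimed from the pre-generated background
register: the claimed pupil's identity fields and school outcomes are
rewritten from the participant, and ``truth_links`` records the claim.
Everything is deterministic given the run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rand import child_rng
from .namebank import (
    FORENAMES_F,
    FORENAMES_M,
    PostcodeLookup,
    build_postcode_lookup,
    sample_names,
)
from .trials import DEFAULT_TRIAL_SPECS, TrialSpec

__all__ = [
    "OutcomeModel",
    "ErrorModel",
    "Register",
    "TrialCohort",
    "simulate_register",
    "simulate_trials",
    "corrupt_identifiers",
    "generate_world",
    "permuted_block_sequence",
    "GCSE_SUBJECTS",
]

GCSE_SUBJECTS = (
    "maths", "english", "science", "history",
    "geography", "french", "art", "dt",
)

#: grades bottom-up; index in this tuple is the points value (U=0 .. A*=8)
GRADES_ASC = ("U", "G", "F", "E", "D", "C", "B", "A", "A*")

#: national grade shares bottom-up (U, G, F, E, D, C, B, A, A*)
_GRADE_PROBS_ASC = (0.04, 0.05, 0.09, 0.12, 0.15, 0.25, 0.15, 0.10, 0.05)


@dataclass(frozen=True)
class OutcomeModel:
    """Latent-ability outcome model shared by register and trials.

    ``arm_effects`` maps trial id to the injected true treatment effect in
    SD units of the exam score scale; the default (all zero) is a null
    model. ``deficit_*`` are non-negative SD penalties applied to the
    preterm and term-SGA trial populations, reproducing the pattern of
    lower raw scores in those cohorts. ``inflation_per_year`` shifts the
    effective score by that amount per exam year after ``reference_year``,
    emulating grade inflation; the per-year national reference used for
    external standardisation tracks the same shift.
    """

    coef_degree: float = 0.30
    coef_smoking: float = -0.15
    coef_male: float = -0.10
    coef_bw_per_kg: float = 0.05  # centred at 3.5 kg
    coef_ga_per_week: float = 0.02  # centred at 40 weeks
    centre_effects: dict = field(
        default_factory=lambda: {"NT": 0.0, "L": 0.02, "C": -0.02, "I": 0.0, "NW": 0.0}
    )
    deficit_preterm: float = 0.45
    deficit_term_sga: float = 0.25
    arm_effects: dict = field(default_factory=dict)
    residual_sd: float = 0.94
    subject_noise_sd: float = 0.30
    ks2_noise_sd: float = 0.45
    inflation_per_year: float = 0.01
    reference_year: int = 2008
    p_missing_gcse: float = 0.04
    p_missing_ks2: float = 0.04
    p_missing_covariate: float = 0.03
    sen_intercept: float = -2.0
    sen_slope: float = -1.3
    p_death_preterm: float = 0.03
    p_death_term: float = 0.005
    twin_fraction_preterm: float = 0.05
    twin_fraction_term: float = 0.01

    # -- grade machinery -------------------------------------------------
    @property
    def _score_sd(self) -> float:
        return float(np.hypot(1.0, self.subject_noise_sd))

    def grade_thresholds(self) -> np.ndarray:
        """Score-scale cut points between successive grades (len 8)."""
        cum = np.cumsum(_GRADE_PROBS_ASC)[:-1]
        return norm.ppf(cum) * self._score_sd

    def year_offset(self, year: int | np.ndarray) -> np.ndarray:
        return self.inflation_per_year * (np.asarray(year) - self.reference_year)

    def grade_points_from_scores(self, scores: np.ndarray, years: np.ndarray) -> np.ndarray:
        """Discretise subject scores to grade points (0..8) per exam year."""
        eff = np.asarray(scores) + self.year_offset(years)
        return np.searchsorted(self.grade_thresholds(), eff).astype(float)

    def national_reference(self, year: int) -> tuple[float, float]:
        """Implied national mean and SD of grade points for one exam year.

        Computed analytically from the standard-normal reference
        population and the (inflation-shifted) thresholds, so simulated
        register marginals match it within sampling error by construction.
        """
        t = self.grade_thresholds() - self.year_offset(year)
        cdf = np.concatenate([[0.0], norm.cdf(t / self._score_sd), [1.0]])
        probs = np.diff(cdf)
        points = np.arange(len(GRADES_ASC), dtype=float)
        mean = float(probs @ points)
        sd = float(np.sqrt(probs @ points**2 - mean**2))
        return mean, sd

    def deficit(self, population: str) -> float:
        return {
            "preterm": self.deficit_preterm,
            "term_sga": self.deficit_term_sga,
            "term": 0.0,
        }[population]

    def covariate_score(
        self,
        male: np.ndarray,
        smoking: np.ndarray,
        degree: np.ndarray,
        birth_weight: np.ndarray,
        gest_age: np.ndarray,
        centre: np.ndarray | None = None,
    ) -> np.ndarray:
        s = (
            self.coef_male * male
            + self.coef_smoking * smoking
            + self.coef_degree * degree
            + self.coef_bw_per_kg * (birth_weight / 1000.0 - 3.5)
            + self.coef_ga_per_week * (gest_age - 40.0)
        )
        if centre is not None:
            s = s + np.array([self.centre_effects.get(c, 0.0) for c in centre])
        return s


@dataclass(frozen=True)
class ErrorModel:
    """Identifier corruption and register-absence probabilities.

    All probabilities act per participant. The zero model is the
    identity: identifiers agree exactly across the trial and register
    views and every (surviving) participant is present in the register.
    """

    p_name_typo: float = 0.05
    p_surname_change: float = 0.03
    p_postcode_move_unrecorded: float = 0.05
    p_dob_error: float = 0.01
    p_missing_field: float = 0.02
    p_register_absent: float = 0.05

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class Register:
    """Synthetic pupil register: one row per pupil plus a census history."""

    pupils: pd.DataFrame
    census: pd.DataFrame
    lookup: PostcodeLookup


@dataclass
class TrialCohort:
    """Trial-side tables: one row per participant plus contact history."""

    participants: pd.DataFrame
    contacts: pd.DataFrame


# ---------------------------------------------------------------------------
# register simulation
# ---------------------------------------------------------------------------

def _random_dates(rng, start: str, end: str, n: int) -> np.ndarray:
    lo = np.datetime64(start)
    hi = np.datetime64(end)
    span = int((hi - lo).astype(int)) + 1
    return lo + rng.integers(0, span, size=n).astype("timedelta64[D]")


def _postcode_sequences(rng, lookup: PostcodeLookup, n_moves: np.ndarray) -> list[list[str]]:
    codes = np.asarray(lookup.postcodes)
    seqs = []
    for k in n_moves:
        seqs.append(list(rng.choice(codes, size=int(k) + 1, replace=False)))
    return seqs


def _school_outcomes(
    model: OutcomeModel,
    rng,
    latent: np.ndarray,
    birth_year: np.ndarray,
    gcse_allowed: np.ndarray,
    register_end_year: int = 2016,
) -> pd.DataFrame:
    """Exam outcome block for a set of children given their latent score."""
    n = len(latent)
    out = pd.DataFrame(index=np.arange(n))
    out["ks2_year"] = birth_year + 11
    out["gcse_year"] = birth_year + 16

    ks2_obs = rng.random(n) >= model.p_missing_ks2
    for subj in ("maths", "english"):
        raw = 50.0 + 15.0 * (latent + rng.normal(0.0, model.ks2_noise_sd, n))
        raw = np.clip(np.round(raw), 0, 100)
        out[f"ks2_{subj}"] = np.where(ks2_obs, raw, np.nan)

    gcse_obs = (
        (out["gcse_year"].to_numpy() <= register_end_year)
        & gcse_allowed
        & (rng.random(n) >= model.p_missing_gcse)
    )
    years = out["gcse_year"].to_numpy()
    for subj in GCSE_SUBJECTS:
        score = latent + rng.normal(0.0, model.subject_noise_sd, n)
        pts = model.grade_points_from_scores(score, years)
        letters = np.array(GRADES_ASC)[pts.astype(int)]
        out[f"gcse_{subj}"] = np.where(gcse_obs, letters, None)

    p_sen = 1.0 / (1.0 + np.exp(-(model.sen_intercept + model.sen_slope * latent)))
    out["sen_ever"] = (rng.random(n) < p_sen).astype(int)
    return out


def simulate_register(
    population_size: int,
    outcome_model: OutcomeModel | None = None,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    lookup: PostcodeLookup | None = None,
    birth_window: tuple[str, str] = ("1993-01-01", "2001-12-31"),
    p_not_in_census: float = 0.02,
    p_move_per_year: float = 0.06,
) -> Register:
    """Generate the background pupil register.

    Returns one pupil row per child (identity, exam outcomes, SEN flag)
    plus a census table of identifier-history segments (a new segment per
    recorded house move). Pupils with ``in_state_census`` false carry no
    census identifiers and can only be reached through exam records,
    which this simulator does not link on; they are effectively invisible
    to the linker.
    """
    model = outcome_model or OutcomeModel()
    error_model = error_model or ErrorModel()  # noqa: F841  (reserved: register-side noise)
    lookup = lookup or build_postcode_lookup()
    rng = child_rng(seed, "register")

    n = int(population_size)
    sex = (rng.random(n) < 0.51).astype(int)
    forename, surname = sample_names(rng, sex)
    dob = _random_dates(rng, *birth_window, n)
    birth_year = dob.astype("datetime64[Y]").astype(int) + 1970
    latent = rng.normal(0.0, 1.0, n)
    in_census = rng.random(n) >= p_not_in_census

    pupils = pd.DataFrame(
        {
            "pupil_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "dob": dob,
            "forename": forename,
            "surname": surname,
            "in_state_census": in_census.astype(int),
            "latent_ability": latent,
        }
    )
    outcomes = _school_outcomes(
        model, rng, latent, birth_year, gcse_allowed=np.ones(n, bool)
    )
    pupils = pd.concat([pupils, outcomes], axis=1)

    n_moves = rng.binomial(11, p_move_per_year, size=n)
    seqs = _postcode_sequences(rng, lookup, n_moves)
    rows: list[tuple] = []
    for i in range(n):
        if not in_census[i]:
            continue
        first = birth_year[i] + 5
        k = len(seqs[i])
        move_years = np.sort(rng.choice(np.arange(first + 1, first + 12), size=k - 1, replace=False)) if k > 1 else []
        years = [first, *move_years]
        for yr, pc in zip(years, seqs[i]):
            rows.append((pupils.at[i, "pupil_id"], int(yr), forename[i], surname[i], dob[i], pc))
    census = pd.DataFrame(
        rows, columns=["pupil_id", "census_year", "forename", "surname", "dob", "postcode"]
    )
    return Register(pupils=pupils, census=census, lookup=lookup)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def permuted_block_sequence(
    n_modified: int, n_standard: int, block_lengths: tuple[int, ...], rng
) -> np.ndarray:
    """Allocation sequence (1 = modified) from permuted blocks of random length.

    Blocks are balanced while both arms have allocations remaining; once
    one arm's target count is exhausted the tail is filled from the other,
    so the configured per-arm totals are met exactly.
    """
    rem = [int(n_standard), int(n_modified)]
    out: list[int] = []
    while sum(rem) > 0:
        length = int(rng.choice(block_lengths))
        half = length // 2
        k1 = min(half, rem[1])
        k0 = min(length - k1, rem[0])
        k1 = min(k1 + (length - k1 - k0), rem[1])  # refill if standard short
        block = [1] * k1 + [0] * k0
        rng.shuffle(block)
        out.extend(block[: sum(rem)])
        rem[1] -= min(k1, rem[1])
        rem[0] -= min(k0, rem[0])
    return np.asarray(out[: n_modified + n_standard])


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `targets`."""
    if targets.sum() == 0:
        out = np.zeros_like(targets, dtype=int)
        out[0] = total
        return out
    quota = targets / targets.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():  # rejection; bounds are several SDs out, converges fast
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def simulate_trials(
    trial_specs: dict[str, TrialSpec] | None,
    register: Register,
    outcome_model: OutcomeModel | None = None,
    seed: int = 0,
    oversampling_factor: float = 2.0,
) -> tuple[TrialCohort, Register]:
    """Simulate the seven trial cohorts and claim their pupils.

    Each participant is allocated by permuted blocks (stratified by
    centre), given covariates drawn from the trial's baseline profile,
    and -- unless they die in infancy -- claims a background pupil whose
    identity and school outcomes are rewritten from the participant's.
    Twin pairs share date of birth, surname and postcode history.

    Returns the cohort and the updated register.
    """
    specs = trial_specs or DEFAULT_TRIAL_SPECS
    model = outcome_model or OutcomeModel()
    rng = child_rng(seed, "trials")

    total = sum(s.n_randomised for s in specs.values())
    pool = register.pupils.index[register.pupils["in_state_census"] == 1].to_numpy()
    if len(pool) < oversampling_factor * total:
        raise ValueError(
            f"register population {len(pool)} too small for {total} participants "
            f"at oversampling factor {oversampling_factor}"
        )
    claim_order = rng.permutation(pool)
    claim_ptr = 0

    pupils = register.pupils.copy()
    lookup = register.lookup
    codes = np.asarray(lookup.postcodes)

    part_rows: list[dict] = []
    contact_rows: list[tuple] = []
    census_new: list[tuple] = []
    claimed_census_drop: list[str] = []

    pid_counter = 0
    for spec in specs.values():
        prof = spec.covariates
        n1, n0 = spec.n_per_arm
        n = n1 + n0

        rand_dates = np.sort(_random_dates(rng, *spec.randomisation_period, n))
        centres = np.asarray(spec.centres)
        centre_idx = rng.integers(0, len(centres), size=n)
        centre = centres[centre_idx]

        # stratified permuted-block allocation with exact per-arm totals
        arm = np.empty(n, dtype=int)
        counts = np.bincount(centre_idx, minlength=len(centres))
        n1_by_centre = _largest_remainder(counts.astype(float), n1)
        for ci in range(len(centres)):
            idx = np.flatnonzero(centre_idx == ci)
            if len(idx) == 0:
                continue
            seq = permuted_block_sequence(
                int(n1_by_centre[ci]), int(counts[ci] - n1_by_centre[ci]),
                spec.block_lengths, rng,
            )
            arm[idx] = seq  # idx is in date order within centre

        sex = (rng.random(n) < prof.p_male).astype(int)
        bw = _truncated_normal(
            rng, prof.birth_weight_mean, prof.birth_weight_sd, *prof.birth_weight_range, n
        )
        ga = _truncated_normal(
            rng, prof.gest_age_mean, prof.gest_age_sd, *prof.gest_age_range, n
        )
        mat_age = _truncated_normal(
            rng, prof.maternal_age_mean, prof.maternal_age_sd, *prof.maternal_age_range, n
        )
        smoking = (rng.random(n) < prof.p_smoking).astype(float)
        degree = (rng.random(n) < prof.p_degree).astype(float)
        forename, surname = sample_names(rng, sex)

        dob = rand_dates - np.timedelta64(int(round(spec.randomised_at_months * 30.44)), "D")

        # twins: adjacent index pairs sharing dob, surname, maternal covariates
        twin_frac = (
            model.twin_fraction_preterm
            if spec.population == "preterm"
            else model.twin_fraction_term
        )
        n_pairs = int(round(twin_frac * n / 2))
        twin_group = np.array([None] * n, dtype=object)
        pair_starts = rng.choice(np.arange(0, n - 1, 2), size=n_pairs, replace=False) if n_pairs else []
        for g, i in enumerate(pair_starts):
            j = i + 1
            twin_group[i] = twin_group[j] = f"{spec.trial_id}-TW{g:03d}"
            dob[j] = dob[i]
            surname[j] = surname[i]
            mat_age[j] = mat_age[i]
            smoking[j] = smoking[i]
            degree[j] = degree[i]
            centre[j] = centre[i]
            if forename[j] == forename[i]:  # co-twins get distinct forenames
                bank = FORENAMES_M if sex[j] == 1 else FORENAMES_F
                alt = [x for x in bank if x != forename[i]]
                forename[j] = rng.choice(alt)

        p_death = (
            model.p_death_preterm if spec.population == "preterm" else model.p_death_term
        )
        death = (rng.random(n) < p_death).astype(int)
        death_days = rng.integers(7, 730, size=n)

        arm_effect = model.arm_effects.get(spec.trial_id, 0.0)
        latent = (
            model.covariate_score(sex, smoking, degree, bw, ga, centre)
            - model.deficit(spec.population)
            + arm_effect * arm
            + rng.normal(0.0, model.residual_sd, n)
        )

        # identifier histories: contacts on the trial side
        n_contacts = np.clip(
            np.round(rng.normal(spec.mean_contacts, spec.sd_contacts, n)), 1, 12
        ).astype(int)
        home = rng.choice(codes, size=n)

        birth_year = dob.astype("datetime64[Y]").astype(int) + 1970
        outc = _school_outcomes(
            model,
            rng,
            latent,
            birth_year,
            gcse_allowed=np.full(n, spec.gcse_available),
        )

        # claim a register pupil for every survivor (bulk identity rewrite)
        alive_idx = np.flatnonzero(death == 0)
        claim_rows = claim_order[claim_ptr : claim_ptr + len(alive_idx)]
        claim_ptr += len(alive_idx)
        claimed_pupil_of = dict(zip(alive_idx, pupils.loc[claim_rows, "pupil_id"]))
        claimed_census_drop.extend(claimed_pupil_of.values())
        pupils.loc[claim_rows, "sex"] = sex[alive_idx]
        pupils.loc[claim_rows, "dob"] = dob[alive_idx]
        pupils.loc[claim_rows, "forename"] = forename[alive_idx]
        pupils.loc[claim_rows, "surname"] = surname[alive_idx]
        pupils.loc[claim_rows, "latent_ability"] = latent[alive_idx]
        pupils.loc[claim_rows, "in_state_census"] = 1
        for col in outc.columns:
            pupils.loc[claim_rows, col] = outc[col].to_numpy()[alive_idx]

        for i in range(n):
            participant_id = f"T{pid_counter:05d}"
            pid_counter += 1
            pcs = [home[i]]
            dates = np.sort(rng.integers(0, 730, size=n_contacts[i]))
            for _ in range(n_contacts[i] - 1):
                if rng.random() < 0.04:  # recorded move between contacts
                    pcs.append(str(rng.choice(codes)))
                else:
                    pcs.append(pcs[-1])
            if twin_group[i] is not None and i - 1 >= 0 and twin_group[i - 1] == twin_group[i]:
                pcs = [contact_rows[-1][5]] * n_contacts[i]  # co-twin shares address
            for d, pc in zip(dates, pcs):
                contact_rows.append(
                    (
                        participant_id,
                        rand_dates[i] + np.timedelta64(int(d), "D"),
                        forename[i],
                        surname[i],
                        dob[i],
                        pc,
                    )
                )

            true_pupil = None
            if not death[i]:
                true_pupil = claimed_pupil_of[i]
                # census history: last contact postcode onward, occasional later move
                yr = birth_year[i] + 5
                pc_seq = [pcs[-1]]
                years = [yr]
                for y in range(yr + 1, birth_year[i] + 17):
                    if rng.random() < 0.05:
                        pc_seq.append(str(rng.choice(codes)))
                        years.append(y)
                for y, pc in zip(years, pc_seq):
                    census_new.append(
                        (true_pupil, int(y), forename[i], surname[i], dob[i], pc)
                    )

            part_rows.append(
                {
                    "participant_id": participant_id,
                    "trial_id": spec.trial_id,
                    "arm": "modified" if arm[i] else "standard",
                    "centre": centre[i],
                    "randomisation_date": rand_dates[i],
                    "dob": dob[i],
                    "sex": sex[i],
                    "birth_weight": round(float(bw[i]), 0),
                    "gestational_age": round(float(ga[i]), 1),
                    "maternal_age": round(float(mat_age[i]), 1),
                    "maternal_smoking": smoking[i],
                    "maternal_degree": degree[i],
                    "death": int(death[i]),
                    "death_date": (dob[i] + np.timedelta64(int(death_days[i]), "D")) if death[i] else pd.NaT,
                    "twin_group": twin_group[i],
                    "forename": forename[i],
                    "surname": surname[i],
                    "true_pupil_id": true_pupil,
                    "latent_ability": latent[i],
                }
            )

    participants = pd.DataFrame(part_rows)
    # covariate missingness at the baseline-table level (truth kept in latent)
    for col in ("maternal_smoking", "maternal_degree"):
        mask = rng.random(len(participants)) < model.p_missing_covariate
        participants.loc[mask, col] = np.nan

    contacts = pd.DataFrame(
        contact_rows,
        columns=["participant_id", "contact_date", "forename", "surname", "dob", "postcode"],
    )
    census = pd.concat(
        [
            register.census[~register.census["pupil_id"].isin(claimed_census_drop)],
            pd.DataFrame(
                census_new,
                columns=["pupil_id", "census_year", "forename", "surname", "dob", "postcode"],
            ),
        ],
        ignore_index=True,
    )
    cohort = TrialCohort(participants=participants, contacts=contacts)
    return cohort, Register(pupils=pupils, census=census, lookup=lookup)


# ---------------------------------------------------------------------------
# identifier corruption
# ---------------------------------------------------------------------------

def _typo(rng, word: str) -> str:
    if len(word) < 2:
        return word + "E"
    for _ in range(5):  # ops can no-op (swap of equal letters); retry
        op = rng.integers(0, 3)
        i = int(rng.integers(1, len(word)))
        if op == 0:  # substitution
            c = chr(ord("a") + int(rng.integers(0, 26)))
            out = word[:i] + c + word[i + 1:]
        elif op == 1:  # deletion
            out = word[:i] + word[i + 1:]
        else:  # transposition
            if i == len(word) - 1:
                i -= 1
            out = word[:i] + word[i + 1] + word[i] + word[i + 2:]
        if out != word:
            return out
    return word + "E"


def _perturb_dob(rng, d: np.datetime64) -> np.datetime64:
    ts = pd.Timestamp(d)
    choice = rng.integers(0, 3)
    if choice == 0 and ts.day <= 12 and ts.month != ts.day:
        return np.datetime64(ts.replace(month=ts.day, day=ts.month), "D")
    if choice <= 1:
        delta = int(rng.choice([-1, 1]))
        new_day = ts.day + delta
        if new_day < 1 or new_day > 28:
            new_day = ts.day - delta if 1 <= ts.day - delta <= 28 else 15
        return np.datetime64(ts.replace(day=new_day), "D")
    try:
        return np.datetime64(ts.replace(month=ts.month % 12 + 1), "D")
    except ValueError:
        return np.datetime64(ts.replace(day=28, month=ts.month % 12 + 1), "D")


def corrupt_identifiers(
    cohort: TrialCohort,
    register: Register,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[TrialCohort, Register, pd.DataFrame]:
    """Apply the error model and emit the ground-truth link table.

    Corruptions hit the trial-side transcription (typos, date-of-birth
    digit errors, missing fields) or the register side (surname change
    after the trial, unrecorded postcode move). Register-absent
    participants have their claimed pupil removed from the register and
    ``true_pupil_id`` cleared. The zero model is the identity.
    """
    em = error_model or ErrorModel()
    rng = child_rng(seed, "corrupt")

    participants = cohort.participants.copy()
    contacts = cohort.contacts.copy()
    pupils = register.pupils
    census = register.census.copy()

    # register absence -------------------------------------------------
    linked_mask = participants["true_pupil_id"].notna()
    absent = linked_mask & (rng.random(len(participants)) < em.p_register_absent)
    absent_pupils = set(participants.loc[absent, "true_pupil_id"])
    if absent_pupils:
        pupils = pupils[~pupils["pupil_id"].isin(absent_pupils)].reset_index(drop=True)
        census = census[~census["pupil_id"].isin(absent_pupils)]
        participants.loc[absent, "true_pupil_id"] = None

    contacts_by_pid = contacts.groupby("participant_id", sort=False)
    contact_index = {pid: grp.index for pid, grp in contacts_by_pid}
    census_by_pupil = census.groupby("pupil_id", sort=False)
    census_index = {pid: grp.index for pid, grp in census_by_pupil}
    codes = np.asarray(register.lookup.postcodes)
    auth_codes: dict[str, list[str]] = {}
    for pc in codes:
        auth_codes.setdefault(register.lookup.authority(pc), []).append(pc)

    n = len(participants)
    u = rng.random((n, 5))
    for i, row in enumerate(participants.itertuples(index=False)):
        idx = contact_index.get(row.participant_id)
        if idx is None:
            continue
        if u[i, 0] < em.p_name_typo:  # transcription typo on the trial side
            col = "surname" if rng.random() < 0.5 else "forename"
            val = contacts.at[idx[0], col]
            contacts.loc[idx, col] = _typo(rng, str(val))
        if u[i, 1] < em.p_dob_error:
            contacts.loc[idx, "dob"] = _perturb_dob(rng, contacts.at[idx[0], "dob"])
        if u[i, 2] < em.p_missing_field:
            col = ["forename", "postcode", "dob"][int(rng.integers(0, 3))]
            contacts.loc[idx, col] = None if col != "dob" else pd.NaT
        cidx = census_index.get(row.true_pupil_id)
        if cidx is None:
            continue
        if u[i, 3] < em.p_surname_change:  # family name change after the trial
            change_year = int(rng.integers(
                census.at[cidx[0], "census_year"], census.at[cidx[0], "census_year"] + 12
            ))
            new_surname = _typo(rng, str(census.at[cidx[0], "surname"])) if rng.random() < 0.3 \
                else str(rng.choice(["Smith", "Jones", "Taylor", "Clark", "Reed", "Fox"]))
            late = [j for j in cidx if census.at[j, "census_year"] >= change_year]
            census.loc[late if late else cidx, "surname"] = new_surname
        if u[i, 4] < em.p_postcode_move_unrecorded:  # move the trial never saw
            old_auth = register.lookup.authority(census.at[cidx[0], "postcode"])
            nbrs = sorted(register.lookup.neighbours.get(old_auth, ()))
            if nbrs and rng.random() < 0.5:
                new_pc = rng.choice(auth_codes[str(rng.choice(nbrs))])
            else:
                new_pc = rng.choice(codes)
            census.loc[cidx[0], "postcode"] = new_pc

    truth = participants[["participant_id", "true_pupil_id"]].rename(
        columns={"true_pupil_id": "pupil_id"}
    )
    new_cohort = TrialCohort(participants=participants, contacts=contacts)
    new_register = Register(pupils=pupils, census=census.reset_index(drop=True), lookup=register.lookup)
    return new_cohort, new_register, truth


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def generate_world(
    seed: int = 0,
    population_size: int = 10_000,
    trial_specs: dict[str, TrialSpec] | None = None,
    outcome_model: OutcomeModel | None = None,
    error_model: ErrorModel | None = None,
    lookup: PostcodeLookup | None = None,
) -> tuple[TrialCohort, Register, pd.DataFrame]:
    """Simulate register + trials + corruption in one call.

    Returns ``(cohort, register, truth_links)``.
    """
    model = outcome_model or OutcomeModel()
    em = error_model or ErrorModel()
    register = simulate_register(
        population_size, model, em, seed=seed, lookup=lookup
    )
    cohort, register = simulate_trials(trial_specs, register, model, seed=seed)
    return corrupt_identifiers(cohort, register, em, seed=seed)
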