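"""Probabilistic record linkage: candidates, agreement weights, selection.

The linker realises the classic Fellegi-Sunter model. Candidate pairs
come from three deterministic blocking passes (exact date of birth;
surname + postcode outward code; birth year + forename initial + local
authority), each participant keeping at most ``max_candidates`` register
pupils. Every identifier field is compared against the best-aligning
entries of the two identifier chronologies and graded into an agreement
level; the candidate score is the sum of per-field log2 likelihood
ratios ``log2(m/u)``, where ``m`` is the probability of that level among
true matches and ``u`` among non-matches. Selection is a greedy
one-to-one assignment by descending score, with auxiliary trial
knowledge applied that the register holder does not have: participants
who died before school entry are excluded outright, and within a twin
group a candidate whose forename disagrees is ceded to the co-twin who
matches it exactly. The acceptance threshold is applied after
assignment, so the linked set at a higher threshold is always a subset
of the linked set at a lower one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .namebank import PostcodeLookup
from .synthcohort import ErrorModel

__all__ = [
    "LEVELS",
    "FIELDS",
    "MatchWeights",
    "generate_candidates",
    "score_candidate",
    "score_candidates",
    "select_best_links",
    "evaluate_linkage",
    "threshold_sweep",
]

FIELDS = ("surname", "forename", "dob", "postcode")
LEVELS = ("exact", "partial", "neighbouring_authority", "disagree", "missing")

#: similarity cut for partial string agreement (normalised edit distance)
PARTIAL_SIMILARITY = 0.8


def _validate_mu(probs: dict[str, float], what: str) -> None:
    total = 0.0
    for level, p in probs.items():
        if not 0.0 < p < 1.0:
            raise ValueError(f"{what}[{level}] must be in (0,1), got {p}")
        total += p
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{what} probabilities must sum to 1, got {total}")


@dataclass
class MatchWeights:
    """Per-field, per-level m/u probabilities and their log2 weights.

    ``m[field][level]`` is P(level | true match), ``u[field][level]`` is
    P(level | non-match); both must be proper distributions over the
    field's levels. A missing field carries zero weight by convention.
    """

    m: dict = field(default_factory=dict)
    u: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.m:
            _validate_mu(self.m[f], f"m[{f}]")
            _validate_mu(self.u[f], f"u[{f}]")

    def weight(self, fieldname: str, level: str) -> float:
        if level == "missing":
            return 0.0
        try:
            m = self.m[fieldname][level]
            u = self.u[fieldname][level]
        except KeyError as exc:
            raise KeyError(f"no weight for {fieldname}/{level}") from exc
        return float(np.log2(m / u))

    @classmethod
    def from_error_model(cls, error_model: ErrorModel | None = None) -> "MatchWeights":
        """Derive default m-probabilities from the identifier error model.

        The u side uses fixed register-frequency estimates for the
        synthetic identifier universe (~120 surnames, ~50 forenames per
        sex, ~3300 distinct dates of birth, ~1000 postcodes over 50
        authorities). All values are overridable in config.
        """
        em = error_model or ErrorModel()
        floor = 1e-3

        def dist(d: dict) -> dict:
            d = {k: max(v, floor) for k, v in d.items()}
            s = sum(d.values())
            return {k: v / s for k, v in d.items()}

        typo_half = em.p_name_typo / 2.0
        miss_third = em.p_missing_field / 3.0
        m = {
            "surname": dist({
                "exact": 1.0 - typo_half - em.p_surname_change,
                "partial": 0.8 * typo_half + 0.15 * em.p_surname_change,
                "disagree": 0.2 * typo_half + 0.85 * em.p_surname_change,
                "missing": floor,
            }),
            "forename": dist({
                "exact": 1.0 - typo_half - miss_third,
                "partial": 0.8 * typo_half,
                "disagree": 0.2 * typo_half,
                "missing": miss_third,
            }),
            "dob": dist({
                "exact": 1.0 - em.p_dob_error - miss_third,
                "partial": 0.9 * em.p_dob_error,
                "disagree": 0.1 * em.p_dob_error,
                "missing": miss_third,
            }),
            "postcode": dist({
                "exact": 1.0 - em.p_postcode_move_unrecorded - miss_third,
                "partial": 0.05 * em.p_postcode_move_unrecorded,
                "neighbouring_authority": 0.5 * em.p_postcode_move_unrecorded,
                "disagree": 0.45 * em.p_postcode_move_unrecorded,
                "missing": miss_third,
            }),
        }
        u = {
            "surname": dist({"exact": 0.012, "partial": 0.02, "disagree": 0.966, "missing": 0.002}),
            "forename": dist({"exact": 0.022, "partial": 0.03, "disagree": 0.946, "missing": 0.002}),
            "dob": dist({"exact": 0.0004, "partial": 0.004, "disagree": 0.9936, "missing": 0.002}),
            "postcode": dist({
                "exact": 0.0012, "partial": 0.02, "neighbouring_authority": 0.08,
                "disagree": 0.8968, "missing": 0.002,
            }),
        }
        return cls(m=m, u=u)


# ---------------------------------------------------------------------------
# agreement evaluation
# ---------------------------------------------------------------------------

def _string_level(a_vals: list[str], b_vals: list[str]) -> str:
    a_vals = [a for a in a_vals if a]
    b_vals = [b for b in b_vals if b]
    if not a_vals or not b_vals:
        return "missing"
    best = "disagree"
    for a in a_vals:
        for b in b_vals:
            if a == b:
                return "exact"
            dist = edlib.align(a, b)["editDistance"]
            sim = 1.0 - dist / max(len(a), len(b))
            if sim >= PARTIAL_SIMILARITY:
                best = "partial"
    return best


def _dob_level(a_vals: list, b_vals: list) -> str:
    a_vals = [a for a in a_vals if pd.notna(a)]
    b_vals = [b for b in b_vals if pd.notna(b)]
    if not a_vals or not b_vals:
        return "missing"
    best = "disagree"
    for a in a_vals:
        ta = pd.Timestamp(a)
        for b in b_vals:
            tb = pd.Timestamp(b)
            if ta == tb:
                return "exact"
            ndiff = (ta.day != tb.day) + (ta.month != tb.month) + (ta.year != tb.year)
            if ndiff == 1:
                best = "partial"
    return best


def _postcode_level(
    a_vals: list[str], b_vals: list[str], lookup: PostcodeLookup
) -> str:
    a_vals = [a for a in a_vals if a]
    b_vals = [b for b in b_vals if b]
    if not a_vals or not b_vals:
        return "missing"
    rank = {"exact": 0, "partial": 1, "neighbouring_authority": 2, "disagree": 3}
    best = "disagree"
    for a in a_vals:
        auth_a = lookup.authority(a)
        for b in b_vals:
            if a == b:
                return "exact"
            level = "disagree"
            auth_b = lookup.authority(b)
            if auth_a is not None and auth_a == auth_b:
                level = "partial"
            elif auth_a is not None and auth_b is not None and lookup.are_neighbours(auth_a, auth_b):
                level = "neighbouring_authority"
            if rank[level] < rank[best]:
                best = level
    return best


def _field_values(canonical: pd.DataFrame, key: str) -> dict:
    """participant/pupil id -> dict of distinct per-field value lists."""
    out: dict = {}
    cols = canonical[[key, "surname", "forename", "dob", "postcode", "authority"]]
    for row in cols.itertuples(index=False):
        rec = out.setdefault(
            row[0],
            {"surname": [], "forename": [], "dob": [], "postcode": [], "authority": []},
        )
        for f, v in zip(("surname", "forename", "dob", "postcode", "authority"), row[1:]):
            if f == "dob":
                if pd.notna(v) and v not in rec[f]:
                    rec[f].append(v)
            elif v and v not in rec[f]:
                rec[f].append(v)
    return out


def generate_candidates(
    trial_canonical: pd.DataFrame,
    register_canonical: pd.DataFrame,
    lookup: PostcodeLookup,
    max_candidates: int = 4,
) -> pd.DataFrame:
    """Candidate register matches per participant, with agreement levels.

    Blocking passes: (1) exact date of birth; (2) surname + postcode
    outward code; (3) birth year + forename initial + authority. The
    union is truncated to ``max_candidates`` pupils per participant by a
    provisional count of exactly-agreeing fields (ties broken by lowest
    pupil id, for determinism). Agreement levels per field are evaluated
    against the best-aligning pair of chronology entries.
    """
    trial_vals = _field_values(trial_canonical, "participant_id")
    reg_vals = _field_values(register_canonical, "pupil_id")

    by_dob: dict = {}
    by_surname_outward: dict = {}
    by_year_initial_auth: dict = {}
    for pid, rec in reg_vals.items():
        for d in rec["dob"]:
            by_dob.setdefault(d, set()).add(pid)
            year = pd.Timestamp(d).year
            for f in rec["forename"]:
                for a in rec["authority"]:
                    by_year_initial_auth.setdefault((year, f[0], a), set()).add(pid)
        for s in rec["surname"]:
            for pc in rec["postcode"]:
                by_surname_outward.setdefault((s, pc.split(" ")[0]), set()).add(pid)

    rows = []
    for part_id, rec in trial_vals.items():
        cands: set = set()
        for d in rec["dob"]:
            cands |= by_dob.get(d, set())
        for s in rec["surname"]:
            for pc in rec["postcode"]:
                cands |= by_surname_outward.get((s, pc.split(" ")[0]), set())
        for d in rec["dob"]:
            year = pd.Timestamp(d).year
            for f in rec["forename"]:
                for a in rec["authority"]:
                    cands |= by_year_initial_auth.get((year, f[0], a), set())
        if not cands:
            continue

        scored = []
        for pupil_id in cands:
            prec = reg_vals[pupil_id]
            n_exact = (
                bool(set(rec["surname"]) & set(prec["surname"]))
                + bool(set(rec["forename"]) & set(prec["forename"]))
                + bool(set(rec["dob"]) & set(prec["dob"]))
                + bool(set(rec["postcode"]) & set(prec["postcode"]))
            )
            scored.append((-n_exact, pupil_id))
        scored.sort()
        for rank, (_, pupil_id) in enumerate(scored[:max_candidates]):
            prec = reg_vals[pupil_id]
            rows.append(
                {
                    "participant_id": part_id,
                    "pupil_id": pupil_id,
                    "surname_level": _string_level(rec["surname"], prec["surname"]),
                    "forename_level": _string_level(rec["forename"], prec["forename"]),
                    "dob_level": _dob_level(rec["dob"], prec["dob"]),
                    "postcode_level": _postcode_level(rec["postcode"], prec["postcode"], lookup),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "pupil_id",
            "surname_level", "forename_level", "dob_level", "postcode_level",
        ],
    )


# ---------------------------------------------------------------------------
# scoring and selection
# ---------------------------------------------------------------------------

def score_candidate(candidate: dict | pd.Series, weights: MatchWeights) -> float:
    """Total log2 agreement weight of one candidate (missing fields add 0)."""
    return sum(weights.weight(f, candidate[f"{f}_level"]) for f in FIELDS)


def score_candidates(candidates: pd.DataFrame, weights: MatchWeights) -> pd.DataFrame:
    """Score all candidates and attach per-participant rank and margin."""
    out = candidates.copy()
    if out.empty:
        out["score"] = pd.Series(dtype=float)
        out["n_exact"] = pd.Series(dtype=int)
        out["rank"] = pd.Series(dtype=int)
        out["margin"] = pd.Series(dtype=float)
        return out
    wtab = {
        f: {lv: weights.weight(f, lv) if lv != "missing" else 0.0
            for lv in (set(weights.m.get(f, {})) | {"missing"})}
        for f in FIELDS
    }
    out["score"] = [
        sum(wtab[f][row[f"{f}_level"]] for f in FIELDS)
        for row in out.to_dict("records")
    ]
    out["n_exact"] = sum(
        (out[f"{f}_level"] == "exact").astype(int) for f in FIELDS
    )
    out = out.sort_values(
        ["participant_id", "score", "n_exact", "pupil_id"],
        ascending=[True, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = out.groupby("participant_id").cumcount() + 1
    best_next = out.groupby("participant_id")["score"].shift(-1)
    out["margin"] = (out["score"] - best_next).where(out["rank"] == 1)
    out["margin"] = out["margin"].fillna(np.inf)
    return out


def _died_before_school(participants: pd.DataFrame) -> pd.Series:
    return participants["death"].fillna(0).astype(int) == 1


def select_best_links(
    candidates: pd.DataFrame,
    participants: pd.DataFrame,
    threshold: float = 0.0,
    tie_margin: float = 0.0,
) -> pd.DataFrame:
    """One decision per participant: linked, unlinked or excluded_death.

    Greedy one-to-one assignment by descending score (ties: more
    exact-agreeing fields, then lowest pupil id). Deceased participants
    are excluded before assignment. Within a twin group, a candidate
    whose forename does not agree exactly is ceded to a co-twin holding a
    forename-exact candidate for the same pupil. Scores below
    ``threshold`` (or margins below ``tie_margin``) are unlinked after
    assignment.
    """
    cand = candidates.copy()
    dead = set(participants.loc[_died_before_school(participants), "participant_id"])
    cand = cand[~cand["participant_id"].isin(dead)]

    # twin ceding: drop forename-discordant candidates claimed by a co-twin
    twins = participants.loc[
        participants["twin_group"].notna(), ["participant_id", "twin_group"]
    ]
    if not twins.empty and not cand.empty:
        twin_of = dict(zip(twins["participant_id"], twins["twin_group"]))
        grp = cand["participant_id"].map(twin_of)
        exact_claims = {
            (g, pupil)
            for g, pupil, lvl in zip(grp, cand["pupil_id"], cand["forename_level"])
            if pd.notna(g) and lvl == "exact"
        }
        drop = [
            idx
            for idx, g, pupil, lvl in zip(
                cand.index, grp, cand["pupil_id"], cand["forename_level"]
            )
            if pd.notna(g) and lvl != "exact" and (g, pupil) in exact_claims
        ]
        cand = cand.drop(index=drop)

    order = cand.sort_values(
        ["score", "n_exact", "pupil_id", "participant_id"],
        ascending=[False, False, True, True],
        kind="stable",
    )
    taken_pupils: set = set()
    assigned: dict = {}
    assigned_score: dict = {}
    assigned_margin: dict = {}
    for row in order.itertuples(index=False):
        if row.participant_id in assigned or row.pupil_id in taken_pupils:
            continue
        assigned[row.participant_id] = row.pupil_id
        assigned_score[row.participant_id] = row.score
        assigned_margin[row.participant_id] = row.margin
        taken_pupils.add(row.pupil_id)

    decisions = []
    for pid in participants["participant_id"]:
        if pid in dead:
            decisions.append((pid, None, "excluded_death", np.nan, np.nan))
            continue
        pupil = assigned.get(pid)
        score = assigned_score.get(pid, np.nan)
        margin = assigned_margin.get(pid, np.nan)
        if pupil is None or score < threshold or margin < tie_margin:
            decisions.append((pid, None, "unlinked", score, margin))
        else:
            decisions.append((pid, pupil, "linked", score, margin))
    out = pd.DataFrame(
        decisions, columns=["participant_id", "pupil_id", "status", "score", "margin"]
    )
    linked = out.loc[out["status"] == "linked", "pupil_id"]
    assert linked.is_unique, "one-to-one assignment violated"
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_linkage(
    decisions: pd.DataFrame,
    truth: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> dict:
    """Precision, recall and link rate of a set of link decisions.

    Precision is over linked decisions (reported as 1.0 with a
    ``zero_links`` flag when nothing was linked); recall is over truth
    pairs whose participant is genuinely present in the register.
    """
    truth_map = dict(
        zip(truth["participant_id"], truth["pupil_id"])
    )
    linked = decisions[decisions["status"] == "linked"]
    n_linked = len(linked)
    correct = sum(
        truth_map.get(pid) == pupil
        for pid, pupil in zip(linked["participant_id"], linked["pupil_id"])
        if truth_map.get(pid) is not None
    )
    n_truth = int(truth["pupil_id"].notna().sum())
    report = {
        "n_decisions": int(len(decisions)),
        "n_linked": n_linked,
        "n_truth_pairs": n_truth,
        "precision": (correct / n_linked) if n_linked else 1.0,
        "zero_links": n_linked == 0,
        "recall": (correct / n_truth) if n_truth else 1.0,
        "link_rate": n_linked / len(decisions) if len(decisions) else 0.0,
    }
    if participants is not None:
        merged = decisions.merge(
            participants[["participant_id", "trial_id", "arm"]], on="participant_id"
        )
        table = (
            merged.assign(linked=(merged["status"] == "linked").astype(int))
            .groupby(["trial_id", "arm"])
            .agg(randomised=("participant_id", "count"), linked=("linked", "sum"))
            .reset_index()
        )
        table["link_rate"] = table["linked"] / table["randomised"]
        report["per_trial_arm"] = table
    return report


def threshold_sweep(
    candidates_scored: pd.DataFrame,
    participants: pd.DataFrame,
    truth: pd.DataFrame,
    thresholds: np.ndarray | list,
) -> pd.DataFrame:
    """Precision/recall trade-off over a grid of acceptance thresholds.

    The assignment is computed once at threshold ``-inf``; each grid
    point then unlinks assigned pairs scoring below it, so the linked
    sets are nested and recall is exactly non-increasing in the
    threshold.
    """
    base = select_best_links(candidates_scored, participants, threshold=-np.inf)
    rows = []
    for t in thresholds:
        dec = base.copy()
        cut = (dec["status"] == "linked") & (dec["score"] < t)
        dec.loc[cut, ["pupil_id", "status"]] = [None, "unlinked"]
        rep = evaluate_linkage(dec, truth)
        rows.append(
            {
                "threshold": float(t),
                "precision": rep["precision"],
                "recall": rep["recall"],
                "n_linked": rep["n_linked"],
            }
        )
    return pd.DataFrame(rows)
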