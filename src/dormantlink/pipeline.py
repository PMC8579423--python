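"""End-to-end orchestration: simulate -> standardise -> link -> analyse.

A run is fully described by a :class:`RunConfig` (serialisable to YAML)
and its seed; every stage writes plain CSV/JSON artifacts into the run
directory so each intermediate is inspectable, and a text report
summarises estimates, linkage quality and power. Stage accounting is
conserved: randomised = linked + unlinked + excluded_death per
trial-arm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .idprep import canonicalise_census, canonicalise_contacts
from .inference import ImputationConfig, power_table, run_sensitivity_matrix
from .linkage import (
    MatchWeights,
    evaluate_linkage,
    generate_candidates,
    score_candidates,
    select_best_links,
)
from .namebank import PostcodeLookup, build_postcode_lookup
from .outcomes import build_analysis_dataset
from .synthcohort import (
    ErrorModel,
    OutcomeModel,
    Register,
    TrialCohort,
    corrupt_identifiers,
    simulate_register,
    simulate_trials,
)
from .trials import DEFAULT_TRIAL_SPECS

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "make_report",
    "run_single_trial_replicate",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (plus the seed)."""

    seed: int = 0
    population_size: int = 10_000
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    threshold: float = 0.0
    tie_margin: float = 0.0
    max_candidates: int = 4
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    output_dir: str = "runs/latest"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        try:
            if "outcome_model" in data:
                data["outcome_model"] = OutcomeModel(**data["outcome_model"])
            if "error_model" in data:
                data["error_model"] = ErrorModel(**data["error_model"])
            if "imputation" in data:
                data["imputation"] = ImputationConfig(**data["imputation"])
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# world I/O
# ---------------------------------------------------------------------------

_DATE_COLS = {
    "trial_register.csv": ["randomisation_date", "dob", "death_date"],
    "trial_contacts.csv": ["contact_date", "dob"],
    "pupil_register.csv": ["dob"],
    "pupil_census.csv": ["dob"],
}


def write_world(
    outdir: Path, cohort: TrialCohort, register: Register, truth: pd.DataFrame
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.participants.drop(columns=["latent_ability"]).to_csv(
        outdir / "trial_register.csv", index=False
    )
    cohort.contacts.to_csv(outdir / "trial_contacts.csv", index=False)
    register.pupils.drop(columns=["latent_ability"]).to_csv(
        outdir / "pupil_register.csv", index=False
    )
    register.census.to_csv(outdir / "pupil_census.csv", index=False)
    truth.to_csv(outdir / "truth_links.csv", index=False)
    register.lookup.to_frame().to_csv(outdir / "postcode_lookup.csv", index=False)


def load_world(outdir: Path) -> tuple[TrialCohort, Register, pd.DataFrame]:
    def read(name: str) -> pd.DataFrame:
        return pd.read_csv(outdir / name, parse_dates=_DATE_COLS.get(name, False))

    participants = read("trial_register.csv")
    contacts = read("trial_contacts.csv")
    pupils = read("pupil_register.csv")
    census = read("pupil_census.csv")
    truth = pd.read_csv(outdir / "truth_links.csv")
    lookup = PostcodeLookup.from_frame(pd.read_csv(outdir / "postcode_lookup.csv"))
    return (
        TrialCohort(participants=participants, contacts=contacts),
        Register(pupils=pupils, census=census, lookup=lookup),
        truth,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> tuple[TrialCohort, Register, pd.DataFrame]:
    lookup = build_postcode_lookup()
    register = simulate_register(
        cfg.population_size, cfg.outcome_model, cfg.error_model, seed=cfg.seed, lookup=lookup
    )
    cohort, register = simulate_trials(
        DEFAULT_TRIAL_SPECS, register, cfg.outcome_model, seed=cfg.seed
    )
    cohort, register, truth = corrupt_identifiers(
        cohort, register, cfg.error_model, seed=cfg.seed
    )
    write_world(outdir, cohort, register, truth)
    log.info(
        "simulate: %d participants, %d pupils, %d truth pairs",
        len(cohort.participants), len(register.pupils), int(truth["pupil_id"].notna().sum()),
    )
    return cohort, register, truth


def stage_link(
    cfg: RunConfig,
    outdir: Path,
    cohort: TrialCohort,
    register: Register,
    truth: pd.DataFrame,
) -> pd.DataFrame:
    trial_canon = canonicalise_contacts(cohort.contacts, register.lookup)
    census_canon = canonicalise_census(register.census, register.lookup)
    trial_canon.to_csv(outdir / "trial_contacts_canonical.csv", index=False)
    census_canon.to_csv(outdir / "pupil_census_canonical.csv", index=False)

    candidates = generate_candidates(
        trial_canon, census_canon, register.lookup, max_candidates=cfg.max_candidates
    )
    weights = MatchWeights.from_error_model(cfg.error_model)
    scored = score_candidates(candidates, weights)
    scored.to_csv(outdir / "candidates.csv", index=False)
    decisions = select_best_links(
        scored, cohort.participants, threshold=cfg.threshold, tie_margin=cfg.tie_margin
    )
    decisions.to_csv(outdir / "links.csv", index=False)

    report = evaluate_linkage(decisions, truth, cohort.participants)
    per_trial = report.pop("per_trial_arm")
    report["per_trial_arm"] = per_trial.to_dict("records")
    with open(outdir / "linkage_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    log.info(
        "link: %d/%d linked (precision %.3f recall %.3f)",
        report["n_linked"], report["n_decisions"], report["precision"], report["recall"],
    )
    return decisions


def stage_analyse(
    cfg: RunConfig,
    outdir: Path,
    cohort: TrialCohort,
    register: Register,
    decisions: pd.DataFrame,
) -> pd.DataFrame:
    analysis = build_analysis_dataset(cohort, register, decisions, cfg.outcome_model)
    analysis.to_csv(outdir / "analysis_dataset.csv", index=False)

    impute_cfg = dataclasses.replace(cfg.imputation, seed=cfg.seed)
    estimates = run_sensitivity_matrix(analysis, impute_cfg)
    estimates.to_csv(outdir / "estimates.csv", index=False)
    power_table().to_csv(outdir / "power.csv", index=False)

    flow = (
        decisions.merge(
            cohort.participants[["participant_id", "trial_id", "arm"]], on="participant_id"
        )
        .groupby(["trial_id", "arm", "status"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
    )
    for col in ("linked", "unlinked", "excluded_death"):
        if col not in flow.columns:
            flow[col] = 0
    flow["randomised"] = flow[["linked", "unlinked", "excluded_death"]].sum(axis=1)
    outcome_avail = (
        analysis[analysis["sd_maths16"].notna()]
        .groupby(["trial_id", "arm"])
        .size()
        .rename("outcome_available")
        .reset_index()
    )
    flow = flow.merge(outcome_avail, on=["trial_id", "arm"], how="left").fillna(
        {"outcome_available": 0}
    )
    flow["outcome_available"] = flow["outcome_available"].astype(int)
    flow.to_csv(outdir / "flow_table.csv", index=False)
    log.info("analyse: %d estimate cells", len(estimates))
    return estimates


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage into ``cfg.output_dir`` and write the report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    try:
        cohort, register, truth = stage_simulate(cfg, outdir)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc
    try:
        decisions = stage_link(cfg, outdir, cohort, register, truth)
    except Exception as exc:
        raise StageError(f"link: {exc}") from exc
    try:
        stage_analyse(cfg, outdir, cohort, register, decisions)
    except Exception as exc:
        raise StageError(f"analyse: {exc}") from exc
    try:
        make_report(outdir)
    except Exception as exc:
        raise StageError(f"report: {exc}") from exc
    return outdir


# ---------------------------------------------------------------------------
# Monte-Carlo replicate of the primary analysis
# ---------------------------------------------------------------------------

def run_single_trial_replicate(
    seed: int,
    trial_id: str = "IRONT",
    arm_effect: float = 0.0,
    population_size: int = 1200,
    m: int = 15,
    outcome: str = "sd_maths16",
) -> tuple[float, float]:
    """One end-to-end replicate of the primary analysis for one trial.

    Simulates a register and the named trial cohort (with the given true
    arm effect), corrupts identifiers, links, derives outcomes, imputes
    the primary-analysis variables and returns the pooled MI-adjusted
    ``(estimate, se)``. Used for type-I-error and power calibration.
    """
    from .inference import fit_mean_difference, impute_chained, pool_rubin
    from .synthcohort import generate_world

    specs = {trial_id: DEFAULT_TRIAL_SPECS[trial_id]}
    model = OutcomeModel(arm_effects={trial_id: arm_effect})
    cohort, register, truth = generate_world(
        seed=seed, population_size=population_size, trial_specs=specs,
        outcome_model=model,
    )
    trial_canon = canonicalise_contacts(cohort.contacts, register.lookup)
    census_canon = canonicalise_census(register.census, register.lookup)
    scored = score_candidates(
        generate_candidates(trial_canon, census_canon, register.lookup),
        MatchWeights.from_error_model(),
    )
    decisions = select_best_links(scored, cohort.participants)
    analysis = build_analysis_dataset(cohort, register, decisions, model)
    alive = analysis[analysis["death"] == 0].reset_index(drop=True)
    imputed = impute_chained(
        alive,
        ImputationConfig(m=m, seed=seed),
        variables=("maternal_smoking", "maternal_degree", outcome),
    )
    fits = [fit_mean_difference(d, outcome, adjusted=True) for d in imputed]
    pooled, total_var, _, _ = pool_rubin(
        [f[0] for f in fits], [f[1] for f in fits]
    )
    return pooled, float(np.sqrt(total_var))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (written to report.txt).

    Pure function of the run directory: regenerating it from the same
    artifacts yields identical content.
    """
    run_dir = Path(run_dir)
    estimates = pd.read_csv(run_dir / "estimates.csv")
    power = pd.read_csv(run_dir / "power.csv")
    with open(run_dir / "linkage_report.json") as fh:
        linkage = json.load(fh)

    lines: list[str] = []
    lines.append("DORMANT-TRIAL REACTIVATION RUN REPORT")
    lines.append("=" * 37)
    lines.append("")
    lines.append(
        f"Linkage: {linkage['n_linked']}/{linkage['n_decisions']} linked "
        f"({100 * linkage['n_linked'] / linkage['n_decisions']:.1f}%), "
        f"precision {linkage['precision']:.3f}, recall {linkage['recall']:.3f}"
    )
    lines.append("")
    lines.append("Effect estimates (mean difference in SD units; OR for binary outcomes)")
    for (trial, outcome), grp in estimates.groupby(["trial_id", "outcome"], sort=True):
        lines.append(f"\n{trial} — {outcome}")
        verdicts = []
        for row in grp.itertuples(index=False):
            if row.status != "ok":
                lines.append(f"  {row.analysis_label:<22} non-estimable")
                continue
            is_or = outcome in ("five_plus_gcse_c", "sen_ever")
            if is_or:
                est, lo, hi = (np.exp(row.estimate), np.exp(row.ci_low), np.exp(row.ci_high))
                null = 1.0
            else:
                est, lo, hi = row.estimate, row.ci_low, row.ci_high
                null = 0.0
            bar = _forest_bar(est, lo, hi, null)
            lines.append(
                f"  {row.analysis_label:<22} {est:+.2f} ({lo:+.2f} to {hi:+.2f})  {bar}"
            )
            verdicts.append(lo > null)  # CI entirely above the null = benefit
        if verdicts:
            lines.append(
                "  verdict: "
                + ("evidence of benefit" if any(verdicts) else "no evidence of benefit")
            )
    lines.append("")
    lines.append("Minimum detectable effect sizes (80% power, alpha 0.05, linked n)")
    for row in power.itertuples(index=False):
        lines.append(f"  {row.trial_id:<8} n={row.n1}+{row.n2:<4} MDES {row.mdes:.2f} SD")
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.txt", "w") as fh:
        fh.write(text)
    return text


def _forest_bar(est: float, lo: float, hi: float, null: float, width: int = 25) -> str:
    span = max(abs(lo - null), abs(hi - null), 0.5)
    scale = (width // 2) / span
    pos = int(round((est - null) * scale)) + width // 2
    cells = ["-"] * width
    cells[width // 2] = "|"
    lo_i = max(0, int(round((lo - null) * scale)) + width // 2)
    hi_i = min(width - 1, int(round((hi - null) * scale)) + width // 2)
    for i in range(lo_i, hi_i + 1):
        cells[i] = "="
    cells[min(max(pos, 0), width - 1)] = "o"
    return "".join(cells)
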