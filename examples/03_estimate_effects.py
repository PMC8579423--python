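"""Estimate formula effects on exam scores for one trial.

Derives the analysis dataset (intention to treat: every randomised
participant keeps a row), then runs the five-cell sensitivity matrix for
the iron-fortified follow-on formula trial: multiple-imputation and
complete-case analyses, adjusted and unadjusted, plus external
standardisation — each with sandwich-robust variance and Rubin pooling.
"""

from dormantlink import (
    ImputationConfig,
    MatchWeights,
    build_analysis_dataset,
    generate_candidates,
    generate_world,
    run_sensitivity_matrix,
    score_candidates,
    select_best_links,
)
from dormantlink.idprep import canonicalise_census, canonicalise_contacts
from dormantlink.trials import DEFAULT_TRIAL_SPECS

specs = {"IRONT": DEFAULT_TRIAL_SPECS["IRONT"]}
cohort, register, truth = generate_world(seed=1, population_size=1500, trial_specs=specs)

trial_canon = canonicalise_contacts(cohort.contacts, register.lookup)
census_canon = canonicalise_census(register.census, register.lookup)
scored = score_candidates(
    generate_candidates(trial_canon, census_canon, register.lookup),
    MatchWeights.from_error_model(),
)
decisions = select_best_links(scored, cohort.participants)
analysis = build_analysis_dataset(cohort, register, decisions)

cells = run_sensitivity_matrix(analysis, ImputationConfig(m=15, seed=1))
primary = cells[cells["outcome"] == "sd_maths16"]
cols = ["analysis_label", "estimate", "se", "ci_low", "ci_high", "n"]
print("IRONT, GCSE mathematics at 16 (SD units, modified minus standard formula):")
print(primary[cols].round(3).to_string(index=False))
print(
    "\nThe simulator injects no true effect, so every cell should hover\n"
    "around 0 with a ~0.23-SD-wide confidence interval; agreement across\n"
    "the five cells is what the sensitivity matrix is designed to show."
)
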