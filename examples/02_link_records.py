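"""Link trial participants to the pupil register and evaluate quality.

Canonicalises identifiers on both sides, generates up to four blocked
candidates per participant, scores them with Fellegi-Sunter log2
agreement weights, selects at most one register pupil per participant,
and scores the result against the simulation's ground truth.
"""

import numpy as np

from dormantlink import (
    MatchWeights,
    evaluate_linkage,
    generate_candidates,
    generate_world,
    score_candidates,
    select_best_links,
    threshold_sweep,
)
from dormantlink.idprep import canonicalise_census, canonicalise_contacts

cohort, register, truth = generate_world(seed=1, population_size=5000)
trial_canon = canonicalise_contacts(cohort.contacts, register.lookup)
census_canon = canonicalise_census(register.census, register.lookup)

candidates = generate_candidates(trial_canon, census_canon, register.lookup)
scored = score_candidates(candidates, MatchWeights.from_error_model())
decisions = select_best_links(scored, cohort.participants, threshold=0.0)

report = evaluate_linkage(decisions, truth, cohort.participants)
print(f"Candidates generated: {len(scored)} for {scored['participant_id'].nunique()} participants")
print(
    f"Linked {report['n_linked']}/{report['n_decisions']} participants "
    f"({100 * report['link_rate']:.1f}%)"
)
print(f"Precision {report['precision']:.3f}, recall {report['recall']:.3f}")

sweep = threshold_sweep(scored, cohort.participants, truth, np.linspace(0, 25, 6))
print("\nThreshold sweep (raising the acceptance score trades recall for precision):")
print(sweep.round(3).to_string(index=False))
print(
    "\nA score of 0 accepts any candidate likelier to be a match than a\n"
    "non-match under the model; the sweep shows the linked set shrinking\n"
    "monotonically as that evidence bar rises."
)
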