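"""Design descriptions of the seven dormant infant-formula trials.

Each :class:`TrialSpec` carries what the generator needs to emulate one
trial: per-arm randomised counts, the infant population (preterm, term
small-for-gestational-age, or healthy term), recruitment centres, the
randomisation period, permitted permuted-block sizes, the expected number
of identifier contacts per participant, and parametric summaries of the
baseline covariates. ``linked_per_arm`` records the per-arm counts that
were successfully linked to an exam record in the original study; these
are the analysable sample sizes that drive the minimum-detectable-effect
calculations and the overall linkage-percentage accounting.

The NUCLEOT cohort was randomised ~7 years after the others, so its
members were too young to have sat GCSEs inside the register extract
window; ``gcse_available`` is False for that trial and its age-16
outcomes are structurally missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CovariateProfile",
    "TrialSpec",
    "DEFAULT_TRIAL_SPECS",
    "total_randomised",
    "total_linked",
    "link_rate_percent",
]


@dataclass(frozen=True)
class CovariateProfile:
    """Parametric baseline-covariate summaries for one trial.

    Continuous covariates are modelled as normals truncated to the
    observed ranges; binaries as Bernoulli at the observed proportions.
    """

    birth_weight_mean: float  # g
    birth_weight_sd: float
    birth_weight_range: tuple[float, float]
    gest_age_mean: float  # completed weeks
    gest_age_sd: float
    gest_age_range: tuple[float, float]
    maternal_age_mean: float  # years
    maternal_age_sd: float
    maternal_age_range: tuple[float, float]
    p_male: float
    p_smoking: float
    p_degree: float


@dataclass(frozen=True)
class TrialSpec:
    trial_id: str
    n_per_arm: tuple[int, int]  # randomised (modified, standard)
    linked_per_arm: tuple[int, int]  # linked to an exam record (modified, standard)
    population: str  # preterm | term_sga | term
    centres: tuple[str, ...]
    randomisation_period: tuple[str, str]  # ISO dates, inclusive
    block_lengths: tuple[int, ...] = (2, 4, 6)
    mean_contacts: float = 4.0
    sd_contacts: float = 1.5
    covariates: CovariateProfile | None = None
    gcse_available: bool = True
    randomised_at_months: int = 0  # IRONT enrolled at the follow-on stage

    def __post_init__(self) -> None:
        if any(b % 2 for b in self.block_lengths):
            raise ValueError(f"{self.trial_id}: permuted-block sizes must be even")

    @property
    def n_randomised(self) -> int:
        return sum(self.n_per_arm)

    @property
    def n_linked(self) -> int:
        return sum(self.linked_per_arm)

    def with_arms(self, n_modified: int, n_standard: int) -> "TrialSpec":
        return replace(self, n_per_arm=(n_modified, n_standard))


DEFAULT_TRIAL_SPECS: dict[str, TrialSpec] = {
    "NEP": TrialSpec(
        trial_id="NEP",
        n_per_arm=(113, 116),
        linked_per_arm=(108, 114),
        population="preterm",
        centres=("NT", "L", "C", "I"),
        randomisation_period=("1993-10-07", "1996-11-19"),
        mean_contacts=5.0,
        sd_contacts=1.5,
        covariates=CovariateProfile(
            birth_weight_mean=1377, birth_weight_sd=320, birth_weight_range=(630, 2160),
            gest_age_mean=30.8, gest_age_sd=2.6, gest_age_range=(25, 36),
            maternal_age_mean=28.2, maternal_age_sd=5.5, maternal_age_range=(16, 44),
            p_male=0.48, p_smoking=0.35, p_degree=0.09,
        ),
    ),
    "NETSGA": TrialSpec(
        trial_id="NETSGA",
        n_per_arm=(152, 147),
        linked_per_arm=(135, 134),
        population="term_sga",
        centres=("NT", "L", "C"),
        randomisation_period=("1993-09-21", "1996-01-11"),
        mean_contacts=4.8,
        sd_contacts=1.9,
        covariates=CovariateProfile(
            birth_weight_mean=2567, birth_weight_sd=320, birth_weight_range=(1400, 3160),
            gest_age_mean=39.2, gest_age_sd=1.2, gest_age_range=(37, 42),
            maternal_age_mean=26.8, maternal_age_sd=5.5, maternal_age_range=(15, 42),
            p_male=0.49, p_smoking=0.47, p_degree=0.04,
        ),
    ),
    "LCPUFAP": TrialSpec(
        trial_id="LCPUFAP",
        n_per_arm=(96, 100),
        linked_per_arm=(82, 89),
        population="preterm",
        centres=("NT", "L"),
        randomisation_period=("1993-08-11", "1996-05-11"),
        mean_contacts=1.7,
        sd_contacts=0.8,
        covariates=CovariateProfile(
            birth_weight_mean=1347, birth_weight_sd=290, birth_weight_range=(640, 1850),
            gest_age_mean=30.3, gest_age_sd=2.6, gest_age_range=(25, 36),
            maternal_age_mean=26.4, maternal_age_sd=5.0, maternal_age_range=(16, 39),
            p_male=0.50, p_smoking=0.42, p_degree=0.08,
        ),
    ),
    "LCPUFAT": TrialSpec(
        trial_id="LCPUFAT",
        n_per_arm=(155, 154),
        linked_per_arm=(137, 143),
        population="term",
        centres=("NT", "L"),
        randomisation_period=("1993-11-02", "1995-06-30"),
        mean_contacts=4.1,
        sd_contacts=1.8,
        covariates=CovariateProfile(
            birth_weight_mean=3593, birth_weight_sd=450, birth_weight_range=(2680, 4930),
            gest_age_mean=40.0, gest_age_sd=1.2, gest_age_range=(37, 42),
            maternal_age_mean=27.4, maternal_age_sd=5.5, maternal_age_range=(17, 44),
            p_male=0.54, p_smoking=0.25, p_degree=0.06,
        ),
    ),
    "IRONT": TrialSpec(
        trial_id="IRONT",
        n_per_arm=(162, 165),
        linked_per_arm=(149, 150),
        population="term",
        centres=("NT", "L", "NW"),
        randomisation_period=("1993-10-26", "1995-05-21"),
        mean_contacts=5.5,
        sd_contacts=1.0,
        randomised_at_months=9,
        covariates=CovariateProfile(
            birth_weight_mean=3475, birth_weight_sd=450, birth_weight_range=(2466, 5046),
            gest_age_mean=39.8, gest_age_sd=1.3, gest_age_range=(35, 43),
            maternal_age_mean=27.7, maternal_age_sd=5.0, maternal_age_range=(15, 40),
            p_male=0.51, p_smoking=0.28, p_degree=0.10,
        ),
    ),
    "PALMT": TrialSpec(
        trial_id="PALMT",
        n_per_arm=(103, 100),
        linked_per_arm=(98, 92),
        population="term",
        centres=("C",),
        randomisation_period=("1995-05-15", "1996-11-26"),
        mean_contacts=3.1,
        sd_contacts=0.8,
        covariates=CovariateProfile(
            birth_weight_mean=3532, birth_weight_sd=470, birth_weight_range=(2460, 5400),
            gest_age_mean=40.0, gest_age_sd=1.2, gest_age_range=(37, 42),
            maternal_age_mean=27.5, maternal_age_sd=5.5, maternal_age_range=(15, 42),
            p_male=0.57, p_smoking=0.31, p_degree=0.08,
        ),
    ),
    "NUCLEOT": TrialSpec(
        trial_id="NUCLEOT",
        n_per_arm=(100, 100),
        linked_per_arm=(90, 86),
        population="term",
        centres=("NT", "L"),
        randomisation_period=("2000-02-11", "2001-10-29"),
        mean_contacts=2.7,
        sd_contacts=0.9,
        gcse_available=False,
        covariates=CovariateProfile(
            birth_weight_mean=3467, birth_weight_sd=470, birth_weight_range=(2170, 5360),
            gest_age_mean=39.4, gest_age_sd=1.2, gest_age_range=(37, 42),
            maternal_age_mean=27.0, maternal_age_sd=5.0, maternal_age_range=(16, 40),
            p_male=0.58, p_smoking=0.33, p_degree=0.08,
        ),
    ),
}


def total_randomised(specs: dict[str, TrialSpec] | None = None) -> int:
    specs = specs or DEFAULT_TRIAL_SPECS
    return sum(s.n_randomised for s in specs.values())


def total_linked(specs: dict[str, TrialSpec] | None = None) -> int:
    specs = specs or DEFAULT_TRIAL_SPECS
    return sum(s.n_linked for s in specs.values())


def link_rate_percent(specs: dict[str, TrialSpec] | None = None) -> float:
    """Overall percentage of randomised participants linked to an exam record."""
    specs = specs or DEFAULT_TRIAL_SPECS
    return 100.0 * total_linked(specs) / total_randomised(specs)
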