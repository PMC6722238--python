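"""Synthetic study cohort emulating a 1/1,000 sample of the US population.

The cohort carries the demographic and behavioural attributes that drive
influenza-like RTI incidence, duration, resource use and work absence:
age, gender, influenza-vaccination status, active/passive smoking, school
enrollment, employment, shared-office work and nursing-home residence.
Default prevalences reproduce the published cohort structure: 19.81%
children aged 0-15, 12.50% active smokers, 26.59% passive smokers, 53.19%
with a daily shared indoor environment and 53.70% unvaccinated.

Only the marginal prevalences are specified, so attributes are drawn
independently given age, except that active and passive smoking are
mutually exclusive.  "Shared indoor environment" is the union of school
enrollment, shared-office work (a configurable fraction of the employed)
and nursing-home residence; the office fraction defaults to the value that
makes the composite prevalence 53.19% while keeping the employment rate at
the level implied by the published missed-work-day totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: US-like age structure (band lower age, band upper age, probability),
#: with the 0-15 mass fixed at the published 19.81% cohort share.
DEFAULT_AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (0, 0, 0.0120),
    (1, 4, 0.0490),
    (5, 15, 0.1371),
    (16, 24, 0.1200),
    (25, 44, 0.2640),
    (45, 64, 0.2569),
    (65, 74, 0.0930),
    (75, 95, 0.0680),
)

PERSON_COLUMNS = [
    "person_id", "age", "is_female", "vaccinated", "active_smoker",
    "passive_smoker", "in_school", "employed", "shared_office",
    "nursing_home", "shared_indoor", "is_child",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic cohort generator.

    ``sample_rate`` is the fraction of ``reference_total`` persons to
    simulate; the defaults give round(329,256,000 / 1,000) = 329,256.
    ``active_smoker_cohort_share`` is the target cohort-level prevalence;
    the conditional probability among eligible ages (>= ``active_smoker_
    min_age``) is apportioned from the configured age distribution.
    """

    sample_rate: float = 1e-3
    reference_total: int = 329_256_000
    age_distribution: tuple[tuple[int, int, float], ...] = field(
        default=DEFAULT_AGE_BANDS)
    female_fraction: float = 0.508
    unvaccinated_prob: float = 0.5370
    active_smoker_cohort_share: float = 0.1250
    active_smoker_min_age: int = 13
    passive_smoker_prob: float = 0.2659
    school_enrollment_prob_1_15: float = 0.95
    employment_rate_16plus: float = 0.58
    shared_office_prob_employed: float = 0.7591
    nursing_home_prob_65plus: float = 0.03
    child_age_cutoff: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "female_fraction": self.female_fraction,
            "unvaccinated_prob": self.unvaccinated_prob,
            "active_smoker_cohort_share": self.active_smoker_cohort_share,
            "passive_smoker_prob": self.passive_smoker_prob,
            "school_enrollment_prob_1_15": self.school_enrollment_prob_1_15,
            "employment_rate_16plus": self.employment_rate_16plus,
            "shared_office_prob_employed": self.shared_office_prob_employed,
            "nursing_home_prob_65plus": self.nursing_home_prob_65plus,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"population.{name} must be in [0, 1], got {p}")
        total = sum(b[2] for b in self.age_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"population.age_distribution probabilities sum to {total}, not 1")
        for lo, hi, p in self.age_distribution:
            if lo > hi or lo < 0 or p < 0:
                raise ConfigurationError(
                    f"population.age_distribution band ({lo}, {hi}, {p}) is invalid")
        if self.expected_size() <= 0:
            raise ConfigurationError(
                "population.sample_rate yields an empty cohort "
                f"(rate={self.sample_rate}, reference={self.reference_total})")

    def expected_size(self) -> int:
        return int(round(self.reference_total * self.sample_rate))

    def prob_age_at_least(self, age: int) -> float:
        """Probability that a person's age is >= ``age`` (ages uniform in band)."""
        total = 0.0
        for lo, hi, p in self.age_distribution:
            n_ages = hi - lo + 1
            n_in = max(0, hi - max(lo, age) + 1)
            total += p * n_in / n_ages
        return total


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort size and the subgroup shares (percent) used for validation."""

    n: int
    pct_children: float
    pct_active_smokers: float
    pct_passive_smokers: float
    pct_shared_indoor: float
    pct_unvaccinated: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pct_children": self.pct_children,
            "pct_active_smokers": self.pct_active_smokers,
            "pct_passive_smokers": self.pct_passive_smokers,
            "pct_shared_indoor": self.pct_shared_indoor,
            "pct_unvaccinated": self.pct_unvaccinated,
        }


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw the synthetic cohort; one row per person, reproducible by seed."""
    n = config.expected_size()
    rng = np.random.default_rng(config.seed)

    bands = config.age_distribution
    band_idx = rng.choice(len(bands), size=n, p=[b[2] for b in bands])
    lo = np.array([b[0] for b in bands])[band_idx]
    hi = np.array([b[1] for b in bands])[band_idx]
    age = lo + (rng.random(n) * (hi - lo + 1)).astype(np.int64)

    is_female = rng.random(n) < config.female_fraction
    vaccinated = rng.random(n) >= config.unvaccinated_prob

    # Active smoking: cohort-level target apportioned over eligible ages.
    p_eligible = config.prob_age_at_least(config.active_smoker_min_age)
    p_active = (config.active_smoker_cohort_share / p_eligible
                if p_eligible > 0 else 0.0)
    if p_active > 1.0:
        raise ConfigurationError(
            "active_smoker_cohort_share unattainable given the age distribution")
    active = (age >= config.active_smoker_min_age) & (rng.random(n) < p_active)
    # Passive smoking drawn among non-active smokers, rescaled so the
    # cohort-level share matches the configured marginal prevalence.
    if config.active_smoker_cohort_share >= 1.0:
        p_passive = 0.0
    else:
        p_passive = config.passive_smoker_prob / (1.0 - config.active_smoker_cohort_share)
    if p_passive > 1.0:
        raise ConfigurationError(
            "passive_smoker_prob incompatible with active smoker share")
    passive = ~active & (rng.random(n) < p_passive)

    in_school = ((age >= 1) & (age <= config.child_age_cutoff)
                 & (rng.random(n) < config.school_enrollment_prob_1_15))
    employed = (age >= 16) & (rng.random(n) < config.employment_rate_16plus)
    shared_office = employed & (rng.random(n) < config.shared_office_prob_employed)
    nursing_home = ((age >= 65) & ~employed
                    & (rng.random(n) < config.nursing_home_prob_65plus))

    df = pd.DataFrame({
        "person_id": np.arange(n, dtype=np.int64),
        "age": age,
        "is_female": is_female,
        "vaccinated": vaccinated,
        "active_smoker": active,
        "passive_smoker": passive,
        "in_school": in_school,
        "employed": employed,
        "shared_office": shared_office,
        "nursing_home": nursing_home,
    })
    df["shared_indoor"] = df.in_school | df.shared_office | df.nursing_home
    df["is_child"] = df.age <= config.child_age_cutoff
    return df[PERSON_COLUMNS]


def validate_population(pop: pd.DataFrame, config: PopulationConfig) -> None:
    """Assert the structural invariants of a person table; raise on violation."""
    if (pop.active_smoker & pop.passive_smoker).any():
        raise ConfigurationError("active and passive smoking must be exclusive")
    if (pop.in_school & ((pop.age < 1) | (pop.age > config.child_age_cutoff))).any():
        raise ConfigurationError("in_school outside ages 1..child_age_cutoff")
    if (pop.employed & (pop.age < 16)).any():
        raise ConfigurationError("employed below age 16")
    if (pop.shared_office & ~pop.employed).any():
        raise ConfigurationError("shared_office requires employment")
    expected = pop.in_school | pop.shared_office | pop.nursing_home
    if not pop.shared_indoor.equals(expected):
        raise ConfigurationError("shared_indoor is not the expected union")
    if not pop.is_child.equals(pop.age <= config.child_age_cutoff):
        raise ConfigurationError("is_child inconsistent with age cutoff")


def summarize_population(pop: pd.DataFrame) -> PopulationSummary:
    """Cohort size and subgroup shares, on the percent scale."""
    if len(pop) == 0:
        raise ConfigurationError("cannot summarize an empty population")
    n = len(pop)
    pct = lambda mask: 100.0 * float(mask.sum()) / n
    return PopulationSummary(
        n=n,
        pct_children=pct(pop.is_child),
        pct_active_smokers=pct(pop.active_smoker),
        pct_passive_smokers=pct(pop.passive_smoker),
        pct_shared_indoor=pct(pop.shared_indoor),
        pct_unvaccinated=pct(~pop.vaccinated),
    )
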