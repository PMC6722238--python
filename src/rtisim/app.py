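"""Pipeline assembly: config -> cohort -> calibrated model -> paired run."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig, config_hash
from .engine import EpisodeLedger, run_paired_simulation
from .epidemiology import (DurationModel, IncidenceModel,
                           build_seasonal_profile, calibrate_incidence)
from .synthpop import generate_population


def build_duration_model(config: RunConfig) -> DurationModel:
    return DurationModel(base_mean_days=config.scenario.base_mean_days,
                         dispersion=config.duration.dispersion,
                         minimum_days=config.duration.minimum_days)


def build_incidence_model(config: RunConfig) -> IncidenceModel:
    profile = build_seasonal_profile(config.profile.preset,
                                     config.profile.peak_day,
                                     config.profile.concentration)
    inc = config.incidence
    return IncidenceModel(
        profile=profile,
        risk=config.risk,
        child_adult_incidence_ratio=inc.child_adult_incidence_ratio,
        calibration_target_episodes=inc.calibration_target_episodes,
        calibration_reference_cohort=inc.calibration_reference_cohort,
        target_unvaccinated_episode_share=inc.target_unvaccinated_episode_share,
    )


@dataclass(frozen=True)
class PreparedModel:
    """Cohort plus calibrated models, reusable across replicate runs."""

    config: RunConfig
    population: pd.DataFrame
    incidence: IncidenceModel
    duration: DurationModel

    def run(self, sim_seed: int | None = None) -> EpisodeLedger:
        seed = self.config.seed if sim_seed is None else sim_seed
        ledger = run_paired_simulation(
            self.population, self.incidence, self.duration,
            self.config.scenario, absent=self.config.absenteeism,
            costs=self.config.costs, seed=seed)
        return EpisodeLedger(
            scenario_name=ledger.scenario_name, seed=ledger.seed,
            cohort_size=ledger.cohort_size, episodes=ledger.episodes,
            config_hash=config_hash(self.config))


def prepare(config: RunConfig) -> PreparedModel:
    """Generate the cohort and calibrate the incidence model."""
    population = generate_population(config.population)
    dm = build_duration_model(config)
    model = calibrate_incidence(population, build_incidence_model(config), dm)
    return PreparedModel(config=config, population=population,
                        incidence=model, duration=dm)


def run_scenario(config: RunConfig, sim_seed: int | None = None) -> EpisodeLedger:
    """Convenience wrapper: prepare and run a single paired simulation."""
    return prepare(config).run(sim_seed)
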