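"""Paired daily-cycle microsimulation over one year.

Each person starts "at risk" and can move to "ongoing RTI" once per spell;
the cycle length is one day and the horizon 365 cycles.  Both intervention
arms (generalized probiotic intake vs none) are evaluated on the same
cohort under common random numbers: one uniform per (person, day) decides
onset — the control arm onsets when u < p_control and the probiotic arm
when u < p_probiotic <= p_control — and one uniform per (person, episode,
resource) decides duration, antibiotic course, other prescribed medication
and work absence.  The two arms share the control arm's renewal clock
(at-risk schedule), so probiotic-arm episodes are an exact subset of
control-arm episodes, paired differences carry no renewal drift, and an
identity effect set reproduces the control arm bit for bit.  The
counterfactual bias of sharing the clock is of order hazard x duration
change per episode (~0.03% of episodes at the default parameters), far
below Monte-Carlo noise.

Episodes with onset inside the horizon contribute their full sampled
duration to day counts even when they run past day 365 (bias < 0.5% at
~7-9-day means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import Stream, keyed_uniform
from .economics import CostParams
from .epidemiology import (HORIZON_DAYS, DurationModel, IncidenceModel,
                           duration_quantile, mean_duration_array,
                           relative_rates)
from .errors import CalibrationError, ConfigurationError
from .parameters import AbsenteeismParams
from .scenarios import ScenarioSpec, effect_arrays

LEDGER_COLUMNS = [
    "arm", "person_id", "episode_index", "onset_day", "duration",
    "had_antibiotic", "had_other_medication", "pcp_visits", "missed_days",
]
PERSON_FLAG_COLUMNS = [
    "age", "is_child", "vaccinated", "employed", "active_smoker",
    "passive_smoker", "in_school", "shared_indoor",
]


@dataclass(frozen=True)
class EpisodeLedger:
    """Per-episode records for both arms of one paired run."""

    scenario_name: str
    seed: int
    cohort_size: int
    episodes: pd.DataFrame
    config_hash: str | None = None

    def arm(self, arm: str) -> pd.DataFrame:
        return self.episodes[self.episodes.arm == arm]

    def totals(self) -> pd.DataFrame:
        """Arm totals of the four headline event counts."""
        rows = {}
        for arm in ("probiotic", "control"):
            eps = self.arm(arm)
            rows[arm] = {
                "rti_episodes": float(len(eps)),
                "rti_days": float(eps.duration.sum()),
                "antibiotic_courses": float(eps.had_antibiotic.sum()),
                "missed_work_days": float(eps.missed_days.sum()),
            }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.episodes.to_csv(path, index=False)


def _absence_amount(u: np.ndarray, mean: np.ndarray, sd_over_mean: float) -> np.ndarray:
    """Conditional absence draw: gamma matched to mean and SD, monotone in u."""
    shape = sd_over_mean ** -2
    return stats.gamma.ppf(u, a=shape) * (mean / shape)


def sample_absence(person, effect, absent: AbsenteeismParams, draws) -> float:
    """Missed work days for one episode (two-part model).

    ``draws`` is a pair of uniforms (any-absence, amount).  Employees use
    the employee parameters; children generate caregiver absence; everyone
    else misses no work.  The arm's absence multiplier rescales the
    conditional mean exactly.
    """
    u_any, u_amt = draws
    if person["employed"]:
        if u_any >= absent.prob_any_employee:
            return 0.0
        mean = absent.mean_days_employee * effect.absence_mult_adult
        cv = absent.sd_days_employee / absent.mean_days_employee
    elif person["is_child"]:
        if u_any >= absent.prob_any_child:
            return 0.0
        mean = absent.mean_days_child * effect.absence_mult_child
        cv = absent.sd_days_child / absent.mean_days_child
    else:
        return 0.0
    return float(_absence_amount(np.asarray(u_amt), np.asarray(mean), cv))


def run_paired_simulation(pop: pd.DataFrame, inc: IncidenceModel,
                          dur: DurationModel, spec: ScenarioSpec,
                          absent: AbsenteeismParams = AbsenteeismParams(),
                          costs: CostParams = CostParams(),
                          seed: int = 0,
                          horizon: int = HORIZON_DAYS) -> EpisodeLedger:
    """Simulate both arms day by day and return the episode ledger."""
    if not inc.calibrated or inc.base_daily_hazard is None:
        raise CalibrationError("incidence model must be calibrated before simulation")
    if not 1 <= horizon <= HORIZON_DAYS:
        raise ConfigurationError("horizon must be in 1..365")

    n = len(pop)
    pid = pop.person_id.to_numpy(np.int64)
    eff = effect_arrays(pop, spec, seed, absent)

    annual_rate = inc.base_daily_hazard * HORIZON_DAYS * relative_rates(pop, inc)
    mean_ctrl = mean_duration_array(pop, dur, inc.risk)
    mean_prob = mean_ctrl * eff["duration"]

    employed = pop.employed.to_numpy()
    child = pop.is_child.to_numpy() & ~employed
    abs_mean_ctrl = np.where(employed, absent.mean_days_employee,
                             np.where(child, absent.mean_days_child, 0.0))
    abs_mult = np.where(employed, eff["absence_adult"],
                        np.where(child, eff["absence_child"], 1.0))
    abs_prob_any = np.where(employed, absent.prob_any_employee,
                            np.where(child, absent.prob_any_child, 0.0))
    abs_cv = absent.sd_days_employee / absent.mean_days_employee  # = 3 for both groups

    sick_until = np.zeros(n)
    episode_index = np.zeros(n, dtype=np.int64)
    events: list[dict] = []

    weights = inc.profile.weights
    for day in range(1, horizon + 1):
        u = keyed_uniform(seed, Stream.ONSET, pid, day)
        exp_draw = -np.log1p(-u)  # onset iff exp_draw < hazard
        lam = annual_rate * weights[day - 1]
        idx = np.nonzero((sick_until <= day) & (exp_draw < lam))[0]
        if idx.size == 0:
            continue
        k = episode_index[idx]
        episode_index[idx] += 1

        kept = exp_draw[idx] < lam[idx] * eff["incidence"][idx]

        u_dur = keyed_uniform(seed, Stream.DURATION, pid[idx], k)
        tau_ctrl = duration_quantile(u_dur, mean_ctrl[idx], dur)
        tau_prob = duration_quantile(u_dur, mean_prob[idx], dur)
        sick_until[idx] = day + tau_ctrl

        u_abx = keyed_uniform(seed, Stream.ANTIBIOTIC, pid[idx], k)
        abx_ctrl = u_abx < costs.abx_prescription_prob
        abx_prob = u_abx < costs.abx_prescription_prob * eff["antibiotic"][idx]

        u_om = keyed_uniform(seed, Stream.OTHER_MED, pid[idx], k)
        other_med = u_om < costs.othermed_prob

        u_any = keyed_uniform(seed, Stream.ABSENCE_ANY, pid[idx], k)
        u_amt = keyed_uniform(seed, Stream.ABSENCE_AMOUNT, pid[idx], k)
        any_abs = u_any < abs_prob_any[idx]
        base_amt = _absence_amount(u_amt, abs_mean_ctrl[idx], abs_cv)
        missed_ctrl = np.where(any_abs, base_amt, 0.0)
        missed_prob = missed_ctrl * abs_mult[idx]

        events.append({
            "person_pos": idx, "episode_index": k,
            "onset_day": np.full(idx.size, day, dtype=np.int64),
            "kept": kept, "tau_ctrl": tau_ctrl, "tau_prob": tau_prob,
            "abx_ctrl": abx_ctrl, "abx_prob": abx_prob, "other_med": other_med,
            "missed_ctrl": missed_ctrl, "missed_prob": missed_prob,
        })

    episodes = _assemble_ledger(pop, events)
    return EpisodeLedger(scenario_name=spec.name, seed=seed, cohort_size=n,
                        episodes=episodes)


def _assemble_ledger(pop: pd.DataFrame, events: list[dict]) -> pd.DataFrame:
    if not events:
        empty = pd.DataFrame(columns=LEDGER_COLUMNS + PERSON_FLAG_COLUMNS)
        return empty
    cat = {key: np.concatenate([e[key] for e in events]) for key in events[0]}
    pos = cat["person_pos"]

    def arm_frame(arm: str, mask: np.ndarray, tau, abx, missed) -> pd.DataFrame:
        return pd.DataFrame({
            "arm": arm,
            "person_id": pop.person_id.to_numpy()[pos[mask]],
            "episode_index": cat["episode_index"][mask],
            "onset_day": cat["onset_day"][mask],
            "duration": tau[mask],
            "had_antibiotic": abx[mask],
            "had_other_medication": cat["other_med"][mask],
            "pcp_visits": 1,
            "missed_days": missed[mask],
        })

    all_mask = np.ones(len(pos), dtype=bool)
    ctrl = arm_frame("control", all_mask, cat["tau_ctrl"], cat["abx_ctrl"],
                     cat["missed_ctrl"])
    prob = arm_frame("probiotic", cat["kept"], cat["tau_prob"], cat["abx_prob"],
                     cat["missed_prob"])
    episodes = pd.concat([ctrl, prob], ignore_index=True)
    flags = pop.set_index("person_id")[
        ["age", "is_child", "vaccinated", "employed", "active_smoker",
         "passive_smoker", "in_school", "shared_indoor"]]
    episodes = episodes.join(flags, on="person_id")
    return episodes
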