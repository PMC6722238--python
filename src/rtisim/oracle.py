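"""Closed-form expected values of the headline outcomes.

Independent of the simulation engine: the expectations below follow
directly from the scenario multipliers and the cohort's episode-share
weights.  Writing u for the unvaccinated share of control-arm episodes and
g for the per-group episode-kept factor ((1-uptake) + uptake x incidence
multiplier), the relative reductions are mixtures over the vaccinated /
unvaccinated groups of products of kept factors and per-episode
multipliers, e.g.

    days%     = 100 x (1 - [u g_u d_u + (1-u) g_v d_v])
    episodes% = 100 x (1 - [u g_u + (1-u) g_v])

with d the duration multiplier per group.  The closed forms ignore
second-order effects (at-risk time lost to ongoing episodes, risk-factor /
duration correlations), which shift results by well under one percentage
point at the published parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .economics import CostParams
from .epidemiology import IncidenceModel
from .errors import ConfigurationError
from .parameters import AbsenteeismParams
from .scenarios import ScenarioSpec


@dataclass(frozen=True)
class OracleInputs:
    """Cohort-level weights entering the closed forms.

    Shares are episode-weighted (children carry the child/adult incidence
    ratio).  Defaults correspond to the default cohort structure and
    calibration targets.
    """

    unvaccinated_episode_share: float = 0.554
    control_episodes: float = 24_671.0
    child_episode_share: float = 0.4132       # ages 0-15 (is_child)
    child_cost_age_share: float = 0.3872      # ages 0-14 (antibiotic price band)
    employed_episode_share: float = 0.3404    # employed persons, all ages
    absent: AbsenteeismParams = field(default_factory=AbsenteeismParams)
    costs: CostParams = field(default_factory=CostParams)

    def __post_init__(self) -> None:
        for name in ("unvaccinated_episode_share", "child_episode_share",
                     "child_cost_age_share", "employed_episode_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"oracle.{name} must be in [0, 1]")
        if self.control_episodes <= 0:
            raise ConfigurationError("oracle.control_episodes must be > 0")

    @property
    def employee_missed_day_share(self) -> float:
        """Share of control-arm missed work days accruing to employees."""
        a = self.absent
        emp = self.employed_episode_share * a.prob_any_employee * a.mean_days_employee
        chd = self.child_episode_share * a.prob_any_child * a.mean_days_child
        return emp / (emp + chd) if emp + chd > 0 else 0.0

    @property
    def control_missed_days(self) -> float:
        a = self.absent
        per_episode = (self.employed_episode_share * a.prob_any_employee
                       * a.mean_days_employee
                       + self.child_episode_share * a.prob_any_child
                       * a.mean_days_child)
        return self.control_episodes * per_episode


def oracle_inputs_from_population(pop: pd.DataFrame, model: IncidenceModel,
                                  control_episodes: float | None = None,
                                  absent: AbsenteeismParams = AbsenteeismParams(),
                                  costs: CostParams = CostParams()) -> OracleInputs:
    """Episode-share weights computed from a concrete cohort's covariates.

    Uses only the relative incidence rates (no renewal dynamics), so it
    stays independent of the simulation path it validates.
    """
    from .epidemiology import relative_rates  # local to keep surface minimal

    r = relative_rates(pop, model)
    total = r.sum()
    if control_episodes is None:
        control_episodes = (model.calibration_target_episodes * len(pop)
                            / model.calibration_reference_cohort)
    return OracleInputs(
        unvaccinated_episode_share=float(r[~pop.vaccinated.to_numpy()].sum() / total),
        control_episodes=float(control_episodes),
        child_episode_share=float(r[pop.is_child.to_numpy()].sum() / total),
        child_cost_age_share=float(
            r[(pop.age <= costs.abx_child_age_max).to_numpy()].sum() / total),
        employed_episode_share=float(r[pop.employed.to_numpy()].sum() / total),
        absent=absent,
        costs=costs,
    )


def _group_factors(spec: ScenarioSpec, kind: str) -> tuple[float, float]:
    """Per-episode multipliers (unvaccinated, vaccinated) for one effect kind,
    diluted by uptake."""
    up = spec.uptake_fraction
    if kind == "incidence":
        value, restricted = spec.incidence_rr, spec.restrict_incidence_to_unvaccinated
    elif kind == "duration":
        value, restricted = spec.duration_mult, spec.restrict_duration_to_unvaccinated
    elif kind == "antibiotic":
        value, restricted = spec.antibiotic_rr, spec.restrict_antibiotic_to_unvaccinated
    else:
        raise ConfigurationError(f"unknown effect kind {kind!r}")
    affected = 1.0 - up + up * value
    return affected, (1.0 if restricted else affected)


def expected_reduction_episodes(spec: ScenarioSpec, u_e: float) -> float:
    """Percent reduction in RTI episodes (positive = fewer episodes)."""
    g_u, g_v = _group_factors(spec, "incidence")
    return 100.0 * (1.0 - (u_e * g_u + (1.0 - u_e) * g_v))


def expected_reduction_days(spec: ScenarioSpec, u_e: float) -> float:
    """Percent reduction in total RTI days."""
    g_u, g_v = _group_factors(spec, "incidence")
    d_u, d_v = _group_factors(spec, "duration")
    return 100.0 * (1.0 - (u_e * g_u * d_u + (1.0 - u_e) * g_v * d_v))


def expected_reduction_antibiotics(spec: ScenarioSpec, u_e: float) -> float:
    """Percent reduction in antibiotic courses."""
    g_u, g_v = _group_factors(spec, "incidence")
    a_u, a_v = _group_factors(spec, "antibiotic")
    return 100.0 * (1.0 - (u_e * g_u * a_u + (1.0 - u_e) * g_v * a_v))


def expected_reduction_missed_days(spec: ScenarioSpec, oi: OracleInputs) -> float:
    """Percent reduction in missed work days (employee + caregiver)."""
    up = spec.uptake_fraction
    w_emp = oi.employee_missed_day_share
    g_u, g_v = _group_factors(spec, "incidence")

    def mult(reduction: float, mean: float, restricted: bool) -> tuple[float, float]:
        m = 1.0 - reduction / mean
        affected = 1.0 - up + up * m
        return affected, (1.0 if restricted else affected)

    a_u, a_v = mult(spec.absent_reduction_adult_days, oi.absent.mean_days_employee,
                    spec.restrict_absence_to_unvaccinated)
    c_u, c_v = mult(spec.absent_reduction_child_days, oi.absent.mean_days_child,
                    spec.restrict_absence_to_unvaccinated)
    u_e = oi.unvaccinated_episode_share
    factor = (u_e * g_u * (w_emp * a_u + (1 - w_emp) * c_u)
              + (1 - u_e) * g_v * (w_emp * a_v + (1 - w_emp) * c_v))
    return 100.0 * (1.0 - factor)


def expected_counts(spec: ScenarioSpec, oi: OracleInputs) -> dict:
    """Expected control totals and avoided counts at sample scale."""
    e0 = oi.control_episodes
    d0 = e0 * spec.base_mean_days
    c0 = e0 * oi.costs.abx_prescription_prob
    m0 = oi.control_missed_days
    return {
        "control_episodes": e0,
        "control_days": d0,
        "control_courses": c0,
        "control_missed_days": m0,
        "avoided_episodes": e0 * expected_reduction_episodes(
            spec, oi.unvaccinated_episode_share) / 100.0,
        "avoided_days": d0 * expected_reduction_days(
            spec, oi.unvaccinated_episode_share) / 100.0,
        "avoided_courses": c0 * expected_reduction_antibiotics(
            spec, oi.unvaccinated_episode_share) / 100.0,
        "avoided_missed_days": m0 * expected_reduction_missed_days(spec, oi) / 100.0,
    }


def expected_savings(spec: ScenarioSpec, oi: OracleInputs) -> dict:
    """Expected national cost savings (USD) by perspective."""
    cp = oi.costs
    counts = expected_counts(spec, oi)
    payer_per_episode = cp.pcp_payer + cp.othermed_prob * cp.othermed_payer
    copay_per_episode = cp.pcp_copay + cp.othermed_prob * cp.othermed_copay
    course_cost = (oi.child_cost_age_share * cp.abx_cost_child
                   + (1.0 - oi.child_cost_age_share) * cp.abx_cost_adult)
    f = cp.projection_factor
    payer = (counts["avoided_episodes"] * payer_per_episode
             + counts["avoided_courses"] * course_cost) * f
    copay = counts["avoided_episodes"] * copay_per_episode * f
    productivity = counts["avoided_missed_days"] * cp.productivity_per_day * f
    return {
        "payer": payer,
        "copay": copay,
        "productivity": productivity,
        "societal": payer + copay + productivity,
    }


def oracle_report(spec: ScenarioSpec, oi: OracleInputs) -> dict:
    """All closed-form expectations for one scenario, JSON-serializable."""
    u_e = oi.unvaccinated_episode_share
    return {
        "scenario": spec.name,
        "pct_reduction": {
            "rti_episodes": expected_reduction_episodes(spec, u_e),
            "rti_days": expected_reduction_days(spec, u_e),
            "antibiotic_courses": expected_reduction_antibiotics(spec, u_e),
            "missed_work_days": expected_reduction_missed_days(spec, oi),
        },
        "counts": expected_counts(spec, oi),
        "national_savings_usd": expected_savings(spec, oi),
    }
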