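"""Outcome tables, subgroup attribution, sensitivity sweeps, convergence.

The outcome table mirrors the published event-outcome layout: probiotic
total, no-probiotic total, absolute difference and percent difference for
RTI episodes, RTI days, antibiotic courses and missed work days.  Subgroup
attribution decomposes paired per-person differences (avoided RTI days,
societal cost savings) into subgroup shares.  The one-way sensitivity
sweep re-runs the paired simulation with one parameter at its lower/upper
bound under the base seed, so parameter effects are not confounded with
Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .app import prepare
from .config import RunConfig, replace_in_config
from .economics import aggregate_costs, episode_costs
from .engine import EpisodeLedger
from .errors import ConfigurationError

OUTCOME_ROWS = ["rti_episodes", "rti_days", "antibiotic_courses", "missed_work_days"]

SUBGROUP_FLAGS = {
    "children": "is_child",
    "active_smokers": "active_smoker",
    "passive_smokers": "passive_smoker",
    "shared_indoor": "shared_indoor",
    "unvaccinated": "unvaccinated",
}


def outcome_table(ledger: EpisodeLedger) -> pd.DataFrame:
    """Four-row event-outcome table with arm totals and differences."""
    totals = ledger.totals()
    if totals["control"].eq(0).all():
        raise ConfigurationError("control arm is empty; cannot build outcome table")
    table = pd.DataFrame(index=OUTCOME_ROWS)
    table["probiotic"] = totals["probiotic"]
    table["control"] = totals["control"]
    table["difference"] = table.probiotic - table.control
    table["pct_difference"] = 100.0 * table.difference / table.control
    return table


@dataclass(frozen=True)
class SensitivityRange:
    """One-way bound pair for a dotted config path."""

    path: str
    base: float
    lower: float
    upper: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.lower <= self.base <= self.upper:
            raise ConfigurationError(
                f"sensitivity range for {self.path} must satisfy lower <= base <= upper")


def default_sensitivity_ranges(scenario: str) -> list[SensitivityRange]:
    """Published lower/upper bounds of variation for the model parameters."""
    common = [
        SensitivityRange("costs.othermed_prob", 0.5662, 0.50, 0.60,
                         "probability of non-antibiotic medication"),
        SensitivityRange("costs.abx_cost_child", 2.95, 1.48, 4.43,
                         "antibiotic cost, ages 0-14 (+/-50%)"),
        SensitivityRange("costs.abx_cost_adult", 3.54, 1.77, 5.31,
                         "antibiotic cost, ages 15+ (+/-50%)"),
        # PCP total 99.16 (69.64..124.44) varied through the payer share,
        # keeping the 25 USD copayment fixed.
        SensitivityRange("costs.pcp_payer", 74.16, 44.64, 99.44,
                         "PCP fee, payer share"),
        SensitivityRange("scenario.antibiotic_rr", 0.65, 0.45, 0.94,
                         "reduced antibiotic prescription (95% CI)"),
        SensitivityRange("scenario.absent_reduction_adult_days", 0.87, 0.153, 1.581,
                         "change in productivity loss, adults (95% CI)"),
        SensitivityRange("scenario.absent_reduction_child_days", 0.26, 0.045, 0.465,
                         "change in productivity loss, children (95% CI)"),
    ]
    if scenario == "yhec":
        return [SensitivityRange("scenario.duration_reduction_days", 0.77, 0.04, 1.5,
                                 "change in duration per episode (95% CI)")] + common
    if scenario == "cochrane":
        return [
            SensitivityRange("scenario.duration_reduction_days", 1.89, 1.75, 2.03,
                             "change in duration per episode (95% CI)"),
            SensitivityRange("scenario.incidence_rr", 0.70, 0.50, 0.84,
                             "reduced incidence (95% CI)"),
        ] + common
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def _headline_outcomes(ledger: EpisodeLedger, config: RunConfig) -> dict:
    table = outcome_table(ledger)
    summary = aggregate_costs(ledger, config.costs)
    savings = summary.national(summary.savings)
    return {
        "avoided_rti_days": -float(table.loc["rti_days", "difference"]),
        "pct_rti_days": -float(table.loc["rti_days", "pct_difference"]),
        "societal_savings_national": savings.societal,
    }


def one_way_sensitivity(config: RunConfig,
                        ranges: list[SensitivityRange] | None = None) -> pd.DataFrame:
    """Re-run the paired simulation at each parameter bound (base seed).

    Returns one row per (parameter, bound) with avoided RTI days (sample
    scale) and saved total societal cost (national scale).
    """
    if ranges is None:
        ranges = default_sensitivity_ranges(config.scenario.name)
    rows = []

    def evaluate(cfg: RunConfig, parameter: str, bound: str, value: float) -> None:
        out = _headline_outcomes(prepare(cfg).run(), cfg)
        rows.append({"parameter": parameter, "bound": bound, "value": value, **out})

    evaluate(config, "base_case", "base", float("nan"))
    for rng in ranges:
        for bound, value in (("lower", rng.lower), ("upper", rng.upper)):
            evaluate(replace_in_config(config, rng.path, value), rng.path, bound, value)
    return pd.DataFrame(rows)


def _paired_person_diffs(ledger: EpisodeLedger, costs,
                         flags: list[str]) -> pd.DataFrame:
    """Per-person avoided RTI days and societal savings with subgroup flags."""
    eps = ledger.episodes.copy()
    c = episode_costs(eps, costs)
    eps["societal_cost"] = c.payer + c.copay + c.productivity
    sign = np.where(eps.arm == "control", 1.0, -1.0)
    eps["avoided_days"] = eps.duration * sign
    eps["saved_cost"] = eps.societal_cost * sign
    if "unvaccinated" in flags and "unvaccinated" not in eps.columns:
        eps["unvaccinated"] = ~eps.vaccinated
    missing = [f for f in flags if f not in eps.columns]
    if missing:
        raise ConfigurationError(f"unknown subgroup flag {missing[0]!r}")
    return eps.groupby("person_id")[["avoided_days", "saved_cost"] + flags].agg(
        {"avoided_days": "sum", "saved_cost": "sum", **{f: "first" for f in flags}})


def subgroup_attribution(ledger: EpisodeLedger, costs,
                         subgroups: dict[str, str] | None = None,
                         population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subgroup shares of population, avoided RTI days and cost savings.

    ``subgroups`` maps report labels to boolean per-person flags (ledger
    columns).  Shares are percentages of the cohort-wide paired totals;
    subgroups may overlap, so shares only partition 100% when the flags do.
    """
    if subgroups is None:
        subgroups = SUBGROUP_FLAGS
    diffs = _paired_person_diffs(ledger, costs, list(dict.fromkeys(subgroups.values())))
    total_days = diffs.avoided_days.sum()
    total_cost = diffs.saved_cost.sum()
    if total_days == 0 or total_cost == 0:
        raise ConfigurationError(
            "no paired differences; subgroup attribution undefined")
    if population is not None:
        pop_flags = population.assign(unvaccinated=~population.vaccinated)
        pop_n = len(population)
    else:
        pop_flags, pop_n = None, None
    rows = []
    for label, flag in subgroups.items():
        mask = diffs[flag].astype(bool)
        if pop_flags is not None:
            pop_share = 100.0 * pop_flags[flag].sum() / pop_n
        else:
            pop_share = 100.0 * mask.sum() / len(diffs)
        rows.append({
            "subgroup": label,
            "pct_of_population": float(pop_share),
            "pct_of_avoided_rti_days":
                100.0 * float(diffs.avoided_days[mask].sum() / total_days),
            "pct_of_societal_savings":
                100.0 * float(diffs.saved_cost[mask].sum() / total_cost),
        })
    return pd.DataFrame(rows)


def convergence_test(config: RunConfig, sample_rates: list[float],
                     replicates: int = 3, cv_threshold: float = 0.02) -> pd.DataFrame:
    """Outcome stability across cohort sizes and replicate seeds.

    For each sample rate, regenerates and re-runs the full pipeline
    ``replicates`` times (distinct seeds) and reports mean and coefficient
    of variation of each headline outcome; the run at the largest rate is
    flagged converged when all CVs fall below ``cv_threshold``.
    """
    import dataclasses

    if len(sample_rates) < 2:
        raise ConfigurationError("convergence test needs at least two sample rates")
    if replicates < 3:
        raise ConfigurationError("convergence test needs at least three replicates")
    rows = []
    for rate in sorted(sample_rates):
        outcomes = []
        for rep in range(replicates):
            seed = config.seed + 10_000 * rep
            cfg = dataclasses.replace(
                config,
                population=dataclasses.replace(config.population, sample_rate=rate,
                                               seed=seed),
                seed=seed)
            outcomes.append(_headline_outcomes(prepare(cfg).run(), cfg))
        frame = pd.DataFrame(outcomes)
        for outcome in frame.columns:
            mean = float(frame[outcome].mean())
            cv = float(frame[outcome].std(ddof=1) / abs(mean)) if mean else float("inf")
            rows.append({"sample_rate": rate, "n": int(round(
                config.population.reference_total * rate)),
                "outcome": outcome, "mean": mean, "cv": cv,
                "replicates": replicates})
    report = pd.DataFrame(rows)
    largest = report[report.sample_rate == max(sample_rates)]
    report.attrs["converged"] = bool((largest.cv < cv_threshold).all())
    return report
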