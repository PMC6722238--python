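"""Costing of episode ledgers from payer, copayment and societal perspectives.

Every RTI episode incurs exactly one primary-care (PCP) consultation
(payer fee 74.16 USD, copayment 25 USD), an antibiotic course with
probability 0.29 (age-specific payer cost: 2.95 USD for ages 0-14, 3.54
USD for 15+, no copayment) and non-antibiotic prescription medication with
probability 0.5662 (payer 26.59 USD, copayment 11 USD).  Productivity
losses are valued with the human-capital approach at 217.92 USD per missed
work day (caregiver days for sick children are valued identically).

The societal total is payer + copayment + productivity.  Sample-scale
totals project to the national scale by an exact multiplicative factor
(1,000 for the default 1/1,000 sample).  Inpatient care, over-the-counter
medication and the probiotic product itself are outside the costing scope.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class CostParams:
    """Unit costs (USD) and resource-use probabilities."""

    pcp_payer: float = 74.16
    pcp_copay: float = 25.0
    abx_prescription_prob: float = 0.29
    abx_cost_child: float = 2.95
    abx_cost_adult: float = 3.54
    abx_child_age_max: int = 14
    abx_copay: float = 0.0
    othermed_prob: float = 0.5662
    othermed_payer: float = 26.59
    othermed_copay: float = 11.0
    productivity_per_day: float = 217.92
    projection_factor: float = 1000.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("abx_prescription_prob", "othermed_prob"):
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"costs.{f.name} must be in [0, 1], got {v}")
            elif f.name == "abx_child_age_max":
                if v < 0:
                    raise ConfigurationError("costs.abx_child_age_max must be >= 0")
            elif v < 0:
                raise ConfigurationError(f"costs.{f.name} must be >= 0, got {v}")

    @property
    def pcp_total(self) -> float:
        return self.pcp_payer + self.pcp_copay


@dataclass(frozen=True)
class CostBreakdown:
    """Payer / copayment / productivity cost of a single episode (USD)."""

    payer: float
    copay: float
    productivity: float

    @property
    def societal(self) -> float:
        return self.payer + self.copay + self.productivity


@dataclass(frozen=True)
class ArmCosts:
    payer: float
    copay: float
    productivity: float

    @property
    def societal(self) -> float:
        return self.payer + self.copay + self.productivity

    def as_dict(self) -> dict:
        return {"payer": self.payer, "copay": self.copay,
                "productivity": self.productivity, "societal": self.societal}


@dataclass(frozen=True)
class CostSummary:
    """Arm totals and savings at sample scale plus the national projection."""

    control: ArmCosts
    probiotic: ArmCosts
    projection_factor: float

    @property
    def savings(self) -> ArmCosts:
        """Control minus probiotic: positive numbers are savings."""
        return ArmCosts(
            payer=self.control.payer - self.probiotic.payer,
            copay=self.control.copay - self.probiotic.copay,
            productivity=self.control.productivity - self.probiotic.productivity,
        )

    def national(self, costs: ArmCosts) -> ArmCosts:
        f = self.projection_factor
        return ArmCosts(costs.payer * f, costs.copay * f, costs.productivity * f)

    def to_dict(self) -> dict:
        savings = self.savings
        return {
            "sample": {
                "control": self.control.as_dict(),
                "probiotic": self.probiotic.as_dict(),
                "savings": savings.as_dict(),
            },
            "national": {
                "control": self.national(self.control).as_dict(),
                "probiotic": self.national(self.probiotic).as_dict(),
                "savings": self.national(savings).as_dict(),
            },
            "projection_factor": self.projection_factor,
        }


def cost_episode(rec, cp: CostParams, person_age: int) -> CostBreakdown:
    """Cost one episode record (mapping with the ledger's episode fields)."""
    abx_cost = cp.abx_cost_child if person_age <= cp.abx_child_age_max else cp.abx_cost_adult
    payer = cp.pcp_payer
    copay = cp.pcp_copay
    if rec["had_other_medication"]:
        payer += cp.othermed_payer
        copay += cp.othermed_copay
    if rec["had_antibiotic"]:
        payer += abx_cost
        copay += cp.abx_copay
    return CostBreakdown(payer=payer, copay=copay,
                         productivity=rec["missed_days"] * cp.productivity_per_day)


def episode_costs(episodes: pd.DataFrame, cp: CostParams) -> pd.DataFrame:
    """Vectorized per-episode cost columns (payer, copay, productivity)."""
    abx_unit = np.where(episodes.age.to_numpy() <= cp.abx_child_age_max,
                        cp.abx_cost_child, cp.abx_cost_adult)
    abx = episodes.had_antibiotic.to_numpy()
    om = episodes.had_other_medication.to_numpy()
    out = pd.DataFrame(index=episodes.index)
    out["payer"] = cp.pcp_payer + om * cp.othermed_payer + abx * abx_unit
    out["copay"] = cp.pcp_copay + om * cp.othermed_copay + abx * cp.abx_copay
    out["productivity"] = episodes.missed_days.to_numpy() * cp.productivity_per_day
    return out


def aggregate_costs(ledger, cp: CostParams) -> CostSummary:
    """Arm-level cost totals and paired savings for a simulation ledger."""
    totals = {}
    for arm in ("control", "probiotic"):
        eps = ledger.episodes[ledger.episodes.arm == arm]
        if len(eps) == 0:
            totals[arm] = ArmCosts(0.0, 0.0, 0.0)
            continue
        c = episode_costs(eps, cp)
        totals[arm] = ArmCosts(payer=float(c.payer.sum()),
                               copay=float(c.copay.sum()),
                               productivity=float(c.productivity.sum()))
    return CostSummary(control=totals["control"], probiotic=totals["probiotic"],
                       projection_factor=cp.projection_factor)
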