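"""Shared behavioural parameter blocks used by several modules.

Work-absence behaviour is a two-part model: a probability that an episode
causes any absence at all, and a heavy-tailed conditional amount with the
printed mean (SD).  Children's "missed days" represent caregiver work loss
and are valued at the same daily cost as employee absence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class AbsenteeismParams:
    """Two-part work-absence model per RTI episode.

    Employees: 42% of episodes cause absence, conditional mean 1.7 days
    (SD 5.1).  Sick children: 18% and 0.5 days (SD 1.5).
    """

    prob_any_employee: float = 0.42
    mean_days_employee: float = 1.7
    sd_days_employee: float = 5.1
    prob_any_child: float = 0.18
    mean_days_child: float = 0.5
    sd_days_child: float = 1.5

    def __post_init__(self) -> None:
        for name in ("prob_any_employee", "prob_any_child"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"absenteeism.{name} must be in [0, 1], got {p}")
        for name in ("mean_days_employee", "sd_days_employee",
                     "mean_days_child", "sd_days_child"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"absenteeism.{name} must be >= 0, got {v}")
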