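"""Paired microsimulation: pairing exactness, conservation, reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import rtisim as rs
from rtisim.engine import sample_absence
from rtisim.parameters import AbsenteeismParams
from rtisim.scenarios import EffectSet

from conftest import scaled_config


def per_person_counts(ledger, arm):
    return ledger.arm(arm).groupby("person_id").size()


def test_null_intervention_reproduces_the_control_arm_exactly():
    """With zero uptake the two arms are identical records."""
    cfg = scaled_config("cochrane", 1e-5, scenario__uptake_fraction=0.0)
    ledger = rs.prepare(cfg).run(5)
    ctrl = ledger.arm("control").drop(columns="arm").reset_index(drop=True)
    prob = ledger.arm("probiotic").drop(columns="arm").reset_index(drop=True)
    pd.testing.assert_frame_equal(ctrl, prob)
    table = rs.outcome_table(ledger)
    assert (table.difference == 0).all()
    assert (table.pct_difference == 0).all()


def test_yhec_episode_sets_are_identical_across_arms(small_yhec_ledger):
    """No incidence effect + shared draws: same persons, same onset days."""
    ctrl = small_yhec_ledger.arm("control")
    prob = small_yhec_ledger.arm("probiotic")
    assert len(ctrl) == len(prob)
    key = ["person_id", "episode_index", "onset_day"]
    pd.testing.assert_frame_equal(ctrl[key].reset_index(drop=True),
                                  prob[key].reset_index(drop=True))


def test_paired_durations_and_antibiotics_are_monotone(small_yhec_ledger):
    """Per shared episode: probiotic duration <= control duration and
    probiotic antibiotic courses are a subset of control courses."""
    key = ["person_id", "episode_index"]
    merged = small_yhec_ledger.arm("control").merge(
        small_yhec_ledger.arm("probiotic"), on=key, suffixes=("_c", "_p"))
    assert (merged.duration_p <= merged.duration_c + 1e-12).all()
    assert not (merged.had_antibiotic_p & ~merged.had_antibiotic_c).any()
    assert (merged.missed_days_p <= merged.missed_days_c + 1e-12).all()


def test_cochrane_episode_counts_monotone_per_person(small_cochrane_ledger):
    ctrl = per_person_counts(small_cochrane_ledger, "control")
    prob = per_person_counts(small_cochrane_ledger, "probiotic")
    aligned = pd.concat([ctrl, prob], axis=1, keys=["c", "p"]).fillna(0)
    assert (aligned.p <= aligned.c).all()


def test_cochrane_vaccinated_records_identical_except_absence(small_cochrane_ledger):
    """Vaccinated persons carry no incidence/duration/antibiotic effect; only
    the (unrestricted) absence multiplier touches their records."""
    eps = small_cochrane_ledger.episodes
    vacc = eps[eps.vaccinated]
    ctrl = vacc[vacc.arm == "control"].set_index(["person_id", "episode_index"])
    prob = vacc[vacc.arm == "probiotic"].set_index(["person_id", "episode_index"])
    assert len(ctrl) == len(prob)
    same = ["onset_day", "duration", "had_antibiotic", "had_other_medication"]
    pd.testing.assert_frame_equal(ctrl[same], prob[same])
    spec = rs.default_scenarios()["cochrane"]
    adult_mult = spec.absence_mult_adult(AbsenteeismParams())
    employed_absent = ctrl.employed & (ctrl.missed_days > 0)
    ratio = prob.missed_days[employed_absent] / ctrl.missed_days[employed_absent]
    assert np.allclose(ratio, adult_mult)


def test_identical_seed_and_config_reproduce_the_ledger(small_yhec):
    a = small_yhec.run(123)
    b = small_yhec.run(123)
    pd.testing.assert_frame_equal(a.episodes, b.episodes)
    c = small_yhec.run(124)
    assert not a.episodes.equals(c.episodes)


def test_totals_are_exact_ledger_sums(small_cochrane_ledger):
    totals = small_cochrane_ledger.totals()
    for arm in ("probiotic", "control"):
        eps = small_cochrane_ledger.arm(arm)
        assert totals.loc["rti_days", arm] == eps.duration.sum()
        assert totals.loc["rti_episodes", arm] == len(eps)
        assert totals.loc["antibiotic_courses", arm] == eps.had_antibiotic.sum()
        assert totals.loc["missed_work_days", arm] == eps.missed_days.sum()


def test_episode_record_invariants(small_cochrane_ledger):
    eps = small_cochrane_ledger.episodes
    assert (eps.pcp_visits == 1).all()
    assert eps.onset_day.between(1, 365).all()
    assert (eps.duration >= 0.5).all()
    non_workers = ~eps.employed & ~eps.is_child
    assert (eps.loc[non_workers, "missed_days"] == 0).all()


def test_episode_spacing_respects_recovery(small_cochrane_ledger):
    """Consecutive control-arm episodes of one person never overlap: the next
    onset falls after the previous onset plus its duration."""
    ctrl = small_cochrane_ledger.arm("control").sort_values(
        ["person_id", "onset_day"])
    grouped = ctrl.groupby("person_id")
    next_onset = grouped.onset_day.shift(-1)
    gap_ok = next_onset.isna() | (next_onset >= ctrl.onset_day + ctrl.duration)
    assert gap_ok.all()


# --------------------------------------------------------------------------
# absence sampling

EMPLOYEE = {"employed": True, "is_child": False}
CHILD = {"employed": False, "is_child": True}
RETIRED = {"employed": False, "is_child": False}


def test_non_working_non_child_misses_no_work():
    assert sample_absence(RETIRED, EffectSet(), AbsenteeismParams(),
                          (0.0, 0.5)) == 0.0


def test_two_part_absence_model_mean_for_employees():
    """Unconditional mean missed days per employee episode is 0.42 x 1.7."""
    from rtisim.engine import _absence_amount
    absent = AbsenteeismParams()
    rng = np.random.default_rng(0)
    u_any, u_amt = rng.random(100_000), rng.random(100_000)
    amounts = _absence_amount(u_amt, np.full(100_000, 1.7), 5.1 / 1.7)
    days = np.where(u_any < 0.42, amounts, 0.0)
    assert days.mean() == pytest.approx(0.42 * 1.7, rel=0.02)


def test_probiotic_absence_multiplier_rescales_the_conditional_mean():
    """Probiotic-arm conditional mean is 1.7 - 0.87 days, exactly via scaling."""
    from rtisim.engine import _absence_amount
    rng = np.random.default_rng(1)
    u = rng.random(100_000)
    mult = 1 - 0.87 / 1.7
    base = _absence_amount(u, np.full(100_000, 1.7), 3.0)
    scaled = _absence_amount(u, np.full(100_000, 1.7 * mult), 3.0)
    assert np.allclose(scaled, base * mult)
    assert scaled.mean() == pytest.approx(1.7 - 0.87, rel=0.02)
    # scalar API agrees with the vectorized path
    eff = EffectSet(absence_mult_adult=mult)
    one = sample_absence(EMPLOYEE, eff, AbsenteeismParams(), (0.0, u[0]))
    assert one == pytest.approx(scaled[0])


def test_child_absence_uses_caregiver_parameters():
    val = sample_absence(CHILD, EffectSet(), AbsenteeismParams(), (0.17, 0.9))
    assert val > 0
    assert sample_absence(CHILD, EffectSet(), AbsenteeismParams(), (0.19, 0.9)) == 0.0
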