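"""IV sequences, switch delay, therapy transitions, congruence, cultures, CIs."""

import numpy as np
import pandas as pd
import pytest

from amskit.config import ATC, CultureConfig, cap_guideline
from amskit.linkage import link_therapy_episodes
from amskit.stewardship import (aggregate_with_ci, classify_congruence,
                                classify_initial_transition, compute_switch_delay,
                                congruence_table, extract_iv_sequences,
                                initial_regimen, link_cultures, transition_mix)
from amskit.synthetic import cap_fixture_episodes

from conftest import T0, D, H, make_bundle, rx_row


def episodes_from(rows):
    rx = pd.DataFrame(rows)
    return link_therapy_episodes(rx, pd.DataFrame()), rx


# ---------------------------------------------------------------------------
# IV sequences
# ---------------------------------------------------------------------------

def test_iv_iv_oral_episode_is_one_converted_sequence():
    eps, rx = episodes_from([
        rx_row("A", route="IV", start=T0, end=T0 + 2 * D),
        rx_row("B", route="IV", start=T0 + 2 * D + 6 * H, end=T0 + 4 * D),
        rx_row("C", route="oral", start=T0 + 4 * D + 6 * H, end=T0 + 6 * D)])
    seqs = extract_iv_sequences(eps[0], rx)
    assert len(seqs) == 1
    assert seqs[0].outcome == "converted_to_oral"
    assert seqs[0].prescription_ids == ["A", "B"]
    assert seqs[0].conversion_time == T0 + 4 * D + 6 * H


def test_all_oral_episode_yields_no_sequences():
    eps, rx = episodes_from([rx_row("A", route="oral")])
    assert extract_iv_sequences(eps[0], rx) == []


def test_iv_oral_iv_episode_yields_two_sequences():
    eps, rx = episodes_from([
        rx_row("A", route="IV", start=T0, end=T0 + 2 * D),
        rx_row("B", route="oral", start=T0 + 2 * D + 6 * H, end=T0 + 3 * D),
        rx_row("C", route="IV", start=T0 + 3 * D + 6 * H, end=T0 + 5 * D)])
    seqs = extract_iv_sequences(eps[0], rx)
    assert [s.outcome for s in seqs] == ["converted_to_oral", "continued_to_end"]


def test_sequence_outcomes_partition_all_sequences(synth):
    bundle = synth["bundle"]
    total = 0
    for ep in synth["episodes"]:
        seqs = extract_iv_sequences(ep, bundle.prescriptions)
        assert all(s.outcome in ("converted_to_oral", "continued_to_end")
                   for s in seqs)
        total += len(seqs)
    assert total > 0


# ---------------------------------------------------------------------------
# switch delay
# ---------------------------------------------------------------------------

def _seq(outcome="converted_to_oral", conv=T0 + 5 * D, end=T0 + 5 * D):
    from amskit.stewardship import IVSequence
    return IVSequence("S0", "E0", ["A"], T0, end, outcome,
                      conversion_time=conv if outcome == "converted_to_oral" else None)


def test_delay_zero_at_boundary_and_simple_arithmetic():
    assert compute_switch_delay(_seq(), T0 + 5 * D) == 0.0
    assert compute_switch_delay(_seq(), T0 + 5 * D - 86.4 * H) == pytest.approx(3.6)


def test_delay_none_when_criteria_met_after_event_or_never():
    assert compute_switch_delay(_seq(), T0 + 6 * D) is None
    assert compute_switch_delay(_seq(), None) is None


def test_delay_for_never_switched_uses_sequence_end():
    s = _seq(outcome="continued_to_end", end=T0 + 4 * D)
    assert compute_switch_delay(s, T0 + 2 * D) == 2.0


# ---------------------------------------------------------------------------
# changes of therapy
# ---------------------------------------------------------------------------

MERO, TAZ = ATC["meropenem"], ATC["piperacillin/tazobactam"]


def test_stopped_after_three_days():
    eps, rx = episodes_from([rx_row("A", drug=MERO, start=T0, end=T0 + 3 * D)])
    t = classify_initial_transition(eps[0], MERO, rx)
    assert (t.outcome, t.successor_drug) == ("stopped", None)
    assert t.duration_before_change == pytest.approx(3.0)


def test_switched_to_successor():
    eps, rx = episodes_from([
        rx_row("A", drug=MERO, start=T0, end=T0 + 1.1 * 24 * H),
        rx_row("B", drug=TAZ, start=T0 + 1.1 * 24 * H + 2 * H, end=T0 + 4 * D)])
    t = classify_initial_transition(eps[0], MERO, rx)
    assert (t.outcome, t.successor_drug) == ("switched", TAZ)
    assert t.duration_before_change == pytest.approx(1.1, abs=1e-6)


def test_represcription_of_same_drug_is_continued():
    eps, rx = episodes_from([
        rx_row("A", drug=MERO, start=T0, end=T0 + 2 * D),
        rx_row("B", drug=MERO, start=T0 + 2 * D + 6 * H, end=T0 + 4 * D)])
    t = classify_initial_transition(eps[0], MERO, rx)
    assert t.outcome == "continued"


def test_focal_drug_must_be_in_initial_regimen():
    eps, rx = episodes_from([rx_row("A", drug=MERO)])
    with pytest.raises(ValueError, match="not part of the initial regimen"):
        classify_initial_transition(eps[0], TAZ, rx)


def test_transition_mix_proportions_sum_to_one():
    eps, rx = episodes_from(
        [rx_row("A", drug=MERO, patient="P1", start=T0, end=T0 + 3 * D)]
        + [rx_row("B", drug=MERO, patient="P2", start=T0, end=T0 + D),
           rx_row("C", drug=TAZ, patient="P2", start=T0 + D + 2 * H,
                  end=T0 + 3 * D)])
    mix = transition_mix(eps, MERO, rx)
    assert mix["proportion"].sum() == pytest.approx(1.0)
    assert set(mix["outcome"]) == {"stopped", "switched"}


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------

GUIDE = cap_guideline()
AMOX, CLAR = ATC["amoxicillin"], ATC["clarithromycin"]
COAMOX, DOXY = ATC["co-amoxiclav"], ATC["doxycycline"]


@pytest.mark.parametrize("regimen, severity, expected", [
    ({AMOX}, 0, "recommended"),
    ({DOXY}, 1, "allergy_alternative"),
    ({COAMOX, CLAR}, 0, "higher_severity_regimen"),
    ({AMOX, CLAR}, 0, "higher_severity_regimen"),
    ({AMOX}, 3, "lower_severity_regimen"),
    ({AMOX, CLAR}, 2, "recommended"),
    ({ATC["moxifloxacin"]}, 3, "allergy_alternative"),
    ({ATC["ceftriaxone"]}, 0, "other"),
    (set(), 0, "other"),
])
def test_congruence_categories(regimen, severity, expected):
    assert classify_congruence("E", regimen, severity, GUIDE).category == expected


def test_congruence_categories_are_mutually_exclusive_and_exhaustive():
    fixture = cap_fixture_episodes()
    cats = {"recommended", "allergy_alternative", "higher_severity_regimen",
            "lower_severity_regimen", "other"}
    for row in fixture.drop_duplicates(["drug_codes", "severity"]).itertuples():
        codes = (frozenset() if row.drug_codes == "OTHER"
                 else frozenset(row.drug_codes.split(";")))
        res = classify_congruence(row.episode_id, codes, row.severity, GUIDE)
        assert res.category in cats


def test_initial_regimen_is_combination_group_at_start():
    eps, rx = episodes_from([
        rx_row("A", drug=COAMOX, start=T0, end=T0 + 3 * D),
        rx_row("B", drug=CLAR, start=T0 + 2 * H, end=T0 + 3 * D),
        rx_row("C", drug=AMOX, start=T0 + 3 * D + 6 * H, end=T0 + 5 * D)])
    assert initial_regimen(eps[0], rx) == frozenset({COAMOX, CLAR})


def test_congruence_table_single_episode_is_100_percent():
    df = pd.DataFrame([{"regimen_label": "Amoxicillin", "severity": 0}])
    table = congruence_table(df)
    assert table.loc["Amoxicillin", "n_0"] == 1
    assert table.loc["Amoxicillin", "pct_0"] == 100.0
    assert table.loc["Total", "n_0"] == 1


def test_congruence_table_matches_bruteforce_crosstab():
    fixture = cap_fixture_episodes()
    table = congruence_table(fixture)
    for label, sub in fixture.groupby("regimen_label"):
        for sev in (0, 1):
            assert table.loc[label, f"n_{sev}"] == (sub["severity"] == sev).sum()
    assert table.loc["Total", "n_0"] == (fixture["severity"] == 0).sum()


def test_congruence_table_collapses_rare_rows():
    df = pd.DataFrame([{"regimen_label": "X", "severity": 0}] * 10
                      + [{"regimen_label": "rare", "severity": 0}])
    table = congruence_table(df, min_count=2)
    assert "rare" not in table.index
    assert table.loc["Other", "n_0"] == 1


# ---------------------------------------------------------------------------
# cultures
# ---------------------------------------------------------------------------

def specimen(sid, group, time, patient="P1"):
    return {"specimen_id": sid, "patient_id": patient,
            "collection_time": time, "specimen_group": group}


def test_blood_culture_day_before_links_in_both_scopes():
    eps, rx = episodes_from([rx_row("A", start=T0, end=T0 + 2 * D)])
    sp = make_bundle(specimens=[specimen("S1", "blood", T0 - 24 * H)]).specimens
    for scope in ("all_qualifying", "blood_only"):
        links = link_cultures(eps, rx, sp, scope=scope)
        assert links["linked"].all(), scope


def test_urine_specimen_does_not_satisfy_blood_only_scope():
    eps, rx = episodes_from([rx_row("A")])
    sp = make_bundle(specimens=[specimen("S1", "urine", T0 - 24 * H)]).specimens
    assert not link_cultures(eps, rx, sp, scope="blood_only")["linked"].any()
    # urine is also outside the default qualifying set
    assert not link_cultures(eps, rx, sp, scope="all_qualifying")["linked"].any()


def test_widening_window_never_unlinks():
    eps, rx = episodes_from([rx_row("A")])
    sp = make_bundle(specimens=[specimen("S1", "blood", T0 - 100 * H)]).specimens
    linked = []
    for hours in (24, 72, 120, 240):
        cfg = CultureConfig(window_hours_before=hours)
        linked.append(bool(link_cultures(eps, rx, sp, cfg)["linked"].any()))
    assert linked == sorted(linked)


# ---------------------------------------------------------------------------
# grouped estimates
# ---------------------------------------------------------------------------

def test_proportion_boundary_and_constant_mean():
    zeros = pd.DataFrame({"flag": [0] * 10, "g": ["a"] * 10})
    out = aggregate_with_ci(zeros, "flag", ["g"], kind="proportion")
    assert out.loc[0, "estimate"] == 0.0
    assert out.loc[0, "ci_low"] == 0.0
    const = pd.DataFrame({"v": [4.2] * 8, "g": ["a"] * 8})
    out = aggregate_with_ci(const, "v", ["g"], kind="mean")
    assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == 4.2


def test_groups_ranked_by_estimate_within_first_key():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "flag": rng.integers(0, 2, 300),
        "spec": rng.choice(["med", "surg"], 300),
        "team": rng.choice(list("ABC"), 300)})
    out = aggregate_with_ci(df, "flag", ["spec", "team"], kind="proportion")
    for _, sub in out.groupby("spec"):
        assert sub["estimate"].is_monotonic_increasing
    assert ((out["ci_low"] <= out["estimate"])
            & (out["estimate"] <= out["ci_high"])).all()
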