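"""Hourly therapy table, ABCD switch criteria and URB-65 scoring."""

import numpy as np
import pandas as pd
import pytest

from amskit.config import CriteriaConfig
from amskit.linkage import link_therapy_episodes
from amskit.therapy_table import (build_therapy_table, compute_urb65,
                                  earliest_criteria_time,
                                  evaluate_switch_criteria, evaluate_table)

from conftest import T0, D, H, admin_rows, make_bundle, rx_row


def obs(patient, concept, time, value):
    units = {"temperature": "°C", "heart_rate": "bpm",
             "respiratory_rate": "breaths/min", "systolic_bp": "mmHg",
             "wcc": "10^9/L", "crp": "mg/L", "urea": "mmol/L"}
    return {"patient_id": patient, "concept": concept, "observed_time": time,
            "value": value, "unit": units[concept]}


def episode_with(investigations, hours=48, route="IV"):
    rows = [rx_row("A", route=route, start=T0, end=T0 + hours * H)]
    bundle = make_bundle(prescriptions=rows,
                         administrations=admin_rows("A", [T0, T0 + hours * H]),
                         investigations=investigations)
    eps = link_therapy_episodes(bundle.prescriptions, bundle.administrations)
    return eps[0], bundle


GOOD_ROW = {
    "n_temp_48h": 4, "temp_min_48h": 36.5, "temp_max_48h": 37.4,
    "max_hr_12h": 80.0, "max_rr_24h": 16.0, "min_sbp_24h": 110.0,
    "sbp_range_24h": 10.0, "last_wcc": 8.0, "wcc_trend_72h": -0.5,
    "last_crp": 60.0, "peak_crp_72h": 150.0,
}


def test_grid_has_one_row_per_hour_inclusive():
    ep, bundle = episode_with([], hours=48)
    table = build_therapy_table(ep, bundle)
    assert len(table) == 49
    assert (table["time"].diff().dropna() == H).all()
    assert table["time"].iloc[0] == ep.episode_start


def test_missing_concept_stays_null():
    ep, bundle = episode_with([obs("P1", "temperature", T0, 37.0)])
    table = build_therapy_table(ep, bundle)
    assert table["last_crp"].isna().all()
    assert table["peak_crp_72h"].isna().all()


def test_mode_follows_active_prescription_routes():
    rows = [rx_row("A", route="IV", start=T0, end=T0 + 24 * H),
            rx_row("B", route="oral", start=T0 + 30 * H, end=T0 + 48 * H)]
    bundle = make_bundle(
        prescriptions=rows,
        administrations=admin_rows("A", [T0, T0 + 24 * H])
        + admin_rows("B", [T0 + 30 * H, T0 + 48 * H]))
    ep = link_therapy_episodes(bundle.prescriptions, bundle.administrations)[0]
    table = build_therapy_table(ep, bundle).set_index("time")
    assert table.loc[T0 + 2 * H, "mode"] == "IV"
    assert table.loc[T0 + 26 * H, "mode"] == "none"   # gap between the two
    assert table.loc[T0 + 36 * H, "mode"] == "oral"


def test_rolling_markers_match_bruteforce_oracle():
    rng = np.random.default_rng(5)
    investigations = []
    series = {}
    for concept in ("temperature", "heart_rate", "respiratory_rate",
                    "systolic_bp", "wcc", "crp"):
        times = sorted(T0 + pd.Timedelta(minutes=int(m))
                       for m in rng.uniform(0, 96 * 60, size=25))
        values = rng.uniform(1, 100, size=25).round(2)
        series[concept] = list(zip(times, values))
        investigations += [obs("P1", concept, t, v)
                           for t, v in series[concept]]
    ep, bundle = episode_with(investigations, hours=96)
    table = build_therapy_table(ep, bundle)

    def in_window(concept, t, hours):
        return [v for (ot, v) in series[concept]
                if t - pd.Timedelta(hours=hours) <= ot <= t]

    for row in table.sample(20, random_state=0).itertuples():
        t = row.time
        hr = in_window("heart_rate", t, 12)
        assert (np.isnan(row.max_hr_12h) if not hr
                else row.max_hr_12h == pytest.approx(max(hr)))
        rr = in_window("respiratory_rate", t, 24)
        assert (np.isnan(row.max_rr_24h) if not rr
                else row.max_rr_24h == pytest.approx(max(rr)))
        sbp = in_window("systolic_bp", t, 24)
        if sbp:
            assert row.min_sbp_24h == pytest.approx(min(sbp))
            assert row.sbp_range_24h == pytest.approx(max(sbp) - min(sbp))
        tmp = in_window("temperature", t, 48)
        assert row.n_temp_48h == len(tmp)
        crp = in_window("crp", t, 72)
        if crp:
            assert row.peak_crp_72h == pytest.approx(max(crp))
        past = [v for (ot, v) in series["wcc"] if ot <= t]
        assert (np.isnan(row.last_wcc) if not past
                else row.last_wcc == pytest.approx(past[-1]))
        wcc_win = [(ot, v) for (ot, v) in series["wcc"]
                   if t - pd.Timedelta(hours=72) <= ot <= t]
        if len(wcc_win) >= 2:
            x = np.array([(ot - wcc_win[0][0]) / D for ot, _ in wcc_win])
            y = np.array([v for _, v in wcc_win])
            slope = np.polyfit(x, y, 1)[0]
            assert row.wcc_trend_72h == pytest.approx(slope, rel=1e-6)


def test_no_lookahead_future_observations_never_change_past_rows():
    base_obs = [obs("P1", c, T0 + k * 6 * H, v)
                for k in range(5)
                for c, v in (("temperature", 37.0), ("heart_rate", 80),
                             ("crp", 50 - k))]
    ep, bundle = episode_with(base_obs, hours=72)
    t_cut = T0 + 30 * H
    before = build_therapy_table(ep, bundle)
    perturbed = base_obs + [obs("P1", "temperature", T0 + 40 * H, 39.9),
                            obs("P1", "crp", T0 + 50 * H, 300.0)]
    ep2, bundle2 = episode_with(perturbed, hours=72)
    after = build_therapy_table(ep2, bundle2)
    cols = [c for c in before.columns if c not in ("time",)]
    pd.testing.assert_frame_equal(
        before[before["time"] <= t_cut].reset_index(drop=True),
        after[after["time"] <= t_cut].reset_index(drop=True))


# ---------------------------------------------------------------------------
# criteria evaluation
# ---------------------------------------------------------------------------

def test_all_markers_good_gives_acd():
    status = evaluate_switch_criteria(GOOD_ROW, diagnoses=["K52.9"])
    assert status.A and status.C and status.D and status.acd
    assert status.failed == []


def test_tachycardia_fails_criterion_c():
    row = GOOD_ROW | {"max_hr_12h": 95.0}
    status = evaluate_switch_criteria(row, diagnoses=[])
    assert status.A and not status.C and not status.acd
    assert "C:heart_rate" in status.failed


def test_endocarditis_code_fails_criterion_d_regardless_of_vitals():
    status = evaluate_switch_criteria(GOOD_ROW, diagnoses=["I33.0"])
    assert status.A and status.C and not status.D and not status.acd


def test_high_wcc_requires_falling_trend():
    ok = evaluate_switch_criteria(GOOD_ROW | {"last_wcc": 15.0,
                                              "wcc_trend_72h": -1.0}, [])
    bad = evaluate_switch_criteria(GOOD_ROW | {"last_wcc": 15.0,
                                               "wcc_trend_72h": 0.5}, [])
    assert ok.C and not bad.C


def test_missing_marker_fails_conservatively_but_can_be_ignored():
    row = GOOD_ROW | {"max_hr_12h": np.nan}
    strict = evaluate_switch_criteria(row, [])
    lax = evaluate_switch_criteria(row, [],
                                   CriteriaConfig(missing_fails=False))
    assert not strict.C and "C:heart_rate (missing)" in strict.failed
    assert lax.C


@pytest.mark.parametrize("key, worse", [
    ("max_hr_12h", 120.0), ("max_rr_24h", 28.0), ("temp_max_48h", 39.0),
    ("min_sbp_24h", 70.0), ("last_crp", 200.0), ("last_wcc", 2.0),
])
def test_worsening_any_marker_never_turns_acd_on(key, worse):
    good = evaluate_switch_criteria(GOOD_ROW, [])
    bad = evaluate_switch_criteria(GOOD_ROW | {key: worse}, [])
    assert good.acd and not bad.acd


def test_earliest_criteria_time_identity_cases():
    ep, bundle = episode_with(
        [obs("P1", c, T0 - H, v) for c, v in
         (("temperature", 37.0), ("heart_rate", 80), ("respiratory_rate", 15),
          ("systolic_bp", 115), ("wcc", 8.0))]
        + [obs("P1", "crp", T0 - 2 * H, 100.0), obs("P1", "crp", T0 - H, 60.0)],
        hours=24)
    table = evaluate_table(build_therapy_table(ep, bundle), [])
    assert table["acd"].iloc[0]
    assert earliest_criteria_time(table) == ep.episode_start
    never = evaluate_table(build_therapy_table(ep, bundle), ["I33"])
    assert earliest_criteria_time(never) is None


# ---------------------------------------------------------------------------
# URB-65
# ---------------------------------------------------------------------------

def urb_bundle(age=70, urea=9.0, rr=18.0, sbp=120.0, offset=H):
    inv = []
    if urea is not None:
        inv.append(obs("P1", "urea", T0 - offset, urea))
    if rr is not None:
        inv.append(obs("P1", "respiratory_rate", T0 - offset, rr))
    if sbp is not None:
        inv.append(obs("P1", "systolic_bp", T0 - offset, sbp))
    return make_bundle(
        investigations=inv,
        admissions=[{"admission_id": "A1", "patient_id": "P1",
                     "admit_time": T0 - 2 * D, "discharge_time": T0 + 5 * D,
                     "method": "emergency", "age_at_admission": age}])


def test_urb65_threshold_application():
    score = compute_urb65(urb_bundle(), "P1", T0)
    assert (score.urea_point, score.rr_point, score.sbp_point,
            score.age_point) == (1, 0, 0, 1)
    assert score.total == 2 and score.components_missing == []


def test_urb65_missing_components_score_zero():
    score = compute_urb65(urb_bundle(age=40, urea=None, rr=None, sbp=None),
                          "P1", T0)
    assert score.total == 0
    assert sorted(score.components_missing) == ["respiratory_rate",
                                                "systolic_bp", "urea"]


def test_urb65_age_sixty_five_scores_a_point():
    assert compute_urb65(urb_bundle(age=65, urea=5.0), "P1", T0).age_point == 1
    assert compute_urb65(urb_bundle(age=64, urea=5.0), "P1", T0).age_point == 0


def test_urb65_ignores_observations_outside_window():
    bundle = urb_bundle(urea=9.0, rr=None, sbp=None,
                        offset=pd.Timedelta(hours=60))
    score = compute_urb65(bundle, "P1", T0, window_hours=48)
    assert score.urea_point == 0 and "urea" in score.components_missing


def test_urb65_total_is_lower_bound_on_full_curb65():
    score = compute_urb65(urb_bundle(), "P1", T0)
    assert 0 <= score.total <= 4
    # adding a hypothetical confusion point raises the total by exactly 1
    assert score.total + 1 <= 5
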