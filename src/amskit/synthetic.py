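"""Synthetic inpatient EHR generator with planted ground truth.

Emits a complete bundle (admissions, care episodes, prescriptions,
administrations, investigations, diagnoses, specimens, isolates,
susceptibilities) whose latent structure is known by construction, so
every analytic stage can be tested without real hospital data:

* the true partition of prescriptions into therapy episodes is exactly
  recoverable, because within-episode gaps are drawn strictly below the
  continuation window and cross-episode gaps strictly above it;
* vitals and labs are piecewise "septic then recovering" series whose
  recovery knot pins the time at which the ACD switch criteria are first
  met, to within one grid hour;
* IV-to-oral conversions happen a known delay after that time;
* culture sampling, URB-65 components, guideline-congruence categories,
  resistance profiles and indication labels are all planted.

Default parameters echo the headline magnitudes of a large UK teaching
hospital cohort (about 35% of admissions treated, 2.4 prescriptions per
episode, mean length of therapy about 5.8 days, 36% of IV sequences
converted to oral, mean switch delay 3.6 days, 22% of episodes cultured
before therapy) as generator targets — a statistical emulation, not a
reproduction of any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import ATC, cap_guideline, demo_category_map, demo_breakpoints
from .ehr_model import EHRBundle, bundle_from_frames, write_bundle

HOUR = pd.Timedelta(hours=1)

SPECIALITIES = ["general medicine", "respiratory medicine", "geriatric medicine",
                "cardiology", "general surgery", "urology"]

QUALIFYING_GROUPS = ["blood", "drain", "respiratory", "intravascular_device",
                     "cns", "aspirate", "tissue_bone"]

# drugs outside the CAP guideline pools, used for generic therapy
GENERIC_DRUGS = [ATC["co-amoxiclav"], ATC["ceftriaxone"], ATC["meropenem"],
                 ATC["piperacillin/tazobactam"], ATC["ciprofloxacin"],
                 ATC["flucloxacillin"], ATC["trimethoprim"], ATC["metronidazole"]]

INDICATION_DRUGS = {
    "UTI": [ATC["trimethoprim"], ATC["ciprofloxacin"]],
    "skin_soft_tissue": [ATC["flucloxacillin"]],
    "intra_abdominal": [ATC["co-amoxiclav"], ATC["metronidazole"]],
}
# deliberately excludes codes on the criterion-D high-risk list, so an
# episode's indication never flips the admission-level deep-seated flag
INDICATION_DX = {"CAP": "J181", "UTI": "N390", "skin_soft_tissue": "L031",
                 "intra_abdominal": "K650", "surgical_prophylaxis": "Z290"}
BENIGN_DX = ["K529", "N179", "I489", "E119", "J449", "R55"]

NON_CAP_INDICATIONS = ["UTI", "skin_soft_tissue", "intra_abdominal", "other",
                       "not_specified", "endocarditis", "bronchiectasis",
                       "surgical_prophylaxis"]
NON_CAP_WEIGHTS = [0.25, 0.15, 0.12, 0.20, 0.18, 0.04, 0.03, 0.03]


@dataclass
class CohortParams:
    """Generator parameters; the defaults are the study conditions."""

    seed: int
    n_patients: int = 500
    start_date: str = "2017-09-01"
    emergency_fraction: float = 0.7
    p_treated: float = 0.35                 # admissions with >=1 antibacterial
    extra_episode_rate: float = 0.15        # Poisson mean for episodes beyond the first
    backbone_extra_rate: float = 1.0        # Poisson mean; sequential rx = 1 + this
    p_combination: float = 0.2              # combination partner per backbone rx
    gap_hours: tuple[float, float] = (2.0, 22.0)        # within-episode, < 36 h window
    # between episodes: above the continuation window AND above the 72 h
    # culture look-back, so one episode's specimen cannot bleed into the next
    cross_gap_hours: tuple[float, float] = (72.5, 140.0)
    rx_duration_mean_days: float = 2.2
    rx_duration_sigma: float = 0.4
    p_iv: float = 0.7                       # episodes starting IV
    p_convert: float = 0.36                 # IV episodes converted to oral
    switch_delay_mean_days: float = 3.6     # lognormal mean (median ~2.2 d)
    switch_delay_sigma: float = 1.0
    oral_tail_hours: tuple[float, float] = (24.0, 72.0)
    obs_interval_hours: float = 6.0
    sick_intervals_max: int = 6             # sick phase lasts 1..6 obs intervals
    p_monitored: float = 0.9                # non-CAP episodes with vitals series
    p_high_risk_dx: float = 0.1             # admissions coded with a criterion-D condition
    p_culture: float = 0.22                 # episodes with a qualifying pre-therapy specimen
    p_offwindow_specimen: float = 0.3       # of the rest: a non-qualifying/late specimen
    p_cap: float = 0.3                      # episodes with CAP indication
    p_urea_high: float = 0.35
    p_rr_high: float = 0.15
    p_sbp_low: float = 0.10
    congruence_weights: tuple[float, float, float, float] = (0.25, 0.35, 0.10, 0.30)
    #                    (recommended, higher, lower, other)
    p_growth: float = 0.6                   # specimens growing an isolate
    mdr_weights: tuple[float, float, float, float] = (0.6, 0.25, 0.1, 0.05)
    #                    (susceptible_profile, MDR, XDR, PDR)
    untreated_los_mean_days: float = 2.5
    untreated_los_sigma: float = 1.0

    def validate(self) -> None:
        probs = [self.emergency_fraction, self.p_treated, self.p_combination,
                 self.p_iv, self.p_convert, self.p_monitored, self.p_high_risk_dx,
                 self.p_culture, self.p_offwindow_specimen, self.p_cap,
                 self.p_urea_high, self.p_rr_high, self.p_sbp_low, self.p_growth]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.p_convert > 0 and self.p_iv == 0:
            raise ValueError("conversion probability requires a non-zero IV fraction")
        if not math.isclose(sum(self.congruence_weights), 1.0, abs_tol=1e-9):
            raise ValueError("congruence_weights must sum to 1")
        if not math.isclose(sum(self.mdr_weights), 1.0, abs_tol=1e-9):
            raise ValueError("mdr_weights must sum to 1")
        if self.gap_hours[1] >= 36:
            raise ValueError("within-episode gaps must stay below the 36 h window")
        if self.cross_gap_hours[0] <= 36:
            raise ValueError("cross-episode gaps must stay above the 36 h window")

    def expected_lot_days(self) -> float:
        """Analytic mean episode LOT implied by the defaults: a mixture of
        converted IV episodes (sick phase + 49 h criteria clearance + switch
        delay + oral tail) and chained-backbone episodes."""
        f_conv = self.p_iv * self.p_convert
        mean_sick_h = self.obs_interval_hours * (1 + self.sick_intervals_max) / 2
        lot_conv = (mean_sick_h + 49) / 24 + self.switch_delay_mean_days \
            + sum(self.oral_tail_hours) / 2 / 24
        n_seq = 1 + self.backbone_extra_rate
        lot_chain = (n_seq * self.rx_duration_mean_days
                     + self.backbone_extra_rate * sum(self.gap_hours) / 2 / 24)
        return f_conv * lot_conv + (1 - f_conv) * lot_chain


@dataclass
class SyntheticGroundTruth:
    """Planted structure consistent with the emitted bundle by construction."""

    episodes: pd.DataFrame   # one row per planted therapy episode
    isolates: pd.DataFrame   # isolate_id -> planted resistance category
    params: CohortParams

    def episode_partition(self) -> list[frozenset[str]]:
        return [frozenset(p.split(";"))
                for p in self.episodes["prescription_ids"]]


def _lognormal_with_mean(rng: np.random.Generator, mean: float, sigma: float,
                         size=None):
    mu = math.log(mean) - sigma ** 2 / 2
    return rng.lognormal(mu, sigma, size)


def _minute(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor("min")


class _Cohort:
    """Mutable accumulation state for one generation run."""

    def __init__(self, params: CohortParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.rows: dict[str, list[dict]] = {k: [] for k in (
            "prescriptions", "administrations", "admissions", "care_episodes",
            "investigations", "diagnoses", "specimens", "isolates",
            "susceptibilities")}
        self.gt_episodes: list[dict] = []
        self.gt_isolates: list[dict] = []
        self._counters = {"rx": 0, "sp": 0, "iso": 0}

    def next_id(self, kind: str) -> str:
        self._counters[kind] += 1
        return f"{kind.upper()}{self._counters[kind]:06d}"


def _pick_regimen(rng, severity: int, weights) -> tuple[str, list[str]]:
    """Choose a congruence category and a concrete CAP regimen realizing it
    for the given planted severity."""
    guide = cap_guideline()
    own = guide.stratum_index(severity)
    strata = guide.strata
    own_sets = set(strata[own].all_regimens())
    higher = [r for i in range(own + 1, len(strata))
              for r in strata[i].all_regimens() if r not in own_sets]
    lower_excl = own_sets | set(higher)
    lower = [r for i in range(own)
             for r in strata[i].all_regimens() if r not in lower_excl]
    other_pool = [frozenset({ATC["clarithromycin"]}), frozenset({ATC["co-amoxiclav"]}),
                  frozenset({ATC["ceftriaxone"]}), frozenset({ATC["meropenem"]})]
    other_pool = [r for r in other_pool
                  if r not in own_sets and r not in higher and r not in lower]

    cat = rng.choice(["recommended", "higher_severity_regimen",
                      "lower_severity_regimen", "other"], p=list(weights))
    if cat == "higher_severity_regimen" and not higher:
        cat = "other"
    if cat == "lower_severity_regimen" and not lower:
        cat = "other"
    pool = {"recommended": list(strata[own].first_line_regimens),
            "higher_severity_regimen": higher,
            "lower_severity_regimen": lower,
            "other": other_pool}[cat]
    regimen = pool[int(rng.integers(len(pool)))]
    return cat, sorted(regimen)


def _emit_prescription(c: _Cohort, patient_id, admission_id, drug, route,
                       start, end, freq_h: float) -> str:
    pid = c.next_id("rx")
    start, end = _minute(start), _minute(end)
    if end <= start:
        end = start + pd.Timedelta(minutes=30)
    dose = float(c.rng.choice([250, 500, 1000]))
    c.rows["prescriptions"].append({
        "prescription_id": pid, "patient_id": patient_id,
        "admission_id": admission_id, "drug_code": drug, "drug_name": drug,
        "route": route, "dose": dose, "dose_unit": "mg",
        "frequency": f"q{int(freq_h)}h",
        "authored_time": start, "start_time": start, "end_time": end,
        "status": "completed"})
    t = start
    step = pd.Timedelta(hours=freq_h)
    while t < end:
        c.rows["administrations"].append({"prescription_id": pid,
                                          "administration_time": t,
                                          "dose_given": dose})
        t = t + step
    c.rows["administrations"].append({"prescription_id": pid,
                                      "administration_time": end,
                                      "dose_given": dose})
    return pid


def _emit_backbone(c: _Cohort, patient_id, admission_id, t0, t_end,
                   route, drugs_first: list[str] | None,
                   indication: str | None) -> list[str]:
    """Chain of sequential prescriptions covering [t0, t_end] exactly, with
    within-episode gaps strictly inside the continuation window; optional
    combination partners. The planned segment count (1 + Poisson) is shrunk
    only when the span is too short to fit it."""
    p = c.params
    rng = c.rng
    span_h = (t_end - t0) / HOUR
    n_seq = 1 + int(rng.poisson(p.backbone_extra_rate))
    gaps: list[float] = []
    while n_seq > 1:
        gaps = [float(rng.uniform(*p.gap_hours)) for _ in range(n_seq - 1)]
        if span_h - sum(gaps) >= 2.0 * n_seq:
            break
        n_seq -= 1
        gaps = []
    avail = span_h - sum(gaps)
    weights = rng.uniform(0.5, 1.5, size=n_seq)
    durs = avail * weights / weights.sum()

    ids: list[str] = []
    s = t0
    for k in range(n_seq):
        e = t_end if k == n_seq - 1 else s + pd.Timedelta(hours=float(durs[k]))
        if k == 0 and drugs_first:
            drug = drugs_first[0]
            partners = drugs_first[1:]
        else:
            drug = _draw_drug(rng, indication)
            partners = ([_draw_drug(rng, indication)]
                        if rng.random() < p.p_combination else [])
        ids.append(_emit_prescription(c, patient_id, admission_id, drug, route,
                                      s, e, float(rng.choice([8.0, 12.0]))))
        for pdrug in partners:
            ps = s + pd.Timedelta(hours=float(rng.uniform(0, 4)))
            pe = min(e, ps + (e - ps) * float(rng.uniform(0.5, 1.0)))
            if pe > ps:
                ids.append(_emit_prescription(c, patient_id, admission_id, pdrug,
                                              route, ps, pe,
                                              float(rng.choice([8.0, 12.0]))))
        if k < n_seq - 1:
            s = e + pd.Timedelta(hours=gaps[k])
    return ids


def _draw_drug(rng, indication: str | None) -> str:
    pool = INDICATION_DRUGS.get(indication)
    if pool and rng.random() < 0.8:
        return pool[int(rng.integers(len(pool)))]
    return GENERIC_DRUGS[int(rng.integers(len(GENERIC_DRUGS)))]


def _emit_vitals(c: _Cohort, patient_id, t0, t_end, t_recovery,
                 rr_sick: float, sbp_sick: float) -> pd.Timestamp | None:
    """Piecewise septic-then-recovering observation series every
    obs_interval hours; returns the last 'sick' observation time (None if
    recovery precedes the first observation)."""
    rng = c.rng
    step = pd.Timedelta(hours=c.params.obs_interval_hours)
    crp_sick, crp_well = 150.0, 120.0
    t = t0
    last_sick = None
    k_well = 0
    while t <= t_end:
        sick = t < t_recovery
        if sick:
            last_sick = t
            vals = {"temperature": 38.3 + rng.uniform(0, 0.5),
                    "heart_rate": 100 + rng.uniform(0, 10),
                    "respiratory_rate": rr_sick + rng.uniform(0, 2),
                    "systolic_bp": sbp_sick + rng.uniform(-3, 3),
                    "wcc": 14.0 + 0.2 * ((t - t0) / HOUR) / 6,
                    "crp": crp_sick + 5 * ((t - t0) / HOUR) / 6}
        else:
            k_well += 1
            vals = {"temperature": 36.8 + rng.uniform(-0.5, 0.5),
                    "heart_rate": 78 + rng.uniform(-6, 6),
                    "respiratory_rate": 15 + rng.uniform(-2, 2),
                    "systolic_bp": 115 + rng.uniform(-5, 5),
                    "wcc": 8.0 + rng.uniform(-1.5, 1.5),
                    "crp": max(5.0, crp_well * math.exp(-0.05 * k_well))}
        for concept, v in vals.items():
            unit = {"temperature": "°C", "heart_rate": "bpm",
                    "respiratory_rate": "breaths/min", "systolic_bp": "mmHg",
                    "wcc": "10^9/L", "crp": "mg/L"}[concept]
            c.rows["investigations"].append({
                "patient_id": patient_id, "concept": concept,
                "observed_time": _minute(t), "value": round(float(v), 2),
                "unit": unit})
        t = t + step
    return last_sick


def _plant_specimen(c: _Cohort, patient_id, t0) -> tuple[bool, str | None]:
    """Culture-before-treatment planting; returns (gt linked, specimen_id)."""
    p, rng = c.params, c.rng
    r = rng.random()
    if r < p.p_culture:
        group = QUALIFYING_GROUPS[int(rng.integers(len(QUALIFYING_GROUPS)))]
        t = t0 - pd.Timedelta(hours=float(rng.uniform(1, 71)))
        linked = True
    elif r < p.p_culture + p.p_offwindow_specimen:
        if rng.random() < 0.5:
            group, t = "urine", t0 - pd.Timedelta(hours=24)       # out of scope
        else:
            group = "blood"
            t = t0 - pd.Timedelta(hours=float(rng.uniform(80, 120)))  # out of window
        linked = False
    else:
        return False, None
    sid = c.next_id("sp")
    c.rows["specimens"].append({"specimen_id": sid, "patient_id": patient_id,
                                "collection_time": _minute(t),
                                "specimen_group": group})
    _plant_isolate(c, sid)
    return linked, sid


_MDR_CATS = ["susceptible_profile", "MDR", "XDR", "PDR"]


def _plant_isolate(c: _Cohort, specimen_id: str) -> None:
    p, rng = c.params, c.rng
    iso_id = c.next_id("iso")
    if rng.random() > p.p_growth:
        c.rows["isolates"].append({"isolate_id": iso_id, "specimen_id": specimen_id,
                                   "organism_code": "no growth", "no_growth": 1})
        return
    cat = str(rng.choice(_MDR_CATS, p=list(p.mdr_weights)))
    group = "enterobacterales"   # 8 single-agent categories: all labels realizable
    agents = list(demo_category_map()[group])
    n = len(agents)
    if cat == "susceptible_profile":
        n_ns = int(rng.integers(0, 3))          # 0..2 non-susceptible categories
    elif cat == "MDR":
        n_ns = int(rng.integers(3, n - 2))      # 3..n-3: not XDR
    elif cat == "XDR":
        n_ns = int(rng.integers(n - 2, n))      # n-2..n-1: all but <=2, not all
    else:
        n_ns = n
    ns_agents = set(rng.choice(agents, size=n_ns, replace=False)) if n_ns else set()
    c.rows["isolates"].append({"isolate_id": iso_id, "specimen_id": specimen_id,
                               "organism_code": group, "no_growth": 0})
    rules = {(r.agent_code): r for r in demo_breakpoints()
             if r.organism_group == group and r.measure_type == "MIC"}
    for agent in agents:
        rule = rules[agent]
        value = rule.r_bound * 4 if agent in ns_agents else rule.s_bound / 2
        c.rows["susceptibilities"].append({
            "isolate_id": iso_id, "agent_code": agent, "measure_type": "MIC",
            "measure_value": float(value), "reported_interpretation": None})
    c.gt_isolates.append({"isolate_id": iso_id, "mdr_category": cat})


def generate_cohort(params: CohortParams) -> tuple[EHRBundle, SyntheticGroundTruth]:
    """Generate a bundle plus its ground truth; deterministic given the seed."""
    params.validate()
    c = _Cohort(params)
    rng = c.rng
    base = pd.Timestamp(params.start_date)
    guide = cap_guideline()

    for i in range(params.n_patients):
        patient_id = f"P{i:05d}"
        admission_id = f"A{i:05d}"
        age = int(rng.integers(18, 96))
        method = "emergency" if rng.random() < params.emergency_fraction else "elective"
        speciality = SPECIALITIES[int(rng.integers(len(SPECIALITIES)))]
        team = f"{speciality.split()[0][:4]}-T{int(rng.integers(1, 5))}"
        treated = rng.random() < params.p_treated
        adm_t0 = base + pd.Timedelta(hours=float(rng.uniform(0, 24 * 300)))

        dx_codes: list[str] = []
        high_risk = treated and rng.random() < params.p_high_risk_dx
        if high_risk:
            dx_codes.append(str(rng.choice(["I330", "M861", "G001", "J850"])))
        dx_codes.append(BENIGN_DX[int(rng.integers(len(BENIGN_DX)))])

        last_end = None
        if treated:
            n_episodes = 1 + int(rng.poisson(params.extra_episode_rate))
            t0 = adm_t0 + pd.Timedelta(hours=float(rng.uniform(2, 48)))
            for ep_index in range(n_episodes):
                ep = _generate_episode(c, patient_id, admission_id, t0,
                                       speciality, team, age, high_risk, guide,
                                       first_episode=(ep_index == 0))
                dx_codes.extend(ep.pop("_dx_codes"))
                c.gt_episodes.append(ep)
                last_end = ep["episode_end"]
                t0 = last_end + pd.Timedelta(
                    hours=float(rng.uniform(*params.cross_gap_hours)))
            admit = adm_t0
            discharge = last_end + pd.Timedelta(hours=float(rng.uniform(2, 48)))
        else:
            admit = adm_t0
            los = float(_lognormal_with_mean(rng, params.untreated_los_mean_days,
                                             params.untreated_los_sigma))
            discharge = admit + pd.Timedelta(days=max(los, 0.1))

        c.rows["admissions"].append({
            "admission_id": admission_id, "patient_id": patient_id,
            "admit_time": _minute(admit), "discharge_time": _minute(discharge),
            "method": method, "age_at_admission": age})
        c.rows["care_episodes"].append({
            "admission_id": admission_id, "consultant_team_id": team,
            "speciality": speciality, "start_time": _minute(admit),
            "end_time": _minute(discharge)})
        for pos, code in enumerate(dict.fromkeys(dx_codes), start=1):
            c.rows["diagnoses"].append({"admission_id": admission_id,
                                        "icd10_code": code, "position": pos})

    frames = {k: pd.DataFrame(v) for k, v in c.rows.items() if v}
    bundle = bundle_from_frames(frames)
    gt = SyntheticGroundTruth(
        episodes=pd.DataFrame(c.gt_episodes, columns=_GT_EPISODE_COLUMNS),
        isolates=pd.DataFrame(c.gt_isolates, columns=["isolate_id", "mdr_category"]),
        params=params)
    return bundle, gt


_GT_EPISODE_COLUMNS = [
    "patient_id", "admission_id", "prescription_ids", "episode_start",
    "episode_end", "is_iv", "converted", "conversion_time", "monitored",
    "high_risk", "acd_time", "delay_days", "culture_linked", "indication",
    "is_cap", "urb_total", "regimen_label", "congruence_category"]


def _generate_episode(c: _Cohort, patient_id, admission_id, t0, speciality,
                      team, age, high_risk, guide,
                      first_episode: bool = True) -> dict:
    p, rng = c.params, c.rng
    t0 = _minute(t0)
    is_cap = rng.random() < p.p_cap
    indication = "CAP" if is_cap else str(
        rng.choice(NON_CAP_INDICATIONS, p=NON_CAP_WEIGHTS))
    monitored = True if is_cap else rng.random() < p.p_monitored
    is_iv = rng.random() < p.p_iv
    converted = is_iv and rng.random() < p.p_convert

    dx_codes = []
    if indication in INDICATION_DX and rng.random() < 0.8:
        dx_codes.append(INDICATION_DX[indication])
    ep_high_risk = high_risk  # admission-level flag; uniform across episodes

    # planted clinical timeline
    m_sick = int(rng.integers(1, p.sick_intervals_max + 1))
    t_last_sick_nominal = t0 + pd.Timedelta(hours=p.obs_interval_hours * m_sick)
    t_recovery = t_last_sick_nominal + pd.Timedelta(minutes=1)
    t_acd_nominal = t_last_sick_nominal + pd.Timedelta(hours=49)

    # URB-65 component planting (observed at initiation when monitored)
    urea_high = rng.random() < p.p_urea_high
    rr_high = rng.random() < p.p_rr_high
    sbp_low = rng.random() < p.p_sbp_low
    urb_total = (int(urea_high) + int(rr_high) + int(sbp_low)
                 + int(age >= 65)) if monitored else int(age >= 65)

    # regimen choice
    if is_cap:
        congruence_cat, regimen = _pick_regimen(rng, urb_total,
                                                p.congruence_weights)
    else:
        congruence_cat, regimen = None, None

    route0 = "IV" if is_iv else "oral"
    if converted:
        delay = float(_lognormal_with_mean(rng, p.switch_delay_mean_days,
                                           p.switch_delay_sigma))
        t_conv = _minute(t_acd_nominal + pd.Timedelta(days=delay))
        t_end = _minute(t_conv + pd.Timedelta(hours=float(
            rng.uniform(*p.oral_tail_hours))))
        gap = pd.Timedelta(hours=float(rng.uniform(1, 12)))
        iv_end = max(t0 + pd.Timedelta(hours=4), t_conv - gap)
        ids = _emit_backbone(c, patient_id, admission_id, t0, iv_end, "IV",
                             regimen, indication)
        oral_drug = regimen[0] if regimen else _draw_drug(rng, indication)
        ids.append(_emit_prescription(c, patient_id, admission_id, oral_drug,
                                      "oral", t_conv, t_end,
                                      float(rng.choice([8.0, 12.0]))))
    else:
        n_seq = 1 + int(rng.poisson(p.backbone_extra_rate))
        durs = [max(4.0, 24 * float(_lognormal_with_mean(
            rng, p.rx_duration_mean_days, p.rx_duration_sigma)))
            for _ in range(n_seq)]
        gaps = [float(rng.uniform(*p.gap_hours)) for _ in range(n_seq - 1)]
        t_end = _minute(t0 + pd.Timedelta(hours=sum(durs) + sum(gaps)))
        ids = _emit_backbone(c, patient_id, admission_id, t0, t_end, route0,
                             regimen, indication)
        t_conv, delay = None, None

    # vitals + planted ACD time
    acd_time = None
    if monitored:
        rr_sick = 33.0 if rr_high else 23.0
        sbp_sick = 85.0 if sbp_low else 112.0
        last_sick = _emit_vitals(c, patient_id, t0, t_end, t_recovery,
                                 rr_sick, sbp_sick)
        if not ep_high_risk and last_sick is not None:
            candidate = last_sick + pd.Timedelta(hours=49)
            if candidate <= t_end:
                acd_time = candidate
        c.rows["investigations"].append({
            "patient_id": patient_id, "concept": "urea",
            "observed_time": t0, "value": 9.5 if urea_high else 5.0,
            "unit": "mmol/L"})

    gt_delay = None
    if acd_time is not None:
        if converted and t_conv >= acd_time:
            gt_delay = float((t_conv - acd_time) / pd.Timedelta(days=1))
        elif not converted and is_iv:
            gt_delay = float((t_end - acd_time) / pd.Timedelta(days=1))

    # cultures planted only on a patient's first episode: later episodes
    # start > 72 h after anything already collected, so windows stay clean
    if first_episode:
        culture_linked, _sid = _plant_specimen(c, patient_id, t0)
    else:
        culture_linked = False

    return {
        "patient_id": patient_id, "admission_id": admission_id,
        "prescription_ids": ";".join(ids),
        "episode_start": t0, "episode_end": t_end,
        "is_iv": is_iv, "converted": converted if is_iv else None,
        "conversion_time": t_conv, "monitored": monitored,
        "high_risk": ep_high_risk, "acd_time": acd_time,
        "delay_days": gt_delay, "culture_linked": culture_linked,
        "indication": indication, "is_cap": is_cap,
        "urb_total": urb_total,
        "regimen_label": ";".join(regimen) if regimen else None,
        "congruence_category": congruence_cat,
        "_dx_codes": dx_codes,
    }


def write_ground_truth(gt: SyntheticGroundTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.episodes.to_csv(directory / "ground_truth_episodes.csv", index=False)
    gt.isolates.to_csv(directory / "ground_truth_isolates.csv", index=False)
    with open(directory / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(gt.params), fh, sort_keys=False)


def load_params(path: str | Path) -> CohortParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "seed" not in data:
        raise ValueError("generator params must include a seed")
    for key in ("gap_hours", "cross_gap_hours", "oral_tail_hours",
                "congruence_weights", "mdr_weights"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortParams(**data)


# ---------------------------------------------------------------------------
# Printed CAP first-line therapy fixture (low-severity episodes)
# ---------------------------------------------------------------------------

_CAP_FIXTURE_ROWS: list[tuple[str, tuple[str, ...], int, int]] = [
    ("Amoxicillin", ("amoxicillin",), 205, 249),
    ("Amoxicillin, clarithromycin", ("amoxicillin", "clarithromycin"), 56, 104),
    ("Azithromycin", ("azithromycin",), 4, 6),
    ("Benzylpenicillin", ("benzylpenicillin",), 2, 3),
    ("Benzylpenicillin, clarithromycin", ("benzylpenicillin", "clarithromycin"), 14, 31),
    ("Benzylpenicillin, metronidazole", ("benzylpenicillin", "metronidazole"), 1, 0),
    ("Ciprofloxacin", ("ciprofloxacin",), 2, 9),
    ("Clarithromycin", ("clarithromycin",), 76, 75),
    ("Clarithromycin, co-amoxiclav", ("clarithromycin", "co-amoxiclav"), 261, 541),
    ("Co-amoxiclav", ("co-amoxiclav",), 104, 211),
    ("Meropenem", ("meropenem",), 9, 24),
    ("Piperacillin/tazobactam", ("piperacillin/tazobactam",), 2, 2),
    ("Ceftriaxone", ("ceftriaxone",), 10, 2),
    ("Clarithromycin, moxifloxacin", ("clarithromycin", "moxifloxacin"), 2, 4),
    ("Clarithromycin, piperacillin/ tazobactam",
     ("clarithromycin", "piperacillin/tazobactam"), 4, 9),
    ("Meropenem, vancomycin", ("meropenem", "vancomycin"), 7, 10),
    ("Other", (), 168, 322),
]


def generate_cap_table_fixture() -> pd.DataFrame:
    """Regimen-count table of first-line therapy in low-severity CAP
    episodes: 17 regimen rows x two severity columns (URB-65 = 0 and 1).
    ``drug_codes`` holds the ;-joined ATC set of each regimen ("OTHER"
    marks the aggregated remainder, which matches no guideline regimen)."""
    rows = []
    for label, drugs, n0, n1 in _CAP_FIXTURE_ROWS:
        codes = sorted(ATC[d] for d in drugs) if drugs else ["OTHER"]
        rows.append({"regimen_label": label, "drug_codes": ";".join(codes),
                     "n_urb0": n0, "n_urb1": n1})
    return pd.DataFrame(rows)


def cap_fixture_episodes() -> pd.DataFrame:
    """Expand the fixture counts into one row per pseudo-episode
    (regimen drug-code set + severity), the input expected by the
    congruence classifier and cross-tabulation."""
    fixture = generate_cap_table_fixture()
    rows = []
    k = 0
    for r in fixture.itertuples():
        for severity, n in ((0, r.n_urb0), (1, r.n_urb1)):
            for _ in range(int(n)):
                rows.append({"episode_id": f"CAPFIX{k:05d}",
                             "regimen_label": r.regimen_label,
                             "drug_codes": r.drug_codes,
                             "severity": severity})
                k += 1
    return pd.DataFrame(rows)
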