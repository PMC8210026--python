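"""Hourly therapy tables and IV-to-oral switch (ACD) criteria.

For every therapy episode a dynamic table is built at one-hour resolution
from episode start to episode end. Each row summarizes the administration
mode (IV/oral/mixed) and rolling clinical markers computed strictly from
observations at or before the row time — never from the future:

* last white cell count and its 72 h least-squares trend (slope/day),
* last C-reactive protein and its 72 h peak,
* temperature range over 48 h, max heart rate over 12 h,
* max respiratory rate over 24 h, min and range of systolic BP over 24 h.

The switch criteria evaluated on each row:

* **A** — afebrile: every temperature in the past 48 h within 36-38 °C
  (at least one reading required);
* **C** — clinically improving: HR < 90 (12 h), RR < 20 (24 h), stable
  systolic BP (24 h), WCC 4-12 x 10^9/L or high-but-falling, and CRP
  below its 72 h peak;
* **D** — no high-risk deep-seated infection coded on the admission.

Criterion B (able to take oral medication) cannot be assessed from
structured records and is deliberately absent; "ACD" is the conjunction
of the three measurable criteria. Missing markers fail their criterion by
default (conservative for recommending a switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CriteriaConfig, Urb65Config
from .ehr_model import EHRBundle
from .linkage import TherapyEpisode

HOUR = pd.Timedelta(hours=1)
DAY_NS = 24 * 3600 * 1e9

MARKER_COLUMNS = [
    "mode", "last_wcc", "wcc_trend_72h", "peak_crp_72h", "last_crp",
    "temp_min_48h", "temp_max_48h", "n_temp_48h",
    "max_hr_12h", "max_rr_24h", "min_sbp_24h", "sbp_range_24h",
]


def _series_for(bundle: EHRBundle, patient_id: str, concept: str):
    inv = bundle.investigations
    sub = inv[(inv["patient_id"] == patient_id) & (inv["concept"] == concept)]
    sub = sub.dropna(subset=["observed_time", "value"]).sort_values("observed_time")
    return (sub["observed_time"].values.astype("datetime64[ns]").astype(np.int64),
            sub["value"].astype(float).to_numpy())


def build_therapy_table(episode: TherapyEpisode,
                        bundle: EHRBundle,
                        config: CriteriaConfig | None = None) -> pd.DataFrame:
    """One row per hour from episode start to episode end (inclusive grid;
    a zero-duration episode yields a single row). Rolling windows are
    closed ``[t - w, t]``; a window with no observation yields NaN, never
    a fabricated value."""
    config = config or CriteriaConfig()
    grid = pd.date_range(episode.episode_start, episode.episode_end, freq="1h")
    if len(grid) == 0:
        grid = pd.DatetimeIndex([episode.episode_start])
    t_ns = grid.values.astype(np.int64)
    n = len(grid)

    concepts = {c: _series_for(bundle, episode.patient_id, c)
                for c in ("wcc", "crp", "temperature", "heart_rate",
                          "respiratory_rate", "systolic_bp")}

    def window_slices(times: np.ndarray, hours: float):
        lo = np.searchsorted(times, t_ns - int(hours * 3600 * 1e9), side="left")
        hi = np.searchsorted(times, t_ns, side="right")
        return lo, hi

    def agg(times, values, hours, fn):
        lo, hi = window_slices(times, hours)
        out = np.full(n, np.nan)
        for i in range(n):
            if hi[i] > lo[i]:
                out[i] = fn(values[lo[i]:hi[i]])
        return out

    def last_value(times, values):
        hi = np.searchsorted(times, t_ns, side="right")
        out = np.full(n, np.nan)
        mask = hi > 0
        out[mask] = values[hi[mask] - 1]
        return out

    wcc_t, wcc_v = concepts["wcc"]
    crp_t, crp_v = concepts["crp"]
    tmp_t, tmp_v = concepts["temperature"]
    hr_t, hr_v = concepts["heart_rate"]
    rr_t, rr_v = concepts["respiratory_rate"]
    bp_t, bp_v = concepts["systolic_bp"]

    # WCC trend: least-squares slope per day over the trailing window
    trend = np.full(n, np.nan)
    lo, hi = window_slices(wcc_t, config.wcc_trend_window_hours)
    for i in range(n):
        if hi[i] - lo[i] >= 2:
            tt = (wcc_t[lo[i]:hi[i]] - wcc_t[lo[i]]) / DAY_NS
            vv = wcc_v[lo[i]:hi[i]]
            if np.ptp(tt) > 0:
                trend[i] = np.polyfit(tt, vv, 1)[0]

    lo_t, hi_t = window_slices(tmp_t, config.temp_window_hours)
    n_temp = (hi_t - lo_t).astype(float)

    # administration mode from prescriptions active in the hour
    rx = bundle.prescriptions
    rx = rx[rx["prescription_id"].isin(episode.prescription_ids)]
    modes = np.full(n, "none", dtype=object)
    iv_active = np.zeros(n, dtype=bool)
    oral_active = np.zeros(n, dtype=bool)
    for row in rx.itertuples():
        active = (grid >= row.start_time) & (grid <= row.end_time)
        if row.route == "IV":
            iv_active |= active.to_numpy() if hasattr(active, "to_numpy") else active
        elif row.route == "oral":
            oral_active |= active.to_numpy() if hasattr(active, "to_numpy") else active
    modes[iv_active & ~oral_active] = "IV"
    modes[~iv_active & oral_active] = "oral"
    modes[iv_active & oral_active] = "mixed"

    return pd.DataFrame({
        "episode_id": episode.episode_id,
        "patient_id": episode.patient_id,
        "time": grid,
        "mode": modes,
        "last_wcc": last_value(wcc_t, wcc_v),
        "wcc_trend_72h": trend,
        "peak_crp_72h": agg(crp_t, crp_v, config.crp_peak_window_hours, np.max),
        "last_crp": last_value(crp_t, crp_v),
        "temp_min_48h": agg(tmp_t, tmp_v, config.temp_window_hours, np.min),
        "temp_max_48h": agg(tmp_t, tmp_v, config.temp_window_hours, np.max),
        "n_temp_48h": n_temp,
        "max_hr_12h": agg(hr_t, hr_v, config.hr_window_hours, np.max),
        "max_rr_24h": agg(rr_t, rr_v, config.rr_window_hours, np.max),
        "min_sbp_24h": agg(bp_t, bp_v, config.sbp_window_hours, np.min),
        "sbp_range_24h": agg(bp_t, bp_v, config.sbp_window_hours, np.ptp),
    })


@dataclass
class CriteriaStatus:
    A: bool
    C: bool
    D: bool
    failed: list[str] = field(default_factory=list)

    @property
    def acd(self) -> bool:
        return self.A and self.C and self.D


def _check(conditions: list[tuple[str, bool | None]],
           missing_fails: bool) -> tuple[bool, list[str]]:
    """Combine sub-markers; None means the marker is unobserved."""
    failed = [name for name, ok in conditions if ok is False]
    missing = [name for name, ok in conditions if ok is None]
    if failed:
        return False, failed + [f"{m} (missing)" for m in missing if missing_fails]
    if missing and missing_fails:
        return False, [f"{m} (missing)" for m in missing]
    return True, []


def evaluate_switch_criteria(row: Mapping,
                             diagnoses: pd.DataFrame | Sequence[str] | None = None,
                             config: CriteriaConfig | None = None) -> CriteriaStatus:
    """Evaluate criteria A, C and D on one therapy-table row.

    ``diagnoses`` is the admission's diagnosis table (or a plain sequence
    of ICD-10 codes); criterion D fails when any code starts with a
    configured high-risk prefix.
    """
    config = config or CriteriaConfig()

    def num(key):
        v = row.get(key) if hasattr(row, "get") else getattr(row, key, None)
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        return float(v)

    # A: all temperatures in the trailing window inside [low, high]
    n_temp = num("n_temp_48h") or 0
    if n_temp < 1:
        a_conditions = [("A:temperature", None)]
    else:
        a_conditions = [("A:temperature_range",
                         config.temp_low <= num("temp_min_48h")
                         and num("temp_max_48h") <= config.temp_high)]
    A, a_failed = _check(a_conditions, config.missing_fails)

    # C: clinically improving
    hr, rr = num("max_hr_12h"), num("max_rr_24h")
    sbp_min, sbp_rng = num("min_sbp_24h"), num("sbp_range_24h")
    wcc, trend = num("last_wcc"), num("wcc_trend_72h")
    crp, crp_peak = num("last_crp"), num("peak_crp_72h")
    if wcc is None:
        wcc_ok = None
    elif config.wcc_low <= wcc <= config.wcc_high:
        wcc_ok = True
    elif wcc > config.wcc_high:
        wcc_ok = None if trend is None else trend < 0
    else:
        wcc_ok = False
    if crp is None or crp_peak is None:
        crp_ok = None
    else:
        crp_ok = crp < crp_peak * (1 - config.crp_relative_drop)
    c_conditions = [
        ("C:heart_rate", None if hr is None else hr < config.hr_max),
        ("C:respiratory_rate", None if rr is None else rr < config.rr_max),
        ("C:sbp_stable", None if sbp_min is None else
         (sbp_min >= config.sbp_min_stable and sbp_rng <= config.sbp_range_stable)),
        ("C:wcc", wcc_ok),
        ("C:crp_falling", crp_ok),
    ]
    C, c_failed = _check(c_conditions, config.missing_fails)

    # D: no high-risk infection coded
    if diagnoses is None:
        codes: list[str] = []
    elif isinstance(diagnoses, pd.DataFrame):
        codes = [] if not len(diagnoses) else list(diagnoses["icd10_code"].astype(str))
    else:
        codes = [str(c) for c in diagnoses]
    codes = [c.replace(".", "") for c in codes]
    risky = [c for c in codes
             if any(c.startswith(p) for p in config.high_risk_icd10_prefixes)]
    D = not risky
    d_failed = [f"D:high_risk_code:{c}" for c in risky]

    return CriteriaStatus(A=A, C=C, D=D, failed=a_failed + c_failed + d_failed)


def evaluate_table(table: pd.DataFrame,
                   diagnoses: pd.DataFrame | Sequence[str] | None = None,
                   config: CriteriaConfig | None = None) -> pd.DataFrame:
    """Evaluate the switch criteria on every row; adds crit_a/crit_c/crit_d
    and acd boolean columns."""
    statuses = [evaluate_switch_criteria(row, diagnoses, config)
                for row in table.to_dict("records")]
    out = table.copy()
    out["crit_a"] = [s.A for s in statuses]
    out["crit_c"] = [s.C for s in statuses]
    out["crit_d"] = [s.D for s in statuses]
    out["acd"] = [s.acd for s in statuses]
    return out


def earliest_criteria_time(table: pd.DataFrame) -> pd.Timestamp | None:
    """First grid time at which all of A, C and D hold; None if never."""
    if "acd" not in table.columns:
        raise ValueError("run evaluate_table first (no 'acd' column)")
    met = table.loc[table["acd"], "time"]
    return None if not len(met) else met.iloc[0]


# ---------------------------------------------------------------------------
# URB-65 severity score (CURB-65 with the confusion item set to zero)
# ---------------------------------------------------------------------------

@dataclass
class URB65Score:
    urea_point: int
    rr_point: int
    sbp_point: int
    age_point: int
    components_missing: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.urea_point + self.rr_point + self.sbp_point + self.age_point


def _nearest_observation(bundle: EHRBundle, patient_id: str, concept: str,
                         reference_time: pd.Timestamp,
                         window_hours: float) -> float | None:
    inv = bundle.investigations
    sub = inv[(inv["patient_id"] == patient_id) & (inv["concept"] == concept)]
    sub = sub.dropna(subset=["observed_time", "value"])
    if not len(sub):
        return None
    delta = (sub["observed_time"] - reference_time).abs()
    idx = delta.idxmin()
    if delta.loc[idx] > pd.Timedelta(hours=window_hours):
        return None
    return float(sub.loc[idx, "value"])


def compute_urb65(bundle: EHRBundle, patient_id: str,
                  reference_time: pd.Timestamp,
                  window_hours: float = 48.0,
                  age: float | None = None,
                  config: Urb65Config | None = None) -> URB65Score:
    """Severity at therapy initiation: one point each for urea > 7 mmol/L,
    respiratory rate > 30/min, systolic BP < 90 mmHg and age >= 65, using
    the observation nearest to ``reference_time`` within +/- ``window_hours``.
    The mental-confusion item of CURB-65 is structurally absent, so the
    total (0-4) is a lower bound on the full score. Missing components
    score zero and are listed."""
    config = config or Urb65Config()
    window_hours = window_hours if window_hours is not None else config.window_hours
    missing: list[str] = []

    urea = _nearest_observation(bundle, patient_id, "urea", reference_time, window_hours)
    rr = _nearest_observation(bundle, patient_id, "respiratory_rate",
                              reference_time, window_hours)
    sbp = _nearest_observation(bundle, patient_id, "systolic_bp",
                               reference_time, window_hours)
    if age is None:
        adm = bundle.admissions
        mine = adm[adm["patient_id"] == patient_id]
        if len(mine):
            covering = mine[(mine["admit_time"] <= reference_time)
                            & (mine["discharge_time"] >= reference_time)]
            pick = covering.iloc[0] if len(covering) else mine.iloc[0]
            age = float(pick["age_at_admission"])

    for name, v in (("urea", urea), ("respiratory_rate", rr),
                    ("systolic_bp", sbp), ("age", age)):
        if v is None:
            missing.append(name)

    return URB65Score(
        urea_point=int(urea is not None and urea > config.urea_threshold),
        rr_point=int(rr is not None and rr > config.rr_threshold),
        sbp_point=int(sbp is not None and sbp < config.sbp_threshold),
        age_point=int(age is not None and age >= config.age_threshold),
        components_missing=missing,
    )
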