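"""Therapy-episode linkage and consumption metrics.

Prescriptions are nodes of a per-patient graph; an edge joins two
prescriptions issued as combination therapy (started within a short window
of each other with overlapping intervals) or as a continuation (the second
starts within the continuation window of the first ending). Connected
components of this graph are *therapy episodes*: maximal periods of
uninterrupted antibacterial therapy. Length of therapy (LOT), days of
therapy (DOT) and defined daily doses (DDD) are then computed per episode,
admission or group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import LinkageConfig, DEFAULT_DDD_GRAMS
from .ehr_model import EHRBundle

DAY = pd.Timedelta(days=1)


@dataclass
class TherapyEpisode:
    """A connected component of linked prescriptions for one patient."""

    episode_id: str
    patient_id: str
    prescription_ids: list[str]           # ordered by (start_time, id)
    episode_start: pd.Timestamp           # earliest administration, else earliest start
    episode_end: pd.Timestamp             # latest administration, else latest end
    spans_admissions: bool = False
    admission_id: str | None = None       # attributed admission (first prescription's)


def classify_prescription_pair(p1: Mapping, p2: Mapping,
                               config: LinkageConfig | None = None) -> str:
    """Label an ordered pair of same-patient prescriptions.

    Returns ``"combination"`` when the start times differ by at most the
    combination window and the intervals overlap; ``"continuation"`` when
    the gap between the earlier prescription's end and the later one's
    start is at most the continuation window; ``"none"`` otherwise.
    All comparisons are closed (<=). The pair is ordered internally, so
    argument order does not matter.
    """
    config = config or LinkageConfig()
    if p1["patient_id"] != p2["patient_id"]:
        raise ValueError("prescriptions belong to different patients")
    if p2["start_time"] < p1["start_time"]:
        p1, p2 = p2, p1
    comb = pd.Timedelta(hours=config.combination_window_hours)
    cont = pd.Timedelta(hours=config.continuation_window_hours)
    starts_close = (p2["start_time"] - p1["start_time"]) <= comb
    overlap = (p2["start_time"] <= p1["end_time"]) and (p1["start_time"] <= p2["end_time"])
    if starts_close and overlap:
        return "combination"
    if (p2["start_time"] - p1["end_time"]) <= cont:
        return "continuation"
    return "none"


def _eligible_prescriptions(prescriptions: pd.DataFrame,
                            config: LinkageConfig) -> pd.DataFrame:
    rx = prescriptions
    if not config.include_cancelled:
        rx = rx[rx["status"] == "completed"]
    mask = rx["drug_code"].map(config.is_antibacterial)
    rx = rx[mask & rx["start_time"].notna() & rx["end_time"].notna()]
    return rx.sort_values(["patient_id", "start_time", "prescription_id"],
                          kind="stable").reset_index(drop=True)


def link_therapy_episodes(prescriptions: pd.DataFrame,
                          administrations: pd.DataFrame,
                          config: LinkageConfig | None = None) -> list[TherapyEpisode]:
    """Partition eligible antibacterial prescriptions into therapy episodes.

    Eligibility: completed status (unless ``include_cancelled``) and an
    antibacterial drug code. Episodes are the connected components of the
    pairwise link graph; the partition is invariant to input row order.
    """
    config = config or LinkageConfig()
    rx = _eligible_prescriptions(prescriptions, config)
    if not len(rx):
        return []

    admin_by_rx = (administrations.groupby("prescription_id")["administration_time"]
                   .agg(["min", "max"]) if len(administrations) else
                   pd.DataFrame(columns=["min", "max"]))

    episodes: list[TherapyEpisode] = []
    for patient_id, group in rx.groupby("patient_id", sort=True):
        g = nx.Graph()
        rows = group.to_dict("records")
        g.add_nodes_from(r["prescription_id"] for r in rows)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if classify_prescription_pair(rows[i], rows[j], config) != "none":
                    g.add_edge(rows[i]["prescription_id"], rows[j]["prescription_id"])
        by_id = {r["prescription_id"]: r for r in rows}
        comps = []
        for comp in nx.connected_components(g):
            members = sorted(comp, key=lambda pid: (by_id[pid]["start_time"], pid))
            comps.append(members)
        comps.sort(key=lambda m: (by_id[m[0]]["start_time"], m[0]))
        for k, members in enumerate(comps):
            admin_min = admin_by_rx["min"].reindex(members).dropna()
            admin_max = admin_by_rx["max"].reindex(members).dropna()
            start = (admin_min.min() if len(admin_min)
                     else min(by_id[m]["start_time"] for m in members))
            end = (admin_max.max() if len(admin_max)
                   else max(by_id[m]["end_time"] for m in members))
            adm_ids = {by_id[m].get("admission_id") for m in members}
            adm_ids = {a for a in adm_ids if a is not None and not pd.isna(a)}
            episodes.append(TherapyEpisode(
                episode_id=f"{patient_id}-E{k:03d}",
                patient_id=str(patient_id),
                prescription_ids=list(members),
                episode_start=start,
                episode_end=end,
                spans_admissions=len(adm_ids) > 1,
                admission_id=(by_id[members[0]].get("admission_id")
                              if adm_ids else None),
            ))
    return episodes


def episodes_frame(episodes: Sequence[TherapyEpisode]) -> pd.DataFrame:
    """Flat export form: one row per episode, prescription ids ;-joined."""
    return pd.DataFrame(
        {
            "episode_id": [e.episode_id for e in episodes],
            "patient_id": [e.patient_id for e in episodes],
            "prescription_ids": [";".join(e.prescription_ids) for e in episodes],
            "episode_start": [e.episode_start for e in episodes],
            "episode_end": [e.episode_end for e in episodes],
            "spans_admissions": [e.spans_admissions for e in episodes],
            "admission_id": [e.admission_id for e in episodes],
        }
    )


# ---------------------------------------------------------------------------
# Consumption metrics
# ---------------------------------------------------------------------------

def compute_lot(episode: TherapyEpisode, administrations: pd.DataFrame) -> float:
    """Length of therapy: days elapsed between the first and the last drug
    administration of the episode. Falls back (with a warning) to the
    prescription interval when the episode has no administrations; NaN when
    neither exists."""
    if len(administrations):
        times = administrations.loc[
            administrations["prescription_id"].isin(episode.prescription_ids),
            "administration_time"].dropna()
    else:
        times = pd.Series(dtype="datetime64[ns]")
    if len(times):
        return float((times.max() - times.min()) / DAY)
    if pd.notna(episode.episode_start) and pd.notna(episode.episode_end):
        warnings.warn(f"episode {episode.episode_id}: no administrations; "
                      "LOT falls back to prescription interval")
        return float((episode.episode_end - episode.episode_start) / DAY)
    warnings.warn(f"episode {episode.episode_id}: LOT undefined")
    return float("nan")


def compute_dot(prescriptions: pd.DataFrame,
                administrations: pd.DataFrame) -> int:
    """Days of therapy over a scope (an episode's or admission's
    prescriptions): sum over drugs of the number of distinct calendar days
    with at least one administration of that drug. Combination therapy
    counts once per drug per day, so DOT >= days with any therapy."""
    if not len(prescriptions) or not len(administrations):
        return 0
    m = administrations.merge(prescriptions[["prescription_id", "drug_code"]],
                              on="prescription_id", how="inner")
    if not len(m):
        return 0
    days = m["administration_time"].dt.normalize()
    return int(pd.DataFrame({"drug": m["drug_code"], "day": days})
               .drop_duplicates().shape[0])


@dataclass
class DDDResult:
    total_ddd: float
    per_drug: dict[str, float]
    uncounted_drugs: list[str]


_UNIT_TO_GRAMS = {"g": 1.0, "mg": 1e-3, "mcg": 1e-6, "ug": 1e-6}


def compute_ddd(prescriptions: pd.DataFrame,
                administrations: pd.DataFrame,
                ddd_table: Mapping[tuple[str, str], float] | None = None) -> DDDResult:
    """Total defined daily doses: administered grams divided by the drug's
    DDD, summed per (drug, route). Drugs missing from the table, or doses
    in non-convertible units, are reported as uncounted."""
    ddd_table = DEFAULT_DDD_GRAMS if ddd_table is None else ddd_table
    per_drug: dict[str, float] = {}
    uncounted: set[str] = set()
    if not len(administrations) or not len(prescriptions):
        return DDDResult(0.0, {}, [])
    m = administrations.merge(
        prescriptions[["prescription_id", "drug_code", "route", "dose_unit"]],
        on="prescription_id", how="inner")
    for (code, route), grp in m.groupby(["drug_code", "route"]):
        key = (code, route)
        if key not in ddd_table:
            uncounted.add(str(code))
            continue
        factors = grp["dose_unit"].str.lower().map(_UNIT_TO_GRAMS)
        if factors.isna().any():
            bad = grp.loc[factors.isna(), "dose_unit"].unique()
            warnings.warn(f"{code}/{route}: unconvertible dose unit(s) {list(bad)}; excluded")
            uncounted.add(str(code))
            grp, factors = grp[factors.notna()], factors.dropna()
        grams = float((grp["dose_given"].astype(float) * factors).sum())
        per_drug[str(code)] = per_drug.get(str(code), 0.0) + grams / ddd_table[key]
    return DDDResult(sum(per_drug.values()), per_drug, sorted(uncounted))


def load_ddd_table(path) -> dict[tuple[str, str], float]:
    """Read a delimited drug_code,route,grams_per_ddd file."""
    df = pd.read_csv(path, sep=None, engine="python")
    return {(str(r.drug_code), str(r.route)): float(r.grams_per_ddd)
            for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Grouped consumption summary
# ---------------------------------------------------------------------------

AGE_BANDS = [(18, 24), (25, 34), (35, 44), (45, 54), (55, 64),
             (65, 74), (75, 84), (85, 94), (95, 200)]


def age_band(age: float) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}" if hi < 200 else f"{lo}+"
    return "<18"


def _poisson_rate_ci(events: float, exposure: float,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) CI for a Poisson rate per unit exposure."""
    if exposure <= 0:
        return (float("nan"), float("nan"))
    lo = stats.chi2.ppf(alpha / 2, 2 * events) / 2 if events > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return (lo / exposure, hi / exposure)


def admission_features(bundle: EHRBundle) -> pd.DataFrame:
    """Admission-level covariates used as grouping keys: speciality and
    consultant team (first care episode), age band, admission method."""
    adm = bundle.admissions.copy()
    adm["los_days"] = (adm["discharge_time"] - adm["admit_time"]) / DAY
    adm["age_band"] = adm["age_at_admission"].astype(float).map(age_band)
    ce = bundle.care_episodes
    if len(ce):
        first = (ce.sort_values("start_time")
                 .groupby("admission_id")[["speciality", "consultant_team_id"]].first())
        adm = adm.merge(first, on="admission_id", how="left")
    else:
        adm["speciality"] = pd.NA
        adm["consultant_team_id"] = pd.NA
    return adm


def consumption_summary(bundle: EHRBundle,
                        episodes: Sequence[TherapyEpisode],
                        group_by: str | None = None,
                        ddd_table: Mapping[tuple[str, str], float] | None = None,
                        config: LinkageConfig | None = None) -> pd.DataFrame:
    """Grouped consumption table: admissions, % with >=1 antibacterial
    prescription, LOS and DOT-rate per 1000 bed-days (exact Poisson CI),
    prescriptions, episodes, LOT and DOT summaries and total DDD. Always
    includes an ``all`` row equal to the ungrouped computation.

    ``group_by`` may be any column of :func:`admission_features`
    (``speciality``, ``consultant_team_id``, ``age_band``, ``method``).
    """
    config = config or LinkageConfig()
    adm = admission_features(bundle)
    rx = _eligible_prescriptions(bundle.prescriptions, config)
    ad = bundle.administrations

    # per-admission prescription/episode attribution
    rx_per_adm = rx.groupby("admission_id")["prescription_id"].agg(list)
    ep_by_adm: dict[str, list[TherapyEpisode]] = {}
    for e in episodes:
        if e.admission_id is not None:
            ep_by_adm.setdefault(e.admission_id, []).append(e)

    lot_by_adm = {a: sum(compute_lot(e, ad) for e in eps)
                  for a, eps in ep_by_adm.items()}
    dot_by_adm = {}
    for a, pids in rx_per_adm.items():
        dot_by_adm[a] = compute_dot(rx[rx["prescription_id"].isin(pids)], ad)

    adm = adm.assign(
        n_rx=adm["admission_id"].map(rx_per_adm.map(len)).fillna(0).astype(int),
        n_episodes=adm["admission_id"].map(lambda a: len(ep_by_adm.get(a, []))),
        lot=adm["admission_id"].map(lot_by_adm),
        dot=adm["admission_id"].map(dot_by_adm).fillna(0.0),
    )
    adm["has_rx"] = adm["n_rx"] > 0

    def _summarize(sub: pd.DataFrame, label: str) -> dict:
        bed_days = float(sub["los_days"].sum())
        total_dot = float(sub["dot"].sum())
        treated = sub[sub["has_rx"]]
        lot = treated["lot"].dropna()
        dot_t = treated["dot"]
        rate_lo, rate_hi = _poisson_rate_ci(total_dot, bed_days)
        sub_rx_ids = [pid for pids in rx_per_adm.reindex(sub["admission_id"]).dropna()
                      for pid in pids]
        sub_rx = rx[rx["prescription_id"].isin(sub_rx_ids)]
        ddd = compute_ddd(sub_rx, ad, ddd_table)
        n_adm = int(len(sub))
        return {
            "group": label,
            "n_patients": int(sub["patient_id"].nunique()),
            "n_admissions": n_adm,
            "los_mean": float(sub["los_days"].mean()) if n_adm else 0.0,
            "los_sd": float(sub["los_days"].std()) if n_adm > 1 else 0.0,
            "los_q25": float(sub["los_days"].quantile(0.25)) if n_adm else float("nan"),
            "los_q75": float(sub["los_days"].quantile(0.75)) if n_adm else float("nan"),
            "dot_per_1000_bed_days": 1000 * total_dot / bed_days if bed_days else 0.0,
            "dot_rate_ci_low": 1000 * rate_lo,
            "dot_rate_ci_high": 1000 * rate_hi,
            "n_admissions_with_rx": int(sub["has_rx"].sum()),
            "pct_admissions_with_rx": 100 * float(sub["has_rx"].mean()) if n_adm else 0.0,
            "n_prescriptions": int(len(sub_rx)),
            "n_episodes": int(sub["n_episodes"].fillna(0).sum()),
            "lot_mean": float(lot.mean()) if len(lot) else float("nan"),
            "lot_sd": float(lot.std()) if len(lot) > 1 else 0.0,
            "lot_q25": float(lot.quantile(0.25)) if len(lot) else float("nan"),
            "lot_q75": float(lot.quantile(0.75)) if len(lot) else float("nan"),
            "dot_mean": float(dot_t.mean()) if len(dot_t) else float("nan"),
            "dot_sd": float(dot_t.std()) if len(dot_t) > 1 else 0.0,
            "lot_per_1000_admissions": 1000 * float(lot.sum()) / n_adm if n_adm else 0.0,
            "dot_per_1000_admissions": 1000 * total_dot / n_adm if n_adm else 0.0,
            "ddd_total": ddd.total_ddd,
        }

    rows = [_summarize(adm, "all")]
    if group_by is not None:
        if group_by not in adm.columns:
            raise KeyError(f"unknown grouping key {group_by!r}")
        for key, sub in adm.groupby(group_by, dropna=False):
            rows.append(_summarize(sub, str(key)))
    return pd.DataFrame(rows)
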