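"""Stewardship metrics built on top of linked therapy episodes.

Covers: extraction of IV prescription sequences and their conversion to
oral therapy; the delay between switch criteria being met and the actual
conversion (or end of therapy); stop/continue/switch outcomes of the
initial drug choice; congruence of the initial regimen with empirical
prescribing guidelines stratified by severity; culture-before-treatment
linkage; and grouped estimates with 95% confidence intervals (Wilson for
proportions, t for means) for team- and speciality-level comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import CriteriaConfig, CultureConfig, GuidelineSet, LinkageConfig
from .ehr_model import EHRBundle
from .linkage import DAY, TherapyEpisode
from .therapy_table import (build_therapy_table, earliest_criteria_time,
                            evaluate_table)


# ---------------------------------------------------------------------------
# IV sequences and switch timing
# ---------------------------------------------------------------------------

@dataclass
class IVSequence:
    sequence_id: str
    episode_id: str
    prescription_ids: list[str]
    seq_start: pd.Timestamp
    seq_end: pd.Timestamp
    outcome: str                           # converted_to_oral | continued_to_end
    conversion_time: pd.Timestamp | None = None
    criteria_met_time: pd.Timestamp | None = None
    delay_days: float | None = None


def extract_iv_sequences(episode: TherapyEpisode,
                         prescriptions: pd.DataFrame) -> list[IVSequence]:
    """Maximal runs of consecutive IV prescriptions in episode time order.

    A run is ``converted_to_oral`` when the next prescription in the
    episode is oral (conversion time = that prescription's start);
    otherwise it is ``continued_to_end``. An all-oral episode yields no
    sequences; an IV->oral->IV episode yields two (the first converted,
    the second continued).
    """
    rx = prescriptions[prescriptions["prescription_id"].isin(episode.prescription_ids)]
    rx = rx.sort_values(["start_time", "prescription_id"], kind="stable")
    sequences: list[IVSequence] = []
    run: list = []

    def close(next_route: str | None, next_start) -> None:
        nonlocal run
        if not run:
            return
        converted = next_route == "oral"
        sequences.append(IVSequence(
            sequence_id=f"{episode.episode_id}-S{len(sequences)}",
            episode_id=episode.episode_id,
            prescription_ids=[r.prescription_id for r in run],
            seq_start=min(r.start_time for r in run),
            seq_end=max(r.end_time for r in run),
            outcome="converted_to_oral" if converted else "continued_to_end",
            conversion_time=next_start if converted else None,
        ))
        run = []

    for row in rx.itertuples():
        if row.route == "IV":
            run.append(row)
        else:
            close(row.route, row.start_time)
    close(None, None)
    return sequences


def compute_switch_delay(sequence: IVSequence,
                         criteria_time: pd.Timestamp | None) -> float | None:
    """Days between switch criteria being met and the conversion (for
    converted sequences) or the end of IV therapy (for never-switched
    ones). None when criteria were never met before the event."""
    if criteria_time is None or pd.isna(criteria_time):
        return None
    event = (sequence.conversion_time
             if sequence.outcome == "converted_to_oral" else sequence.seq_end)
    delay = (event - criteria_time) / DAY
    return float(delay) if delay >= 0 else None


def iv_switch_summary(episodes: Sequence[TherapyEpisode],
                      bundle: EHRBundle,
                      criteria_config: CriteriaConfig | None = None) -> pd.DataFrame:
    """Sequence-level table: outcome, conversion time, earliest time the
    ACD criteria were met in the episode, and the resulting delay.

    The therapy table is built and evaluated once per episode that
    contains IV therapy; admission diagnoses feed criterion D.
    """
    criteria_config = criteria_config or CriteriaConfig()
    dx = bundle.diagnoses
    records = []
    for ep in episodes:
        seqs = extract_iv_sequences(ep, bundle.prescriptions)
        if not seqs:
            continue
        ep_dx = (dx[dx["admission_id"] == ep.admission_id]
                 if ep.admission_id is not None and len(dx) else None)
        table = evaluate_table(build_therapy_table(ep, bundle, criteria_config),
                               ep_dx, criteria_config)
        t_met = earliest_criteria_time(table)
        for s in seqs:
            s.criteria_met_time = t_met
            s.delay_days = compute_switch_delay(s, t_met)
            records.append({
                "sequence_id": s.sequence_id,
                "episode_id": s.episode_id,
                "admission_id": ep.admission_id,
                "patient_id": ep.patient_id,
                "seq_start": s.seq_start,
                "seq_end": s.seq_end,
                "outcome": s.outcome,
                "converted": s.outcome == "converted_to_oral",
                "conversion_time": s.conversion_time,
                "criteria_met_time": t_met,
                "criteria_met_before_event": s.delay_days is not None,
                "delay_days": s.delay_days,
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Changes of therapy
# ---------------------------------------------------------------------------

@dataclass
class TransitionOutcome:
    episode_id: str
    focal_drug: str
    outcome: str                      # stopped | continued | switched
    successor_drug: str | None
    duration_before_change: float     # days


def classify_initial_transition(episode: TherapyEpisode,
                                focal_drug: str,
                                prescriptions: pd.DataFrame,
                                config: LinkageConfig | None = None) -> TransitionOutcome:
    """What happened at the end of the episode-initiating run of
    ``focal_drug``: stopped (nothing follows), continued (the same drug is
    re-prescribed) or switched (a different drug follows, recorded as the
    successor). Duration is from episode start to the end of the first
    focal prescription, in days."""
    config = config or LinkageConfig()
    rx = prescriptions[prescriptions["prescription_id"].isin(episode.prescription_ids)]
    rx = rx.sort_values(["start_time", "prescription_id"], kind="stable")
    first_start = rx["start_time"].iloc[0]
    comb = pd.Timedelta(hours=config.combination_window_hours)
    initial = rx[rx["start_time"] <= first_start + comb]
    if focal_drug not in set(initial["drug_code"]):
        raise ValueError(f"{focal_drug} is not part of the initial regimen")
    focal_rx = initial[initial["drug_code"] == focal_drug].iloc[0]
    duration = float((focal_rx["end_time"] - first_start) / DAY)

    followers = rx[rx["start_time"] > first_start + comb]
    if not len(followers):
        return TransitionOutcome(episode.episode_id, focal_drug, "stopped",
                                 None, duration)
    nxt = followers.iloc[0]
    if nxt["drug_code"] == focal_drug:
        return TransitionOutcome(episode.episode_id, focal_drug, "continued",
                                 None, duration)
    return TransitionOutcome(episode.episode_id, focal_drug, "switched",
                             str(nxt["drug_code"]), duration)


def transition_mix(episodes: Sequence[TherapyEpisode],
                   focal_drug: str,
                   prescriptions: pd.DataFrame,
                   config: LinkageConfig | None = None) -> pd.DataFrame:
    """Outcome mix for all episodes initiated with ``focal_drug``:
    proportion and mean duration per (outcome, successor) combination."""
    rows = []
    for ep in episodes:
        rx = prescriptions[prescriptions["prescription_id"].isin(ep.prescription_ids)]
        rx = rx.sort_values(["start_time", "prescription_id"], kind="stable")
        if not len(rx):
            continue
        cfg = config or LinkageConfig()
        comb = pd.Timedelta(hours=cfg.combination_window_hours)
        initial = rx[rx["start_time"] <= rx["start_time"].iloc[0] + comb]
        if focal_drug not in set(initial["drug_code"]):
            continue
        t = classify_initial_transition(ep, focal_drug, prescriptions, config)
        rows.append({"episode_id": t.episode_id, "outcome": t.outcome,
                     "successor_drug": t.successor_drug,
                     "duration_before_change": t.duration_before_change})
    df = pd.DataFrame(rows)
    if not len(df):
        return pd.DataFrame(columns=["outcome", "successor_drug", "n",
                                     "proportion", "mean_duration_days"])
    out = (df.groupby(["outcome", "successor_drug"], dropna=False)
             .agg(n=("episode_id", "size"),
                  mean_duration_days=("duration_before_change", "mean"))
             .reset_index())
    out["proportion"] = out["n"] / len(df)
    return out.sort_values("n", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Guideline congruence
# ---------------------------------------------------------------------------

@dataclass
class CongruenceResult:
    episode_id: str
    severity: int
    initial_regimen: frozenset[str]
    category: str   # recommended | allergy_alternative | higher_severity_regimen
    #               | lower_severity_regimen | other


def initial_regimen(episode: TherapyEpisode,
                    prescriptions: pd.DataFrame,
                    config: LinkageConfig | None = None) -> frozenset[str]:
    """Drug codes of the episode's first combination group: prescriptions
    starting within the combination window of the first start."""
    config = config or LinkageConfig()
    rx = prescriptions[prescriptions["prescription_id"].isin(episode.prescription_ids)]
    rx = rx.sort_values(["start_time", "prescription_id"], kind="stable")
    if not len(rx):
        return frozenset()
    first = rx["start_time"].iloc[0]
    comb = pd.Timedelta(hours=config.combination_window_hours)
    return frozenset(rx.loc[rx["start_time"] <= first + comb, "drug_code"])


def classify_congruence(episode_id: str,
                        regimen: frozenset[str] | set[str],
                        severity: int,
                        guideline: GuidelineSet) -> CongruenceResult:
    """Exact set-match of the initial regimen against the guideline.

    Matching the patient's own severity stratum yields ``recommended``
    (or ``allergy_alternative``); an exact match only to a more severe
    stratum yields ``higher_severity_regimen``; only to a less severe one,
    ``lower_severity_regimen``; no match, ``other``. Categories are
    mutually exclusive, with own-stratum taking precedence and higher
    before lower when both match."""
    regimen = frozenset(regimen)
    own = guideline.stratum_index(severity)
    strata = guideline.strata
    if regimen in strata[own].first_line_regimens:
        cat = "recommended"
    elif regimen in strata[own].allergy_regimens:
        cat = "allergy_alternative"
    elif any(regimen in strata[i].all_regimens() for i in range(own + 1, len(strata))):
        cat = "higher_severity_regimen"
    elif any(regimen in strata[i].all_regimens() for i in range(own)):
        cat = "lower_severity_regimen"
    else:
        cat = "other"
    return CongruenceResult(episode_id, int(severity), regimen, cat)


def congruence_table(episodes: pd.DataFrame,
                     severity_col: str = "severity",
                     regimen_col: str = "regimen_label",
                     min_count: int = 0) -> pd.DataFrame:
    """Cross-tabulate regimens by severity stratum.

    ``episodes`` has one row per therapy episode. Output: one row per
    regimen label (rows whose total is below ``min_count`` collapse into
    "Other") plus a Total row; per severity column, counts and column
    percentages rounded to one decimal."""
    df = episodes[[regimen_col, severity_col]].copy()
    totals_by_regimen = df.groupby(regimen_col)[severity_col].size()
    if min_count > 0:
        small = set(totals_by_regimen[totals_by_regimen < min_count].index)
        df.loc[df[regimen_col].isin(small), regimen_col] = "Other"
    ct = pd.crosstab(df[regimen_col], df[severity_col])
    out = pd.DataFrame(index=ct.index)
    for col in ct.columns:
        out[f"n_{col}"] = ct[col]
        out[f"pct_{col}"] = (100 * ct[col] / ct[col].sum()).round(1)
    total = {f"n_{c}": int(ct[c].sum()) for c in ct.columns}
    total |= {f"pct_{c}": 100.0 for c in ct.columns}
    out.loc["Total"] = total
    for col in [c for c in out.columns if c.startswith("n_")]:
        out[col] = out[col].astype(int)
    return out


# ---------------------------------------------------------------------------
# Culture-before-treatment linkage
# ---------------------------------------------------------------------------

@dataclass
class CultureLinkResult:
    prescription_id: str
    episode_id: str
    linked: bool
    matched_specimen_ids: list[str]
    specimen_scope: str


def link_cultures(episodes: Sequence[TherapyEpisode],
                  prescriptions: pd.DataFrame,
                  specimens: pd.DataFrame,
                  config: CultureConfig | None = None,
                  scope: str = "all_qualifying") -> pd.DataFrame:
    """Flag each prescription whose therapy episode started with a
    qualifying microbial specimen collected in the look-back window
    ``[episode_start - window_hours_before, episode_start + grace]``.

    ``scope`` is ``all_qualifying`` (blood, drains, respiratory,
    intravascular devices, CNS, aspirates, tissue/bone) or ``blood_only``.
    """
    config = config or CultureConfig()
    if scope == "blood_only":
        groups = {"blood"}
    elif scope == "all_qualifying":
        groups = set(config.qualifying_groups)
    else:
        raise ValueError(f"unknown specimen scope {scope!r}")
    before = pd.Timedelta(hours=config.window_hours_before)
    grace = pd.Timedelta(hours=config.grace_hours_after)

    sp = specimens[specimens["specimen_group"].isin(groups)]
    rows = []
    for ep in episodes:
        mine = sp[sp["patient_id"] == ep.patient_id]
        in_window = mine[(mine["collection_time"] >= ep.episode_start - before)
                         & (mine["collection_time"] <= ep.episode_start + grace)]
        matched = list(in_window["specimen_id"])
        for pid in ep.prescription_ids:
            rows.append({"prescription_id": pid, "episode_id": ep.episode_id,
                         "linked": bool(matched),
                         "matched_specimen_ids": ";".join(matched),
                         "specimen_scope": scope})
    return pd.DataFrame(rows, columns=["prescription_id", "episode_id", "linked",
                                       "matched_specimen_ids", "specimen_scope"])


# ---------------------------------------------------------------------------
# Grouped estimates with confidence intervals
# ---------------------------------------------------------------------------

def aggregate_with_ci(observations: pd.DataFrame,
                      value_col: str,
                      group_cols: Sequence[str] | None = None,
                      kind: str = "proportion",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Point and 95% CI estimates per group.

    ``kind="proportion"``: ``value_col`` holds 0/1 flags; Wilson interval.
    ``kind="mean"``: real values; t-based interval (zero width at n=1 or
    constant values). Groups with n=0 are omitted. Output is ranked by
    ascending estimate within the first grouping key, matching the
    team-by-speciality comparison layout.
    """
    df = observations.dropna(subset=[value_col])
    group_cols = list(group_cols or [])
    grouped = df.groupby(group_cols, dropna=False) if group_cols else [((), df)]
    rows = []
    for key, sub in grouped:
        n = len(sub)
        if n == 0:
            continue
        vals = sub[value_col].astype(float)
        if kind == "proportion":
            successes = int(vals.sum())
            est = successes / n
            lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
        elif kind == "mean":
            est = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            half = (stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
                    if n > 1 and sd > 0 else 0.0)
            lo, hi = est - half, est + half
        else:
            raise ValueError(f"unknown kind {kind!r}")
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_cols, key)) |
                    {"n": n, "estimate": float(est),
                     "ci_low": float(lo), "ci_high": float(hi)})
    out = pd.DataFrame(rows)
    if len(out) and group_cols:
        out = out.sort_values([group_cols[0], "estimate"],
                              kind="stable").reset_index(drop=True)
    return out
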