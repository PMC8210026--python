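"""End-to-end pipeline: load -> validate -> link -> therapy tables -> metrics.

Each metric family is independently runnable; :func:`run_pipeline` chains
them and writes delimited tables plus JSON summaries to an output
directory, suitable for audit-and-feedback reporting by speciality, ward
or consultant team.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .config import (CriteriaConfig, CultureConfig, GuidelineSet, LinkageConfig,
                     cap_guideline, demo_breakpoints, demo_category_map)
from .ehr_model import EHRBundle, load_ehr_bundle, validate_bundle
from .linkage import (TherapyEpisode, consumption_summary, episodes_frame,
                      link_therapy_episodes)
from .micro_amr import profile_isolates
from .stewardship import (aggregate_with_ci, classify_congruence,
                          congruence_table, initial_regimen, iv_switch_summary,
                          link_cultures)
from .therapy_table import compute_urb65

ALL_METRICS = ("consumption", "switch", "congruence", "culture", "mdr")


@dataclass
class RunConfig:
    table_paths: dict[str, str]
    out_dir: str
    metrics: tuple[str, ...] = ALL_METRICS
    group_by: str = "speciality"
    seed: int = 0
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    culture: CultureConfig = field(default_factory=CultureConfig)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _episode_groups(bundle: EHRBundle,
                    episodes: Sequence[TherapyEpisode]) -> pd.DataFrame:
    """Episode-level grouping keys (speciality, team) via the attributed
    admission's first care episode."""
    ce = bundle.care_episodes
    first = (ce.sort_values("start_time")
             .groupby("admission_id")[["speciality", "consultant_team_id"]]
             .first()) if len(ce) else pd.DataFrame()
    rows = []
    for e in episodes:
        spec = team = None
        if e.admission_id is not None and e.admission_id in first.index:
            spec = first.loc[e.admission_id, "speciality"]
            team = first.loc[e.admission_id, "consultant_team_id"]
        rows.append({"episode_id": e.episode_id, "admission_id": e.admission_id,
                     "speciality": spec, "consultant_team_id": team})
    return pd.DataFrame(rows)


def congruence_metrics(bundle: EHRBundle,
                       episodes: Sequence[TherapyEpisode],
                       guideline: GuidelineSet | None = None,
                       linkage_config: LinkageConfig | None = None,
                       indication_dx_prefix: str = "J18") -> pd.DataFrame:
    """Classify guideline congruence of the initial regimen for episodes
    whose admission carries a matching indication diagnosis (community-
    acquired pneumonia by default), using the severity score linked within
    48 h of initiation."""
    guideline = guideline or cap_guideline()
    dx = bundle.diagnoses
    cap_admissions = (set(dx.loc[dx["icd10_code"].astype(str)
                                 .str.startswith(indication_dx_prefix),
                                 "admission_id"]) if len(dx) else set())
    rows = []
    for e in episodes:
        if e.admission_id not in cap_admissions:
            continue
        urb = compute_urb65(bundle, e.patient_id, e.episode_start)
        regimen = initial_regimen(e, bundle.prescriptions, linkage_config)
        res = classify_congruence(e.episode_id, regimen, urb.total, guideline)
        rows.append({"episode_id": e.episode_id, "severity": res.severity,
                     "regimen_label": ";".join(sorted(res.initial_regimen)),
                     "category": res.category})
    return pd.DataFrame(rows, columns=["episode_id", "severity",
                                       "regimen_label", "category"])


def run_pipeline(config: RunConfig,
                 bundle: EHRBundle | None = None) -> dict[str, Path]:
    """Execute the pipeline and write report artifacts; returns written
    paths. Any stage failure raises :class:`PipelineError` naming the
    stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    if bundle is None:
        bundle = _stage("load", lambda: load_ehr_bundle(config.table_paths,
                                                        config.linkage))
    report = _stage("validate", lambda: validate_bundle(bundle))
    (out / "validation.json").write_text(report.to_json())
    written["validation"] = out / "validation.json"

    episodes = _stage("link", lambda: link_therapy_episodes(
        bundle.prescriptions, bundle.administrations, config.linkage))
    ep_path = out / "therapy_episodes.csv"
    episodes_frame(episodes).to_csv(ep_path, index=False)
    written["episodes"] = ep_path
    groups = _episode_groups(bundle, episodes)

    if "consumption" in config.metrics:
        df = _stage("consumption", lambda: consumption_summary(
            bundle, episodes, group_by=config.group_by, config=config.linkage))
        df.to_csv(out / "consumption_summary.csv", index=False)
        written["consumption"] = out / "consumption_summary.csv"

    if "switch" in config.metrics:
        seq = _stage("switch", lambda: iv_switch_summary(
            episodes, bundle, config.criteria))
        seq.to_csv(out / "iv_switch_sequences.csv", index=False)
        written["switch"] = out / "iv_switch_sequences.csv"
        if len(seq):
            seq = seq.merge(groups, on="episode_id", how="left")
            conv = aggregate_with_ci(seq, "converted",
                                     ["speciality", "consultant_team_id"],
                                     kind="proportion")
            conv.to_csv(out / "iv_conversion_by_team.csv", index=False)
            written["switch_groups"] = out / "iv_conversion_by_team.csv"
            delays = seq.dropna(subset=["delay_days"])
            summary = {
                "n_sequences": int(len(seq)),
                "n_converted": int(seq["converted"].sum()),
                "prop_converted": float(seq["converted"].mean()),
                "n_with_delay": int(len(delays)),
                "delay_mean_days": (float(delays["delay_days"].mean())
                                    if len(delays) else None),
                "delay_median_days": (float(delays["delay_days"].median())
                                      if len(delays) else None),
            }
            (out / "iv_switch_summary.json").write_text(json.dumps(summary, indent=2))
            written["switch_summary"] = out / "iv_switch_summary.json"

    if "congruence" in config.metrics:
        cong = _stage("congruence", lambda: congruence_metrics(
            bundle, episodes, linkage_config=config.linkage))
        cong.to_csv(out / "congruence_episodes.csv", index=False)
        written["congruence"] = out / "congruence_episodes.csv"
        if len(cong):
            congruence_table(cong).to_csv(out / "congruence_table.csv")
            written["congruence_table"] = out / "congruence_table.csv"

    if "culture" in config.metrics:
        links = _stage("culture", lambda: link_cultures(
            episodes, bundle.prescriptions, bundle.specimens, config.culture))
        links.to_csv(out / "culture_links.csv", index=False)
        written["culture"] = out / "culture_links.csv"
        if len(links):
            ep_links = links.drop_duplicates("episode_id").merge(
                groups, on="episode_id", how="left")
            props = aggregate_with_ci(ep_links, "linked", ["speciality"],
                                      kind="proportion")
            props.to_csv(out / "culture_by_speciality.csv", index=False)
            written["culture_groups"] = out / "culture_by_speciality.csv"

    if "mdr" in config.metrics:
        mdr = _stage("mdr", lambda: profile_isolates(
            bundle, demo_breakpoints(), demo_category_map()))
        mdr.to_csv(out / "mdr_profiles.csv", index=False)
        written["mdr"] = out / "mdr_profiles.csv"

    log = {"version": __version__, "seed": config.seed,
           "metrics": list(config.metrics), "group_by": config.group_by,
           "linkage": asdict(config.linkage),
           "n_episodes": len(episodes),
           "tables": {k: str(v) for k, v in config.table_paths.items()}}
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    written["log"] = out / "run_log.json"
    return written
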