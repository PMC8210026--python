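"""Configuration objects for the stewardship analytics pipeline.

Every clinically contestable constant (linkage windows, switch-criteria
thresholds, culture look-back, guideline regimens, breakpoints) lives here
rather than in the algorithms, so a hospital can adapt the pipeline to its
own formulary and policies by editing a YAML file instead of code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

# ---------------------------------------------------------------------------
# Drug vocabulary (ATC codes for the agents used in examples and simulation)
# ---------------------------------------------------------------------------

ATC = {
    "amoxicillin": "J01CA04",
    "co-amoxiclav": "J01CR02",
    "benzylpenicillin": "J01CE01",
    "piperacillin/tazobactam": "J01CR05",
    "ceftriaxone": "J01DD04",
    "meropenem": "J01DH02",
    "clarithromycin": "J01FA09",
    "azithromycin": "J01FA10",
    "doxycycline": "J01AA02",
    "ciprofloxacin": "J01MA02",
    "moxifloxacin": "J01MA14",
    "vancomycin": "J01XA01",
    "metronidazole": "J01XD01",
    "gentamicin": "J01GB03",
    "trimethoprim": "J01EA01",
    "flucloxacillin": "J01CF05",
}

ATC_NAME = {v: k for k, v in ATC.items()}


@dataclass
class LinkageConfig:
    """Windows governing how prescriptions chain into therapy episodes.

    combination_window_hours
        Two prescriptions started within this window whose intervals
        overlap are treated as combination therapy (default 6 h).
    continuation_window_hours
        A prescription starting no more than this many hours after a
        previous one ends continues the same episode (default 36 h).
    Both comparisons are closed (<=).
    """

    combination_window_hours: float = 6.0
    continuation_window_hours: float = 36.0
    antibacterial_code_prefixes: tuple[str, ...] = ("J01",)
    include_cancelled: bool = False

    def is_antibacterial(self, drug_code: str) -> bool:
        return any(str(drug_code).startswith(p) for p in self.antibacterial_code_prefixes)


# High-risk / deep-seated infection list for switch criterion D,
# expressed as ICD-10 prefixes. Editable; covers liver abscess,
# osteomyelitis and septic arthritis, empyema and lung abscess,
# S. aureus bacteraemia, necrotizing fasciitis, neutropenia,
# device infections, meningitis/encephalitis, intracranial abscess,
# mediastinitis, endocarditis and cystic fibrosis.
HIGH_RISK_ICD10_PREFIXES: tuple[str, ...] = (
    "K750",        # liver abscess
    "M86", "M00",  # osteomyelitis, septic arthritis
    "J85", "J86",  # lung abscess / empyema (incl. cavitating pneumonia)
    "A410", "A411",  # staphylococcal sepsis
    "M726",        # necrotizing fasciitis
    "D70",         # neutropenia
    "T826", "T827", "T845", "T846", "T847",  # infected implants/prostheses
    "G00", "G01", "G02", "G03", "G04", "G05", "G06", "G07",  # meningitis/encephalitis/abscess
    "J985",        # mediastinitis
    "I33", "I38", "I39",  # endocarditis
    "E84",         # cystic fibrosis
    "J47",         # bronchiectasis
)


@dataclass
class CriteriaConfig:
    """Thresholds and look-back windows for the ABCD switch criteria.

    Criterion B (able to take oral medication) is structurally absent:
    it cannot be assessed from structured inpatient records.
    """

    temp_window_hours: float = 48.0
    temp_low: float = 36.0
    temp_high: float = 38.0
    hr_window_hours: float = 12.0
    hr_max: float = 90.0
    rr_window_hours: float = 24.0
    rr_max: float = 20.0
    sbp_window_hours: float = 24.0
    sbp_min_stable: float = 90.0
    sbp_range_stable: float = 40.0
    wcc_low: float = 4.0
    wcc_high: float = 12.0
    wcc_trend_window_hours: float = 72.0
    crp_peak_window_hours: float = 72.0
    crp_relative_drop: float = 0.0   # any decrease from 72 h peak counts as falling
    missing_fails: bool = True       # conservative: a missing marker fails its criterion
    high_risk_icd10_prefixes: tuple[str, ...] = HIGH_RISK_ICD10_PREFIXES


@dataclass
class Urb65Config:
    """Severity score thresholds (CURB-65 without the confusion item)."""

    urea_threshold: float = 7.0    # mmol/L, strictly greater scores a point
    rr_threshold: float = 30.0     # breaths/min, strictly greater
    sbp_threshold: float = 90.0    # mmHg, strictly lower
    age_threshold: int = 65        # years, >= scores a point
    window_hours: float = 48.0     # observation search window around initiation


@dataclass
class CultureConfig:
    """Window and specimen scope for culture-before-treatment linkage."""

    window_hours_before: float = 72.0
    grace_hours_after: float = 0.0
    qualifying_groups: tuple[str, ...] = (
        "blood", "drain", "respiratory", "intravascular_device",
        "cns", "aspirate", "tissue_bone",
    )


# ---------------------------------------------------------------------------
# Guidelines
# ---------------------------------------------------------------------------

@dataclass
class GuidelineStratum:
    severity_key: str
    min_severity: int
    first_line_regimens: tuple[frozenset[str], ...]
    allergy_regimens: tuple[frozenset[str], ...] = ()

    def all_regimens(self) -> tuple[frozenset[str], ...]:
        return self.first_line_regimens + self.allergy_regimens


@dataclass
class GuidelineSet:
    """Empirical-therapy recommendations for one indication, ordered by severity."""

    indication: str
    strata: tuple[GuidelineStratum, ...]

    def stratum_for(self, severity: int) -> GuidelineStratum:
        chosen = self.strata[0]
        for s in self.strata:
            if severity >= s.min_severity:
                chosen = s
        return chosen

    def stratum_index(self, severity: int) -> int:
        return self.strata.index(self.stratum_for(severity))


def cap_guideline() -> GuidelineSet:
    """Community-acquired pneumonia guideline used as the worked example.

    Score 0-1: amoxicillin (doxycycline if penicillin-allergic).
    Score 2: amoxicillin + clarithromycin, or benzylpenicillin +
    clarithromycin (moxifloxacin if allergic).
    Score 3+: co-amoxiclav + clarithromycin (moxifloxacin if allergic).
    """
    fz = frozenset
    return GuidelineSet(
        indication="CAP",
        strata=(
            GuidelineStratum(
                "0-1", 0,
                first_line_regimens=(fz({ATC["amoxicillin"]}),),
                allergy_regimens=(fz({ATC["doxycycline"]}),),
            ),
            GuidelineStratum(
                "2", 2,
                first_line_regimens=(
                    fz({ATC["amoxicillin"], ATC["clarithromycin"]}),
                    fz({ATC["benzylpenicillin"], ATC["clarithromycin"]}),
                ),
                allergy_regimens=(fz({ATC["moxifloxacin"]}),),
            ),
            GuidelineStratum(
                "3+", 3,
                first_line_regimens=(fz({ATC["co-amoxiclav"], ATC["clarithromycin"]}),),
                allergy_regimens=(fz({ATC["moxifloxacin"]}),),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Defined daily doses (grams per DDD, WHO ATC/DDD index subset for the
# bundled drug vocabulary; demonstration subset, not a full reference table)
# ---------------------------------------------------------------------------

DEFAULT_DDD_GRAMS: dict[tuple[str, str], float] = {
    (ATC["amoxicillin"], "oral"): 1.5,
    (ATC["amoxicillin"], "IV"): 3.0,
    (ATC["co-amoxiclav"], "oral"): 1.5,
    (ATC["co-amoxiclav"], "IV"): 3.0,
    (ATC["benzylpenicillin"], "IV"): 3.6,
    (ATC["piperacillin/tazobactam"], "IV"): 14.0,
    (ATC["ceftriaxone"], "IV"): 2.0,
    (ATC["meropenem"], "IV"): 3.0,
    (ATC["clarithromycin"], "oral"): 0.5,
    (ATC["clarithromycin"], "IV"): 1.0,
    (ATC["azithromycin"], "oral"): 0.3,
    (ATC["doxycycline"], "oral"): 0.1,
    (ATC["ciprofloxacin"], "oral"): 1.0,
    (ATC["ciprofloxacin"], "IV"): 0.8,
    (ATC["moxifloxacin"], "oral"): 0.4,
    (ATC["moxifloxacin"], "IV"): 0.4,
    (ATC["vancomycin"], "IV"): 2.0,
    (ATC["metronidazole"], "oral"): 1.5,
    (ATC["metronidazole"], "IV"): 1.5,
    (ATC["gentamicin"], "IV"): 0.24,
    (ATC["trimethoprim"], "oral"): 0.4,
    (ATC["flucloxacillin"], "oral"): 2.0,
    (ATC["flucloxacillin"], "IV"): 2.0,
}


# ---------------------------------------------------------------------------
# Susceptibility interpretation (demonstration breakpoint subset) and
# antimicrobial categories for resistance profiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointRule:
    """One interpretive rule: organism group x agent x measure type.

    For MIC (mg/L): value <= s_bound -> S, value > r_bound -> R, else I.
    For disc zones (mm) the direction flips: value >= s_bound -> S,
    value < r_bound -> R, else I.
    """

    organism_group: str
    agent_code: str
    measure_type: str  # "MIC" | "disc_zone"
    s_bound: float
    r_bound: float


def demo_breakpoints() -> tuple[BreakpointRule, ...]:
    """Small demonstration breakpoint table for Enterobacterales-like and
    staphylococcus-like organism groups; a real deployment loads a
    versioned file."""
    rows = [
        ("enterobacterales", ATC["amoxicillin"], "MIC", 8.0, 8.0),
        ("enterobacterales", ATC["co-amoxiclav"], "MIC", 8.0, 8.0),
        ("enterobacterales", ATC["piperacillin/tazobactam"], "MIC", 8.0, 16.0),
        ("enterobacterales", ATC["ceftriaxone"], "MIC", 1.0, 2.0),
        ("enterobacterales", ATC["meropenem"], "MIC", 2.0, 8.0),
        ("enterobacterales", ATC["ciprofloxacin"], "MIC", 0.25, 0.5),
        ("enterobacterales", ATC["gentamicin"], "MIC", 2.0, 2.0),
        ("enterobacterales", ATC["trimethoprim"], "MIC", 4.0, 4.0),
        ("staphylococcus", ATC["flucloxacillin"], "MIC", 2.0, 2.0),
        ("staphylococcus", ATC["vancomycin"], "MIC", 2.0, 2.0),
        ("staphylococcus", ATC["clarithromycin"], "MIC", 1.0, 2.0),
        ("staphylococcus", ATC["doxycycline"], "MIC", 1.0, 2.0),
        ("staphylococcus", ATC["gentamicin"], "disc_zone", 18.0, 18.0),
    ]
    return tuple(BreakpointRule(*r) for r in rows)


def demo_category_map() -> dict[str, dict[str, str]]:
    """agent code -> antimicrobial category, per organism group.

    Categories follow the resistance-profiling convention of grouping
    agents by class; an isolate non-susceptible to >=1 agent in >=3
    categories is multidrug-resistant.
    """
    e = {
        ATC["amoxicillin"]: "aminopenicillins",
        ATC["co-amoxiclav"]: "bl_bl_inhibitor",
        ATC["piperacillin/tazobactam"]: "antipseudomonal_penicillins",
        ATC["ceftriaxone"]: "cephalosporins_3g",
        ATC["meropenem"]: "carbapenems",
        ATC["ciprofloxacin"]: "fluoroquinolones",
        ATC["gentamicin"]: "aminoglycosides",
        ATC["trimethoprim"]: "folate_pathway_inhibitors",
    }
    s = {
        ATC["flucloxacillin"]: "antistaphylococcal_penicillins",
        ATC["vancomycin"]: "glycopeptides",
        ATC["clarithromycin"]: "macrolides",
        ATC["doxycycline"]: "tetracyclines",
        ATC["gentamicin"]: "aminoglycosides",
    }
    return {"enterobacterales": e, "staphylococcus": s}


# ---------------------------------------------------------------------------
# YAML round-trip helpers
# ---------------------------------------------------------------------------

def guideline_to_dict(g: GuidelineSet) -> dict:
    return {
        "indication": g.indication,
        "strata": [
            {
                "severity_key": s.severity_key,
                "min_severity": s.min_severity,
                "first_line_regimens": [sorted(r) for r in s.first_line_regimens],
                "allergy_regimens": [sorted(r) for r in s.allergy_regimens],
            }
            for s in g.strata
        ],
    }


def guideline_from_dict(d: Mapping) -> GuidelineSet:
    strata = tuple(
        GuidelineStratum(
            severity_key=s["severity_key"],
            min_severity=int(s["min_severity"]),
            first_line_regimens=tuple(frozenset(r) for r in s["first_line_regimens"]),
            allergy_regimens=tuple(frozenset(r) for r in s.get("allergy_regimens", [])),
        )
        for s in d["strata"]
    )
    return GuidelineSet(indication=d["indication"], strata=strata)


def load_guideline(path: str | Path) -> GuidelineSet:
    with open(path) as fh:
        return guideline_from_dict(yaml.safe_load(fh))


def save_guideline(g: GuidelineSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(guideline_to_dict(g), fh, sort_keys=False)


def load_config(path: str | Path, cls):
    """Load a dataclass config (LinkageConfig, CriteriaConfig, ...) from YAML;
    keys absent from the file keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = asdict(cls())
    unknown = set(data) - set(base)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    base.update(data)
    # tuples survive the YAML round trip as lists
    return cls(**{k: tuple(v) if isinstance(base_v := getattr(cls(), k), tuple) else v
                  for k, v in base.items()})


def save_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
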