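"""Susceptibility interpretation and multidrug-resistance profiling.

MIC or disc-zone measurements are interpreted into S/I/R against a
configurable breakpoint table. Isolates are then profiled into the
standard resistance categories: MDR (non-susceptible to at least one
agent in three or more antimicrobial categories), XDR (non-susceptible in
all but two or fewer of the categories tested) and PDR (non-susceptible
to every agent tested). Intermediate results count as non-susceptible by
convention (configurable); fewer than three categories tested makes an
isolate unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import BreakpointRule


@dataclass
class ASTResult:
    interpretation: str          # "S" | "I" | "R" | "unclassified"
    used_fallback: bool = False  # True when the lab-reported value was used


def interpret_ast(susceptibility: Mapping,
                  rules: Sequence[BreakpointRule],
                  organism_group: str | None = None) -> ASTResult:
    """Interpret one measurement.

    MIC: value <= S bound -> S; value > R bound -> R; else I.
    Disc zones mirror: value >= S bound -> S; value < R bound -> R; else I.
    When no rule matches, the laboratory-reported interpretation (if any)
    is used as a flagged fallback; otherwise the result is unclassified.
    """
    org = organism_group or susceptibility.get("organism_group")
    agent = susceptibility["agent_code"]
    mtype = susceptibility["measure_type"]
    value = float(susceptibility["measure_value"])
    rule = next((r for r in rules
                 if r.organism_group == org and r.agent_code == agent
                 and r.measure_type == mtype), None)
    if rule is None:
        reported = susceptibility.get("reported_interpretation")
        if reported in ("S", "I", "R"):
            return ASTResult(reported, used_fallback=True)
        return ASTResult("unclassified")
    if mtype == "MIC":
        if value <= rule.s_bound:
            return ASTResult("S")
        if value > rule.r_bound:
            return ASTResult("R")
        return ASTResult("I")
    if mtype == "disc_zone":
        if value >= rule.s_bound:
            return ASTResult("S")
        if value < rule.r_bound:
            return ASTResult("R")
        return ASTResult("I")
    raise ValueError(f"unknown measure type {mtype!r}")


@dataclass
class MDRProfile:
    isolate_id: str
    category: str                # susceptible_profile | MDR | XDR | PDR | unclassifiable
    categories_tested: int
    categories_nonsusceptible: int
    agents_tested: int = 0
    agents_nonsusceptible: int = 0


def classify_mdr(isolate_id: str,
                 interpretations: Mapping[str, str],
                 category_map: Mapping[str, str],
                 i_is_nonsusceptible: bool = True,
                 exclude_agents: Iterable[str] = ()) -> MDRProfile:
    """Profile one isolate from per-agent interpretations.

    ``interpretations`` maps agent code -> "S"/"I"/"R";
    ``category_map`` maps agent code -> antimicrobial category for the
    isolate's organism group. Agents without a category (or listed in
    ``exclude_agents``, e.g. intrinsic resistances) are ignored.

    PDR implies the XDR condition, which implies the MDR condition; the
    most severe applicable label is returned.
    """
    ns_values = {"R", "I"} if i_is_nonsusceptible else {"R"}
    excluded = set(exclude_agents)
    usable = {a: v for a, v in interpretations.items()
              if a in category_map and a not in excluded and v in {"S", "I", "R"}}

    tested_categories = {category_map[a] for a in usable}
    ns_categories = {category_map[a] for a, v in usable.items() if v in ns_values}
    agents_ns = sum(v in ns_values for v in usable.values())

    n_tested, n_ns = len(tested_categories), len(ns_categories)
    # XDR additionally requires the MDR floor (>=3 non-susceptible
    # categories) so that PDR => XDR => MDR nests even on small panels.
    if n_tested < 3:
        category = "unclassifiable"
    elif agents_ns == len(usable) and len(usable) > 0:
        category = "PDR"
    elif n_tested - n_ns <= 2 and n_ns >= 3:
        category = "XDR"
    elif n_ns >= 3:
        category = "MDR"
    else:
        category = "susceptible_profile"
    return MDRProfile(isolate_id, category, n_tested, n_ns,
                      agents_tested=len(usable), agents_nonsusceptible=agents_ns)


def profile_isolates(bundle,
                     rules: Sequence[BreakpointRule],
                     category_maps: Mapping[str, Mapping[str, str]],
                     organism_groups: Mapping[str, str] | None = None,
                     i_is_nonsusceptible: bool = True) -> pd.DataFrame:
    """Interpret and profile every isolate with growth in a bundle.

    ``category_maps`` maps organism group -> (agent -> category);
    ``organism_groups`` optionally maps organism code -> organism group
    (defaults to the organism code itself).
    """
    iso = bundle.isolates
    sus = bundle.susceptibilities
    rows = []
    for r in iso.itertuples():
        if float(r.no_growth) == 1:
            continue
        group = (organism_groups or {}).get(r.organism_code, r.organism_code)
        mine = sus[sus["isolate_id"] == r.isolate_id]
        interps = {}
        for s in mine.to_dict("records"):
            res = interpret_ast(s, rules, organism_group=group)
            if res.interpretation in {"S", "I", "R"}:
                interps[s["agent_code"]] = res.interpretation
        cmap = category_maps.get(group, {})
        prof = classify_mdr(r.isolate_id, interps, cmap,
                            i_is_nonsusceptible=i_is_nonsusceptible)
        rows.append({"isolate_id": prof.isolate_id,
                     "organism_group": group,
                     "category": prof.category,
                     "categories_tested": prof.categories_tested,
                     "categories_nonsusceptible": prof.categories_nonsusceptible})
    return pd.DataFrame(rows, columns=["isolate_id", "organism_group", "category",
                                       "categories_tested",
                                       "categories_nonsusceptible"])
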