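"""Shared fixtures: hand-built micro-bundles and a module-scoped synthetic
cohort. All data is generated programmatically at test time."""

from __future__ import annotations

import pandas as pd
import pytest

from amskit.ehr_model import bundle_from_frames
from amskit.linkage import link_therapy_episodes
from amskit.synthetic import CohortParams, generate_cohort

T0 = pd.Timestamp("2018-07-01 08:00")
H = pd.Timedelta(hours=1)
D = pd.Timedelta(days=1)


def rx_row(pid, patient="P1", drug="J01CA04", route="IV",
           start=T0, end=None, status="completed", admission="A1"):
    return {
        "prescription_id": pid, "patient_id": patient, "admission_id": admission,
        "drug_code": drug, "drug_name": drug, "route": route,
        "dose": 500.0, "dose_unit": "mg", "frequency": "q8h",
        "authored_time": start, "start_time": start,
        "end_time": end if end is not None else start + 2 * D,
        "status": status,
    }


def admin_rows(pid, times, dose=500.0):
    return [{"prescription_id": pid, "administration_time": t, "dose_given": dose}
            for t in times]


def make_bundle(**frames):
    return bundle_from_frames({k: pd.DataFrame(v) for k, v in frames.items()})


@pytest.fixture(scope="session")
def synth():
    """A mid-sized synthetic cohort shared across tests (read-only)."""
    params = CohortParams(seed=11, n_patients=120)
    bundle, gt = generate_cohort(params)
    episodes = link_therapy_episodes(bundle.prescriptions, bundle.administrations)
    return {"params": params, "bundle": bundle, "gt": gt, "episodes": episodes}
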