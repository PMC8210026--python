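"""Prescribing-indication inference harness.

Clinical indication (pneumonia, urinary tract infection, ...) is often
missing from structured prescribing records, so it is inferred with a
supervised classifier trained on audit labels. The contribution here is
the harness, not the learner: class-size filtering (small categories are
reclassified as "other"), leakage-free feature extraction from
initiation-time context only, and repeated stratified cross-validated
balanced accuracy. Any scikit-learn style fit/predict estimator can be
plugged in; a random forest is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .ehr_model import EHRBundle
from .linkage import TherapyEpisode, age_band

OTHER_LABEL = "other"


def prepare_training(labels: pd.DataFrame,
                     label_col: str = "indication_label",
                     min_class_size: int = 50,
                     valid_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Reclassify categories with fewer than ``min_class_size`` episodes as
    "other"; drop (and count) records with invalid labels.

    Returns a copy with the relabelled column plus attrs
    ``n_dropped_invalid`` and ``relabelled_classes``.
    """
    df = labels.copy()
    if valid_labels is not None:
        ok = df[label_col].isin(set(valid_labels) | {OTHER_LABEL})
        n_dropped = int((~ok).sum())
        df = df[ok].copy()
    else:
        n_dropped = int(df[label_col].isna().sum())
        df = df[df[label_col].notna()].copy()
    counts = df[label_col].value_counts()
    small = set(counts[counts < min_class_size].index) - {OTHER_LABEL}
    df.loc[df[label_col].isin(small), label_col] = OTHER_LABEL
    df.attrs["n_dropped_invalid"] = n_dropped
    df.attrs["relabelled_classes"] = sorted(small)
    return df


FEATURE_SCHEMA_VERSION = 1
_LAB_LOOKBACK_HOURS = 72.0


def extract_features(episode: TherapyEpisode, bundle: EHRBundle) -> dict:
    """Deterministic features from context at or before episode start.

    Covers the initial drug set and route, speciality, admission method,
    age band, ICD-10 chapter flags of the admission, and the most recent
    WCC/CRP/urea in the 72 h before initiation (with missingness flags).
    Records after episode start never influence the output.
    """
    t0 = episode.episode_start
    rx = bundle.prescriptions
    mine = rx[rx["prescription_id"].isin(episode.prescription_ids)]
    mine = mine.sort_values(["start_time", "prescription_id"], kind="stable")
    first = mine["start_time"].iloc[0] if len(mine) else t0
    initial = mine[mine["start_time"] <= first + pd.Timedelta(hours=6)]
    feats: dict = {
        "schema_version": FEATURE_SCHEMA_VERSION,
        "episode_id": episode.episode_id,
        "n_initial_drugs": int(len(initial)),
        "any_iv": bool((initial["route"] == "IV").any()) if len(initial) else False,
    }
    for code in sorted(set(initial["drug_code"].astype(str))):
        feats[f"drug_{code}"] = 1

    adm = bundle.admissions
    adm_row = None
    if episode.admission_id is not None and len(adm):
        hit = adm[adm["admission_id"] == episode.admission_id]
        adm_row = hit.iloc[0] if len(hit) else None
    if adm_row is not None:
        feats["admission_method"] = str(adm_row["method"])
        feats["age_band"] = age_band(float(adm_row["age_at_admission"]))
    ce = bundle.care_episodes
    if adm_row is not None and len(ce):
        mine_ce = ce[ce["admission_id"] == episode.admission_id]
        if len(mine_ce):
            feats["speciality"] = str(mine_ce.sort_values("start_time")
                                      .iloc[0]["speciality"])
    dx = bundle.diagnoses
    if adm_row is not None and len(dx):
        codes = dx.loc[dx["admission_id"] == episode.admission_id, "icd10_code"]
        for ch in sorted({str(c)[0] for c in codes}):
            feats[f"dx_chapter_{ch}"] = 1

    inv = bundle.investigations
    lookback = t0 - pd.Timedelta(hours=_LAB_LOOKBACK_HOURS)
    for concept in ("wcc", "crp", "urea"):
        sub = inv[(inv["patient_id"] == episode.patient_id)
                  & (inv["concept"] == concept)
                  & (inv["observed_time"] >= lookback)
                  & (inv["observed_time"] <= t0)]
        if len(sub):
            feats[f"last_{concept}"] = float(
                sub.sort_values("observed_time")["value"].iloc[-1])
            feats[f"{concept}_missing"] = 0
        else:
            feats[f"last_{concept}"] = np.nan
            feats[f"{concept}_missing"] = 1
    return feats


def features_frame(episodes: Sequence[TherapyEpisode],
                   bundle: EHRBundle) -> pd.DataFrame:
    """Stack per-episode features into a model matrix: categorical columns
    one-hot encoded (a stateless, leakage-free encoding), indicator and
    numeric columns zero/NaN-filled."""
    raw = pd.DataFrame([extract_features(e, bundle) for e in episodes])
    raw = raw.set_index("episode_id").drop(columns=["schema_version"])
    cat_cols = [c for c in ("admission_method", "age_band", "speciality")
                if c in raw.columns]
    enc = pd.get_dummies(raw, columns=cat_cols, dummy_na=True)
    flag_cols = [c for c in enc.columns if c.startswith(("drug_", "dx_chapter_"))]
    enc[flag_cols] = enc[flag_cols].fillna(0)
    num_cols = [c for c in enc.columns if c.startswith("last_")]
    enc[num_cols] = enc[num_cols].fillna(-1.0)  # sentinel; missingness flags kept
    return enc.astype(float)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 2
    seed: int = 0


@dataclass
class CVReport:
    per_class: pd.DataFrame          # class, balanced_accuracy, precision, recall
    overall_balanced_accuracy: float
    folds: int = 5
    repeats: int = 1
    merged_small_classes: list[str] = field(default_factory=list)


def _per_class_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       classes: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in classes:
        pos = y_true == c
        neg = ~pos
        pred_pos = y_pred == c
        sens = float((pred_pos & pos).sum() / pos.sum()) if pos.sum() else np.nan
        spec = float((~pred_pos & neg).sum() / neg.sum()) if neg.sum() else np.nan
        prec = (float((pred_pos & pos).sum() / pred_pos.sum())
                if pred_pos.sum() else np.nan)
        rows.append({"class": c, "recall": sens, "specificity": spec,
                     "precision": prec,
                     "balanced_accuracy": np.nanmean([sens, spec])})
    return pd.DataFrame(rows)


def evaluate_classifier(features: pd.DataFrame,
                        labels: pd.Series | np.ndarray,
                        cv_config: CVConfig | None = None,
                        learner=None) -> CVReport:
    """Repeated stratified K-fold evaluation of an injected learner.

    Per class: one-vs-rest balanced accuracy ((sensitivity +
    specificity) / 2), precision and recall pooled over held-out folds of
    all repeats. Overall balanced accuracy is the unweighted mean over
    classes. Classes with fewer members than folds are merged into
    "other" (with a note in the report). Fully reproducible from the seed.
    """
    cv_config = cv_config or CVConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(pd.Series(labels).astype(str))

    counts = pd.Series(y).value_counts()
    too_small = sorted(set(counts[counts < cv_config.folds].index) - {OTHER_LABEL})
    if too_small:
        y = np.where(np.isin(y, too_small), OTHER_LABEL, y)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes after preparation")

    cv = RepeatedStratifiedKFold(n_splits=cv_config.folds,
                                 n_repeats=cv_config.repeats,
                                 random_state=cv_config.seed)
    preds = []
    truths = []
    for k, (train_idx, test_idx) in enumerate(cv.split(X, y)):
        model = (RandomForestClassifier(n_estimators=100,
                                        random_state=cv_config.seed + k)
                 if learner is None else clone_learner(learner, cv_config.seed + k))
        model.fit(X[train_idx], y[train_idx])
        preds.append(model.predict(X[test_idx]))
        truths.append(y[test_idx])
    y_pred = np.concatenate(preds)
    y_true = np.concatenate(truths)

    per_class = _per_class_metrics(y_true, y_pred, classes)
    overall = float(per_class["balanced_accuracy"].mean())
    return CVReport(per_class=per_class, overall_balanced_accuracy=overall,
                    folds=cv_config.folds, repeats=cv_config.repeats,
                    merged_small_classes=too_small)


def clone_learner(learner, seed: int):
    """Fresh copy of an estimator per fold, reseeded when it exposes
    ``random_state``."""
    from sklearn.base import clone
    model = clone(learner)
    if "random_state" in model.get_params():
        model.set_params(random_state=seed)
    return model
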