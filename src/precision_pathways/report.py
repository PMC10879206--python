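"""Machine-readable summaries backing the standard pathway figures.

Each builder returns a plain table; the rendering in
:mod:`precision_pathways.plotting` is a thin untested layer over these.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .ensemble import EnsemblePredictions, TrainedPlatformEnsemble
from .optimize import PathwayComparison
from .pathway import PathwayResult

__all__ = [
    "build_flowchart",
    "build_strata",
    "build_bubble",
    "build_cohort_summary",
    "build_feature_importance",
]


def build_flowchart(result: PathwayResult) -> pd.DataFrame:
    """Stage-wise patient flow: entering, classified per class, progressed.

    Conservation holds exactly: patients entering stage ``s+1`` equal
    those progressed from stage ``s``, and classified counts across
    stages sum to the cohort size.
    """
    n = len(result.patients)
    classes = sorted(result.predicted.unique())
    rows = []
    entering = n
    for s, name in enumerate(result.sequence, start=1):
        mask = result.routes["stage"] == s
        classified = int(mask.sum())
        row = {
            "stage": s,
            "platform": name,
            "entering": entering,
            "classified": classified,
            "progressed": entering - classified,
            "proportion_classified": classified / n,
        }
        for c in classes:
            row[f"classified_{c}"] = int((result.predicted[mask] == c).sum())
        rows.append(row)
        entering -= classified
    return pd.DataFrame(rows)


def build_strata(
    result: PathwayResult,
    ensembles: Mapping[str, EnsemblePredictions],
    truth: pd.Series,
) -> pd.DataFrame:
    """Per-patient strata rows: stage, true class, vote-level accuracy.

    Accuracy is the patient's vote-level accuracy at the platform that
    classified them; rows sort by stage, then true class, then accuracy,
    deterministically (patient id as the final key).
    """
    truth = truth.loc[result.patients]
    acc_by_platform = {
        name: preds.accuracy(truth) for name, preds in ensembles.items()
    }
    rows = []
    for pid in result.patients:
        stage = int(result.routes.at[pid, "stage"])
        platform = result.routes.at[pid, "platform"]
        rows.append(
            {
                "patient": pid,
                "stage": stage,
                "platform": platform,
                "true_class": truth[pid],
                "predicted": result.routes.at[pid, "predicted"],
                "accuracy": float(acc_by_platform[platform][pid]),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["stage", "true_class", "accuracy", "patient"], kind="stable"
    ).reset_index(drop=True)


def build_bubble(comparison: PathwayComparison) -> pd.DataFrame:
    """Per-candidate rows for the accuracy-vs-cost bubble view.

    One row per sequence with total cost, balanced accuracy and per-tier
    classified proportions (which sum to 1 per row).
    """
    if comparison.table.empty:
        raise ValueError("comparison is empty")
    tier_cols = [c for c in comparison.table.columns if c.startswith("tier")]
    cols = ["sequence", "balanced_accuracy", "total_cost", "assay_count", "score"]
    return comparison.table[cols + tier_cols].copy()


def build_cohort_summary(
    result: PathwayResult, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Covariate summaries of classified vs progressed patients per stage.

    For each stage and each of the two groups (classified at the stage,
    progressed beyond it), numeric covariates are summarized by their
    mean and categorical covariates by level counts.  Tidy output:
    ``stage, group, covariate, level, value, n``.
    """
    if metadata is None or metadata.shape[1] == 0:
        raise ValueError("metadata with at least one covariate is required")
    metadata = metadata.loc[result.patients]
    stages = result.routes["stage"]
    rows = []
    for s in range(1, len(result.sequence) + 1):
        groups = {
            "classified": metadata[stages == s],
            "progressed": metadata[stages > s],
        }
        for group, sub in groups.items():
            for cov in metadata.columns:
                series = sub[cov]
                if pd.api.types.is_numeric_dtype(series):
                    rows.append(
                        {
                            "stage": s,
                            "group": group,
                            "covariate": cov,
                            "level": None,
                            "value": float(series.mean()) if len(series) else np.nan,
                            "n": len(series),
                        }
                    )
                else:
                    for level, count in series.value_counts().items():
                        rows.append(
                            {
                                "stage": s,
                                "group": group,
                                "covariate": cov,
                                "level": level,
                                "value": int(count),
                                "n": len(series),
                            }
                        )
    return pd.DataFrame(rows)


def build_feature_importance(ensemble: TrainedPlatformEnsemble) -> pd.DataFrame:
    """How often each feature was selected across the fold models, with sign.

    ``frequency`` is the fraction of the ``r * k`` models that selected
    the feature; ``direction`` is the mean (over selecting models) of the
    class-mean difference, second-listed class minus first, so its sign
    says which class higher values point to.  Sorted by frequency then
    |direction|, descending.
    """
    counts: dict[str, int] = {}
    diffs: dict[str, list[float]] = {}
    for model in ensemble.models:
        delta = model.means[1] - model.means[0]
        for f, d in zip(model.features, delta):
            counts[f] = counts.get(f, 0) + 1
            diffs.setdefault(f, []).append(float(d))
    table = pd.DataFrame(
        {
            "feature": list(counts),
            "frequency": [counts[f] / ensemble.n_models for f in counts],
            "direction": [float(np.mean(diffs[f])) for f in counts],
        }
    )
    table["abs_direction"] = table["direction"].abs()
    table = table.sort_values(
        ["frequency", "abs_direction", "feature"], ascending=[False, False, True],
        kind="stable",
    ).drop(columns="abs_direction")
    return table.reset_index(drop=True)
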