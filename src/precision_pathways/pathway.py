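"""Sequential classify-or-progress pathways and their evaluation.

Patients walk an ordered sequence of platforms.  At each stage a patient
whose ensemble confidence clears the threshold is classified with that
platform's majority class; everyone else is "uncertain" and progresses to
the next platform.  The final platform classifies whoever remains,
regardless of confidence.  Evaluation compares the final classes with the
truth and accumulates, per patient, the monetary cost of every platform
consumed along the way.

"Clears the threshold" means ``confidence >= threshold``; a threshold of
1.0 therefore classifies on unanimity.  With 50 repeats the attainable
confidences form the grid {2|m/50 - 0.5|}, on which ``>= 0.9`` and
``> 0.9`` route identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsemblePredictions

__all__ = [
    "PathwayResult",
    "PathwayEvaluation",
    "construct_pathway",
    "evaluate_pathway",
    "stage_cost",
    "threshold_sweep",
    "balanced_accuracy_from_rates",
    "f1_from_precision_recall",
]


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy is the arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 score is the harmonic mean of precision and recall (0 if both 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class PathwayResult:
    """Per-patient routes through one platform sequence at one threshold.

    ``routes`` has one row per patient with the 1-based ``stage`` at which
    the patient was classified, the ``platform`` that classified them, the
    final ``predicted`` class, and one ``conf_<platform>`` column per
    stage of the sequence (confidences at stages after classification are
    retained for inspection but were never consulted).
    """

    sequence: tuple[str, ...]
    threshold: float
    routes: pd.DataFrame

    @property
    def patients(self) -> pd.Index:
        return self.routes.index

    def consumed(self, patient) -> tuple[str, ...]:
        """The platform prefix actually assayed for one patient."""
        return self.sequence[: int(self.routes.at[patient, "stage"])]

    @property
    def predicted(self) -> pd.Series:
        return self.routes["predicted"]

    def stage_counts(self) -> pd.Series:
        """Number of patients classified at each stage (1..len(sequence))."""
        counts = self.routes["stage"].value_counts()
        return counts.reindex(range(1, len(self.sequence) + 1), fill_value=0).sort_index()

    def tier_proportions(self) -> pd.Series:
        return self.stage_counts() / len(self.routes)

    def route_table(self, truth: pd.Series | None = None) -> pd.DataFrame:
        """Serializable per-patient route table."""
        table = self.routes.copy()
        table.insert(
            2, "consumed", [" > ".join(self.consumed(p)) for p in table.index]
        )
        if truth is not None:
            table["truth"] = truth.loc[table.index]
        table.index.name = "patient"
        return table


def construct_pathway(
    sequence: Sequence[str],
    confidences: Mapping[str, EnsemblePredictions],
    threshold: float,
) -> PathwayResult:
    """Route every patient through ``sequence`` at the given threshold.

    All patients start at the first platform; at each stage those with
    confidence >= threshold take that platform's majority class and stop,
    the rest progress; the final platform classifies everyone remaining.
    """
    sequence = tuple(sequence)
    if not sequence:
        raise ValueError("platform sequence is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    for name in sequence:
        if name not in confidences:
            raise KeyError(f"no predictions supplied for platform {name!r}")
    patients = confidences[sequence[0]].confidence.index
    for name in sequence[1:]:
        missing = patients.difference(confidences[name].confidence.index)
        if len(missing):
            raise ValueError(
                f"platform {name!r} lacks predictions for patient(s) {missing.tolist()}"
            )

    conf = np.column_stack(
        [confidences[name].confidence.loc[patients].to_numpy() for name in sequence]
    )
    maj = np.column_stack(
        [confidences[name].majority.loc[patients].to_numpy(dtype=object) for name in sequence]
    )
    cleared = conf >= threshold
    cleared[:, -1] = True  # final platform always classifies
    stage_idx = cleared.argmax(axis=1)  # first stage that classifies
    routes = pd.DataFrame(
        {
            "stage": stage_idx + 1,
            "platform": [sequence[i] for i in stage_idx],
            "predicted": maj[np.arange(len(patients)), stage_idx],
        },
        index=patients,
    )
    for j, name in enumerate(sequence):
        routes[f"conf_{name}"] = conf[:, j]
    return PathwayResult(sequence=sequence, threshold=threshold, routes=routes)


def stage_cost(consumed: Sequence[str], costs: Mapping[str, float]) -> float:
    """Money spent on one patient who consumed the given platform prefix."""
    missing = [p for p in consumed if p not in costs]
    if missing:
        raise KeyError(f"no cost given for platform(s) {missing}")
    return float(sum(costs[p] for p in consumed))


@dataclass
class PathwayEvaluation:
    """Classification metrics plus cost accounting for one pathway run.

    Metrics are computed with respect to the configured positive class.
    ``total_cost`` sums, over patients, the costs of the platforms each
    patient consumed; ``assay_count`` counts assays the same way.
    ``stage_table`` gives per-stage occupancy and accuracy.
    """

    sequence: tuple[str, ...]
    threshold: float
    n_patients: int
    positive_class: str
    accuracy: float
    balanced_accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    total_cost: float
    assay_count: int
    stage_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "sequence": list(self.sequence),
            "threshold": self.threshold,
            "n_patients": self.n_patients,
            "positive_class": self.positive_class,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "total_cost": self.total_cost,
            "assay_count": self.assay_count,
        }


def evaluate_pathway(
    result: PathwayResult,
    truth: pd.Series,
    costs: Mapping[str, float],
    positive_class: str | None = None,
) -> PathwayEvaluation:
    """Score a routed pathway against the true classes.

    ``positive_class`` defaults to the lexicographically larger of the two
    observed classes.  Undefined ratios (empty denominator) evaluate to 0.
    """
    truth = truth.loc[result.patients]
    classes = sorted(truth.unique())
    if positive_class is None:
        positive_class = classes[-1]
    pred = result.predicted
    is_pos = truth == positive_class
    tp = int(((pred == positive_class) & is_pos).sum())
    fn = int(((pred != positive_class) & is_pos).sum())
    tn = int(((pred != positive_class) & ~is_pos).sum())
    fp = int(((pred == positive_class) & ~is_pos).sum())

    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    accuracy = _ratio(tp + tn, len(truth))

    for name in result.sequence:
        if name not in costs:
            raise KeyError(f"no cost given for platform {name!r}")
    cum_cost = np.cumsum([costs[p] for p in result.sequence])
    stages = result.routes["stage"].to_numpy()
    total_cost = float(cum_cost[stages - 1].sum())
    assay_count = int(stages.sum())

    rows = []
    entering = len(result.patients)
    for s, name in enumerate(result.sequence, start=1):
        mask = result.routes["stage"] == s
        classified = int(mask.sum())
        correct = int((pred[mask] == truth[mask]).sum())
        rows.append(
            {
                "stage": s,
                "platform": name,
                "entering": entering,
                "classified": classified,
                "progressed": entering - classified,
                "stage_accuracy": correct / classified if classified else np.nan,
            }
        )
        entering -= classified
    stage_table = pd.DataFrame(rows)

    return PathwayEvaluation(
        sequence=result.sequence,
        threshold=result.threshold,
        n_patients=len(truth),
        positive_class=positive_class,
        accuracy=accuracy,
        balanced_accuracy=balanced_accuracy_from_rates(sensitivity, specificity),
        f1=f1_from_precision_recall(precision, sensitivity),
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        total_cost=total_cost,
        assay_count=assay_count,
        stage_table=stage_table,
    )


def threshold_sweep(
    sequence: Sequence[str],
    confidences: Mapping[str, EnsemblePredictions],
    thresholds: Sequence[float],
    truth: pd.Series,
    costs: Mapping[str, float],
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Evaluate one sequence over a grid of confidence thresholds.

    With confidences fixed, raising the threshold can only push patients
    deeper into the sequence, so total cost is non-decreasing in the
    threshold.  Returns one row of metrics and costs per threshold.
    """
    rows = []
    for threshold in thresholds:
        result = construct_pathway(sequence, confidences, threshold)
        ev = evaluate_pathway(result, truth, costs, positive_class)
        row = ev.to_dict()
        row["sequence"] = " > ".join(sequence)
        for s, count in result.stage_counts().items():
            row[f"stage{s}_classified"] = int(count)
        rows.append(row)
    return pd.DataFrame(rows)
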