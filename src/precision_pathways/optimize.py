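"""Candidate-ordering enumeration, rank-based scoring and baselines.

Every ordering of the platforms (with an optional fixed leading prefix,
e.g. clinical data always first) defines a candidate pathway.  Per-platform
ensemble confidences do not depend on a platform's position in a sequence,
so they are computed once and shared by all orderings.  Candidates are
ranked on balanced accuracy (higher is better) and on total cost (lower is
better); a weighted average of the two ranks is the final score, lower
being better.

Baselines mirror common practice: a model per single omics platform
concatenated with the clinical platform, and one merged model over all
platforms, each paying the full cost of every platform it uses for every
patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CohortDataset, PlatformAssay, RunConfig
from .ensemble import EnsemblePredictions, run_repeated_cv
from .pathway import PathwayResult, PathwayEvaluation, construct_pathway, evaluate_pathway

__all__ = [
    "PathwayComparison",
    "enumerate_sequences",
    "weighted_rank_score",
    "compare_pathways",
    "baseline_single_platform",
    "baseline_merged",
]


def enumerate_sequences(
    platforms: Sequence[str], fixed_tiers: int
) -> list[tuple[str, ...]]:
    """All platform orderings whose first ``fixed_tiers`` entries are pinned.

    The leading ``fixed_tiers`` platforms keep their given positions; the
    rest are permuted.  Output order is deterministic lexicographic with
    respect to the input platform order.
    """
    platforms = list(platforms)
    if not 0 <= fixed_tiers <= len(platforms):
        raise ValueError(
            f"fixed_tiers={fixed_tiers} out of range for {len(platforms)} platforms"
        )
    head = tuple(platforms[:fixed_tiers])
    return [head + tail for tail in permutations(platforms[fixed_tiers:])]


def weighted_rank_score(
    criteria_table: pd.DataFrame, weights: tuple[float, float] = (0.5, 0.5)
) -> pd.DataFrame:
    """Aggregate per-criterion ranks into a single score (lower is better).

    ``criteria_table`` needs columns ``balanced_accuracy`` and
    ``total_cost``.  Rank 1 is the highest balanced accuracy and,
    separately, the lowest cost; exact ties share their average rank.
    The score is the weighted mean of the two ranks with ``weights``
    normalized to sum to one, so scores lie between 1 and the number of
    candidates.
    """
    if criteria_table.empty:
        raise ValueError("criteria table is empty")
    if any(w < 0 for w in weights) or sum(weights) == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w_acc, w_cost = (w / sum(weights) for w in weights)
    out = criteria_table.copy()
    out["rank_accuracy"] = out["balanced_accuracy"].rank(ascending=False, method="average")
    out["rank_cost"] = out["total_cost"].rank(ascending=True, method="average")
    out["score"] = w_acc * out["rank_accuracy"] + w_cost * out["rank_cost"]
    return out


@dataclass
class PathwayComparison:
    """All candidate orderings with their metrics, ranks and scores.

    ``table`` holds one row per sequence (balanced accuracy, total cost,
    assay count, per-tier classified proportions, per-criterion ranks and
    the aggregated score); ``results`` maps each sequence to its routed
    :class:`~precision_pathways.pathway.PathwayResult`.  ``best`` is the
    lowest-scoring sequence, ties resolved by lower cost then
    lexicographic order.
    """

    table: pd.DataFrame
    results: dict[tuple[str, ...], PathwayResult]
    evaluations: dict[tuple[str, ...], PathwayEvaluation]
    predictions: dict[str, EnsemblePredictions]
    best: tuple[str, ...]


def compare_pathways(
    cohort: CohortDataset,
    config: RunConfig,
    predictions: Mapping[str, EnsemblePredictions] | None = None,
) -> PathwayComparison:
    """Build, evaluate and score every candidate ordering of a cohort.

    Runs the repeated-CV ensemble once per platform (pass
    ``predictions`` to reuse precomputed ones), routes every enumerated
    sequence at ``config.confidence_threshold``, and scores the
    candidates with :func:`weighted_rank_score`.
    """
    if predictions is None:
        predictions = {
            a.name: run_repeated_cv(a, cohort.labels, config) for a in cohort.assays
        }
    sequences = enumerate_sequences(cohort.platform_names, config.fixed_tiers)
    costs = cohort.costs
    n_stages = len(cohort.platform_names)

    rows, results, evaluations = [], {}, {}
    for seq in sequences:
        result = construct_pathway(seq, predictions, config.confidence_threshold)
        ev = evaluate_pathway(result, cohort.labels, costs, config.positive_class)
        results[seq] = result
        evaluations[seq] = ev
        row = {
            "sequence": " > ".join(seq),
            "balanced_accuracy": ev.balanced_accuracy,
            "accuracy": ev.accuracy,
            "f1": ev.f1,
            "total_cost": ev.total_cost,
            "assay_count": ev.assay_count,
        }
        for s, prop in result.tier_proportions().items():
            row[f"tier{s}_proportion"] = float(prop)
        rows.append(row)
    table = weighted_rank_score(pd.DataFrame(rows), config.weights)

    order = table.assign(_seq=[" > ".join(s) for s in sequences]).sort_values(
        ["score", "total_cost", "_seq"], kind="stable"
    )
    best = sequences[order.index[0]]
    return PathwayComparison(
        table=table, results=results, evaluations=evaluations,
        predictions=dict(predictions), best=best,
    )


def _concat_assays(assays: Sequence[PlatformAssay], name: str) -> PlatformAssay:
    """Column-wise concatenation with platform-prefixed feature names."""
    parts = [a.matrix.add_prefix(f"{a.name}__") for a in assays]
    merged = pd.concat(parts, axis=1)
    return PlatformAssay(name=name, matrix=merged, cost=sum(a.cost for a in assays))


def _evaluate_single_stage(
    assay: PlatformAssay, cohort: CohortDataset, config: RunConfig
) -> PathwayEvaluation:
    preds = run_repeated_cv(assay, cohort.labels, config)
    result = construct_pathway((assay.name,), {assay.name: preds}, 0.0)
    return evaluate_pathway(
        result, cohort.labels, {assay.name: assay.cost}, config.positive_class
    )


def baseline_single_platform(
    cohort: CohortDataset,
    platform_name: str,
    clinical_name: str,
    config: RunConfig,
) -> PathwayEvaluation:
    """Repeated-CV model on one platform concatenated with the clinical one.

    Every patient pays both platforms' costs.  Passing the clinical
    platform for both arguments yields the plain clinical model.  The
    same folds, repeats, selector and classifier as the pathways are used
    so the comparison is fair.
    """
    platform = cohort.assay(platform_name)
    if platform_name == clinical_name:
        merged = PlatformAssay(
            name=platform_name,
            matrix=platform.matrix.add_prefix(f"{platform_name}__"),
            cost=platform.cost,
        )
    else:
        merged = _concat_assays(
            [cohort.assay(clinical_name), platform],
            name=f"{clinical_name}+{platform_name}",
        )
    return _evaluate_single_stage(merged, cohort, config)


def baseline_merged(cohort: CohortDataset, config: RunConfig) -> PathwayEvaluation:
    """Repeated-CV model on all platforms concatenated; all costs paid."""
    if len(cohort.assays) < 2:
        raise ValueError("merged baseline needs at least two platforms")
    merged = _concat_assays(cohort.assays, name="+".join(cohort.platform_names))
    return _evaluate_single_stage(merged, cohort, config)
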