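"""Cross-cohort transfer via scale-free log-ratio features.

Models trained on one cohort rarely apply directly to another measured on
a different technology (e.g. RNA-seq counts vs microarray fluorescence).
The transfer pipeline makes each platform scale-free: per-sample library
size normalization, restriction to features common to both cohorts, an
optional training-side standard-deviation prefilter, the log-ratio of
every feature pair, and a patient-level standardization of the resulting
pair features (each patient's row to mean 0, variance 1).  Because the
standardization uses no cohort statistics, a frozen ensemble applies to
future incoming patients one at a time.

Pair retention is decided on the training data only: pairs whose training
standard deviation falls below 0.1 are removed for model stability, and
that decision is frozen in a :class:`LogRatioSpec` that external data
consumes verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, PlatformAssay, RunConfig
from .ensemble import (
    EnsemblePredictions,
    TrainedPlatformEnsemble,
    apply_ensemble,
    run_repeated_cv,
    train_full_ensemble,
)
from .optimize import compare_pathways
from .pathway import PathwayEvaluation, PathwayResult, construct_pathway, evaluate_pathway

__all__ = [
    "LogRatioSpec",
    "TransferResult",
    "intersect_and_normalize",
    "prefilter_by_sd",
    "logratio_transform",
    "standardize_per_patient",
    "transfer_pipeline",
]

#: Pairs whose log-ratio standard deviation on the training data falls
#: below this value are removed for model stability.
MIN_PAIR_SD = 0.1

#: Library-size normalization target: every sample row is rescaled to sum
#: to one million (counts-per-million style).
LIBRARY_SIZE_TARGET = 1e6


@dataclass(frozen=True)
class LogRatioSpec:
    """Frozen description of a platform's log-ratio feature space.

    ``pairs`` lists feature pairs ``(i, j)`` with ``i`` before ``j`` in
    training feature order; ``retained`` flags the pairs whose training
    standard deviation reached :data:`MIN_PAIR_SD`; ``pair_sds`` records
    those training SDs.  External cohorts apply the spec verbatim —
    retention is never recomputed.
    """

    pairs: tuple[tuple[str, str], ...]
    retained: tuple[bool, ...]
    pair_sds: tuple[float, ...]
    pseudocount: float

    @property
    def retained_pairs(self) -> list[tuple[str, str]]:
        return [p for p, r in zip(self.pairs, self.retained) if r]

    @property
    def features(self) -> list[str]:
        seen: dict[str, None] = {}
        for i, j in self.pairs:
            seen.setdefault(i)
            seen.setdefault(j)
        return list(seen)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "pairs": [list(p) for p in self.pairs],
                "retained": list(self.retained),
                "pair_sds": list(self.pair_sds),
                "pseudocount": self.pseudocount,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LogRatioSpec":
        text = str(source)
        if isinstance(source, Path) or not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        return cls(
            pairs=tuple((a, b) for a, b in data["pairs"]),
            retained=tuple(bool(r) for r in data["retained"]),
            pair_sds=tuple(float(s) for s in data["pair_sds"]),
            pseudocount=float(data["pseudocount"]),
        )


def intersect_and_normalize(
    train_assay: PlatformAssay,
    external_assay: PlatformAssay,
    normalize: bool = True,
) -> tuple[PlatformAssay, PlatformAssay]:
    """Library-size normalize both assays and keep their common features.

    Each sample row is rescaled to sum to :data:`LIBRARY_SIZE_TARGET`
    (skip with ``normalize=False`` for intensity data that is not
    count-like), after which both assays are restricted to the features
    present in both, in the training assay's column order.
    """
    common = [f for f in train_assay.features if f in set(external_assay.features)]
    if len(common) < 2:
        raise ValueError(
            f"assays {train_assay.name!r}/{external_assay.name!r} share "
            f"{len(common)} feature(s); need at least 2"
        )

    def _norm(matrix: pd.DataFrame) -> pd.DataFrame:
        if not normalize:
            return matrix
        totals = matrix.sum(axis=1)
        if (totals <= 0).any():
            bad = matrix.index[totals <= 0].tolist()
            raise ValueError(f"non-positive library size for sample(s) {bad}")
        return matrix.mul(LIBRARY_SIZE_TARGET / totals, axis=0)

    train = replace(train_assay, matrix=_norm(train_assay.matrix)[common])
    external = replace(external_assay, matrix=_norm(external_assay.matrix)[common])
    return train, external


def prefilter_by_sd(assay: PlatformAssay, min_sd: float) -> PlatformAssay:
    """Keep features whose across-sample standard deviation exceeds ``min_sd``.

    Used on the training side of high-dimensional platforms (e.g. SD > 5
    on microRNA counts) to keep the subsequent pairwise expansion
    tractable while retaining variable features.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    sds = assay.matrix.std(axis=0, ddof=1)
    kept = assay.matrix.loc[:, sds > min_sd]
    if kept.shape[1] == 0:
        raise ValueError(f"no features of {assay.name!r} have SD > {min_sd}")
    return replace(assay, matrix=kept)


def logratio_transform(
    assay: PlatformAssay,
    spec: LogRatioSpec | None = None,
    pseudocount: float = 0.0,
) -> tuple[PlatformAssay, LogRatioSpec]:
    """Expand an assay into natural-log ratios of all feature pairs.

    Training mode (``spec=None``): builds every unordered pair ``(i, j)``
    in column order, computes ``log((x_i + c) / (x_j + c))`` with
    pseudocount ``c``, records each pair's training SD and flags pairs
    with SD >= 0.1 as retained.  External mode: applies the given spec's
    pairs and retention flags verbatim.  In both modes only retained
    pairs appear in the returned assay.

    Multiplying any sample's row by a positive constant leaves its
    log-ratios unchanged (when ``c`` is 0), which is what makes the
    representation transferable across measurement scales.
    """
    if spec is not None:
        pseudocount = spec.pseudocount
        pairs = spec.pairs
        missing = sorted(set(spec.features) - set(assay.features))
        if missing:
            raise KeyError(f"assay {assay.name!r} lacks spec feature(s): {missing}")
    else:
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        pairs = tuple(combinations(assay.features, 2))
        if not pairs:
            raise ValueError(f"assay {assay.name!r} needs >= 2 features for pairs")

    values = assay.matrix
    if (values.to_numpy() < 0).any():
        raise ValueError(f"assay {assay.name!r} has negative values; log-ratios need >= 0")
    shifted = values + pseudocount
    if (shifted.to_numpy() <= 0).any():
        raise ValueError(
            f"assay {assay.name!r} has zero entries; use a positive pseudocount"
        )
    logged = np.log(shifted)
    ratio = pd.DataFrame(
        {
            f"{i}/{j}": logged[i] - logged[j]
            for i, j in pairs
        },
        index=values.index,
    )

    if spec is None:
        sds = ratio.std(axis=0, ddof=1).to_numpy()
        retained = tuple(bool(s >= MIN_PAIR_SD) for s in sds)
        spec = LogRatioSpec(
            pairs=pairs, retained=retained, pair_sds=tuple(float(s) for s in sds),
            pseudocount=pseudocount,
        )
    kept_cols = [f"{i}/{j}" for (i, j), r in zip(spec.pairs, spec.retained) if r]
    if not kept_cols:
        raise ValueError(f"no pairs of {assay.name!r} survive the SD >= {MIN_PAIR_SD} filter")
    return replace(assay, matrix=ratio[kept_cols]), spec


def standardize_per_patient(pair_assay: PlatformAssay) -> PlatformAssay:
    """Shift each patient's row to mean 0 and scale it to variance 1.

    The standardization is row-local: it uses no statistics of other
    patients, so it commutes with adding or removing patients and needs
    nothing from the training cohort at deployment time.
    """
    matrix = pair_assay.matrix
    if matrix.shape[1] < 2:
        raise ValueError("patient-level standardization needs >= 2 pair features")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = matrix.index[sds == 0].tolist()
        raise ValueError(f"zero row variance for patient(s) {bad}")
    out = matrix.sub(means, axis=0).div(sds, axis=0)
    return replace(pair_assay, matrix=out)


@dataclass
class TransferResult:
    """Outcome of applying a frozen pathway to an external cohort."""

    sequence: tuple[str, ...]
    pathway_result: PathwayResult
    evaluation: PathwayEvaluation | None
    train_result: PathwayResult
    train_evaluation: PathwayEvaluation
    specs: dict[str, LogRatioSpec]
    ensembles: dict[str, TrainedPlatformEnsemble]
    external_predictions: dict[str, EnsemblePredictions]


def _transform_platform(
    train_assay: PlatformAssay,
    external_assay: PlatformAssay,
    normalize: bool,
    prefilter_sd: float | None,
    pseudocount: float,
) -> tuple[PlatformAssay, PlatformAssay, LogRatioSpec]:
    train, external = intersect_and_normalize(train_assay, external_assay, normalize)
    if prefilter_sd is not None:
        train = prefilter_by_sd(train, prefilter_sd)
        external = replace(external, matrix=external.matrix[list(train.features)])
    train_pairs, spec = logratio_transform(train, pseudocount=pseudocount)
    external_pairs, _ = logratio_transform(external, spec=spec)
    return (
        standardize_per_patient(train_pairs),
        standardize_per_patient(external_pairs),
        spec,
    )


def transfer_pipeline(
    train_cohort: CohortDataset,
    external_cohort: CohortDataset,
    config: RunConfig,
    sequence: Sequence[str] | None = None,
    normalize: bool | Mapping[str, bool] = True,
    prefilter_sd: Mapping[str, float] | None = None,
    pseudocount: float | Mapping[str, float] = 0.0,
) -> TransferResult:
    """Train on one cohort, route an external cohort through the pathway.

    Per platform: library-size normalization and common-feature
    intersection, an optional training-side SD prefilter
    (``prefilter_sd`` maps platform name to the cutoff), log-ratio
    expansion with training-frozen pair retention, patient-level
    standardization, then the full ``r * k`` fold-model ensemble is
    trained on the transformed training assay and applied unchanged to
    the transformed external assay.

    If ``sequence`` is not given, candidate orderings are compared on the
    transformed training cohort (out-of-sample repeated CV) and the
    best-scoring sequence is used.  The external evaluation is computed
    when the external cohort carries truth labels.
    """
    train_assays: dict[str, PlatformAssay] = {}
    external_assays: dict[str, PlatformAssay] = {}
    specs: dict[str, LogRatioSpec] = {}
    for assay in train_cohort.assays:
        ext = external_cohort.assay(assay.name)
        norm = normalize if isinstance(normalize, bool) else normalize.get(assay.name, True)
        pc = (
            pseudocount
            if isinstance(pseudocount, (int, float))
            else pseudocount.get(assay.name, 0.0)
        )
        sd_cut = None if prefilter_sd is None else prefilter_sd.get(assay.name)
        tr, ex, spec = _transform_platform(assay, ext, norm, sd_cut, pc)
        train_assays[assay.name] = tr
        external_assays[assay.name] = ex
        specs[assay.name] = spec

    transformed_train = CohortDataset(
        assays=[train_assays[n] for n in train_cohort.platform_names],
        labels=train_cohort.labels,
        metadata=train_cohort.metadata,
    )

    train_predictions = {
        name: run_repeated_cv(a, train_cohort.labels, config)
        for name, a in train_assays.items()
    }
    if sequence is None:
        comparison = compare_pathways(transformed_train, config, train_predictions)
        sequence = comparison.best
    sequence = tuple(sequence)

    train_result = construct_pathway(
        sequence, train_predictions, config.confidence_threshold
    )
    train_evaluation = evaluate_pathway(
        train_result, train_cohort.labels, train_cohort.costs, config.positive_class
    )

    ensembles = {
        name: train_full_ensemble(a, train_cohort.labels, config)
        for name, a in train_assays.items()
    }
    external_predictions = {
        name: apply_ensemble(ensembles[name], external_assays[name])
        for name in train_assays
    }
    pathway_result = construct_pathway(
        sequence, external_predictions, config.confidence_threshold
    )
    evaluation = None
    if external_cohort.labels is not None and len(external_cohort.labels):
        evaluation = evaluate_pathway(
            pathway_result,
            external_cohort.labels,
            external_cohort.costs,
            config.positive_class,
        )
    return TransferResult(
        sequence=sequence,
        pathway_result=pathway_result,
        evaluation=evaluation,
        train_result=train_result,
        train_evaluation=train_evaluation,
        specs=specs,
        ensembles=ensembles,
        external_predictions=external_predictions,
    )
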