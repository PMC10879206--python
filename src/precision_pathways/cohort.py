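"""Data model and I/O for multi-platform patient cohorts.

A cohort couples one feature matrix per assay platform (samples in rows,
features in columns) with a binary outcome label per sample and a monetary
cost per platform.  All platforms of a cohort share an identical, ordered
set of sample identifiers so that downstream cross-validation folds and
pathway routing refer to the same patients everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.impute import KNNImputer

__all__ = [
    "PlatformAssay",
    "CohortDataset",
    "RunConfig",
    "load_cohort",
    "read_matrix",
    "preprocess_assay",
    "write_cohort",
]

#: Table of default run parameters (confidence threshold, fixed tiers,
#: criteria weights, folds, repeats, seed, candidate feature counts).
DEFAULT_FEATURE_COUNTS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass(frozen=True)
class PlatformAssay:
    """One platform's feature matrix plus the monetary cost of assaying it.

    Parameters
    ----------
    name:
        Platform name, unique within a cohort (e.g. ``"clinical"``).
    matrix:
        ``samples x features`` numeric table.  The index holds sample
        identifiers, the columns hold feature identifiers; both must be
        unique.
    cost:
        Non-negative money charged per patient each time this platform's
        assay is performed.
    """

    name: str
    matrix: pd.DataFrame
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in assay {self.name!r}: {dup}")
        if self.matrix.columns.has_duplicates:
            dup = self.matrix.columns[self.matrix.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers in assay {self.name!r}: {dup}")
        if self.cost < 0:
            raise ValueError(f"assay {self.name!r} has negative cost {self.cost}")

    @property
    def samples(self) -> pd.Index:
        return self.matrix.index

    @property
    def features(self) -> pd.Index:
        return self.matrix.columns

    def restrict(self, samples: Sequence[str]) -> "PlatformAssay":
        """Return the assay restricted to ``samples``, in that order."""
        return replace(self, matrix=self.matrix.loc[list(samples)])


@dataclass
class CohortDataset:
    """An ordered collection of aligned platform assays with outcome labels.

    Invariants: every labelled sample appears in every assay, rows are in
    identical order across assays, and both outcome classes are present
    with at least two samples each.  ``labels`` may be ``None`` for an
    external cohort whose truth is unknown (evaluation is then skipped
    downstream).
    """

    assays: list[PlatformAssay]
    labels: pd.Series | None
    metadata: pd.DataFrame | None = None
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assays:
            raise ValueError("a cohort needs at least one assay")
        ref = self.assays[0].samples
        for assay in self.assays[1:]:
            if not ref.equals(assay.samples):
                raise ValueError(
                    f"assay {assay.name!r} sample order differs from {self.assays[0].name!r}"
                )
        if self.labels is not None:
            if not ref.equals(self.labels.index):
                raise ValueError("label index does not match assay sample order")
            counts = self.labels.value_counts()
            if len(counts) != 2 or (counts < 2).any():
                raise ValueError(
                    f"need exactly two classes with >= 2 samples each, got {counts.to_dict()}"
                )
        if self.metadata is not None and not ref.equals(self.metadata.index):
            self.metadata = self.metadata.loc[ref]

    @property
    def samples(self) -> pd.Index:
        return self.assays[0].samples

    @property
    def platform_names(self) -> list[str]:
        return [a.name for a in self.assays]

    @property
    def classes(self) -> tuple[str, str]:
        """The two outcome classes in sorted, deterministic order."""
        return tuple(sorted(self.labels.unique()))  # type: ignore[return-value]

    @property
    def costs(self) -> dict[str, float]:
        return {a.name: a.cost for a in self.assays}

    def assay(self, name: str) -> PlatformAssay:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(f"no assay named {name!r}; have {self.platform_names}")


@dataclass(frozen=True)
class RunConfig:
    """Run parameters controlling cross-validation, routing and scoring.

    Defaults give the standard configuration: confidence threshold 0.9,
    one fixed leading tier, equal accuracy/cost weights, 2-fold
    cross-validation with 50 repeats, seed 1, candidate feature counts
    10..100 in steps of 10, t-test selection and the DLDA classifier.
    """

    confidence_threshold: float = 0.9
    fixed_tiers: int = 1
    weights: tuple[float, float] = (0.5, 0.5)
    folds: int = 2
    repeats: int = 50
    seed: int = 1
    feature_counts: tuple[int, ...] = DEFAULT_FEATURE_COUNTS
    classifier: str = "dlda"
    selector: str = "ttest"
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.fixed_tiers < 0:
            raise ValueError("fixed_tiers must be >= 0")
        if any(w < 0 for w in self.weights) or sum(self.weights) == 0:
            raise ValueError("weights must be non-negative and not all zero")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.feature_counts or any(c < 1 for c in self.feature_counts):
            raise ValueError("feature_counts must be positive integers")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "weights" in data:
            data["weights"] = tuple(data["weights"])
        if "feature_counts" in data:
            data["feature_counts"] = tuple(data["feature_counts"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "confidence_threshold": self.confidence_threshold,
            "fixed_tiers": self.fixed_tiers,
            "weights": list(self.weights),
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "feature_counts": list(self.feature_counts),
            "classifier": self.classifier,
            "selector": self.selector,
            "positive_class": self.positive_class,
        }


def read_matrix(path: str | Path, *, features_in_rows: bool = False) -> pd.DataFrame:
    """Read a CSV/TSV numeric matrix with sample ids in the first column.

    The delimiter is inferred from the extension (``.tsv``/``.txt`` use
    tabs).  Set ``features_in_rows=True`` to transpose a file stored with
    features in rows; orientation is never guessed silently.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if features_in_rows:
        df = df.T
    return df.astype(float)


def _read_config(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def load_cohort(config_path: str | Path) -> CohortDataset:
    """Load a cohort from a JSON/YAML configuration file.

    The configuration names one or more assay matrix files (with costs),
    a two-column label file and optionally a metadata table::

        assays:
          - {name: clinical, path: clinical.csv, cost: 30}
          - {name: lipidomics, path: lipids.csv, cost: 50}
        labels: labels.csv
        classes: [noCAD, CAD]       # optional; inferred otherwise
        positive_class: CAD          # optional
        metadata: covariates.csv     # optional

    Samples are aligned to the intersection of the identifiers present in
    every assay and the label file; samples outside the intersection are
    recorded in ``CohortDataset.dropped_samples``.  Relative paths resolve
    against the configuration file's directory.
    """
    config_path = Path(config_path)
    cfg = _read_config(config_path)
    base = config_path.parent
    if not cfg.get("assays"):
        raise ValueError(f"{config_path} lists no assays")

    assays = []
    for spec in cfg["assays"]:
        matrix = read_matrix(
            base / spec["path"], features_in_rows=bool(spec.get("features_in_rows", False))
        )
        assays.append(PlatformAssay(spec["name"], matrix, float(spec.get("cost", 0.0))))

    label_path = base / cfg["labels"]
    sep = "\t" if label_path.suffix.lower() in {".tsv", ".txt"} else ","
    label_df = pd.read_csv(label_path, sep=sep, dtype=str)
    labels = pd.Series(
        label_df.iloc[:, 1].values, index=label_df.iloc[:, 0].values, name="class"
    )
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in label file: {dup}")

    if "classes" in cfg:
        allowed = set(cfg["classes"])
        bad = sorted(set(labels.unique()) - allowed)
        if bad:
            raise ValueError(f"unknown class value(s) in label file: {bad}")
    elif labels.nunique() > 2:
        extra = sorted(labels.value_counts().index[2:])
        raise ValueError(f"more than two class values in label file: extra {extra}")

    common = labels.index
    for assay in assays:
        common = common.intersection(assay.samples)
    all_ids = set(labels.index).union(*(set(a.samples) for a in assays))
    dropped = sorted(all_ids - set(common))
    common = pd.Index([s for s in labels.index if s in set(common)])  # label-file order

    counts = labels.loc[common].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError(
            f"fewer than 2 samples per class after sample intersection: {counts.to_dict()}"
        )

    metadata = None
    if cfg.get("metadata"):
        meta_path = base / cfg["metadata"]
        msep = "\t" if meta_path.suffix.lower() in {".tsv", ".txt"} else ","
        metadata = pd.read_csv(meta_path, sep=msep, index_col=0)
        metadata.index = metadata.index.astype(str)
        metadata = metadata.loc[common]

    return CohortDataset(
        assays=[a.restrict(common) for a in assays],
        labels=labels.loc[common],
        metadata=metadata,
        dropped_samples=dropped,
    )


def preprocess_assay(
    assay: PlatformAssay,
    max_missing_fraction: float = 0.5,
    impute_neighbors: int = 5,
) -> PlatformAssay:
    """Drop over-missing features, then impute the rest by k nearest samples.

    Features missing in more than ``max_missing_fraction`` of samples are
    removed.  Each remaining missing cell is replaced by the mean of that
    feature in the ``impute_neighbors`` nearest samples, with nearness
    measured by Euclidean distance over mutually observed features.
    A complete matrix passes through unchanged (the operation is
    idempotent).
    """
    matrix = assay.matrix
    missing_frac = matrix.isna().mean(axis=0)
    kept = matrix.loc[:, missing_frac <= max_missing_fraction]
    if kept.shape[1] == 0:
        raise ValueError(f"no features of assay {assay.name!r} survive the missingness filter")
    all_missing = kept.isna().all(axis=1)
    if all_missing.any():
        bad = kept.index[all_missing].tolist()
        raise ValueError(f"sample(s) with all entries missing in {assay.name!r}: {bad}")
    if not kept.isna().any().any():
        return replace(assay, matrix=kept)
    if impute_neighbors >= kept.shape[0]:
        raise ValueError(
            f"impute_neighbors={impute_neighbors} must be smaller than "
            f"the number of samples ({kept.shape[0]})"
        )
    imputer = KNNImputer(n_neighbors=impute_neighbors, weights="uniform")
    filled = pd.DataFrame(imputer.fit_transform(kept), index=kept.index, columns=kept.columns)
    return replace(assay, matrix=filled)


def write_cohort(cohort: CohortDataset, outdir: str | Path, config_extra: dict | None = None) -> Path:
    """Write a cohort as CSV files plus a loadable YAML configuration.

    Emits one ``<platform>.csv`` per assay, ``labels.csv``, an optional
    ``metadata.csv`` and a ``cohort.yaml`` that :func:`load_cohort`
    accepts, so generated cohorts round-trip through the same entry
    points as user-supplied data.  Returns the configuration path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"assays": []}
    for assay in cohort.assays:
        fname = f"{assay.name}.csv"
        assay.matrix.to_csv(outdir / fname)
        cfg["assays"].append({"name": assay.name, "path": fname, "cost": assay.cost})
    if cohort.labels is not None:
        pd.DataFrame(
            {"sample": cohort.labels.index, "class": cohort.labels.values}
        ).to_csv(outdir / "labels.csv", index=False)
        cfg["labels"] = "labels.csv"
        cfg["classes"] = list(cohort.classes)
    if cohort.metadata is not None:
        cohort.metadata.to_csv(outdir / "metadata.csv")
        cfg["metadata"] = "metadata.csv"
    if config_extra:
        cfg.update(config_extra)
    path = outdir / "cohort.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
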