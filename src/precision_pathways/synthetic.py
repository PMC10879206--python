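"""Seeded synthetic multi-platform cohorts with planted structure.

The generator emulates the situation a sequential diagnostic pathway is
built for: several platforms of differing dimensionality measured on the
same patients, where each platform separates the two outcome classes only
for its own subpopulation of patients — the rest of the cohort looks like
noise on that platform and must progress to a later, usually more
expensive, assay.  Ground truth records which platform "resolves" each
patient, so stage occupancies and routing accuracy can be checked against
the planted design.

Defaults describe a sparse-biomarker platform: 100 features of which 3 are
informative, unit noise, Gaussian intensities.  Count-like platforms
(``distribution="lognormal"``) produce strictly positive values suitable
for library-size normalization and log-ratio transfer.  External cohorts
add per-sample scale factors and partial feature overlap, mimicking the
shift between a count-based and a fluorescence-based technology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset, PlatformAssay

__all__ = ["PlatformSpec", "SyntheticSpec", "SyntheticTruth", "generate_cohort", "generate_external"]

CLASSES = ("healthy", "disease")


@dataclass(frozen=True)
class PlatformSpec:
    """Generative description of one platform.

    ``effect_size`` is the between-class mean difference on informative
    features in units of ``noise_sd``, applied only to patients of this
    platform's subpopulation; ``subpop_fraction`` is that subpopulation's
    share of the cohort.  ``distribution`` is ``"gaussian"`` for
    intensity-like data or ``"lognormal"`` for strictly positive
    count-like data (the class shift is planted on the log scale).
    """

    name: str
    n_features: int = 100
    n_informative: int = 3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    cost: float = 0.0
    subpop_fraction: float = 1.0
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.subpop_fraction <= 1.0:
            raise ValueError("subpop_fraction must lie in [0, 1]")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if self.distribution not in {"gaussian", "lognormal"}:
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full cohort recipe: patients, class balance, platforms, external shift.

    Platform subpopulations are disjoint and assigned in platform order
    (fractions must sum to at most 1; leftover patients are resolved by no
    platform).  ``external_scale_range`` draws log-uniform per-sample
    scale factors for the external cohort; ``external_feature_overlap``
    is the fraction of training features the external platform shares.
    """

    platforms: tuple[PlatformSpec, ...]
    n_patients: int = 200
    class_balance: float = 0.5
    classes: tuple[str, str] = CLASSES
    seed: int = 1
    external_n_patients: int | None = None
    external_scale_range: tuple[float, float] = (1.0, 1.0)
    external_feature_overlap: float = 1.0
    external_offset_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.platforms:
            raise ValueError("need at least one platform")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        total = sum(p.subpop_fraction for p in self.platforms)
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"platform subpopulation fractions sum to {total:.3f} > 1"
            )
        if not 0.0 <= self.external_feature_overlap <= 1.0:
            raise ValueError("external_feature_overlap must lie in [0, 1]")
        if self.external_scale_range[0] <= 0:
            raise ValueError("external scale factors must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-patient resolver and informative features."""

    table: pd.DataFrame  # patient, class, resolving_platform
    informative_features: dict[str, list[str]]


def _assign_classes(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(spec.class_balance * n))
    n_pos = min(max(n_pos, 2), n - 2)
    y = np.array([spec.classes[1]] * n_pos + [spec.classes[0]] * (n - n_pos), dtype=object)
    rng.shuffle(y)
    return y


def _assign_subpops(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    resolver = np.array(["none"] * n, dtype=object)
    start = 0
    for p in spec.platforms:
        size = int(round(p.subpop_fraction * n))
        resolver[order[start : start + size]] = p.name
        start += size
    return resolver


def _platform_matrix(
    p: PlatformSpec,
    y: np.ndarray,
    resolver: np.ndarray,
    classes: tuple[str, str],
    rng: np.random.Generator,
    n_extra_features: int = 0,
    feature_prefix: str = "",
) -> pd.DataFrame:
    n = len(y)
    n_feat = p.n_features + n_extra_features
    X = rng.normal(0.0, p.noise_sd, size=(n, n_feat))
    in_subpop = resolver == p.name
    shift = p.effect_size * p.noise_sd / 2.0
    sign = np.where(y == classes[1], 1.0, -1.0)
    X[:, : p.n_informative] += np.where(in_subpop, sign, 0.0)[:, None] * shift
    if p.distribution == "lognormal":
        X = np.exp(X + 5.0)  # log-normal counts around e^5
    columns = [f"{feature_prefix}{p.name}_f{i}" for i in range(n_feat)]
    return pd.DataFrame(X, columns=columns)


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortDataset, SyntheticTruth]:
    """Draw a cohort from the spec; byte-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patients = pd.Index([f"P{i:04d}" for i in range(n)], name="patient")
    y = _assign_classes(spec, n, rng)
    resolver = _assign_subpops(spec, n, rng)

    assays, informative = [], {}
    for p in spec.platforms:
        matrix = _platform_matrix(p, y, resolver, spec.classes, rng)
        matrix.index = patients
        assays.append(PlatformAssay(name=p.name, matrix=matrix, cost=p.cost))
        informative[p.name] = list(matrix.columns[: p.n_informative])

    labels = pd.Series(y, index=patients, name="class")
    metadata = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.integers(35, 80, size=n).astype(float),
        },
        index=patients,
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"class": y, "resolving_platform": resolver}, index=patients
        ),
        informative_features=informative,
    )
    return CohortDataset(assays=assays, labels=labels, metadata=metadata), truth


def generate_external(
    spec: SyntheticSpec, cohort: CohortDataset | None = None
) -> tuple[CohortDataset, SyntheticTruth]:
    """Draw an external cohort under the spec's distortion parameters.

    The class-conditional structure is that of the training spec; new
    patients are drawn with an independent seeded stream and then
    distorted: each sample's row is multiplied by a log-uniform scale
    factor from ``external_scale_range`` (platform shift), optional
    per-feature offsets are added (``external_offset_sd``; Gaussian
    platforms only), and only a fraction ``external_feature_overlap`` of
    each platform's training features is kept, padded with external-only
    features so feature intersection is non-trivial.
    """
    rng = np.random.default_rng([spec.seed, 987654321])
    n = spec.external_n_patients or spec.n_patients
    patients = pd.Index([f"E{i:04d}" for i in range(n)], name="patient")
    y = _assign_classes(spec, n, rng)
    resolver = _assign_subpops(spec, n, rng)

    lo, hi = spec.external_scale_range
    assays, informative = [], {}
    for p in spec.platforms:
        matrix = _platform_matrix(p, y, resolver, spec.classes, rng)
        matrix.index = patients

        n_keep = int(round(spec.external_feature_overlap * p.n_features))
        kept = list(matrix.columns[:n_keep])
        dropped = p.n_features - n_keep
        matrix = matrix[kept]
        if dropped:
            extra = pd.DataFrame(
                rng.normal(0.0, p.noise_sd, size=(n, dropped)),
                index=patients,
                columns=[f"{p.name}_ext{i}" for i in range(dropped)],
            )
            if p.distribution == "lognormal":
                extra = np.exp(extra + 5.0)
            matrix = pd.concat([matrix, extra], axis=1)

        if spec.external_offset_sd > 0 and p.distribution == "gaussian":
            matrix = matrix + rng.normal(0.0, spec.external_offset_sd, size=matrix.shape[1])
        scales = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        matrix = matrix.mul(scales, axis=0)

        assays.append(PlatformAssay(name=p.name, matrix=matrix, cost=p.cost))
        informative[p.name] = [f for f in kept if f in set(cohort.assay(p.name).features)] if cohort else kept

    labels = pd.Series(y, index=patients, name="class")
    truth = SyntheticTruth(
        table=pd.DataFrame({"class": y, "resolving_platform": resolver}, index=patients),
        informative_features=informative,
    )
    return CohortDataset(assays=assays, labels=labels), truth
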