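"""1-nearest-neighbor classification of muscle patterns with leave-one-out CV.

Each trial-limb pattern of one muscle is flattened to a feature vector
(14 bands x 300 frames = 4200 features for the whole hop, 14 x 100 =
1400 for a single phase) and classified by its Euclidean-nearest
neighbor among the remaining vectors.  Three pair-wise comparisons are
supported:

1. ``Control_Idx vs Control_Contra`` — limb symmetry in controls,
2. ``ACLR_Sx vs ACLR_Contra``       — limb symmetry in patients,
3. ``ACLR_Contra vs Control_Idx``   — patient contralateral vs control.

Cross-validation can leave out a single trial (``cv_unit="trial"``) or
all trials of a subject at once (``cv_unit="subject"``, the default):
repeated trials of one subject are highly correlated, and a same-subject
nearest neighbor in comparisons 1-2 or a same-subject fold in
comparison 3 would leak identity into the label prediction.  Ties at
equal distance are broken toward the lowest sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError
from .patterning import NormalizedPattern
from .signal_io import MUSCLES

__all__ = [
    "ComparisonSpec",
    "ClassificationResult",
    "COMPARISONS",
    "vectorize",
    "knn_loocv",
    "run_comparisons",
]

COMPARISON_NAMES = (
    "Control_Idx vs Control_Contra",
    "ACLR_Sx vs ACLR_Contra",
    "ACLR_Contra vs Control_Idx",
)


@dataclass(frozen=True)
class ComparisonSpec:
    """One pair-wise comparison at one phase scope."""

    name: str
    phase_scope: str = "all"  # all | take-off | airborne | landing
    cv_unit: str = "subject"  # subject | trial
    k: int = 1
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.name not in COMPARISON_NAMES:
            raise ConfigurationError(f"unknown comparison {self.name!r}")
        if self.cv_unit not in ("subject", "trial"):
            raise ConfigurationError(f"unknown cv_unit {self.cv_unit!r}")
        if self.k != 1:
            raise ConfigurationError("only k = 1 is supported")


COMPARISONS = tuple(ComparisonSpec(name) for name in COMPARISON_NAMES)


@dataclass(frozen=True)
class ClassificationResult:
    """Correct/total counts for one muscle under one comparison."""

    muscle: str
    comparison: str
    phase_scope: str
    n_correct: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise ConfigurationError("need 0 <= n_correct <= n_total")

    @property
    def rate_percent(self) -> float:
        return round(100.0 * self.n_correct / self.n_total, 1)


def vectorize(pattern: NormalizedPattern, phase_scope: str = "all") -> np.ndarray:
    """Row-major flattening of the pattern's sub-matrix for one scope."""
    cols = pattern.phase_columns(phase_scope)
    return pattern.values[:, cols].ravel(order="C").copy()


def _check_leakage(X: np.ndarray, labels: np.ndarray) -> None:
    # identical vectors carrying different labels indicate a data-handling bug
    order = np.lexsort(X.T)
    for a, b in zip(order[:-1], order[1:]):
        if labels[a] != labels[b] and np.array_equal(X[a], X[b]):
            warnings.warn(
                "identical feature vectors appear in both classes; possible leakage",
                RuntimeWarning,
                stacklevel=3,
            )
            return


def knn_loocv(
    X: np.ndarray,
    labels,
    spec: ComparisonSpec,
    groups=None,
    muscle: str = "",
) -> ClassificationResult:
    """1-NN leave-one-out cross-validation over labeled vectors.

    ``groups`` assigns each row to a CV unit (e.g. a subject id); with
    ``cv_unit="subject"`` every row sharing the held-out row's group is
    excluded from the reference set.  With untied distances the result
    is deterministic; exact ties resolve to the lowest row index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ConfigurationError("need at least 2 samples for leave-one-out CV")
    if len(set(labels.tolist())) < 2:
        raise ConfigurationError("need samples from both classes")
    if groups is None or spec.cv_unit == "trial":
        groups = np.arange(n)
    else:
        groups = np.asarray(groups)
    _check_leakage(X, labels)
    dist = cdist(X, X, metric=spec.distance)
    correct = 0
    for i in range(n):
        mask = groups == groups[i]
        row = dist[i].copy()
        row[mask] = np.inf
        if not np.isfinite(row).any():
            raise ConfigurationError("a CV fold left no reference samples")
        j = int(np.argmin(row))  # argmin takes the lowest index on ties
        correct += int(labels[j] == labels[i])
    return ClassificationResult(
        muscle=muscle,
        comparison=spec.name,
        phase_scope=spec.phase_scope,
        n_correct=correct,
        n_total=n,
    )


def _select(patterns, muscle, group, limb):
    return [
        p
        for p in patterns
        if p.muscle == muscle and p.group == group and p.limb == limb
    ]


def _comparison_sides(name: str):
    # each side: (group, limb, class label)
    if name == "Control_Idx vs Control_Contra":
        return ("Control", "index", "index"), ("Control", "contralateral", "contralateral")
    if name == "ACLR_Sx vs ACLR_Contra":
        return ("ACLR", "index", "surgical"), ("ACLR", "contralateral", "contralateral")
    return ("ACLR", "contralateral", "ACLR"), ("Control", "index", "Control")


def run_comparisons(patterns, specs=COMPARISONS, muscles=MUSCLES) -> list[ClassificationResult]:
    """The per-muscle grid of classification results for the given specs.

    ``patterns`` is a flat collection of NormalizedPattern with their
    provenance labels filled in; subjects missing a limb simply
    contribute no vectors on that side.
    """
    results = []
    for spec in specs:
        (ga, la, lab_a), (gb, lb, lab_b) = _comparison_sides(spec.name)
        for muscle in muscles:
            side_a = _select(patterns, muscle, ga, la)
            side_b = _select(patterns, muscle, gb, lb)
            if not side_a or not side_b:
                raise ConfigurationError(
                    f"comparison {spec.name!r} has an empty class for muscle {muscle}"
                )
            sel = side_a + side_b
            X = np.stack([vectorize(p, spec.phase_scope) for p in sel])
            labels = np.array([lab_a] * len(side_a) + [lab_b] * len(side_b))
            groups = np.array([p.subject_id for p in sel])
            results.append(
                knn_loocv(X, labels, spec, groups=groups, muscle=muscle)
            )
    return results
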