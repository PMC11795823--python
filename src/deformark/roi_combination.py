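"""Exhaustive region-subset search and final test-set evaluation.

All 2^n - 1 nonempty subsets of the refined regions are scored by
cross-validated training AUC of a linear SVM on the union of their
pixels' deformation magnitudes. The winning subset (ties: smaller
subset, then lexicographic) is refit once on the full training set and
evaluated exactly once on the reserved test subjects, producing the
ROC curve, test AUC and the Youden-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .locale_screening import auc_from_scores
from .roi_refinement import Region, RegionScorer

MAX_REGIONS = 22  # 2^22 subsets is the enumerability guard


@dataclass
class LinearModel:
    """Frozen linear scoring rule: score(x) = ((x - mu) / sd) . w + b."""

    pixels: list[tuple[int, int]]
    mu: np.ndarray
    sd: np.ndarray
    w: np.ndarray
    b: float

    def score(self, magnitude_stack: np.ndarray, subject_indices: np.ndarray) -> np.ndarray:
        rows = np.array([p[0] for p in self.pixels])
        cols = np.array([p[1] for p in self.pixels])
        idx = np.asarray(subject_indices)
        X = magnitude_stack[idx[:, None], rows[None, :], cols[None, :]]
        return ((X - self.mu) / self.sd) @ self.w + self.b

    def to_dict(self) -> dict:
        return {
            "pixels": [list(p) for p in self.pixels],
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "w": self.w.tolist(),
            "b": float(self.b),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            pixels=[tuple(p) for p in d["pixels"]],
            mu=np.asarray(d["mu"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
        )


@dataclass
class CombinationResult:
    region_indices: tuple[int, ...]
    train_auc: float
    test_auc: float
    roc: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    sensitivity: float
    specificity: float
    operating_threshold: float
    all_subset_aucs: dict[tuple[int, ...], float] = field(default_factory=dict)
    model: LinearModel | None = None

    def to_dict(self) -> dict:
        return {
            "region_indices": list(self.region_indices),
            "train_auc": self.train_auc,
            "test_auc": self.test_auc,
            "roc": [list(v) for v in self.roc],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "operating_threshold": self.operating_threshold,
            "subset_train_aucs": {
                ",".join(map(str, k)): v for k, v in self.all_subset_aucs.items()
            },
            "model": self.model.to_dict() if self.model else None,
        }


def _union_pixels(regions: list[Region], subset: tuple[int, ...]) -> frozenset:
    return frozenset().union(*(regions[i].pixels for i in subset))


def evaluate_combination(
    regions: list[Region], subset: tuple[int, ...], scorer: RegionScorer
) -> float:
    """Cross-validated training AUC of the union of the subset's pixels.

    Duplicate region indices are idempotent (the pixel sets union).
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    return scorer.score(_union_pixels(regions, tuple(set(subset))))


def operating_point(roc: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) maximizing Youden's J.

    J = sensitivity + specificity - 1 = tpr - fpr; ties resolve to the
    vertex with higher sensitivity.
    """
    if not roc:
        raise ValueError("ROC is empty")
    best = max(roc, key=lambda v: (v[1] - v[0], v[1]))
    fpr, tpr, thr = best
    return (float(tpr), float(1.0 - fpr), float(thr))


def fit_final_model(
    regions: list[Region], subset: tuple[int, ...], scorer: RegionScorer
) -> LinearModel:
    """Refit the linear SVM on the full training set for the subset's union."""
    pixels = sorted(_union_pixels(regions, subset))
    X = scorer.features(pixels, scorer.train_idx)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((X - mu) / sd, scorer.y_train)
    return LinearModel(
        pixels=pixels,
        mu=mu,
        sd=sd,
        w=clf.coef_.ravel().copy(),
        b=float(clf.intercept_[0]),
    )


def search_combinations(
    regions: list[Region], scorer: RegionScorer
) -> CombinationResult:
    """Exhaustively evaluate every nonempty region subset.

    The winner (max training AUC; ties to the smallest then
    lexicographically first subset) is refit on the full training set
    and scored once on the reserved test subjects.
    """
    n = len(regions)
    if n == 0:
        raise ValueError("no regions to combine")
    if n > MAX_REGIONS:
        raise ValueError(
            f"{n} regions gives 2^{n} subsets; raise the AUC threshold (or max_regions cap) "
            f"to at most {MAX_REGIONS} regions"
        )
    subset_aucs: dict[tuple[int, ...], float] = {}
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            subset_aucs[subset] = evaluate_combination(regions, subset, scorer)
    winner = max(subset_aucs, key=lambda s: (subset_aucs[s], -len(s), tuple(-i for i in s)))
    train_auc = subset_aucs[winner]

    model = fit_final_model(regions, winner, scorer)
    test_idx = scorer.cohort.test_indices
    y_test = scorer.cohort.labels[test_idx]
    scores = model.score(scorer.cohort.magnitude_stack, test_idx)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test subjects must contain both classes")
    test_auc = auc_from_scores(scores, y_test)
    fpr, tpr, thr = roc_curve(y_test, scores)
    roc = [(float(f), float(t), float(h)) for f, t, h in zip(fpr, tpr, thr)]
    sens, spec, op_thr = operating_point(roc)
    return CombinationResult(
        region_indices=winner,
        train_auc=train_auc,
        test_auc=test_auc,
        roc=roc,
        sensitivity=sens,
        specificity=spec,
        operating_threshold=op_thr,
        all_subset_aucs=subset_aucs,
        model=model,
    )


def crosscheck_fraction_negative(
    model: LinearModel,
    operating_threshold: float,
    magnitude_stack: np.ndarray,
) -> float:
    """Fraction of an external cohort scored below the operating threshold.

    The external-cohort analogue of specificity: with a cohort known to
    lack the condition, this is the frozen model's negative rate.
    """
    n = magnitude_stack.shape[0]
    if n == 0:
        raise ValueError("external cohort is empty")
    scores = model.score(magnitude_stack, np.arange(n))
    return float(np.mean(scores < operating_threshold))
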