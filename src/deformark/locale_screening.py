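"""Searchlight screening: per-pixel cross-validated AUC of locale features.

Every pixel of the reference grid is treated as a candidate biomarker
seed: the deformation magnitudes in its k x k neighborhood (the
"locale", 9 x 9 = 81 features by default), collected across subjects,
feed a linear maximum-margin classifier evaluated with stratified
8-fold cross-validation on the training subjects. The per-seed mean
validation AUC forms the AUC map; the reserved test subjects are never
touched at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import _libsvm as _libsvm

_libsvm.set_verbosity_wrap(0)


def linear_svm_scores(Z_train: np.ndarray, y_train: np.ndarray, Z_eval: np.ndarray) -> np.ndarray:
    """Decision values of a linear-kernel SVM (C = 1) on ``Z_eval``.

    Calls libsvm's C-SVC solver directly (the same solver behind
    ``sklearn.svm.SVC``), skipping the per-call validation layer: the
    searchlight sweep fits this model at every pixel, so the wrapper
    overhead dominates otherwise. Agreement with
    ``SVC(kernel='linear').decision_function`` is exact and asserted in
    the test suite.
    """
    out = _libsvm.fit(
        np.ascontiguousarray(Z_train, dtype=np.float64),
        np.ascontiguousarray(y_train, dtype=np.float64),
        svm_type=0,
        kernel="linear",
        C=1.0,
    )
    sv, dual_coef, intercept = out[1], out[3], out[4]
    w = dual_coef[0] @ sv
    return -(np.asarray(Z_eval, dtype=np.float64) @ w + intercept[0])

from .registration import DeformationField, field_magnitude


# --------------------------------------------------------------------------
# Cohort feature container
# --------------------------------------------------------------------------


@dataclass
class CohortFeatures:
    """Per-subject deformation-magnitude maps plus labels and the split.

    ``labels`` uses 0 = control, 1 = disease. ``split`` is a boolean
    train mask over subjects (True = training).
    """

    magnitude_stack: np.ndarray  # (n_subjects, H, W)
    labels: np.ndarray  # (n_subjects,) in {0, 1}
    subject_ids: list[str]
    split: np.ndarray  # (n_subjects,) bool, True = train

    def __post_init__(self) -> None:
        self.magnitude_stack = np.asarray(self.magnitude_stack, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.split = np.asarray(self.split, dtype=bool)
        n = self.magnitude_stack.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == len(self.split) == n):
            raise ValueError("inconsistent cohort sizes")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("labels must contain both classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude_stack.shape[1:]

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.split)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.split)


def cohort_features_from_fields(
    fields: dict[str, DeformationField],
    labels: np.ndarray | list[int],
    subject_ids: list[str],
    split: np.ndarray,
) -> CohortFeatures:
    stack = np.stack([field_magnitude(fields[sid]) for sid in subject_ids])
    return CohortFeatures(stack, np.asarray(labels), list(subject_ids), split)


@dataclass
class AUCMap:
    """Per-pixel mean cross-validated AUC with a validity mask.

    The mask is False wherever the k x k locale would exit the image —
    a border band of width (k - 1) / 2.
    """

    auc: np.ndarray
    valid_mask: np.ndarray
    k: int

    def __post_init__(self) -> None:
        vals = self.auc[self.valid_mask]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("AUC values must lie in [0, 1] on the valid mask")


# --------------------------------------------------------------------------
# Core statistics
# --------------------------------------------------------------------------


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic.

    Fraction of (disease, control) pairs where the disease score is
    higher, ties counting one half — computed exactly via average
    ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def stratified_split(
    labels: np.ndarray | list[int], ratio: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Boolean train mask with round(ratio * class size) per class.

    Deterministic given the seed; rounding is half-up so the per-class
    train count is unambiguous.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects")
        n_train = int(np.floor(ratio * len(idx) + 0.5))
        chosen = rng.permutation(idx)[:n_train]
        train[chosen] = True
    return train


def make_folds(labels: np.ndarray, n_folds: int = 8, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs (train, validation) over ``labels``."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds and counts.min() < 2:
        raise ValueError("each class needs at least 2 subjects for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]


def cv_auc(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 8,
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean validation AUC of a linear SVM over stratified folds.

    Per fold: features are standardized by the fold-train mean/SD (no
    leakage from validation), a linear-kernel SVM with unit cost is
    fitted, and the held-out decision values are scored with
    ``auc_from_scores``. Folds whose validation part contains a single
    class are skipped and the mean renormalized over the rest.
    Degenerate (all-identical) features return the chance value 0.5.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        X = X.reshape(len(y), -1)
    if np.ptp(X) == 0:
        return 0.5
    if folds is None:
        folds = make_folds(y, n_folds=n_folds, seed=seed)
    aucs = []
    for tr, va in folds:
        y_tr, y_va = y[tr], y[va]
        if len(np.unique(y_va)) < 2 or len(np.unique(y_tr)) < 2:
            continue
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Z_tr = (X[tr] - mu) / sd
        Z_va = (X[va] - mu) / sd
        aucs.append(auc_from_scores(linear_svm_scores(Z_tr, y_tr, Z_va), y_va))
    if not aucs:
        return 0.5
    return float(np.mean(aucs))


def peak_location(auc_map: "AUCMap") -> tuple[float, float]:
    """Location of the AUC map's maximum, robust to saturated plateaus.

    A strong effect saturates the cross-validated AUC at 1.0 over a
    contiguous plateau (the locale window extends every seed's reach by
    (k-1)/2 pixels), making the raster-first argmax a biased estimate
    of the plateau's edge. The centroid of the maximal-AUC pixel set is
    returned instead; for a unique maximum it is that pixel.
    """
    vals = np.where(auc_map.valid_mask, np.nan_to_num(auc_map.auc, nan=-1.0), -1.0)
    ties = np.argwhere(vals == vals.max())
    r, c = ties.mean(axis=0)
    return (float(r), float(c))


# --------------------------------------------------------------------------
# Locale extraction and the full sweep
# --------------------------------------------------------------------------


def extract_locale(
    magnitude_stack: np.ndarray, seed_pixel: tuple[int, int], k: int = 9
) -> np.ndarray:
    """Subjects x k^2 feature matrix of the locale centered on ``seed_pixel``."""
    if k % 2 != 1 or k < 1:
        raise ValueError("locale size k must be odd and positive")
    h = k // 2
    r, c = seed_pixel
    n, H, W = magnitude_stack.shape
    if not (h <= r < H - h and h <= c < W - h):
        raise IndexError(f"seed {seed_pixel} closer than {h} px to the border of {(H, W)}")
    return magnitude_stack[:, r - h : r + h + 1, c - h : c + h + 1].reshape(n, k * k)


def screen_all_seeds(
    cohort: CohortFeatures,
    k: int = 9,
    n_folds: int = 8,
    seed: int = 0,
) -> AUCMap:
    """Sweep every valid seed pixel and build the AUC map.

    Only training subjects enter the cross-validation; the fold
    partition is drawn once and reused for every seed so that maps are
    comparable across pixels.
    """
    if k % 2 != 1 or k < 1:
        raise ValueError("locale size k must be odd and positive")
    h = k // 2
    H, W = cohort.shape
    tr_idx = cohort.train_indices
    y_tr = cohort.labels[tr_idx]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training subjects must contain both classes")
    folds = make_folds(y_tr, n_folds=n_folds, seed=seed)

    # (n, H-k+1, W-k+1, k, k) sliding view: no copies until flattening
    windows = sliding_window_view(cohort.magnitude_stack[tr_idx], (k, k), axis=(1, 2))

    auc = np.full((H, W), np.nan)
    valid = np.zeros((H, W), dtype=bool)
    valid[h : H - h, h : W - h] = True
    n_tr = len(tr_idx)
    for r in range(h, H - h):
        block = windows[:, r - h]  # (n, W-k+1, k, k)
        for c in range(h, W - h):
            X = block[:, c - h].reshape(n_tr, k * k)
            auc[r, c] = cv_auc(X, y_tr, folds=folds)
    return AUCMap(auc=auc, valid_mask=valid, k=k)
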