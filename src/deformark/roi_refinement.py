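"""Region extraction and greedy boundary optimization on the AUC map.

The AUC map is thresholded (default 0.62 — deliberately low so small
highly-predictive regions bordered by weaker pixels survive) into
8-connected components. Each component is then refined by a greedy
two-stage local search: (1) whole-ring dilation until the
cross-validated AUC plateaus, rolling back to the best state, and
(2) per-pixel inclusion/exclusion sweeps over the boundary until a full
pass makes no change. Regions that end up touching are merged and
re-scored once. The search is greedy by construction — it finds a
local, not global, optimum of the region-AUC objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .locale_screening import CohortFeatures, cv_auc, make_folds

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class Region:
    """A set of reference-grid pixels with its training AUC.

    ``history`` records (step-name, auc) pairs through refinement.
    """

    pixels: frozenset[tuple[int, int]]
    train_auc: float
    history: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("region must be nonempty")
        if not (-1e-9 <= self.train_auc <= 1 + 1e-9):
            raise ValueError("train AUC must lie in [0, 1]")

    @property
    def sorted_pixels(self) -> list[tuple[int, int]]:
        return sorted(self.pixels)

    def __len__(self) -> int:
        return len(self.pixels)


class RegionScorer:
    """Scores arbitrary pixel sets by cross-validated AUC.

    The feature vector of a pixel set is the per-subject deformation
    magnitude at each member pixel (the locale feature construction
    generalized to arbitrary sets). Folds are fixed once so every
    candidate region is scored under the same partition; scores are
    cached, which makes the repeated evaluations of the greedy search
    cheap when states are revisited.
    """

    def __init__(self, cohort: CohortFeatures, n_folds: int = 8, seed: int = 0):
        self.cohort = cohort
        self.train_idx = cohort.train_indices
        self.y_train = cohort.labels[self.train_idx]
        self.folds = make_folds(self.y_train, n_folds=n_folds, seed=seed)
        self._cache: dict[frozenset, float] = {}

    def features(self, pixels, subject_indices: np.ndarray) -> np.ndarray:
        px = sorted(pixels)
        rows = np.array([p[0] for p in px])
        cols = np.array([p[1] for p in px])
        idx = np.asarray(subject_indices)
        return self.cohort.magnitude_stack[idx[:, None], rows[None, :], cols[None, :]]

    def score(self, pixels) -> float:
        key = frozenset(pixels)
        if key not in self._cache:
            X = self.features(key, self.train_idx)
            self._cache[key] = cv_auc(X, self.y_train, folds=self.folds)
        return self._cache[key]


def threshold_regions(
    auc_map, scorer: RegionScorer, threshold: float = 0.62
) -> list[Region]:
    """8-connected components of supra-threshold valid pixels.

    Each component is scored by cross-validated AUC over its pixels'
    magnitudes; the list is sorted by descending pixel count.
    """
    mask = auc_map.valid_mask & (np.nan_to_num(auc_map.auc, nan=-1.0) > threshold)
    labeled, n = ndimage.label(mask, structure=_EIGHT)
    regions = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labeled == lab)
        pixels = frozenset((int(r), int(c)) for r, c in coords)
        auc = scorer.score(pixels)
        regions.append(Region(pixels=pixels, train_auc=auc, history=[("threshold", auc)]))
    regions.sort(key=lambda rg: (-len(rg.pixels), rg.sorted_pixels[0]))
    return regions


def _ring(pixels, valid_mask: np.ndarray) -> set[tuple[int, int]]:
    """Exterior one-pixel 8-neighborhood of a pixel set, inside the mask."""
    H, W = valid_mask.shape
    out: set[tuple[int, int]] = set()
    for r, c in pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and valid_mask[rr, cc]:
                    out.add((rr, cc))
    return out - set(pixels)


def grow_region(
    region: Region,
    scorer: RegionScorer,
    valid_mask: np.ndarray,
    plateau_eps: float = 1e-3,
    patience: int = 2,
    max_dilations: int = 25,
) -> Region:
    """Dilate by whole one-pixel rings until the AUC plateaus.

    Stops when the AUC drops, or improves by less than ``plateau_eps``
    for ``patience`` consecutive dilations, then rolls back to the
    best-scoring state seen. ``max_dilations`` bounds the search.
    """
    history = list(region.history)
    cur = set(region.pixels)
    prev_auc = region.train_auc
    best_pixels, best_auc = frozenset(cur), region.train_auc
    stalled = 0
    for _ in range(max_dilations):
        ring = _ring(cur, valid_mask)
        if not ring:
            break
        cur |= ring
        auc = scorer.score(cur)
        history.append(("dilate", auc))
        if auc > best_auc:
            best_pixels, best_auc = frozenset(cur), auc
        if auc < prev_auc:
            break
        if auc - prev_auc < plateau_eps:
            stalled += 1
            if stalled >= patience:
                break
        else:
            stalled = 0
        prev_auc = auc
    history.append(("rollback", best_auc))
    return Region(pixels=best_pixels, train_auc=best_auc, history=history)


def boundary_sweep(
    region: Region,
    scorer: RegionScorer,
    valid_mask: np.ndarray,
    max_passes: int = 10,
) -> Region:
    """Per-pixel greedy inclusion/exclusion passes over the boundary.

    Each pass tests every exterior 8-neighbor for inclusion and every
    boundary pixel for exclusion, in raster order, accepting a move
    only if the AUC strictly increases (exclusion additionally may not
    empty the region). Stops at a fixed point or after ``max_passes``.
    """
    cur = set(region.pixels)
    auc = region.train_auc
    history = list(region.history)
    for _ in range(max_passes):
        changed = False
        for px in sorted(_ring(cur, valid_mask)):
            trial = scorer.score(cur | {px})
            if trial > auc:
                cur.add(px)
                auc = trial
                history.append(("include", auc))
                changed = True
        boundary = [p for p in sorted(cur) if _ring({p}, valid_mask) - cur]
        for px in boundary:
            if len(cur) == 1:
                break
            if px not in cur:
                continue
            trial = scorer.score(cur - {px})
            if trial > auc:
                cur.discard(px)
                auc = trial
                history.append(("exclude", auc))
                changed = True
        if not changed:
            break
    return Region(pixels=frozenset(cur), train_auc=auc, history=history)


def _merge_touching(regions: list[Region], scorer: RegionScorer) -> list[Region]:
    """Union-find merge of regions sharing or 8-adjacent pixels."""
    n = len(regions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    expanded = []
    for rg in regions:
        s = set(rg.pixels)
        grown = set(s)
        for r, c in s:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    grown.add((r + dr, c + dc))
        expanded.append(grown)
    for i in range(n):
        for j in range(i + 1, n):
            if expanded[i] & set(regions[j].pixels) or expanded[j] & set(regions[i].pixels):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) == 1:
            out.append(regions[members[0]])
            continue
        union = frozenset().union(*(regions[i].pixels for i in members))
        auc = scorer.score(union)
        hist = [h for i in members for h in regions[i].history] + [("merge", auc)]
        out.append(Region(pixels=union, train_auc=auc, history=hist))
    return out


def refine_all(
    auc_map,
    scorer: RegionScorer,
    threshold: float = 0.62,
    plateau_eps: float = 1e-3,
    patience: int = 2,
    max_passes: int = 10,
    max_regions: int | None = 10,
) -> list[Region]:
    """Threshold, grow, sweep and merge; returns regions by descending AUC.

    ``max_regions`` caps how many components (the best-scoring ones)
    enter refinement; it bounds both the greedy search and the
    exhaustive combination stage downstream.
    """
    regions = threshold_regions(auc_map, scorer, threshold=threshold)
    if not regions:
        return []
    if max_regions is not None and len(regions) > max_regions:
        regions = sorted(regions, key=lambda rg: -rg.train_auc)[:max_regions]
    refined = []
    for rg in regions:
        grown = grow_region(
            rg, scorer, auc_map.valid_mask, plateau_eps=plateau_eps, patience=patience
        )
        swept = boundary_sweep(grown, scorer, auc_map.valid_mask, max_passes=max_passes)
        refined.append(swept)
    merged = _merge_touching(refined, scorer)
    merged.sort(key=lambda rg: (-rg.train_auc, rg.sorted_pixels[0]))
    return merged


def regions_to_mask(regions: list[Region], shape: tuple[int, int]) -> np.ndarray:
    """Integer label mask (0 = background, i = region i, 1-based)."""
    mask = np.zeros(shape, dtype=np.int16)
    for i, rg in enumerate(regions, start=1):
        for r, c in rg.pixels:
            mask[r, c] = i
    return mask
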