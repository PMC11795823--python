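"""Region extraction, greedy growth and boundary sweeps on the AUC map."""

import numpy as np

import deformark as dm
from deformark.locale_screening import AUCMap
from deformark.roi_refinement import (
    RegionScorer,
    _merge_touching,
    boundary_sweep,
    grow_region,
    refine_all,
    regions_to_mask,
    threshold_regions,
)

SHAPE = (24, 24)


def _cohort(rng=None, bump=(12, 12), bump_amp=3.0):
    rng = rng or np.random.default_rng(0)
    n = 24
    stack = rng.normal(loc=3.0, scale=1.0, size=(n,) + SHAPE)
    labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    if bump is not None:
        rr, cc = np.meshgrid(np.arange(SHAPE[0]), np.arange(SHAPE[1]), indexing="ij")
        env = np.exp(-((rr - bump[0]) ** 2 + (cc - bump[1]) ** 2) / (2 * 2.5**2))
        stack[labels == 1] += bump_amp * env
    split = dm.stratified_split(labels, ratio=1.0, seed=0)
    return dm.CohortFeatures(stack, labels, [f"s{i}" for i in range(n)], split)


def _scorer(cohort):
    return RegionScorer(cohort, n_folds=4, seed=0)


def _map_from(values, border=1):
    valid = np.zeros(SHAPE, dtype=bool)
    valid[border:-border, border:-border] = True
    return AUCMap(auc=np.where(valid, values, np.nan), valid_mask=valid, k=2 * border + 1)


def flood_fill_components(mask):
    """Oracle: 8-connected components by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r, c in zip(*np.nonzero(mask)):
        if seen[r, c]:
            continue
        comp, stack = set(), [(r, c)]
        seen[r, c] = True
        while stack:
            cr, cc = stack.pop()
            comp.add((cr, cc))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = cr + dr, cc + dc
                    if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                            and mask[nr, nc] and not seen[nr, nc]):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
        comps.append(frozenset(comp))
    return comps


class TestThresholdRegions:
    def test_two_disjoint_blobs_give_two_regions(self):
        vals = np.full(SHAPE, 0.5)
        vals[4:7, 4:7] = 0.8
        vals[15:18, 15:18] = 0.8
        regions = threshold_regions(_map_from(vals), _scorer(_cohort()), threshold=0.62)
        assert len(regions) == 2

    def test_uniform_chance_map_is_empty(self):
        regions = threshold_regions(_map_from(np.full(SHAPE, 0.5)), _scorer(_cohort()))
        assert regions == []

    def test_diagonal_touching_pixel_joins_under_8_connectivity(self):
        vals = np.full(SHAPE, 0.5)
        vals[5:8, 5:8] = 0.9  # 3x3 block
        vals[8, 8] = 0.9  # diagonal neighbor of the corner
        regions = threshold_regions(_map_from(vals), _scorer(_cohort()))
        assert len(regions) == 1
        assert len(regions[0]) == 10
        oracle = flood_fill_components(vals > 0.62)
        assert regions[0].pixels in oracle

    def test_components_match_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        vals = np.where(rng.random(SHAPE) < 0.25, 0.9, 0.4)
        amap = _map_from(vals)
        regions = threshold_regions(amap, _scorer(_cohort()))
        mask = amap.valid_mask & (vals > 0.62)
        assert {rg.pixels for rg in regions} == set(flood_fill_components(mask))


class TestGrowRegion:
    def test_growth_rolls_back_when_no_dilation_helps(self):
        """Seed already covering the informative disc: growth may explore
        but must return the best-scoring (possibly initial) state."""
        cohort = _cohort()
        scorer = _scorer(cohort)
        pixels = frozenset(
            (r, c) for r in range(9, 16) for c in range(9, 16)
        )
        region = dm.Region(pixels=pixels, train_auc=scorer.score(pixels))
        grown = grow_region(region, scorer, np.ones(SHAPE, dtype=bool))
        assert grown.train_auc >= region.train_auc

    def test_growth_expands_partial_core(self):
        """A seed smaller than the informative disc grows and never
        loses training AUC."""
        cohort = _cohort(bump_amp=1.5)
        scorer = _scorer(cohort)
        pixels = frozenset({(12, 12), (12, 13), (13, 12)})
        region = dm.Region(pixels=pixels, train_auc=scorer.score(pixels))
        grown = grow_region(region, scorer, np.ones(SHAPE, dtype=bool))
        assert len(grown) > len(region)
        assert grown.train_auc >= region.train_auc

    def test_growth_respects_valid_mask(self):
        cohort = _cohort()
        scorer = _scorer(cohort)
        valid = np.zeros(SHAPE, dtype=bool)
        valid[10:15, 10:15] = True
        pixels = frozenset({(12, 12)})
        region = dm.Region(pixels=pixels, train_auc=scorer.score(pixels))
        grown = grow_region(region, scorer, valid)
        assert all(valid[r, c] for r, c in grown.pixels)


class TestBoundarySweep:
    def test_sweep_never_decreases_auc(self):
        cohort = _cohort()
        scorer = _scorer(cohort)
        pixels = frozenset((r, c) for r in range(10, 14) for c in range(10, 14))
        region = dm.Region(pixels=pixels, train_auc=scorer.score(pixels))
        swept = boundary_sweep(region, scorer, np.ones(SHAPE, dtype=bool), max_passes=3)
        assert swept.train_auc >= region.train_auc
        # per-move history is strictly increasing
        moves = [a for step, a in swept.history if step in ("include", "exclude")]
        assert all(b > a for a, b in zip(moves, moves[1:]))

    def test_single_pixel_region_never_emptied(self):
        cohort = _cohort(bump=None)  # pure noise: most pixels are harmful
        scorer = _scorer(cohort)
        pixels = frozenset({(5, 5)})
        region = dm.Region(pixels=pixels, train_auc=scorer.score(pixels))
        swept = boundary_sweep(region, scorer, np.ones(SHAPE, dtype=bool), max_passes=2)
        assert len(swept) >= 1

    def test_fixed_point_terminates_unchanged(self):
        """With a frozen scorer cache forcing every move to look harmful,
        a single pass leaves the region untouched."""
        cohort = _cohort()
        scorer = _scorer(cohort)
        pixels = frozenset((r, c) for r in range(11, 14) for c in range(11, 14))
        auc = scorer.score(pixels)

        class VetoScorer:
            cohort = scorer.cohort

            def score(self, p):
                return auc if frozenset(p) == pixels else 0.0

        region = dm.Region(pixels=pixels, train_auc=auc)
        swept = boundary_sweep(region, VetoScorer(), np.ones(SHAPE, dtype=bool))
        assert swept.pixels == pixels
        assert swept.train_auc == auc


class TestRefineAll:
    def test_empty_threshold_gives_empty_list(self):
        amap = _map_from(np.full(SHAPE, 0.5))
        assert refine_all(amap, _scorer(_cohort())) == []

    def test_touching_regions_merge(self):
        cohort = _cohort()
        scorer = _scorer(cohort)
        a = dm.Region(pixels=frozenset({(5, 5), (5, 6)}), train_auc=0.7)
        b = dm.Region(pixels=frozenset({(6, 7)}), train_auc=0.7)  # 8-adjacent to (5,6)
        c = dm.Region(pixels=frozenset({(15, 15)}), train_auc=0.7)
        merged = _merge_touching([a, b, c], scorer)
        assert len(merged) == 2
        sizes = sorted(len(rg) for rg in merged)
        assert sizes == [1, 3]

    def test_train_auc_nondecreasing_through_refinement(self):
        cohort = _cohort(bump_amp=4.0)
        scorer = _scorer(cohort)
        amap_vals = np.full(SHAPE, 0.5)
        amap_vals[11:14, 11:14] = 0.9
        amap = _map_from(amap_vals)
        regions = refine_all(amap, scorer)
        assert regions
        for rg in regions:
            stage_aucs = [a for step, a in rg.history if step in ("threshold", "rollback")]
            assert all(b >= a - 1e-12 for a, b in zip(stage_aucs, stage_aucs[1:]))
            assert all(amap.valid_mask[r, c] for r, c in rg.pixels)

    def test_max_regions_caps_component_count(self):
        rng = np.random.default_rng(9)
        vals = np.where(rng.random(SHAPE) < 0.2, 0.9, 0.4)
        amap = _map_from(vals)
        regions = refine_all(amap, _scorer(_cohort()), max_regions=3)
        # merging can only reduce the count further
        assert len(regions) <= 3


def test_regions_to_mask_labels_are_one_based():
    a = dm.Region(pixels=frozenset({(1, 1)}), train_auc=0.8)
    b = dm.Region(pixels=frozenset({(3, 3), (3, 4)}), train_auc=0.7)
    mask = regions_to_mask([a, b], (6, 6))
    assert mask[1, 1] == 1 and mask[3, 3] == 2 and mask[0, 0] == 0
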