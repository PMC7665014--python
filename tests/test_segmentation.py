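"""Tests for the score-map -> instance-mask pipeline.

Seed finding is checked against a brute-force local-maxima scan of the
distance transform; merging against an exhaustive merge-order oracle.
"""

import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import disc_mask, dumbbell_support, labels_equal_up_to_relabel
from yeastseg.segmentation import (SegmentationParams, boundary_pixels,
                                   boundary_score, find_seeds,
                                   merge_oversegmented, segment,
                                   threshold_scores, watershed_assign)
from yeastseg.synthetic import SynthFieldParams, generate_field, ideal_score_map


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_seed_clusters(foreground, radius):
    """Literal definition: a pixel is a local max if no strictly greater EDT
    value lies within the Euclidean disc of the given radius; 8-connected
    clusters of maxima count once."""
    edt = ndi.distance_transform_edt(foreground)
    H, W = foreground.shape
    offsets = [(dr, dc) for dr in range(-radius, radius + 1)
               for dc in range(-radius, radius + 1)
               if dr * dr + dc * dc <= radius * radius]
    is_max = np.zeros_like(foreground)
    for r, c in np.argwhere(foreground):
        v = edt[r, c]
        ok = True
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and edt[rr, cc] > v:
                ok = False
                break
        is_max[r, c] = ok
    return ndi.label(is_max, structure=np.ones((3, 3)))[1]


def exhaustive_merge_partition(score, labels, params):
    """Merge adjacent high-scoring pairs in *every* order until no pair
    qualifies; returns the resulting set of frozen pixel-sets.  On fixtures
    where all erroneous interfaces score uniformly 1, every order reaches the
    same partition."""
    def adjacent_pairs(lab):
        pairs = set()
        for (a, b) in itertools.combinations(sorted(set(lab.ravel()) - {0}), 2):
            if boundary_pixels(lab, a, b):
                pairs.add((a, b))
        return pairs

    def canon(lab):
        return frozenset(
            frozenset(map(tuple, np.argwhere(lab == i)))
            for i in set(lab.ravel()) - {0}
        )

    results = set()
    stack = [np.asarray(labels).copy()]
    seen = set()
    while stack:
        lab = stack.pop()
        key = canon(lab)
        if key in seen:
            continue
        seen.add(key)
        mergeable = [
            p for p in adjacent_pairs(lab)
            if boundary_score(score, boundary_pixels(lab, *p),
                              params.boundary_quantile) > params.merge_threshold
        ]
        if not mergeable:
            results.add(key)
            continue
        for a, b in mergeable:
            nxt = lab.copy()
            nxt[nxt == b] = a
            stack.append(nxt)
    return results


# ---------------------------------------------------------------------------
# step 1: threshold
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_uniform_above(self):
        assert threshold_scores(np.full((4, 4), 0.7), 0.5).all()

    def test_exactly_at_threshold_is_background(self):
        assert not threshold_scores(np.full((4, 4), 0.5), 0.5).any()

    def test_matches_cell_supports_on_ideal_map(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=2, rng_seed=5))
        fg = threshold_scores(ideal_score_map(mask), 0.5)
        assert (fg == (mask > 0)).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_out_of_range(self, bad):
        with pytest.raises(ValueError):
            threshold_scores(np.zeros((3, 3)), bad)


# ---------------------------------------------------------------------------
# step 2: seeding
# ---------------------------------------------------------------------------

class TestFindSeeds:
    def test_disc_has_single_central_seed(self):
        disc = disc_mask(radius=20)
        seeds = find_seeds(disc, 5)
        assert len(seeds) == brute_force_seed_clusters(disc, 5) == 1
        assert tuple(seeds[0]) == (30, 30)

    def test_dumbbell_matches_brute_force_with_one_seed_per_lobe(self):
        sup = dumbbell_support(lobe_radius=10, separation=30, neck_width=4)
        seeds = find_seeds(sup, 5)
        # the EDT has a maximum in each lobe plus an isolated neck plateau;
        # the implementation must agree with the exhaustive scan exactly
        assert len(seeds) == brute_force_seed_clusters(sup, 5) == 3
        assert {(25, 40), (55, 40)} <= {tuple(s) for s in seeds}

    def test_empty_foreground(self):
        assert find_seeds(np.zeros((10, 10), bool), 5).shape == (0, 2)

    def test_every_component_gets_a_seed(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=10, rng_seed=7))
        seeds = find_seeds(mask > 0, 5)
        comp, n = ndi.label(mask > 0, structure=np.ones((3, 3)))
        assert {comp[r, c] for r, c in seeds} == set(range(1, n + 1))

    def test_seed_count_monotone_in_radius(self):
        sup = dumbbell_support(lobe_radius=10, separation=30, neck_width=4)
        counts = [len(find_seeds(sup, r)) for r in (2, 3, 5, 8, 12)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# step 3: watershed
# ---------------------------------------------------------------------------

class TestWatershed:
    def test_single_seed_labels_whole_disc(self):
        disc = disc_mask()
        labels = watershed_assign(disc, np.array([[30, 30]]))
        assert ((labels == 1) == disc).all()

    def test_symmetric_dumbbell_split_is_balanced(self):
        sup = dumbbell_support(lobe_radius=10, separation=30, neck_width=4)
        labels = watershed_assign(sup, np.array([[25, 40], [55, 40]]))
        neck_px = (sup[:, 38:43].sum())  # generous neck bound
        a1, a2 = (labels == 1).sum(), (labels == 2).sum()
        assert abs(a1 - a2) <= neck_px

    def test_partition_conserves_foreground(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=6, rng_seed=2))
        fg = mask > 0
        labels = watershed_assign(fg, find_seeds(fg, 5))
        assert ((labels > 0) == fg).all()

    def test_seed_off_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            watershed_assign(disc_mask(), np.array([[0, 0]]))


# ---------------------------------------------------------------------------
# step 4: boundary test
# ---------------------------------------------------------------------------

class TestBoundaryPixels:
    def test_two_adjacent_strips(self):
        h = 7
        labels = np.zeros((h, 4), int)
        labels[:, 1] = 1
        labels[:, 2] = 2
        assert len(boundary_pixels(labels, 1, 2)) == 2 * h

    def test_separated_regions_share_nothing(self):
        labels = np.zeros((5, 7), int)
        labels[:, 1] = 1
        labels[:, 5] = 2
        assert boundary_pixels(labels, 1, 2) == set()

    def test_symmetry(self):
        labels = np.zeros((6, 6), int)
        labels[:3] = 1
        labels[3:] = 2
        assert boundary_pixels(labels, 1, 2) == boundary_pixels(labels, 2, 1)

    def test_missing_label_rejected(self):
        labels = np.ones((3, 3), int)
        with pytest.raises(ValueError, match="not present"):
            boundary_pixels(labels, 1, 9)


class TestBoundaryScore:
    def test_bottom_quarter_ignored(self):
        score = np.array([[1.0, 1.0, 1.0, 0.0]])
        boundary = {(0, 0), (0, 1), (0, 2), (0, 3)}
        assert boundary_score(score, boundary, 0.75) == 1.0

    def test_uniform_scores(self):
        score = np.full((1, 8), 0.5)
        boundary = {(0, c) for c in range(8)}
        for q in (0.25, 0.5, 0.75, 1.0):
            assert boundary_score(score, boundary, q) == 0.5

    def test_single_pixel_keeps_one(self):
        score = np.array([[0.42]])
        assert boundary_score(score, {(0, 0)}, 0.75) == pytest.approx(0.42)

    def test_empty_boundary_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            boundary_score(np.ones((2, 2)), set(), 0.75)


class TestMerge:
    def test_dumbbell_rejoined(self):
        sup = dumbbell_support()
        labels = watershed_assign(sup, find_seeds(sup, 5))
        assert labels.max() >= 2
        merged = merge_oversegmented(sup.astype(float), labels)
        assert merged.max() == 1 and ((merged > 0) == sup).all()

    def test_true_cells_with_zero_border_untouched(self):
        mask = np.zeros((40, 40), int)
        mask[5:35, 5:19] = 1
        mask[5:35, 21:35] = 2
        score = ideal_score_map(mask)
        labels = watershed_assign(threshold_scores(score, 0.5),
                                  find_seeds(threshold_scores(score, 0.5), 5))
        merged = merge_oversegmented(score, labels)
        assert merged.max() == 2

    def test_three_collinear_fragments_reach_fixed_point(self):
        labels = np.zeros((20, 60), int)
        labels[5:15, 5:20] = 1
        labels[5:15, 20:40] = 2
        labels[5:15, 40:55] = 3
        score = (labels > 0).astype(float)
        params = SegmentationParams()
        merged = merge_oversegmented(score, labels, params)
        oracle = exhaustive_merge_partition(score, labels, params)
        assert len(oracle) == 1, "all merge orders must agree on this fixture"
        got = frozenset(
            frozenset(map(tuple, np.argwhere(merged == i)))
            for i in set(merged.ravel()) - {0}
        )
        assert got in oracle
        assert merged.max() == 1

    def test_label_count_never_increases(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=8, rng_seed=11))
        score = ideal_score_map(mask)
        fg = threshold_scores(score, 0.5)
        labels = watershed_assign(fg, find_seeds(fg, 3))
        merged = merge_oversegmented(score, labels)
        assert merged.max() <= labels.max()


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestSegment:
    def test_five_cell_round_trip(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=5, rng_seed=0))
        assert labels_equal_up_to_relabel(mask, segment(ideal_score_map(mask)))

    def test_all_zero_scores(self):
        assert not segment(np.zeros((32, 32))).any()

    def test_dumbbell_support_is_one_cell(self):
        sup = dumbbell_support()
        assert segment(sup.astype(float)).max() == 1

    def test_conservation_labels_within_foreground(self):
        mask, _ = generate_field(SynthFieldParams(n_cells=9, rng_seed=4))
        score = ideal_score_map(mask)
        labels = segment(score)
        assert ((labels > 0) <= threshold_scores(score, 0.5)).all()

    @pytest.mark.parametrize("merge_threshold", [0.5, 0.75, 0.99])
    def test_no_false_merges_on_ideal_maps(self, merge_threshold):
        mask, _ = generate_field(SynthFieldParams(n_cells=10, rng_seed=6))
        params = SegmentationParams(merge_threshold=merge_threshold)
        labels = segment(ideal_score_map(mask), params)
        assert labels.max() == 10

    def test_min_area_filter_drops_specks(self):
        score = np.zeros((40, 40))
        score[5:25, 5:25] = 1.0   # 400-px cell
        score[32:34, 32:34] = 1.0  # 4-px speck
        labels = segment(score, SegmentationParams(min_area_px=10))
        assert labels.max() == 1 and (labels > 0).sum() == 400
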