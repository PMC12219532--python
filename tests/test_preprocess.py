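"""Mask preprocessing: hole filling, morphology, overlap resolution,
labeling and size filtering."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from orgspat.preprocess import (
    MaskStack,
    derive_cytosol,
    dilate_ld,
    fill_holes,
    label_objects,
    preprocess_stack,
    resolve_overlaps,
    size_filter,
    smooth_er,
)


def _border_flood_fill_oracle(mask):
    """Holes = background not reachable from the border (BFS oracle)."""
    h, w = mask.shape
    bg = ~mask
    seen = np.zeros_like(bg)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if bg[r, c] and (r in (0, h - 1) or c in (0, w - 1))
    ]
    for s in stack:
        seen[s] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and bg[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                stack.append((rr, cc))
    return mask | (bg & ~seen)


class TestFillHoles:
    def test_annulus_becomes_disc(self):
        m = np.zeros((11, 11), bool)
        yy, xx = np.mgrid[:11, :11]
        r2 = (yy - 5) ** 2 + (xx - 5) ** 2
        m[(r2 <= 25) & (r2 >= 9)] = True
        filled = fill_holes(m)
        assert filled[(r2 <= 25)].all()

    def test_solid_rectangle_unchanged(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 1:7] = True
        assert np.array_equal(fill_holes(m), m)

    def test_c_shape_open_to_border_unchanged(self):
        m = np.zeros((7, 7), bool)
        m[1:6, 1:3] = True
        m[1:3, 3:6] = True
        m[4:6, 3:6] = True  # opening faces the right border through row 3
        assert np.array_equal(fill_holes(m), _border_flood_fill_oracle(m))
        assert np.array_equal(fill_holes(m), m)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(20):
            m = rng.random((24, 24)) < 0.45
            assert np.array_equal(fill_holes(m), _border_flood_fill_oracle(m))

    def test_never_removes_foreground(self, rng):
        m = rng.random((32, 32)) < 0.5
        assert (m & ~fill_holes(m)).sum() == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            fill_holes(np.arange(9).reshape(3, 3))


class TestMorphology:
    def test_square_erosion_shrinks_9x9_to_1x1(self):
        m = np.zeros((13, 13), bool)
        m[2:11, 2:11] = True
        out = smooth_er(m)
        assert out.sum() == 1 and out[6, 6]
        # per-pass border removal: 9 -> 7 -> 5 -> 3 -> 1 on a side
        side = m
        for expect in (7, 5, 3, 1):
            side = smooth_er(side, iterations=1)
            assert side.sum() == expect**2

    def test_thin_ribbon_erodes_away(self):
        m = np.zeros((30, 30), bool)
        m[5:13, 2:28] = True  # 8 px wide
        assert smooth_er(m).sum() == 0
        assert smooth_er(np.zeros((5, 5), bool)).sum() == 0

    def test_diamond_dilation_of_single_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        out = dilate_ld(m)
        expected = {
            (4 + dy, 4 + dx)
            for dy in range(-2, 3)
            for dx in range(-2, 3)
            if abs(dy) + abs(dx) <= 2
        }
        assert {tuple(p) for p in np.argwhere(out)} == expected
        assert out.sum() == 13

    def test_dilation_merges_pixels_four_apart(self):
        m = np.zeros((7, 11), bool)
        m[3, 3] = m[3, 7] = True
        out = dilate_ld(m)
        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1
        assert dilate_ld(np.zeros((4, 4), bool)).sum() == 0

    def test_erosion_dilation_monotone(self, rng):
        m = rng.random((40, 40)) < 0.6
        assert (smooth_er(m, 1) & ~m).sum() == 0
        assert (m & ~dilate_ld(m, 1)).sum() == 0


def _stack(shape=(10, 10), **classes):
    cell = np.zeros(shape, bool)
    cell[1:-1, 1:-1] = True
    masks = {"cell": classes.pop("cell", cell)}
    masks.update(classes)
    return MaskStack(masks, pixel_size_nm=5.0)


class TestResolveOverlaps:
    def test_contested_pixel_goes_to_mitochondria(self):
        mito = np.zeros((10, 10), bool)
        er = np.zeros((10, 10), bool)
        mito[4, 4] = er[4, 4] = True
        er[4, 5] = True
        out = resolve_overlaps(_stack(mitochondria=mito, er=er))
        assert out.masks["mitochondria"][4, 4]
        assert not out.masks["er"][4, 4]
        assert out.masks["er"][4, 5]

    def test_pixels_outside_cell_removed(self):
        mito = np.zeros((10, 10), bool)
        mito[0, 0] = mito[5, 5] = True  # (0,0) is outside the cell
        out = resolve_overlaps(_stack(mitochondria=mito))
        assert not out.masks["mitochondria"][0, 0]
        assert out.masks["mitochondria"][5, 5]

    def test_disjoint_stack_unchanged_and_idempotent(self, rng):
        mito = np.zeros((10, 10), bool)
        er = np.zeros((10, 10), bool)
        mito[2:4, 2:4] = True
        er[6:8, 6:8] = True
        s = _stack(mitochondria=mito, er=er)
        once = resolve_overlaps(s)
        assert np.array_equal(once.masks["mitochondria"], mito)
        assert np.array_equal(once.masks["er"], er)
        twice = resolve_overlaps(once)
        for cls in once.masks:
            assert np.array_equal(once.masks[cls], twice.masks[cls])

    def test_output_pairwise_disjoint_on_random_overlaps(self, rng):
        classes = {
            c: rng.random((10, 10)) < 0.4
            for c in ("nucleus", "mitochondria", "er", "glycogen", "ld")
        }
        out = resolve_overlaps(_stack(**classes))
        for a, b in itertools.combinations(
            ("nucleus", "mitochondria", "er", "glycogen", "ld"), 2
        ):
            assert not (out.masks[a] & out.masks[b]).any()
        for c in classes:
            assert not (out.masks[c] & ~out.masks["cell"]).any()

    def test_missing_cell_mask_rejected(self):
        with pytest.raises(ValueError):
            MaskStack({"mitochondria": np.zeros((5, 5), bool)})


class TestCytosol:
    def test_arithmetic(self):
        cell = np.zeros((20, 20), bool)
        cell[0:10, 0:10] = True  # 100 px
        nucleus = np.zeros_like(cell); nucleus[0:2, 0:5] = True   # 10
        mito = np.zeros_like(cell); mito[3:7, 0:5] = True         # 20
        ld = np.zeros_like(cell); ld[8, 0:5] = True               # 5
        s = MaskStack({"cell": cell, "nucleus": nucleus, "mitochondria": mito, "ld": ld})
        assert derive_cytosol(s).sum() == 65

    def test_no_organelles_gives_whole_cell(self):
        cell = np.ones((5, 5), bool)
        assert derive_cytosol(MaskStack({"cell": cell})).sum() == 25

    def test_er_not_subtracted(self):
        cell = np.ones((6, 6), bool)
        er = np.zeros_like(cell); er[2:4, 2:4] = True
        s = MaskStack({"cell": cell, "er": er})
        assert derive_cytosol(s).sum() == 36


def _bfs_components(mask):
    """Brute-force 8-connected components, raster order (oracle)."""
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < h and 0 <= xx < w
                                and mask[yy, xx] and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


class TestLabeling:
    def test_diagonal_touch_is_one_object(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert label_objects(m).n_objects == 1

    def test_empty_mask(self):
        assert label_objects(np.zeros((3, 3), bool)).n_objects == 0

    def test_matches_bfs_oracle_on_random_masks(self, rng):
        for _ in range(15):
            m = rng.random((20, 20)) < 0.35
            labeled = label_objects(m)
            oracle = _bfs_components(m)
            assert labeled.n_objects == len(oracle)
            got = [
                {tuple(p) for p in labeled.pixels(i)} for i in labeled.ids
            ]
            assert got == oracle  # ids follow raster order of first pixel


class TestSizeFilter:
    def test_boundary_at_threshold(self):
        m = np.zeros((200, 200), bool)
        m[:25, :200] = True  # 5000 px exactly
        m[100:150, :98] = True  # 4900 px, separated
        objs = label_objects(m, cls="mitochondria")
        out = size_filter(objs)
        assert out.n_objects == 1
        assert out.areas()[1] == 5000

    def test_er_fragment_kept_above_500(self):
        m = np.zeros((40, 40), bool)
        m[5:25, 5:35] = True  # 600 px
        assert size_filter(label_objects(m, cls="er")).n_objects == 1

    def test_empty_and_unknown_class(self):
        empty = label_objects(np.zeros((5, 5), bool), cls="er")
        assert size_filter(empty).n_objects == 0
        m = np.zeros((5, 5), bool)
        m[1, 1] = True
        with pytest.raises(KeyError):
            size_filter(label_objects(m, cls="unknown_class"))


class TestPipeline:
    def test_scene_preprocess_disjoint_and_inside_cell(self, scene):
        resolved, objects = preprocess_stack(scene.mask_stack)
        cell = resolved.masks["cell"]
        for a, b in itertools.combinations(resolved.organelle_classes, 2):
            assert not (resolved.masks[a] & resolved.masks[b]).any()
        for c in resolved.organelle_classes:
            assert not (resolved.masks[c] & ~cell).any()
        labs = objects.labels
        assert set(np.unique(labs)) - {0} == set(objects.ids)
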