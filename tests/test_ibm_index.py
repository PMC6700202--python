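"""Shell-template morphology and the IBM association index."""

import numpy as np
import pytest

from mitoloc.core import Image2D, ImageStack, PipelineError
from mitoloc.ibm_index import (IBMIndexParams, ShellTemplates, binary_morph,
                               compute_templates, ibm_association_index,
                               ibm_index_timecourse)

from conftest import make_disk_mask, make_disk_image


def morph_oracle(mask, op, iterations, count):
    """Pure-python neighbourhood rule; outside the image is background."""
    m = [[bool(v) for v in row] for row in mask]
    h, w = len(m), len(m[0])
    for _ in range(iterations):
        out = [row[:] for row in m]
        for y in range(h):
            for x in range(w):
                fg = 0
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == dx == 0:
                            continue
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and m[yy][xx]:
                            fg += 1
                if op == "dilate" and not m[y][x] and fg >= count:
                    out[y][x] = True
                if op == "erode" and m[y][x] and (8 - fg) >= count:
                    out[y][x] = False
        m = out
    return np.array(m, dtype=bool)


class TestBinaryMorph:
    def test_single_pixel_dilates_to_block(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = binary_morph(m, "dilate", iterations=1, count=1)
        expected = np.zeros((5, 5), bool)
        expected[1:4, 1:4] = True
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("op", ["dilate", "erode"])
    @pytest.mark.parametrize("count", [1, 3, 5])
    def test_matches_neighbourhood_oracle_on_random_masks(self, op, count, rng):
        for _ in range(200):
            m = rng.random((16, 16)) < 0.4
            it = int(rng.integers(1, 4))
            assert np.array_equal(binary_morph(m, op, it, count),
                                  morph_oracle(m, op, it, count))

    def test_opening_restores_convex_solid(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        out = binary_morph(binary_morph(m, "erode", 1, 1), "dilate", 1, 1)
        assert np.array_equal(out, m)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            binary_morph(np.ones((3, 3), bool), "open", 1, 1)
        with pytest.raises(ValueError):
            binary_morph(np.ones((3, 3), bool), "dilate", 0, 1)


class TestComputeTemplates:
    def test_disk_reference_yields_brute_force_annulus(self):
        img = make_disk_image((40, 40), (20, 20), 10)
        params = IBMIndexParams(dilate_iterations=2, erode_iterations=3)
        tpl = compute_templates(img, params)
        base = make_disk_mask((40, 40), (20, 20), 10)
        dil = morph_oracle(base, "dilate", 2, 1)
        ero = morph_oracle(base, "erode", 3, 1)
        assert np.array_equal(tpl.ibm_mask, dil & ~ero)
        assert np.array_equal(tpl.cm_mask, ero)
        # a disk dilated 2 / eroded 3 leaves a shell of radial extent 5
        assert tpl.ibm_area_px > 0 and tpl.cm_area_px > 0

    def test_fill_holes_makes_ring_equivalent_to_disk(self):
        shape, c = (40, 40), (20, 20)
        ring = make_disk_mask(shape, c, 10) & ~make_disk_mask(shape, c, 6)
        ring_img = Image2D(np.where(ring, 200.0, 10.0), 32.0)
        disk_img = make_disk_image(shape, c, 10)
        params = IBMIndexParams(fill_holes=True)
        tpl_ring = compute_templates(ring_img, params)
        tpl_disk = compute_templates(disk_img, params)
        assert np.array_equal(tpl_ring.ibm_mask, tpl_disk.ibm_mask)
        assert np.array_equal(tpl_ring.cm_mask, tpl_disk.cm_mask)

    def test_flat_reference_rejected(self):
        with pytest.raises(PipelineError):
            compute_templates(Image2D(np.zeros((20, 20)), 32.0))

    def test_templates_disjoint_enforced(self):
        with pytest.raises(ValueError):
            ShellTemplates(ibm_mask=np.ones((4, 4), bool),
                           cm_mask=np.ones((4, 4), bool),
                           dilated_mask=np.ones((4, 4), bool))


class TestAssociationIndex:
    @pytest.fixture
    def templates(self):
        return compute_templates(make_disk_image((40, 40), (20, 20), 10))

    def test_uniform_object_gives_exactly_one(self, templates):
        obj = Image2D(np.full((40, 40), 7.5), 32.0)
        assert ibm_association_index(obj, templates).index == 1.0

    def test_hand_computed_ratio(self, templates):
        px = np.zeros((40, 40))
        px[templates.ibm_mask] = 1.0
        px[templates.cm_mask] = 0.1
        res = ibm_association_index(Image2D(px, 32.0), templates)
        # direct pixel summation oracle
        expected = (px[templates.ibm_mask].sum() / templates.ibm_area_px) \
            / (px[templates.cm_mask].sum() / templates.cm_area_px)
        assert res.index == pytest.approx(10.0)
        assert res.index == pytest.approx(expected)

    def test_gain_invariance_exact(self, templates, rng):
        px = rng.uniform(1, 10, (40, 40))
        i1 = ibm_association_index(Image2D(px, 32.0), templates).index
        i2 = ibm_association_index(Image2D(37.0 * px, 32.0), templates).index
        assert i1 == pytest.approx(i2, rel=1e-12)

    def test_moving_intensity_to_shell_increases_index(self, templates, rng):
        px = rng.uniform(1, 2, (40, 40))
        base = ibm_association_index(Image2D(px, 32.0), templates).index
        moved = px.copy()
        # move a fixed quantum from one cm pixel to one ibm pixel
        cm_xy = tuple(np.argwhere(templates.cm_mask)[0])
        ibm_xy = tuple(np.argwhere(templates.ibm_mask)[0])
        moved[cm_xy] -= 0.5
        moved[ibm_xy] += 0.5
        up = ibm_association_index(Image2D(moved, 32.0), templates).index
        assert up > base

    def test_zero_cm_mean_flagged_not_raised(self, templates):
        px = np.zeros((40, 40))
        px[templates.ibm_mask] = 1.0
        res = ibm_association_index(Image2D(px, 32.0), templates)
        assert np.isnan(res.index)
        assert res.flag == "zero_cm_mean"


class TestTimecourse:
    def _stack(self, frames):
        return ImageStack(np.stack(frames), 32.0)

    def test_static_phantom_gives_identical_indices(self, rng):
        ref = make_disk_image((40, 40), (20, 20), 10).pixels
        obj = rng.uniform(1, 5, (40, 40))
        df = ibm_index_timecourse(self._stack([obj] * 10),
                                  self._stack([ref] * 10))
        assert len(df) == 10
        assert df["index"].nunique() == 1
        assert (df["status"] == "ok").all()

    def test_migration_from_shell_to_interior_decreases_index(self):
        ref_img = make_disk_image((40, 40), (20, 20), 10)
        tpl = compute_templates(ref_img)
        objs = []
        for w in np.linspace(1.0, 0.0, 8):
            px = np.zeros((40, 40))
            px[tpl.ibm_mask] = w
            px[tpl.cm_mask] = 1.0 - w
            objs.append(px + 0.01)
        df = ibm_index_timecourse(self._stack(objs),
                                  self._stack([ref_img.pixels] * 8))
        assert (np.diff(df["index"].to_numpy()) < 0).all()

    def test_bad_frame_flagged_and_run_continues(self, rng):
        ref = make_disk_image((40, 40), (20, 20), 10).pixels
        blank = np.zeros((40, 40))
        obj = rng.uniform(1, 5, (40, 40))
        df = ibm_index_timecourse(self._stack([obj] * 3),
                                  self._stack([ref, blank, ref]))
        assert df["status"].str.startswith("failed").tolist() == \
            [False, True, False]
        assert np.isnan(df["index"][1])
        assert np.isfinite(df["index"][[0, 2]]).all()
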