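"""Rolling-ball subtraction, thresholding, binary refinement, size gating
and punctum-to-cell assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from helpers import brute_rolling_ball_subtract, flood_fill_label
from punctacount.calibration import derive_size_gate
from punctacount.puncta import (
    PunctumRecord,
    assign_to_cells,
    extract_candidates,
    puncta_per_cell_table,
    refine_binary,
    subtract_background,
    threshold_puncta,
)
from punctacount.segmentation import CellRecord
from punctacount.synthetic import SceneSpec, generate_scene

GATE = derive_size_gate()


def disc(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_cell(cell_id, mask):
    return CellRecord(id=cell_id, mask=mask, nucleus_id=cell_id,
                      mean_marker_intensity=150.0, area=int(mask.sum()),
                      centroid=(0.0, 0.0))


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background(np.full((24, 24), 93.0), 3.0)
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("seed,radius", [(0, 2.5), (1, 3.0), (2, 4.215)])
    def test_matches_brute_force_opening_oracle(self, seed, radius):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, size=(24, 24))
        assert np.allclose(subtract_background(img, radius),
                           brute_rolling_ball_subtract(img, radius), atol=1e-9)

    def test_small_spot_preserved(self):
        """A spot much narrower than the ball survives subtraction at
        ≥ 95% of its amplitude."""
        img = np.full((40, 40), 20.0)
        img[disc((40, 40), (20, 20), 1.5)] += 100.0
        out = subtract_background(img, 4.215)
        assert out.max() >= 0.95 * 100.0

    def test_gradient_removed_spots_remain(self):
        shape = (64, 64)
        ramp = np.linspace(0, 30, shape[1])[None, :] * np.ones((shape[0], 1))
        spots = np.zeros(shape)
        spots[disc(shape, (20, 20), 1.5)] = 120.0
        spots[disc(shape, (44, 44), 1.5)] = 120.0
        out = subtract_background(ramp + spots, 4.215)
        off_spot = (spots == 0)
        off_spot[:6, :] = off_spot[-6:, :] = False
        off_spot[:, :6] = off_spot[:, -6:] = False
        assert out[off_spot].mean() < 2.0
        assert out.max() > 100.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(img=hnp.arrays(float, (20, 20),
                          elements=st.floats(min_value=0, max_value=255)))
    def test_anti_extensive(self, img):
        out = subtract_background(img, 2.5)
        assert (out <= img + 1e-9).all()
        assert (out >= -1e-9).all()

    def test_translation_equivariant_in_interior(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, size=(40, 40))
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        a = np.roll(subtract_background(img, 2.5), (3, 5), axis=(0, 1))
        b = subtract_background(shifted, 2.5)
        interior = np.s_[10:-10, 10:-10]
        assert np.allclose(a[interior], b[interior], atol=1e-9)

    def test_large_radius_path_still_bounded(self):
        """The down-sampled large-ball path stays anti-extensive and kills
        a broad plateau."""
        img = np.full((120, 120), 50.0)
        img[disc((120, 120), (60, 60), 2.0)] += 150.0
        out = subtract_background(img, 40.0)
        assert (out <= img + 1e-6).all()
        assert out[5, 5] < 5.0
        assert out.max() > 100.0

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), 0.0)


class TestThresholdPuncta:
    def test_all_zero_empty_mask(self):
        assert not threshold_puncta(np.zeros((16, 16))).any()

    def test_two_level_image_exact(self):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 200.0
        mask = threshold_puncta(img)
        assert np.array_equal(mask, img == 200.0)

    def test_fixed_threshold_mode(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        assert np.array_equal(threshold_puncta(img, 50.0), img > 50.0)

    def test_covers_true_punctum_pixels_on_synthetic_field(self):
        """On a seeded scene the thresholded mask covers ≥ 90% of the true
        punctum pixels."""
        image, truth = generate_scene(SceneSpec(seed=5))
        sub = subtract_background(image[:, :, 1].astype(float), 4.215)
        mask = threshold_puncta(sub)
        true = np.zeros(image.shape[:2], dtype=bool)
        for p in truth.puncta:
            true |= disc(image.shape[:2], p.center, p.radius_px)
        assert (mask & true).sum() / true.sum() >= 0.90


class TestRefineBinary:
    def test_annulus_filled(self):
        mask = disc((48, 48), (24, 24), 12) & ~disc((48, 48), (24, 24), 6)
        out = refine_binary(mask, upscale_factor=2, min_marker_distance_px=20)
        assert out[24, 24]  # hole filled
        assert out.sum() >= disc((48, 48), (24, 24), 11).sum()

    def test_overlapping_discs_split_in_two(self):
        """Two discs with centres 1.5 radii apart are separated by the
        distance-transform watershed into two comparable components."""
        r = 8
        mask = disc((48, 64), (24, 22), r) | disc((48, 64), (24, 34), r)
        assert flood_fill_label(mask).max() == 1
        out = refine_binary(mask, upscale_factor=4, min_marker_distance_px=4)
        labels = flood_fill_label(out)
        assert labels.max() == 2
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert areas[0] > 0.5 * areas[1]

    def test_separated_blobs_unchanged_count(self):
        mask = disc((48, 64), (14, 14), 5) | disc((48, 64), (34, 44), 5)
        out = refine_binary(mask, upscale_factor=4, min_marker_distance_px=3)
        assert flood_fill_label(out).max() == 2

    def test_no_upscale_path(self):
        mask = disc((32, 32), (16, 16), 6)
        out = refine_binary(mask, upscale_factor=1, min_marker_distance_px=3)
        assert flood_fill_label(out).max() == 1

    def test_empty_mask(self):
        assert not refine_binary(np.zeros((16, 16), bool), 4).any()


class TestExtractCandidates:
    def block(self, shape_hw):
        mask = np.zeros((20, 80), dtype=bool)
        mask[2 : 2 + shape_hw[0], 2 : 2 + shape_hw[1]] = True
        return mask

    def test_below_gate_rejected(self):
        assert extract_candidates(self.block((1, 5)), GATE) == []

    def test_above_gate_rejected(self):
        assert extract_candidates(self.block((3, 19)), GATE) == []  # 57 px

    def test_inclusive_bounds_and_interior(self):
        """Components of exactly 6, 30 and 56 px all pass the 6–56 gate."""
        mask = np.zeros((30, 90), dtype=bool)
        mask[2:4, 2:5] = True       # 6 px
        mask[10:15, 10:16] = True   # 30 px
        mask[20:27, 40:48] = True   # 56 px
        records = extract_candidates(mask, GATE)
        assert sorted(r.area for r in records) == [6, 30, 56]


class TestAssignToCells:
    def setup_cells(self):
        shape = (40, 80)
        left = np.zeros(shape, dtype=bool)
        left[:, :38] = True
        right = np.zeros(shape, dtype=bool)
        right[:, 42:] = True
        return [make_cell(3, left), make_cell(7, right)], shape

    def punctum(self, pid, r, c):
        return PunctumRecord(id=pid, centroid=(r, c), area=10)

    def test_containment_assignment(self):
        cells, _ = self.setup_cells()
        out = assign_to_cells([self.punctum(1, 10.0, 10.0)], cells)
        assert out[0].cell_id == 3

    def test_background_centroid_discarded(self):
        cells, _ = self.setup_cells()
        assert assign_to_cells([self.punctum(1, 10.0, 40.0)], cells) == []

    def test_count_conservation(self):
        cells, _ = self.setup_cells()
        rng = np.random.default_rng(2)
        puncta = [self.punctum(i, rng.uniform(0, 39), rng.uniform(0, 79))
                  for i in range(40)]
        assigned = assign_to_cells(puncta, cells)
        table = puncta_per_cell_table(assigned, cells)
        assert table["count"].sum() == len(assigned)

    def test_no_cells_discards_everything(self):
        assert assign_to_cells([self.punctum(1, 5.0, 5.0)], []) == []


class TestGateSoundnessProperty:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), density=st.floats(0.05, 0.4))
    def test_no_emitted_area_outside_gate_and_conservation(self, seed, density):
        """Over random masks: every accepted punctum area is inside the
        inclusive integer gate, and Σ per-cell counts equals the number of
        retained puncta."""
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < density
        records = extract_candidates(mask, GATE)
        for rec in records:
            assert GATE.min_area_int <= rec.area <= GATE.max_area_int
        left = np.zeros((32, 32), dtype=bool)
        left[:, :16] = True
        cells = [make_cell(1, left), make_cell(2, ~left)]
        assigned = assign_to_cells(records, cells)
        table = puncta_per_cell_table(assigned, cells)
        assert table["count"].sum() == len(assigned)


class TestPerCellTable:
    def test_zero_count_rows_present(self):
        cells = [make_cell(1, np.ones((4, 4), bool))]
        table = puncta_per_cell_table([], cells, field_id="f0", group="control")
        assert len(table) == 1
        assert table.iloc[0]["count"] == 0

    def test_order_invariance(self):
        cells, _ = TestAssignToCells().setup_cells()
        puncta = [PunctumRecord(i, (10.0, 5.0 + i), 8, cell_id=3) for i in range(5)]
        t1 = puncta_per_cell_table(puncta, cells)
        t2 = puncta_per_cell_table(list(reversed(puncta)), cells)
        assert t1.equals(t2)

    def test_unassigned_punctum_rejected(self):
        cells = [make_cell(1, np.ones((4, 4), bool))]
        with pytest.raises(ValueError):
            puncta_per_cell_table([PunctumRecord(1, (1.0, 1.0), 8)], cells)
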