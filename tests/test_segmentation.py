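"""Channel splitting, preprocessing, object segmentation, adherent-cell
splitting and the mutual-exclusion validation rules."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from helpers import flood_fill_label, nearest_marker_partition, partition_sets
from punctacount.pipeline import RunConfig, analyze_field
from punctacount.segmentation import (
    ChannelImage,
    NucleusRecord,
    apply_mutual_exclusion,
    count_cells_per_field,
    preprocess_channel,
    segment_objects,
    split_adherent,
    split_channels,
)
from punctacount.synthetic import SceneSpec, generate_scene


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestSplitChannels:
    def test_pure_red_basis(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:, :, 0] = 77
        marker, puncta, nuclear = split_channels(img)
        assert (marker.pixels == 77).all()
        assert (puncta.pixels == 0).all() and (nuclear.pixels == 0).all()
        assert marker.role == "cell_marker"

    def test_planes_reassemble_composite(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        marker, puncta, nuclear = split_channels(img)
        recomposed = np.stack([marker.pixels, puncta.pixels, nuclear.pixels], axis=2)
        assert np.array_equal(recomposed, img)

    def test_custom_role_order(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:, :, 0] = 9  # first plane is the nuclear stain here
        marker, puncta, nuclear = split_channels(
            img, roles=("nuclear", "cell_marker", "puncta")
        )
        assert (nuclear.pixels == 9).all() and (marker.pixels == 0).all()

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError):
            split_channels(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            split_channels(np.zeros((8, 8, 4), dtype=np.uint8))


class TestPreprocessChannel:
    def test_constant_field_flattens_to_zero(self):
        img = ChannelImage(np.full((32, 32), 77, dtype=np.uint8), "nuclear")
        out = preprocess_channel(img, median_radius=1, background_radius_px=5.0)
        assert (out.pixels == 0).all()

    def test_constant_field_without_background_correction(self):
        img = ChannelImage(np.full((32, 32), 77, dtype=np.uint8), "nuclear")
        out = preprocess_channel(img, median_radius=1, background_radius_px=None)
        assert (out.pixels == 77).all()

    def test_salt_pixel_removed_by_median(self):
        arr = np.full((21, 21), 10, dtype=np.uint8)
        arr[10, 10] = 200
        out = preprocess_channel(ChannelImage(arr, "puncta"), median_radius=1,
                                 background_radius_px=None)
        assert (out.pixels == 10).all()

    def test_16bit_rescaled_to_8bit(self):
        arr = np.full((8, 8), 65535, dtype=np.uint16)
        out = preprocess_channel(ChannelImage(arr, "puncta"), 0, None)
        assert (out.pixels == 255).all()

    def test_near_idempotent_on_preprocessed_image(self):
        """Re-running preprocessing changes almost nothing: only disc-edge
        pixels move (median rounding), the bulk is stable."""
        rng = np.random.default_rng(0)
        base = np.full((96, 96), 20.0)
        for _ in range(6):
            r, c = rng.uniform(15, 80, 2)
            base[disc_mask((96, 96), (r, c), rng.uniform(2, 3))] += 120
        img = ChannelImage(np.clip(base, 0, 255).astype(np.uint8), "puncta")
        p1 = preprocess_channel(img, 1, 5.0)
        p2 = preprocess_channel(p1, 1, 5.0)
        diff = np.abs(p2.pixels.astype(float) - p1.pixels.astype(float))
        assert diff.mean() < 1.0
        assert (diff > 0).mean() < 0.01


class TestSegmentObjects:
    def test_single_disc_single_label(self):
        img = np.where(disc_mask((48, 48), (24, 24), 10), 200, 0).astype(np.uint8)
        labels = segment_objects(img)
        assert labels.max() == 1

    def test_blank_field_empty(self):
        assert segment_objects(np.zeros((32, 32), dtype=np.uint8)).max() == 0

    def test_min_area_filter(self):
        img = np.zeros((48, 48), dtype=np.uint8)
        img[disc_mask((48, 48), (12, 12), 2)] = 200   # ~13 px
        img[disc_mask((48, 48), (32, 32), 6)] = 200   # ~113 px
        labels = segment_objects(img, min_area=50)
        assert labels.max() == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_labeling_matches_flood_fill_oracle(self, seed):
        """Connected-component labelling agrees with a brute-force flood
        fill on random ≤64×64 binary fixtures."""
        rng = np.random.default_rng(seed)
        mask = ndi.binary_dilation(rng.random((48, 48)) < 0.12,
                                   np.ones((2, 2), bool))
        img = (mask * 255).astype(np.uint8)
        labels = segment_objects(img, threshold=127, clean=False)
        oracle = flood_fill_label(mask, connectivity=2)
        assert partition_sets(labels) == partition_sets(oracle)

    def test_two_separated_discs_match_oracle(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[disc_mask((64, 64), (16, 16), 8)] = 255
        img[disc_mask((64, 64), (46, 46), 8)] = 255
        labels = segment_objects(img, threshold=127, clean=False)
        oracle = flood_fill_label(img > 127)
        assert labels.max() == 2
        assert partition_sets(labels) == partition_sets(oracle)


def dumbbell_fixture():
    """Two overlapping-intensity nuclei: union-of-discs mask and a
    two-bump intensity surface, symmetric about the column midline."""
    shape = (64, 64)
    centers = [(32, 20), (32, 43)]
    mask = disc_mask(shape, centers[0], 11) | disc_mask(shape, centers[1], 11)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    intensity = np.zeros(shape)
    for r, c in centers:
        intensity += 200 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 6.0**2))
    labels = flood_fill_label(mask)
    return labels, np.clip(intensity, 0, 255).astype(np.uint8), centers


class TestSplitAdherent:
    def test_single_peak_region_unchanged(self):
        mask = disc_mask((48, 48), (24, 24), 10)
        labels = flood_fill_label(mask)
        yy, xx = np.mgrid[0:48, 0:48]
        bump = (200 * np.exp(-((yy - 24) ** 2 + (xx - 24) ** 2) / 50.0)).astype(np.uint8)
        out = split_adherent(labels, bump, min_peak_distance_px=5)
        assert out.max() == 1
        assert np.array_equal(out > 0, mask)

    def test_dumbbell_matches_nearest_marker_oracle(self):
        """Two adherent nuclei split along the watershed line equal the
        per-pixel nearest-marker partition of the object."""
        labels, intensity, centers = dumbbell_fixture()
        assert labels.max() == 1  # genuinely adherent before splitting
        out = split_adherent(labels, intensity, min_peak_distance_px=8,
                             smoothing_sigma=1.0)
        assert out.max() == 2
        oracle = nearest_marker_partition(labels > 0, centers)
        assert partition_sets(out) == partition_sets(oracle)

    def test_peak_outside_objects_ignored(self):
        mask = disc_mask((48, 48), (24, 24), 8)
        labels = flood_fill_label(mask)
        intensity = np.zeros((48, 48), dtype=np.uint8)
        intensity[5, 5] = 250  # bright speck in the background
        intensity[24, 24] = 200
        out = split_adherent(labels, intensity, min_peak_distance_px=3,
                             smoothing_sigma=0.8)
        assert out.max() == 1
        assert np.array_equal(out > 0, mask)

    def test_explicit_markers_split_on_distance(self):
        mask = np.zeros((40, 70), dtype=bool)
        mask[10:30, 5:65] = True
        out = split_adherent(flood_fill_label(mask), markers=np.array([[20, 15], [20, 50]]))
        assert out.max() == 2
        assert (out > 0).sum() == mask.sum()


class TestMutualExclusion:
    def fixture_field(self):
        """Marker image with one valid cell, one dim nucleus region and one
        anucleate debris blob, plus the corresponding candidate label map."""
        shape = (96, 96)
        marker = np.zeros(shape, dtype=np.uint8)
        cells = np.zeros(shape, dtype=np.int32)
        bright = disc_mask(shape, (25, 25), 12)
        dim = disc_mask(shape, (25, 70), 12)
        debris = disc_mask(shape, (70, 48), 10)
        marker[bright] = 150
        marker[dim] = 12
        marker[debris] = 150
        cells[bright], cells[dim], cells[debris] = 1, 2, 3
        nuclei = [
            NucleusRecord(1, (25.0, 25.0), 50),
            NucleusRecord(2, (25.0, 70.0), 50),
        ]
        return cells, nuclei, marker

    def test_debris_and_dim_regions_excluded(self):
        cells, nuclei, marker = self.fixture_field()
        records = apply_mutual_exclusion(cells, nuclei, marker, adequacy_threshold=50)
        assert len(records) == 1
        assert records[0].nucleus_id == 1
        assert records[0].mean_marker_intensity >= 50

    def test_auto_threshold_matches_explicit_decision(self):
        cells, nuclei, marker = self.fixture_field()
        records = apply_mutual_exclusion(cells, nuclei, marker)  # auto Otsu
        assert [r.nucleus_id for r in records] == [1]

    def test_never_invents_cells(self):
        cells, nuclei, marker = self.fixture_field()
        records = apply_mutual_exclusion(cells, nuclei, marker, adequacy_threshold=0)
        foreground = cells > 0
        union = np.zeros_like(foreground)
        for rec in records:
            assert not (union & rec.mask).any()  # masks disjoint
            union |= rec.mask
        assert not (union & ~foreground).any()  # subset of input foreground

    def test_multi_nucleus_region_is_split(self):
        shape = (48, 96)
        cells = np.zeros(shape, dtype=np.int32)
        cells[14:34, 8:88] = 1  # one elongated region, two nuclei
        marker = np.where(cells > 0, 150, 0).astype(np.uint8)
        nuclei = [NucleusRecord(1, (24.0, 25.0), 40), NucleusRecord(2, (24.0, 70.0), 40)]
        records = apply_mutual_exclusion(cells, nuclei, marker, adequacy_threshold=50)
        assert len(records) == 2
        assert {r.nucleus_id for r in records} == {1, 2}

    def test_min_cell_area(self):
        cells, nuclei, marker = self.fixture_field()
        records = apply_mutual_exclusion(cells, nuclei, marker,
                                         adequacy_threshold=50, min_cell_area=10_000)
        assert records == []


class TestCountCells:
    def test_empty(self):
        assert count_cells_per_field([]) == 0

    def test_synthetic_field_with_confounders(self):
        """12 well-separated cells plus debris and free nuclei: the count
        equals the generator's truth, confounders excluded."""
        spec = SceneSpec(n_cells=12, n_debris=3, n_free_nuclei=2,
                         adherent_pair_fraction=0.0, seed=21)
        image, truth = generate_scene(spec)
        result = analyze_field(image, RunConfig())
        assert count_cells_per_field(result.cells) == len(truth.cells) == 12
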