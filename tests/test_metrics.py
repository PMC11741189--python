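import warnings

import numpy as np
import pytest
from skimage.draw import disk as skdisk

from adipoquant import (
    AdipocyteRule,
    BinaryMask,
    DiskRegion,
    DropletConfig,
    DropletSegmentation,
    FieldMetrics,
    Nucleus,
    NucleusSet,
    cell_lipid_content,
    classify_adipocytes,
    connected_particles,
    differentiation_efficiency,
    field_metrics,
    sample_cells,
    summarize_condition,
)

PX = 0.31


def _seg_from_mask(mask: np.ndarray) -> DropletSegmentation:
    bm = BinaryMask(mask, PX)
    return DropletSegmentation(bm, connected_particles(bm), DropletConfig(), "f")


def _nuclei(centroids, shape=(512, 512)) -> NucleusSet:
    return NucleusSet([Nucleus(tuple(map(float, c)), 5.0) for c in centroids], "f", shape, PX)


def _disks_around(center, n, dist_um, radius_px=4.0, shape=(512, 512)):
    mask = np.zeros(shape, bool)
    for k in range(n):
        theta = 2 * np.pi * k / n
        r = center[0] + dist_um / PX * np.sin(theta)
        c = center[1] + dist_um / PX * np.cos(theta)
        rr, cc = skdisk((r, c), radius_px, shape=shape)
        mask[rr, cc] = True
    return mask


class TestClassifyAdipocytes:
    def test_no_particles_means_no_adipocytes(self):
        nuclei = _nuclei([(100, 100), (300, 300)])
        records = classify_adipocytes(nuclei, _seg_from_mask(np.zeros((512, 512), bool)))
        assert not any(r.is_adipocyte for r in records)

    def test_five_round_droplets_at_8um_qualify(self):
        nuclei = _nuclei([(250, 250)])
        seg = _seg_from_mask(_disks_around((250, 250), 5, 8.0))
        records = classify_adipocytes(nuclei, seg)
        assert records[0].is_adipocyte

    def test_droplets_beyond_search_radius_do_not_count(self):
        nuclei = _nuclei([(250, 250)])
        seg = _seg_from_mask(_disks_around((250, 250), 5, 25.0))
        assert not classify_adipocytes(nuclei, seg)[0].is_adipocyte

    def test_too_few_droplets_do_not_qualify(self):
        nuclei = _nuclei([(250, 250)])
        seg = _seg_from_mask(_disks_around((250, 250), 2, 8.0))
        assert not classify_adipocytes(nuclei, seg)[0].is_adipocyte

    def test_irregular_particles_fail_circularity(self):
        # three 1-px-wide streaks near the nucleus: count passes, shape fails
        mask = np.zeros((512, 512), bool)
        for k, off in enumerate((-20, 0, 20)):
            mask[250 + off, 230:280] = True
        nuclei = _nuclei([(250, 250)])
        assert not classify_adipocytes(nuclei, _seg_from_mask(mask))[0].is_adipocyte

    def test_field_mismatch_rejected(self):
        nuclei = _nuclei([(10, 10)])
        seg = _seg_from_mask(np.zeros((512, 512), bool))
        seg.field_id = "other"
        with pytest.raises(ValueError):
            classify_adipocytes(nuclei, seg)


class TestEfficiency:
    @pytest.mark.parametrize(
        "n_adipo,n_total,expected", [(0, 50, 0.0), (50, 50, 1.0), (44, 100, 0.44)]
    )
    def test_definition_arithmetic(self, n_adipo, n_total, expected):
        nuclei = _nuclei([(10 + 12 * i, 10) for i in range(n_total)], shape=(2048, 32))
        records = classify_adipocytes(nuclei, _seg_from_mask(np.zeros((2048, 32), bool)))
        for r in records[:n_adipo]:
            r.is_adipocyte = True
        assert differentiation_efficiency(records) == pytest.approx(expected)

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            differentiation_efficiency([])


class TestSampleCells:
    def test_one_nucleus_per_region_is_forced(self):
        # quadrant centers + field center, one nucleus each
        nuclei = _nuclei([(128, 128), (128, 384), (384, 128), (384, 384), (256, 256)])
        for seed in (0, 1, 99):
            assert sample_cells(nuclei, 5, seed) == [0, 1, 2, 3, 4]

    def test_same_seed_reproduces_selection(self, rng):
        pts = rng.uniform(0, 512, (40, 2))
        nuclei = _nuclei(pts)
        assert sample_cells(nuclei, 5, seed=7) == sample_cells(nuclei, 5, seed=7)

    def test_fewer_nuclei_than_requested_returns_all_with_warning(self):
        nuclei = _nuclei([(10, 10), (400, 400)])
        with pytest.warns(UserWarning):
            assert sample_cells(nuclei, 5, seed=0) == [0, 1]

    def test_empty_region_falls_back_to_nearest(self):
        # all nuclei in the top-left quadrant; still returns 5 distinct ids
        pts = [(40 + 10 * i, 40 + 7 * i) for i in range(8)]
        nuclei = _nuclei(pts)
        chosen = sample_cells(nuclei, 5, seed=3)
        assert len(chosen) == 5 and len(set(chosen)) == 5

    def test_uniform_within_region(self):
        # 20 nuclei packed in one region; the region's own draw is uniform
        pts = [(30 + 9 * i, 35 + 8 * (i % 5)) for i in range(20)]
        other = [(128, 384), (384, 128), (384, 384), (256, 256)]
        nuclei = _nuclei(pts + other)
        counts = np.zeros(20)
        n_draws = 2000
        for seed in range(n_draws):
            chosen = sample_cells(nuclei, 5, seed)
            picked = [i for i in chosen if i < 20]
            assert len(picked) == 1
            counts[picked[0]] += 1
        p = 1 / 20
        sd = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) <= 4 * sd)


class TestLipidContent:
    def test_full_coverage_is_100(self):
        seg = _seg_from_mask(np.ones((64, 64), bool))
        region = BinaryMask(np.ones((64, 64), bool), PX)
        assert cell_lipid_content(region, seg) == 100.0

    def test_no_droplets_is_0(self):
        seg = _seg_from_mask(np.zeros((64, 64), bool))
        assert cell_lipid_content(DiskRegion((32, 32), 5.0), seg) == 0.0

    def test_quarter_coverage(self):
        droplet = np.zeros((64, 64), bool)
        droplet[:10, :25] = True  # 250 px
        region = np.zeros((64, 64), bool)
        region[:25, :40] = True  # 1000 px
        assert cell_lipid_content(BinaryMask(region, PX), _seg_from_mask(droplet)) == 25.0

    def test_zero_area_region_rejected(self):
        seg = _seg_from_mask(np.zeros((64, 64), bool))
        with pytest.raises(ValueError):
            cell_lipid_content(BinaryMask(np.zeros((64, 64), bool), PX), seg)


class TestFieldAndCondition:
    def _fm(self, eff):
        return FieldMetrics("f", 100, int(100 * eff), eff, 4.0, 2.0, 20.0)

    def test_mean_content_over_sampled_cells(self):
        nuclei = _nuclei([(60 + 90 * i, 256) for i in range(5)])
        seg = _seg_from_mask(np.zeros((512, 512), bool))
        records = classify_adipocytes(nuclei, seg)
        for r, c in zip(records, (10.0, 20.0, 30.0, 40.0, 50.0)):
            r.lipid_content_pct = c
        fm = field_metrics(nuclei, seg, records, [0, 1, 2, 3, 4])
        assert fm.mean_lipid_content_pct == pytest.approx(30.0)

    def test_summary_mean_and_sem(self):
        fields = [self._fm(e) for e in (0.4, 0.5, 0.6)]
        summary = summarize_condition(fields, "cond")
        mean, sem, n = summary.stats["differentiation_efficiency"]
        assert mean == pytest.approx(0.5)
        assert sem == pytest.approx(0.1 / np.sqrt(3), rel=1e-6)
        assert n == 3

    def test_single_field_sem_undefined(self):
        with pytest.warns(UserWarning):
            summary = summarize_condition([self._fm(0.4)], "cond")
        assert np.isnan(summary.stats["differentiation_efficiency"][1])

    def test_identical_fields_have_zero_sem(self):
        summary = summarize_condition([self._fm(0.4)] * 3, "cond")
        assert summary.stats["differentiation_efficiency"][1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            summarize_condition([], "cond")


class TestRuleValidation:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            AdipocyteRule(search_radius_um=0)
        with pytest.raises(ValueError):
            AdipocyteRule(min_circularity=1.5)
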