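"""Segmentation, ring geometry and per-cell measurements, checked against
ground-truth masks and brute-force per-pixel oracles."""

import numpy as np
import pytest

from _oracles import brute_erode_chebyshev, brute_rings
from splicexport import image_quant as iq
from splicexport import synthetic_data as sd
from splicexport.exceptions import EmptyResultError, ParameterError


def _square_mask(shape=(40, 40), top=10, left=10, size=20, label=1):
    mask = np.zeros(shape, dtype=np.int32)
    mask[top:top + size, left:left + size] = label
    return mask


class TestSegmentNuclei:
    def test_blank_image_gives_zero_labels(self):
        assert iq.segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_recovers_synthetic_nuclei_with_high_jaccard(self, small_fish):
        _, frame, truth = small_fish
        labels = iq.segment_nuclei(frame["dapi"], min_area_px=100)
        assert labels.max() == truth.nuclear_labels.max() == 5
        for k in range(1, 6):
            true_mask = truth.nuclear_labels == k
            # match by majority overlap, then check Jaccard
            seg_label = np.bincount(labels[true_mask]).argmax()
            assert seg_label > 0
            seg_mask = labels == seg_label
            jaccard = (true_mask & seg_mask).sum() / (true_mask | seg_mask).sum()
            assert jaccard >= 0.9

    def test_touching_nuclei_split_only_when_requested(self):
        img = np.zeros((80, 120))
        rr, cc = np.mgrid[:80, :120]
        img[(rr - 40) ** 2 + (cc - 45) ** 2 <= 15**2] = 1000.0
        img[(rr - 40) ** 2 + (cc - 73) ** 2 <= 15**2] = 1000.0
        assert iq.segment_nuclei(img, min_area_px=50, split_touching=False).max() == 1
        assert iq.segment_nuclei(img, min_area_px=50, split_touching=True).max() == 2

    def test_non_2d_input_rejected(self):
        with pytest.raises(ParameterError):
            iq.segment_nuclei(np.zeros((4, 4, 4)))


class TestRegionPairs:
    def test_zero_parameters_give_identity_nucleus_and_empty_ring(self):
        mask = _square_mask()
        (rp,) = iq.build_region_pairs(mask, erosion_px=0, ring_gap_px=0, ring_width_px=0)
        np.testing.assert_array_equal(rp.nuclear, mask > 0)
        assert not rp.ring.any()

    def test_square_erosion_two_chebyshev_leaves_16x16(self):
        mask = _square_mask(size=20)
        (rp,) = iq.build_region_pairs(mask, erosion_px=2, ring_width_px=0)
        assert rp.nuclear.sum() == 16 * 16
        np.testing.assert_array_equal(rp.nuclear, brute_erode_chebyshev(mask > 0, 2))

    def test_erosion_matches_brute_force_on_random_blobs(self, rng):
        from scipy import ndimage
        for _ in range(5):
            blob = ndimage.binary_dilation(
                rng.random((40, 40)) > 0.97, iterations=4
            )
            mask = blob.astype(np.int32)
            pairs = iq.build_region_pairs(
                ndimage.label(mask)[0], erosion_px=2, ring_width_px=0
            )
            combined = np.zeros_like(blob)
            for rp in pairs:
                combined |= rp.nuclear
            np.testing.assert_array_equal(combined, brute_erode_chebyshev(blob, 2))

    def test_ring_matches_exhaustive_distance_band_single_nucleus(self):
        mask = _square_mask(shape=(60, 60), top=20, left=20, size=14)
        (rp,) = iq.build_region_pairs(mask, erosion_px=0, ring_gap_px=2, ring_width_px=8)
        oracle = brute_rings(mask, gap=2, width=8)
        np.testing.assert_array_equal(rp.ring, oracle[1])

    def test_ring_matches_exhaustive_oracle_with_contested_pixels(self):
        mask = np.zeros((50, 64), dtype=np.int32)
        mask[20:30, 8:18] = 1
        mask[18:32, 30:42] = 2
        pairs = iq.build_region_pairs(mask, erosion_px=1, ring_gap_px=2, ring_width_px=10)
        oracle = brute_rings(mask, gap=2, width=10)
        for rp in pairs:
            np.testing.assert_array_equal(rp.ring, oracle[rp.label])

    def test_rings_disjoint_from_all_nuclei_and_each_other(self, small_fish):
        _, _, truth = small_fish
        pairs = iq.build_region_pairs(truth.nuclear_labels)
        any_nucleus = truth.nuclear_labels > 0
        claimed = np.zeros_like(any_nucleus)
        for rp in pairs:
            assert not (rp.ring & any_nucleus).any()
            assert not (rp.ring & claimed).any()
            assert (rp.nuclear & ~(truth.nuclear_labels == rp.label)).sum() == 0
            claimed |= rp.ring

    def test_vanishing_nucleus_flagged(self):
        mask = _square_mask(size=3)
        (rp,) = iq.build_region_pairs(mask, erosion_px=2)
        assert rp.eroded_away and not rp.nuclear.any()


class TestMeasureNcRatio:
    def test_uniform_image_gives_unit_ratios(self, small_fish):
        _, _, truth = small_fish
        pairs = iq.build_region_pairs(truth.nuclear_labels)
        cells = iq.measure_nc_ratio(np.full(truth.nuclear_labels.shape, 7.0), pairs)
        np.testing.assert_allclose(cells["nc_ratio"], 1.0)

    def test_noiseless_synthetic_ratio_recovered(self, small_fish):
        _, frame, truth = small_fish
        pairs = iq.build_region_pairs(truth.nuclear_labels)
        cells = iq.measure_nc_ratio(frame["signal"], pairs)
        kept = cells[cells["included"]]
        assert len(kept) == 5
        np.testing.assert_allclose(kept["nc_ratio"], 2.0, rtol=1e-12)

    def test_zero_signal_ring_flagged_and_excluded(self):
        mask = _square_mask(shape=(60, 60), top=20, left=20, size=10)
        pairs = iq.build_region_pairs(mask, ring_width_px=5)
        signal = np.zeros((60, 60))
        signal[mask > 0] = 50.0
        cells = iq.measure_nc_ratio(signal, pairs)
        assert bool(cells.loc[0, "qc_zero_denominator"])
        assert not bool(cells.loc[0, "included"])
        assert np.isnan(cells.loc[0, "nc_ratio"])

    def test_ratio_invariant_under_positive_scaling(self, small_fish):
        _, frame, truth = small_fish
        pairs = iq.build_region_pairs(truth.nuclear_labels)
        r1 = iq.measure_nc_ratio(frame["signal"], pairs)["nc_ratio"]
        r2 = iq.measure_nc_ratio(frame["signal"] * 3.7, pairs)["nc_ratio"]
        np.testing.assert_allclose(r1, r2, rtol=1e-12)


class TestScoreFoci:
    def test_background_only_all_zero(self):
        frame, truth = sd.generate_foci_image(sd.FociImageSpec(foci_counts=(0, 0), seed=21))
        table, frac = iq.score_foci(frame["foci"], truth.nuclear_labels)
        assert table["foci_count"].tolist() == [0, 0]
        assert frac == 0.0

    def test_planted_counts_recovered_and_fraction_half(self):
        frame, truth = sd.generate_foci_image(sd.FociImageSpec(foci_counts=(0, 3, 5, 8), seed=22))
        table, frac = iq.score_foci(frame["foci"], truth.nuclear_labels)
        assert table.sort_values("label")["foci_count"].tolist() == [0, 3, 5, 8]
        assert frac == 0.5

    def test_threshold_is_inclusive(self):
        frame, truth = sd.generate_foci_image(sd.FociImageSpec(foci_counts=(5, 5, 5), seed=23))
        _, frac = iq.score_foci(frame["foci"], truth.nuclear_labels, min_foci=5)
        assert frac == 1.0

    def test_fraction_monotone_in_threshold(self):
        frame, truth = sd.generate_foci_image(
            sd.FociImageSpec(foci_counts=(1, 2, 4, 5, 7, 9), seed=24)
        )
        fracs = [
            iq.score_foci(frame["foci"], truth.nuclear_labels, min_foci=m)[1]
            for m in range(1, 11)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_min_foci_below_one_rejected(self, small_fish):
        _, frame, truth = small_fish
        with pytest.raises(ParameterError):
            iq.score_foci(frame["signal"], truth.nuclear_labels, min_foci=0)


class TestReporterRatio:
    def test_identical_channels_give_unit_ratio(self):
        frame, truth = sd.generate_reporter_image(sd.ReporterImageSpec(seed=31))
        img = frame["denominator"]
        table, mean = iq.reporter_ratio(img, img, truth.cell_labels, min_denominator=0)
        np.testing.assert_allclose(table["reporter_ratio"], 1.0)
        assert mean == pytest.approx(1.0)

    def test_noiseless_ratios_recovered_under_one_percent(self):
        spec = sd.ReporterImageSpec(true_ratios=(0.3, 1.0, 2.0), seed=32)
        frame, truth = sd.generate_reporter_image(spec)
        table, _ = iq.reporter_ratio(
            frame["numerator"], frame["denominator"], truth.cell_labels,
            min_denominator=200,
        )
        expected = [truth.true_ratios[k] for k in table["label"]]
        np.testing.assert_allclose(table["reporter_ratio"], expected, rtol=0.01)

    def test_untransfected_cell_excluded(self):
        spec = sd.ReporterImageSpec(true_ratios=(1.0, 1.0), denominator_level=500, seed=33)
        frame, truth = sd.generate_reporter_image(spec)
        den = frame["denominator"].copy()
        den[truth.cell_labels == 2] = 10.0  # kill the reporter in cell 2
        table, _ = iq.reporter_ratio(frame["numerator"], den, truth.cell_labels,
                                     min_denominator=200)
        assert table["label"].tolist() == [1]

    def test_all_cells_excluded_raises(self):
        frame, truth = sd.generate_reporter_image(sd.ReporterImageSpec(seed=34))
        with pytest.raises(EmptyResultError):
            iq.reporter_ratio(frame["numerator"], frame["denominator"],
                              truth.cell_labels, min_denominator=1e9)

    def test_equivariant_under_per_channel_scaling(self):
        frame, truth = sd.generate_reporter_image(sd.ReporterImageSpec(seed=35))
        t1, _ = iq.reporter_ratio(frame["numerator"], frame["denominator"],
                                  truth.cell_labels, min_denominator=0)
        t2, _ = iq.reporter_ratio(frame["numerator"] * 6.0, frame["denominator"] * 2.0,
                                  truth.cell_labels, min_denominator=0)
        np.testing.assert_allclose(t2["reporter_ratio"], 3.0 * t1["reporter_ratio"],
                                   rtol=1e-12)


class TestMeanNuclearSignal:
    def test_uniform_image(self):
        mask = _square_mask()
        mean, sem, _ = iq.mean_nuclear_signal(np.full((40, 40), 5.0), mask)
        assert mean == 5.0 and np.isnan(sem)

    def test_two_nuclei_average(self):
        mask = np.zeros((30, 60), dtype=np.int32)
        mask[10:20, 5:15] = 1
        mask[10:20, 40:50] = 2
        signal = np.zeros((30, 60))
        signal[mask == 1] = 10.0
        signal[mask == 2] = 30.0
        mean, sem, table = iq.mean_nuclear_signal(signal, mask)
        assert mean == 20.0
        assert sem == pytest.approx(10.0)  # sd 14.14 / sqrt 2
        assert table["nuclear_mean"].tolist() == [10.0, 30.0]

    def test_matches_brute_force_population_average(self, small_fish):
        _, frame, truth = small_fish
        mean, _, _ = iq.mean_nuclear_signal(frame["signal"], truth.nuclear_labels)
        per_cell = [
            frame["signal"][truth.nuclear_labels == k].mean()
            for k in sorted(truth.true_nc_ratios)
        ]
        assert mean == pytest.approx(np.mean(per_cell), rel=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyResultError):
            iq.mean_nuclear_signal(np.zeros((10, 10)), np.zeros((10, 10), dtype=np.int32))
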