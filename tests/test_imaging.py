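"""Image quantification: projections, ROI correction, 3-D masks, I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from circatrace.imaging import (
    ROISet,
    StackSeries,
    corrected_intensity,
    mask_intensity_sum,
    measure_stack_series,
    nuclear_cytoplasmic_ratio,
    read_stack_series,
    sum_project,
    write_stack_series,
)
from circatrace.synthetic import BlobSpec, StackSpec, gaussian_blob_mass_above, render_stack_series
from circatrace.trace import Trace


def _roiset(shape=(16, 16)):
    cell = np.zeros(shape, bool)
    cell[6:10, 6:10] = True
    bgs = []
    for oy, ox in [(0, 0), (0, shape[1] - 3), (shape[0] - 3, 0)]:
        m = np.zeros(shape, bool)
        m[oy:oy + 3, ox:ox + 3] = True
        bgs.append(m)
    return ROISet(cell_rois={"c0": cell}, background_rois=tuple(bgs))


class TestSumProject:
    def test_uniform_slices_sum(self):
        vol = np.full((8, 4, 4), 2)
        assert np.all(sum_project(vol) == 16)

    def test_single_slice_identity(self):
        vol = np.arange(12).reshape(1, 3, 4)
        np.testing.assert_array_equal(sum_project(vol)[None], vol)

    @given(hnp.arrays(np.float64, (5, 6, 7),
                      elements=st.floats(0, 1e6, allow_nan=False)))
    def test_conserves_total_intensity(self, vol):
        assert sum_project(vol).sum() == pytest.approx(vol.sum(), rel=1e-12)

    def test_integer_inputs_widen(self):
        vol = np.full((300, 2, 2), 10_000_000, dtype=np.int32)
        proj = sum_project(vol)
        assert proj.dtype == np.int64
        assert proj[0, 0] == 3_000_000_000  # would overflow int32

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sum_project(np.empty((0, 4, 4)))
        with pytest.raises(ValueError):
            sum_project(np.zeros((4, 4)))


class TestCorrectedIntensity:
    def test_mean_minus_mean_of_background_means(self):
        rois = _roiset()
        img = np.zeros((16, 16))
        img[rois.cell_rois["c0"]] = 50.0
        for m, v in zip(rois.background_rois, (10.0, 12.0, 14.0)):
            img[m] = v
        assert corrected_intensity(img, rois, "c0") == pytest.approx(38.0)

    def test_uniform_image_gives_zero(self):
        img = np.full((16, 16), 7.3)
        assert corrected_intensity(img, _roiset(), "c0") == pytest.approx(0.0)

    @given(st.floats(-100, 100, allow_nan=False))
    def test_invariant_to_constant_offset(self, c):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (16, 16))
        rois = _roiset()
        base = corrected_intensity(img, rois, "c0")
        assert corrected_intensity(img + c, rois, "c0") == pytest.approx(base, abs=1e-9)

    def test_missing_cell_roi(self):
        with pytest.raises(KeyError):
            corrected_intensity(np.zeros((16, 16)), _roiset(), "ghost")

    def test_background_count_enforced(self):
        rois = _roiset()
        with pytest.raises(ValueError):
            ROISet(cell_rois=rois.cell_rois,
                   background_rois=rois.background_rois[:2])

    def test_negative_corrected_value_retained(self):
        rois = _roiset()
        img = np.full((16, 16), 20.0)
        img[rois.cell_rois["c0"]] = 5.0
        assert corrected_intensity(img, rois, "c0") == pytest.approx(-15.0)

    def test_synthetic_blob_recovery_within_5pct(self):
        blob = BlobSpec(center=(8.0, 24.0, 20.0), radius_voxels=2.5,
                        peak_intensity=60.0)
        spec = StackSpec(shape=(16, 48, 48), cells=(blob,),
                         background_level=10.0)
        tr = Trace("c0", "LNv", "g", [0.0, 3.0], [100.0, 100.0])
        vols, gt = render_stack_series(spec, [tr])
        img = sum_project(vols[0])
        yy, xx = np.mgrid[:48, :48]
        cell = (yy - 24.0) ** 2 + (xx - 20.0) ** 2 <= (3.5 * 2.5) ** 2
        bgs = []
        for oy, ox in [(0, 0), (0, 43), (43, 0)]:
            m = np.zeros((48, 48), bool)
            m[oy:oy + 5, ox:ox + 5] = True
            bgs.append(m)
        rois = ROISet(cell_rois={"c0": cell}, background_rois=tuple(bgs))
        recovered = corrected_intensity(img, rois, "c0") * cell.sum()
        truth = gt["true_integral"].iloc[0]
        assert recovered == pytest.approx(truth, rel=0.05)


class TestMaskIntensitySum:
    def test_uniform_background_gives_empty_flagged_mask(self):
        vol = np.full((8, 8, 8), 10.0)
        res = mask_intensity_sum(vol, threshold=1.0, background=10.0)
        assert res.empty and res.total_sum == 0.0

    def test_blob_sum_matches_analytic_mass_above_threshold(self):
        blob = BlobSpec(center=(10.0, 24.0, 24.0), radius_voxels=2.5,
                        peak_intensity=60.0)
        spec = StackSpec(shape=(20, 48, 48), cells=(blob,),
                         background_level=10.0)
        tr = Trace("c0", "LNv", "g", [0.0, 3.0], [100.0, 100.0])
        vols, gt = render_stack_series(spec, [tr])
        thr = 0.1 * 60.0
        res = mask_intensity_sum(vols[0], threshold=thr, background=10.0)
        truth = gaussian_blob_mass_above(gt["true_integral"].iloc[0], 60.0, thr)
        assert res.total_sum == pytest.approx(truth, rel=0.05)
        assert len(res.component_sums) == 1

    def test_two_blobs_scored_independently(self):
        b1 = BlobSpec(center=(10.0, 12.0, 12.0), radius_voxels=2.0,
                      peak_intensity=50.0)
        b2 = BlobSpec(center=(10.0, 36.0, 36.0), radius_voxels=2.0,
                      peak_intensity=80.0)
        spec = StackSpec(shape=(20, 48, 48), cells=(b1, b2),
                         background_level=5.0)
        traces = [Trace(f"c{i}", "LNv", "g", [0.0, 3.0], [100.0, 100.0])
                  for i in range(2)]
        vols, gt = render_stack_series(spec, traces)
        thr = 0.1 * 50.0
        res = mask_intensity_sum(vols[0], threshold=thr, background=5.0)
        assert len(res.component_sums) == 2
        sums = sorted(res.component_sums.values())
        truths = sorted(
            gaussian_blob_mass_above(row["true_integral"], row["peak"], thr)
            for _, row in gt[gt["time_hr"] == 0.0].iterrows())
        for s, t in zip(sums, truths):
            assert s == pytest.approx(t, rel=0.05)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 100, (10, 10, 10))
        sums = [mask_intensity_sum(vol, thr, background=5.0).total_sum
                for thr in (50.0, 30.0, 10.0, 1.0)]
        assert sums == sorted(sums)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            mask_intensity_sum(np.zeros((2, 2, 2)), 0.0, 0.0)


class TestNuclearCytoplasmicRatio:
    def _rois(self):
        nuc = np.zeros((10, 10), bool)
        nuc[4:6, 4:6] = True
        cyt = np.zeros((10, 10), bool)
        cyt[1:3, 1:3] = True
        return nuc, cyt

    def test_simple_ratio(self):
        nuc, cyt = self._rois()
        img = np.zeros((10, 10))
        img[nuc] = 40.0
        img[cyt] = 20.0
        assert nuclear_cytoplasmic_ratio(img, nuc, cyt, 0.0) == pytest.approx(2.0)

    def test_equal_compartments_give_one_regardless_of_background(self):
        nuc, cyt = self._rois()
        img = np.full((10, 10), 30.0)
        assert nuclear_cytoplasmic_ratio(img, nuc, cyt, 12.0) == pytest.approx(1.0)

    def test_generator_ratio_recovered_under_noise(self, rng):
        nuc, cyt = self._rois()
        ratios = []
        for _ in range(50):
            img = np.full((10, 10), 10.0) + rng.normal(0, 1.0, (10, 10))
            img[nuc] += 30.0
            img[cyt] += 10.0
            ratios.append(nuclear_cytoplasmic_ratio(img, nuc, cyt, 10.0))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.10)

    def test_nonpositive_cytoplasm_is_error(self):
        nuc, cyt = self._rois()
        img = np.zeros((10, 10))
        img[nuc] = 40.0
        with pytest.raises(ValueError):
            nuclear_cytoplasmic_ratio(img, nuc, cyt, 5.0)

    def test_overlapping_rois_rejected(self):
        nuc, _ = self._rois()
        with pytest.raises(ValueError):
            nuclear_cytoplasmic_ratio(np.ones((10, 10)), nuc, nuc, 0.0)


class TestStackSeriesIO:
    def test_roundtrip(self, tmp_path):
        vols = [np.random.default_rng(i).uniform(0, 100, (4, 8, 8))
                for i in range(3)]
        series = StackSeries(volumes=vols, time_hr=np.array([0.0, 3.0, 6.0]),
                             channel="VNP")
        write_stack_series(series, tmp_path / "stk")
        back = read_stack_series(tmp_path / "stk")
        assert back.channel == "VNP"
        np.testing.assert_array_equal(back.time_hr, series.time_hr)
        for a, b in zip(vols, back.volumes):
            np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_measure_stack_series_records(self):
        rois = _roiset()
        vols = [np.full((2, 16, 16), float(v)) for v in (5, 6)]
        series = StackSeries(volumes=vols, time_hr=[0.0, 1.0])
        rec = measure_stack_series(series, rois)
        assert set(rec.columns) >= {"cell_id", "time_hr", "raw_mean",
                                    "background_mean", "corrected_intensity",
                                    "negative_flag"}
        assert np.allclose(rec["corrected_intensity"], 0.0)
        assert not rec["negative_flag"].any()
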