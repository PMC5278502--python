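"""Generators: trace model, cohorts, drug experiments, image stacks."""

import numpy as np
import pandas as pd
import pytest

from circatrace.synthetic import (
    BlobSpec,
    DrugEffectSpec,
    StackSpec,
    TraceModelParams,
    generate_cohort,
    generate_response_experiment,
    generate_trace,
    render_stack_series,
)
from circatrace.trace import Trace


class TestGenerateTrace:
    def test_degenerate_model_is_constant(self):
        params = TraceModelParams(mesor=100.0, amplitude=0.0, drift_rate=0.0,
                                  noise_sd=0.0)
        tr = generate_trace(params, seed=0)
        assert np.all(tr.intensity == 100.0)
        assert len(tr) == int(48 // 3) + 1

    def test_cosine_extrema_at_phase_plus_period_multiples(self):
        params = TraceModelParams(mesor=100.0, amplitude=50.0, period_hr=24.0,
                                  phase_hr=0.0, damping_rate=0.0,
                                  drift_rate=0.0, noise_sd=0.0,
                                  sampling_interval_hr=3.0, duration_hr=48.0)
        tr = generate_trace(params, seed=0)
        peaks = tr.time_hr[tr.intensity == tr.intensity.max()]
        assert list(peaks) == [0.0, 24.0, 48.0]

    def test_seed_determinism(self):
        params = TraceModelParams()
        a = generate_trace(params, seed=7)
        b = generate_trace(params, seed=7)
        c = generate_trace(params, seed=8)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_intensities_never_negative(self):
        params = TraceModelParams(mesor=5.0, amplitude=0.0, noise_sd=50.0)
        tr = generate_trace(params, seed=3)
        assert np.all(tr.intensity >= 0.0)

    @pytest.mark.parametrize("bad", [
        dict(period_hr=0.0),
        dict(period_hr=-24.0),
        dict(noise_sd=-1.0),
        dict(damping_rate=-0.1),
        dict(mesor=float("nan")),
        dict(amplitude=float("inf")),
        dict(duration_hr=1.0, sampling_interval_hr=3.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_trace(TraceModelParams(**bad), seed=0)

    def test_trace_length_matches_duration(self):
        params = TraceModelParams(duration_hr=50.0, sampling_interval_hr=3.0)
        assert len(generate_trace(params, seed=0)) == 17  # floor(50/3)+1


class TestGenerateCohort:
    def test_all_rhythmic_when_fraction_one(self):
        _, gt = generate_cohort(10, rhythmic_fraction=1.0, seed=0)
        assert gt["is_rhythmic"].all()

    def test_exact_rhythmic_count(self):
        _, gt = generate_cohort(100, rhythmic_fraction=0.6, seed=5)
        assert gt["is_rhythmic"].sum() == 60

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0)

    def test_bad_class_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(10, class_mix={"LNv": 0.7, "DN1": 0.7}, seed=0)

    def test_nonrhythmic_cells_have_nan_period_and_rise(self):
        traces, gt = generate_cohort(20, rhythmic_fraction=0.5, seed=2)
        nonr = gt[~gt["is_rhythmic"]]
        assert nonr["true_period_hr"].isna().all()
        by_id = {t.cell_id: t for t in traces}
        for cid in nonr["cell_id"]:
            tr = by_id[cid]
            # positive drift: late mean exceeds early mean despite noise
            assert tr.intensity[-5:].mean() > tr.intensity[:5].mean()

    def test_class_mix_allocation(self):
        _, gt = generate_cohort(20, class_mix={"LNv": 0.5, "DN1": 0.25,
                                               "DN2": 0.25}, seed=0)
        counts = gt["neuron_class"].value_counts()
        assert counts["LNv"] == 10 and counts["DN1"] == 5 and counts["DN2"] == 5

    def test_determinism(self):
        t1, g1 = generate_cohort(15, seed=9)
        t2, g2 = generate_cohort(15, seed=9)
        pd.testing.assert_frame_equal(g1, g2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.intensity, b.intensity)


class TestResponseExperiment:
    def test_ramp_effect_arithmetic_noise_free(self):
        # 0.1/h ramp from t=1 on LNv in the PDF group: at t=8 the mean
        # fold-change exceeds vehicle by exactly 0.7 before noise
        spec = DrugEffectSpec(onset_hr=1.0, effect_shape="ramp",
                              effect_size=0.1,
                              affected_groups=frozenset({"PDF"}),
                              affected_classes=frozenset({"LNv"}))
        df = generate_response_experiment(spec, groups=["Vehicle", "PDF"],
                                          classes=["LNv"], n_per_group_class=4,
                                          seed=0, noise_cv=0.0)
        at8 = df[df["time_hr"] == 8.0]
        norm = at8.set_index("cell_id")["intensity"] / df[df["time_hr"] == 0.0
                                                          ].set_index("cell_id")["intensity"]
        groups = at8.set_index("cell_id")["group"]
        diff = norm[groups == "PDF"].mean() - norm[groups == "Vehicle"].mean()
        assert diff == pytest.approx(0.7, abs=1e-9)

    def test_blocked_group_matches_vehicle_in_expectation(self):
        spec = DrugEffectSpec(blocked_by=frozenset({"TTX"}))
        df = generate_response_experiment(
            spec, groups=["Vehicle", "PDF+TTX"], classes=["LNv", "DN1"],
            n_per_group_class=3, seed=0, noise_cv=0.0)
        # noise-free: both groups perfectly flat at their mesor
        for _, sub in df.groupby("cell_id"):
            assert sub["intensity"].nunique() == 1

    def test_flat_before_onset(self):
        spec = DrugEffectSpec(onset_hr=3.0, effect_shape="step", effect_size=0.5)
        df = generate_response_experiment(spec, groups=["Vehicle", "PDF"],
                                          n_per_group_class=2, seed=1,
                                          noise_cv=0.0)
        pre = df[df["time_hr"] < 3.0]
        for _, sub in pre.groupby("cell_id"):
            assert sub["intensity"].nunique() == 1

    def test_unknown_labels_rejected(self):
        spec = DrugEffectSpec(affected_groups=frozenset({"NOPE"}))
        with pytest.raises(ValueError):
            generate_response_experiment(spec, groups=["Vehicle", "PDF"], seed=0)
        spec = DrugEffectSpec(affected_classes=frozenset({"LNv", "LPN"}))
        with pytest.raises(ValueError):
            generate_response_experiment(spec, groups=["Vehicle", "PDF"],
                                         classes=["LNv", "DN1"], seed=0)

    def test_baseline_must_precede_end(self):
        with pytest.raises(ValueError):
            generate_response_experiment(DrugEffectSpec(), baseline_hr=9.0,
                                         duration_hr=8.0, seed=0)


class TestRenderStackSeries:
    def _flat_trace(self, cid="c0"):
        return Trace(cid, "LNv", "g", [0.0, 3.0], [100.0, 100.0])

    def test_background_only(self):
        spec = StackSpec(shape=(4, 8, 8), cells=(), background_level=10.0,
                         background_gradient=0.0)
        vols, gt = render_stack_series(spec, [])
        assert np.all(vols[0] == 10.0)
        assert gt.empty

    def test_background_gradient(self):
        spec = StackSpec(shape=(2, 4, 6), cells=(), background_level=5.0,
                         background_gradient=1.0)
        vols, _ = render_stack_series(spec, [])
        np.testing.assert_array_equal(vols[0][0, 0, :],
                                      5.0 + np.arange(6, dtype=float))

    def test_ground_truth_matches_rendered_blob(self):
        blob = BlobSpec(center=(8.0, 24.0, 24.0), radius_voxels=2.5,
                        peak_intensity=60.0)
        spec = StackSpec(shape=(16, 48, 48), cells=(blob,),
                         background_level=10.0)
        vols, gt = render_stack_series(spec, [self._flat_trace()])
        rendered = vols[0].sum() - 10.0 * vols[0].size
        assert rendered == pytest.approx(gt["true_integral"].iloc[0], rel=1e-9)

    def test_intensity_scales_with_trace(self):
        blob = BlobSpec(center=(8.0, 24.0, 24.0), radius_voxels=2.0,
                        peak_intensity=50.0)
        spec = StackSpec(shape=(16, 48, 48), cells=(blob,), background_level=0.1)
        tr = Trace("c0", "LNv", "g", [0.0, 3.0], [100.0, 150.0])
        _, gt = render_stack_series(spec, [tr])
        ratio = gt["true_integral"].iloc[1] / gt["true_integral"].iloc[0]
        assert ratio == pytest.approx(1.5, rel=1e-9)

    def test_fixed_seed_bitwise_identical(self):
        blob = BlobSpec(center=(4.0, 10.0, 10.0), radius_voxels=2.0,
                        peak_intensity=40.0)
        spec = StackSpec(shape=(8, 20, 20), cells=(blob,), background_level=5.0,
                         noise_model=("gaussian", 2.0))
        v1, _ = render_stack_series(spec, [self._flat_trace()], seed=4)
        v2, _ = render_stack_series(spec, [self._flat_trace()], seed=4)
        np.testing.assert_array_equal(v1[0], v2[0])

    def test_overlapping_cells_flagged(self):
        b1 = BlobSpec(center=(8.0, 20.0, 20.0), radius_voxels=2.0,
                      peak_intensity=40.0)
        b2 = BlobSpec(center=(8.0, 22.0, 20.0), radius_voxels=2.0,
                      peak_intensity=40.0)
        b3 = BlobSpec(center=(8.0, 40.0, 40.0), radius_voxels=2.0,
                      peak_intensity=40.0)
        spec = StackSpec(shape=(16, 48, 48), cells=(b1, b2, b3),
                         background_level=1.0)
        traces = [self._flat_trace(f"c{i}") for i in range(3)]
        _, gt = render_stack_series(spec, traces)
        flags = gt.groupby("cell_id")["overlaps"].first()
        assert flags["blob0"] and flags["blob1"] and not flags["blob2"]

    def test_center_outside_volume_rejected(self):
        blob = BlobSpec(center=(99.0, 0.0, 0.0), radius_voxels=2.0,
                        peak_intensity=40.0)
        spec = StackSpec(shape=(8, 20, 20), cells=(blob,))
        with pytest.raises(ValueError):
            render_stack_series(spec, [self._flat_trace()])
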