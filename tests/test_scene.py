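"""Synthetic scene generator: emission models, layout, ground truth."""

import numpy as np
import pandas as pd
import pytest

import tifffile

from ppixquant.camera import external_camera
from ppixquant.kinetics import fit_log_decay
from ppixquant.quantify import ROI, extract_timeseries
from ppixquant.scene import (
    DARK_FLOOR,
    LayoutError,
    StandardSpec,
    StudyDesign,
    TissueSpec,
    generate_series,
    standard_emission,
    tissue_emission,
    write_study,
)


class TestStandardEmission:
    def test_zero_thickness_emits_nothing(self):
        s = StandardSpec(standard_id=0, thickness_in=0.0, concentration_ppt=0.5)
        assert standard_emission(s, 25.2, 0.0) == 0.0

    def test_higher_concentration_outshines_lower_at_same_thickness(self):
        lo = StandardSpec(standard_id=1, thickness_in=0.04, concentration_ppt=0.5)
        hi = StandardSpec(standard_id=8, thickness_in=0.04, concentration_ppt=8.1)
        assert standard_emission(hi, 25.2, 0.0) > standard_emission(lo, 25.2, 0.0)

    def test_linear_in_thickness_with_concentration_dependent_slope(self):
        conc_slopes = []
        for conc in (0.5, 8.1):
            vals = [standard_emission(
                StandardSpec(standard_id=0, thickness_in=th, concentration_ppt=conc),
                25.2, 0.0) for th in (0.02, 0.04, 0.08)]
            slopes = np.diff(vals) / np.diff([0.02, 0.04, 0.08])
            assert slopes[0] == pytest.approx(slopes[1], rel=1e-12)  # linear
            conc_slopes.append(slopes[0])
        assert conc_slopes[1] > conc_slopes[0]

    def test_maximum_drift_reaches_3_5_percent_at_30_min(self):
        s = StandardSpec(standard_id=1, thickness_in=0.02, concentration_ppt=0.5,
                         drift_30min=0.035)
        ratio = standard_emission(s, 25.2, 30.0) / standard_emission(s, 25.2, 0.0)
        assert ratio == pytest.approx(1.035, abs=1e-12)

    def test_drift_bounded_within_30_min(self):
        s = StandardSpec(standard_id=1, thickness_in=0.02, concentration_ppt=0.5)
        base = standard_emission(s, 25.2, 0.0)
        for t in np.linspace(0, 30, 13):
            assert abs(standard_emission(s, 25.2, t) / base - 1) <= 0.035 + 1e-12

    def test_negative_inputs_rejected(self):
        s = StandardSpec(standard_id=1, thickness_in=0.02, concentration_ppt=0.5)
        with pytest.raises(ValueError):
            standard_emission(s, -1.0, 0.0)
        with pytest.raises(ValueError):
            StandardSpec(standard_id=1, thickness_in=0.02, concentration_ppt=0.5,
                         drift_30min=0.2)


class TestTissueEmission:
    tumor = TissueSpec(role="tumor", I0=36.8, c_log=-8.94)

    def test_time_zero_returns_initial_radiance_exactly(self):
        assert tissue_emission(self.tumor, 25.2, 0.0) == 36.8

    def test_default_tumor_trajectory_at_10_min(self):
        # 36.8 - 8.94*ln(11) = 15.36 at full central irradiance
        assert tissue_emission(self.tumor, 25.2, 10.0) == pytest.approx(15.363, abs=0.001)

    def test_no_light_no_bleaching(self):
        for t in (0.0, 10.0, 30.0):
            assert tissue_emission(self.tumor, 0.0, t) == 36.8

    def test_monotone_non_increasing_and_floored_at_zero(self):
        t = np.linspace(0, 300, 50)
        vals = [tissue_emission(self.tumor, 25.2, ti) for ti in t]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 0.0  # long exposures clamp at zero, never negative

    def test_bleaching_rate_scales_with_irradiance(self):
        drop_full = 36.8 - tissue_emission(self.tumor, 25.2, 10.0)
        drop_half = 36.8 - tissue_emission(self.tumor, 12.6, 10.0)
        assert drop_half == pytest.approx(drop_full / 2, rel=1e-12)

    def test_role_validation(self):
        with pytest.raises(ValueError):
            TissueSpec(role="tumor", I0=10.0, c_log=0.5)
        with pytest.raises(ValueError):
            TissueSpec(role="dark_background", I0=1.0, c_log=-0.1)


class TestGenerateSeries:
    def test_default_schedule_has_15_frames(self, default_study):
        # every 1 min for 10 min then every 5 min to 30 -> 11 + 4 frames
        stack = default_study.frames["external"][0]
        assert stack.shape[0] == 15
        assert default_study.design.times_min == tuple(range(11)) + (15, 20, 25, 30)

    def test_same_seed_gives_bit_identical_stacks(self, small_design):
        a = generate_series(small_design)
        b = generate_series(small_design)
        for cam in a.frames:
            for s in range(small_design.n_specimens):
                assert np.array_equal(a.frames[cam][s], b.frames[cam][s])

    def test_ground_truth_covers_standards_tumor_brain_per_specimen(self, small_study):
        gt = small_study.ground_truth
        labels = set(gt["label"].unique())
        assert {"standard-1", "standard-4", "standard-6", "standard-9",
                "tumor", "brain", "dark_background"} == labels
        per = gt.groupby(["specimen", "time_min"]).size().unique()
        assert list(per) == [7]

    def test_ground_truth_tumor_matches_closed_form(self, small_study):
        gt = small_study.ground_truth
        g = small_study.specimen_gains
        j = small_study.tumor_jitters
        t0 = gt[(gt["label"] == "tumor") & (gt["time_min"] == 0)]
        for s, row in zip(t0["specimen"], t0["radiance"]):
            assert row == pytest.approx(36.8 * g[s] * j[s], rel=1e-12)
        b0 = gt[(gt["label"] == "brain") & (gt["time_min"] == 0)]
        for s, row in zip(b0["specimen"], b0["radiance"]):
            assert row == pytest.approx(8.0 * g[s], rel=1e-12)
        dk = gt[gt["label"] == "dark_background"]
        assert np.allclose(dk["radiance"], DARK_FLOOR)

    def test_rendered_roi_means_track_ground_truth(self, small_study):
        """End-to-end: external-camera ROI means ~= red_gain * true radiance
        (tissue sits near the beam centre; noise/quantization average out)."""
        cam = next(c for c in small_study.design.cameras if c.name == "external")
        rois = [ROI(id=r["id"], center=(r["row"], r["col"]), radius=r["radius"],
                    label=r["label"]) for r in small_study.rois]
        ts = extract_timeseries(small_study.frames["external"][0], rois,
                                small_study.design.times_min)
        gt = small_study.ground_truth
        for label in ("tumor", "brain"):
            truth = gt[(gt["specimen"] == 0) & (gt["label"] == label)]
            meas = ts.mean_series(label)
            expected = cam.red_gain * truth.set_index("time_min")["radiance"]
            np.testing.assert_allclose(meas.to_numpy(), expected.to_numpy(),
                                       rtol=0.07)

    def test_standards_stable_tumor_strictly_decreasing(self, default_study):
        rois = [ROI(id=r["id"], center=(r["row"], r["col"]), radius=r["radius"],
                    label=r["label"]) for r in default_study.rois]
        ts = extract_timeseries(default_study.frames["external"][0], rois,
                                default_study.design.times_min)
        for k in (1, 4, 6, 9):
            s = ts.mean_series(f"standard-{k}")
            assert abs(s.iloc[-1] / s.iloc[0] - 1) < 0.04
        tumor = ts.mean_series("tumor")
        assert np.all(np.diff(tumor.to_numpy()) < 0)

    def test_central_bleaching_faster_than_peripheral(self, default_study):
        """Fit the decay at the tumor-disc centre vs. near its rim: the
        brighter (more central) location must bleach faster."""
        stack = default_study.frames["external"][0]
        tumor_roi = next(r for r in default_study.rois if r["label"] == "tumor")
        rr, cc = tumor_roi["row"], tumor_roi["col"]
        centre = ROI(id="centre", center=(rr, cc), radius=10)
        # 4 mm toward the field edge, still inside the 5.8 mm disc
        perip = ROI(id="periph", center=(rr, cc - 40), radius=10)
        ts = extract_timeseries(stack, [centre, perip],
                                default_study.design.times_min)
        fits = {rid: fit_log_decay(ts.mean_series(rid).index.to_numpy(),
                                   ts.mean_series(rid).to_numpy())
                for rid in ("centre", "periph")}
        assert fits["centre"].c < fits["periph"].c < 0

    def test_overlapping_regions_raise_layout_error(self):
        tissues = (
            TissueSpec(role="tumor", I0=36.8, c_log=-8.94, center_mm=(0.0, -2.0)),
            TissueSpec(role="brain", I0=8.0, c_log=-1.048, center_mm=(0.0, 2.0)),
            TissueSpec(role="dark_background", I0=DARK_FLOOR, c_log=0.0,
                       center_mm=(18.0, 0.0)),
        )
        with pytest.raises(LayoutError, match="overlap"):
            generate_series(StudyDesign(n_specimens=1, tissues=tissues))

    def test_times_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            StudyDesign(times_min=(1.0, 2.0))
        with pytest.raises(ValueError):
            StudyDesign(times_min=(0.0, 5.0, 5.0))


def test_write_study_round_trip(tmp_path, small_study):
    write_study(small_study, tmp_path)
    stack = tifffile.imread(tmp_path / "specimen00_external.tif")
    assert np.array_equal(stack, small_study.frames["external"][0])
    assert (tmp_path / "rois.json").exists()
    assert (tmp_path / "design.json").exists()
    gt = pd.read_csv(tmp_path / "ground_truth.csv")
    assert len(gt) == len(small_study.ground_truth)
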