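import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtctqa.landmark_engine import DeltaResult
from rtctqa.qa_battery import (
    ScanRecord,
    check_bladder_filling,
    check_breathing_phase,
    check_contrast,
    check_fov_truncation,
    check_metal_imar,
    check_misapplied_thorax,
    check_slice_count,
    check_topogram,
    classify_bladder,
    run_battery,
)
from rtctqa.synthetic_data import PhantomSpec, generate_phantom


def record(**overrides):
    defaults = dict(
        pseudo_id="P-1",
        group="Thorax",
        protocol_name="Thorax_Lunge_3D",
        study_date="2023-01-01",
        slice_count=180,
        slice_thickness_mm=3.0,
        volumetric_length_mm=540.0,
        topogram_length_mm=560.0,
    )
    defaults.update(overrides)
    return ScanRecord(**defaults)


def delta(top, bot):
    return DeltaResult(
        delta_top=top, delta_bot=bot,
        top_method="direct" if top is not None else "unavailable",
        bot_method="direct" if bot is not None else "unavailable",
        guideline_flag_top=False, guideline_flag_bot=False,
    )


class TestContrast:
    def test_volume_passthrough(self):
        f = check_contrast(record(contrast_volume_ml=88.0))
        assert f.status == "pass" and f.details == {"applied": True, "volume_ml": 88.0}

    def test_absent_means_not_applied(self):
        assert check_contrast(record()).details["applied"] is False

    def test_negative_volume_flagged(self):
        assert check_contrast(record(contrast_volume_ml=-10.0)).status == "flag"


class TestMetalImar:
    @pytest.mark.parametrize(
        "max_hu,recon,expected_status,expected_metal",
        [
            (4500.0, "Br40s iMAR", "pass", True),
            (3999.0, "Br40s", "pass", False),  # strict inequality at 4000
            (4000.0, "Br40s", "pass", False),
            (4500.0, "Br40s", "flag", True),
        ],
    )
    def test_threshold_and_imar_token(self, max_hu, recon, expected_status,
                                      expected_metal):
        image = np.full((4, 4, 4), 40.0)
        image[1, 1, 1] = max_hu
        f = check_metal_imar(image, record(recon_description=recon))
        assert f.status == expected_status
        assert f.details["metal"] is expected_metal

    def test_missing_image_not_applicable(self):
        assert check_metal_imar(None, record()).status == "not_applicable"

    @settings(max_examples=25, deadline=None)
    @given(hu=st.floats(4000.1, 30000))
    def test_monotone_adding_metal_voxel(self, hu):
        image = np.full((3, 3, 3), 40.0)
        base = check_metal_imar(image, record())
        image[0, 0, 0] = hu
        after = check_metal_imar(image, record())
        assert not base.details["metal"] and after.details["metal"]


class TestTopogramAndSliceCount:
    @pytest.mark.parametrize(
        "topo,vol,status",
        [(500.0, 520.0, "flag"), (600.0, 520.0, "pass"), (None, 520.0, "not_applicable")],
    )
    def test_topogram_rule(self, topo, vol, status):
        rec = record(topogram_length_mm=topo, volumetric_length_mm=vol)
        assert check_topogram(rec).status == status

    @pytest.mark.parametrize(
        "count,status", [(100, "pass"), (399, "pass"), (400, "flag")]
    )
    def test_slice_limit_boundary(self, count, status):
        assert check_slice_count(record(slice_count=count)).status == status


class TestBreathingPhase:
    def test_plausible_ordering_passes(self):
        scans = [
            (record(breathing_label="inspiration"), 5000.0),
            (record(breathing_label="expiration"), 3000.0),
        ]
        assert check_breathing_phase(scans).status == "pass"

    def test_inverted_ordering_flags(self):
        scans = [
            (record(breathing_label="inspiration"), 2500.0),
            (record(breathing_label="expiration"), 3000.0),
        ]
        assert check_breathing_phase(scans).status == "flag"

    def test_single_scan_not_applicable(self):
        scans = [(record(breathing_label="inspiration"), 5000.0)]
        assert check_breathing_phase(scans).status == "not_applicable"


class TestBladder:
    @pytest.mark.parametrize(
        "volume,state",
        [
            (150.0, "empty"),
            (199.9, "empty"),
            (200.0, "partially_filled"),  # boundary in the middle class
            (300.0, "partially_filled"),
            (400.0, "partially_filled"),
            (450.0, "full"),
        ],
    )
    def test_filling_classes(self, volume, state):
        assert classify_bladder(volume) == state

    @settings(max_examples=50, deadline=None)
    @given(volume=st.floats(0, 5000))
    def test_classes_partition_the_volume_axis(self, volume):
        assert classify_bladder(volume) in {"empty", "partially_filled", "full"}

    def test_bladder_protocol_expects_empty(self, registry):
        data = generate_phantom(
            PhantomSpec(group="Abdomen", seed=1, bladder_volume_ml=450.0,
                        protocol_name="Abdomen_Bladder_3D"),
            registry,
        )
        f = check_bladder_filling(data.label_map, data.scan_record)
        assert f.details["state"] == "full"
        assert f.status == "flag"

    def test_pelvic_protocol_accepts_partial_filling(self, registry):
        data = generate_phantom(
            PhantomSpec(group="Pelvis", seed=1, bladder_volume_ml=300.0,
                        protocol_name="Pelvis_Prostate_3D"),
            registry,
        )
        f = check_bladder_filling(data.label_map, data.scan_record)
        assert f.details["state"] == "partially_filled"
        assert f.status == "pass"

    def test_no_expectation_not_applicable(self, registry):
        data = generate_phantom(PhantomSpec(group="Brain", seed=1), registry)
        f = check_bladder_filling(data.label_map, data.scan_record)
        assert f.status == "not_applicable"


class TestMisappliedThorax:
    @pytest.mark.parametrize(
        "top,bot,status",
        [
            (-120.0, 110.0, "flag"),
            (-120.0, 50.0, "pass"),     # conjunction required
            (-100.0, 150.0, "pass"),    # strict inequality at 10 cm
            (None, 150.0, "not_applicable"),
        ],
    )
    def test_rule(self, top, bot, status):
        assert check_misapplied_thorax(delta(top, bot)).status == status


class TestFovTruncation:
    def test_body_within_circle_passes(self, registry):
        data = generate_phantom(PhantomSpec(group="Thorax", seed=2), registry)
        f = check_fov_truncation(data.image, data.scan_record)
        assert f.status == "pass" and not f.details["truncation"]

    def test_body_crossing_circle_flags_without_hdfov(self, registry):
        spec = PhantomSpec(group="Thorax", seed=2, body_radius_mm=115.0,
                           fov_radius_mm=100.0)
        data = generate_phantom(spec, registry)
        f = check_fov_truncation(data.image, data.scan_record)
        assert f.details["truncation"] and not f.details["hdfov_used"]
        assert f.status == "flag"

    def test_hdfov_reconstruction_suppresses_flag(self, registry):
        spec = PhantomSpec(group="Thorax", seed=2, body_radius_mm=115.0,
                           fov_radius_mm=100.0, hdfov=True)
        data = generate_phantom(spec, registry)
        f = check_fov_truncation(data.image, data.scan_record)
        assert f.details["truncation"] and f.details["hdfov_used"]
        assert f.status == "pass"

    def test_missing_image_not_applicable(self):
        assert check_fov_truncation(None, record()).status == "not_applicable"


class TestRunBattery:
    def test_complete_record_yields_eight_findings(self, registry):
        data = generate_phantom(PhantomSpec(group="Thorax", seed=3), registry)
        vol_event = data.dose_report.volumetric_events[0]
        findings = run_battery(data.scan_record, delta=delta(10.0, 10.0),
                               dose_event=vol_event)
        assert len(findings) == 8
        assert [f.check_id for f in findings] == [
            "contrast", "metal_imar", "topogram", "slice_count",
            "bladder_filling", "misapplied_thorax", "fov_truncation",
            "dlp_consistency",
        ]

    def test_image_free_record_degrades_to_not_applicable(self):
        findings = run_battery(record())
        by_id = {f.check_id: f.status for f in findings}
        assert by_id["metal_imar"] == "not_applicable"
        assert by_id["fov_truncation"] == "not_applicable"

    def test_determinism(self, registry):
        data = generate_phantom(PhantomSpec(group="Pelvis", seed=4), registry)
        a = run_battery(data.scan_record, delta=delta(5.0, 5.0))
        b = run_battery(data.scan_record, delta=delta(5.0, 5.0))
        assert [(f.check_id, f.status) for f in a] == [
            (f.check_id, f.status) for f in b
        ]
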