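import numpy as np
import pytest

from rtctqa.landmark_engine import (
    LabelMapError,
    LandmarkSet,
    ScanExtent,
    compute_deltas,
    estimate_missing_boundary,
    extract_extents,
    resolve_boundary,
)
from rtctqa.synthetic_data import PhantomSpec, generate_phantom


def brute_force_extent(label_map, structure):
    """Oracle: z range over every labelled voxel centre via the affine."""
    target = [k for k, v in label_map.label_names.items() if v == structure]
    ii, jj, kk = np.nonzero(np.isin(label_map.grid, target))
    voxels = np.stack([ii, jj, kk, np.ones_like(ii)])
    zs = (label_map.affine @ voxels)[2]
    half = label_map.slice_thickness / 2.0
    return float(zs.max() + half), float(zs.min() - half)


class TestExtractExtents:
    def test_extent_spans_outer_slice_faces(self, label_map_factory):
        # a structure filling slices 10..20 at 3 mm: 11 slices -> 33 mm
        lm = label_map_factory({"organ": (10, 20), "other": (0, 5)})
        landmarks = extract_extents(lm)
        z_cr, z_ca = landmarks.extents["organ"]
        assert z_cr - z_ca == pytest.approx(33.0)
        assert (z_cr, z_ca) == pytest.approx(brute_force_extent(lm, "organ"))

    def test_boundary_touching_structures_recorded(self, label_map_factory):
        lm = label_map_factory({"low": (0, 3), "high": (8, 12), "mid": (4, 7)})
        landmarks = extract_extents(lm)
        assert "low" in landmarks.touches_bottom
        assert "high" in landmarks.touches_top
        assert "mid" not in landmarks.touches_top | landmarks.touches_bottom

    def test_empty_map_raises(self, label_map_factory):
        lm = label_map_factory({"organ": (0, 3)})
        lm.grid[:] = 0
        with pytest.raises(LabelMapError):
            extract_extents(lm)

    def test_unknown_label_id_raises(self, label_map_factory):
        lm = label_map_factory({"organ": (0, 3)})
        lm.grid[0, 0, 0] = 99
        with pytest.raises(LabelMapError, match="99"):
            extract_extents(lm)

    def test_alias_unions_members(self, label_map_factory):
        lm = label_map_factory({"lobe_a": (2, 5), "lobe_b": (5, 9)})
        landmarks = extract_extents(lm, {"lung": ("lobe_a", "lobe_b")})
        z_cr, z_ca = landmarks.extents["lung"]
        assert z_cr == landmarks.extents["lobe_b"][0]
        assert z_ca == landmarks.extents["lobe_a"][1]


def landmark_set(extents, touches_top=(), touches_bottom=()):
    return LandmarkSet(
        extents=extents,
        touches_top=frozenset(touches_top),
        touches_bottom=frozenset(touches_bottom),
    )


class TestResolveBoundary:
    def test_brain_top_applies_cranial_offset(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0)})
        assert resolve_boundary(registry.sop("Brain"), lm, "top") == (510.0, "direct")

    def test_pelvis_bot_equivalent_with_caudal_offset(self, registry):
        lm = landmark_set({"hip": (280.0, 100.0)})
        z, method = resolve_boundary(registry.sop("Pelvis"), lm, "bot")
        assert (z, method) == (0.0, "direct")

    def test_missing_landmark_returns_none(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0)})
        assert resolve_boundary(registry.sop("Brain"), lm, "bot") is None

    def test_border_cut_landmark_unusable(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0)}, touches_top={"skull"})
        assert resolve_boundary(registry.sop("Brain"), lm, "top") is None

    def test_upper_abdomen_bot_uses_cranial_extent_of_hip(self, registry):
        # hip reaches the caudal scan border, but its cranial end is what
        # anchors the iliac-crest boundary, so it stays usable
        lm = landmark_set({"hip": (150.0, 20.0)}, touches_bottom={"hip"})
        z, method = resolve_boundary(registry.sop("Upper abdomen"), lm, "bot")
        assert (z, method) == (150.0, "direct")


class TestEstimateMissingBoundary:
    def test_brain_bot_bridges_missing_c4_c3(self, registry):
        lm = landmark_set({"vertebrae_C2": (425.0, 400.0),
                           "vertebrae_C1": (450.0, 425.0)})
        z, method = estimate_missing_boundary(
            registry.sop("Brain"), lm, registry.vblut, "bot"
        )
        assert (z, method) == (360.0, "lut-estimated")

    def test_thorax_top_bridges_missing_c1(self, registry):
        lm = landmark_set({"vertebrae_C2": (600.0, 575.0)})
        z, method = estimate_missing_boundary(
            registry.sop("Thorax"), lm, registry.vblut, "top"
        )
        assert (z, method) == (625.0, "lut-estimated")

    def test_no_visible_chain_structure_returns_none(self, registry):
        lm = landmark_set({"liver": (300.0, 100.0)})
        assert estimate_missing_boundary(
            registry.sop("Brain"), lm, registry.vblut, "bot"
        ) is None

    def test_border_cut_chain_elements_skipped(self, registry):
        lm = landmark_set(
            {"vertebrae_C2": (425.0, 400.0), "vertebrae_C1": (450.0, 425.0)},
            touches_bottom={"vertebrae_C2"},
        )
        z, _ = estimate_missing_boundary(
            registry.sop("Brain"), lm, registry.vblut, "bot"
        )
        # anchored on C1 instead: 425 - (20 + 20 + 25)
        assert z == 360.0


class TestComputeDeltas:
    def test_exact_sop_match_gives_zero_delta(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0), "vertebrae_C4": (290.0, 270.0)})
        scan = ScanExtent(z_top=510.0, z_bot=270.0, slice_thickness=3.0, n_slices=80)
        res = compute_deltas(scan, registry.sop("Brain"), lm, registry.vblut)
        assert res.delta_top == 0.0
        assert res.delta_bot == 0.0
        assert not res.guideline_flag_top

    def test_unavailable_end_reports_none_not_zero(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0)})
        scan = ScanExtent(z_top=510.0, z_bot=270.0, slice_thickness=3.0, n_slices=80)
        res = compute_deltas(scan, registry.sop("Brain"), lm, registry.vblut)
        assert res.delta_bot is None
        assert res.bot_method == "unavailable"

    def test_guideline_flag_beyond_50mm(self, registry):
        lm = landmark_set({"skull": (500.0, 290.0), "vertebrae_C4": (290.0, 270.0)})
        scan = ScanExtent(z_top=570.0, z_bot=270.0, slice_thickness=3.0, n_slices=100)
        res = compute_deltas(scan, registry.sop("Brain"), lm, registry.vblut)
        assert res.delta_top == 60.0
        assert res.guideline_flag_top and not res.guideline_flag_bot


class TestPhantomRecovery:
    def test_brain_overcoverage_recovered(self, registry):
        spec = PhantomSpec(group="Brain", seed=5, intended_overcoverage=(15.0, 9.0))
        data = generate_phantom(spec, registry)
        lm = extract_extents(data.label_map, registry.aliases)
        scan = ScanExtent.from_label_map(data.label_map)
        res = compute_deltas(scan, registry.sop("Brain"), lm, registry.vblut)
        assert res.top_method == res.bot_method == "direct"
        assert res.delta_top == pytest.approx(data.ground_truth.true_delta_top, abs=3.0)
        assert res.delta_bot == pytest.approx(data.ground_truth.true_delta_bot, abs=3.0)

    def test_shift_equivariance(self, registry):
        spec = PhantomSpec(group="Thorax", seed=6, intended_overcoverage=(12.0, 18.0))
        data = generate_phantom(spec, registry)
        lm = extract_extents(data.label_map, registry.aliases)
        scan = ScanExtent.from_label_map(data.label_map)
        base = compute_deltas(scan, registry.sop("Thorax"), lm, registry.vblut)

        shifted_map = data.label_map
        shifted_map.affine[2, 3] += 37.0  # translate scan and anatomy together
        lm2 = extract_extents(shifted_map, registry.aliases)
        scan2 = ScanExtent.from_label_map(shifted_map)
        shifted = compute_deltas(scan2, registry.sop("Thorax"), lm2, registry.vblut)
        assert shifted.delta_top == pytest.approx(base.delta_top)
        assert shifted.delta_bot == pytest.approx(base.delta_bot)

    def test_cranial_extension_shifts_delta_top_exactly(self, registry):
        sop = registry.sop("Brain")
        lm = landmark_set({"skull": (500.0, 290.0), "vertebrae_C4": (290.0, 270.0)})
        for extra in (0.0, 9.0, 30.0):
            scan = ScanExtent(z_top=519.0 + extra, z_bot=270.0,
                              slice_thickness=3.0,
                              n_slices=int((519.0 + extra - 270.0) / 3))
            res = compute_deltas(scan, sop, lm, registry.vblut)
            assert res.delta_top == pytest.approx(9.0 + extra)

    def test_lut_estimate_converges_to_direct_for_small_truncation(self, registry):
        """Truncating just past the landmark switches to chain estimation
        whose value stays within one slice + LUT deviation of the truth."""
        spec = PhantomSpec(group="Brain", seed=8, slice_thickness_mm=3.0,
                           intended_overcoverage=(12.0, -6.0))
        data = generate_phantom(spec, registry)
        lm = extract_extents(data.label_map, registry.aliases)
        scan = ScanExtent.from_label_map(data.label_map)
        res = compute_deltas(scan, registry.sop("Brain"), lm, registry.vblut)
        assert res.bot_method == "lut-estimated"
        assert res.delta_bot == pytest.approx(-6.0, abs=3.0)
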