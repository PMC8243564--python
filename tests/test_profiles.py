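"""Normalization, profile extraction, clipping and measured-profile I/O."""

import numpy as np
import pytest

from beamtune.profiles import (
    DoseProfile,
    ProfileSpec,
    clip_profile,
    extract_profiles,
    normalize_dose3d,
    normalize_measured_set,
    prof_max_specs,
    read_measured_profile,
    write_profile,
)
from beamtune.surrogate import Dose3D, depth_dose, generate_dose3d


@pytest.fixture(scope="module")
def normalized10(noiseless_dose10):
    return normalize_dose3d(noiseless_dose10)


class TestNormalizeDose3D:
    def test_constant_field_becomes_100_everywhere(self):
        d = Dose3D(field_size=10.0, values=np.full((100, 100, 100), 3.7))
        out = normalize_dose3d(d)
        assert np.allclose(out.values, 100.0)

    def test_scale_invariance(self, noiseless_dose10):
        a = normalize_dose3d(noiseless_dose10)
        doubled = Dose3D(field_size=10.0, values=2.0 * noiseless_dose10.values)
        b = normalize_dose3d(doubled)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_on_axis_dmax_value_is_100(self, normalized10):
        spec = ProfileSpec(field_size=10.0, kind="depth", range_cm=(1.0, 2.0))
        prof = extract_profiles(normalized10, [spec])[0]
        v = float(np.interp(1.4, prof.positions, prof.doses))
        assert v == pytest.approx(100.0, abs=1e-6)

    def test_nonpositive_reference_rejected(self):
        d = Dose3D(field_size=10.0, values=np.zeros((100, 100, 100)))
        with pytest.raises(ValueError):
            normalize_dose3d(d)


class TestExtractProfiles:
    def test_prof_max_yields_18_profiles_per_tuple(self, example_params):
        total = 0
        for field in (3.0, 10.0, 30.0):
            dose = normalize_dose3d(
                generate_dose3d(example_params, field, noise=False)
            )
            specs = [s for s in prof_max_specs() if s.field_size == field]
            total += len(extract_profiles(dose, specs))
        assert total == 18

    def test_full_range_depth_profile_has_495_samples(self, normalized10):
        spec = ProfileSpec(field_size=10.0, kind="depth")
        prof = extract_profiles(normalized10, [spec])[0]
        assert prof.spec.n_points == 495
        assert prof.positions[0] == pytest.approx(0.3)
        assert prof.positions[-1] == pytest.approx(49.7)

    def test_symmetric_dose_makes_averaged_cut_equal_single_cut(self, normalized10):
        from beamtune.profiles import _axis_dose_interpolator, _extract_one

        spec = ProfileSpec(field_size=10.0, kind="lateral", depth=10.0)
        interp = _axis_dose_interpolator(normalized10)
        averaged = _extract_one(normalized10, interp, spec, average_xy=True)
        single = _extract_one(normalized10, interp, spec, average_xy=False)
        assert np.allclose(averaged.doses, single.doses, atol=1e-9)

    def test_extraction_is_linear_in_dose(self, noiseless_dose10):
        spec = ProfileSpec(field_size=10.0, kind="lateral", depth=5.0)
        a = extract_profiles(noiseless_dose10, [spec])[0]
        scaled = Dose3D(field_size=10.0, values=3.0 * noiseless_dose10.values)
        b = extract_profiles(scaled, [spec])[0]
        assert np.allclose(b.doses, 3.0 * a.doses, rtol=1e-12)

    def test_matches_direct_surrogate_evaluation_away_from_edges(
        self, normalized10, example_params
    ):
        """Trilinear resampling of the 0.5 cm tally grid reproduces the
        analytic depth dose to well under 0.5% of D_max beyond the build-up
        region; inside the build-up (and in lateral penumbrae) the voxel
        pitch itself limits the agreement."""
        ref = depth_dose(1.4, example_params, 10.0)
        spec = ProfileSpec(field_size=10.0, kind="depth")
        prof = extract_profiles(normalized10, [spec])[0]
        analytic = (
            depth_dose(prof.positions, example_params, 10.0) / ref * 100.0
        )
        mask = prof.positions >= 2.0
        assert np.max(np.abs(prof.doses - analytic)[mask]) < 0.5

    def test_out_of_span_range_rejected(self, normalized10):
        spec = ProfileSpec(field_size=10.0, kind="depth", range_cm=(0.0, 49.7))
        with pytest.raises(ValueError, match="span"):
            extract_profiles(normalized10, [spec])

    def test_field_mismatch_rejected(self, normalized10):
        spec = ProfileSpec(field_size=30.0, kind="depth")
        with pytest.raises(ValueError, match="field"):
            extract_profiles(normalized10, [spec])


class TestClipProfile:
    def _profile(self):
        spec = ProfileSpec(field_size=10.0, kind="lateral", depth=10.0)
        return DoseProfile(spec=spec, doses=np.linspace(1, 2, spec.n_points))

    def test_clip_to_full_range_is_identity(self):
        p = self._profile()
        q = clip_profile(p, p.spec.range_cm)
        assert np.array_equal(q.doses, p.doses)

    def test_clip_counts_lattice_points(self):
        q = clip_profile(self._profile(), (-10.0, 10.0))
        assert q.spec.n_points == 201
        assert q.positions[0] == pytest.approx(-10.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            clip_profile(self._profile(), (0.0, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            clip_profile(self._profile(), (-30.0, 10.0))


class TestMeasuredProfileIO:
    def test_linear_resampling(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "# field_cm: 10\n# kind: depth\n0 10\n1 20\n2 30\n"
        )
        prof = read_measured_profile(path, step=0.5)
        assert np.allclose(prof.doses, [10, 15, 20, 25, 30])

    def test_header_parsing(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "# field_cm: 30\n# kind: lateral\n# depth_cm: 10\n"
            "# position_unit: mm\n-100 50\n0 100\n100 50\n"
        )
        prof = read_measured_profile(path)
        assert prof.spec.kind == "lateral"
        assert prof.spec.depth == 10.0
        assert prof.spec.field_size == 30.0
        assert prof.positions[0] == pytest.approx(-10.0)  # mm converted to cm

    def test_duplicate_positions_rejected_with_row_numbers(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("# field_cm: 10\n# kind: depth\n0 10\n1 20\n1 21\n2 30\n")
        with pytest.raises(ValueError, match="rows 2 and 3"):
            read_measured_profile(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("0 10\n1 20\n")
        with pytest.raises(ValueError, match="field_cm"):
            read_measured_profile(path)

    def test_write_read_round_trip(self, tmp_path):
        spec = ProfileSpec(
            field_size=10.0, kind="lateral", depth=5.0, range_cm=(-3.0, 3.0)
        )
        prof = DoseProfile(spec=spec, doses=np.linspace(10, 90, spec.n_points))
        path = tmp_path / "p.txt"
        write_profile(prof, path)
        back = read_measured_profile(path)
        assert back.spec.label() == prof.spec.label()
        assert np.allclose(back.doses, prof.doses, atol=1e-6)


class TestNormalizeMeasuredSet:
    def _depth(self, peak=2.07):
        spec = ProfileSpec(field_size=10.0, kind="depth", range_cm=(0.3, 30.0))
        z = spec.positions
        doses = peak * (1 - np.exp(-3 * z)) * np.exp(-0.05 * z)
        return DoseProfile(spec=spec, doses=doses)

    def _lateral(self, field=10.0, depth=10.0, centre=1.0):
        spec = ProfileSpec(
            field_size=field, kind="lateral", depth=depth, range_cm=(-10.0, 10.0)
        )
        x = spec.positions
        doses = centre * np.where(np.abs(x) < 5, 1.0, 0.05)
        return DoseProfile(spec=spec, doses=doses)

    def test_depth_profile_rescaled_to_100_at_peak(self):
        out = normalize_measured_set([self._depth()])
        assert out[0].doses.max() == pytest.approx(100.0, abs=0.01)

    def test_lateral_anchored_to_depth_dose_at_its_depth(self):
        depth = self._depth()
        out = normalize_measured_set([depth, self._lateral()])
        norm_depth = out[0]
        expected = float(np.interp(10.0, norm_depth.positions, norm_depth.doses))
        lat = out[1]
        assert float(np.interp(0.0, lat.positions, lat.doses)) == pytest.approx(
            expected
        )

    def test_fallback_reference_used_without_depth_profile(self):
        out = normalize_measured_set(
            [self._lateral(depth=1.4)], fallback_reference=100.0
        )
        assert float(np.interp(0.0, out[0].positions, out[0].doses)) == pytest.approx(
            100.0
        )

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="no depth profile"):
            normalize_measured_set([self._lateral()])
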