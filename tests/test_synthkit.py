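"""Generator-side tests: presets encode the published phenotype differences,
every output is seed-deterministic, and the forward models are exact where
they should be."""

import numpy as np
import pandas as pd
import pytest

from danioeye import synthkit as sk
from danioeye.stats_mixed import size_match_filter


class TestPresets:
    def test_wt_retinal_thickness_thins_with_age(self):
        assert sk.make_eye_geometry("wt_2mpf").retinal_thickness == 152.0
        assert sk.make_eye_geometry("wt_4mpf").retinal_thickness == 137.0
        assert sk.make_eye_geometry("wt_6mpf").retinal_thickness == 126.0

    @pytest.mark.parametrize(
        "mutant, age, component, delta",
        [
            ("prss56", 2, "lens_diameter", -32.0),
            ("prss56", 2, "retinal_thickness", 7.0),
            ("prss56", 2, "rpe_thickness", 3.0),
            ("prss56", 4, "acd", -7.0),
            ("prss56", 4, "lens_diameter", -34.0),
            ("prss56", 4, "retinal_thickness", 19.0),
            ("prss56", 4, "rpe_thickness", -5.0),
            ("prss56", 6, "corneal_thickness", 5.0),
            ("prss56", 6, "acd", -6.0),
            ("prss56", 6, "lens_diameter", -73.0),
            ("prss56", 6, "retinal_thickness", 32.0),
            ("fbn1", 2, "acd", 3.0),
            ("fbn1", 4, "acd", 11.0),
            ("fbn1", 6, "acd", 27.0),
            ("fbn1", 6, "vcd", -51.0),
            ("fbn1", 6, "retinal_thickness", 10.0),
            # non-significant components carry no difference
            ("fbn1", 2, "lens_diameter", 0.0),
            ("fbn1", 6, "corneal_thickness", 0.0),
            ("prss56", 2, "corneal_thickness", 0.0),
        ],
    )
    def test_mutant_component_deltas(self, mutant, age, component, delta):
        wt = sk.make_eye_geometry(f"wt_{age}mpf")
        mut = sk.make_eye_geometry(f"{mutant}_{age}mpf")
        assert getattr(mut, component) - getattr(wt, component) == pytest.approx(delta)

    @pytest.mark.parametrize("age, delta", [(2, -157.0), (4, -260.0), (6, -330.0)])
    def test_prss56_axial_deltas_match_headline_effects(self, age, delta):
        wt = sk.make_eye_geometry(f"wt_{age}mpf")
        mut = sk.make_eye_geometry(f"prss56_{age}mpf")
        assert mut.axial_length - wt.axial_length == pytest.approx(delta)

    def test_unknown_preset_names_known_ones(self):
        with pytest.raises(KeyError, match="wt_6mpf"):
            sk.make_eye_geometry("wt_60mpf")

    def test_refraction_presets_encode_hyperopic_shift(self):
        assert sk.refraction_preset("fbn1_4mpf") - sk.refraction_preset("wt_4mpf") == 8.0
        assert sk.refraction_preset("fbn1_6mpf") - sk.refraction_preset("wt_6mpf") == 12.0
        with pytest.raises(KeyError, match="not measurable"):
            sk.refraction_preset("prss56_6mpf")

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            sk.EyeGeometrySpec(10, -1, 100, 100, 50, 10, 300, 300)
        with pytest.raises(ValueError):
            sk.EyeGeometrySpec(0, 5, 100, 100, 50, 10, 300, 300)
        # lens touching cornea is anatomically valid
        sk.EyeGeometrySpec(10, 0.0, 100, 100, 50, 10, 300, 300)


class TestOctRender:
    def test_noiseless_render_is_seed_independent(self, small_geometry, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, speckle_sd=0.0)
        a = sk.render_oct_volume(small_geometry, cfg, rng_seed=1)
        b = sk.render_oct_volume(small_geometry, cfg, rng_seed=2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_speckle_render_is_seed_deterministic(self, small_geometry, small_cfg):
        a = sk.render_oct_volume(small_geometry, small_cfg, rng_seed=7)
        b = sk.render_oct_volume(small_geometry, small_cfg, rng_seed=7)
        c = sk.render_oct_volume(small_geometry, small_cfg, rng_seed=8)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_interface_positions_are_optical_path(self, small_geometry, small_cfg, indices):
        """Along the axis, boundary k sits at the cumulative sum of geometric
        thickness times refractive index."""
        from dataclasses import replace

        cfg = replace(small_cfg, speckle_sd=0.0, curvature_radius_um=1e9)
        vol = sk.render_oct_volume(small_geometry, cfg, indices, rng_seed=0)
        optical = np.array(list(small_geometry.axial_dict().values())) * np.array(
            indices.compartment_order
        )
        expected_um = cfg.z_offset_um + np.concatenate([[0.0], np.cumsum(optical)])
        nz, ny, nx = cfg.volume_shape
        axis_scan = vol.data[:, ny // 2, nx // 2]
        z_um = (np.arange(nz) + 0.5) * cfg.z_pitch
        for b in expected_um:
            window = np.abs(z_um - b) < 6.0
            assert axis_scan[window].max() > 0.5 * cfg.interface_brightness
        # lens optical extent is n_lens times its geometric extent
        assert expected_um[3] - expected_um[2] == pytest.approx(
            indices.lens * small_geometry.lens_diameter
        )

    def test_geometry_deeper_than_volume_errors(self, small_geometry):
        cfg = sk.OctRenderConfig(volume_shape=(100, 32, 32))
        with pytest.raises(ValueError, match="exceeds"):
            sk.render_oct_volume(small_geometry, cfg, rng_seed=0)


class TestPupilFrames:
    def test_zero_slope_gives_uniform_disk(self):
        img = sk.render_pupil_frame(0.0, noise_sd=0.0)
        disk_values = img[img > 0.2]
        assert np.ptp(disk_values) == 0.0

    def test_slope_sign_convention(self):
        """Positive slope brightens the bottom (rows increase downward),
        negative slope inverts the ramp."""
        pos = sk.render_pupil_frame(0.2, noise_sd=0.0)
        neg = sk.render_pupil_frame(-0.2, noise_sd=0.0)
        cy = 64
        assert pos[cy + 15, 64] > pos[cy - 15, 64]
        assert neg[cy + 15, 64] < neg[cy - 15, 64]

    def test_small_pupil_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sk.render_pupil_frame(0.1, pupil_radius=3.0)


class TestIopReadings:
    def test_zero_sd_gives_identical_readings(self):
        readings = sk.synth_iop_readings(12.0, sd=0.0, n=6, rng_seed=5)
        assert np.ptp(readings) == 0.0 and len(readings) == 6

    def test_sample_mean_near_truth(self):
        readings = sk.synth_iop_readings(12.0, sd=1.0, n=6, rng_seed=11)
        assert abs(readings.mean() - 12.0) < 3.0 / np.sqrt(6)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            sk.synth_iop_readings(12.0, sd=1.0, n=0)


class TestCohortSampling:
    def test_shared_scale_noise_calibration(self):
        """Axial length varies with SD ~10 µm between fish, ~4 µm between
        eyes, and all components of one eye share the scale factor."""
        spec = sk.CohortSpec.from_presets(["wt_6mpf"], n_fish_per_genotype=400, seed=5)
        df = sk.sample_cohort_geometries(spec)
        axial = df[list(sk.AXIAL_COMPONENTS)].sum(axis=1)
        fish_means = axial.groupby(df["fish_id"]).mean()
        eye_diffs = axial.groupby(df["fish_id"]).diff().dropna()
        sd_eye = eye_diffs.std() / np.sqrt(2)
        sd_fish = np.sqrt(max(fish_means.var() - sd_eye**2 / 2, 0.0))
        assert sd_fish == pytest.approx(10.0, rel=0.15)
        assert sd_eye == pytest.approx(4.0, rel=0.15)
        # per-eye components are perfectly correlated through the factor
        one = df.iloc[0]
        base = sk.make_eye_geometry("wt_6mpf")
        ratios = [one[c] / getattr(base, c) for c in sk.AXIAL_COMPONENTS]
        assert np.ptp(ratios) < 1e-9

    def test_seed_determinism(self):
        spec = sk.CohortSpec.from_presets(["wt_6mpf", "fbn1_6mpf"], 5, seed=9)
        a = sk.sample_cohort_geometries(spec)
        b = sk.sample_cohort_geometries(spec)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def cohort(tmp_path_factory, small_cfg):
    out = tmp_path_factory.mktemp("cohort")
    spec = sk.CohortSpec.from_presets(
        ["wt_6mpf", "prss56_6mpf"], n_fish_per_genotype=2, seed=3
    )
    # small eyes so the fast render config can hold them
    small = sk.EyeGeometrySpec(20, 25, 200, 120, 60, 12, 500, 500)
    spec.genotypes = {g: small for g in spec.genotypes}
    manifest = sk.make_cohort(
        spec, out, oct_cfg=small_cfg, pupil_frames_per_eye=2, okr_duration=30.0
    )
    return spec, out, manifest


class TestMakeCohort:
    def test_counts(self, cohort):
        spec, out, manifest = cohort
        assert len(manifest["eyes"]) == 2 * 2 * 2  # genotypes * fish * eyes
        meta = pd.read_csv(out / "metadata.csv")
        assert len(meta) == 8
        assert meta.groupby("genotype")["fish_id"].nunique().eq(2).all()
        assert len(manifest["fish"]) == 4

    def test_files_exist(self, cohort):
        _, out, manifest = cohort
        for entry in manifest["eyes"]:
            assert (out / entry["oct"]).exists()
            assert (out / entry["iop"]).exists()
        for entry in manifest["fish"]:
            assert (out / entry["okr"]).exists()

    def test_metadata_deterministic(self, cohort, tmp_path, small_cfg):
        spec, out, _ = cohort
        sk.make_cohort(spec, tmp_path, oct_cfg=small_cfg, write_oct=False,
                       write_pupil=False, okr_duration=30.0)
        assert (tmp_path / "metadata.csv").read_bytes() == (out / "metadata.csv").read_bytes()

    def test_body_lengths_size_matched(self, cohort):
        _, out, _ = cohort
        meta = pd.read_csv(out / "metadata.csv")
        passed, report = size_match_filter(meta, reference="wt")
        assert passed, report

    def test_unwritable_path_errors(self, cohort, tmp_path):
        spec, _, _ = cohort
        blocker = tmp_path / "file"
        blocker.write_text("")
        with pytest.raises(OSError):
            sk.make_cohort(spec, blocker / "sub")
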