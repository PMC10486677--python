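"""Forward-model properties of the layered-skin phantom."""

import numpy as np
import pytest

from dermoct import (AScan, CohortSpec, GroupSpec, PhantomSpec, fit_extinction,
                     gaussian_smooth, healthy_spec, lymphedema_spec,
                     noiseless_template, normalize_to_max, simulate_ascan,
                     simulate_averaged_ascan, simulate_bscan, simulate_cohort,
                     two_group_cohort_spec)
from dermoct.phantom import (cohort_metadata, read_bscan_tiff,
                             simulate_cohort_volumes, write_bscan_tiff)
from dermoct.preprocess import detect_surface

from conftest import random_spec


class TestTemplateShape:
    def test_single_interior_minimum_between_peaks(self, small_spec):
        t = noiseless_template(small_spec)
        sc_region = int((small_spec.air_gap_um + small_spec.sc_thickness_um)
                        / small_spec.axial_pitch_um)
        sc_peak = int(np.argmax(t[:sc_region]))
        dermis_idx = int(
            round((small_spec.air_gap_um + small_spec.sc_thickness_um
                   + small_spec.epi_thickness_um) / small_spec.axial_pitch_um))
        segment = t[sc_peak:dermis_idx + 1]
        interior = (segment[1:-1] < segment[:-2]) & (segment[1:-1] < segment[2:])
        assert interior.sum() == 1

    def test_minimum_depth_is_air_gap_plus_sc_thickness(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            spec = random_spec(rng)
            t = noiseless_template(spec)
            expected = spec.air_gap_um + spec.sc_thickness_um
            sc_peak_z = spec.air_gap_um + spec.sc_rise_frac * spec.sc_thickness_um
            lo = int(np.ceil(sc_peak_z / spec.axial_pitch_um)) + 1
            hi = int((expected + spec.epi_thickness_um) / spec.axial_pitch_um)
            valley = lo + int(np.argmin(t[lo:hi]))
            assert abs(valley * spec.axial_pitch_um - expected) <= spec.axial_pitch_um

    def test_monotone_nonincreasing_beyond_dermis_peak(self, small_spec):
        t = noiseless_template(small_spec)
        dermis_idx = int(np.ceil(
            (small_spec.air_gap_um + small_spec.sc_thickness_um
             + small_spec.epi_thickness_um) / small_spec.axial_pitch_um))
        tail = t[dermis_idx:]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_dermis_decay_is_exactly_exponential(self, small_spec):
        """log(I - B) on the decay segment is linear in depth with slope -mu."""
        t = noiseless_template(small_spec)
        z = np.arange(t.size) * small_spec.axial_pitch_um
        onset = (small_spec.air_gap_um + small_spec.sc_thickness_um
                 + small_spec.epi_thickness_um)
        sel = z >= onset + small_spec.axial_pitch_um
        logs = np.log(t[sel] - small_spec.baseline)
        slope, intercept = np.polyfit(z[sel] * 1e-4, logs, 1)
        fitted = slope * z[sel] * 1e-4 + intercept
        ss_res = np.sum((logs - fitted) ** 2)
        ss_tot = np.sum((logs - logs.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-small_spec.dermis_mu_per_cm, rel=1e-9)

    def test_example_minimum_index(self):
        spec = PhantomSpec(air_gap_um=10, sc_thickness_um=20, axial_pitch_um=2,
                           n_samples=400, speckle_cv=0)
        t = noiseless_template(spec)
        # exhaustive scan between the stratum-corneum peak (16 um) and the
        # dermis peak
        valley = int(np.argmin(t[9:60])) + 9
        assert abs(valley - 15) <= 1


class TestSpeckle:
    def test_zero_noise_equals_template(self, small_spec):
        spec = small_spec.replace(speckle_cv=0.0)
        scan = simulate_ascan(spec, seed=7)
        np.testing.assert_array_equal(scan.intensities, noiseless_template(spec))

    def test_seed_contract(self, small_spec):
        a = simulate_ascan(small_spec, seed=1)
        b = simulate_ascan(small_spec, seed=1)
        c = simulate_ascan(small_spec, seed=2)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_speckle_cv_matches_request(self, small_spec):
        scan = simulate_ascan(small_spec.replace(speckle_cv=0.3), seed=3)
        factors = scan.intensities / noiseless_template(small_spec)
        assert factors.mean() == pytest.approx(1.0, abs=0.06)
        assert factors.std() == pytest.approx(0.3, rel=0.15)

    def test_ensemble_mean_converges_to_template(self, small_spec):
        template = noiseless_template(small_spec)
        rng = np.random.default_rng(5)
        acc = np.zeros_like(template)
        for _ in range(1000):
            acc += template * rng.gamma(25.0, 1 / 25.0, template.size)
        mean = acc / 1000
        rel_err = np.linalg.norm(mean - template) / np.linalg.norm(template)
        assert rel_err < 0.02

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(dermis_mu_per_cm=-5)
        with pytest.raises(ValueError):
            PhantomSpec(sc_thickness_um=0)
        with pytest.raises(ValueError):
            PhantomSpec(valley_rel=0.95, sc_peak_rel=0.9)
        with pytest.raises(ValueError):
            PhantomSpec(i0=float("nan"))


class TestBScan:
    def test_no_tilt_shares_surface_index(self, small_spec):
        img = simulate_bscan(small_spec.replace(speckle_cv=0), 20, seed=1)
        surfaces = [detect_surface(AScan(col, small_spec.axial_pitch_um))
                    for col in img]
        assert len(set(surfaces)) == 1

    def test_tilt_shifts_surface_linearly(self):
        spec = PhantomSpec(air_gap_um=20, axial_pitch_um=2.0, speckle_cv=0,
                           n_samples=400)
        img = simulate_bscan(spec, 100, tilt_um_per_ascan=2.0, seed=1)
        s0 = detect_surface(AScan(img[0], 2.0))
        s99 = detect_surface(AScan(img[99], 2.0))
        assert abs((s99 - s0) - 99) <= 1

    def test_hair_column_is_darker_below_surface(self, small_spec):
        img = simulate_bscan(small_spec, 10, hair_columns={5}, seed=2)
        below = small_spec.air_gap_um
        sel = np.arange(img.shape[1]) * small_spec.axial_pitch_um >= below
        others = [j for j in range(10) if j != 5]
        assert img[5, sel].mean() < np.mean([img[j, sel].mean() for j in others])

    def test_hair_column_bounds_checked(self, small_spec):
        with pytest.raises(ValueError):
            simulate_bscan(small_spec, 10, hair_columns={10}, seed=0)


class TestCohort:
    def _tiny_cohort(self, sd=None, **kw):
        sd = sd if sd is not None else {}
        mk = lambda mean: GroupSpec(mean=mean, between_subject_sd=sd,
                                    n_subjects=4, scans_per_subject=3)
        return CohortSpec(groups={"healthy": mk(healthy_spec(n_samples=300)),
                                  "lymphedema": mk(lymphedema_spec(n_samples=300))},
                          columns_per_scan=20, **kw)

    def test_counts_and_subject_ids(self):
        out = simulate_cohort(self._tiny_cohort(), seed=0)
        assert len(out) == 2 * 4 * 3
        assert len(out.subjects()) == 8
        assert set(out.groups()) == {"healthy", "lymphedema"}

    def test_zero_sd_shares_parameters_within_group(self):
        meta = cohort_metadata(self._tiny_cohort(), seed=1)
        by_group = {}
        for row in meta:
            by_group.setdefault(row["group"], []).append(row["dermis_mu_per_cm"])
        for mus in by_group.values():
            assert len(set(mus)) == 1

    def test_reproducible_byte_identical(self):
        cohort = self._tiny_cohort(sd={"dermis_mu_per_cm": 5.0})
        a = simulate_cohort(cohort, seed=9)
        b = simulate_cohort(cohort, seed=9)
        for pa, pb in zip(a, b):
            assert pa.subject_id == pb.subject_id
            np.testing.assert_array_equal(pa.scan.intensities, pb.scan.intensities)

    def test_group_mu_ordering_recovered_by_fitting(self):
        """Groups generated with distinct dermal extinction stay ordered
        after per-profile fitting."""
        cohort = two_group_cohort_spec(n_subjects=4, scans_per_subject=2,
                                       columns_per_scan=100)
        out = simulate_cohort(cohort, seed=3)
        means = {}
        for g in out.groups():
            mus = []
            for p in out.select(group=g):
                prof = normalize_to_max(gaussian_smooth(p.scan))
                mus.append(fit_extinction(prof, (80, 180)).mu_per_cm)
            means[g] = np.mean(mus)
        assert means["healthy"] > means["lymphedema"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(mean=healthy_spec(), n_subjects=0)

    def test_metadata_matches_simulated_subjects(self):
        cohort = self._tiny_cohort(sd={"sc_thickness_um": 2.0})
        meta = cohort_metadata(cohort, seed=4)
        out = simulate_cohort(cohort, seed=4)
        assert [m["subject_id"] for m in meta] == list(out.subjects())


class TestTiffRoundTrip:
    def test_volume_round_trip_preserves_shape_and_scale(self, tmp_path):
        spec = PhantomSpec(n_samples=150)
        vols = list(simulate_cohort_volumes(
            CohortSpec(groups={"healthy": GroupSpec(mean=spec.replace(),
                                                    n_subjects=1,
                                                    scans_per_subject=2)},
                       columns_per_scan=10), seed=0))
        _, _, vol = vols[0]
        path = tmp_path / "v.tiff"
        write_bscan_tiff(path, vol)
        back = read_bscan_tiff(path)
        assert back.shape == vol.shape
        # 16-bit quantization: shapes agree to ~1/65535 of the peak
        np.testing.assert_allclose(back / back.max(), vol / vol.max(), atol=2e-4)

    def test_cohort_spec_config_round_trip(self):
        cohort = two_group_cohort_spec(n_subjects=3, scans_per_subject=2)
        assert CohortSpec.from_dict(cohort.to_dict()) == cohort
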