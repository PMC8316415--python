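"""Monte Carlo dose engine: decay sampling, transport physics, dose maps."""

import numpy as np
import pytest

import voxdose as vd
from voxdose.materials import (
    ELECTRON_REST_MEV,
    AttenuationTable,
    Material,
    MaterialMap,
    default_materials,
)
from voxdose.mc import DoseRateCurve, _sample_compton, transport_photons
from voxdose.volume import ImageVolume


def klein_nishina_mean_eps(energy_mev: float) -> float:
    """Numeric-integration oracle for the mean scattered-to-incident energy
    ratio of Compton scattering."""
    a = energy_mev / ELECTRON_REST_MEV
    eps = np.linspace(1 / (1 + 2 * a), 1.0, 200_001)
    cos_t = 1 - (1 - eps) / (a * eps)
    sin2 = 1 - cos_t**2
    dsde = (1 / eps + eps) * (1 - eps * sin2 / (1 + eps**2))
    return float(np.trapezoid(eps * dsde, eps) / np.trapezoid(dsde, eps))


class TestSegmentation:
    @pytest.mark.parametrize("hu,expected", [(-1000.0, 0), (-400.0, 1),
                                             (0.0, 2), (1000.0, 3)])
    def test_default_thresholds_map_hu_to_material(self, hu, expected):
        vol = ImageVolume(np.full((2, 2, 2), hu), (1, 1, 1), "HU")
        assert vd.segment_materials(vol).labels[0, 0, 0] == expected

    def test_out_of_range_hu_clamped_with_warning(self):
        vol = ImageVolume(np.full((2, 2, 2), 5000.0), (1, 1, 1), "HU")
        with pytest.warns(UserWarning, match="clamped"):
            seg = vd.segment_materials(vol)
        assert np.all(seg.labels == 3)

    def test_unordered_thresholds_rejected(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1), "HU")
        with pytest.raises(ValueError, match="increasing"):
            vd.segment_materials(vol, thresholds=(0.0, -10.0, 100.0))


class TestDecaySampling:
    def test_beta_branch_fraction_within_3_se(self):
        scheme = vd.ga68_scheme()
        prim = vd.sample_decay(scheme, np.random.default_rng(1), 100_000)
        p = scheme.beta_plus_branching
        se = np.sqrt(p * (1 - p) / len(prim))
        assert abs(prim.has_beta.mean() - p) < 3 * se

    def test_annihilation_pair_directions_sum_to_zero(self):
        prim = vd.sample_decay(vd.ga68_scheme(), np.random.default_rng(2), 1000)
        d1, d2 = prim.annihilation_photon_directions()
        assert np.allclose(d1 + d2, 0.0)
        assert np.allclose(np.linalg.norm(d1, axis=1), 1.0)

    def test_beta_energies_in_range_and_mean_matches_spectrum(self):
        scheme = vd.ga68_scheme()
        prim = vd.sample_decay(scheme, np.random.default_rng(3), 200_000)
        e = prim.beta_energy_mev[prim.has_beta]
        assert np.all(e > 0) and np.all(e <= scheme.beta_e_max_mev)
        # oracle: numeric integration of the allowed spectrum shape
        grid = np.linspace(0, scheme.beta_e_max_mev, 20_001)
        pdf = scheme.spectrum.pdf(grid)
        mean_oracle = np.trapezoid(grid * pdf, grid) / np.trapezoid(pdf, grid)
        se = e.std() / np.sqrt(len(e))
        assert abs(e.mean() - mean_oracle) < 3 * se

    def test_prompt_gamma_off_by_default_on_in_full_scheme(self):
        rng = np.random.default_rng(4)
        assert not vd.sample_decay(vd.ga68_scheme(), rng, 1000).has_prompt.any()
        full = vd.ga68_scheme(full=True)
        prim = vd.sample_decay(full, rng, 100_000)
        se = np.sqrt(full.prompt_gamma_intensity / len(prim))
        assert abs(prim.has_prompt.mean() - full.prompt_gamma_intensity) < 4 * se


class TestPhotonTransport:
    def test_all_air_phantom_deposits_nothing(self):
        air = default_materials()[0]
        mat = MaterialMap(np.zeros((10, 10, 10), dtype=np.int8), [air], (1.0,) * 3)
        edep, esc = transport_photons([[5, 5, 5.0]], [[0, 0, 1.0]], [0.511],
                                      mat, np.random.default_rng(5))
        assert edep.sum() == 0.0
        assert esc == pytest.approx(0.511)

    def test_511_kev_attenuation_matches_exponential(self):
        """Unattenuated fraction through 30 mm of soft tissue vs exp(-mu x)."""
        soft = default_materials()[2]
        mat = MaterialMap(np.zeros((40, 40, 30), dtype=np.int8), [soft], (1.0,) * 3)
        mu = AttenuationTable([soft]).mu_total_per_mm(0, np.array([0.511]))[0]
        n = 100_000
        rng = np.random.default_rng(6)
        pos = np.column_stack([np.full(n, 20.0), np.full(n, 20.0), np.full(n, 1e-9)])
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        inter = np.zeros(n)
        transport_photons(pos, dirs, np.full(n, 0.511), mat, rng,
                          interactions_out=inter)
        expected = np.exp(-mu * 30.0)
        frac = (inter == 0).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_photoelectric_only_material_deposits_full_energy_locally(self):
        """With the Compton channel switched off (zero electron density)
        every real interaction absorbs the photon in one voxel."""
        pe_only = Material("pe_only", 1.0, "soft_tissue", 0.0)
        mat = MaterialMap(np.zeros((30, 30, 30), dtype=np.int8), [pe_only], (1.0,) * 3)
        rng = np.random.default_rng(7)
        for _ in range(20):
            hits = vd.transport_photon([15.0, 15.0, 15.0],
                                       [0.0, 0.0, 1.0], 0.2, mat, rng)
            assert len(hits) <= 1
            if hits:
                assert hits[0][1] == pytest.approx(0.2, rel=1e-12)

    def test_compton_mean_scattered_energy_matches_klein_nishina(self):
        rng = np.random.default_rng(8)
        eps, cos_t = _sample_compton(np.full(300_000, 0.511), rng)
        oracle = klein_nishina_mean_eps(0.511)
        se = eps.std() / np.sqrt(len(eps))
        assert abs(eps.mean() - oracle) < 3 * se
        assert np.all((cos_t >= -1) & (cos_t <= 1))

    def test_nonfinite_direction_rejected(self):
        soft = default_materials()[2]
        mat = MaterialMap(np.zeros((5, 5, 5), dtype=np.int8), [soft], (1.0,) * 3)
        with pytest.raises(ValueError, match="direction"):
            transport_photons([[1, 1, 1.0]], [[np.nan, 0, 1.0]], [0.5],
                              mat, np.random.default_rng(0))


class TestSimulateFrame:
    def test_energy_ledger_balances(self, soft_cube):
        src, mat = soft_cube(50_000)
        dm = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0, seed=9)
        assert dm.emitted_mev > 0
        residual = abs(dm.deposited_mev + dm.escaped_mev - dm.emitted_mev)
        assert residual / dm.emitted_mev < 1e-9

    def test_zero_source_returns_zero_map_with_warning(self, soft_cube):
        src, mat = soft_cube(10)
        zero = src.with_values(np.zeros_like(src.values))
        with pytest.warns(UserWarning, match="zero"):
            dm = vd.simulate_frame(zero, mat, 1.0, time_fraction=1.0, seed=0)
        assert dm.dose_rate.values.sum() == 0.0

    def test_doubling_decays_preserves_mean_and_shrinks_uncertainty(self, soft_cube):
        src1, mat = soft_cube(40_000)
        dm1 = vd.simulate_frame(src1, mat, 1.0, time_fraction=1.0, seed=10)
        # doubling the simulated time doubles N at the same activity; the
        # dose *rate* estimate is unchanged in expectation
        dm2 = vd.simulate_frame(src1, mat, 2.0, time_fraction=1.0, seed=11)
        assert dm2.n_decays == 2 * dm1.n_decays
        # mean dose over the cube is unchanged within a few relative MC SE
        m1 = dm1.dose_rate.values.mean()
        m2 = dm2.dose_rate.values.mean()
        assert m2 == pytest.approx(m1, rel=0.02)
        ratio = np.median(dm2.rel_uncertainty) / np.median(dm1.rel_uncertainty)
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.15)

    def test_expected_dose_linear_in_activity(self, soft_cube):
        src1, mat = soft_cube(40_000)
        dm1 = vd.simulate_frame(src1, mat, 1.0, time_fraction=1.0, seed=12)
        src2 = src1.with_values(src1.values * 3.0)
        dm2 = vd.simulate_frame(src2, mat, 1.0, time_fraction=1.0, seed=13)
        assert dm2.dose_rate.values.mean() == pytest.approx(
            3.0 * dm1.dose_rate.values.mean(), rel=0.03)

    def test_time_fraction_rescaling_matches_full_run(self, soft_cube):
        """One-tenth of the decays rescaled by 10 estimates the same dose
        rate (the acquisition-time reduction convention)."""
        src, mat = soft_cube(100_000)
        full = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0, seed=14)
        tenth = vd.simulate_frame(src, mat, 1.0, time_fraction=0.1, seed=15)
        assert tenth.n_decays == pytest.approx(full.n_decays / 10, rel=0.01)
        assert tenth.dose_rate.values.mean() == pytest.approx(
            full.dose_rate.values.mean(), rel=0.05)

    def test_seeded_determinism(self, soft_cube):
        src, mat = soft_cube(20_000)
        a = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0, seed=42)
        b = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0, seed=42)
        assert np.array_equal(a.dose_rate.values, b.dose_rate.values)

    def test_point_source_dose_symmetric_under_axis_permutation(self):
        soft = default_materials()[2]
        n = 21
        mat = MaterialMap(np.zeros((n,) * 3, dtype=np.int8), [soft], (2.0,) * 3)
        conc = np.zeros((n,) * 3)
        conc[n // 2, n // 2, n // 2] = 200_000 / (8.0 / 1000.0)
        src = ImageVolume(conc, (2.0,) * 3, "Bq/ml")
        dm = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0, seed=16)
        c = n // 2
        profiles = [dm.edep_mev[:, c, c], dm.edep_mev[c, :, c], dm.edep_mev[c, c, :]]
        # off-centre shells carry few-percent MC noise; compare coarsely
        for p in profiles[1:]:
            near = slice(c - 3, c + 4)
            assert np.allclose(p[near], profiles[0][near], rtol=0.25, atol=1e-4)

    def test_uncertainty_estimator_calibrated_against_replicates(self, soft_cube):
        """Empirical SD of per-voxel dose over independent runs matches the
        reported batch SE within 30%."""
        n_runs = 20
        src, mat = soft_cube(30_000, n=10, voxel_mm=2.0)
        totals, reported = [], []
        for i in range(n_runs):
            dm = vd.simulate_frame(src, mat, 1.0, time_fraction=1.0,
                                   seed=100 + i, n_batches=50)
            totals.append(dm.edep_mev.reshape(-1))
            reported.append(dm.rel_uncertainty.reshape(-1) * dm.edep_mev.reshape(-1))
        totals = np.array(totals)
        reported = np.array(reported)
        emp_sd = totals.std(axis=0, ddof=1)
        mean_reported = reported.mean(axis=0)
        sel = totals.mean(axis=0) > 0
        ratio = np.median(mean_reported[sel] / emp_sd[sel])
        assert 0.7 < ratio < 1.3


class TestOrganDoseRate:
    def _uniform_map(self, value, shape=(4, 4, 4), rel=0.0):
        soft = default_materials()[2]
        mat = MaterialMap(np.zeros(shape, dtype=np.int8), [soft], (1.0,) * 3)
        rate = ImageVolume(np.full(shape, value), (1.0,) * 3, "Gy/s")
        dm = vd.DoseRateMap(dose_rate=rate, rel_uncertainty=np.full(shape, rel),
                            edep_mev=np.zeros(shape), n_decays=1,
                            frame_duration_s=1.0, time_fraction=1.0)
        return dm, mat

    def test_uniform_map_gives_that_rate(self, mouse):
        import voxdose.phantom as ph
        dm, mat = self._uniform_map(2.5)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        voi = ph.VoiSet({"organ": mask}, (1.0, 1.0, 1.0))
        rates = vd.organ_dose_rate(dm, voi, mat)
        assert rates["organ"][0] == pytest.approx(2.5)

    def test_equal_mass_two_voxel_average(self):
        import voxdose.phantom as ph
        dm, mat = self._uniform_map(0.0)
        dm.dose_rate.values[0, 0, 0] = 3.0
        dm.dose_rate.values[0, 0, 1] = 5.0
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, :2] = True
        voi = ph.VoiSet({"o": mask}, (1.0, 1.0, 1.0))
        assert vd.organ_dose_rate(dm, voi, mat)["o"][0] == pytest.approx(4.0)

    def test_mixed_density_mass_weighting_on_three_voxels(self):
        import voxdose.phantom as ph
        soft = default_materials()[2]
        bone = default_materials()[3]
        labels = np.zeros((3, 1, 1), dtype=np.int8)
        labels[2] = 1  # bone voxel
        mat = MaterialMap(labels, [soft, bone], (1.0, 1.0, 1.0))
        rates = np.array([[[1.0]], [[2.0]], [[4.0]]])
        dm = vd.DoseRateMap(dose_rate=ImageVolume(rates, (1, 1, 1), "Gy/s"),
                            rel_uncertainty=np.zeros((3, 1, 1)),
                            edep_mev=np.zeros((3, 1, 1)), n_decays=1,
                            frame_duration_s=1.0, time_fraction=1.0)
        voi = ph.VoiSet({"o": np.ones((3, 1, 1), dtype=bool)}, (1, 1, 1))
        by_hand = (1.0 * 1.04 + 2.0 * 1.04 + 4.0 * 1.92) / (1.04 + 1.04 + 1.92)
        assert vd.organ_dose_rate(dm, voi, mat)["o"][0] == pytest.approx(by_hand)


class TestIntegrateDoseRate:
    def test_constant_rate_closed_form(self):
        lam = 0.01  # per min
        t = np.linspace(0, 300, 301)
        r = 2e-5
        curve = DoseRateCurve("o", t, np.full_like(t, r), np.zeros_like(t))
        dose, _ = vd.integrate_dose_rate(curve, lam, 2.0)
        expected = (r * 300 * 60 + r / (lam / 60)) / 2.0
        assert dose == pytest.approx(expected, rel=1e-12)

    def test_zero_curve_gives_zero(self):
        t = np.linspace(0, 300, 10)
        curve = DoseRateCurve("o", t, np.zeros_like(t), np.zeros_like(t))
        assert vd.integrate_dose_rate(curve, 0.01, 1.0)[0] == 0.0

    def test_exponential_curve_matches_closed_form(self):
        lam = np.log(2) / 67.71
        t = np.arange(0.0, 301.0)
        r = np.exp(-lam * t)
        curve = DoseRateCurve("o", t, r, np.zeros_like(t))
        dose, _ = vd.integrate_dose_rate(curve, lam, 1.0)
        assert dose == pytest.approx(1 / (lam / 60), rel=1e-3)

    def test_negative_rates_rejected(self):
        curve = DoseRateCurve.__new__(DoseRateCurve)
        curve.times_min = np.array([1.0, 2.0])
        curve.dose_rate_gy_s = np.array([1.0, -0.5])
        curve.uncertainty_gy_s = np.zeros(2)
        with pytest.raises(ValueError, match="negative"):
            vd.integrate_dose_rate(curve, 0.01, 1.0)


class TestReferenceCube:
    def test_cube_audit(self):
        """Soft-tissue reference cube: ledger balances, positron kinetic
        energy is >= 99% locally absorbed, and two seeds agree within the
        combined MC error."""
        rep1 = vd.validate_reference_cube(n_decays=40_000, seed=21)
        assert rep1.ledger_residual < 1e-9
        beta_frac = rep1.beta_kinetic_deposited_mev / rep1.beta_kinetic_emitted_mev
        assert beta_frac >= 0.99
        assert 0.0 < rep1.escape_fraction < 1.0
        rep2 = vd.validate_reference_cube(n_decays=40_000, seed=22)
        d1, d2 = rep1.deposited_mev, rep2.deposited_mev
        # total deposited energy has sub-percent spread at this decay count
        assert abs(d1 - d2) / d1 < 0.02
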