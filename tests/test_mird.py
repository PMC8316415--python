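"""MIRD organ-level dosimetry: S values, residence times, human scaling."""

import numpy as np
import pytest

import voxdose as vd
from voxdose.kinetics import CumulatedActivity
from voxdose.mird import (
    SphereSValueCurve,
    SValueTable,
    default_human_model,
)


def make_table(organs, rng=None, body_mass=25.0):
    """Random dense S-value table over the given organs."""
    rng = rng or np.random.default_rng(0)
    s = {}
    for a in organs:
        for b in organs:
            base = 1e-4 if a == b else 1e-6
            s[(a, b)] = base * (0.5 + rng.random())
    masses = {o: 0.1 + rng.random() for o in organs}
    return SValueTable(s_values=s, organ_masses_g=masses, body_mass_g=body_mass)


class TestMirdDose:
    def test_single_organ_self_dose_arithmetic(self):
        table = SValueTable({("kidneys", "kidneys"): 1e-4}, {"kidneys": 0.3}, 25.0)
        cums = [CumulatedActivity("kidneys", 900.0, 0.3)]
        doses, per_mbq = vd.mird_dose(cums, table, injected_mbq=3.0)
        assert doses["kidneys"] == pytest.approx(0.09, rel=1e-12)
        assert per_mbq["kidneys"] == pytest.approx(0.03, rel=1e-12)

    def test_two_sources_superpose(self):
        organs = ["a", "b"]
        table = make_table(organs)
        c_a = [CumulatedActivity("a", 500.0, 0.2)]
        c_b = [CumulatedActivity("b", 700.0, 0.4)]
        d_a, _ = vd.mird_dose(c_a, table)
        d_b, _ = vd.mird_dose(c_b, table)
        d_ab, _ = vd.mird_dose(c_a + c_b, table)
        for t in organs:
            assert d_ab[t] == pytest.approx(d_a[t] + d_b[t], rel=1e-12)

    def test_five_organ_system_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        organs = ["a", "b", "c", "d", "e"]
        table = make_table(organs, rng)
        cums = [CumulatedActivity(o, 100 + 1000 * rng.random(), 0.5) for o in organs]
        doses, _ = vd.mird_dose(cums, table)
        for target in organs:
            brute = sum(c.a_tilde_mbq_s * table.s_values[(c.organ, target)]
                        for c in cums)
            assert doses[target] == pytest.approx(brute, rel=1e-12)

    def test_missing_source_rejected_missing_cross_term_warns(self):
        table = SValueTable({("a", "a"): 1e-4, ("b", "b"): 1e-4},
                            {"a": 0.1, "b": 0.1}, 25.0)
        with pytest.raises(ValueError, match="absent"):
            vd.mird_dose([CumulatedActivity("zzz", 1.0, 0.1)], table)
        with pytest.warns(UserWarning, match="treated as zero"):
            doses, _ = vd.mird_dose([CumulatedActivity("a", 100.0, 0.1)], table)
        assert doses["b"] == 0.0

    def test_self_only_mode_drops_cross_terms(self):
        table = make_table(["a", "b"])
        cums = [CumulatedActivity("a", 500.0, 0.2), CumulatedActivity("b", 300.0, 0.2)]
        doses, _ = vd.mird_dose(cums, table, self_only=True)
        assert doses["a"] == pytest.approx(500.0 * table.s_values[("a", "a")])

    def test_diagonal_table_makes_organs_independent(self):
        organs = ["a", "b", "c"]
        s = {(o, o): 1e-4 for o in organs}
        table = SValueTable(s, {o: 0.1 for o in organs}, 25.0)
        cums1 = [CumulatedActivity("a", 100.0, 0.1), CumulatedActivity("b", 200.0, 0.1),
                 CumulatedActivity("c", 300.0, 0.1)]
        cums2 = [CumulatedActivity("a", 999.0, 0.1), CumulatedActivity("b", 200.0, 0.1),
                 CumulatedActivity("c", 300.0, 0.1)]
        with pytest.warns(UserWarning):
            d1, _ = vd.mird_dose(cums1, table)
            d2, _ = vd.mird_dose(cums2, table)
        assert d1["b"] == d2["b"] and d1["c"] == d2["c"]
        assert d1["a"] != d2["a"]

    def test_csv_round_trip(self, tmp_path):
        table = make_table(["kidneys", "liver"])
        path = table.to_csv(tmp_path / "svalues.csv")
        back = SValueTable.from_csv(path)
        assert back.body_mass_g == table.body_mass_g
        assert back.organ_masses_g == pytest.approx(table.organ_masses_g)
        for key, val in table.s_values.items():
            assert back.s_values[key] == pytest.approx(val, rel=1e-9)

    def test_missing_self_entry_rejected(self):
        with pytest.raises(ValueError, match="self-irradiation"):
            SValueTable({("a", "b"): 1e-5}, {"a": 0.1, "b": 0.1}, 25.0)


class TestResidenceTime:
    def test_arithmetic(self):
        r = vd.residence_time([CumulatedActivity("k", 900.0, 0.3)], 3.0)
        assert r.values_s["k"] == pytest.approx(300.0)

    def test_zero_cumulated_gives_zero(self):
        r = vd.residence_time([CumulatedActivity("k", 0.0, 0.3)], 3.0)
        assert r.values_s["k"] == 0.0

    def test_total_residence_bounded_by_physical_decay(self, mouse, truth,
                                                       noise_free_study):
        """Summed residence times cannot exceed 1/lambda, the value reached
        when every decay happens inside the scored organs."""
        _, voi, _ = mouse
        lam = truth.scheme.lambda_per_min
        cums = []
        for organ in voi.organs:
            tac = vd.extract_tac(noise_free_study["frames"], voi.masks[organ],
                                 noise_free_study["injected_mbq"], organ=organ,
                                 decay_lambda_per_min=lam)
            mass = vd.estimate_organ_mass(voi.masks[organ], voi.spacing_mm)
            cums.append(vd.cumulated_activity(tac, mass, lam))
        r = vd.residence_time(cums, noise_free_study["injected_mbq"])
        assert sum(r.values_s.values()) <= 1.0 / truth.scheme.lambda_per_s


class TestHumanScaling:
    def test_same_relative_organ_size_is_identity(self):
        r = vd.ResidenceTimes({"liver": 250.0}, 3.0)
        out = vd.scale_residence_to_human(r, 25.0, {"liver": 1.25},
                                          {"liver": 1800.0}, 36000.0)
        # O_r/B_r = 0.05 = O_h/B_h -> unchanged
        assert out.values_s["liver"] == pytest.approx(250.0, rel=1e-12)

    def test_worked_arithmetic(self):
        r = vd.ResidenceTimes({"kidneys": 300.0}, 3.0)
        out = vd.scale_residence_to_human(r, 25.0, {"kidneys": 0.25},
                                          {"kidneys": 310.0}, 73000.0)
        assert out.values_s["kidneys"] == pytest.approx(300 * 100 * 310 / 73000,
                                                        rel=1e-12)
        assert out.values_s["kidneys"] == pytest.approx(127.4, abs=0.05)

    def test_linear_in_human_organ_mass(self):
        r = vd.ResidenceTimes({"liver": 100.0}, 3.0)
        one = vd.scale_residence_to_human(r, 25.0, {"liver": 1.0},
                                          {"liver": 1000.0}, 73000.0)
        two = vd.scale_residence_to_human(r, 25.0, {"liver": 1.0},
                                          {"liver": 2000.0}, 73000.0)
        assert two.values_s["liver"] == pytest.approx(2 * one.values_s["liver"])

    def test_round_trip_recovers_mouse_values(self):
        r = vd.ResidenceTimes({"liver": 123.456, "kidneys": 9.87}, 3.0)
        mouse_m = {"liver": 1.2, "kidneys": 0.25}
        human_m = {"liver": 1800.0, "kidneys": 310.0}
        fwd = vd.scale_residence_to_human(r, 25.0, mouse_m, human_m, 73000.0)
        back = vd.scale_residence_to_human(fwd, 73000.0, human_m, mouse_m, 25.0)
        for o in r.values_s:
            assert back.values_s[o] == pytest.approx(r.values_s[o], rel=1e-12)

    def test_missing_human_mass_skipped_with_warning(self):
        r = vd.ResidenceTimes({"tumor": 10.0, "liver": 5.0}, 3.0)
        with pytest.warns(UserWarning, match="tumor"):
            out = vd.scale_residence_to_human(r, 25.0, {"tumor": 0.18, "liver": 1.2},
                                              {"liver": 1800.0}, 73000.0)
        assert "tumor" not in out.values_s


class TestEffectiveDose:
    def test_single_organ_unit_weight(self):
        table = SValueTable({("liver", "liver"): 2e-6}, {"liver": 1800.0}, 73000.0)
        r = vd.ResidenceTimes({"liver": 100.0}, 3.0)
        e, equivalent = vd.effective_dose(r, table, {"liver": 1.0})
        assert e == pytest.approx(equivalent["liver"])
        assert e == pytest.approx(100.0 * 2e-6 * 1000.0)

    def test_zero_residence_gives_zero(self):
        table = SValueTable({("liver", "liver"): 2e-6}, {"liver": 1800.0}, 73000.0)
        r = vd.ResidenceTimes({"liver": 0.0}, 3.0)
        with pytest.warns(UserWarning):
            e, _ = vd.effective_dose(r, table, {"liver": 0.5})
        assert e == 0.0

    def test_random_system_equals_brute_force_triple_sum(self):
        rng = np.random.default_rng(11)
        organs = ["a", "b", "c"]
        table = make_table(organs, rng, body_mass=73000.0)
        r = vd.ResidenceTimes({o: 100 * rng.random() for o in organs}, 3.0)
        w = {o: 1 / 3 for o in organs}
        e, _ = vd.effective_dose(r, table, w)
        brute = sum(w[t] * sum(r.values_s[s] * table.s_values[(s, t)]
                               for s in organs) * 1000.0
                    for t in organs)
        assert e == pytest.approx(brute, rel=1e-12)

    def test_fixture_human_model_runs_end_to_end(self):
        table, weights = default_human_model()
        assert sum(weights.values()) == pytest.approx(1.0)
        r = vd.ResidenceTimes({o: 50.0 for o in table.sources}, 3.0)
        e, _ = vd.effective_dose(r, table, weights)
        assert e > 0


class TestSphereModel:
    CURVE = SphereSValueCurve(
        masses_g=np.array([0.05, 0.1, 0.2, 0.5, 1.0]),
        s_gy_per_mbq_s=np.array([2.0e-3, 1.1e-3, 6.0e-4, 2.6e-4, 1.4e-4]),
    )

    def test_node_mass_returns_node_value(self):
        assert self.CURVE.interpolate(0.2) == pytest.approx(6.0e-4, rel=1e-12)

    def test_between_nodes_is_bracketed(self):
        s = self.CURVE.interpolate(0.3)
        assert 2.6e-4 < s < 6.0e-4

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="outside"):
            self.CURVE.interpolate(3.0)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            SphereSValueCurve(np.array([0.1, 0.2]), np.array([1e-4, 2e-4]))

    def test_tumor_dose_arithmetic(self):
        cum = CumulatedActivity("tumor", 500.0, 0.2)
        dose = vd.sphere_tumor_dose(cum, self.CURVE, 3.0)
        assert dose == pytest.approx(500.0 * 6.0e-4 / 3.0, rel=1e-12)

    def test_mc_generated_curve_is_monotone_decreasing(self):
        """Self-dose S of uniform spheres falls with mass across the grid
        (larger spheres spread the same decay energy over more tissue)."""
        curve = vd.sphere_self_svalues([0.05, 0.2, 1.0], decays=20_000, seed=31)
        assert np.all(np.diff(curve.s_gy_per_mbq_s) < 0)
        # physical scale: S ~ E_per_decay / m within a factor of a few
        s_mid = curve.interpolate(0.2)
        assert 1e-4 < s_mid < 3e-3
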