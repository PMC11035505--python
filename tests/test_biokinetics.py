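import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nmdose import biokinetics as bk
from nmdose.regions import BLADDER


def one_compartment(lam_out=0.02, lam_p=0.003):
    return bk.CompartmentModel(
        name="one", compartments=("A",),
        transfer_coeffs={("A", "Urine"): lam_out},
        injection_compartment="A", physical_decay=lam_p,
        region_map={"A": "Remainder"},
    )


def chain_model(l1=0.05, l2=0.02, lam_p=0.003):
    return bk.CompartmentModel(
        name="chain", compartments=("A", "B"),
        transfer_coeffs={("A", "B"): l1, ("B", "Urine"): l2},
        injection_compartment="A", physical_decay=lam_p,
        region_map={"A": "Remainder", "B": "Kidneys"},
    )


class TestSolver:
    def test_single_compartment_closed_form(self):
        lam_out, lam_p = 0.02, 0.003
        t = np.linspace(0, 300, 61)
        curve = bk.solve_compartments(one_compartment(lam_out, lam_p), t)["A"]
        assert curve.a == pytest.approx(np.exp(-(lam_out + lam_p) * t), rel=1e-12)

    def test_pure_physical_decay(self):
        lam_p = 0.003
        t = np.linspace(0, 300, 31)
        curve = bk.solve_compartments(one_compartment(0.0, lam_p), t)["A"]
        assert curve.a == pytest.approx(np.exp(-lam_p * t), rel=1e-12)

    def test_two_compartment_chain_matches_bateman_and_ode(self):
        l1, l2, lam_p = 0.05, 0.02, 0.003
        t = np.linspace(0, 240, 49)
        model = chain_model(l1, l2, lam_p)
        b = bk.solve_compartments(model, t)["B"].a
        bateman = l1 / (l2 - l1) * (np.exp(-l1 * t) - np.exp(-l2 * t)) * np.exp(-lam_p * t)
        assert b == pytest.approx(bateman, rel=1e-9, abs=1e-12)
        a_mat = model.rate_matrix()
        y0 = model.initial_state()
        ode = solve_ivp(lambda _t, y: a_mat @ y, (0, 240), y0, t_eval=t,
                        rtol=1e-11, atol=1e-14)
        assert b[1:] == pytest.approx(ode.y[1, 1:], rel=1e-6)

    def test_degenerate_rates_handled(self):
        # equal eigen-rates force the t*exp(-lt) limit form
        l1 = l2 = 0.03
        t = np.linspace(0, 200, 41)
        model = chain_model(l1, l2, 0.002)
        b = bk.solve_compartments(model, t)["B"].a
        expected = l1 * t * np.exp(-l1 * t) * np.exp(-0.002 * t)
        assert b == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_random_models_match_ode_oracle(self):
        # randomized small compartment systems vs a high-accuracy integrator
        rng = np.random.default_rng(42)
        regions = ["Remainder", "Kidneys", "Liver", "Blood"]
        for _ in range(100):
            n = rng.integers(2, 5)
            comps = tuple(f"C{i}" for i in range(n))
            transfer = {}
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.5:
                        transfer[(comps[i], comps[j])] = float(rng.uniform(0.001, 0.1))
                if rng.random() < 0.5:
                    transfer[(comps[i], "Urine")] = float(rng.uniform(0.001, 0.05))
            model = bk.CompartmentModel(
                name="rand", compartments=comps, transfer_coeffs=transfer,
                injection_compartment=comps[0],
                physical_decay=float(rng.uniform(0.0005, 0.01)),
                region_map={c: regions[i % 4] for i, c in enumerate(comps)},
            )
            t_eval = [30.0, 60.0, 180.0]
            sol = bk.BiokineticSolution(model, schedule=None)
            ours = np.stack([sol.state(t) for t in t_eval])
            a_mat = model.rate_matrix()
            ode = solve_ivp(lambda _t, y: a_mat @ y, (0, 180), model.initial_state(),
                            t_eval=t_eval, rtol=1e-11, atol=1e-14)
            assert np.max(np.abs(ours - ode.y.T)) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bk.CompartmentModel(
                name="bad", compartments=("A",),
                transfer_coeffs={("A", "Urine"): -0.1},
                injection_compartment="A", physical_decay=0.001,
                region_map={"A": "Remainder"})
        with pytest.raises(ValueError):
            bk.CompartmentModel(
                name="bad", compartments=("A",), transfer_coeffs={},
                injection_compartment="A", physical_decay=0.001,
                region_map={"A": "NotARegion"})
        with pytest.raises(ValueError):
            bk.solve_compartments(one_compartment(), np.array([0.0, 10.0, 5.0]))


class TestVoiding:
    def test_regular_schedule_void_times(self):
        sched = bk.VoidingSchedule(first_void=45, interval=60)
        assert sched.times_until(240) == [45, 105, 165, 225]

    def test_interval_schedule_first_void_at_interval(self):
        assert bk.VoidingSchedule.every(120).times_until(360) == [120, 240, 360]

    def test_bladder_empties_completely_at_voids(self):
        model = bk.load_model("tc99m_hdp")
        sched = bk.VoidingSchedule(first_void=45, interval=60)
        sol = bk.BiokineticSolution(model, sched)
        for tv in (45.0, 105.0, 165.0):
            assert sol.region_activity(tv)[BLADDER] == pytest.approx(0.0, abs=1e-14)
            assert sol.region_activity(tv - 1e-6)[BLADDER] > 1e-3

    def test_bladder_continuous_nonnegative_between_voids(self):
        model = bk.load_model("tc99m_hdp")
        t = np.linspace(0, 240, 481)
        curve = bk.solve_with_voiding(model, bk.VoidingSchedule.every(120), t)[BLADDER]
        assert np.all(curve.a >= 0)
        jumps = np.abs(np.diff(curve.a))
        big = t[1:][jumps > 0.01]
        assert set(np.round(big, 1)).issubset({120.0, 240.0})

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            bk.VoidingSchedule(void_times=[30, 20])
        with pytest.raises(ValueError):
            bk.VoidingSchedule(first_void=-5, interval=60)

    def test_callable_inflow_matches_model_route(self):
        lam_out, lam_p = 0.02, 0.003
        model = one_compartment(lam_out, lam_p)
        sched = bk.VoidingSchedule(void_times=[60.0])
        t = np.linspace(0, 120, 121)
        exact = bk.bladder_tac(model, sched, t)
        numeric = bk.bladder_tac(
            lambda tt: lam_out * np.exp(-(lam_out + lam_p) * tt), sched, t,
            physical_decay=lam_p)
        assert numeric.a == pytest.approx(exact.a, rel=1e-7, abs=1e-10)


class TestFractionalActivities:
    def test_initial_condition(self):
        model = bk.load_model("tc99m_hdp")
        fa = bk.fractional_activities(model, bk.VoidingSchedule.every(120), 0.0)
        assert fa["Remainder"] == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0, abs=1e-14)
                   for r, v in fa.items() if r != "Remainder")

    def test_void_removes_exactly_bladder_content(self):
        model = bk.load_model("tc99m_hdp")
        sched = bk.VoidingSchedule.every(120)
        before = bk.fractional_activities(model, sched, 120.0 - 1e-9)
        after = bk.fractional_activities(model, sched, 120.0)
        drop = sum(before.values()) - sum(after.values())
        assert drop == pytest.approx(before[BLADDER], rel=1e-6)

    def test_total_bounded_by_physical_decay(self):
        model = bk.load_model("i131_nai")
        sched = bk.VoidingSchedule.every(210)
        for t in (0.0, 60.0, 200.0, 600.0):
            fa = bk.fractional_activities(model, sched, t)
            assert sum(fa.values()) <= np.exp(-model.physical_decay * t) + 1e-12

    def test_activity_conservation_with_decay_correction(self):
        model = bk.load_model("tc99m_hdp")
        sched = bk.VoidingSchedule(first_void=45, interval=60)
        sol = bk.BiokineticSolution(model, sched)
        lam = model.physical_decay
        for t in (10.0, 100.0, 230.0):
            y = sol.state(t)
            total = y.sum() * np.exp(lam * t) + sum(
                v * np.exp(lam * tv) for tv, v in sol.voided if tv <= t)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestTimeIntegratedActivity:
    def test_exponential_infinite_horizon(self):
        lam_out, lam_p = 0.02, 0.003
        t = np.linspace(0, 100, 11)
        sol = bk.BiokineticSolution(one_compartment(lam_out, lam_p), None)
        curve = sol.curves(t)["Remainder"]
        assert bk.time_integrated_activity(curve, np.inf) == pytest.approx(
            1.0 / (lam_out + lam_p), rel=1e-12)

    def test_zero_curve(self):
        curve = bk.TimeActivityCurve("Liver", np.linspace(0, 10, 11), np.zeros(11))
        assert bk.time_integrated_activity(curve, 10.0) == 0.0

    def test_bladder_with_void_matches_dense_trapezoid(self):
        model = bk.load_model("tc99m_hdp")
        sched = bk.VoidingSchedule(void_times=[90.0])
        t_dense = np.linspace(0, 240, 100_001)
        curve = bk.solve_with_voiding(model, sched, t_dense)[BLADDER]
        exact = bk.time_integrated_activity(curve, 240.0)
        approx = np.trapezoid(curve.a, t_dense)
        assert abs(exact - approx) / exact < 1e-4

    def test_horizon_validation(self):
        curve = bk.TimeActivityCurve("Liver", np.linspace(0, 10, 11), np.zeros(11))
        with pytest.raises(ValueError):
            bk.time_integrated_activity(curve, -1.0)
        with pytest.raises(ValueError):
            bk.time_integrated_activity(curve, np.inf)  # sampled curve, no tail
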