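import numpy as np
import pytest

import aortuq as aq
from aortuq.network0d import SolverSettings, _da_flow_nonlinear
from aortuq.windkessel import wk_periodic_pressure

TOTALS = aq.WindkesselParams(rp=56.32, rd=845.56, c=1.06e-3)


def equal_outlets(params=TOTALS):
    """Four identical outlets whose parallel combination equals `params`."""
    quarter = aq.WindkesselParams(rp=4 * params.rp, rd=4 * params.rd,
                                  c=params.c / 4)
    return aq.OutletBCSet(bca=quarter, lcca=quarter, lsa=quarter, da=quarter)


def constant_inflow(q0=100.0, n=350, period=0.7):
    t = np.linspace(0, period, n, endpoint=False)
    return aq.Waveform(times=t, values=np.full(n, float(q0)), period=period)


@pytest.fixture(scope="module")
def pre_bcs(pre_fixture):
    return aq.apply_alpha(pre_fixture.totals, pre_fixture.geometry, -0.13)


class TestSimulateBasics:
    def test_symmetric_outlets_split_evenly(self):
        inflow = constant_inflow(120.0)
        res = aq.simulate(inflow, equal_outlets(),
                          SolverSettings(max_cycles=40))
        for name in aq.OUTLET_NAMES:
            np.testing.assert_allclose(res.outlet_flows[name].values, 30.0,
                                       rtol=1e-6)

    def test_degenerate_network_matches_windkessel(self, pre_fixture):
        """Equal outlets reduce the junction to a single RCR; the closed-form
        Windkessel solution is the independent oracle."""
        inflow = aq.make_inflow(pre_fixture.pulse, 1024)
        res = aq.simulate(inflow, equal_outlets(),
                          SolverSettings(dt=0.7 / 1024, max_cycles=80,
                                         periodicity_tol=1e-10))
        expected = wk_periodic_pressure(TOTALS, inflow)
        np.testing.assert_allclose(res.junction_pressure.values,
                                   expected.values, rtol=1e-6)

    def test_constant_inflow_resistive_divider(self, pre_bcs):
        inflow = constant_inflow(100.0)
        res = aq.simulate(inflow, pre_bcs, SolverSettings(max_cycles=60))
        r_tot = aq.parallel_total_resistance(pre_bcs)
        for name in aq.OUTLET_NAMES:
            expected = 100.0 * r_tot / pre_bcs[name].r_total
            np.testing.assert_allclose(res.outlet_flows[name].values,
                                       expected, rtol=1e-6)

    def test_flow_conservation_every_sample(self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        res = aq.simulate(inflow, pre_bcs)
        total = sum(res.outlet_flows[n].values for n in aq.OUTLET_NAMES)
        q_in = inflow(res.junction_pressure.times)
        np.testing.assert_allclose(total, q_in, rtol=1e-8,
                                   atol=1e-8 * np.max(np.abs(q_in)))

    def test_mean_pressure_over_mean_flow_is_parallel_resistance(
            self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        res = aq.simulate(inflow, pre_bcs, SolverSettings(max_cycles=40))
        assert res.converged
        ratio = res.junction_pressure.time_average() / inflow.time_average()
        assert ratio == pytest.approx(aq.parallel_total_resistance(pre_bcs),
                                      rel=1e-3)

    def test_monotone_da_flow_in_alpha(self, pre_fixture):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        means = []
        for alpha in (-0.15, -0.13, -0.10, -0.08):
            bcs = aq.apply_alpha(pre_fixture.totals, pre_fixture.geometry, alpha)
            res = aq.simulate(inflow, bcs, SolverSettings(max_cycles=40))
            means.append(res.outlet_flows["da"].time_average())
        assert np.all(np.diff(means) > 0)

    def test_dt_refinement_first_order_or_better(self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 1400)
        sims = {dt: aq.simulate(inflow, pre_bcs,
                                SolverSettings(dt=dt, max_cycles=30,
                                               periodicity_tol=1e-9))
                for dt in (0.004, 0.002, 0.001)}
        ref = sims[0.001].junction_pressure
        err = {}
        for dt in (0.004, 0.002):
            p = sims[dt].junction_pressure
            err[dt] = np.max(np.abs(p.values - ref(p.times)))
        assert err[0.004] / err[0.002] > 1.8


class TestSolverSettings:
    def test_dt_must_resolve_cycle(self):
        inflow = constant_inflow()
        with pytest.raises(ValueError, match="dt"):
            aq.simulate(inflow, equal_outlets(), SolverSettings(dt=0.05))

    def test_nonconvergence_reported_not_raised(self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        res = aq.simulate(inflow, pre_bcs,
                          SolverSettings(max_cycles=2, periodicity_tol=1e-12))
        assert not res.converged
        assert res.cycles_run == 2


class TestCoaElement:
    def test_quadratic_element_solver(self):
        rp, c2 = 50.0, 3.0
        for head in (1e4, -2e4, 0.0):
            q = _da_flow_nonlinear(head, rp, c2)
            assert rp * q + c2 * q * abs(q) == pytest.approx(head, abs=1e-8)

    def test_stenosis_element_raises_pressure_drop(self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        base = aq.simulate(inflow, pre_bcs, SolverSettings(max_cycles=20))
        sten = aq.simulate(inflow, pre_bcs, SolverSettings(max_cycles=20),
                           coa_element=2.0,
                           coa_area=pre_fixture.geometry.area_coa)
        assert sten.dp.values.max() > base.dp.values.max()
        total = sum(sten.outlet_flows[n].values for n in aq.OUTLET_NAMES)
        np.testing.assert_allclose(total, inflow(sten.dp.times), rtol=1e-8)

    def test_element_requires_area(self, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        with pytest.raises(ValueError, match="coa_area"):
            aq.simulate(inflow, pre_bcs, coa_element=1.0)


class TestSimResultIO:
    def test_round_trip_bundle(self, tmp_path, pre_fixture, pre_bcs):
        inflow = aq.make_inflow(pre_fixture.pulse, 350)
        res = aq.simulate(inflow, pre_bcs)
        aq.write_sim_result(res, tmp_path / "sim")
        back = aq.read_sim_result(tmp_path / "sim")
        for name in aq.OUTLET_NAMES:
            np.testing.assert_array_equal(back.outlet_flows[name].values,
                                          res.outlet_flows[name].values)
        np.testing.assert_array_equal(back.dp.values, res.dp.values)
        assert back.converged == res.converged
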