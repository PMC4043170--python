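import math

import numpy as np
import pytest

from clonewave.capacity import capacity_neutral
from clonewave.dynamics import (
    AccumulationRegimeError,
    assemble_flow_rates,
    closed_form_grid,
    closed_form_multimutant,
    closed_form_unmutated,
    cumulative_count,
    integrate_dynamics,
    peak_numeric,
    peak_summary,
)
from clonewave.params import HierarchyParams, build_rate_schedule, validate_params


def rel_err(a, b, floor):
    mask = np.abs(b) > floor
    if not mask.any():
        return 0.0
    return float(np.max(np.abs(a[mask] - b[mask]) / np.abs(b[mask])))


class TestFlowField:
    def test_isolated_compartment_net_rate(self):
        # single compartment, eps = 0.85, u = 0, r = 1, N = 1:
        # gains (1 - eps) r, losses eps r -> net (1 - 2 eps) r = -0.7
        p = validate_params(
            HierarchyParams(n_compartments=1, epsilon=0.85, u=0.0, r0=1.0, gamma=1.0, k_max=0)
        )
        state = np.array([[1.0]])
        d = assemble_flow_rates(state, p, p.rate_schedule())
        assert d[0, 0] == pytest.approx(-0.7)

    def test_upstream_influx_two_daughters(self):
        # one cell upstream, empty downstream: influx 2 * 0.85 * 1 * 1 = 1.7
        p = validate_params(
            HierarchyParams(n_compartments=2, epsilon=0.85, u=0.0, r0=1.0, gamma=1.0, k_max=0)
        )
        state = np.array([[1.0], [0.0]])
        d = assemble_flow_rates(state, p, p.rate_schedule())
        assert d[1, 0] == pytest.approx(1.7)

    def test_mutation_classes_decouple_without_mutation(self):
        p = validate_params(
            HierarchyParams(n_compartments=3, epsilon=0.8, u=0.0, r0=1.0, gamma=1.2, k_max=2)
        )
        state = np.zeros((3, 3))
        state[:, 0] = [1.0, 2.0, 0.5]
        d = assemble_flow_rates(state, p, p.rate_schedule())
        assert np.all(d[:, 1:] == 0.0)

    def test_dimension_mismatch(self):
        p = validate_params(HierarchyParams(n_compartments=3, k_max=1))
        with pytest.raises(ValueError, match="shape"):
            assemble_flow_rates(np.zeros((2, 2)), p, p.rate_schedule())


class TestClosedFormsAgainstODE:
    def test_initial_condition(self, small_hot):
        grid = integrate_dynamics(small_hot, np.array([0.0]))
        expected = np.zeros((5, 4))
        expected[small_hot.founder_compartment - 1, 0] = small_hot.n0
        assert np.allclose(grid.counts[:, :, 0], expected)
        assert closed_form_unmutated(small_hot, 1, 0.0) == pytest.approx(small_hot.n0)

    def test_single_compartment_linear_solution(self):
        # N_1^0(t) = n0 exp((1 - 2 alpha) r_1 t), written out independently
        p = validate_params(
            HierarchyParams(n_compartments=3, epsilon=0.8, u=0.01, r0=0.5, gamma=1.3, n0=7.0, k_max=1)
        )
        r1 = 1.3 * 0.5
        for t in (0.0, 1.0, 3.7):
            direct = 7.0 * math.exp((1 - 2 * 0.81) * r1 * t)
            assert closed_form_unmutated(p, 1, t) == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.6, 0.75, 0.85])
    @pytest.mark.parametrize("u", [0.0, 1e-3, 1e-2])
    def test_oracle_equivalence_matrix(self, eps, u):
        """Closed forms agree with the adaptive integrator to <= 1e-6
        relative error over the (i <= 5, k <= 3) test matrix."""
        p = validate_params(
            HierarchyParams(n_compartments=5, epsilon=eps, u=u, r0=1.0, gamma=1.26, k_max=3)
        )
        ts = np.linspace(0.0, 15.0, 16)
        grid = integrate_dynamics(p, ts)
        for i in range(1, 6):
            for k in range(4):
                cf = closed_form_multimutant(p, i, k, ts)
                ode = grid.counts[i - 1, k, :]
                floor = max(ode.max(), 1e-30) * 1e-7
                assert rel_err(np.atleast_1d(cf), ode, floor) < 1e-6

    def test_haematopoiesis_compartment4(self, haem):
        p = haem.with_(n0=1000.0)
        ts = np.array([0.0, 200.0])
        grid = integrate_dynamics(p, ts)
        cf = closed_form_unmutated(p, 4, 200.0)
        assert cf == pytest.approx(grid.counts[3, 0, 1], rel=1e-6)

    def test_multimutant_consistency_k0(self, small_hot):
        ts = np.linspace(0.0, 10.0, 7)
        a = closed_form_unmutated(small_hot, 3, ts)
        b = closed_form_multimutant(small_hot, 3, 0, ts)
        assert np.allclose(a, b, rtol=0, atol=0)

    def test_no_mutants_without_mutation(self):
        p = validate_params(
            HierarchyParams(n_compartments=4, epsilon=0.8, u=0.0, r0=1.0, gamma=1.2, k_max=2)
        )
        ts = np.linspace(0.0, 8.0, 5)
        for i in (1, 2, 4):
            assert np.all(closed_form_multimutant(p, i, 1, ts) == 0.0)

    def test_linearity_in_n0(self, small_hot):
        ts = np.array([2.0, 6.0])
        base = closed_form_multimutant(small_hot, 4, 1, ts)
        scaled = closed_form_multimutant(small_hot.with_(n0=13.0), 4, 1, ts)
        assert np.allclose(scaled, 13.0 * base, rtol=1e-12)

    def test_wave_regime_washout(self, small):
        # alpha > 1/2: every class decays to zero at long times
        late = closed_form_unmutated(small, 3, 400.0)
        peak = closed_form_unmutated(small, 3, np.linspace(0, 50, 200)).max()
        assert late < 1e-12 * peak

    def test_accumulation_regime_unbounded(self):
        p = validate_params(
            HierarchyParams(n_compartments=2, epsilon=0.4, u=0.0, r0=1.0, gamma=1.2, k_max=0)
        )
        n1 = closed_form_unmutated(p, 1, 20.0)
        n2 = closed_form_unmutated(p, 1, 40.0)
        assert n2 > 2.0 * n1 > 0.0

    def test_degenerate_rates_handled_exactly(self):
        # gamma = 1 repeats every decay rate; the resonant branch must still
        # match the integrator
        p = validate_params(
            HierarchyParams(n_compartments=4, epsilon=0.8, u=1e-2, r0=1.0, gamma=1.0, k_max=2)
        )
        ts = np.linspace(0.0, 12.0, 13)
        grid = integrate_dynamics(p, ts)
        for i, k in [(1, 0), (3, 0), (4, 2)]:
            cf = closed_form_multimutant(p, i, k, ts)
            ode = grid.counts[i - 1, k, :]
            floor = max(ode.max(), 1e-30) * 1e-7
            assert rel_err(np.atleast_1d(cf), ode, floor) < 1e-6

    def test_k_beyond_truncation_rejected(self, small):
        with pytest.raises(ValueError, match="k_max"):
            closed_form_multimutant(small, 2, small.k_max + 1, 1.0)


class TestPeaks:
    def test_peak_times_equally_spaced(self, small_hot):
        t = [peak_summary(small_hot, k).t_peak for k in range(4)]
        gaps = np.diff(t)
        assert t[0] == 0.0
        assert np.allclose(gaps, gaps[0], rtol=1e-12)

    def test_peak_time_matches_numeric_argmax(self, small_hot):
        for k in (1, 2):
            summ = peak_summary(small_hot, k)
            t_num, n_num = peak_numeric(small_hot, k)
            assert summ.t_peak == pytest.approx(t_num, rel=2e-2)
            assert summ.n_peak_exact == pytest.approx(n_num, rel=1e-9)
            # Stirling approximation of k! is within a few percent already at k=1
            assert summ.n_peak == pytest.approx(n_num, rel=0.1)

    def test_peak_height_scales_with_u(self, small):
        # the ratio of successive peak heights is proportional to u (up to
        # the small shift of alpha = eps + u itself)
        lo = small.with_(u=1e-3)
        hi = small.with_(u=1e-2)
        r_lo = peak_summary(lo, 2).n_peak / peak_summary(lo, 1).n_peak
        r_hi = peak_summary(hi, 2).n_peak / peak_summary(hi, 1).n_peak
        assert r_hi / r_lo == pytest.approx(10.0, rel=0.05)

    def test_peak_ordering(self, small_hot):
        summaries = [peak_summary(small_hot, k) for k in range(4)]
        tps = [s.t_peak for s in summaries]
        nps = [s.n_peak_exact for s in summaries]
        assert np.all(np.diff(tps) > 0)
        assert np.all(np.diff(nps) < 0)

    def test_no_peak_in_accumulation_regime(self):
        p = validate_params(HierarchyParams(n_compartments=2, epsilon=0.4, u=0.0, k_max=1))
        with pytest.raises(AccumulationRegimeError):
            peak_summary(p, 1)


class TestCumulativeCount:
    def test_zero_horizon(self, small_hot):
        assert cumulative_count(small_hot, 2, 0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_horizon(self, small_hot):
        ts = [1.0, 3.0, 10.0, 50.0]
        vals = [cumulative_count(small_hot, 3, 1, t) for t in ts]
        assert np.all(np.diff(vals) >= 0)

    def test_infinite_limit_equals_capacity(self, small_hot):
        for i, k in [(1, 0), (3, 1), (5, 2)]:
            lim = cumulative_count(small_hot, i, k, None)
            cap = capacity_neutral(small_hot, i, k)
            assert lim == pytest.approx(cap, rel=1e-4)

    def test_divergent_in_accumulation_regime(self):
        p = validate_params(HierarchyParams(n_compartments=2, epsilon=0.45, u=0.0, k_max=0))
        with pytest.warns(RuntimeWarning, match="diverges"):
            assert math.isinf(cumulative_count(p, 1, 0, None))
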