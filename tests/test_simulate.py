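"""Delayed synchronous simulation, cycle detection and viability."""

import numpy as np
import pytest

from boolclock.core import LogicConfiguration, Topology
from boolclock.light import LightProgram
from boolclock.models import builtin_model, experimental_parameter_sets
from boolclock.simulate import (
    ZeroDelayLoopError,
    check_viability,
    detect_limit_cycle,
    seed_bank,
    simulate,
)


def _inverter_ring(tau: float):
    """Single gene repressing itself: a delayed Boolean inverter."""
    topo = Topology(name="ring", genes=("A",), gene_edges=(("A", "A"),))
    return topo, LogicConfiguration((1,)), (tau,)


DD = LightProgram(pulses=())


class TestSimulate:
    def test_single_negative_loop_oscillates(self, n1):
        traj = simulate(
            n1, LogicConfiguration((0, 1)), (5.0, 6.5, 7.5),
            n1.free_run_program(), np.zeros(2, dtype=int), horizon=200.0,
        )
        tail = traj.states[100:]
        assert tail.min(axis=0).sum() == 0 and tail.max(axis=0).sum() == 2

    def test_determinism_bit_identical(self, n2):
        runs = [
            simulate(
                n2, n2.default_lc, n2.default_delays, n2.light_program(12.0),
                np.zeros(3, dtype=int), horizon=240.0,
            ).states
            for _ in range(2)
        ]
        assert (runs[0] == runs[1]).all()

    def test_attractor_invariance(self, n2):
        """A history on the limit cycle stays on that cycle."""
        rep = detect_limit_cycle(
            n2, n2.default_lc, n2.default_delays, n2.free_run_program(),
            seed_bank(n2.topology)["all_off"],
        )
        window = int(round(max(n2.default_delays) / 0.5))
        hist = np.tile(rep.cycle, (3, 1))[:window]
        traj = simulate(
            n2, n2.default_lc, n2.default_delays, n2.free_run_program(),
            hist, horizon=100.0,
        )
        period_steps = int(round(rep.period / 0.5))
        expected = np.tile(rep.cycle, (traj.n_steps // period_steps + 2, 1))
        assert (traj.states == expected[: traj.n_steps]).all()

    def test_insufficient_history_rejected(self, n2):
        with pytest.raises(ValueError, match="history"):
            simulate(
                n2, n2.default_lc, n2.default_delays, n2.free_run_program(),
                np.zeros((3, 3), dtype=int), horizon=10.0,
            )

    def test_zero_delay_loop_rejected(self):
        topo, lc, _ = _inverter_ring(0.0)
        with pytest.raises(ZeroDelayLoopError):
            simulate(topo, lc, (0.0,), DD, np.zeros(1, dtype=int), horizon=5.0)

    def test_non_multiple_delay_rejected(self, n1):
        with pytest.raises(ValueError, match="multiple"):
            simulate(
                n1, n1.default_lc, (5.25, 6.5, 7.5), n1.free_run_program(),
                np.zeros(2, dtype=int), horizon=5.0,
            )

    def test_non_binary_history_rejected(self, n1):
        with pytest.raises(ValueError):
            simulate(
                n1, n1.default_lc, n1.default_delays, n1.free_run_program(),
                np.full((14, 2), 2), horizon=5.0,
            )

    def test_zero_delay_edges_resolved_in_topological_order(self, a3):
        """The published luciferase-fit parameter sets carry zero delays and must simulate."""
        ps = experimental_parameter_sets()["G_OPT"]
        traj = simulate(
            a3, ps["lc"], ps["delays"], a3.free_run_program(),
            seed_bank(a3.topology)["all_off"], horizon=100.0,
        )
        # X mirrors TOC1 instantaneously (tau2 = 0, identity gate)
        assert (traj.series("X") == traj.series("TOC1")).all()


class TestDetectLimitCycle:
    def test_fixed_point_reported_as_period_zero(self, n1):
        # identity loop with light OR in darkness keeps the all-off state
        rep = detect_limit_cycle(
            n1, LogicConfiguration((0, 0)), n1.default_delays,
            n1.free_run_program(), np.zeros(2, dtype=int),
        )
        assert rep.found and rep.period == 0.0 and rep.is_fixed_point

    @pytest.mark.parametrize("tau", [1.0, 2.5, 7.0, 11.5])
    def test_inverter_ring_period_is_twice_the_delay(self, tau):
        topo, lc, delays = _inverter_ring(tau)
        rep = detect_limit_cycle(topo, lc, delays, DD, np.zeros(1, dtype=int))
        assert rep.period == pytest.approx(2 * tau)

    def test_negative_ring_period_twice_loop_delay_sum(self, n1):
        """Two-gene negative loop in darkness: period = 2(tau1+tau2)."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            t1, t2 = np.round(rng.uniform(0.5, 10.5, size=2) * 2) / 2
            rep = detect_limit_cycle(
                n1, LogicConfiguration((0, 1)), (t1, t2, 0.0),
                n1.free_run_program(), np.zeros(2, dtype=int),
            )
            assert rep.period == pytest.approx(2 * (t1 + t2))

    def test_1loop_published_parameters_period_near_22h(self, n1):
        rep = detect_limit_cycle(
            n1, n1.default_lc, n1.default_delays, n1.free_run_program(),
            seed_bank(n1.topology)["all_off"],
        )
        assert rep.period > 0
        assert abs(rep.period - 22.0) / 22.0 <= 0.2

    def test_replay_invariant(self, any_model):
        """Re-simulating from the reported cycle reproduces the cycle."""
        spec = any_model
        rep = detect_limit_cycle(
            spec, spec.default_lc, spec.default_delays, spec.free_run_program(),
            seed_bank(spec.topology)["all_off"],
        )
        assert rep.found and rep.period > 0
        t_s = rep.t_s
        window = max(1, int(round(max(spec.default_delays) / t_s)))
        reps = int(np.ceil(window / rep.cycle.shape[0])) + 1
        hist = np.tile(rep.cycle, (reps, 1))[-window:]
        traj = simulate(
            spec, spec.default_lc, spec.default_delays, spec.free_run_program(),
            hist, horizon=rep.period,
        )
        # the tiled history ends on a cycle boundary, so the continuation
        # must replay the cycle from its first row
        n = rep.cycle.shape[0]
        assert (traj.states[window : window + n] == rep.cycle).all()

    def test_entrained_detection_under_ld(self, n1):
        rep = detect_limit_cycle(
            n1, n1.default_lc, n1.default_delays, n1.light_program(12.0),
            seed_bank(n1.topology)["all_off"],
        )
        assert rep.period == 24.0


class TestViability:
    def test_published_synthetic_fits_are_viable(self, any_model):
        report = check_viability(any_model)
        assert report.viable and report.free_run_viable and report.entrained
        assert report.rel_deviation <= 0.2

    def test_constant_rules_not_viable(self, n1):
        # all-identity configuration settles to a fixed point in darkness
        report = check_viability(n1, LogicConfiguration((0, 0)))
        assert not report.viable and not report.free_run_viable

    def test_g_opt_free_runs_near_24h_in_ll(self, a3):
        ps = experimental_parameter_sets()["G_OPT"]
        report = check_viability(
            a3, ps["lc"], ps["delays"], require_entrainment=False
        )
        assert report.viable
        assert abs(report.free_run_period - 24.0) / 24.0 <= 0.2

    def test_zero_delay_loop_classified_not_viable(self, a3):
        delays = (0.0, 0.0, 0.0) + builtin_model("arabidopsis_3loop").default_delays[3:]
        report = check_viability(a3, delays=delays)
        assert not report.viable and not report.free_run_viable
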