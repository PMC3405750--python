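"""Phase markers, photoperiod curves and dawn/dusk locking."""

import numpy as np
import pandas as pd
import pytest

from boolclock.core import LogicConfiguration, Topology
from boolclock.discretize import ContinuousSeries, binarize
from boolclock.phase import (
    PhaseTable,
    boolean_phase,
    classify_locking,
    continuous_phase,
    max_symmetric_interval,
    phase_photoperiod_curve,
)
from boolclock.simulate import BitTrajectory


def _cycle(bits, t_s=0.5, t0=0.0):
    return BitTrajectory(
        t_s=t_s, genes=("g",), states=np.array(bits).reshape(-1, 1), t0=t0
    )


class TestBooleanPhase:
    def test_on_half_cycle_transitions_at_noon_boundary(self):
        n = 48  # 24 h at 0.5 h
        bits = [1] * 24 + [0] * 24  # ON for [0, 12), OFF after
        assert boolean_phase(_cycle(bits), "g") == [12.0]

    def test_constant_species_has_no_marker(self):
        assert boolean_phase(_cycle([1] * 48), "g") == []
        assert boolean_phase(_cycle([0] * 48), "g") == []

    def test_dual_peaks_yield_two_markers(self):
        bits = [1] * 6 + [0] * 18 + [1] * 12 + [0] * 12
        assert boolean_phase(_cycle(bits), "g") == [3.0, 18.0]

    def test_wrap_around_transition(self):
        bits = [0] * 24 + [1] * 24  # ON across the cycle boundary
        assert boolean_phase(_cycle(bits), "g") == [0.0]

    def test_invariant_to_whole_cycle_rotation(self):
        bits = [1] * 20 + [0] * 28
        assert boolean_phase(_cycle(bits, t0=48.0), "g") == boolean_phase(
            _cycle(bits, t0=0.0), "g"
        )


class TestContinuousPhase:
    def test_triangle_wave_down_crossing_interpolated(self):
        t_s = 0.5
        t = np.arange(0, 24, t_s)
        v = np.where(t <= 6, t / 6.0, np.clip(1 - (t - 6) / 12.0, 0, None))
        s = ContinuousSeries(t_s=t_s, data=pd.DataFrame({"g": v}))
        (phase,) = continuous_phase(s, 0.5, "g")
        assert 6.0 < phase < 18.0
        assert phase == pytest.approx(12.0, abs=t_s)  # crosses 0.5 at t=12

    def test_always_below_threshold_is_empty(self):
        s = ContinuousSeries(t_s=0.5, data=pd.DataFrame({"g": np.full(48, 0.2)}))
        assert continuous_phase(s, 0.5, "g") == []

    def test_matches_boolean_phase_after_grid_rounding(self):
        rng = np.random.default_rng(2)
        t_s = 0.5
        t = np.arange(0, 24, t_s)
        v = 0.5 + 0.45 * np.sin(2 * np.pi * (t + rng.uniform(0, 24)) / 24)
        s = ContinuousSeries(t_s=t_s, data=pd.DataFrame({"g": v}))
        for threshold in (0.3, 0.5, 0.7):
            cont = continuous_phase(s, threshold, "g")
            boolean = boolean_phase(binarize(s, threshold), "g")
            rounded = sorted(np.ceil(np.array(cont) / t_s - 1e-9) * t_s % 24.0)
            assert rounded == pytest.approx(boolean)


class TestPhotoperiodCurves:
    PHOTOPERIODS = np.arange(6.0, 18.5, 2.0)

    def test_1loop_phases_lock_to_dusk(self, n1):
        tables = phase_photoperiod_curve(n1, photoperiods=self.PHOTOPERIODS)
        assert all(t.entrained for t in tables)
        offsets = {(t.phases["frq"][0] - t.dusk) % 24.0 for t in tables}
        assert len(offsets) == 1  # constant lag behind dusk at every daylength
        labels = classify_locking(tables)
        assert labels == {"frq": "dusk-locked", "FRQ": "dusk-locked"}

    def test_3loop_predominately_dawn_locked(self, a3):
        tables = phase_photoperiod_curve(a3, photoperiods=np.arange(10.0, 16.5, 2.0))
        labels = classify_locking(tables)
        assert labels["LHY"] == "dawn-locked"
        assert labels["PRR"] == "dawn-locked"

    def test_lightless_circuit_flagged_not_entrained(self):
        topo = Topology(name="free", genes=("a", "b"),
                        gene_edges=(("a", "b"), ("b", "a")))
        from boolclock.models import ModelSpec

        spec = ModelSpec(
            topology=topo, tau_fr=22.0, default_lc=LogicConfiguration((0, 1)),
            default_delays=(5.0, 6.0), default_thresholds={"a": 0.5, "b": 0.5},
            light_pulses=(), de_pattern=(0, 1), omega=25.0,
        )
        tables = phase_photoperiod_curve(spec, photoperiods=[8.0, 12.0, 16.0])
        assert not any(t.entrained for t in tables)

    def test_phase_table_tidy_frame(self, n1):
        (table,) = phase_photoperiod_curve(n1, photoperiods=[12.0])
        df = table.to_frame()
        assert list(df.columns) == [
            "photoperiod", "species", "marker", "phase", "dawn", "dusk",
        ]
        assert set(df["species"]) == {"frq", "FRQ"}


class TestLocking:
    def _tables(self, phase_of):
        tables = []
        for p in (8.0, 12.0, 16.0):
            tables.append(
                PhaseTable(
                    photoperiod=p, dawn=0.0, dusk=p, entrained=True,
                    phases={"g": [phase_of(p) % 24.0]},
                )
            )
        return tables

    def test_constant_offset_from_dusk_is_dusk_locked(self):
        labels = classify_locking(self._tables(lambda p: p + 3.0))
        assert labels == {"g": "dusk-locked"}

    def test_constant_absolute_phase_is_dawn_locked(self):
        labels = classify_locking(self._tables(lambda p: 5.0))
        assert labels == {"g": "dawn-locked"}

    def test_drifting_phase_is_mixed(self):
        labels = classify_locking(self._tables(lambda p: 0.5 * p + 2.0))
        assert labels == {"g": "mixed"}

    def test_requires_three_entrained_photoperiods(self):
        with pytest.raises(ValueError):
            classify_locking(self._tables(lambda p: p)[:2])


class TestMaxSymmetricInterval:
    def test_1loop_entrains_over_a_symmetric_range(self, n1):
        p_max = max_symmetric_interval(n1)
        assert p_max > 0.0

    def test_full_range_when_every_photoperiod_entrains(self, n1):
        # the 1-loop circuit entrains across the whole scanned range
        assert max_symmetric_interval(n1) == 12.0
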