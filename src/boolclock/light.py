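"""Binary light-input programs.

Each external light input k is a 24 h-periodic binary signal that
switches on at dawn and stays on for a pulse length ``p_k``:
``L_k(t) = 1`` iff ``(t - t_dawn) mod 24 < p_k``.  The limits are exact:
``p_k = 0`` is constant darkness (DD), ``p_k = 24`` constant light (LL),
and ``p_k = t_dusk - t_dawn`` a full light–dark (LD) cycle; shorter
pulses model acute light impulses at dawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DAY_HOURS = 24.0

__all__ = ["LightProgram", "light_signal"]


@dataclass(frozen=True)
class LightProgram:
    """Pulse lengths per light input plus the dawn/dusk convention.

    ``pulses[k-1]`` is the pulse length of light input k in hours.
    Dawn defaults to ZT0; ``t_dusk = t_dawn + photoperiod``.
    """

    pulses: tuple[float, ...]
    t_dawn: float = 0.0
    photoperiod: float = 12.0

    def __post_init__(self) -> None:
        for p in self.pulses:
            if not 0.0 <= p <= DAY_HOURS:
                raise ValueError(f"pulse length {p} outside [0, 24] h")
        if not 0.0 <= self.photoperiod <= DAY_HOURS:
            raise ValueError("photoperiod must lie in [0, 24] h")

    @property
    def n_lights(self) -> int:
        return len(self.pulses)

    @property
    def t_dusk(self) -> float:
        return self.t_dawn + self.photoperiod

    @property
    def is_constant(self) -> bool:
        """True when every light signal is constant in time (all p in {0, 24})."""
        return all(p in (0.0, DAY_HOURS) for p in self.pulses)

    def signal(self, k: int, t: float | np.ndarray) -> int | np.ndarray:
        """State of light input ``k`` (1-based) at time ``t`` (hours)."""
        return light_signal(k, t, self)

    def signals(self, t: float) -> tuple[int, ...]:
        return tuple(light_signal(k, t, self) for k in range(1, self.n_lights + 1))


def light_signal(k: int, t: float | np.ndarray, program: LightProgram):
    """Evaluate light input ``k`` of ``program`` at time(s) ``t`` in hours.

    The lit interval is half-open, ``[dawn, dawn + p_k)`` modulo 24 h, so
    the dawn sample itself counts as light and the p=0 / p=24 limits are
    exact.
    """
    if not 1 <= k <= program.n_lights:
        raise ValueError(f"light index {k} out of range 1..{program.n_lights}")
    p = program.pulses[k - 1]
    phase = np.mod(np.asarray(t, dtype=float) - program.t_dawn, DAY_HOURS)
    out = (phase < p).astype(int)
    if out.ndim == 0:
        return int(out)
    return out
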