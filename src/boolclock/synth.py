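"""Synthetic continuous expression data with known Boolean ground truth.

The generator emulates noisy continuous observations of a clock whose
underlying logic is known: the Boolean ground truth is simulated onto
its attractor in each light regime, the bits are mapped to OFF/ON
plateau levels, switching is smoothed by first-order exponential
rise/decay, and seeded Gaussian amplitude noise is added (clipped at
zero, as expression levels are non-negative).

The noise scale emulates the system-size scaling of stochastic kinetic
simulations, sigma = 1/sqrt(Omega); the built-in circuits carry Omega
values of 25, 50, 1000 and 1000, the sizes near the self-sustained
oscillation limit of the corresponding kinetic models.

Default protocol: five 24 h cycles in entrained LD 12:12 plus five
cycles in the model's free-running regime, sampled every 0.5 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LogicConfiguration
from .discretize import ContinuousSeries
from .io import write_json, write_timeseries
from .light import DAY_HOURS
from .models import ModelSpec, builtin_model
from .simulate import check_viability, detect_limit_cycle, seed_bank

__all__ = ["SyntheticSpec", "generate", "make_benchmark"]


@dataclass
class SyntheticSpec:
    """Ground truth plus observation model for one synthetic dataset."""

    model: ModelSpec
    lc: LogicConfiguration | None = None
    delays: tuple[float, ...] | None = None
    cycles: int = 5
    t_s: float = 0.5
    photoperiod: float = 12.0
    off_level: float = 0.1
    on_level: float = 0.9
    rise: float = 0.0  # exponential rise time constant, hours (0 = instantaneous)
    decay: float = 0.0
    sigma: float | None = None  # None -> 1/sqrt(model.omega)
    seed: int | None = None
    regimes: tuple[str, ...] | None = None  # default: ("LD", free-run)

    def __post_init__(self) -> None:
        if self.regimes is not None:
            allowed = {"LD", self.model.free_run_regime}
            if not set(self.regimes) <= allowed or not self.regimes:
                raise ValueError(f"regimes must be a non-empty subset of {allowed}")
        if self.lc is None:
            self.lc = self.model.default_lc
        if self.delays is None:
            self.delays = self.model.default_delays
        if self.sigma is None:
            self.sigma = 1.0 / np.sqrt(self.model.omega)
        if not 0.0 <= self.off_level < self.on_level:
            raise ValueError("need 0 <= off_level < on_level")

    @property
    def emit_regimes(self) -> tuple[str, ...]:
        if self.regimes is not None:
            return self.regimes
        return ("LD", self.model.free_run_regime)


def _attractor_bits(spec: SyntheticSpec, regime: str, n_steps: int) -> np.ndarray:
    """Bits of the ground-truth attractor, tiled to ``n_steps`` samples.

    LD output is aligned so that the first sample sits at dawn (ZT0).
    """
    model, t_s = spec.model, spec.t_s
    free = detect_limit_cycle(
        model, spec.lc, spec.delays, model.free_run_program(),
        seed_bank(model.topology)["all_off"], t_s=t_s,
    )
    if not free.found or free.period <= 0:
        # all-off seed settled on a fixed point: scan the rest of the bank
        for name, hist in seed_bank(model.topology).items():
            free = detect_limit_cycle(
                model, spec.lc, spec.delays, model.free_run_program(), hist, t_s=t_s
            )
            if free.found and free.period > 0:
                break
    if not free.found or free.period <= 0:
        raise ValueError("ground-truth model has no free-running limit cycle")
    if regime == "LD":
        window = max(1, int(round(max(spec.delays) / t_s)))
        reps = int(np.ceil(window / free.cycle.shape[0])) + 1
        hist = np.tile(free.cycle, (reps, 1))[-window:]
        rep = detect_limit_cycle(
            model, spec.lc, spec.delays, model.light_program(spec.photoperiod),
            hist, t_s=t_s,
        )
        if not rep.found or rep.period <= 0:
            raise ValueError("ground-truth model does not entrain in LD")
        cycle = rep.cycle
        # rotate the cycle so index 0 is at ZT0 (dawn)
        phase_steps = int(round((rep.t_start % DAY_HOURS) / t_s))
        cycle = np.roll(cycle, phase_steps, axis=0)
    else:
        cycle = free.cycle
    reps = int(np.ceil(n_steps / cycle.shape[0]))
    return np.tile(cycle, (reps, 1))[:n_steps]


def _shape_and_noise(
    bits: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    levels = np.where(bits > 0, spec.on_level, spec.off_level).astype(float)
    y = np.empty_like(levels)
    y[0] = levels[0]
    for k in range(1, levels.shape[0]):
        target = levels[k]
        kappa = np.where(target > y[k - 1], spec.rise, spec.decay)
        with np.errstate(divide="ignore"):
            alpha = np.where(kappa > 0, np.exp(-spec.t_s / np.maximum(kappa, 1e-12)), 0.0)
        y[k] = target + (y[k - 1] - target) * alpha
    if spec.sigma > 0:
        y = y + rng.normal(0.0, spec.sigma, size=y.shape)
    return np.clip(y, 0.0, None)


def generate(
    spec: SyntheticSpec,
) -> tuple[dict[str, ContinuousSeries], dict]:
    """Generate one synthetic dataset (all regimes) plus its truth record.

    The ground truth must be a viable clock; the emitted truth record
    carries everything needed to score parameter recovery: the
    generating configuration, delays, the threshold band separating the
    plateaus, and the waveform/noise settings.
    """
    model = spec.model
    report = check_viability(
        model, spec.lc, spec.delays, t_s=spec.t_s, photoperiod=spec.photoperiod,
        require_entrainment="LD" in spec.emit_regimes,
    )
    if not report.viable:
        raise ValueError(
            f"ground truth is not a viable clock (free-run period "
            f"{report.free_run_period} h, entrained={report.entrained})"
        )
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.cycles * DAY_HOURS / spec.t_s)) + 1
    out: dict[str, ContinuousSeries] = {}
    truth_bits: dict[str, np.ndarray] = {}
    for regime in spec.emit_regimes:
        bits = _attractor_bits(spec, regime, n_steps)
        values = _shape_and_noise(bits, spec, rng)
        out[regime] = ContinuousSeries(
            t_s=spec.t_s,
            data=pd.DataFrame(values, columns=list(model.topology.genes)),
            regime=regime,
        )
        truth_bits[regime] = bits
    truth = {
        "model": model.name,
        "lc": spec.lc.bitstring,
        "encoding": spec.lc.encoding,
        "delays": list(spec.delays),
        "threshold_band": [spec.off_level, spec.on_level],
        "off_level": spec.off_level,
        "on_level": spec.on_level,
        "rise": spec.rise,
        "decay": spec.decay,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "cycles": spec.cycles,
        "t_s": spec.t_s,
        "photoperiod": spec.photoperiod,
        "free_run_period": report.free_run_period,
        "bits": {r: b.tolist() for r, b in truth_bits.items()},
    }
    return out, truth


def make_benchmark(
    model_name: str,
    noise_levels: Sequence[float],
    replicates: int,
    seed: int,
    outdir: str | Path,
    **spec_kwargs,
) -> dict:
    """Write a benchmark bundle: per-replicate LD + free-run series and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = builtin_model(model_name)
    seeds = np.random.SeedSequence(seed).generate_state(
        max(1, len(noise_levels) * replicates)
    )
    manifest = {"model": model_name, "seed": seed, "entries": []}
    idx = 0
    for ni, sigma in enumerate(noise_levels):
        for rep in range(replicates):
            sub_seed = int(seeds[idx] % (2**31))
            idx += 1
            spec = SyntheticSpec(
                model=model, sigma=float(sigma), seed=sub_seed, **spec_kwargs
            )
            series, truth = generate(spec)
            truth.pop("bits")
            entry = {"sigma": float(sigma), "replicate": rep, "truth": truth, "files": {}}
            for regime, s in series.items():
                fname = f"{model_name}_n{ni}_r{rep}_{regime}.csv"
                write_timeseries(s, outdir / fname)
                entry["files"][regime] = fname
            manifest["entries"].append(entry)
    write_json(manifest, outdir / "manifest.json")
    return manifest
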