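"""Synthetic glucose-stimulus experiments.

Emulates the bench measurement scheme: a glucose step at t = 0 and
cAMP sampled over a 12-minute course — every 15 s for the first two
minutes, every 30 s for the next five, and every minute for the last
five — with multiplicative (lognormal) measurement noise whose spread
scales with the signal, as immunoassay error does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeries
from .params import DimensionalScale, GenotypeConfig
from .simulate import run_timecourse

__all__ = [
    "SamplingScheme",
    "NoiseModel",
    "experimental_grid",
    "generate_dataset",
    "noiseless_curve",
]

#: Default 12-minute scheme: (duration_min, interval_min) segments.
DEFAULT_SEGMENTS: tuple[tuple[float, float], ...] = ((2.0, 0.25), (5.0, 0.5), (5.0, 1.0))


@dataclass(frozen=True)
class SamplingScheme:
    """Piecewise-uniform sampling grid, as (duration, interval) segments."""

    segments: tuple[tuple[float, float], ...] = DEFAULT_SEGMENTS

    def __post_init__(self) -> None:
        for dur, step in self.segments:
            if dur <= 0 or step <= 0:
                raise ValueError("segment durations and intervals must be > 0")

    @property
    def total_span(self) -> float:
        return sum(dur for dur, _ in self.segments)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    The multiplier is mean-one: ``exp(sigma Z - sigma^2/2)`` with
    ``sigma^2 = ln(1 + cv^2)``, so the expected observation equals the
    model curve at every sampling time.
    """

    cv: float = 0.1
    seed: int = 0
    kind: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")
        if self.kind != "multiplicative-lognormal":
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def sample_multipliers(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)


def experimental_grid(scheme: SamplingScheme | None = None) -> np.ndarray:
    """Sampling times in minutes, starting with the t = 0 baseline."""
    scheme = scheme or SamplingScheme()
    times = [0.0]
    t = 0.0
    for dur, step in scheme.segments:
        seg_end = t + dur
        n = int(round(dur / step))
        seg = t + step * np.arange(1, n + 1)
        if seg.size and seg[-1] > seg_end + 1e-9:
            raise ValueError("sampling segment overruns its duration")
        times.extend(seg.tolist())
        t = seg_end
    grid = np.array(times)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sampling scheme produced non-increasing times")
    return grid


def noiseless_curve(
    cfg: GenotypeConfig,
    scale: DimensionalScale,
    times_min: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Model cAMP (fmol per 10^6 cells) at the given minutes grid.

    Simulates the stimulus protocol from the starved steady state with
    the glucose step at t = 0 and converts to dimensional units.
    """
    times_min = np.asarray(times_min, dtype=float)
    t_dimless = times_min / scale.t_scale
    t_end = max(t_dimless[-1], 1e-6)
    traj = run_timecourse(
        cfg,
        t_end=t_end,
        stimulus_time=0.0,
        output_times=t_dimless,
        rtol=rtol,
        atol=atol,
    )
    return traj.x * scale.x_scale


def generate_dataset(
    cfg: GenotypeConfig,
    scale: DimensionalScale,
    scheme: SamplingScheme | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    strain: str = "synthetic",
) -> list[TimeSeries]:
    """Simulate a noisy replicated glucose-stimulus experiment.

    Each replicate is the same noiseless model curve with independent
    multiplicative noise; identical seeds give bit-identical output.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    scheme = scheme or SamplingScheme()
    noise = noise or NoiseModel()
    times = experimental_grid(scheme)
    curve = noiseless_curve(cfg, scale, times)
    rng = np.random.default_rng(noise.seed)
    out = []
    for rep in range(1, n_replicates + 1):
        values = curve * noise.sample_multipliers(rng, curve.size)
        out.append(
            TimeSeries(
                times=times.copy(), values=values, strain=strain, replicate=str(rep)
            )
        )
    return out
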