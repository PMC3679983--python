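"""Glucose-stimulus time courses and trajectory summary metrics.

A simulation follows the experimental protocol: the system starts at
the steady state it reaches under glucose starvation (G = 0), and at
the stimulus time the glucose input switches to its post-stimulus
value.  The integration is restarted at the switch so the
discontinuity in the vector field never crosses a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import rhs_full_array
from .params import DimensionalScale, GenotypeConfig
from .steady_state import full_steady_state, starved_initial_state

__all__ = [
    "Trajectory",
    "TransientMetrics",
    "OscillationMetrics",
    "run_timecourse",
    "dimensionalize",
    "dedimensionalize",
    "transient_metrics",
    "oscillation_metrics",
]


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course of the pathway.

    ``states`` has one row per time point and one column per state
    variable in ``cfg.var_names`` order.  Times are dimensionless and
    strictly increasing; ``stimulus_time`` marks the glucose switch.
    """

    times: np.ndarray
    states: np.ndarray
    cfg: GenotypeConfig
    stimulus_time: float
    post_stimulus_G: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, self.cfg.ndim):
            raise ValueError("states shape does not match times/genotype")

    def var(self, name: str) -> np.ndarray:
        return self.states[:, self.cfg.var_names.index(name)]

    @property
    def r(self) -> np.ndarray:
        return self.var("r")

    @property
    def z(self) -> np.ndarray:
        return self.var("z")

    @property
    def p(self) -> np.ndarray | None:
        return self.var("p") if self.cfg.pde_branch_active else None

    @property
    def x(self) -> np.ndarray:
        return self.var("x")

    @property
    def pka(self) -> np.ndarray:
        return self.x**2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.cfg.var_names))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class TransientMetrics:
    """Summary of the post-stimulus cAMP excursion.

    Two measures of the transient are reported: ``amplitude`` is the
    peak minus the pre-stimulus baseline, and ``excursion`` is the peak
    minus the analytic post-stimulus steady state — the overshoot that
    decays away as the system settles.  Genotype-to-genotype transient
    comparisons use the excursion, which is insensitive to how far the
    run has settled.
    """

    baseline: float
    peak: float
    peak_time: float
    amplitude: float
    excursion: float
    final_ss: float
    final_ss_analytic: float
    final_ss_relerr: float

    def __post_init__(self) -> None:
        if self.peak >= self.baseline and self.amplitude < 0:
            raise ValueError("inconsistent transient metrics")


@dataclass(frozen=True)
class OscillationMetrics:
    """Peak structure of a (possibly oscillatory) trajectory segment."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    period: float | None
    amplitude: float | None
    decaying: bool
    sustained: bool


def run_timecourse(
    cfg: GenotypeConfig,
    t_end: float,
    stimulus_time: float = 0.0,
    output_times: np.ndarray | None = None,
    n_points: int = 2000,
    post_stimulus_G: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    initial_state=None,
) -> Trajectory:
    """Integrate the glucose-stimulus protocol.

    The trajectory starts at the starved equilibrium of ``cfg`` (G
    forced to 0) and switches G to ``post_stimulus_G`` (default: the
    value carried by ``cfg``, or 1 if that is 0) at ``stimulus_time``.
    Dense output is evaluated at ``output_times`` (default: ``n_points``
    uniform points on [0, t_end]).  A stiff-capable adaptive integrator
    is used with tight tolerances; the switch restarts the integration.
    """
    if not (t_end > stimulus_time >= 0.0):
        raise ValueError("require t_end > stimulus_time >= 0")
    if post_stimulus_G is None:
        post_stimulus_G = cfg.params.G if cfg.params.G > 0 else 1.0
    if output_times is None:
        output_times = np.linspace(0.0, t_end, n_points)
    else:
        output_times = np.asarray(output_times, dtype=float)
        if output_times.size and (
            output_times[0] < 0.0 or output_times[-1] > t_end * (1 + 1e-12)
        ):
            raise ValueError("output_times must lie within [0, t_end]")

    if initial_state is None:
        y0 = np.array(starved_initial_state(cfg).to_array())
    else:
        y0 = np.asarray(initial_state, dtype=float)

    cfg_pre = cfg.with_glucose(0.0)
    cfg_post = cfg.with_glucose(post_stimulus_G)

    out = np.empty((output_times.size, cfg.ndim))

    pre_mask = output_times < stimulus_time
    if stimulus_time > 0.0:
        t_eval = output_times[pre_mask]
        sol = solve_ivp(
            lambda t, y: rhs_full_array(y, cfg_pre),
            (0.0, stimulus_time),
            y0,
            t_eval=t_eval if t_eval.size else None,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed before stimulus at t={sol.t[-1]:.6g}: {sol.message}"
            )
        if t_eval.size:
            out[pre_mask] = sol.y.T
        y0 = sol.y[:, -1]

    t_eval = output_times[~pre_mask]
    sol = solve_ivp(
        lambda t, y: rhs_full_array(y, cfg_post),
        (stimulus_time, t_end),
        y0,
        t_eval=t_eval if t_eval.size else None,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed after stimulus at t={sol.t[-1]:.6g}: {sol.message}"
        )
    if t_eval.size:
        out[~pre_mask] = sol.y.T

    # Clip integrator round-off excursions outside the physical region.
    r_col = 0
    out[:, r_col] = np.clip(out[:, r_col], 0.0, 1.0)
    out[out < 0.0] = 0.0
    return Trajectory(
        times=output_times,
        states=out,
        cfg=cfg,
        stimulus_time=stimulus_time,
        post_stimulus_G=post_stimulus_G,
    )


def dimensionalize(traj: Trajectory, scale: DimensionalScale) -> pd.DataFrame:
    """Convert a trajectory to laboratory units.

    Returns a DataFrame with ``time_min`` (minutes) and
    ``camp_fmol_per_1e6cells``; the remaining state variables are
    passed through unscaled under their dimensionless names.
    """
    df = pd.DataFrame(
        {
            "time_min": traj.times * scale.t_scale,
            "camp_fmol_per_1e6cells": traj.x * scale.x_scale,
        }
    )
    for name in traj.cfg.var_names:
        if name != "x":
            df[f"{name}_dimensionless"] = traj.var(name)
    return df


def dedimensionalize(
    df: pd.DataFrame, scale: DimensionalScale
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`dimensionalize` for the (time, cAMP) columns."""
    return (
        df["time_min"].to_numpy() / scale.t_scale,
        df["camp_fmol_per_1e6cells"].to_numpy() / scale.x_scale,
    )


def transient_metrics(traj: Trajectory) -> TransientMetrics:
    """Baseline, peak and settling summary of the stimulus response.

    The baseline is the cAMP level at the stimulus time, the peak the
    post-stimulus maximum, and the amplitude their difference.  The
    final value is validated against the analytic fed equilibrium.
    """
    t, x = traj.times, traj.x
    if not (t[0] <= traj.stimulus_time <= t[-1]):
        raise ValueError("stimulus time lies outside the trajectory")
    baseline = float(np.interp(traj.stimulus_time, t, x))
    post = t >= traj.stimulus_time
    i_peak = int(np.argmax(x[post]))
    peak = float(x[post][i_peak])
    peak_time = float(t[post][i_peak])
    final = float(x[-1])
    eq = full_steady_state(traj.cfg.with_glucose(traj.post_stimulus_G))
    relerr = abs(final - eq.state.x) / eq.state.x if eq.state.x > 0 else abs(final)
    return TransientMetrics(
        baseline=baseline,
        peak=peak,
        peak_time=peak_time,
        amplitude=peak - baseline,
        excursion=peak - eq.state.x,
        final_ss=final,
        final_ss_analytic=float(eq.state.x),
        final_ss_relerr=relerr,
    )


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus break to the earliest index."""
    idx = []
    n = x.size
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                idx.append(i)
                i = j + 1
                continue
        i += 1
    return np.array(idx, dtype=int)


def oscillation_metrics(
    traj: Trajectory,
    discard_fraction: float = 0.5,
    amplitude_tol: float = 1e-3,
) -> OscillationMetrics:
    """Period/amplitude/decay summary of the oscillatory part of a run.

    The first ``discard_fraction`` of the time span is discarded as
    transient.  Peaks are strict local maxima of cAMP on the output
    grid; the period is the mean spacing of successive peaks and the
    amplitude the last-cycle peak-to-trough difference.  ``decaying``
    means successive peak heights strictly decrease; ``sustained``
    means the amplitude stays above ``amplitude_tol`` at the end of
    the horizon without such decay — the two flags are mutually
    exclusive.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    t0 = traj.times[0] + discard_fraction * (traj.times[-1] - traj.times[0])
    keep = traj.times >= t0
    if keep.sum() < 10:
        raise ValueError("need at least 10 output points after the discard window")
    t, x = traj.times[keep], traj.x[keep]
    peaks = _local_maxima(x)
    if peaks.size == 0:
        return OscillationMetrics(
            peak_times=np.array([]),
            peak_values=np.array([]),
            period=None,
            amplitude=None,
            decaying=False,
            sustained=False,
        )
    peak_times = t[peaks]
    peak_values = x[peaks]
    period = float(np.mean(np.diff(peak_times))) if peaks.size >= 2 else None
    if peaks.size >= 2:
        trough = float(np.min(x[peaks[-2] : peaks[-1] + 1]))
        amplitude = float(peak_values[-1] - trough)
    else:
        amplitude = float(peak_values[-1] - np.min(x))
    decaying = peaks.size >= 2 and bool(np.all(np.diff(peak_values) < 0))
    sustained = amplitude > amplitude_tol and not decaying
    return OscillationMetrics(
        peak_times=peak_times,
        peak_values=peak_values,
        period=period,
        amplitude=amplitude,
        decaying=decaying,
        sustained=sustained,
    )
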