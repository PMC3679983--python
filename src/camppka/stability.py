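"""Linear stability analysis: damped-oscillation criterion and Hopf scan.

Two analyses live here.  For the two-variable (Pde, cAMP) reduction
the Jacobian trace is always negative, so the equilibrium can only be
a stable node or a stable focus: the closed-form criterion

    (M - D0 - Gamma D x_ss^2/(Gamma + x_ss)^2)^2 < 8 M D x_ss^2/(Gamma + x_ss)

decides whether the approach to steady state is oscillatory (complex
eigenvalues) or monotone.  Pde feedback alone therefore never produces
sustained oscillations.

For the full system, sustained oscillations arise through a Hopf
bifurcation as the Ras activation rate A (the stress input) varies:
a complex eigenvalue pair of the equilibrium Jacobian crosses the
imaginary axis, bounding a window of A values in which cAMP settles
onto a limit cycle rather than a steady state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import GenotypeConfig, PathwayState, ReducedParams
from .steady_state import Equilibrium, full_steady_state, reduced_steady_state

__all__ = [
    "Regime",
    "StabilityResult",
    "jacobian_reduced",
    "jacobian_full",
    "oscillation_condition",
    "region_sweep",
    "classify_regime",
    "hopf_scan",
]


class Regime(str, Enum):
    LOW_STEADY_STATE = "low_steady_state"
    HIGH_STEADY_STATE = "high_steady_state"
    SUSTAINED_OSCILLATION = "sustained_oscillation"


@dataclass(frozen=True)
class StabilityResult:
    """Equilibrium, its eigenvalues, and the resulting classification."""

    equilibrium: Equilibrium
    eigenvalues: tuple[complex, ...]
    stable: bool
    oscillatory: bool
    regime: Regime | None = None


def jacobian_reduced(rp: ReducedParams, x_ss: float) -> np.ndarray:
    """Jacobian of the reduction at the equilibrium (p, x) = (x_ss^2, x_ss)."""
    if x_ss < 0:
        raise ValueError("x_ss must be nonnegative")
    g = rp.Gamma + x_ss
    return np.array(
        [
            [-rp.M, 2.0 * rp.M * x_ss],
            [-rp.D * x_ss / g, -rp.D0 - rp.D * rp.Gamma * x_ss**2 / g**2],
        ]
    )


def oscillation_condition(rp: ReducedParams) -> tuple[float, float, bool, float]:
    """Closed-form test for a damped-oscillatory approach to steady state.

    Computes the equilibrium cAMP level ``x_ss`` of the reduction and
    evaluates

        lhs = (M - D0 - Gamma D x_ss^2 / (Gamma + x_ss)^2)^2
        rhs = 8 M D x_ss^2 / (Gamma + x_ss)

    The approach to equilibrium is oscillatory (the 2x2 Jacobian has a
    complex eigenvalue pair) iff ``lhs < rhs``.  Returns
    ``(lhs, rhs, oscillatory, x_ss)``.
    """
    x_ss = reduced_steady_state(rp)
    g = rp.Gamma + x_ss
    lhs = (rp.M - rp.D0 - rp.Gamma * rp.D * x_ss**2 / g**2) ** 2
    rhs = 8.0 * rp.M * rp.D * x_ss**2 / g
    return lhs, rhs, bool(lhs < rhs), x_ss


def region_sweep(
    M: float,
    C0: float,
    Gamma: float,
    D0_grid: np.ndarray,
    D_grid: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Map the damped-oscillation criterion over a (D0, D) grid.

    Element ``[i, j]`` is the oscillation flag at
    ``(D0_grid[i], D_grid[j])``; the second return value is the
    fraction of grid cells that oscillate.  High Pde affinity for cAMP
    (small Gamma) enlarges the oscillatory region.
    """
    D0_grid = np.asarray(D0_grid, dtype=float)
    D_grid = np.asarray(D_grid, dtype=float)
    if D0_grid.size == 0 or D_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if np.any(D0_grid <= 0) or np.any(D_grid <= 0):
        raise ValueError("parameter grids must be strictly positive")
    if np.any(np.diff(D0_grid) <= 0) or np.any(np.diff(D_grid) <= 0):
        raise ValueError("parameter grids must be strictly increasing")
    mask = np.empty((D0_grid.size, D_grid.size), dtype=bool)
    for i, d0 in enumerate(D0_grid):
        for j, d in enumerate(D_grid):
            rp = ReducedParams(C0=C0, M=M, D0=d0, D=d, Gamma=Gamma)
            mask[i, j] = oscillation_condition(rp)[2]
    return mask, float(mask.mean())


def jacobian_full(cfg: GenotypeConfig, state: PathwayState) -> np.ndarray:
    """Analytic Jacobian of the full vector field at ``state``.

    Rows/columns are ordered (r, z, p, x), or (r, z, x) for the
    three-variable double-knockout system.
    """
    q = cfg.params
    r, z, x = state.r, state.z, state.x
    g1m = q.Gamma1 + 1.0 - r
    g1p = q.Gamma1 + r
    j_rr = -q.A * q.Gamma1 / g1m**2 - q.B * z * q.Gamma1 / g1p**2
    j_rz = -q.B * r / g1p
    if cfg.pde_branch_active:
        p = state.p
        g = q.Gamma + x
        return np.array(
            [
                [j_rr, j_rz, 0.0, 0.0],
                [0.0, -q.N, 0.0, 2.0 * q.N * x],
                [0.0, 0.0, -q.M, 2.0 * q.M * x],
                [q.G, 0.0, -q.D * x / g, -q.D0 - q.D * p * q.Gamma / g**2],
            ]
        )
    return np.array(
        [
            [j_rr, j_rz, 0.0],
            [0.0, -q.N, 2.0 * q.N * x],
            [q.G, 0.0, -q.D0],
        ]
    )


def _max_complex_real_part(eig: np.ndarray, imag_tol: float = 1e-12) -> float:
    """Largest real part among genuinely complex eigenvalues (-inf if none)."""
    cplx = eig[np.abs(eig.imag) > imag_tol * (1.0 + np.abs(eig))]
    return float(cplx.real.max()) if cplx.size else -np.inf


def classify_regime(
    cfg: GenotypeConfig,
    sim_check: bool = False,
    x_threshold: float | None = None,
    threshold_A_span: tuple[float, float] = (1e-3, 2.0),
    sim_horizon: float = 6000.0,
    sim_amplitude_tol: float = 1e-3,
) -> StabilityResult:
    """Classify the long-term fate of cAMP for a parameter set.

    Eigenvalues of the equilibrium Jacobian decide stability: a complex
    pair with positive real part means the equilibrium has undergone a
    Hopf bifurcation and cAMP settles onto sustained oscillations.
    Stable equilibria are split into high and low steady states by
    comparing x_ss to ``x_threshold``; by default the threshold is the
    geometric mean of the equilibrium cAMP levels at the extremes of
    ``threshold_A_span`` (the stress-parameter scan range), since the
    high/low distinction is qualitative.

    With ``sim_check`` the oscillation verdict is confirmed by
    simulation: the trajectory past the transient must keep a
    peak-to-trough amplitude above ``sim_amplitude_tol``.
    """
    eq = full_steady_state(cfg)
    jac = jacobian_full(cfg, eq.state)
    eig = np.linalg.eigvals(jac)
    stable = bool(np.all(eig.real < 0.0))
    oscillatory = bool(np.any(np.abs(eig.imag) > 1e-12 * (1.0 + np.abs(eig))))
    if not stable and _max_complex_real_part(eig) > 0.0:
        regime = Regime.SUSTAINED_OSCILLATION
        if sim_check:
            from .simulate import oscillation_metrics, run_timecourse

            traj = run_timecourse(
                cfg.with_glucose(cfg.params.G),
                t_end=sim_horizon,
                stimulus_time=0.0,
                n_points=4000,
            )
            om = oscillation_metrics(traj, discard_fraction=0.5)
            if not (om.amplitude is not None and om.amplitude > sim_amplitude_tol):
                raise RuntimeError(
                    "eigenvalues predict sustained oscillation but the "
                    "simulated amplitude is below tolerance"
                )
    else:
        if x_threshold is None:
            lo, hi = threshold_A_span
            x_lo = full_steady_state(cfg.with_params(A=lo)).state.x
            x_hi = full_steady_state(cfg.with_params(A=hi)).state.x
            x_threshold = float(np.sqrt(x_lo * x_hi))
        regime = (
            Regime.HIGH_STEADY_STATE
            if eq.state.x > x_threshold
            else Regime.LOW_STEADY_STATE
        )
    return StabilityResult(
        equilibrium=eq,
        eigenvalues=tuple(eig),
        stable=stable,
        oscillatory=oscillatory,
        regime=regime,
    )


def hopf_scan(
    cfg: GenotypeConfig,
    A_grid: np.ndarray,
    refine_tol: float = 1e-6,
) -> list[float]:
    """Locate Hopf bifurcations in the Ras activation rate A.

    For each A in the (sorted, positive) grid the largest real part
    among complex eigenvalue pairs at the equilibrium is evaluated;
    sign changes between neighbouring grid points are refined by
    bisection to an interval shorter than ``refine_tol``.  Typically
    two crossings bound the window of sustained oscillation.  Returns
    an empty list when no crossing occurs (e.g. with B = 0 the Ras
    feedback loop is broken and no Hopf bifurcation exists).
    """
    A_grid = np.asarray(A_grid, dtype=float)
    if np.any(A_grid <= 0) or np.any(np.diff(A_grid) <= 0):
        raise ValueError("A_grid must be sorted and strictly positive")

    def mu(a: float) -> float:
        c = cfg.with_params(A=a)
        eq = full_steady_state(c)
        eig = np.linalg.eigvals(jacobian_full(c, eq.state))
        return _max_complex_real_part(eig)

    vals = np.array([mu(a) for a in A_grid])
    crossings: list[float] = []
    for k in range(len(A_grid) - 1):
        lo, hi = vals[k], vals[k + 1]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            continue
        if lo == 0.0 or lo * hi >= 0.0:
            continue
        a, b = float(A_grid[k]), float(A_grid[k + 1])
        fa = lo
        while b - a > refine_tol:
            m = 0.5 * (a + b)
            fm = mu(m)
            if fa * fm <= 0.0:
                b = m
            else:
                a, fa = m, fm
        crossings.append(0.5 * (a + b))
    return crossings
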