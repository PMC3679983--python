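"""Equilibria of the reduced and full pathway systems.

Both systems have a unique nonnegative equilibrium.  For the
two-variable reduction the steady-state cAMP level solves

    C0 - D0 x - D x^3 / (Gamma + x) = 0,

equivalent (for Gamma + x > 0) to the cubic

    C0 Gamma + (C0 - D0 Gamma) x - D0 x^2 - D x^3 = 0,

whose left side is strictly decreasing in x wherever it is positive,
so the nonnegative root is unique.  For the full system, z = p = x^2
at equilibrium; for fixed x the Ras equation has a unique root r(x)
in [0, 1] (its left side decreases and right side increases in r),
and the remaining scalar equation in x is strictly decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinetics import rhs_full_array
from .params import GenotypeConfig, PathwayState, ReducedParams

__all__ = [
    "Equilibrium",
    "reduced_steady_state",
    "full_steady_state",
    "starved_initial_state",
    "ras_equilibrium_fraction",
]

#: Absolute residual tolerances on the returned equilibria.
REDUCED_TOL = 1e-10
FULL_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium point together with its residual diagnostics."""

    state: PathwayState
    residual_norm: float
    unique: bool = True


def reduced_steady_state(rp: ReducedParams) -> float:
    """Steady-state cAMP level of the two-variable reduction.

    Solves ``C0 - D0 x - D x^3/(Gamma + x) = 0`` through the
    equivalent cubic and returns its unique nonnegative root.

    Raises
    ------
    ValueError
        If ``C0``, ``D0`` and ``D`` are all zero (every x is then an
        equilibrium).
    """
    C0, D0, D, Gamma = rp.C0, rp.D0, rp.D, rp.Gamma
    if C0 == 0.0:
        if D0 == 0.0 and D == 0.0:
            raise ValueError("degenerate input: C0, D0 and D all vanish")
        return 0.0
    if D == 0.0:
        if D0 == 0.0:
            raise ValueError("degenerate input: no decay terms but C0 > 0")
        return C0 / D0
    coeffs = [-D, -D0, C0 - D0 * Gamma, C0 * Gamma]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots))].real
    nonneg = real[real >= -1e-12]
    if len(nonneg) == 0:  # pragma: no cover - cannot occur for C0 > 0
        raise RuntimeError("no nonnegative root found for the steady-state cubic")
    x = float(max(nonneg.min(), 0.0))
    # Polish with Newton steps on the original equation for the stated residual.
    for _ in range(50):
        f = C0 - D0 * x - D * x**3 / (Gamma + x)
        if abs(f) < REDUCED_TOL:
            break
        df = -D0 - D * x**2 * (3.0 * Gamma + 2.0 * x) / (Gamma + x) ** 2
        x -= f / df
    return x


def ras_equilibrium_fraction(cfg: GenotypeConfig, x: float) -> float:
    """Equilibrium Ras-GTP fraction for a fixed cAMP level ``x``.

    Solves ``A(1-r)/(Gamma1+1-r) = B x^2 r/(Gamma1+r)`` on [0, 1] by
    bracketing; the left side is decreasing and the right side
    increasing in r, so the root is unique.
    """
    q = cfg.params
    if q.A == 0.0:
        return 0.0
    if q.B == 0.0 or x == 0.0:
        return 1.0

    def f(r: float) -> float:
        return q.A * (1.0 - r) / (q.Gamma1 + 1.0 - r) - q.B * x * x * r / (q.Gamma1 + r)

    # f(0) = A/(Gamma1+1) > 0, f(1) = -B x^2 / (Gamma1 + 1) < 0.
    return float(brentq(f, 0.0, 1.0, xtol=1e-14, rtol=8.9e-16))


def full_steady_state(cfg: GenotypeConfig) -> Equilibrium:
    """Unique equilibrium of the full (four- or three-variable) system.

    At equilibrium ``z = x**2`` (and ``p = x**2`` when the Pde branch
    is active); the remaining scalar equation in x,

        C + G r(x) - D0 x - D x^3/(Gamma + x) = 0,

    is strictly decreasing and is solved by bracketing on
    ``[0, (C + G)/D0]`` (the upper bound drops the Pde decay term).
    """
    q = cfg.params

    def g(x: float) -> float:
        r = ras_equilibrium_fraction(cfg, x)
        val = q.C + q.G * r - q.D0 * x
        if cfg.pde_branch_active:
            val -= q.D * x**3 / (q.Gamma + x)
        return val

    if q.D0 == 0.0 and not (cfg.pde_branch_active and q.D > 0.0):
        raise ValueError("no cAMP decay terms: the full system has no equilibrium")
    hi = (q.C + q.G) / q.D0 if q.D0 > 0 else 1.0
    while g(hi) > 0.0:  # pragma: no cover - safety net for D0 == 0
        hi *= 2.0
    if g(0.0) <= 0.0:
        x_ss = 0.0  # only possible for C = 0
    else:
        x_ss = float(brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16))
    r_ss = ras_equilibrium_fraction(cfg, x_ss)
    z_ss = x_ss**2
    state = PathwayState(
        r=r_ss,
        z=z_ss,
        p=z_ss if cfg.pde_branch_active else None,
        x=x_ss,
    )
    resid = float(np.max(np.abs(rhs_full_array(state.to_array(), cfg))))
    if resid >= FULL_TOL:
        raise RuntimeError(
            f"equilibrium residual {resid:.3e} exceeds tolerance {FULL_TOL:.0e}"
        )
    return Equilibrium(state=state, residual_norm=resid, unique=True)


def starved_initial_state(cfg: GenotypeConfig) -> PathwayState:
    """Pre-stimulus initial condition: the equilibrium with G forced to 0.

    Simulations of the glucose-stimulus protocol start from the steady
    state reached under starvation, with all other parameters as given.
    """
    return full_steady_state(cfg.with_glucose(0.0)).state
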