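"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own solution paths:
the steady state is found by plain bisection of the scalar equilibrium
equation, and Jacobians are built by central finite differences of the
vector fields.  Tests compare the package's analytic/polynomial routes
against these.
"""

from __future__ import annotations

import numpy as np
import pytest

from camppka.kinetics import rhs_full_array
from camppka.params import GenotypeConfig, ReducedParams, genotype_params


def bisect_reduced_xss(
    C0: float, D0: float, D: float, Gamma: float, tol: float = 1e-12
) -> float:
    """Steady-state cAMP of the reduction by bisection (oracle).

    Solves C0 - D0 x - D x^3/(Gamma + x) = 0 on a bracket that always
    contains the root: f(0) = C0 >= 0 and f decreases without bound.
    """
    def f(x: float) -> float:
        return C0 - D0 * x - D * x**3 / (Gamma + x)

    lo, hi = 0.0, 1.0
    while f(hi) > 0:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fd_jacobian_reduced(rp: ReducedParams, p: float, x: float, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the reduced vector field (oracle).

    Uses its own transcription of the reduced equations so the check is
    independent of the package's implementation (and of its domain
    guards, which central differences may step across)."""
    def field(v):
        pp, xx = v
        return np.array(
            [
                rp.M * (xx**2 - pp),
                rp.C0 - rp.D0 * xx - rp.D * pp * xx / (rp.Gamma + xx),
            ]
        )

    v0 = np.array([p, x], dtype=float)
    jac = np.empty((2, 2))
    for j in range(2):
        dv = np.zeros(2)
        dv[j] = h * max(1.0, abs(v0[j]))
        jac[:, j] = (field(v0 + dv) - field(v0 - dv)) / (2 * dv[j])
    return jac


def fd_jacobian_full(cfg: GenotypeConfig, y: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the full vector field (oracle)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    jac = np.empty((n, n))
    for j in range(n):
        dv = np.zeros(n)
        dv[j] = h * max(1.0, abs(y[j]))
        jac[:, j] = (rhs_full_array(y + dv, cfg) - rhs_full_array(y - dv, cfg)) / (2 * dv[j])
    return jac


def reduced_oscillates_oracle(rp: ReducedParams) -> bool:
    """Claim-1 oracle: complex eigenvalues of the finite-difference
    Jacobian at the bisection equilibrium."""
    x_ss = bisect_reduced_xss(rp.C0, rp.D0, rp.D, rp.Gamma)
    jac = fd_jacobian_reduced(rp, x_ss**2, x_ss)
    eig = np.linalg.eigvals(jac)
    return bool(np.any(np.abs(eig.imag) > 1e-10))


@pytest.fixture(scope="session")
def wt_cfg() -> GenotypeConfig:
    return genotype_params("wt")


@pytest.fixture(scope="session")
def dko_cfg() -> GenotypeConfig:
    return genotype_params("pde1d_pde2d")


@pytest.fixture(scope="session")
def wt_reduction() -> ReducedParams:
    """Fed-state (r ~ 1) reduction of the reference wild type."""
    return ReducedParams(C0=1.044, M=0.01, D0=0.013, D=1.0, Gamma=33.6)
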