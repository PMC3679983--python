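"""Right-hand sides and feedback kinetics of the pathway model.

The four-variable system is

    dr/dt = A (1 - r) / (Gamma1 + 1 - r) - B z r / (Gamma1 + r)
    dz/dt = N (x^2 - z)
    dp/dt = M (x^2 - p)
    dx/dt = C + G r - D0 x - D p x / (Gamma + x)

with PKA activity entering as x^2.  When the Pde branch is inactive
(double phosphodiesterase knockout) the p equation and the D-term are
dropped and the system is three-dimensional.

The two-variable reduction freezes Ras at one of its extreme states
(r ~ 1 or r ~ 0), folding the production terms into a single constant
C0:

    dp/dt = M (x^2 - p)
    dx/dt = C0 - D0 x - D p x / (Gamma + x)
"""

from __future__ import annotations

import numpy as np

from .params import (
    CompetitiveFeedbackParams,
    GenotypeConfig,
    PathwayParams,
    PathwayState,
    ReducedParams,
)

__all__ = [
    "rhs_full",
    "rhs_full_array",
    "rhs_reduced",
    "competitive_velocities",
    "check_condition_a",
]


def rhs_full_array(y, cfg: GenotypeConfig):
    """Vector field of the full system on a raw state array.

    ``y`` is ``(r, z, p, x)`` or ``(r, z, x)`` depending on
    ``cfg.pde_branch_active``.  No domain validation is performed;
    this is the hot path handed to the ODE integrator.
    """
    q: PathwayParams = cfg.params
    if cfg.pde_branch_active:
        r, z, p, x = y
    else:
        r, z, x = y
    dr = q.A * (1.0 - r) / (q.Gamma1 + 1.0 - r) - q.B * z * r / (q.Gamma1 + r)
    dz = q.N * (x * x - z)
    dx = q.C + q.G * r - q.D0 * x
    if cfg.pde_branch_active:
        dp = q.M * (x * x - p)
        dx -= q.D * p * x / (q.Gamma + x)
        return np.array([dr, dz, dp, dx])
    return np.array([dr, dz, dx])


def rhs_full(state: PathwayState, cfg: GenotypeConfig) -> tuple[float, ...]:
    """Time derivative of a validated :class:`PathwayState`.

    Returns ``(dr/dt, dz/dt, dp/dt, dx/dt)``, or the three-component
    derivative without ``dp/dt`` when the Pde branch is inactive.

    Raises
    ------
    ValueError
        If the state shape does not match the genotype topology
        (state validation itself happens in ``PathwayState``).
    """
    if cfg.pde_branch_active and state.p is None:
        raise ValueError("state has no p component but the Pde branch is active")
    if not cfg.pde_branch_active and state.p is not None:
        raise ValueError("state has a p component but the Pde branch is inactive")
    return tuple(rhs_full_array(state.to_array(), cfg))


def rhs_reduced(p: float, x: float, rp: ReducedParams) -> tuple[float, float]:
    """Time derivative of the two-variable (Pde, cAMP) reduction."""
    if p < 0 or x < 0:
        raise ValueError("p and x must be nonnegative")
    dp = rp.M * (x * x - p)
    dx = rp.C0 - rp.D0 * x - rp.D * p * x / (rp.Gamma + x)
    return dp, dx


def competitive_velocities(
    cfp: CompetitiveFeedbackParams,
) -> tuple[float, float, float]:
    """Phosphorylation velocities of Pde1, Pde2 and Ira by shared PKA.

    The three substrates compete for the PKA catalytic subunits; each
    velocity is Michaelis-Menten in its own substrate with the
    competitors inflating the denominator through ratios of Michaelis
    constants:

        v_pde1 = Rp1 [Pde1] [PKA] /
                 (Gp1 + [Pde1] + (Gp1/Gp2)[Pde2] + (Gp1/Gz)[Ira])

    and symmetrically for Pde2 and Ira.
    """
    s1, s2, sz, e = cfp.conc_pde1, cfp.conc_pde2, cfp.conc_ira, cfp.conc_pka
    v1 = cfp.Rp1 * s1 * e / (
        cfp.Gp1 + s1 + (cfp.Gp1 / cfp.Gp2) * s2 + (cfp.Gp1 / cfp.Gz) * sz
    )
    v2 = cfp.Rp2 * s2 * e / (
        cfp.Gp2 + s2 + (cfp.Gp2 / cfp.Gp1) * s1 + (cfp.Gp2 / cfp.Gz) * sz
    )
    vz = cfp.Rz * sz * e / (
        cfp.Gz + sz + (cfp.Gz / cfp.Gp1) * s1 + (cfp.Gz / cfp.Gp2) * s2
    )
    return v1, v2, vz


def check_condition_a(
    cfp: CompetitiveFeedbackParams, threshold: float = 0.1
) -> tuple[float, float, bool]:
    """Check the separation-of-affinities condition for model reduction.

    The reduction of the competitive kinetics to a single case-dependent
    Pde variable requires

        Gp1 [Pde2] / (Gp2 [Pde1])  and  Gp2 [Ira] / (Gz [Pde2])

    to be small.  "Much less than one" is made operational as
    ``ratio < threshold`` (default 0.1).  Returns
    ``(ratio1, ratio2, satisfied)``.
    """
    if cfp.conc_pde1 == 0 or cfp.conc_pde2 == 0:
        # Ratios with a vanished competitor in the numerator are zero by
        # convention; a zero denominator with a nonzero numerator is an error.
        r1 = 0.0 if cfp.conc_pde2 == 0 else None
        r2 = 0.0 if cfp.conc_ira == 0 else None
        if r1 is None or r2 is None:
            raise ZeroDivisionError(
                "condition (a) ratio has a zero denominator with nonzero numerator"
            )
        return r1, r2, True
    r1 = cfp.Gp1 * cfp.conc_pde2 / (cfp.Gp2 * cfp.conc_pde1)
    r2 = cfp.Gp2 * cfp.conc_ira / (cfp.Gz * cfp.conc_pde2)
    return r1, r2, bool(r1 < threshold and r2 < threshold)
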