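"""Parameterization of the nondimensional cAMP-PKA pathway model.

The model tracks four dimensionless state variables: the fraction of
Ras2 in its active GTP-bound form (``r``), the PKA-activated pool of
the Ras-GAPs Ira1/Ira2 (``z``), the PKA-activated phosphodiesterase
pool (``p``), and the cAMP concentration (``x``).  PKA activity is
approximated by ``x**2`` (two cAMP molecules per released catalytic
subunit after simplifying the 4:2 binding stoichiometry).

All model constants are dimensionless composites of biochemical rate
constants; dimensional units are restored through a
:class:`DimensionalScale` (fmol cAMP per 10^6 cells and minutes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterator

__all__ = [
    "PathwayParams",
    "GenotypeConfig",
    "PathwayState",
    "ReducedParams",
    "CompetitiveFeedbackParams",
    "DimensionalScale",
    "genotype_params",
    "load_parameter_fixture",
    "available_fixtures",
    "GENOTYPE_LABELS",
]

#: Genotype labels understood by :func:`genotype_params`.
GENOTYPE_LABELS = ("wt", "pde1d", "pde2d", "pde1_ala152", "pde1d_pde2d", "custom")


@dataclass(frozen=True)
class PathwayParams:
    """Dimensionless constants of the four-variable pathway model.

    Parameters
    ----------
    A : float
        Activation rate of Ras-GTP catalyzed by the GEF Cdc25.
    B : float
        Inactivation rate of Ras-GTP catalyzed by the GAPs Ira1/Ira2.
    Gamma1 : float
        Affinity of Cdc25 and Ira1/2 for Ras (saturation constant of
        both terms in the Ras equation).
    N : float
        Relaxation rate of the Ira1/2 activity toward PKA activity.
    M : float
        Relaxation rate of phosphodiesterase activity toward PKA
        activity.
    C : float
        Basal (Ras-independent) cAMP production rate.
    G : float
        Glucose input, normalized so that ``G = 1`` after a glucose
        stimulus; ``G = 0`` under starvation.
    D0 : float
        Basal cAMP decay rate in the absence of activated Pde.
    D : float
        PKA-enhanced cAMP decay rate through activated Pde.
    Gamma : float
        Affinity of activated Pde for cAMP (Michaelis constant of the
        Pde decay term).
    """

    A: float = 1.45
    B: float = 0.0051
    Gamma1: float = 0.0004
    N: float = 0.032
    M: float = 0.01
    C: float = 0.044
    G: float = 0.0
    D0: float = 0.013
    D: float = 1.0
    Gamma: float = 33.6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")

    def with_glucose(self, G: float) -> "PathwayParams":
        """Return a copy with the glucose input set to ``G``."""
        return replace(self, G=G)

    def replace(self, **kwargs: float) -> "PathwayParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GenotypeConfig:
    """A genotype: pathway parameters plus the Pde-branch topology.

    ``pde_branch_active`` is ``False`` only for the double
    phosphodiesterase knockout, in which case the ``p`` equation and
    the Pde decay term are dropped from the dynamics and the state is
    three-dimensional (r, z, x).
    """

    label: str
    params: PathwayParams
    pde_branch_active: bool = True

    def __post_init__(self) -> None:
        if self.label not in GENOTYPE_LABELS:
            raise ValueError(
                f"unknown genotype label {self.label!r}; expected one of {GENOTYPE_LABELS}"
            )

    @property
    def ndim(self) -> int:
        """Dimension of the state vector (4, or 3 without the Pde branch)."""
        return 4 if self.pde_branch_active else 3

    @property
    def var_names(self) -> tuple[str, ...]:
        return ("r", "z", "p", "x") if self.pde_branch_active else ("r", "z", "x")

    def with_params(self, **overrides: float) -> "GenotypeConfig":
        return replace(self, params=self.params.replace(**overrides))

    def with_glucose(self, G: float) -> "GenotypeConfig":
        return replace(self, params=self.params.with_glucose(G))


@dataclass(frozen=True)
class PathwayState:
    """State of the pathway: Ras-GTP fraction, Ira, Pde, cAMP.

    ``p`` is ``None`` for the three-variable double-knockout system.
    Ras-GDP is represented implicitly as ``1 - r``.
    """

    r: float
    z: float
    p: float | None
    x: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise ValueError(f"r must lie in [0, 1], got {self.r!r}")
        if self.z < 0 or self.x < 0 or (self.p is not None and self.p < 0):
            raise ValueError("state components z, p, x must be nonnegative")

    @property
    def pka(self) -> float:
        """PKA activity, the square of the cAMP level."""
        return self.x**2

    def to_array(self) -> list[float]:
        if self.p is None:
            return [self.r, self.z, self.x]
        return [self.r, self.z, self.p, self.x]

    @classmethod
    def from_array(cls, y, pde_branch_active: bool = True) -> "PathwayState":
        y = list(y)
        if pde_branch_active:
            r, z, p, x = y
            return cls(r=r, z=z, p=p, x=x)
        r, z, x = y
        return cls(r=r, z=z, p=None, x=x)

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


@dataclass(frozen=True)
class ReducedParams:
    """Constants of the two-variable (Pde, cAMP) reduction.

    When Ras is pinned in its GTP-bound state (``r_ss ~ 1``) the
    effective production is ``C0 = 1 + C``; when GDP-bound
    (``r_ss ~ 0``), ``C0 = C``.  Any nonnegative ``C0`` is accepted.
    """

    C0: float
    M: float
    D0: float
    D: float
    Gamma: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"parameter {f.name} must be >= 0")


@dataclass(frozen=True)
class CompetitiveFeedbackParams:
    """Kinetic constants for Pde1/Pde2/Ira competition for PKA.

    ``Rp1``, ``Rp2``, ``Rz`` are maximal phosphorylation velocities and
    ``Gp1``, ``Gp2``, ``Gz`` the corresponding Michaelis constants;
    ``conc_*`` are substrate and enzyme concentrations.
    """

    Rp1: float = 1.0
    Rp2: float = 1.0
    Rz: float = 1.0
    Gp1: float = 1.0
    Gp2: float = 1.0
    Gz: float = 1.0
    conc_pde1: float = 1.0
    conc_pde2: float = 1.0
    conc_ira: float = 1.0
    conc_pka: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0")
        for name in ("Gp1", "Gp2", "Gz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Michaelis constant {name} must be > 0")


@dataclass(frozen=True)
class DimensionalScale:
    """Conversion between dimensionless and laboratory units.

    ``x_scale`` is fmol cAMP per 10^6 cells per dimensionless cAMP
    unit; ``t_scale`` is minutes per dimensionless time unit.
    """

    x_scale: float = 24.95
    t_scale: float = 0.038

    def __post_init__(self) -> None:
        if self.x_scale <= 0 or self.t_scale <= 0:
            raise ValueError("scale factors must be > 0")


# Per-genotype parameter columns for the reference (W303, Ma et al.-style)
# short-term data; stored as decimal strings to match the printed values
# exactly.  The double knockout has no Pde branch: M, D, Gamma are absent
# and B is two orders of magnitude larger.
_GENOTYPE_TABLE: dict[str, dict[str, str]] = {
    "wt": {"M": "0.01", "D": "1", "Gamma": "33.6", "B": ".0051"},
    "pde1d": {"M": "0.0005", "D": "0.26", "Gamma": "16.8", "B": ".0051"},
    "pde2d": {"M": "0.01", "D": "1", "Gamma": "33.6", "B": ".0051"},
    "pde1_ala152": {"M": "0.0025", "D": "0.54", "Gamma": "33.6", "B": ".0051"},
    "pde1d_pde2d": {"B": ".51"},
}

_SHARED_TABLE: dict[str, str] = {
    "A": "1.45",
    "Gamma1": "0.0004",
    "N": "0.032",
    "C": "0.044",
    "D0": "0.013",
}


def genotype_params(label: str, **overrides: float) -> GenotypeConfig:
    """Build the :class:`GenotypeConfig` for a named genotype.

    Parameters default to the reference short-term fit for that
    genotype; keyword ``overrides`` are applied last.  ``label`` must
    be one of ``wt``, ``pde1d``, ``pde2d``, ``pde1_ala152``,
    ``pde1d_pde2d`` (or ``custom``, which takes the wild-type values
    as its base).

    For the double knockout ``pde1d_pde2d`` the Pde branch is inactive:
    the returned config drops the ``p`` equation and the Pde decay term
    from the dynamics.
    """
    base = "wt" if label == "custom" else label
    if base not in _GENOTYPE_TABLE:
        raise KeyError(
            f"unknown genotype {label!r}; available: {sorted(_GENOTYPE_TABLE)} or 'custom'"
        )
    values = {k: float(v) for k, v in _SHARED_TABLE.items()}
    values.update({k: float(v) for k, v in _GENOTYPE_TABLE[base].items()})
    pde_active = base != "pde1d_pde2d"
    if not pde_active:
        # Inert Pde branch: equivalent to D = 0 with the p equation dropped.
        values.update(M=0.0, D=0.0, Gamma=1.0)
    values.update(overrides)
    return GenotypeConfig(
        label=label, params=PathwayParams(**values), pde_branch_active=pde_active
    )


def _fixture_dir():
    return resources.files("camppka") / "fixtures"


def available_fixtures() -> list[str]:
    """Names of the shipped parameter fixtures."""
    return sorted(p.name[: -len(".json")] for p in _fixture_dir().iterdir() if p.name.endswith(".json"))


def load_parameter_fixture(name: str) -> tuple[GenotypeConfig, DimensionalScale]:
    """Load a shipped genotype/strain parameter fixture by name.

    Fixtures cover the reference short-term dataset (``ma_*``), the
    Sigma-1278b wild type and PDE mutants (``sigma1278b_*``), and the
    S288c wild type (``s288c_wt``).  Values are stored as the printed
    decimal strings and parsed on load.
    """
    path = _fixture_dir() / f"{name}.json"
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        ) from None
    label = raw.pop("label")
    pde_active = raw.pop("pde_branch_active", True)
    scale = DimensionalScale(
        x_scale=float(raw.pop("x_scale")), t_scale=float(raw.pop("t_scale"))
    )
    raw.pop("t_scale_alt", None)  # alternative printed time scale, informational
    params = PathwayParams(**{k: float(v) for k, v in raw.items()})
    return GenotypeConfig(label=label, params=params, pde_branch_active=pde_active), scale
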