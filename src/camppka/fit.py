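"""Least-squares estimation of pathway parameters from cAMP time series.

The forward map simulates the glucose-stimulus protocol with candidate
parameters and samples the dimensional cAMP curve at the observation
times; a Levenberg-Marquardt minimizer (MINPACK lmdif via lmfit)
drives the residual sum of squares down over a chosen free-parameter
subset.  Free parameters are log10-transformed internally, which
enforces positivity and equalizes step sizes across the orders of
magnitude spanned by the model constants.

Residuals are unweighted, so the densely sampled first two minutes of
the experimental grid dominate the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .io import TimeSeries
from .params import DimensionalScale, GenotypeConfig
from .synthetic import noiseless_curve

__all__ = [
    "FitSpec",
    "FitResult",
    "smooth_blackman",
    "model_prediction",
    "fit_timeseries",
    "fit_report",
]

#: Parameter names that may be freed in a fit.
FITTABLE = ("A", "B", "Gamma1", "N", "M", "C", "D0", "D", "Gamma", "t_scale", "x_scale")

#: Default positivity bounds for free parameters (log-parameterized inside).
DEFAULT_BOUNDS = (1e-6, 1e3)

#: Residual value substituted when the integrator fails at a candidate
#: point, steering the optimizer away without crashing the fit.
PENALTY_RESIDUAL = 1e6


def smooth_blackman(series: TimeSeries, window_len: int) -> TimeSeries:
    """Smooth a time series by convolution with a Blackman window.

    The kernel ``w(n) = 0.42 - 0.5 cos(2 pi n/(L-1)) + 0.08 cos(4 pi
    n/(L-1))`` is normalized to unit sum; edges are handled by
    reflection padding, so a constant series passes through unchanged.
    ``window_len`` must be odd, >= 1 and no longer than the series.
    """
    L = window_len
    if L < 1 or L % 2 == 0:
        raise ValueError("window_len must be an odd integer >= 1")
    if L > len(series):
        raise ValueError("window_len exceeds the series length")
    if L == 1:
        return series
    w = np.blackman(L)
    w = w / w.sum()
    half = L // 2
    padded = np.pad(series.values, half, mode="reflect")
    smoothed = np.convolve(padded, w, mode="valid")
    return TimeSeries(
        times=series.times.copy(),
        values=np.clip(smoothed, 0.0, None),
        strain=series.strain,
        replicate=series.replicate,
    )


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters, their starts and bounds, the scaffold.

    ``free`` names the parameters optimized over (pathway constants
    and/or the dimensional scales); everything else is pinned to the
    values carried by ``config`` and ``scale``.  ``initial`` overrides
    the per-parameter starting values (default: the pinned values).
    """

    config: GenotypeConfig
    scale: DimensionalScale = field(default_factory=DimensionalScale)
    free: tuple[str, ...] = ("M", "D", "Gamma", "t_scale")
    initial: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        for name in self.free:
            if name not in FITTABLE:
                raise ValueError(f"cannot free unknown parameter {name!r}")
        for name in self.initial:
            if name not in self.free:
                raise ValueError(f"initial value given for non-free parameter {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lo < hi")

    def base_value(self, name: str) -> float:
        if name == "t_scale":
            return self.scale.t_scale
        if name == "x_scale":
            return self.scale.x_scale
        return getattr(self.config.params, name)

    def start_value(self, name: str) -> float:
        return self.initial.get(name, self.base_value(name))

    def assemble(self, values: dict[str, float]) -> tuple[GenotypeConfig, DimensionalScale]:
        """Merge free-parameter values into a full (config, scale) pair."""
        overrides = {k: v for k, v in values.items() if k not in ("t_scale", "x_scale")}
        cfg = self.config.with_params(**overrides) if overrides else self.config
        scale = DimensionalScale(
            x_scale=values.get("x_scale", self.scale.x_scale),
            t_scale=values.get("t_scale", self.scale.t_scale),
        )
        return cfg, scale


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit."""

    params: dict[str, float]
    rss: float
    nfev: int
    converged: bool
    residuals: np.ndarray
    initial_rss: float
    strain: str = "custom"
    message: str = ""

    def summary_row(self) -> dict[str, float | str | bool]:
        row: dict[str, float | str | bool] = {"strain": self.strain or "custom"}
        row.update(self.params)
        row["rss"] = self.rss
        row["converged"] = self.converged
        return row


def model_prediction(
    values: dict[str, float],
    spec: FitSpec,
    times_min: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Predicted dimensional cAMP at the observation times.

    ``values`` maps free-parameter names to candidate values; the
    remaining constants come from the spec.  An integrator failure
    yields a constant large-residual penalty curve instead of raising,
    so the optimizer can back away from pathological parameter
    combinations.
    """
    times_min = np.asarray(times_min, dtype=float)
    if np.any(times_min < 0):
        raise ValueError("observation times must be >= 0 minutes")
    try:
        cfg, scale = spec.assemble(values)
        return noiseless_curve(cfg, scale, times_min, rtol=rtol, atol=atol)
    except (RuntimeError, ValueError):
        return np.full(times_min.shape, PENALTY_RESIDUAL)


def _pooled(data: TimeSeries | list[TimeSeries]) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(data, TimeSeries):
        data = [data]
    if not data:
        raise ValueError("no data to fit")
    t = np.concatenate([ts.times for ts in data])
    y = np.concatenate([ts.values for ts in data])
    order = np.argsort(t, kind="stable")
    strain = data[0].strain
    return t[order], y[order], strain


def fit_timeseries(
    data: TimeSeries | list[TimeSeries],
    spec: FitSpec,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Fit the free parameters of ``spec`` to observed cAMP series.

    Multiple replicates are pooled into one unweighted residual
    vector.  Minimization is Levenberg-Marquardt on log10-transformed
    parameters within the spec bounds (default ``[1e-6, 1e3]``); the
    fit is deterministic given the data and starting point.
    """
    t_obs, y_obs, strain = _pooled(data)
    if t_obs.size < len(spec.free):
        raise ValueError("need at least as many observations as free parameters")

    # Sorted unique times: the ODE is solved once per objective call.
    t_unique, inverse = np.unique(t_obs, return_inverse=True)

    def unpack(p: lmfit.Parameters) -> dict[str, float]:
        return {name: 10.0 ** p[f"log10_{name}"].value for name in spec.free}

    def residual(p: lmfit.Parameters) -> np.ndarray:
        pred = model_prediction(unpack(p), spec, t_unique, rtol=rtol, atol=atol)
        return pred[inverse] - y_obs

    pars = lmfit.Parameters()
    for name in spec.free:
        lo, hi = spec.bounds.get(name, DEFAULT_BOUNDS)
        start = spec.start_value(name)
        start = min(max(start, lo), hi)
        pars.add(
            f"log10_{name}",
            value=np.log10(start),
            min=np.log10(lo),
            max=np.log10(hi),
        )

    initial_rss = float(np.sum(residual(pars) ** 2))
    out = lmfit.minimize(
        residual, pars, method="leastsq", max_nfev=spec.max_nfev, xtol=1e-12, ftol=1e-12
    )
    fitted = unpack(out.params)
    resid = residual(out.params)
    rss = float(np.sum(resid**2))
    if rss > initial_rss:  # pragma: no cover - LM accepts only improving steps
        fitted = {name: spec.start_value(name) for name in spec.free}
        resid = residual(pars)
        rss = initial_rss
    return FitResult(
        params=fitted,
        rss=rss,
        nfev=int(out.nfev),
        converged=bool(out.success),
        residuals=resid,
        initial_rss=initial_rss,
        strain=strain,
        message=str(out.message),
    )


def fit_report(results: dict[str, FitResult] | list[FitResult]) -> pd.DataFrame:
    """Tabulate fits across strains/genotypes (exportable as CSV).

    Accepts either a mapping of row label to result or a list (rows
    labeled by each result's strain, empty labels becoming "custom").
    """
    if isinstance(results, dict):
        items = list(results.items())
    else:
        items = [(res.strain or "custom", res) for res in results]
    if not items:
        raise ValueError("no fit results to report")
    rows = []
    for label, res in items:
        row = res.summary_row()
        row["strain"] = label or "custom"
        rows.append(row)
    return pd.DataFrame(rows).set_index("strain")
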