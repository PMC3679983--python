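"""Model/Results interface for fitting the pathway to cAMP data.

This is the estimation front end of the package, organized the way
statistical modelling libraries present fitted models: a
:class:`CampPkaModel` is built from observed cAMP time series plus a
genotype scaffold, its :meth:`~CampPkaModel.fit` returns a
:class:`CampPkaResults` carrying the estimates, residual diagnostics
and a ``summary()`` table, and prediction, simulation and plotting
hang off those two objects.

Example
-------
>>> model = CampPkaModel(series, genotype="wt", free=("M", "D", "Gamma"))
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .fit import FitResult, FitSpec, fit_timeseries, model_prediction
from .io import TimeSeries
from .params import DimensionalScale, GenotypeConfig, genotype_params
from .simulate import Trajectory, run_timecourse
from .stability import StabilityResult, classify_regime
from .steady_state import Equilibrium, full_steady_state

__all__ = ["CampPkaModel", "CampPkaResults"]


class CampPkaModel:
    """The pathway model bound to observed cAMP time series.

    Parameters
    ----------
    data : TimeSeries or list of TimeSeries
        Observations in laboratory units (minutes, fmol per 10^6
        cells); replicates are pooled with equal weight.
    genotype : str or GenotypeConfig
        The genotype scaffold supplying the pinned parameter values
        (a label accepted by :func:`camppka.params.genotype_params`,
        or a full config).
    free : tuple of str
        Parameters to estimate; the default mirrors the Pde-feedback
        fits (``M``, ``D``, ``Gamma``) with the time scale free.
    scale : DimensionalScale, optional
        Unit conversion; the amplitude scale is fixed by default.
    bounds, initial : dict, optional
        Per-parameter overrides forwarded to the fit specification.
    """

    def __init__(
        self,
        data: TimeSeries | list[TimeSeries],
        genotype: str | GenotypeConfig = "wt",
        free: tuple[str, ...] = ("M", "D", "Gamma", "t_scale"),
        scale: DimensionalScale | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        initial: dict[str, float] | None = None,
    ):
        self.data = [data] if isinstance(data, TimeSeries) else list(data)
        if not self.data:
            raise ValueError("no data supplied")
        cfg = genotype_params(genotype) if isinstance(genotype, str) else genotype
        self.config = cfg
        self.scale = scale or DimensionalScale()
        self.spec = FitSpec(
            config=cfg,
            scale=self.scale,
            free=tuple(free),
            initial=dict(initial or {}),
            bounds=dict(bounds or {}),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        genotype: str | GenotypeConfig = "wt",
        **kwargs,
    ) -> "CampPkaModel":
        """Build from a DataFrame in the documented CSV dialect.

        Required columns: ``time_min``, ``camp_fmol_per_1e6cells``;
        optional ``strain`` and ``replicate`` split the rows into
        replicates.
        """
        if "replicate" not in df.columns:
            df = df.assign(replicate="1")
        if "strain" not in df.columns:
            df = df.assign(strain="custom")
        series = [
            TimeSeries(
                times=g["time_min"].to_numpy(dtype=float),
                values=g["camp_fmol_per_1e6cells"].to_numpy(dtype=float),
                strain=str(s),
                replicate=str(r),
            ).sorted()
            for (s, r), g in df.groupby(["strain", "replicate"])
        ]
        return cls(series, genotype=genotype, **kwargs)

    # -- analysis that does not require a fit -------------------------------

    def steady_state(self, glucose: float | None = None) -> Equilibrium:
        """Equilibrium of the scaffold config (optionally at a given G)."""
        cfg = self.config if glucose is None else self.config.with_glucose(glucose)
        return full_steady_state(cfg)

    def simulate(self, t_end_min: float = 12.0, n_points: int = 2000, **kwargs) -> Trajectory:
        """Stimulus-protocol trajectory at the scaffold parameter values."""
        return run_timecourse(
            self.config,
            t_end=t_end_min / self.scale.t_scale,
            n_points=n_points,
            **kwargs,
        )

    def fit(
        self,
        start: dict[str, float] | None = None,
        multistart_factors: tuple[float, ...] = (),
    ) -> "CampPkaResults":
        """Estimate the free parameters by Levenberg-Marquardt.

        ``start`` overrides the starting values; with
        ``multistart_factors`` the fit is additionally restarted from
        the start values scaled by each factor (e.g. ``(3.0, 1/3.0)``)
        and the lowest-RSS solution is kept, guarding against local
        minima.
        """
        spec = self.spec if start is None else replace(self.spec, initial=dict(start))
        best = fit_timeseries(self.data, spec)
        for fac in multistart_factors:
            shifted = {
                name: fac * spec.start_value(name) for name in spec.free
            }
            alt = fit_timeseries(self.data, replace(spec, initial=shifted))
            if alt.rss < best.rss:
                best = alt
        return CampPkaResults(self, best)


class CampPkaResults:
    """Estimates, diagnostics and derived analyses of a fitted model."""

    def __init__(self, model: CampPkaModel, result: FitResult):
        self.model = model
        self._result = result
        self.params = pd.Series(result.params, name="estimate")
        self.rss = result.rss
        self.nfev = result.nfev
        self.converged = result.converged
        self.resid = result.residuals
        self.config, self.scale = model.spec.assemble(result.params)

    @property
    def nobs(self) -> int:
        return int(sum(len(ts) for ts in self.model.data))

    @property
    def fittedvalues(self) -> np.ndarray:
        """Model curve at the pooled observation times."""
        t = np.concatenate([ts.times for ts in self.model.data])
        t = np.sort(t)
        return self.predict(np.unique(t))

    def predict(self, times_min: np.ndarray) -> np.ndarray:
        """Predicted cAMP (fmol per 10^6 cells) at arbitrary times."""
        return model_prediction(dict(self.params), self.model.spec, times_min)

    def simulate(self, t_end_min: float = 12.0, n_points: int = 2000, **kwargs) -> Trajectory:
        """Trajectory of all state variables at the fitted parameters."""
        return run_timecourse(
            self.config,
            t_end=t_end_min / self.scale.t_scale,
            n_points=n_points,
            **kwargs,
        )

    def stability(self, glucose: float = 1.0, **kwargs) -> StabilityResult:
        """Linear stability of the fed equilibrium at the fitted parameters."""
        return classify_regime(self.config.with_glucose(glucose), **kwargs)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "cAMP-PKA pathway model fit (Levenberg-Marquardt)",
            "=" * 50,
            f"genotype:        {self.model.config.label}",
            f"strain:          {self._result.strain}",
            f"n observations:  {self.nobs}",
            f"free parameters: {', '.join(self.model.spec.free)}",
            f"converged:       {self.converged}  (nfev={self.nfev})",
            f"RSS:             {self.rss:.6g}   (at start: {self._result.initial_rss:.6g})",
            "-" * 50,
            f"{'parameter':<12}{'estimate':>14}{'start':>14}",
        ]
        for name in self.model.spec.free:
            lines.append(
                f"{name:<12}{self.params[name]:>14.6g}"
                f"{self.model.spec.start_value(name):>14.6g}"
            )
        lines.append("=" * 50)
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_curve: int = 400):
        """Data (points) and fitted curve (line) in laboratory units."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_max = max(ts.times.max() for ts in self.model.data)
        for ts in self.model.data:
            ax.plot(ts.times, ts.values, "x", alpha=0.7, label=f"rep {ts.replicate}")
        t_curve = np.linspace(0.0, t_max, n_curve)
        ax.plot(t_curve, self.predict(t_curve), "-", color="k", label="model")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("cAMP (fmol per $10^6$ cells)")
        ax.legend(frameon=False)
        return ax
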