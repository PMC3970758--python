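"""Hill binding model for electrophoretic mobility shift titrations.

A labeled oligonucleotide at trace concentration is titrated with
protein; the free and bound band intensities, normalized to the
no-protein lane, follow the pair of simultaneous Hill equations

    I_free/I0  = K_half^h / (K_half^h + c^h)
    I_bound/I0 = c^h      / (K_half^h + c^h)

where ``c`` is the protein concentration (uM), ``K_half`` the
concentration of half-binding and ``h`` the Hill (cooperativity)
coefficient.  Both fractions are fitted jointly by least squares, with
free and bound residuals weighted equally.

The modelling surface follows the Model/Results idiom: build a
:class:`HillModel` from a :class:`TitrationSeries` (or a DataFrame) and
call :meth:`HillModel.fit`, which returns a :class:`HillResults` carrying
estimates, approximate standard errors, diagnostics and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError

_H_MIN, _H_MAX = 0.1, 10.0


@dataclass
class TitrationSeries:
    """One EMSA titration: concentrations (uM) with free/bound fractions."""

    concentrations: np.ndarray
    frac_free: np.ndarray
    frac_bound: np.ndarray
    label: str = ""
    sum_tolerance: float = 0.2

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.frac_free = np.asarray(self.frac_free, dtype=float)
        self.frac_bound = np.asarray(self.frac_bound, dtype=float)
        n = len(self.concentrations)
        if len(self.frac_free) != n or len(self.frac_bound) != n:
            raise ValueError("concentrations and fractions must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        for name, arr in (("frac_free", self.frac_free),
                          ("frac_bound", self.frac_bound)):
            if np.any((arr < -1e-9) | (arr > 1 + 1e-9)):
                raise ValueError(f"{name} outside [0, 1]")
        gap = np.abs(self.frac_free + self.frac_bound - 1.0)
        if np.any(gap > self.sum_tolerance):
            raise ValueError(
                "free + bound fractions deviate from 1 beyond tolerance "
                f"(max deviation {gap.max():.3f})"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "",
                       **kwargs) -> "TitrationSeries":
        """Build from a table with columns ``conc`` plus either
        ``frac_free``/``frac_bound`` or raw intensities ``i_free``/
        ``i_bound`` (normalized by the conc==0 lane, which is then
        dropped)."""
        cols = set(df.columns)
        if {"frac_free", "frac_bound"} <= cols:
            sub = df
            free = sub["frac_free"].to_numpy(dtype=float)
            bound = sub["frac_bound"].to_numpy(dtype=float)
        elif {"i_free", "i_bound"} <= cols:
            zero = df[df["conc"] == 0]
            if zero.empty:
                raise ValueError(
                    "raw-intensity table needs a conc == 0 reference lane"
                )
            i0 = float(zero["i_free"].iloc[0])
            if i0 <= 0:
                raise ValueError("reference-lane intensity must be positive")
            sub = df[df["conc"] > 0]
            free = sub["i_free"].to_numpy(dtype=float) / i0
            bound = sub["i_bound"].to_numpy(dtype=float) / i0
        else:
            raise ValueError(
                "table needs conc with frac_free/frac_bound or i_free/i_bound"
            )
        return cls(
            concentrations=sub["conc"].to_numpy(dtype=float),
            frac_free=free, frac_bound=bound, label=label, **kwargs
        )


def hill_model(conc, k_half: float, h: float):
    """Free and bound fractions at concentration(s) ``conc``; the two
    fractions sum to 1 exactly."""
    if k_half <= 0 or h <= 0:
        raise FitError("hill_model requires k_half > 0 and h > 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise FitError("concentrations must be >= 0")
    # work on log-scaled ratio for numerical stability at extreme h
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / k_half) ** h, 0.0)
    bound = ratio / (1.0 + ratio)
    free = 1.0 / (1.0 + ratio)
    if np.isscalar(conc):
        return float(free), float(bound)
    return free, bound


class HillModel:
    """Joint Hill fit of an EMSA titration.

    Parameters
    ----------
    series :
        The titration data; at least three distinct positive
        concentrations are required, and the series must straddle the
        transition (not all-free or all-bound).
    """

    param_names = ("k_half", "h")

    def __init__(self, series: TitrationSeries):
        pos = series.concentrations > 0
        if len(np.unique(series.concentrations[pos])) < 3:
            raise FitError(
                "need >= 3 distinct positive concentrations to fit"
            )
        if series.frac_bound.max() < 0.05 or series.frac_bound.min() > 0.95:
            raise FitError(
                "degenerate series (all-free or all-bound); the transition "
                "is not sampled"
            )
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "HillModel":
        return cls(TitrationSeries.from_dataframe(df, label=label))

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        k_half, h = params
        free, bound = hill_model(self.series.concentrations, k_half, h)
        return np.concatenate(
            [free - self.series.frac_free, bound - self.series.frac_bound]
        )

    def fit(self) -> "HillResults":
        s = self.series
        # initialize K_half at the concentration whose free fraction is
        # nearest one half, h at 1 (non-cooperative)
        pos = s.concentrations > 0
        idx = np.argmin(np.abs(s.frac_free[pos] - 0.5))
        k0 = float(s.concentrations[pos][idx])
        x0 = np.array([max(k0, 1e-6), 1.0])
        sol = least_squares(
            self._residuals,
            x0,
            bounds=([1e-9, _H_MIN], [np.inf, _H_MAX]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        rss = float(sol.cost * 2.0)
        n_obs = 2 * len(s.concentrations)
        dof = max(n_obs - 2, 1)
        # Gauss-Newton covariance; near-singular at a flat optimum
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            bse = np.array([np.nan, np.nan])
        return HillResults(
            model=self,
            params=dict(zip(self.param_names, map(float, sol.x))),
            bse=dict(zip(self.param_names, map(float, bse))),
            rss=rss,
            nobs=n_obs,
            converged=bool(sol.success),
            message=sol.status and sol.message or "",
            cov_params=cov,
        )


@dataclass
class HillResults:
    """Fitted Hill parameters with uncertainties and diagnostics."""

    model: HillModel
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    nobs: int
    converged: bool
    message: str = ""
    cov_params: np.ndarray = field(default_factory=lambda: np.eye(2))

    @property
    def k_half(self) -> float:
        return self.params["k_half"]

    @property
    def h(self) -> float:
        return self.params["h"]

    def predict(self, conc) -> pd.DataFrame:
        free, bound = hill_model(conc, self.k_half, self.h)
        return pd.DataFrame(
            {"conc": np.atleast_1d(conc), "frac_free": np.atleast_1d(free),
             "frac_bound": np.atleast_1d(bound)}
        )

    def summary(self) -> str:
        lines = [
            "Hill binding fit" + (
                f" [{self.model.series.label}]" if self.model.series.label
                else ""
            ),
            "=" * 44,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
            "-" * 44,
            f"{'K_half (uM)':<12}{self.k_half:>12.4g}"
            f"{self.bse['k_half']:>12.3g}",
            f"{'h':<12}{self.h:>12.4g}{self.bse['h']:>12.3g}",
            "-" * 44,
            f"observations: {self.nobs}    RSS: {self.rss:.4g}    "
            f"converged: {self.converged}",
        ]
        return "\n".join(lines)


def fit_titration(series: TitrationSeries) -> HillResults:
    """Convenience wrapper: ``HillModel(series).fit()``."""
    return HillModel(series).fit()


def fold_change(mutant: HillResults, wildtype: HillResults) -> float:
    """Binding-defect fold change as the ratio of half-binding
    concentrations, mutant over wild type (>1 = weaker binding)."""
    for name, res in (("mutant", mutant), ("wildtype", wildtype)):
        if not res.converged:
            raise FitError(f"{name} fit did not converge")
    return mutant.k_half / wildtype.k_half
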