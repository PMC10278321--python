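"""Fitting exponential rise curves and time-constant regressions.

Two estimators follow the scikit-learn protocol and compose with its
pipelines and model-selection tools:

* :class:`ExponentialRiseEstimator` — nonlinear least squares for the
  first-order step response ``h(t) = (P_inf/rho)(1 - exp(-t/tau))``,
  jointly over (P_inf, tau) or with either parameter held fixed.
* :class:`TauResistanceRegression` — ordinary least squares of measured
  time constants on needle resistances; by ``tau = R*A/rho`` the slope
  estimates the manometer cross-sectional area.

Module-level functions (:func:`fit_exponential_rise`,
:func:`tau_vs_r_regression`, ...) are thin wrappers over these
estimators operating on :class:`RiseDataset` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, EstimationError, SummaryError
from .hydraulics import CSF_NOMINAL, FluidProperties, time_to_fraction

__all__ = [
    "RiseObservation",
    "RiseDataset",
    "FitResult",
    "LinearFit",
    "ExponentialRiseEstimator",
    "TauResistanceRegression",
    "fit_exponential_rise",
    "rms_error",
    "equilibration_time_summary",
    "times_to_percentages",
    "tau_vs_r_regression",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiseObservation:
    """One graduation crossing: the column reached ``height`` cm at ``time`` s."""

    time: float
    height: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DomainError(f"time must be nonnegative, got {self.time!r}")
        if self.height < 0:
            raise DomainError(f"height must be nonnegative, got {self.height!r}")


@dataclass(frozen=True)
class RiseDataset:
    """Ordered rise observations for one needle replicate.

    Times must be strictly increasing and heights nondecreasing — the
    column in a constant-head experiment never falls.
    """

    needle_label: str
    replicate_label: str
    observations: Tuple[RiseObservation, ...]

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        times = [o.time for o in obs]
        heights = [o.height for o in obs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError(
                f"{self.needle_label}/{self.replicate_label}: observation "
                "times must be strictly increasing"
            )
        if any(h2 < h1 for h1, h2 in zip(heights, heights[1:])):
            raise DomainError(
                f"{self.needle_label}/{self.replicate_label}: heights must be nondecreasing"
            )

    @classmethod
    def from_arrays(cls, needle_label, replicate_label, times, heights) -> "RiseDataset":
        obs = tuple(RiseObservation(float(t), float(h)) for t, h in zip(times, heights))
        return cls(needle_label, replicate_label, obs)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([o.height for o in self.observations], dtype=float)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class FitResult:
    """Estimated step-response parameters for one dataset."""

    p_inf: float  # cmH2O
    tau: float  # s
    r_squared: float
    rmse: float  # cmH2O
    residuals: Tuple[float, ...]  # cm, observed - fitted
    mode: str  # joint | fixed_tau | fixed_p
    density: float = 1.0
    n_iter: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.p_inf / self.density) * (1.0 - np.exp(-t / self.tau))


@dataclass(frozen=True)
class LinearFit:
    """Ordinary-least-squares line tau = slope*R + intercept."""

    slope: float  # cm^2 when regressing tau on R
    intercept: float  # s
    r_squared: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def implied_bore_diameter(self) -> float:
        """Manometer bore (cm) implied by reading the slope as an area."""
        if self.slope <= 0:
            raise DomainError("slope must be positive to imply a bore diameter")
        return math.sqrt(4.0 * self.slope / math.pi)


# ---------------------------------------------------------------------------
# Exponential rise estimator
# ---------------------------------------------------------------------------


def _as_time_vector(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2:
        if t.shape[1] != 1:
            raise DomainError("X must be a 1-d time vector or a single-column matrix")
        t = t[:, 0]
    elif t.ndim != 1:
        raise DomainError("X must be a 1-d time vector or a single-column matrix")
    if np.any(t < 0):
        raise DomainError("observation times must be nonnegative")
    return t


class ExponentialRiseEstimator(RegressorMixin, BaseEstimator):
    """Least-squares fit of the first-order rise h(t) = (P/rho)(1 - exp(-t/tau)).

    Parameters
    ----------
    mode : {"joint", "fixed_tau", "fixed_p"}
        Which parameters to estimate. ``fixed_tau`` solves the remaining
        linear problem in closed form; ``fixed_p`` optimizes tau alone.
    fixed_value : float, optional
        The held value (tau in s, or P_inf in cmH2O); required unless
        ``mode == "joint"``.
    density : float
        Fluid density rho (g/ml) linking pressure to column height.
    max_iter : int
        Iteration budget for the nonlinear solver.
    ssr_rtol : float
        Convergence threshold on the relative change of the sum of
        squared residuals.

    Attributes
    ----------
    p_inf_, tau_ : float
        Estimated equilibrium pressure (cmH2O) and time constant (s).
    r_squared_, rmse_ : float
        Coefficient of determination (1 - SS_res/SS_tot about the mean
        observed height) and root-mean-square residual (cm).
    residuals_ : ndarray
        Observed minus fitted heights.
    """

    def __init__(
        self,
        mode: str = "joint",
        fixed_value: Optional[float] = None,
        density: float = 1.0,
        max_iter: int = 500,
        ssr_rtol: float = 1e-10,
    ):
        self.mode = mode
        self.fixed_value = fixed_value
        self.density = density
        self.max_iter = max_iter
        self.ssr_rtol = ssr_rtol

    # -- initial guesses -------------------------------------------------

    @staticmethod
    def _initial_tau(t: np.ndarray, h: np.ndarray, h_inf: float) -> float:
        """Time at which the data cross 63% of the plateau estimate.

        At t = tau the noiseless curve sits at 1 - 1/e ~ 63% of its
        asymptote, so interpolating the observations at that level gives
        a scale-free starting value.
        """
        target = (1.0 - math.exp(-1.0)) * h_inf
        order = np.argsort(h, kind="stable")
        tau0 = float(np.interp(target, h[order], t[order]))
        if tau0 <= 0:
            tau0 = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
        return tau0

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        t = _as_time_vector(X)
        h = np.asarray(y, dtype=float)
        if h.shape != t.shape:
            raise DomainError("X and y must have matching lengths")
        if not self.density > 0:
            raise DomainError("density must be strictly positive")
        if self.mode not in ("joint", "fixed_tau", "fixed_p"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.mode != "joint" and self.fixed_value is None:
            raise DomainError(f"mode {self.mode!r} requires fixed_value")
        min_n = 3 if self.mode == "joint" else 1
        if len(t) < min_n:
            raise DomainError(f"mode {self.mode!r} needs at least {min_n} observations")
        if np.ptp(h) == 0 and self.mode == "joint":
            raise EstimationError("degenerate data: all heights are equal")

        rho = self.density
        n_iter = 0

        if self.mode == "fixed_tau":
            tau = float(self.fixed_value)
            if tau <= 0:
                raise DomainError("fixed tau must be strictly positive")
            basis = 1.0 - np.exp(-t / tau)
            denom = float(basis @ basis)
            if denom == 0:
                raise EstimationError("degenerate design: all times are zero")
            h_inf = float(basis @ h) / denom
            p_inf = rho * h_inf
        elif self.mode == "fixed_p":
            p_inf = float(self.fixed_value)
            h_inf = p_inf / rho

            def resid(theta):
                return h_inf * (1.0 - np.exp(-t / theta[0])) - h

            tau0 = self._initial_tau(t, h, h_inf)
            sol = least_squares(
                resid, x0=[tau0], ftol=self.ssr_rtol, xtol=1e-12, gtol=1e-12,
                max_nfev=self.max_iter, bounds=([1e-12], [np.inf]),
            )
            n_iter = sol.nfev
            if sol.status == 0:
                raise EstimationError(
                    "tau fit did not converge within the iteration budget",
                    best={"p_inf": p_inf, "tau": float(sol.x[0])},
                )
            tau = float(sol.x[0])
        else:  # joint
            h_inf0 = float(h.max())
            tau0 = self._initial_tau(t, h, h_inf0)

            def resid(theta):
                return theta[0] * (1.0 - np.exp(-t / theta[1])) - h

            sol = least_squares(
                resid, x0=[h_inf0, tau0], ftol=self.ssr_rtol, xtol=1e-12, gtol=1e-12,
                max_nfev=self.max_iter, bounds=([0.0, 1e-12], [np.inf, np.inf]),
            )
            n_iter = sol.nfev
            if sol.status == 0:
                raise EstimationError(
                    "joint fit did not converge within the iteration budget",
                    best={"p_inf": rho * float(sol.x[0]), "tau": float(sol.x[1])},
                )
            h_inf, tau = float(sol.x[0]), float(sol.x[1])
            p_inf = rho * h_inf

        fitted = h_inf * (1.0 - np.exp(-t / tau))
        residuals = h - fitted
        ss_res = float(residuals @ residuals)
        ss_tot = float(np.sum((h - h.mean()) ** 2))
        self.p_inf_ = p_inf
        self.tau_ = tau
        self.residuals_ = residuals
        self.rmse_ = math.sqrt(ss_res / len(h))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        self.n_iter_ = n_iter
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        t = _as_time_vector(X)
        return (self.p_inf_ / self.density) * (1.0 - np.exp(-t / self.tau_))

    def to_result(self) -> FitResult:
        return FitResult(
            p_inf=self.p_inf_,
            tau=self.tau_,
            r_squared=self.r_squared_,
            rmse=self.rmse_,
            residuals=tuple(float(r) for r in self.residuals_),
            mode=self.mode,
            density=self.density,
            n_iter=self.n_iter_,
        )


class TauResistanceRegression(RegressorMixin, BaseEstimator):
    """OLS of time constants (s) on needle resistances (cmH2O.s/ml).

    Under tau = R*A/rho the fitted slope is an estimate of the manometer
    cross-sectional area A (cm^2) for unit density, so
    ``implied_bore_diameter_`` back-calculates the bore from pooled
    measurements.
    """

    def fit(self, X, y):
        R = _as_time_vector(X)  # same shape handling; R values are nonnegative
        tau = np.asarray(y, dtype=float)
        if tau.shape != R.shape:
            raise DomainError("X and y must have matching lengths")
        if len(R) < 2 or np.ptp(R) == 0:
            raise DomainError("need at least two distinct resistance values")
        design = np.column_stack([R, np.ones_like(R)])
        coef, _, _, _ = np.linalg.lstsq(design, tau, rcond=None)
        self.slope_, self.intercept_ = float(coef[0]), float(coef[1])
        fitted = design @ coef
        ss_res = float(np.sum((tau - fitted) ** 2))
        ss_tot = float(np.sum((tau - tau.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if self.slope_ > 0:
            self.implied_bore_diameter_ = math.sqrt(4.0 * self.slope_ / math.pi)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        R = _as_time_vector(X)
        return self.slope_ * R + self.intercept_

    def to_result(self) -> LinearFit:
        return LinearFit(slope=self.slope_, intercept=self.intercept_, r_squared=self.r_squared_)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_exponential_rise(
    data: RiseDataset,
    mode: str = "joint",
    fluid: FluidProperties = CSF_NOMINAL,
    fixed_value: Optional[float] = None,
) -> FitResult:
    """Fit the first-order rise curve to one replicate's observations."""
    est = ExponentialRiseEstimator(mode=mode, fixed_value=fixed_value, density=fluid.density)
    est.fit(data.times, data.heights)
    return est.to_result()


def rms_error(data: RiseDataset, p_inf: float, tau: float, density: float = 1.0) -> float:
    """RMS residual (cm) of the curve (p_inf, tau) against observed heights."""
    if not tau > 0:
        raise DomainError(f"tau must be strictly positive, got {tau!r}")
    if len(data) == 0:
        raise DomainError("dataset is empty")
    model = (p_inf / density) * (1.0 - np.exp(-data.times / tau))
    return float(np.sqrt(np.mean((data.heights - model) ** 2)))


def equilibration_time_summary(
    datasets: Iterable[RiseDataset], final_height: float
) -> Mapping[str, float]:
    """Mean time (s) per needle at which replicates reached ``final_height``."""
    per_needle: dict[str, list[float]] = {}
    for ds in datasets:
        match = [o.time for o in ds.observations if o.height == final_height]
        if not match:
            raise SummaryError(
                f"replicate {ds.needle_label}/{ds.replicate_label} has no "
                f"observation at height {final_height} cm"
            )
        per_needle.setdefault(ds.needle_label, []).append(match[0])
    return {needle: float(np.mean(times)) for needle, times in per_needle.items()}


def times_to_percentages(fit: FitResult, percentages: Sequence[float]) -> np.ndarray:
    """Times (s) to reach the given percentages of equilibrium pressure."""
    out = []
    for pct in percentages:
        if not 0.0 < pct < 100.0:
            raise DomainError(f"percentage must lie in (0, 100), got {pct!r}")
        out.append(time_to_fraction(pct / 100.0, fit.tau))
    return np.asarray(out)


def tau_vs_r_regression(pairs: Sequence[Tuple[float, float]]) -> LinearFit:
    """OLS line through (resistance, time-constant) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be a sequence of (R, tau) tuples")
    est = TauResistanceRegression()
    est.fit(arr[:, 0], arr[:, 1])
    return est.to_result()
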