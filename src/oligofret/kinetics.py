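"""Empirical kinetic fits: sigmoidal fibrillization, exponential-with-lag
oligomer growth, and proteinase-K degradation midpoints.

All three fitters are scikit-learn style estimators (``fit``/``predict``,
fitted attributes with a trailing underscore) over 1-D time or concentration
axes, with parametric-bootstrap confidence intervals.  Time is in hours for
these empirical fits (the mechanistic model works in seconds; see
:mod:`oligofret.nucleation`).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitFailureError
from .simulate import sigmoid_with_baselines

__all__ = [
    "SigmoidalGrowthModel",
    "ExponentialLagModel",
    "ProteinaseKModel",
    "fit_sigmoid",
    "fit_exp_lag",
    "fit_pk_cm",
    "conversion_halftime",
]


def _columnless(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-D axis (or a single-column 2-D array)")
    return x


class _BootstrapMixin:
    """Parametric bootstrap CIs shared by the curve fitters."""

    def bootstrap_ci(self, n_boot: int = 200, seed: int = 0, level: float = 0.95):
        self._check_fitted()
        x, y = self._fit_data_
        yhat = self.predict(x)
        sd = np.std(y - yhat, ddof=min(len(y) - 1, self._n_params))
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            yb = yhat + rng.normal(0.0, sd, size=y.size)
            try:
                m = type(self)(**self.get_params())
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(x, yb)
                draws.append(m._param_vector())
            except (FitFailureError, RuntimeError):
                continue
        if len(draws) < n_boot // 4:
            raise FitFailureError("bootstrap refits mostly failed")
        draws = np.array(draws)
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        bounds = np.percentile(draws, [lo, hi], axis=0)
        return {
            name: (bounds[0, i], bounds[1, i])
            for i, name in enumerate(self._param_names)
        }

    def _check_fitted(self):
        if not hasattr(self, "_fit_data_"):
            raise FitFailureError("model is not fitted")


class SigmoidalGrowthModel(_BootstrapMixin, RegressorMixin, BaseEstimator):
    """Sigmoidal fibrillization curve with sloped baselines.

    ``y = (yi + mi*x) + (yf + mf*x) / (1 + exp(-(x - x0)/tau))`` — a
    logistic transition of half-width ``tau`` (hr) centered at ``x0`` (hr)
    between the initial baseline line and the final one.  The lag time is
    extracted by the standard tangent construction, ``x0 - 2*tau``.

    Attributes: ``yi_``, ``mi_``, ``yf_``, ``mf_``, ``x0_``, ``tau_``,
    ``lag_time_``.
    """

    _param_names = ("yi", "mi", "yf", "mf", "x0", "tau")
    _n_params = 6

    def __init__(self, min_points: int = 7):
        self.min_points = min_points

    def fit(self, x, y):
        x = _columnless(x)
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if x.size < self.min_points:
            raise FitFailureError(
                f"need >= {self.min_points} points spanning both baselines"
            )
        span = y.max() - y.min()
        noise = np.std(np.diff(y)) / np.sqrt(2) if y.size > 2 else 0.0
        if span <= 0 or (noise > 0 and span < 5 * noise):
            raise FitFailureError(
                "no transition detected: data range is within the noise",
                details={"span": float(span), "noise_sd": float(noise)},
            )

        order = np.argsort(x)
        xs, ys = x[order], y[order]
        k = max(2, xs.size // 5)
        yi0 = ys[:k].mean()
        amp0 = ys[-k:].mean() - yi0
        # midpoint: first crossing of the half-amplitude level
        half = yi0 + amp0 / 2
        cross = np.nonzero(np.diff(np.sign(ys - half)))[0]
        x00 = xs[cross[0]] if cross.size else xs[xs.size // 2]
        tau0 = max((xs[-1] - xs[0]) / 20, 1e-3)

        def residuals(p):
            return sigmoid_with_baselines(xs, *p) - ys

        sol = least_squares(
            residuals,
            x0=[yi0, 0.0, amp0, 0.0, x00, tau0],
            bounds=([-np.inf] * 5 + [1e-9], [np.inf] * 6),
        )
        if not sol.success:
            raise FitFailureError(
                "sigmoid fit did not converge",
                details={"message": sol.message,
                         "residual_rms": float(np.sqrt(np.mean(sol.fun**2)))},
            )
        self.yi_, self.mi_, self.yf_, self.mf_, self.x0_, self.tau_ = sol.x
        self.lag_time_ = self.x0_ - 2.0 * self.tau_
        self.residual_rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        self._fit_data_ = (x, y)
        return self

    def predict(self, x):
        self._check_fitted()
        return sigmoid_with_baselines(
            _columnless(x), self.yi_, self.mi_, self.yf_, self.mf_,
            self.x0_, self.tau_,
        )

    def _param_vector(self):
        return np.array([self.yi_, self.mi_, self.yf_, self.mf_,
                         self.x0_, self.tau_])


def exp_lag_curve(x, A: float, r: float, x0: float):
    """Single exponential with a lag: 0 before ``x0``, then
    ``A * (1 - exp(-(x - x0) * r))``."""
    x = np.asarray(x, dtype=float)
    return np.where(x <= x0, 0.0, A * -np.expm1(-np.clip(x - x0, 0, None) * r))


class ExponentialLagModel(_BootstrapMixin, RegressorMixin, BaseEstimator):
    """Single-exponential oligomer formation kinetics with a lag time.

    ``y = A * (1 - exp(-(x - x0) * r))`` for ``x > x0``, 0 before — ``A``
    the plateau concentration, ``r`` the apparent growth rate (hr^-1), and
    ``x0`` the lag time (hr).  Scale-equivariant: rescaling y rescales only
    ``A``.

    Attributes: ``A_``, ``r_``, ``x0_``.
    """

    _param_names = ("A", "r", "x0")
    _n_params = 3

    def __init__(self, min_points: int = 5, allow_negative_lag: bool = False):
        self.min_points = min_points
        self.allow_negative_lag = allow_negative_lag

    def fit(self, x, y):
        x = _columnless(x)
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if np.unique(x).size < self.min_points:
            raise FitFailureError(f"need >= {self.min_points} distinct points")
        if np.all(y == 0) or y.max() <= 0:
            raise FitFailureError("all-zero data cannot constrain the model")

        a0 = float(np.quantile(y, 0.95))
        # lag guess: last time the (averaged) signal is still below 10% of A
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        below = xs[ys < 0.1 * a0]
        x00 = float(below[-1]) if below.size else float(xs[0])
        x00 = min(x00, float(xs[-1]) * 0.5)
        r0 = 1.0 / max((xs[-1] - x00) / 3.0, 1e-6)

        lag_lo = -np.inf if self.allow_negative_lag else 0.0

        def residuals(p):
            return exp_lag_curve(x, *p) - y

        best = None
        for x0_start in {x00, 0.0, float(xs[xs.size // 3])}:
            sol = least_squares(
                residuals,
                x0=[a0, r0, max(x0_start, 0.0 if not self.allow_negative_lag else x0_start)],
                bounds=([0.0, 1e-9, lag_lo], [np.inf, np.inf, float(xs[-1])]),
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitFailureError("exponential-lag fit did not converge")
        self.A_, self.r_, self.x0_ = best.x
        self.residual_rms_ = float(np.sqrt(np.mean(best.fun**2)))
        self._fit_data_ = (x, y)
        return self

    def predict(self, x):
        self._check_fitted()
        return exp_lag_curve(_columnless(x), self.A_, self.r_, self.x0_)

    def _param_vector(self):
        return np.array([self.A_, self.r_, self.x0_])


def pk_logistic(conc, cm: float, hill_slope: float):
    """Fraction intact after limited digestion: logistic in log
    concentration, ``1 / (1 + (c/cm)^h)``; equals 1/2 at ``c = cm``."""
    conc = np.asarray(conc, dtype=float)
    return 1.0 / (1.0 + (conc / cm) ** hill_slope)


class ProteinaseKModel(_BootstrapMixin, RegressorMixin, BaseEstimator):
    """Proteinase-K degradation midpoint (Cm) fit.

    Two-parameter logistic in log10(protease concentration); ``cm_`` is the
    concentration at which half the species is degraded, ``hill_slope_`` the
    steepness.  Warns (wide CI expected) when the data do not bracket the
    midpoint.
    """

    _param_names = ("cm", "hill_slope")
    _n_params = 2

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, conc, fraction_intact):
        c = _columnless(conc)
        y = np.asarray(fraction_intact, dtype=float).ravel()
        if c.size != y.size:
            raise ValueError("conc and fraction_intact must have the same length")
        if np.any(c <= 0):
            raise ValueError("protease concentrations must be positive")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("fractions must be in [0, 1]")
        if np.unique(c).size < self.min_points:
            raise FitFailureError(f"need >= {self.min_points} concentrations")
        if y.min() > 0.9:
            raise FitFailureError(
                "no degradation observed: all fractions near 1",
                details={"min_fraction": float(y.min())},
            )
        if not (y.min() < 0.5 < y.max()):
            warnings.warn(
                "data do not bracket the midpoint; Cm is an extrapolation "
                "with a wide confidence interval",
                stacklevel=2,
            )

        logc = np.log10(c)
        # midpoint guess: log-interpolate the 0.5 crossing
        order = np.argsort(logc)
        interp = np.interp(0.5, y[order][::-1], logc[order][::-1])
        theta0 = [np.clip(interp, logc.min() - 2, logc.max() + 2), 1.0]

        def residuals(p):
            log_cm, h = p
            return 1.0 / (1.0 + 10.0 ** (h * (logc - log_cm))) - y

        sol = least_squares(residuals, theta0,
                            bounds=([-np.inf, 1e-3], [np.inf, 50.0]))
        if not sol.success:
            raise FitFailureError("PK logistic fit did not converge")
        self.cm_ = float(10.0 ** sol.x[0])
        self.hill_slope_ = float(sol.x[1])
        self.residual_rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        self._fit_data_ = (c, y)
        return self

    def predict(self, conc):
        self._check_fitted()
        return pk_logistic(_columnless(conc), self.cm_, self.hill_slope_)

    def _param_vector(self):
        return np.array([self.cm_, self.hill_slope_])


def fit_sigmoid(times, values, **kwargs) -> SigmoidalGrowthModel:
    return SigmoidalGrowthModel(**kwargs).fit(times, values)


def fit_exp_lag(times, values, **kwargs) -> ExponentialLagModel:
    return ExponentialLagModel(**kwargs).fit(times, values)


def fit_pk_cm(pk_concs, fraction_intact, **kwargs) -> ProteinaseKModel:
    return ProteinaseKModel(**kwargs).fit(pk_concs, fraction_intact)


def conversion_halftime(kc: float) -> float:
    """Half-time ln(2)/kc of the first-order A->B structural conversion,
    converted from seconds to hours (kc in s^-1)."""
    if kc <= 0:
        raise ValueError("kc must be positive")
    return float(np.log(2) / kc / 3600.0)
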