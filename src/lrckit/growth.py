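"""Homing efficiency and exponential-vs-logistic growth model selection.

Burden trajectories of engrafting leukemia are log-linear early and saturate
as the marrow niche fills.  Both candidate models are fitted to log burden
(multiplicative, lognormal noise):

    exponential:  N(t) = N0 * exp(r t)
    logistic:     N(t) = K / (1 + (K/N0 - 1) * exp(-r t))

Fitting minimizes squared residuals of log N, which is the Gaussian MLE on
the log scale.  Model choice uses AICc (small samples, one extra parameter
for the logistic capacity K); a difference below 2 is reported as equivocal
rather than forced.

The API follows the model/results convention: construct a model from a
burden series, call ``fit()``, and read estimates, standard errors, AICc and
diagnostics off the :class:`GrowthResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "homing_efficiency",
    "HomingEstimate",
    "ExponentialGrowth",
    "LogisticGrowth",
    "GrowthResults",
    "ModelSelection",
    "select_model",
]


@dataclass(frozen=True)
class HomingEstimate:
    """Fraction of injected cells recovered from the marrow at day 3."""

    estimate: float
    ci: tuple[float, float]
    n_injected: int
    n_recovered: int

    def __str__(self) -> str:
        return (
            f"homing {self.estimate:.3g} "
            f"(95% CI {self.ci[0]:.3g}-{self.ci[1]:.3g}, "
            f"{self.n_recovered}/{self.n_injected})"
        )


def homing_efficiency(n_injected: int, n_recovered_day3: int) -> HomingEstimate:
    """Point estimate and Wilson 95% CI for the homing probability."""
    if n_injected <= 0:
        raise ValueError("n_injected must be positive")
    if n_recovered_day3 < 0:
        raise ValueError("n_recovered_day3 must be non-negative")
    if n_recovered_day3 > n_injected:
        raise ValueError(
            f"recovered {n_recovered_day3} exceeds injected {n_injected}; "
            "check the counts"
        )
    lo, hi = proportion_confint(
        n_recovered_day3, n_injected, alpha=0.05, method="wilson"
    )
    # boundary counts give one-sided intervals
    if n_recovered_day3 == 0:
        lo = 0.0
    if n_recovered_day3 == n_injected:
        hi = 1.0
    return HomingEstimate(
        estimate=n_recovered_day3 / n_injected,
        ci=(float(lo), float(hi)),
        n_injected=int(n_injected),
        n_recovered=int(n_recovered_day3),
    )


def _extract_series(series, detection_limit=None):
    """Normalize a burden series to (days, burden) float arrays."""
    if isinstance(series, pd.DataFrame):
        if "day" not in series.columns:
            raise ValueError("burden series needs a 'day' column")
        for col in ("burden", "n_cells", "pct_blasts"):
            if col in series.columns:
                days = series["day"].to_numpy(float)
                burden = series[col].to_numpy(float)
                break
        else:
            raise ValueError(
                "burden series needs a 'burden', 'n_cells' or 'pct_blasts' column"
            )
    else:
        days, burden = series
        days = np.asarray(days, dtype=float)
        burden = np.asarray(burden, dtype=float)
    if days.shape != burden.shape or days.ndim != 1:
        raise ValueError("days and burden must be equal-length 1-D arrays")
    if np.any(burden < 0):
        raise ValueError("burdens must be non-negative")
    zero = burden == 0
    if zero.any():
        if detection_limit is None:
            raise ValueError(
                "zero burdens present; pass detection_limit to left-censor "
                "them at half the detection limit"
            )
        warnings.warn(
            f"{int(zero.sum())} zero burden(s) left-censored at "
            f"{detection_limit / 2:g} (half the detection limit)",
            stacklevel=3,
        )
        burden = np.where(zero, detection_limit / 2.0, burden)
    return days, burden


@dataclass
class GrowthResults:
    """Fitted growth model: estimates, uncertainty, AICc, diagnostics."""

    model: str
    params: dict[str, float]
    bse: dict[str, float]
    llf: float
    nobs: int
    n_params: int
    converged: bool
    days: np.ndarray
    burden: np.ndarray
    resid_log: np.ndarray
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        k = self.n_params + 1  # + residual variance
        aic = -2.0 * self.llf + 2.0 * k
        denom = self.nobs - k - 1
        if denom <= 0:
            return math.inf
        return aic + 2.0 * k * (k + 1) / denom

    @property
    def bic(self) -> float:
        k = self.n_params + 1
        return -2.0 * self.llf + k * math.log(self.nobs)

    def conf_int(self, param: str, alpha: float = 0.05) -> tuple[float, float]:
        """Wald interval; for positive parameters computed on the log scale."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        est, se = self.params[param], self.bse[param]
        if est > 0 and np.isfinite(se):
            # lognormal-style interval keeps the bound positive
            se_log = se / est
            return est * math.exp(-z * se_log), est * math.exp(z * se_log)
        return est - z * se, est + z * se

    def predict(self, days=None) -> np.ndarray:
        t = self.days if days is None else np.asarray(days, dtype=float)
        p = self.params
        if self.model == "exponential":
            return p["N0"] * np.exp(p["r"] * t)
        k_over_n0 = p["K"] / p["N0"]
        return p["K"] / (1.0 + (k_over_n0 - 1.0) * np.exp(-p["r"] * t))

    def summary(self) -> str:
        lines = [
            f"{self.model.capitalize()} growth fit ({self.nobs} observations)",
            f"  converged: {self.converged}",
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:>3} = {value:.6g}  (SE {se:.3g})")
        lines.append(
            f"  log-likelihood {self.llf:.4g}, AICc {self.aicc:.4g}, "
            f"BIC {self.bic:.4g}"
        )
        rms = float(np.sqrt(np.mean(self.resid_log**2)))
        lines.append(f"  RMS log-residual {rms:.3g}")
        for flag, value in self.flags.items():
            lines.append(f"  flag {flag}: {value}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed burden (log scale) with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.days, self.burden, "o", label="observed")
        grid = np.linspace(self.days.min(), self.days.max(), 200)
        ax.semilogy(grid, self.predict(grid), "-", label=f"{self.model} fit")
        ax.set_xlabel("day")
        ax.set_ylabel("burden")
        ax.legend()
        return ax


def _gaussian_llf(resid: np.ndarray) -> float:
    n = resid.size
    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0:
        sigma2 = 1e-300  # exact fit; keep the likelihood finite
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


class ExponentialGrowth:
    """Exponential growth model N(t) = N0*exp(r t), lognormal noise."""

    MIN_POINTS = 3

    def __init__(self, series, detection_limit: float | None = None):
        self.days, self.burden = _extract_series(series, detection_limit)
        if self.days.size < self.MIN_POINTS:
            raise ValueError(
                f"need at least {self.MIN_POINTS} time points, "
                f"got {self.days.size}"
            )

    def fit(self) -> GrowthResults:
        """OLS of log burden on day (the lognormal-noise MLE)."""
        import statsmodels.api as sm

        y = np.log(self.burden)
        X = sm.add_constant(self.days)
        res = sm.OLS(y, X).fit()
        log_n0, r = res.params
        se_log_n0, se_r = res.bse
        n0 = math.exp(log_n0)
        resid = y - res.fittedvalues
        return GrowthResults(
            model="exponential",
            params={"N0": n0, "r": float(r)},
            bse={"N0": n0 * float(se_log_n0), "r": float(se_r)},
            llf=_gaussian_llf(resid),
            nobs=self.days.size,
            n_params=2,
            converged=True,
            days=self.days,
            burden=self.burden,
            resid_log=resid,
        )


class LogisticGrowth:
    """Logistic growth model N(t) = K / (1 + (K/N0 - 1) e^{-r t}).

    Fitted by nonlinear least squares on log burden with multi-start
    initialization: N0 from the first observation, r from the early
    log-slope, K from a {2, 10, 100} x max-burden grid.  Parameters are
    optimized on the log scale to enforce positivity.  ``fixed_k`` pins the
    capacity (useful for the K -> infinity exponential limit).
    """

    MIN_POINTS = 4

    def __init__(
        self,
        series,
        detection_limit: float | None = None,
        fixed_k: float | None = None,
    ):
        self.days, self.burden = _extract_series(series, detection_limit)
        if self.days.size < self.MIN_POINTS:
            raise ValueError(
                f"need at least {self.MIN_POINTS} time points, "
                f"got {self.days.size}"
            )
        if fixed_k is not None and fixed_k <= 0:
            raise ValueError("fixed_k must be positive")
        self.fixed_k = fixed_k

    def _log_model(self, theta: np.ndarray) -> np.ndarray:
        if self.fixed_k is None:
            log_n0, log_r, log_k = theta
        else:
            log_n0, log_r = theta
            log_k = math.log(self.fixed_k)
        r = math.exp(log_r)
        # log N(t) = log K - logaddexp(0, log(K/N0 - 1) - r t), guarded K>N0
        ratio = math.exp(min(log_k - log_n0, 700.0))
        if ratio <= 1.0:
            # capacity below N0: degenerate, strongly penalized via residuals
            ratio = 1.0 + 1e-12
        log_b = math.log(ratio - 1.0)
        return log_k - np.logaddexp(0.0, log_b - r * self.days)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return np.log(self.burden) - self._log_model(theta)

    def _starts(self) -> list[np.ndarray]:
        n0_init = max(self.burden[0], 1e-12)
        head = slice(0, max(3, self.days.size // 3))
        with np.errstate(all="ignore"):
            slope = np.polyfit(self.days[head], np.log(self.burden[head]), 1)[0]
        r_init = slope if np.isfinite(slope) and slope > 1e-6 else 0.5
        starts = []
        if self.fixed_k is not None:
            starts.append(np.array([math.log(n0_init), math.log(r_init)]))
            return starts
        for mult in (2.0, 10.0, 100.0):
            k_init = mult * self.burden.max()
            starts.append(
                np.array(
                    [math.log(n0_init), math.log(r_init), math.log(k_init)]
                )
            )
        return starts

    def fit(self) -> GrowthResults:
        best = None
        for theta0 in self._starts():
            sol = optimize.least_squares(
                self._residuals, theta0, method="lm", max_nfev=2000
            )
            if best is None or sol.cost < best.cost:
                best = sol
        resid = self._residuals(best.x)
        n = self.days.size

        # Wald covariance of the log-parameters from the Jacobian
        sigma2 = float(np.sum(resid**2)) / max(n - best.x.size, 1)
        jtj = best.jac.T @ best.jac
        try:
            cov = sigma2 * np.linalg.inv(jtj)
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_log = np.full(best.x.size, np.inf)

        if self.fixed_k is None:
            log_n0, log_r, log_k = best.x
            k_val = math.exp(log_k)
            se_log_k = se_log[2]
        else:
            log_n0, log_r = best.x
            k_val = self.fixed_k
            se_log_k = 0.0
        n0, r = math.exp(log_n0), math.exp(log_r)
        params = {"N0": n0, "r": r, "K": k_val}
        bse = {
            "N0": n0 * float(se_log[0]),
            "r": r * float(se_log[1]),
            "K": k_val * float(se_log_k),
        }
        # capacity is unidentifiable when its log-SE is huge (early-phase data)
        k_identifiable = bool(np.isfinite(se_log_k) and se_log_k < 2.0)
        n_params = 2 if self.fixed_k is not None else 3
        return GrowthResults(
            model="logistic",
            params=params,
            bse=bse,
            llf=_gaussian_llf(resid),
            nobs=n,
            n_params=n_params,
            converged=bool(best.success),
            days=self.days,
            burden=self.burden,
            resid_log=resid,
            flags={"k_identifiable": k_identifiable},
        )


@dataclass
class ModelSelection:
    """Outcome of information-criterion model comparison."""

    table: pd.DataFrame
    best: str
    equivocal: bool
    criterion: str

    def __str__(self) -> str:
        verdict = "equivocal" if self.equivocal else self.best
        return f"model selection ({self.criterion}): {verdict}\n{self.table}"


def select_model(
    fits: list[GrowthResults], criterion: str = "aicc", tie_delta: float = 2.0
) -> ModelSelection:
    """Pick the model with the smallest AICc (or BIC).

    All fits must be on the identical series.  A gap below ``tie_delta``
    between the two best models is reported as equivocal rather than forcing
    a winner.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select a model")
    if criterion not in ("aicc", "bic"):
        raise ValueError("criterion must be 'aicc' or 'bic'")
    ref = fits[0]
    for other in fits[1:]:
        if not (
            np.array_equal(ref.days, other.days)
            and np.allclose(ref.burden, other.burden)
        ):
            raise ValueError("fits were made on different series")
    scores = [getattr(f, criterion) for f in fits]
    order = np.argsort(scores)
    table = pd.DataFrame(
        {
            "model": [fits[i].model for i in order],
            criterion: [scores[i] for i in order],
        }
    )
    table["delta"] = table[criterion] - table[criterion].iloc[0]
    equivocal = bool(len(table) > 1 and table["delta"].iloc[1] < tie_delta)
    return ModelSelection(
        table=table,
        best=str(table["model"].iloc[0]),
        equivocal=equivocal,
        criterion=criterion,
    )
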