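"""Single-hit Poisson limiting-dilution analysis of initiating-cell frequency.

A transplant of ``d`` cells engrafts iff it contains at least one
leukemia-initiating cell.  If each cell initiates independently with
frequency ``f``, the engraftment probability is

    P(engraft | d) = 1 - (1 - f)**d,

and the per-dose engraftment counts are binomial.  :class:`SingleHitModel`
maximizes the binomial log-likelihood over log f and inverts the profile
likelihood at the chi-square(1) cutoff (3.84/2 = 1.92 log-likelihood units)
for the 95% confidence interval — the standard machinery behind
limiting-dilution calculators.  Goodness of fit is a likelihood-ratio test
against the saturated per-dose model; :func:`compare_frequencies` tests
f_a = f_b between two assays by the same route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "SingleHitModel",
    "LDAResult",
    "FrequencyComparison",
    "call_engraftment",
    "fit_single_hit",
    "compare_frequencies",
    "DETECTION_THRESHOLD",
]

DETECTION_THRESHOLD = 5e5  # photons/s
_CHI2_95_HALF = chi2.ppf(0.95, df=1) / 2.0  # 1.92 profile cutoff
_LOG_F_MIN = math.log(1e-12)


def call_engraftment(photon_fluxes, threshold: float = DETECTION_THRESHOLD):
    """Binary engraftment calls from an imaging readout.

    A mouse is engrafted iff its flux is at or above the detection
    threshold (default 5e5 photons/s).
    """
    flux = np.asarray(photon_fluxes, dtype=float)
    if np.any(flux < 0):
        raise ValueError("photon fluxes must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return flux >= threshold


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"dose", "n_mice", "n_engrafted"}
    if not required.issubset(table.columns):
        raise ValueError(f"LDA table needs columns {sorted(required)}")
    if len(table) == 0:
        raise ValueError("LDA table is empty")
    t = table[["dose", "n_mice", "n_engrafted"]].astype(float)
    if np.any(t["dose"] <= 0):
        raise ValueError("doses must be positive")
    if np.any(t["n_mice"] <= 0):
        raise ValueError("n_mice must be positive")
    if np.any((t["n_engrafted"] < 0) | (t["n_engrafted"] > t["n_mice"])):
        raise ValueError("need 0 <= n_engrafted <= n_mice in every row")
    return t


@dataclass
class LDAResult:
    """MLE of the initiating-cell frequency with a profile-likelihood CI."""

    frequency: float
    ci: tuple[float, float]
    llf: float
    gof_p: float
    table: pd.DataFrame
    boundary: str | None = None  # None | 'all_negative' | 'all_positive'

    @property
    def one_in(self) -> str:
        """The frequency in the conventional '1/n cells' form."""
        if self.frequency <= 0:
            return "0"
        return f"1/{round(1.0 / self.frequency)}"

    def ci_one_in(self) -> str:
        lo, hi = self.ci
        hi_s = f"1/{round(1.0 / hi)}" if hi > 0 else "0"
        lo_s = f"1/{round(1.0 / lo)}" if lo > 0 else "0"
        return f"{hi_s} to {lo_s}"  # larger denominator = rarer

    def summary(self) -> str:
        lines = [
            f"Single-hit limiting dilution fit on {len(self.table)} dose(s), "
            f"{int(self.table['n_mice'].sum())} mice",
            f"  frequency f = {self.frequency:.4g} ({self.one_in} cells)",
            f"  95% CI [{self.ci[0]:.4g}, {self.ci[1]:.4g}] "
            f"({self.ci_one_in()} cells)",
            f"  log-likelihood {self.llf:.4g}",
        ]
        if np.isfinite(self.gof_p):
            lines.append(f"  single-hit goodness-of-fit p = {self.gof_p:.3g}")
        if self.boundary:
            lines.append(f"  boundary case: {self.boundary}")
        return "\n".join(lines)


class SingleHitModel:
    """Binomial single-hit model for a limiting-dilution table."""

    def __init__(self, table: pd.DataFrame):
        self.table = _validate_table(pd.DataFrame(table))
        self._dose = self.table["dose"].to_numpy()
        self._n = self.table["n_mice"].to_numpy()
        self._k = self.table["n_engrafted"].to_numpy()

    # -- likelihood ---------------------------------------------------------

    def loglik(self, f: float) -> float:
        """Binomial log-likelihood at frequency f (constants dropped)."""
        if f <= 0.0:
            return 0.0 if self._k.sum() == 0 else -math.inf
        if f >= 1.0:
            return 0.0 if (self._k == self._n).all() else -math.inf
        log_q = math.log1p(-f)  # log(1 - f)
        log_miss = self._dose * log_q  # log P(no engraftment)
        with np.errstate(divide="ignore"):
            log_hit = np.log(-np.expm1(log_miss))
        ll = self._k * log_hit + (self._n - self._k) * log_miss
        return float(ll.sum())

    def loglik_logf(self, log_f: float) -> float:
        return self.loglik(math.exp(log_f))

    # -- fitting ------------------------------------------------------------

    def fit(self) -> LDAResult:
        """MLE over log f with a profile-likelihood 95% CI.

        All-negative tables give f=0 with a one-sided upper bound;
        all-positive tables give f=1 with a one-sided lower bound; both are
        flagged.  Goodness of fit is an LR test against the saturated
        per-dose model (df = number of doses - 1).
        """
        total_k = self._k.sum()
        if total_k == 0:
            # l(f) = sum(n*d) log(1-f); solve l = -1.92 for the upper bound
            upper = -math.expm1(-_CHI2_95_HALF / float((self._n * self._dose).sum()))
            return LDAResult(
                frequency=0.0,
                ci=(0.0, upper),
                llf=0.0,
                gof_p=float("nan"),
                table=self.table,
                boundary="all_negative",
            )
        if (self._k == self._n).all():
            lower = self._profile_bound(0.0, math.log(1.0 - 1e-12), side="lower")
            return LDAResult(
                frequency=1.0,
                ci=(lower, 1.0),
                llf=0.0,
                gof_p=float("nan"),
                table=self.table,
                boundary="all_positive",
            )

        sol = optimize.minimize_scalar(
            lambda lf: -self.loglik_logf(lf),
            bounds=(_LOG_F_MIN, -1e-12),
            method="bounded",
            options={"xatol": 1e-12},
        )
        log_f_hat = float(sol.x)
        llf = self.loglik_logf(log_f_hat)
        f_hat = math.exp(log_f_hat)
        ci = (
            self._profile_bound(llf, log_f_hat, side="lower"),
            self._profile_bound(llf, log_f_hat, side="upper"),
        )
        return LDAResult(
            frequency=f_hat,
            ci=ci,
            llf=llf,
            gof_p=self._gof_p(llf),
            table=self.table,
        )

    def fit_wald(self) -> LDAResult:
        """Wald interval on log f (numeric curvature); for comparison only."""
        base = self.fit()
        if base.boundary:
            return base
        log_f = math.log(base.frequency)
        h = 1e-4
        curv = (
            self.loglik_logf(log_f + h)
            - 2 * self.loglik_logf(log_f)
            + self.loglik_logf(log_f - h)
        ) / h**2
        se = math.sqrt(-1.0 / curv) if curv < 0 else math.inf
        lo = math.exp(log_f - 1.959963984540054 * se)
        hi = min(math.exp(log_f + 1.959963984540054 * se), 1.0)
        return LDAResult(
            frequency=base.frequency,
            ci=(lo, hi),
            llf=base.llf,
            gof_p=base.gof_p,
            table=self.table,
        )

    def _profile_bound(self, llf_max: float, log_f_hat: float, side: str) -> float:
        """Invert llf(f_hat) - llf(f) = 1.92 on one side of the MLE."""

        def g(log_f: float) -> float:
            return llf_max - self.loglik_logf(log_f) - _CHI2_95_HALF

        if side == "lower":
            lo, hi = _LOG_F_MIN, log_f_hat
            if g(lo) < 0:  # cutoff never reached: bound at the floor
                return 0.0
        else:
            lo, hi = log_f_hat, math.log(1.0 - 1e-12)
            if g(hi) < 0:
                return 1.0
        try:
            root = optimize.brentq(g, lo, hi, xtol=1e-12)
        except ValueError:
            return 0.0 if side == "lower" else 1.0
        return math.exp(root)

    def _gof_p(self, llf: float) -> float:
        """LR test of the single-hit fit against the saturated model."""
        if len(self.table) < 2:
            return float("nan")
        with np.errstate(divide="ignore", invalid="ignore"):
            p_hat = self._k / self._n
            sat = np.where(self._k > 0, self._k * np.log(p_hat), 0.0) + np.where(
                self._n - self._k > 0, (self._n - self._k) * np.log(1 - p_hat), 0.0
            )
        stat = 2.0 * (float(sat.sum()) - llf)
        return float(chi2.sf(max(stat, 0.0), df=len(self.table) - 1))


def fit_single_hit(table: pd.DataFrame) -> LDAResult:
    """Convenience wrapper: ``SingleHitModel(table).fit()``."""
    return SingleHitModel(table).fit()


@dataclass
class FrequencyComparison:
    """Likelihood-ratio test of equal initiating-cell frequency."""

    statistic: float
    pvalue: float
    fit_a: LDAResult
    fit_b: LDAResult
    fit_pooled: LDAResult

    def __str__(self) -> str:
        return (
            f"LR test f_a = f_b: statistic {self.statistic:.4g}, "
            f"p = {self.pvalue:.3g} "
            f"(f_a {self.fit_a.one_in}, f_b {self.fit_b.one_in})"
        )


def compare_frequencies(a: pd.DataFrame, b: pd.DataFrame) -> FrequencyComparison:
    """Test f_a = f_b by a 1-df likelihood-ratio against the pooled fit."""
    model_a, model_b = SingleHitModel(a), SingleHitModel(b)
    pooled = SingleHitModel(
        pd.concat([model_a.table, model_b.table], ignore_index=True)
    )
    fit_a, fit_b, fit_p = model_a.fit(), model_b.fit(), pooled.fit()
    if fit_a.boundary or fit_b.boundary:
        warnings.warn(
            "boundary MLE in one of the assays; the chi-square reference for "
            "the LR statistic is only approximate",
            stacklevel=2,
        )
    stat = max(2.0 * (fit_a.llf + fit_b.llf - fit_p.llf), 0.0)
    return FrequencyComparison(
        statistic=stat,
        pvalue=float(chi2.sf(stat, df=1)),
        fit_a=fit_a,
        fit_b=fit_b,
        fit_pooled=fit_p,
    )
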