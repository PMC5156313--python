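"""Label-retention gating: reference calibration, division counting, classes.

A proliferation dye halves with every division, so the number of divisions a
cell has undergone since staining ("bisections") is ``log2(M0 / mfi)`` where
M0 is the reference intensity measured at day 3 after injection, once
bleaching has ceased and before proliferation begins.  Cells with at most
``lrc_max_bisections`` (default 3) bisections are label-retaining cells
(LRC, the dormant candidates), cells with at least ``nonlrc_min_bisections``
(default 7) have fully diluted the label (non-LRC), and everything in
between is "others".

Gating operates on raw MFI thresholds (``reference * 2**-k``), while the
per-cell division estimate rounds the log2 ratio to the nearest integer;
because a rounded count crosses an integer exactly where the MFI crosses the
corresponding threshold, the two views never disagree at the gate
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .simulate import FlowSample

__all__ = [
    "GateConfig",
    "GatedSample",
    "calibrate_reference",
    "count_divisions",
    "classify_cells",
    "lrc_kinetics",
]

_STATISTICS = ("geometric_mean", "median", "mode", "maximum")


@dataclass(frozen=True)
class GateConfig:
    """Gate thresholds in bisection units and the reference statistic."""

    lrc_max_bisections: int = 3
    nonlrc_min_bisections: int = 7
    reference_statistic: str = "geometric_mean"

    def __post_init__(self) -> None:
        if not (0 <= self.lrc_max_bisections < self.nonlrc_min_bisections):
            raise ValueError(
                "require 0 <= lrc_max_bisections < nonlrc_min_bisections"
            )
        if self.reference_statistic not in _STATISTICS:
            raise ValueError(
                f"reference_statistic must be one of {_STATISTICS}"
            )


@dataclass
class GatedSample:
    """Classification of one flow sample.

    labels: per-cell class in {'LRC', 'others', 'nonLRC'};
    divisions_est: per-cell rounded bisection count;
    counts: class -> cell count; lrc_fraction with a Wilson 95% CI.
    """

    labels: pd.Series
    divisions_est: pd.Series
    reference: float
    gate: GateConfig
    counts: dict[str, int]
    n: int
    lrc_fraction: float
    lrc_ci: tuple[float, float]
    day: int | None = None

    @property
    def is_empty(self) -> bool:
        return self.n == 0


def _as_mfi(sample) -> np.ndarray:
    if isinstance(sample, FlowSample):
        return sample.mfi
    if isinstance(sample, pd.DataFrame):
        return sample["measured_mfi"].to_numpy(float)
    return np.asarray(sample, dtype=float)


def calibrate_reference(day3_sample, statistic: str = "geometric_mean") -> float:
    """Estimate the pre-proliferation reference MFI from a day-3 sample.

    The geometric mean is the default: under median-preserving lognormal
    noise it is a consistent estimator of the true M0.  The distribution
    mode (kernel-density argmax on the log scale) and the maximum are
    available but noise-fragile.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    mfi = _as_mfi(day3_sample)
    if mfi.size == 0:
        raise ValueError("day-3 sample is empty; cannot calibrate a reference")
    bad = np.flatnonzero(~(mfi > 0))
    if bad.size:
        raise ValueError(
            f"nonpositive MFI values at sample positions {bad[:10].tolist()}"
        )
    log_mfi = np.log(mfi)
    if statistic == "geometric_mean":
        return float(np.exp(log_mfi.mean()))
    if statistic == "median":
        return float(np.median(mfi))
    if statistic == "maximum":
        return float(mfi.max())
    # mode: KDE argmax on the log scale (robust to the multiplicative noise)
    if mfi.size == 1 or np.allclose(log_mfi, log_mfi[0]):
        return float(mfi[0])
    kde = stats.gaussian_kde(log_mfi)
    grid = np.linspace(log_mfi.min(), log_mfi.max(), 512)
    return float(np.exp(grid[np.argmax(kde(grid))]))


def count_divisions(mfi, reference: float):
    """Estimated bisection count: round(log2(reference/mfi)), floored at 0."""
    if reference <= 0:
        raise ValueError("reference MFI must be positive")
    arr = np.asarray(mfi, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("MFI values must be positive")
    k = np.rint(np.log2(reference / arr)).astype(np.int64)
    k = np.maximum(k, 0)
    if np.isscalar(mfi) or arr.ndim == 0:
        return int(k)
    return k


def classify_cells(
    sample, reference: float, gate: GateConfig | None = None
) -> GatedSample:
    """Classify every cell into LRC / others / nonLRC by raw MFI thresholds.

    LRC iff mfi >= reference * 2**-lrc_max_bisections (boundary inclusive);
    nonLRC iff mfi <= reference * 2**-nonlrc_min_bisections (inclusive);
    otherwise others.  The LRC fraction gets a 95% Wilson interval.  An
    empty sample yields an explicit empty result (n=0, NaN fraction) rather
    than an error.
    """
    gate = gate or GateConfig()
    if reference <= 0:
        raise ValueError("reference MFI must be positive")
    mfi = _as_mfi(sample)
    day = sample.day if isinstance(sample, FlowSample) else None
    if mfi.size == 0:
        return GatedSample(
            labels=pd.Series([], dtype=object),
            divisions_est=pd.Series([], dtype=np.int64),
            reference=reference,
            gate=gate,
            counts={"LRC": 0, "others": 0, "nonLRC": 0},
            n=0,
            lrc_fraction=float("nan"),
            lrc_ci=(float("nan"), float("nan")),
            day=day,
        )
    if np.any(~(mfi > 0)):
        raise ValueError("MFI values must be positive")
    lrc_thresh = reference * 2.0 ** -gate.lrc_max_bisections
    nonlrc_thresh = reference * 2.0 ** -gate.nonlrc_min_bisections
    labels = np.where(
        mfi >= lrc_thresh, "LRC", np.where(mfi <= nonlrc_thresh, "nonLRC", "others")
    )
    counts = {
        cls: int((labels == cls).sum()) for cls in ("LRC", "others", "nonLRC")
    }
    n = mfi.size
    lo, hi = proportion_confint(counts["LRC"], n, alpha=0.05, method="wilson")
    return GatedSample(
        labels=pd.Series(labels),
        divisions_est=pd.Series(count_divisions(mfi, reference)),
        reference=reference,
        gate=gate,
        counts=counts,
        n=n,
        lrc_fraction=counts["LRC"] / n,
        lrc_ci=(float(lo), float(hi)),
        day=day,
    )


def lrc_kinetics(samples) -> pd.DataFrame:
    """Tabulate LRC counts and fractions over time.

    ``samples`` is an iterable of (day, GatedSample) pairs, or of
    GatedSamples whose ``day`` attribute is set.  Duplicate days are
    rejected; rows come back in day order.
    """
    rows = []
    for item in samples:
        if isinstance(item, GatedSample):
            day, gs = item.day, item
            if day is None:
                raise ValueError("GatedSample without a day; pass (day, sample)")
        else:
            day, gs = item
        rows.append(
            {
                "day": day,
                "n": gs.n,
                "lrc_count": gs.counts["LRC"],
                "lrc_fraction": gs.lrc_fraction,
                "ci_low": gs.lrc_ci[0],
                "ci_high": gs.lrc_ci[1],
            }
        )
    if not rows:
        raise ValueError("need at least one gated sample")
    table = pd.DataFrame(rows)
    if table["day"].duplicated().any():
        dupes = sorted(table.loc[table["day"].duplicated(), "day"].unique())
        raise ValueError(f"duplicate days in kinetics input: {dupes}")
    return table.sort_values("day", ignore_index=True)
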