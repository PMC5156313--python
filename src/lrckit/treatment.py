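"""Differential drug response of dormant (label-retaining) vs cycling cells.

Chemotherapy preferentially kills proliferating cells.  Comparing treated
and control animals gives per-gate-class survival fractions; the headline
statistic scales the drug's elimination of LRC against its elimination of
non-LRC (set to 100%), so 10% means the drug removed label-retaining cells
ten-fold less efficiently.  Because LRC survive, their proportion of the
residual leukemia rises (enrichment fold), and sufficiently treated animals
drop below the minimal-residual-disease threshold of 1% blasts in marrow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SurvivalFraction",
    "DrugEffectResult",
    "survival_fractions",
    "relative_drug_effect",
    "call_mrd",
    "MRDCall",
    "lrc_enrichment",
    "EnrichmentFold",
    "drug_effect",
    "MRD_THRESHOLD_PCT",
    "MOLECULAR_REMISSION_PCT",
]

MRD_THRESHOLD_PCT = 1.0
MOLECULAR_REMISSION_PCT = 0.1
_Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class SurvivalFraction:
    """treated/control count ratio for one gate class, with a 95% CI.

    The CI treats the two counts as independent Poisson and conditions on
    their total, turning the ratio into a transformed binomial proportion
    (Wilson interval on treated/(treated+control)).
    """

    cls: str
    control: int
    treated: int
    fraction: float
    ci: tuple[float, float]


def _poisson_ratio_ci(treated: int, control: int) -> tuple[float, float]:
    lo_p, hi_p = proportion_confint(
        treated, treated + control, alpha=0.05, method="wilson"
    )
    to_ratio = lambda p: p / (1.0 - p) if p < 1.0 else math.inf
    return (to_ratio(float(lo_p)), to_ratio(float(hi_p)))


def survival_fractions(
    control: dict[str, int], treated: dict[str, int]
) -> dict[str, SurvivalFraction]:
    """Per-class survival (treated count / control count).

    ``control`` and ``treated`` map gate class names (e.g. 'LRC', 'others',
    'nonLRC') to cell counts; a ``GatedSample.counts`` dict works directly.
    Classes with a zero control count are excluded with a warning.
    """
    out: dict[str, SurvivalFraction] = {}
    for cls, n_control in control.items():
        if cls not in treated:
            continue
        n_treated = int(treated[cls])
        n_control = int(n_control)
        if n_control < 0 or n_treated < 0:
            raise ValueError("counts must be non-negative")
        if n_control == 0:
            warnings.warn(
                f"class {cls!r} has zero control count; excluded", stacklevel=2
            )
            continue
        out[cls] = SurvivalFraction(
            cls=cls,
            control=n_control,
            treated=n_treated,
            fraction=n_treated / n_control,
            ci=_poisson_ratio_ci(n_treated, n_control),
        )
    return out


def relative_drug_effect(lrc_survival: float, nonlrc_survival: float) -> float:
    """Drug effect on LRC as a percentage of the non-LRC effect (100%).

    Effect = elimination = 1 - survival; returns
    100 * (1 - lrc_survival) / (1 - nonlrc_survival).  Equal eliminations
    give 100; untouched LRC give 0; 1.0 corresponds to a hundred-fold less
    efficient elimination of LRC.
    """
    if lrc_survival < 0 or nonlrc_survival < 0:
        raise ValueError("survival fractions must be non-negative")
    elim_nonlrc = 1.0 - nonlrc_survival
    if elim_nonlrc <= 0:
        raise ValueError(
            "non-LRC elimination is zero; the relative effect is undefined"
        )
    return 100.0 * (1.0 - lrc_survival) / elim_nonlrc


@dataclass(frozen=True)
class MRDCall:
    """Residual-disease call for one animal."""

    pct_blasts: float
    is_mrd: bool
    tier: str  # 'overt' | 'mrd' | 'molecular-remission-like'


def call_mrd(
    pct_blasts: float,
    threshold: float = MRD_THRESHOLD_PCT,
    molecular_threshold: float = MOLECULAR_REMISSION_PCT,
) -> MRDCall:
    """Call minimal residual disease from the marrow blast percentage.

    MRD iff pct_blasts < threshold (strictly below 1% by default); burdens
    below the molecular threshold (0.1%) are additionally tiered as
    molecular-remission-like.
    """
    if not (0.0 <= pct_blasts <= 100.0):
        raise ValueError("pct_blasts must lie in [0, 100]")
    if not (0.0 < molecular_threshold <= threshold):
        raise ValueError("need 0 < molecular_threshold <= threshold")
    is_mrd = pct_blasts < threshold
    if not is_mrd:
        tier = "overt"
    elif pct_blasts < molecular_threshold:
        tier = "molecular-remission-like"
    else:
        tier = "mrd"
    return MRDCall(pct_blasts=float(pct_blasts), is_mrd=is_mrd, tier=tier)


@dataclass(frozen=True)
class EnrichmentFold:
    """Post/pre fold-change of the LRC proportion, delta-method 95% CI."""

    fold: float
    ci: tuple[float, float] | None
    pre_fraction: float
    post_fraction: float


def lrc_enrichment(
    pre_fraction: float,
    post_fraction: float,
    pre_n: int | None = None,
    post_n: int | None = None,
) -> EnrichmentFold:
    """Fold-enrichment of the LRC proportion after treatment.

    fold = post_fraction / pre_fraction.  When the sample sizes behind the
    two binomial fractions are supplied, a delta-method CI on the log fold
    is attached: var(log fold) ~ (1-p1)/(n1 p1) + (1-p2)/(n2 p2).
    """
    if pre_fraction <= 0:
        raise ValueError("pre_fraction must be positive")
    if post_fraction < 0:
        raise ValueError("post_fraction must be non-negative")
    fold = post_fraction / pre_fraction
    ci = None
    if pre_n is not None and post_n is not None and post_fraction > 0:
        var_log = (1.0 - pre_fraction) / (pre_n * pre_fraction) + (
            1.0 - post_fraction
        ) / (post_n * post_fraction)
        half = _Z95 * math.sqrt(var_log)
        ci = (fold * math.exp(-half), fold * math.exp(half))
    return EnrichmentFold(
        fold=fold, ci=ci, pre_fraction=pre_fraction, post_fraction=post_fraction
    )


@dataclass
class DrugEffectResult:
    """Combined drug-response summary for a control/treated pair."""

    survival: dict[str, SurvivalFraction]
    relative_effect_pct: float | None
    elimination_fold: float | None
    enrichment: EnrichmentFold | None
    mrd: MRDCall | None

    def summary(self) -> str:
        lines = ["Drug effect summary"]
        for cls, sf in self.survival.items():
            lines.append(
                f"  {cls}: survival {sf.fraction:.3g} "
                f"(95% CI {sf.ci[0]:.3g}-{sf.ci[1]:.3g}, "
                f"{sf.treated}/{sf.control})"
            )
        if self.relative_effect_pct is not None:
            lines.append(
                f"  relative drug effect on LRC vs non-LRC (100%): "
                f"{self.relative_effect_pct:.3g}%"
            )
        if self.elimination_fold is not None:
            lines.append(
                f"  elimination fold-difference (non-LRC / LRC): "
                f"{self.elimination_fold:.3g}x"
            )
        if self.enrichment is not None:
            lines.append(f"  LRC enrichment fold: {self.enrichment.fold:.3g}")
        if self.mrd is not None:
            lines.append(
                f"  residual burden {self.mrd.pct_blasts:.3g}% -> {self.mrd.tier}"
            )
        return "\n".join(lines)


def drug_effect(
    control_counts: dict[str, int],
    treated_counts: dict[str, int],
    treated_pct_blasts: float | None = None,
) -> DrugEffectResult:
    """Full drug-response readout from per-class counts of both arms.

    Computes per-class survival, the relative drug effect on LRC (non-LRC =
    100%), the elimination fold-difference, LRC enrichment among surviving
    cells, and (if a burden is given) the MRD call.
    """
    survival = survival_fractions(control_counts, treated_counts)
    rel = fold = None
    if "LRC" in survival and "nonLRC" in survival:
        s_lrc = survival["LRC"].fraction
        s_non = survival["nonLRC"].fraction
        if s_non < 1.0:
            rel = relative_drug_effect(s_lrc, s_non)
            elim_lrc = 1.0 - s_lrc
            fold = (1.0 - s_non) / elim_lrc if elim_lrc > 0 else math.inf

    enrichment = None
    pre_total = sum(control_counts.values())
    post_total = sum(treated_counts.values())
    if pre_total > 0 and post_total > 0 and control_counts.get("LRC", 0) > 0:
        enrichment = lrc_enrichment(
            control_counts["LRC"] / pre_total,
            treated_counts.get("LRC", 0) / post_total,
            pre_n=pre_total,
            post_n=post_total,
        )
    mrd = call_mrd(treated_pct_blasts) if treated_pct_blasts is not None else None
    return DrugEffectResult(
        survival=survival,
        relative_effect_pct=rel,
        elimination_fold=fold,
        enrichment=enrichment,
        mrd=mrd,
    )
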