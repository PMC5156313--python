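"""Stochastic simulator of label-diluting, niche-limited leukemia growth.

The generator produces the synthetic counterpart of a xenograft dormancy
experiment: cells are injected intravenously, a small sample-specific
fraction homes to the bone marrow, and the homed population grows
logistically toward a niche carrying capacity.  Every division halves a
proliferation-sensitive dye (CFSE-like), so the division count of each cell
is encoded in its fluorescence.  A rare compartment of dormant cells divides
slowly or not at all and therefore retains the label over weeks; dormancy is
a memoryless, reversible state, so re-transplantation regenerates the same
dormant fraction from formerly cycling cells.

Time advances in discrete steps (default one day) with binomial thinning:
each active cell divides with probability ``r*dt*(1 - N/K)`` (floored at 0),
dies with the per-step equivalent of the daily death probability ``d``, and
switches compartment with the per-step wake/sleep probabilities.  Cytotoxic
treatment preferentially kills cells that divided during the preceding day,
which is what makes dormant, label-retaining cells drug resistant in this
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TreatmentPlan",
    "Cohort",
    "FlowSample",
    "ExpressionMatrix",
    "EmptyCohortError",
    "PopulationCapError",
    "simulate_engraftment",
    "measure_flow",
    "apply_treatment",
    "simulate_lda",
    "simulate_expression",
    "retransplant",
]

DEFAULT_HARD_CAP = 20_000_000
DETECTION_THRESHOLD = 5e5  # photons/s, imaging engraftment call


class EmptyCohortError(ValueError):
    """Raised when an operation requires at least one (alive) cell."""


class PopulationCapError(RuntimeError):
    """Raised when the simulated population exceeds the configured hard cap."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one in vivo growth experiment.

    Defaults describe the reference study conditions: 1e5 cells injected, a
    homing efficiency of 0.5% (sample-specific values span more than two
    orders of magnitude, 1e-4 to 1e-1), logistic growth at r = 0.9/day toward
    a marrow capacity of 1e6 cells, a 1% dormant seed that neither divides
    nor (by default) wakes during a three-week experiment, and a
    post-bleaching day-3 label intensity of 1000 units measured with a 20%
    lognormal CV.

    Attributes
    ----------
    n_injected : number of cells injected intravenously.
    homing_prob : probability a single injected cell lodges in the marrow.
    r : per-day division rate of active cells at low density (r*dt <= 1).
    K : niche carrying capacity in cells; division probability scales by
        (1 - N/K).  May be ``math.inf`` for pure exponential growth.
    d : per-day death probability.
    p_dormant_seed : probability an engrafting cell starts dormant.
    p_wake : per-day dormant -> active switch probability.
    p_sleep : per-day active -> dormant switch probability.
    dormant_div_rate : per-day division probability of dormant cells (<< r).
    m0 : true post-bleaching day-3 label MFI (arbitrary units).
    cv_mfi : lognormal coefficient of variation of measured MFI.
    photons_per_cell : bioluminescence flux per cell.
    detection_threshold : flux (photons/s) above which engraftment is called.
    n_days : experiment horizon in days.
    lag_days : days after injection before any division occurs; the day-3
        reference sample is taken inside this window, so it reflects zero
        divisions as in the calibration protocol.
    dt : step size in days (1/dt must be an integer).
    hard_cap : abort threshold on population size.
    seed : RNG seed.
    """

    n_injected: int = 100_000
    homing_prob: float = 0.005
    r: float = 0.9
    K: float = 1e6
    d: float = 0.0
    p_dormant_seed: float = 0.01
    p_wake: float = 0.0
    p_sleep: float = 0.0
    dormant_div_rate: float = 0.0
    m0: float = 1000.0
    cv_mfi: float = 0.2
    photons_per_cell: float = 100.0
    detection_threshold: float = DETECTION_THRESHOLD
    n_days: int = 21
    lag_days: int = 3
    dt: float = 1.0
    hard_cap: int = DEFAULT_HARD_CAP
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_injected < 0:
            raise ValueError("n_injected must be non-negative")
        if not (0.0 < self.homing_prob <= 1.0):
            raise ValueError("homing_prob must lie in (0, 1]")
        for name in ("d", "p_dormant_seed", "p_wake", "p_sleep"):
            _check_prob(name, getattr(self, name))
        if self.d >= 1.0:
            raise ValueError("d must lie in [0, 1)")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.dormant_div_rate < 0 or self.dormant_div_rate * self.dt > 1:
            raise ValueError("dormant_div_rate*dt must lie in [0, 1]")
        if self.r * self.dt > 1.0 + 1e-12:
            raise ValueError(
                f"r*dt = {self.r * self.dt:g} exceeds 1; shrink dt or r"
            )
        if not self.K > 0:
            raise ValueError("K must be positive")
        if self.K < self.n_injected * self.homing_prob:
            raise ValueError("K must be at least the expected homed count")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if self.cv_mfi < 0:
            raise ValueError("cv_mfi must be non-negative")
        if self.n_days < 0 or self.lag_days < 0:
            raise ValueError("n_days and lag_days must be non-negative")
        if self.dt <= 0 or abs(round(1.0 / self.dt) - 1.0 / self.dt) > 1e-9:
            raise ValueError("1/dt must be a positive integer")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TreatmentPlan:
    """Schedule of cytotoxic treatments.

    Each entry is ``(day, kill_prob_divided, kill_prob_undivided)``: on that
    day, cells that divided within the preceding day die with the first
    probability, others with the second.  Proliferation-dependent kill means
    kill_prob_divided >= kill_prob_undivided.
    """

    schedule: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        norm = tuple(
            (int(day), float(kd), float(ku)) for day, kd, ku in self.schedule
        )
        object.__setattr__(self, "schedule", norm)
        days = [day for day, _, _ in norm]
        if len(set(days)) != len(days):
            raise ValueError("duplicate treatment days in schedule")
        for day, kd, ku in norm:
            if day < 0:
                raise ValueError("treatment days must be non-negative")
            _check_prob("kill_prob_divided", kd)
            _check_prob("kill_prob_undivided", ku)
            if kd < ku:
                raise ValueError(
                    "kill_prob_divided must be >= kill_prob_undivided "
                    "(proliferation-dependent kill)"
                )

    @property
    def days(self) -> list[int]:
        return [day for day, _, _ in self.schedule]


@dataclass
class Cohort:
    """A simulated cell population at a single time point.

    ``cells`` has one row per cell with columns: cell_id, divisions,
    compartment ('dormant'/'active'), alive, divided_last_day, true_mfi
    (= m0 * 2**-divisions).
    """

    cells: pd.DataFrame
    m0: float
    day: int = 0

    @classmethod
    def from_arrays(
        cls,
        divisions: np.ndarray,
        dormant: np.ndarray,
        divided_last: np.ndarray,
        m0: float,
        day: int,
    ) -> "Cohort":
        n = divisions.size
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(n, dtype=np.int64),
                "divisions": divisions.astype(np.int64),
                "compartment": np.where(dormant, "dormant", "active"),
                "alive": np.ones(n, dtype=bool),
                "divided_last_day": divided_last.astype(bool),
                "true_mfi": m0 * np.exp2(-divisions.astype(float)),
            }
        )
        return cls(cells=cells, m0=m0, day=day)

    @property
    def n_alive(self) -> int:
        return int(self.cells["alive"].sum())

    def alive(self) -> pd.DataFrame:
        return self.cells[self.cells["alive"]]

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class FlowSample:
    """Per-cell label readout for one animal and time point.

    ``data`` columns: cell_id, measured_mfi, divisions_truth,
    compartment_truth.  ``reference`` holds the calibrated day-3 MFI once
    gating.calibrate_reference has been applied.
    """

    data: pd.DataFrame
    day: int = 0
    reference: float | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def mfi(self) -> np.ndarray:
        return self.data["measured_mfi"].to_numpy(float)


@dataclass
class ExpressionMatrix:
    """Synthetic count matrix with group labels and planted truth.

    counts: genes x cells integer DataFrame; groups: per-cell label Series
    aligned with counts columns; truth: per-gene planted log2 fold-changes
    (group A over group B; 0 for unplanted genes).
    """

    counts: pd.DataFrame
    groups: pd.Series
    truth: pd.DataFrame


def _per_step(p_day: float, dt: float) -> float:
    """Per-step probability equivalent to a per-day probability."""
    if dt == 1.0:
        return p_day
    return 1.0 - (1.0 - p_day) ** dt


def simulate_engraftment(
    config: SimConfig,
    plan: TreatmentPlan | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Run one engraftment experiment.

    Returns the final-day :class:`Cohort` and a burden series DataFrame with
    columns ``day``, ``n_cells`` and ``pct_blasts`` (100*N/K, capped at 100,
    reading K as total accessible marrow cellularity).

    Dynamics per step: division (active probability ``r*dt*(1-N/K)`` floored
    at 0, dormant probability ``dormant_div_rate*dt``; both zero during the
    post-injection lag), then death, then compartment switching, then any
    scheduled treatment for the day being completed.  Both daughters of a
    division carry the parent's count plus one.  Cells dying inside the loop
    are dropped; standalone :func:`apply_treatment` instead marks them dead
    so survival fractions remain computable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if plan is not None:
        bad = [day for day in plan.days if day > config.n_days]
        if bad:
            raise ValueError(
                f"treatment days {bad} fall beyond the {config.n_days}-day horizon"
            )
    kill_by_day = (
        {day: (kd, ku) for day, kd, ku in plan.schedule} if plan else {}
    )

    n0 = int(rng.binomial(config.n_injected, config.homing_prob))
    divisions = np.zeros(n0, dtype=np.int64)
    dormant = rng.random(n0) < config.p_dormant_seed
    divided_last = np.zeros(n0, dtype=bool)

    steps_per_day = int(round(1.0 / config.dt))
    d_step = _per_step(config.d, config.dt)
    wake_step = _per_step(config.p_wake, config.dt)
    sleep_step = _per_step(config.p_sleep, config.dt)

    records = [(0, n0)]
    for day in range(1, config.n_days + 1):
        for _ in range(steps_per_day):
            n = divisions.size
            if n == 0:
                break
            if day <= config.lag_days:
                p_active = 0.0
                p_dorm = 0.0
            else:
                p_active = min(
                    max(config.r * config.dt * (1.0 - n / config.K), 0.0), 1.0
                )
                p_dorm = config.dormant_div_rate * config.dt
            p_div = np.where(dormant, p_dorm, p_active)
            div = rng.random(n) < p_div
            n_keep = int((~div).sum())
            divisions = np.concatenate(
                [divisions[~div], np.repeat(divisions[div] + 1, 2)]
            )
            dormant = np.concatenate([dormant[~div], np.repeat(dormant[div], 2)])
            divided_last = np.zeros(divisions.size, dtype=bool)
            divided_last[n_keep:] = True
            if d_step > 0 and divisions.size:
                survive = rng.random(divisions.size) >= d_step
                divisions = divisions[survive]
                dormant = dormant[survive]
                divided_last = divided_last[survive]
            if (wake_step > 0 or sleep_step > 0) and divisions.size:
                u = rng.random(divisions.size)
                wake = dormant & (u < wake_step)
                sleep = ~dormant & (u < sleep_step)
                dormant = (dormant & ~wake) | sleep
            if divisions.size > config.hard_cap:
                raise PopulationCapError(
                    f"population {divisions.size} exceeded hard cap "
                    f"{config.hard_cap} on day {day}; raise hard_cap or "
                    "lower r/K/n_injected"
                )
        if day in kill_by_day and divisions.size:
            kd, ku = kill_by_day[day]
            p_kill = np.where(divided_last, kd, ku)
            survive = rng.random(divisions.size) >= p_kill
            divisions = divisions[survive]
            dormant = dormant[survive]
            divided_last = divided_last[survive]
        records.append((day, divisions.size))

    burden = pd.DataFrame(records, columns=["day", "n_cells"])
    burden["pct_blasts"] = np.minimum(
        100.0 * burden["n_cells"] / config.K, 100.0
    )
    cohort = Cohort.from_arrays(
        divisions, dormant, divided_last, config.m0, config.n_days
    )
    return cohort, burden


def measure_flow(
    cohort: Cohort,
    cv_mfi: float | None = None,
    seed: int | None = None,
    allow_empty: bool = False,
) -> FlowSample:
    """Read out the label intensity of every alive cell.

    Measurement noise is lognormal and median-preserving: with coefficient
    of variation ``cv``, measured = true * exp(sigma*Z) where
    sigma^2 = ln(1 + cv^2), so the geometric mean of replicate readouts of a
    cell equals its true MFI.  cv_mfi=0 gives the exact readout.  An empty
    cohort raises :class:`EmptyCohortError` unless ``allow_empty`` is set,
    distinguishing accidental empties from an explicit zero-cell request.
    """
    if cv_mfi is None:
        cv_mfi = 0.0
    if cv_mfi < 0:
        raise ValueError("cv_mfi must be non-negative")
    alive = cohort.alive()
    if alive.empty and not allow_empty:
        raise EmptyCohortError(
            "cohort has no alive cells; pass allow_empty=True to accept an "
            "empty flow sample"
        )
    rng = np.random.default_rng(seed)
    true_mfi = alive["true_mfi"].to_numpy(float)
    if cv_mfi == 0.0:
        measured = true_mfi.copy()
    else:
        sigma = math.sqrt(math.log1p(cv_mfi**2))
        measured = true_mfi * np.exp(sigma * rng.standard_normal(true_mfi.size))
    data = pd.DataFrame(
        {
            "cell_id": alive["cell_id"].to_numpy(),
            "measured_mfi": measured,
            "divisions_truth": alive["divisions"].to_numpy(),
            "compartment_truth": alive["compartment"].to_numpy(),
        }
    )
    return FlowSample(data=data, day=cohort.day)


def apply_treatment(
    cohort: Cohort, plan: TreatmentPlan, seed: int | None = None
) -> Cohort:
    """Apply a treatment plan to a cohort snapshot.

    Each scheduled event draws independent deaths: cells flagged as having
    divided within the preceding day die with kill_prob_divided, others with
    kill_prob_undivided.  Killed cells are kept with ``alive=False`` so
    per-class survival fractions can be computed against a control cohort.
    """
    for day in plan.days:
        if day < cohort.day:
            raise ValueError(
                f"treatment day {day} precedes the cohort's day {cohort.day}"
            )
    rng = np.random.default_rng(seed)
    cells = cohort.cells.copy()
    divided = cells["divided_last_day"].to_numpy(bool)
    for _, kd, ku in plan.schedule:
        alive = cells["alive"].to_numpy(bool)
        p_kill = np.where(divided, kd, ku)
        die = alive & (rng.random(len(cells)) < p_kill)
        cells.loc[die, "alive"] = False
    return Cohort(cells=cells, m0=cohort.m0, day=cohort.day)


def simulate_lda(
    f_true: float,
    doses: list[int],
    mice_per_dose: int,
    config: SimConfig | None = None,
    seed: int | None = None,
    emit_flux: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a limiting-dilution transplantation assay.

    Under the single-hit model each transplanted cell is an initiator with
    probability ``f_true`` independently, so a mouse receiving ``d`` cells
    engrafts with probability 1 - (1 - f_true)**d.  Returns a table with
    columns dose, n_mice, n_engrafted; with ``emit_flux`` also a per-mouse
    photon-flux table (engrafted mice draw flux above the detection
    threshold, non-engrafted below) for the imaging-readout path.
    """
    if not (0.0 <= f_true <= 1.0):
        raise ValueError("f_true must lie in [0, 1]")
    if mice_per_dose <= 0:
        raise ValueError("mice_per_dose must be positive")
    doses = [int(d) for d in doses]
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive cell counts")
    rng = np.random.default_rng(seed)
    threshold = config.detection_threshold if config else DETECTION_THRESHOLD

    rows = []
    flux_rows = []
    for dose in doses:
        p = -math.expm1(dose * math.log1p(-f_true)) if f_true < 1.0 else 1.0
        engrafted = rng.random(mice_per_dose) < p
        rows.append((dose, mice_per_dose, int(engrafted.sum())))
        if emit_flux:
            # Engrafted mice land 0.5-2 decades above threshold, others below.
            decades = rng.uniform(0.5, 2.0, mice_per_dose)
            flux = np.where(
                engrafted, threshold * 10.0**decades, threshold * 10.0**-decades
            )
            for i in range(mice_per_dose):
                flux_rows.append((dose, i, flux[i]))
    table = pd.DataFrame(rows, columns=["dose", "n_mice", "n_engrafted"])
    if emit_flux:
        fluxes = pd.DataFrame(flux_rows, columns=["dose", "mouse", "flux"])
        return table, fluxes
    return table


def simulate_expression(
    n_genes: int,
    n_cells_per_group: int,
    planted: dict[str, float] | None = None,
    dispersion: float = 0.5,
    seed: int | None = None,
    library_factor_a: float = 1.0,
    base_log_mean: float = 1.5,
    base_log_sd: float = 1.0,
) -> ExpressionMatrix:
    """Draw a two-group negative-binomial count matrix with planted effects.

    Genes are named g0000..; planted maps gene name -> log2 fold-change of
    group A (the dormant-like group) over group B.  ``library_factor_a`` < 1
    scales every group-A mean, emulating the globally reduced RNA content of
    dormant cells.  Counts follow NB with variance mu + dispersion*mu^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_genes <= 0 or n_cells_per_group < 1:
        raise ValueError("need at least one gene and one cell per group")
    if library_factor_a <= 0:
        raise ValueError("library_factor_a must be positive")
    planted = dict(planted or {})
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    unknown = sorted(set(planted) - gene_set)
    if unknown:
        raise ValueError(f"planted genes outside the gene universe: {unknown}")
    for g, lfc in planted.items():
        if not np.isfinite(lfc):
            raise ValueError(f"planted log2FC for {g} must be finite")

    rng = np.random.default_rng(seed)
    base_mu = np.exp(rng.normal(base_log_mean, base_log_sd, n_genes))
    lfc = np.array([planted.get(g, 0.0) for g in genes])
    mu_a = base_mu * np.exp2(lfc) * library_factor_a
    mu_b = base_mu

    size = 1.0 / dispersion  # NB2: var = mu + mu^2/size

    def draw(mu: np.ndarray, n_cells: int) -> np.ndarray:
        mu2 = np.repeat(mu[:, None], n_cells, axis=1)
        return rng.negative_binomial(size, size / (size + mu2))

    counts = np.concatenate(
        [draw(mu_a, n_cells_per_group), draw(mu_b, n_cells_per_group)], axis=1
    )
    cells = [f"A{i:03d}" for i in range(n_cells_per_group)] + [
        f"B{i:03d}" for i in range(n_cells_per_group)
    ]
    groups = pd.Series(
        ["A"] * n_cells_per_group + ["B"] * n_cells_per_group,
        index=cells,
        name="group",
    )
    truth = pd.DataFrame(
        {"gene": genes, "planted_log2fc": lfc, "planted": lfc != 0.0}
    ).set_index("gene")
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        groups=groups,
        truth=truth,
    )


def retransplant(
    cohort: Cohort,
    config: SimConfig,
    seed: int | None = None,
    subset: pd.DataFrame | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Re-transplant alive cells of a cohort into a fresh recipient.

    Dormancy is a reversible, environment-dependent state: dissociation from
    the niche erases it.  The label is re-applied (divisions reset against a
    fresh m0) and compartment membership is re-randomized with
    p_dormant_seed, so a re-transplant of any subpopulation — including
    cells sorted as label-retaining or as fully diluted — is statistically
    identical to a fresh transplant of the same number of cells.
    """
    cells = subset if subset is not None else cohort.alive()
    n = int(cells["alive"].sum()) if "alive" in cells else len(cells)
    if n == 0:
        raise EmptyCohortError("no alive cells available for re-transplant")
    cfg = config.with_(n_injected=n, seed=seed)
    return simulate_engraftment(cfg)
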