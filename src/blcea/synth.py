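"""Synthetic stand-ins for model inputs that are not printed anywhere.

Three generators live here:

* :func:`simulate_patients` draws patient-level right-censored survival
  records with the same Weibull proportional-hazards structure the cohort
  model uses, for parameter-recovery testing of the fitting code.
* :func:`make_life_table_fixture` builds a Tanzania-like abridged life
  table (constant child/young-adult mortality with a Gompertz adult tail)
  scaled by a one-dimensional root find so that remaining life expectancy
  at age 10 hits a target — 65 years by default, the anchor the analysis
  relies on.  Background disability weights are piecewise by age band and
  monotone non-decreasing with age, emulating all-cause GBD-style
  morbidity rates.  The schedule is an explicit synthetic stand-in for
  real GBD Tanzania mortality / eastern-SSA morbidity data, not a
  reconstruction of it.
* :func:`make_ae_stub` returns an adverse-event probability/cost table:
  empty (the default analysis configuration) or a small illustrative
  table for exercising the AE costing path.  The nominal values are NOT
  study estimates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .survival import (
    STAGE_ADVANCED,
    STAGE_LIMITED,
    LifeTable,
    PatientRecord,
    SurvivalParams,
    remaining_life_expectancy,
)


@dataclass
class SimulationSpec:
    """Specification of a synthetic survival cohort."""

    n_patients: int = 86
    p_limited: float = 34.0 / 86.0
    survival: SurvivalParams = None
    #: Uniform early-dropout window; with the 24-month administrative
    #: cut-off the default yields roughly one-third dropout before cut-off.
    censoring_window_months: float = 72.0
    admin_censor_months: float = 24.0
    p_rituximab: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.survival is None:
            self.survival = SurvivalParams()

    def validate(self) -> list[str]:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if not 0.0 <= self.p_limited <= 1.0:
            problems.append("p_limited must lie in [0, 1]")
        if not 0.0 <= self.p_rituximab <= 1.0:
            problems.append("p_rituximab must lie in [0, 1]")
        if self.censoring_window_months <= 0:
            problems.append("censoring window must be positive")
        return problems


def draw_event_times(n: int, stage: str, p: SurvivalParams, rng) -> np.ndarray:
    """Inverse-transform draws from the Weibull PH event-time distribution."""
    u = rng.uniform(size=n)
    rate = math.exp(p.log_rate(stage))
    with np.errstate(over="ignore", divide="ignore"):
        return (-np.log(u) / rate) ** (1.0 / p.gamma)


def simulate_patients(spec: SimulationSpec) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of right-censored records.

    Stage is Bernoulli(p_limited); the event time comes from the stage's
    Weibull survival function by inverse transform; observation stops at
    the earliest of the event, a uniform early-dropout draw on
    (0, censoring window] and the administrative cut-off (24 months by
    default, matching the two-year analysis window of the survival data).
    """
    problems = spec.validate()
    if problems:
        raise ValueError("; ".join(problems))
    rng = np.random.default_rng(spec.seed)
    records = []
    for _ in range(spec.n_patients):
        stage = STAGE_LIMITED if rng.uniform() < spec.p_limited else STAGE_ADVANCED
        t_event = float(draw_event_times(1, stage, spec.survival, rng)[0])
        t_drop = rng.uniform(0.0, spec.censoring_window_months)
        t_cens = min(t_drop, spec.admin_censor_months)
        observed = min(t_event, t_cens)
        records.append(
            PatientRecord(
                stage=stage,
                time=max(observed, 1e-9),
                event=t_event <= t_cens,
                rituximab=bool(rng.uniform() < spec.p_rituximab),
                treatment_cycles=int(rng.integers(1, 7)),
            )
        )
    return records


def patients_to_csv(records, path) -> None:
    """Write patient records in the documented CSV layout."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stage", "time_months", "event", "rituximab", "cycles"])
        for r in records:
            w.writerow([r.stage, f"{r.time:.6f}", int(r.event),
                        int(r.rituximab), r.treatment_cycles])


def patients_from_csv(path) -> list[PatientRecord]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    return [
        PatientRecord(
            stage=r["stage"],
            time=float(r["time_months"]),
            event=bool(int(r["event"])),
            rituximab=bool(int(r["rituximab"])),
            treatment_cycles=int(r["cycles"]),
        )
        for r in rows
    ]


# ---------------------------------------------------------------------------
# Life-table fixture
# ---------------------------------------------------------------------------

# Baseline (unscaled) schedule: abridged bands with infant/child mortality,
# a low plateau through young adulthood and a Gompertz-like tail from age 30.
# Background disability weights rise monotonically with age, shaped like
# all-cause per-capita YLD rates.
_BAND_STARTS = [0, 1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60,
                65, 70, 75, 80, 85, 90, 95]
_BG_WEIGHTS = [0.035, 0.038, 0.040, 0.040, 0.055, 0.060, 0.065, 0.075,
               0.085, 0.095, 0.105, 0.120, 0.135, 0.155, 0.180, 0.210,
               0.235, 0.255, 0.270, 0.280, 0.290]


def _baseline_q(age: float) -> float:
    if age < 1:
        return 0.040
    if age < 5:
        return 0.004
    if age < 15:
        return 0.0012
    if age < 30:
        return 0.0020
    # Gompertz adult tail
    return 0.003 * math.exp(0.09 * (age - 30.0))


def make_life_table_fixture(target_e10: float = 65.0,
                            max_age: float = 100.0) -> LifeTable:
    """Calibrated synthetic life table with e(10) equal to ``target_e10``.

    A single scale factor multiplies every annual mortality probability
    (clipped at 1) and is root-found so that the remaining life expectancy
    at age 10 matches the target to within 1e-6 years.

    Raises
    ------
    ValueError
        If the target is not achievable under ``max_age`` (target must be
        below ``max_age - 10``).
    """
    if target_e10 >= max_age - 10.0:
        raise ValueError(
            f"target e(10) = {target_e10} not achievable with max_age {max_age}"
        )
    if target_e10 <= 0:
        raise ValueError("target e(10) must be positive")
    base = np.array([_baseline_q(a) for a in _BAND_STARTS])

    def table_for(scale: float) -> LifeTable:
        return LifeTable(
            age_start=np.array(_BAND_STARTS, dtype=float),
            q_annual=np.clip(scale * base, 0.0, 1.0),
            disability_weight=np.array(_BG_WEIGHTS),
            max_age=max_age,
        )

    def gap(scale: float) -> float:
        return remaining_life_expectancy(10.0, table_for(scale)) - target_e10

    # e(10) is monotone decreasing in the scale; bracket then solve.
    lo, hi = 1e-9, 1.0
    while gap(hi) > 0.0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("life-table calibration failed to bracket the target")
    scale = optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12)
    lt = table_for(scale)
    achieved = remaining_life_expectancy(10.0, lt)
    if abs(achieved - target_e10) > 0.1:
        raise ValueError(
            f"life-table calibration off target: e(10) = {achieved:.3f}"
        )
    return lt


# ---------------------------------------------------------------------------
# Adverse-event table stub
# ---------------------------------------------------------------------------

def make_ae_stub(level: str = "zero"):
    """Adverse-event table stand-in.

    ``"zero"`` returns an empty table (no AE probability or cost — the
    default analysis configuration).  ``"nominal"`` returns a small
    illustrative table for exercising the AE cost path; its values are
    synthetic and carry no evidential weight.
    """
    from .parameters import AEEntry  # local import to avoid a cycle

    if level == "zero":
        return []
    if level == "nominal":
        return [
            AEEntry(label="febrile_neutropenia", p_limited=0.20,
                    p_advanced=0.30, cost=250_000.0),
            AEEntry(label="severe_anaemia", p_limited=0.10,
                    p_advanced=0.20, cost=150_000.0),
        ]
    raise ValueError(f"unknown AE stub level {level!r}")
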