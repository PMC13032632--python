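"""Cost accrual for decision-tree branches and cohort traces.

All values are Tanzanian Shillings.  Diagnosis costs fall at time zero
(undiscounted); the published unit costs are treated as fully loaded by
the microcosting, so facility overheads (20%) are applied to treatment,
adverse-event, follow-up and end-of-life costs only — a flag restores
the literal all-medical-costs reading.  Treatment (stage-specific drug
and non-drug chemotherapy plus expected adverse-event costs) is incurred
by the whole branch cohort during the first cycle and discounted at its
midpoint.  Follow-up accrues per alive, half-cycle-corrected patient at
the quarterly rate of the year the cycle midpoint falls in (quarters
1-4, 5-8, 9-20; nothing after year 5), and end-of-life care is incurred
by each incident disease death in its cycle.  Background deaths carry no
end-of-life cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Branch, CohortTrace, half_cycle_occupancy
from .parameters import CostInputs, DiagnosticParams, ModelConfig


@dataclass
class CostResult:
    diagnosis: float = 0.0
    treatment: float = 0.0
    adverse_events: float = 0.0
    followup: float = 0.0
    end_of_life: float = 0.0
    overheads: float = 0.0

    @property
    def total(self) -> float:
        return (self.diagnosis + self.treatment + self.adverse_events
                + self.followup + self.end_of_life + self.overheads)

    def scaled(self, w: float) -> "CostResult":
        return CostResult(*(w * v for v in (
            self.diagnosis, self.treatment, self.adverse_events,
            self.followup, self.end_of_life, self.overheads)))

    def __add__(self, other: "CostResult") -> "CostResult":
        return CostResult(self.diagnosis + other.diagnosis,
                          self.treatment + other.treatment,
                          self.adverse_events + other.adverse_events,
                          self.followup + other.followup,
                          self.end_of_life + other.end_of_life,
                          self.overheads + other.overheads)

    def to_frame(self, exchange_rate: float | None = None) -> pd.DataFrame:
        cats = ["diagnosis", "treatment", "adverse_events", "followup",
                "end_of_life", "overheads", "total"]
        vals = [self.diagnosis, self.treatment, self.adverse_events,
                self.followup, self.end_of_life, self.overheads, self.total]
        df = pd.DataFrame({"category": cats, "cost_tzs": vals})
        if exchange_rate:
            df["cost_usd"] = df["cost_tzs"] / exchange_rate
        return df


def diagnosis_cost(arm: str, branch: Branch, d: DiagnosticParams) -> float:
    """Diagnostic cost (TZS) of one branch, incurred at time zero.

    Resolves each (component, multiplier) event on the branch: a
    pathology work-up at the pathology unit cost, and liquid-biopsy
    samples at the throughput-tier unit cost times the number needed to
    test.  Liquid-arm false-negative branches carry both.
    """
    total = 0.0
    for component, mult in branch.diag_cost_events:
        if component == "pathology":
            total += mult * d.pathology_unit_cost.value
        elif component == "liquid":
            total += mult * d.liquid_unit_cost()
        else:
            raise ValueError(f"unknown diagnosis cost component {component!r}")
    return total


def treatment_cost(stage: str, c: CostInputs) -> float:
    """Per-patient treatment cost for a stage: chemotherapy drug and
    non-drug costs plus probability-weighted adverse-event costs."""
    return (c.chemo_drug(stage) + c.chemo_nondrug(stage)
            + c.ae_expected_cost(stage))


def accrue_costs(trace: CohortTrace, branch: Branch,
                 cfg: ModelConfig) -> CostResult:
    """Discounted per-patient cost decomposition for one branch trace."""
    g = trace.grid
    c = cfg.costs
    stage = branch.stage_at_treatment
    disc = g.disc_costs_mid

    diag = diagnosis_cost("", branch, cfg.diag)

    # treatment incurred by the entering cohort during the first cycle
    treat = (c.chemo_drug(stage) + c.chemo_nondrug(stage)) \
        * trace.occ_start[0] * disc[0]
    ae = c.ae_expected_cost(stage) * trace.occ_start[0] * disc[0]

    # follow-up: quarterly rate by the quarter the cycle midpoint falls in
    eff = half_cycle_occupancy(trace)
    quarter = np.floor(g.t_mid / 3.0).astype(int)
    rate = np.zeros(len(quarter))
    rate[quarter < 4] = c.followup_q_year1.value
    rate[(quarter >= 4) & (quarter < 8)] = c.followup_q_year2.value
    rate[(quarter >= 8) & (quarter < 20)] = c.followup_q_years3_5.value
    followup = float(np.sum(eff * (g.dt_months / 3.0) * rate * disc))

    eol = float(np.sum(trace.deaths_disease * disc)) * c.end_of_life.value

    oh_base = treat + ae + followup + eol
    if cfg.econ.overhead_on_diagnosis:
        oh_base += diag
    overheads = cfg.econ.overhead_rate * oh_base

    return CostResult(diagnosis=diag, treatment=treat, adverse_events=ae,
                      followup=followup, end_of_life=eol, overheads=overheads)
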