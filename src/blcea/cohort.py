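"""Decision tree and Markov cohort engine.

Each diagnostic arm expands into weighted branches: true positives split
by stage at treatment start, and false negatives start treatment late
with (by the base-case assumption) advanced-stage prognosis.  Liquid-arm
false negatives follow the full histopathology pathway — including, in
the default recursive mode, its own false-negative rate — and incur the
pathology diagnosis cost on top of the liquid test.

Every branch then runs as a deterministic Markov cohort over four health
states: one cycle on treatment, post-treatment until the end of the
24-month disease-risk window (per-cycle death probabilities from the
Weibull model), then a post-disease state subject only to background
mortality, until age 100.  Transitions between the live states are fixed
by elapsed time, so at any cycle all survivors of a branch occupy a
single live state.  A half-cycle correction treats transitions as
occurring mid-cycle: person-time uses the mean of start- and end-of-cycle
occupancy and deaths are timed at the cycle midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ARM_LIQUID, ARM_PATHOLOGY, DiagnosticParams, ModelConfig, StageMix
from .survival import (
    STAGE_ADVANCED,
    STAGE_LIMITED,
    cycle_boundaries,
    cycle_death_probs,
    remaining_life_expectancy,
    survival_at,
)

STATE_ON_TREATMENT = "on_treatment"
STATE_POST_TREATMENT = "post_treatment"
STATE_POST_DISEASE = "post_disease"
STATE_DEAD = "dead"


@dataclass
class Branch:
    """One weighted path through the decision tree."""

    weight: float
    stage_at_treatment: str
    #: (cost component id, multiplier) pairs; components are "pathology"
    #: (one histopathology work-up) and "liquid" (one liquid-biopsy sample,
    #: multiplied by the number needed to test).
    diag_cost_events: list = field(default_factory=list)
    label: str = ""


def build_decision_tree(arm: str, d: DiagnosticParams, s: StageMix) -> list[Branch]:
    """Expand a diagnostic arm into decision-tree branches.

    Branch weights always sum to one.  With zero false-negative
    probabilities each arm reduces to the two true-positive branches with
    weights equal to the stage mix.
    """
    if arm == ARM_PATHOLOGY:
        return _pathology_tree(d, s, prefix="", extra_events=[], scale=1.0)
    if arm == ARM_LIQUID:
        fn = d.fn_prob_liquid.value
        p_lim = s.p_limited_liquid.value
        liquid_events = [("liquid", float(d.nnt))]
        branches = [
            Branch(weight=(1.0 - fn) * p_lim, stage_at_treatment=STAGE_LIMITED,
                   diag_cost_events=list(liquid_events), label="liquid:TP-limited"),
            Branch(weight=(1.0 - fn) * (1.0 - p_lim), stage_at_treatment=STAGE_ADVANCED,
                   diag_cost_events=list(liquid_events), label="liquid:TP-advanced"),
        ]
        if fn > 0.0:
            if d.fn_recursive:
                # FN subtree = the full pathology pathway, scaled by the
                # liquid FN probability, with the liquid test cost added.
                sub = _pathology_tree(d, s, prefix="liquid:FN/",
                                      extra_events=liquid_events, scale=fn)
            else:
                # Non-recursive mode: all liquid FNs are eventually
                # correctly diagnosed by pathology, with the control-arm
                # stage mix.
                p_lim_c = s.p_limited_pathology.value
                events = liquid_events + [("pathology", 1.0)]
                sub = [
                    Branch(weight=fn * p_lim_c, stage_at_treatment=STAGE_LIMITED,
                           diag_cost_events=list(events), label="liquid:FN-limited"),
                    Branch(weight=fn * (1.0 - p_lim_c), stage_at_treatment=STAGE_ADVANCED,
                           diag_cost_events=list(events), label="liquid:FN-advanced"),
                ]
            branches.extend(sub)
        return branches
    raise ValueError(f"unknown arm {arm!r}")


def _pathology_tree(d: DiagnosticParams, s: StageMix, prefix: str,
                    extra_events: list, scale: float) -> list[Branch]:
    fn = d.fn_prob_pathology.value
    p_lim = s.p_limited_pathology.value
    events = list(extra_events) + [("pathology", 1.0)]
    branches = [
        Branch(weight=scale * (1.0 - fn) * p_lim, stage_at_treatment=STAGE_LIMITED,
               diag_cost_events=list(events), label=prefix + "pathology:TP-limited"),
        Branch(weight=scale * (1.0 - fn) * (1.0 - p_lim),
               stage_at_treatment=STAGE_ADVANCED,
               diag_cost_events=list(events), label=prefix + "pathology:TP-advanced"),
    ]
    if fn > 0.0:
        if d.fn_stage_policy == "advanced":
            branches.append(Branch(
                weight=scale * fn, stage_at_treatment=STAGE_ADVANCED,
                diag_cost_events=list(events), label=prefix + "pathology:FN-advanced"))
        else:  # retain the presenting stage distribution
            branches.append(Branch(
                weight=scale * fn * p_lim, stage_at_treatment=STAGE_LIMITED,
                diag_cost_events=list(events), label=prefix + "pathology:FN-limited"))
            branches.append(Branch(
                weight=scale * fn * (1.0 - p_lim), stage_at_treatment=STAGE_ADVANCED,
                diag_cost_events=list(events),
                label=prefix + "pathology:FN-advanced"))
    return branches


@dataclass
class CycleGrid:
    """Shared per-cycle quantities that do not depend on drawn parameters."""

    t_start: np.ndarray      # months
    t_end: np.ndarray
    n_disease: int           # cycles inside the disease-risk window
    state: np.ndarray        # live-state name per cycle
    age_start: np.ndarray    # years, cohort age at cycle start
    disc_costs_mid: np.ndarray    # (1+r)^(-t_mid) factors
    disc_outcomes_mid: np.ndarray
    q_background: np.ndarray  # per-cycle background death prob (post window)
    bg_weight: np.ndarray     # background disability weight at cycle start
    yll_mid: np.ndarray       # discounted YLL per death at cycle midpoint

    @property
    def dt_months(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def t_mid(self) -> np.ndarray:
        return 0.5 * (self.t_start + self.t_end)


def build_cycle_grid(cfg: ModelConfig) -> CycleGrid:
    """Precompute the time grid, state labels, discount factors, background
    mortality and YLL-at-death lookups for a configuration."""
    run = cfg.run
    horizon = run.disease_risk_horizon_months
    b_dis = cycle_boundaries(run.cycle_length_months, horizon)
    months_total = (run.max_age - run.cohort_entry_age) * 12.0
    if months_total > horizon + 1e-9:
        n_post = int(np.ceil((months_total - horizon) / 3.0 - 1e-9))
        b_post = horizon + 3.0 * np.arange(1, n_post + 1)
        b_post[-1] = min(b_post[-1], months_total)
        b = np.concatenate([b_dis, b_post])
    else:
        b = b_dis
    t_start, t_end = b[:-1], b[1:]
    n_disease = len(b_dis) - 1
    state = np.empty(len(t_start), dtype=object)
    for i, ts in enumerate(t_start):
        if i >= n_disease:
            state[i] = STATE_POST_DISEASE
        elif ts < min(run.treatment_duration_months, horizon) - 1e-9:
            state[i] = STATE_ON_TREATMENT
        else:
            state[i] = STATE_POST_TREATMENT
    age_start = run.cohort_entry_age + t_start / 12.0
    t_mid_y = 0.5 * (t_start + t_end) / 12.0
    r_c, r_o = cfg.econ.r_costs, cfg.econ.r_outcomes
    disc_c = (1.0 + r_c) ** (-t_mid_y)
    disc_o = (1.0 + r_o) ** (-t_mid_y)
    lt = cfg.life_table
    q_bg = np.zeros(len(t_start))
    for i in range(n_disease, len(t_start)):
        q_annual = lt.q_at(age_start[i])
        q_bg[i] = 1.0 - (1.0 - q_annual) ** ((t_end[i] - t_start[i]) / 12.0)
    bg_w = np.array([lt.weight_at(a) for a in age_start])
    age_mid = run.cohort_entry_age + t_mid_y
    yll = np.array([_discounted_yll_scalar(a, r_o, lt) for a in age_mid])
    return CycleGrid(t_start=t_start, t_end=t_end, n_disease=n_disease,
                     state=state, age_start=age_start,
                     disc_costs_mid=disc_c, disc_outcomes_mid=disc_o,
                     q_background=q_bg, bg_weight=bg_w, yll_mid=yll)


def _discounted_yll_scalar(age: float, r: float, lt) -> float:
    L = remaining_life_expectancy(age, lt)
    if r == 0.0:
        return L
    return (1.0 - np.exp(-r * L)) / r


@dataclass
class CohortTrace:
    """Per-cycle occupancy and incident deaths for one branch cohort.

    ``occ_start[k]`` is the live occupancy at the start of cycle ``k``
    (all survivors share the single live state ``grid.state[k]``);
    ``occ_end[k]`` the occupancy at its end.  Deaths are split by cause
    only for costing and DALY attribution — disease deaths occur inside
    the disease-risk window, background deaths after it.
    """

    grid: CycleGrid
    occ_start: np.ndarray
    occ_end: np.ndarray
    deaths_disease: np.ndarray
    deaths_background: np.ndarray

    @property
    def deaths_total(self) -> np.ndarray:
        return self.deaths_disease + self.deaths_background

    def conservation_error(self) -> float:
        """Max per-cycle deviation of live occupancy + cumulative deaths from 1."""
        cum = np.cumsum(self.deaths_total)
        return float(np.max(np.abs(self.occ_end + cum - 1.0)))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export."""
        g = self.grid
        return pd.DataFrame({
            "cycle": np.arange(1, len(g.t_start) + 1),
            "time_months": g.t_start,
            "state": g.state,
            "occupancy": self.occ_start,
            "incident_disease_deaths": self.deaths_disease,
            "incident_background_deaths": self.deaths_background,
            "mean_age": g.age_start,
        })


def run_markov_branch(b: Branch, cfg: ModelConfig,
                      grid: CycleGrid | None = None) -> CohortTrace:
    """Propagate a unit cohort through the Markov chain for one branch.

    The returned trace conserves mass exactly: occupancy is updated
    multiplicatively and deaths are taken as successive differences.
    """
    if grid is None:
        grid = build_cycle_grid(cfg)
    n = len(grid.t_start)
    q = grid.q_background.copy()
    q_dis = cycle_death_probs(cfg.run.cycle_length_months,
                              cfg.run.disease_risk_horizon_months,
                              b.stage_at_treatment, cfg.survival)
    q[:grid.n_disease] = q_dis
    occ_end = np.cumprod(1.0 - q)
    occ_start = np.concatenate(([1.0], occ_end[:-1]))
    deaths = occ_start - occ_end
    dd = np.zeros(n)
    db = np.zeros(n)
    dd[:grid.n_disease] = deaths[:grid.n_disease]
    db[grid.n_disease:] = deaths[grid.n_disease:]
    return CohortTrace(grid=grid, occ_start=occ_start, occ_end=occ_end,
                       deaths_disease=dd, deaths_background=db)


def half_cycle_occupancy(trace: CohortTrace) -> np.ndarray:
    """Effective person-time weight per cycle under the half-cycle correction
    (arithmetic mean of start- and end-of-cycle live occupancy)."""
    return 0.5 * (trace.occ_start + trace.occ_end)


def verify_branch_anchor(cfg: ModelConfig) -> tuple[float, float]:
    """Sanity anchor: live occupancy at the end of the disease window for a
    pure advanced branch equals S(horizon | advanced), and likewise for
    limited.  Returns the (limited, advanced) occupancies."""
    out = []
    for stage in (STAGE_LIMITED, STAGE_ADVANCED):
        tr = run_markov_branch(Branch(1.0, stage), cfg)
        out.append(tr.occ_start[tr.grid.n_disease])
    return tuple(out)
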