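"""Cost-effectiveness evaluation, sensitivity and scenario analyses.

The top layer of the model: evaluates each diagnostic arm as the
branch-weighted sum of Markov cohort results, forms the incremental
cost-effectiveness ratio (ICER, TZS and USD per DALY averted) against
willingness-to-pay thresholds, and runs

* one-way (tornado) sensitivity analysis over the published ranges,
* probabilistic sensitivity analysis (Monte Carlo over Beta / Gamma /
  Normal parameter distributions) with cost-effectiveness plane points,
  percentile confidence intervals and the cost-effectiveness
  acceptability curve (CEAC), and
* the scenario suite: number-needed-to-test 2-6 (with the 300/yr unit
  cost for NNT 2-3), liquid-biopsy availability 20-100% (throughput-
  adjusted unit costs, proportional blending with the pathology arm),
  extended disease-risk horizons, false negatives retaining their
  presenting stage, 1-week model cycles, the stage-shift sweep, and
  hooks for rituximab-free / subgroup survival inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import build_cycle_grid, build_decision_tree, run_markov_branch
from .costing import CostResult, accrue_costs
from .daly import DalyResult, total_dalys
from .parameters import (
    ARM_LIQUID,
    ARM_PATHOLOGY,
    ModelConfig,
    Unc,
    validate_config,
)
from .survival import MONTHS_PER_WEEK

INFINITE_ICER = float("inf")


@dataclass
class ArmResult:
    arm: str
    cost_tzs: float
    dalys: float
    cost_breakdown: CostResult
    daly_breakdown: DalyResult


@dataclass
class CEAResult:
    delta_cost_tzs: float
    delta_dalys_averted: float
    icer_tzs_per_daly: float
    icer_usd_per_daly: float
    net_benefit_usd: dict
    dominant: bool
    label: str = "base"
    reference: ArmResult | None = None
    comparator: ArmResult | None = None


@dataclass
class PSAResult:
    """Paired Monte Carlo draws of per-arm costs and DALY burdens."""

    seed: int
    cost_pathology: np.ndarray
    cost_liquid: np.ndarray
    dalys_pathology: np.ndarray
    dalys_liquid: np.ndarray
    exchange_rate: float
    n_resampled: int = 0

    @property
    def iterations(self) -> int:
        return len(self.cost_pathology)

    @property
    def delta_cost_tzs(self) -> np.ndarray:
        return self.cost_liquid - self.cost_pathology

    @property
    def delta_cost_usd(self) -> np.ndarray:
        return self.delta_cost_tzs / self.exchange_rate

    @property
    def delta_dalys_averted(self) -> np.ndarray:
        return self.dalys_pathology - self.dalys_liquid

    def ci_delta_cost_usd(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.delta_cost_usd, [2.5, 97.5])
        return float(lo), float(hi)

    def ci_delta_dalys(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.delta_dalys_averted, [2.5, 97.5])
        return float(lo), float(hi)

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_cost_usd": self.delta_cost_usd,
            "delta_dalys_averted": self.delta_dalys_averted,
        })


# ---------------------------------------------------------------------------
# Arm evaluation and ICER
# ---------------------------------------------------------------------------

def evaluate_branches(arm: str, cfg: ModelConfig, grid=None):
    """Yield (branch, trace, CostResult, DalyResult) for each tree branch."""
    if grid is None:
        grid = build_cycle_grid(cfg)
    for b in build_decision_tree(arm, cfg.diag, cfg.stages):
        trace = run_markov_branch(b, cfg, grid)
        yield b, trace, accrue_costs(trace, b, cfg), total_dalys(trace, cfg)


def evaluate_arm(arm: str, cfg: ModelConfig, grid=None) -> ArmResult:
    """Branch-weighted per-patient discounted cost (TZS) and DALY burden."""
    cost = CostResult()
    dalys = DalyResult(0.0, 0.0, 0.0, 0.0)
    for b, _trace, c, d in evaluate_branches(arm, cfg, grid):
        cost = cost + c.scaled(b.weight)
        dalys = dalys + d.scaled(b.weight)
    return ArmResult(arm=arm, cost_tzs=cost.total, dalys=dalys.total,
                     cost_breakdown=cost, daly_breakdown=dalys)


def compute_icer(reference: ArmResult, comparator: ArmResult,
                 econ, label: str = "base") -> CEAResult:
    """ICER of ``comparator`` (liquid biopsy) against ``reference``.

    Incremental cost is comparator minus reference; effect is DALYs
    averted (reference burden minus comparator burden).  Unrounded values
    are used throughout; a zero effect yields an infinite-ICER sentinel
    and simultaneous savings with health gain set the dominance flag.
    """
    d_cost = comparator.cost_tzs - reference.cost_tzs
    d_eff = reference.dalys - comparator.dalys
    if d_eff == 0.0:
        icer_tzs = INFINITE_ICER if d_cost > 0 else -INFINITE_ICER
    else:
        icer_tzs = d_cost / d_eff
    icer_usd = icer_tzs / econ.exchange_rate
    dominant = (d_cost < 0 and d_eff > 0) or (d_cost > 0 and d_eff < 0)
    nb = {
        float(lam): lam * d_eff - d_cost / econ.exchange_rate
        for lam in econ.thresholds_usd
    }
    return CEAResult(delta_cost_tzs=d_cost, delta_dalys_averted=d_eff,
                     icer_tzs_per_daly=icer_tzs, icer_usd_per_daly=icer_usd,
                     net_benefit_usd=nb, dominant=dominant, label=label,
                     reference=reference, comparator=comparator)


def evaluate_basecase(cfg: ModelConfig) -> CEAResult:
    grid = build_cycle_grid(cfg)
    ref = evaluate_arm(ARM_PATHOLOGY, cfg, grid)
    comp = evaluate_arm(ARM_LIQUID, cfg, grid)
    return compute_icer(ref, comp, cfg.econ)


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

def _set_unc(u: Unc, v: float) -> None:
    u.value = v


_ONE_WAY_SETTERS = {
    "discount_rate_outcomes": lambda c, v: setattr(c.econ, "discount_rate_outcomes", v),
    "discount_rate_costs": lambda c, v: setattr(c.econ, "discount_rate_costs", v),
    "overhead_rate": lambda c, v: setattr(c.econ, "overhead_rate", v),
    "fn_prob_pathology": lambda c, v: _set_unc(c.diag.fn_prob_pathology, v),
    "fn_prob_liquid": lambda c, v: _set_unc(c.diag.fn_prob_liquid, v),
    "p_limited_pathology": lambda c, v: _set_unc(c.stages.p_limited_pathology, v),
    "p_limited_liquid": lambda c, v: _set_unc(c.stages.p_limited_liquid, v),
    "pathology_unit_cost": lambda c, v: _set_unc(c.diag.pathology_unit_cost, v),
    "liquid_unit_cost_multiplier": lambda c, v: _set_unc(c.diag.liquid_cost_multiplier, v),
    "chemo_drug_limited": lambda c, v: _set_unc(c.costs.chemo_drug_limited, v),
    "chemo_drug_advanced": lambda c, v: _set_unc(c.costs.chemo_drug_advanced, v),
    "chemo_nondrug_limited": lambda c, v: _set_unc(c.costs.chemo_nondrug_limited, v),
    "chemo_nondrug_advanced": lambda c, v: _set_unc(c.costs.chemo_nondrug_advanced, v),
    "followup_q_year1": lambda c, v: _set_unc(c.costs.followup_q_year1, v),
    "end_of_life": lambda c, v: _set_unc(c.costs.end_of_life, v),
}


def default_one_way_grid(cfg: ModelConfig) -> dict:
    """Published one-way ranges: explicit intervals where stated, ±20%
    otherwise.  The liquid-arm stage mix is explored by its dedicated
    scenario sweep rather than here."""
    pm20 = lambda u: (0.8 * u.value, 1.2 * u.value)
    return {
        "discount_rate_outcomes": (0.035, 0.10),
        "discount_rate_costs": (0.035, 0.10),
        "overhead_rate": (0.15, 0.25),
        "fn_prob_pathology": (0.13, 0.31),
        "fn_prob_liquid": (0.08, 0.22),
        "p_limited_pathology": (0.30, 0.50),
        "pathology_unit_cost": pm20(cfg.diag.pathology_unit_cost),
        "liquid_unit_cost_multiplier": (0.8, 1.2),
        "chemo_drug_limited": pm20(cfg.costs.chemo_drug_limited),
        "chemo_drug_advanced": pm20(cfg.costs.chemo_drug_advanced),
        "chemo_nondrug_limited": pm20(cfg.costs.chemo_nondrug_limited),
        "chemo_nondrug_advanced": pm20(cfg.costs.chemo_nondrug_advanced),
        "followup_q_year1": pm20(cfg.costs.followup_q_year1),
        "end_of_life": pm20(cfg.costs.end_of_life),
    }


def one_way_sa(cfg: ModelConfig, grid: dict | None = None) -> pd.DataFrame:
    """Tornado table: ICER (USD/DALY) at the low and high value of each
    parameter with all others at base, sorted by span."""
    if grid is None:
        grid = default_one_way_grid(cfg)
    unknown = set(grid) - set(_ONE_WAY_SETTERS)
    if unknown:
        raise KeyError(
            f"unknown one-way parameter(s) {sorted(unknown)}; "
            f"valid names: {sorted(_ONE_WAY_SETTERS)}")
    base = evaluate_basecase(cfg).icer_usd_per_daly
    rows = []
    for name, (lo, hi) in grid.items():
        icers = []
        for v in (lo, hi):
            c2 = cfg.copy()
            _ONE_WAY_SETTERS[name](c2, v)
            icers.append(evaluate_basecase(c2).icer_usd_per_daly)
        rows.append({"parameter": name, "low_value": lo, "high_value": hi,
                     "icer_low": icers[0], "icer_high": icers[1],
                     "icer_base": base,
                     "span": abs(icers[1] - icers[0])})
    return (pd.DataFrame(rows)
            .sort_values("span", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters by the method of moments."""
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError("SE too large for a Beta distribution at this mean")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) by the method of moments."""
    return (mean / se) ** 2, se * se / mean


def _draw_beta(u: Unc, rng) -> float:
    if u.se == 0.0:
        return u.value
    a, b = beta_moments(u.value, u.se)
    return float(rng.beta(a, b))


def _draw_gamma(u: Unc, rng) -> float:
    if u.se == 0.0 or u.value == 0.0:
        return u.value
    shape, scale = gamma_moments(u.value, u.se)
    return float(rng.gamma(shape, scale))


def _draw_normal(mean: float, se: float, rng) -> float:
    if se == 0.0:
        return mean
    return float(rng.normal(mean, se))


def draw_psa_params(cfg: ModelConfig, rng) -> ModelConfig:
    """One Monte Carlo parameter draw.

    Proportions and disability weights are Beta, costs Gamma, survival
    coefficients independent Normal; the number needed to test, discount
    and overhead rates, availability and the life table are fixed.  The
    draw order is fixed for reproducibility.
    """
    c = cfg.copy()
    c.diag.fn_prob_pathology.value = _draw_beta(cfg.diag.fn_prob_pathology, rng)
    c.diag.fn_prob_liquid.value = _draw_beta(cfg.diag.fn_prob_liquid, rng)
    c.stages.p_limited_pathology.value = _draw_beta(cfg.stages.p_limited_pathology, rng)
    c.stages.p_limited_liquid.value = _draw_beta(cfg.stages.p_limited_liquid, rng)
    c.weights.active_disease.value = _draw_beta(cfg.weights.active_disease, rng)
    c.weights.terminal_disease.value = _draw_beta(cfg.weights.terminal_disease, rng)
    c.weights.post_treatment.value = _draw_beta(cfg.weights.post_treatment, rng)
    s = cfg.survival
    c.survival.beta0 = _draw_normal(s.beta0, s.beta0_se, rng)
    c.survival.beta_advanced = _draw_normal(s.beta_advanced, s.beta_advanced_se, rng)
    c.survival.gamma = _draw_normal(s.gamma, s.gamma_se, rng)
    c.diag.pathology_unit_cost.value = _draw_gamma(cfg.diag.pathology_unit_cost, rng)
    c.diag.liquid_cost_multiplier.value = _draw_gamma(cfg.diag.liquid_cost_multiplier, rng)
    for name in ("chemo_drug_limited", "chemo_drug_advanced",
                 "chemo_nondrug_limited", "chemo_nondrug_advanced",
                 "followup_q_year1", "followup_q_year2", "followup_q_years3_5",
                 "end_of_life"):
        getattr(c.costs, name).value = _draw_gamma(getattr(cfg.costs, name), rng)
    for e_base, e_new in zip(cfg.costs.ae_table, c.costs.ae_table):
        e_new.cost = _draw_gamma(Unc(e_base.cost, 0.2 * e_base.cost), rng)
    return c


def run_psa(cfg: ModelConfig, iterations: int | None = None,
            seed: int | None = None) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Per iteration: draw a parameter set, evaluate both arms, record the
    paired (cost, DALY) results.  Reproducible under a fixed seed; a
    failed iteration (e.g. an invalid draw) is resampled and counted.
    """
    n = cfg.econ.psa_iterations if iterations is None else iterations
    seed = cfg.econ.psa_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    grid = build_cycle_grid(cfg)  # discounting/life-table lookups are not drawn
    cp = np.empty(n)
    cl = np.empty(n)
    dp = np.empty(n)
    dl = np.empty(n)
    resampled = 0
    i = 0
    while i < n:
        try:
            draw = draw_psa_params(cfg, rng)
            if draw.survival.gamma <= 0:
                raise ValueError("non-positive Weibull shape drawn")
            ref = evaluate_arm(ARM_PATHOLOGY, draw, grid)
            comp = evaluate_arm(ARM_LIQUID, draw, grid)
        except (ValueError, FloatingPointError):
            resampled += 1
            if resampled > 100 * n:
                raise RuntimeError("PSA resampling failed to converge")
            continue
        cp[i], cl[i] = ref.cost_tzs, comp.cost_tzs
        dp[i], dl[i] = ref.dalys, comp.dalys
        i += 1
    return PSAResult(seed=seed, cost_pathology=cp, cost_liquid=cl,
                     dalys_pathology=dp, dalys_liquid=dl,
                     exchange_rate=cfg.econ.exchange_rate,
                     n_resampled=resampled)


def ceac(psa: PSAResult, lambda_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value λ (USD/DALY averted): the fraction
    of iterations with positive incremental net benefit λ·ΔE − ΔC.
    """
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 5001.0, 10.0)
    lam = np.asarray(lambda_grid, dtype=float)
    nb = lam[:, None] * psa.delta_dalys_averted[None, :] \
        - psa.delta_cost_usd[None, :]
    prob = (nb > 0.0).mean(axis=1)
    return pd.DataFrame({"wtp_usd_per_daly": lam, "prob_cost_effective": prob})


def ceac_crossing(curve: pd.DataFrame) -> float:
    """Smallest λ on the grid with acceptability above 0.5.

    Returns NaN (with a log message) if the curve never crosses.
    """
    above = curve[curve["prob_cost_effective"] > 0.5]
    if above.empty:
        import logging
        logging.getLogger(__name__).warning(
            "CEAC never exceeds 0.5 on the evaluated grid")
        return float("nan")
    return float(above["wtp_usd_per_daly"].iloc[0])


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------

SCENARIO_KINDS = ("nnt", "availability", "extended_risk", "fn_retain_stage",
                  "cycle_length", "stage_shift", "rituximab_free",
                  "tanzania_only")


@dataclass
class ScenarioSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    label: str = ""


def run_scenario(cfg: ModelConfig, spec: ScenarioSpec) -> CEAResult:
    """Evaluate one scenario against the base-case pathology arm."""
    if spec.kind not in SCENARIO_KINDS:
        raise ValueError(
            f"unknown scenario kind {spec.kind!r}; valid: {SCENARIO_KINDS}")
    label = spec.label or spec.kind
    c = cfg.copy()

    if spec.kind == "nnt":
        k = int(spec.parameters["nnt"])
        c.diag.nnt = k
        # NNT 2-3 reflects lower throughput: the 300 samples/yr unit cost.
        c.diag.annual_throughput = spec.parameters.get(
            "annual_throughput", 300.0 if k <= 3 else 900.0)
        res = evaluate_basecase(c)
        res.label = label
        return res

    if spec.kind == "availability":
        a = float(spec.parameters["availability"])
        if not 0.0 < a <= 1.0:
            raise ValueError("availability must lie in (0, 1]")
        c.diag.availability = a
        c.diag.annual_throughput = spec.parameters.get(
            "annual_throughput", a * 900.0)
        grid = build_cycle_grid(c)
        ref = evaluate_arm(ARM_PATHOLOGY, c, grid)
        liq = evaluate_arm(ARM_LIQUID, c, grid)
        blended = ArmResult(
            arm=f"liquid@{a:.0%}",
            cost_tzs=a * liq.cost_tzs + (1.0 - a) * ref.cost_tzs,
            dalys=a * liq.dalys + (1.0 - a) * ref.dalys,
            cost_breakdown=liq.cost_breakdown.scaled(a)
            + ref.cost_breakdown.scaled(1.0 - a),
            daly_breakdown=liq.daly_breakdown.scaled(a)
            + ref.daly_breakdown.scaled(1.0 - a),
        )
        res = compute_icer(ref, blended, c.econ, label=label)
        return res

    if spec.kind == "extended_risk":
        c.run.disease_risk_horizon_months = float(
            spec.parameters["horizon_months"])
    elif spec.kind == "fn_retain_stage":
        c.diag.fn_stage_policy = "retain"
    elif spec.kind == "cycle_length":
        c.run.cycle_length_months = float(
            spec.parameters.get("cycle_length_months", MONTHS_PER_WEEK))
        c.run.allow_partial_final_cycle = True
    elif spec.kind == "stage_shift":
        c.stages.p_limited_liquid.value = float(
            spec.parameters["p_limited_liquid"])
    elif spec.kind in ("rituximab_free", "tanzania_only"):
        # Hooks: these scenarios need survival coefficients (and, for the
        # rituximab case, a drug-cost adjustment) estimated from patient
        # data that is not packaged; callers supply them explicitly.
        if "survival" in spec.parameters:
            c.survival = spec.parameters["survival"]
        for stage_name in ("chemo_drug_limited", "chemo_drug_advanced"):
            key = f"{stage_name}_value"
            if key in spec.parameters:
                getattr(c.costs, stage_name).value = float(spec.parameters[key])
    problems = validate_config(c)
    if problems:
        raise ValueError("; ".join(problems))
    res = evaluate_basecase(c)
    res.label = label
    return res


def stage_shift_sweep(cfg: ModelConfig, values=None) -> pd.DataFrame:
    """ICER as a function of the liquid-arm limited-stage proportion."""
    if values is None:
        values = np.round(np.arange(0.40, 0.801, 0.05), 3)
    rows = []
    for v in values:
        r = run_scenario(cfg, ScenarioSpec("stage_shift",
                                           {"p_limited_liquid": float(v)},
                                           label=f"stage_shift={v:.2f}"))
        rows.append({"p_limited_liquid": float(v),
                     "delta_cost_tzs": r.delta_cost_tzs,
                     "dalys_averted": r.delta_dalys_averted,
                     "icer_usd_per_daly": r.icer_usd_per_daly})
    return pd.DataFrame(rows)


def scenario_table(cfg: ModelConfig) -> pd.DataFrame:
    """Base case plus the NNT and availability panels as one table."""
    rows = []

    def add(label, res: CEAResult):
        rows.append({
            "scenario": label,
            "cost_liquid_tzs": res.comparator.cost_tzs,
            "dalys_liquid": res.comparator.dalys,
            "cost_pathology_tzs": res.reference.cost_tzs,
            "dalys_pathology": res.reference.dalys,
            "icer_tzs": res.icer_tzs_per_daly,
            "icer_usd": res.icer_usd_per_daly,
        })

    add("base_case", evaluate_basecase(cfg))
    for k in range(2, 7):
        add(f"nnt={k}", run_scenario(cfg, ScenarioSpec("nnt", {"nnt": k})))
    for a in (0.2, 0.4, 0.6, 0.8, 1.0):
        add(f"availability={a:.0%}",
            run_scenario(cfg, ScenarioSpec("availability", {"availability": a})))
    for h in (36.0, 48.0, 60.0):
        add(f"extended_risk={h:.0f}m",
            run_scenario(cfg, ScenarioSpec("extended_risk", {"horizon_months": h})))
    add("fn_retain_stage", run_scenario(cfg, ScenarioSpec("fn_retain_stage")))
    add("cycle=1week", run_scenario(cfg, ScenarioSpec("cycle_length")))
    return pd.DataFrame(rows)
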