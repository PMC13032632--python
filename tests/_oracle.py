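"""Brute-force scalar reference implementation of the whole model.

A deliberately slow, pure-Python, per-cycle loop that re-derives the
arm-level discounted cost and DALY burden from the written-down model
equations (Weibull survival, half-cycle correction, quarterly follow-up
schedule, continuous-discount YLL).  Used to pin the vectorised engine:
both must agree to 1e-9 relative.
"""

import math


def _survival(t, stage, sp):
    lin = sp.beta0 + (sp.beta_advanced if stage == "advanced" else 0.0)
    return math.exp(-math.exp(lin) * t ** sp.gamma)


def _e_remaining(age, lt):
    l_cur, e, a = 1.0, 0.0, float(age)
    while a < lt.max_age - 1e-12 and l_cur > 0.0:
        step = min(1.0, lt.max_age - a)
        q = lt.q_at(a)
        q_step = 1.0 - (1.0 - q) ** step
        l_next = l_cur * (1.0 - q_step)
        e += 0.5 * (l_cur + l_next) * step
        l_cur, a = l_next, a + step
    return e


def _boundaries(cycle_len, horizon):
    n_full = int(math.floor(horizon / cycle_len + 1e-9))
    b = [i * cycle_len for i in range(n_full + 1)]
    if horizon - b[-1] > 1e-9 * max(1.0, horizon):
        b.append(horizon)
    else:
        b[-1] = horizon
    return b


def _branches(arm, cfg):
    """Enumerate (weight, stage, diagnosis cost) leaves of the decision tree."""
    d, s = cfg.diag, cfg.stages
    c_path = d.pathology_unit_cost.value
    tiers = sorted(d.liquid_unit_cost_by_tier)
    tier = min(tiers, key=lambda k: abs(k - d.annual_throughput))
    c_liq = (d.nnt * d.liquid_unit_cost_by_tier[tier]
             * d.liquid_cost_multiplier.value)

    def path_leaves(scale, extra_cost):
        fn, pl = d.fn_prob_pathology.value, s.p_limited_pathology.value
        out = [(scale * (1 - fn) * pl, "limited", extra_cost + c_path),
               (scale * (1 - fn) * (1 - pl), "advanced", extra_cost + c_path)]
        if fn > 0:
            if d.fn_stage_policy == "advanced":
                out.append((scale * fn, "advanced", extra_cost + c_path))
            else:
                out.append((scale * fn * pl, "limited", extra_cost + c_path))
                out.append((scale * fn * (1 - pl), "advanced", extra_cost + c_path))
        return out

    if arm == "pathology":
        return path_leaves(1.0, 0.0)
    fn, pl = d.fn_prob_liquid.value, s.p_limited_liquid.value
    out = [((1 - fn) * pl, "limited", c_liq),
           ((1 - fn) * (1 - pl), "advanced", c_liq)]
    if fn > 0:
        if d.fn_recursive:
            out += path_leaves(fn, c_liq)
        else:
            plc = s.p_limited_pathology.value
            out += [(fn * plc, "limited", c_liq + c_path),
                    (fn * (1 - plc), "advanced", c_liq + c_path)]
    return out


def oracle_arm(arm, cfg):
    """Return (total discounted cost TZS, total discounted DALYs) for an arm."""
    run, econ, w, c, lt = cfg.run, cfg.econ, cfg.weights, cfg.costs, cfg.life_table
    horizon = run.disease_risk_horizon_months
    b = _boundaries(run.cycle_length_months, horizon)
    months_total = (run.max_age - run.cohort_entry_age) * 12.0
    t = horizon
    while t < months_total - 1e-9:
        t = min(t + 3.0, months_total)
        b.append(t)
    n_disease = len(_boundaries(run.cycle_length_months, horizon)) - 1
    r_c, r_o = econ.r_costs, econ.r_outcomes

    total_cost = 0.0
    total_dalys = 0.0
    for weight, stage, diag_cost in _branches(arm, cfg):
        treat = c.chemo_drug(stage) + c.chemo_nondrug(stage)
        ae = sum(e.prob(stage) * e.cost for e in c.ae_table)
        occ = 1.0
        cost_treat = cost_ae = cost_fu = cost_eol = 0.0
        dalys = 0.0
        for k in range(len(b) - 1):
            t0, t1 = b[k], b[k + 1]
            dt = t1 - t0
            t_mid_y = 0.5 * (t0 + t1) / 12.0
            disc_c = (1.0 + r_c) ** (-t_mid_y)
            disc_o = (1.0 + r_o) ** (-t_mid_y)
            age0 = run.cohort_entry_age + t0 / 12.0
            if k < n_disease:
                q = 1.0 - _survival(t1, stage, cfg.survival) \
                    / _survival(t0, stage, cfg.survival)
                state_w = (w.active_disease.value
                           if t0 < min(run.treatment_duration_months, horizon) - 1e-9
                           else w.post_treatment.value)
            else:
                q = 1.0 - (1.0 - lt.q_at(age0)) ** (dt / 12.0)
                state_w = 0.0
            occ_next = occ * (1.0 - q)
            deaths = occ - occ_next
            eff = 0.5 * (occ + occ_next)
            if k == 0:
                cost_treat += treat * occ * disc_c
                cost_ae += ae * occ * disc_c
            quarter = int(math.floor(0.5 * (t0 + t1) / 3.0))
            if quarter < 4:
                rate = c.followup_q_year1.value
            elif quarter < 8:
                rate = c.followup_q_year2.value
            elif quarter < 20:
                rate = c.followup_q_years3_5.value
            else:
                rate = 0.0
            cost_fu += eff * (dt / 3.0) * rate * disc_c
            # DALYs
            bg_w = lt.weight_at(age0) if run.background_yld_all_states or \
                k >= n_disease else 0.0
            dalys += eff * (dt / 12.0) * (state_w + bg_w) * disc_o
            L = _e_remaining(run.cohort_entry_age + 0.5 * (t0 + t1) / 12.0, lt)
            yll = L if r_o == 0.0 else (1.0 - math.exp(-r_o * L)) / r_o
            dalys += deaths * yll * disc_o
            if k < n_disease:
                cost_eol += deaths * c.end_of_life.value * disc_c
                dalys += deaths * w.terminal_disease.value * (dt / 12.0) * disc_o
            occ = occ_next
        oh_base = cost_treat + cost_ae + cost_fu + cost_eol
        if econ.overhead_on_diagnosis:
            oh_base += diag_cost
        cost = diag_cost + cost_treat + cost_ae + cost_fu + cost_eol \
            + econ.overhead_rate * oh_base
        total_cost += weight * cost
        total_dalys += weight * dalys
    return total_cost, total_dalys
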