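"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: plain Python
loops and scalars only, written directly from the algebra of the two-step
procedure and the annual lifetable cycle.
"""

from __future__ import annotations


def oracle_two_step(q_b, p_b, p_a, eps, eta, tfee):
    """Spreadsheet-style recomputation of the full two-step procedure.

    Returns (q_a, x_a, dq_pes, fpi_fraction).
    """
    n = len(q_b)
    x_b = sum(q_b[i] / 100.0 * p_b[i] for i in range(n))
    dp = [p_a[j] / p_b[j] - 1.0 for j in range(n)]
    dq_pe = [sum(dp[j] * eps[i][j] for j in range(n)) for i in range(n)]
    x_pe = sum((1.0 + dq_pe[i]) * q_b[i] / 100.0 * p_a[i] for i in range(n))
    dq_pes = [x_b / x_pe * (1.0 + dq_pe[i]) - 1.0 for i in range(n)]
    fpi = sum(q_b[i] / 100.0 * p_a[i] for i in range(n)) / x_b - 1.0
    delta_x = fpi * tfee * x_b
    dq_ee = [fpi * tfee * eta[i] for i in range(n)]
    delta_q_ee = [dq_ee[i] * (1.0 + dq_pes[i]) * q_b[i] for i in range(n)]
    delta_x_ee = sum(delta_q_ee[i] / 100.0 * p_a[i] for i in range(n))
    scalar = 0.0 if delta_x == 0.0 else delta_x / delta_x_ee
    q_a = [scalar * delta_q_ee[i] + dq_pes[i] * q_b[i] + q_b[i]
           for i in range(n)]
    x_a = sum(q_a[i] / 100.0 * p_a[i] for i in range(n))
    return q_a, x_a, dq_pes, fpi


def oracle_conditional_step(q_b, p_b, p_a, eps):
    """Step 1 only: scaled fractional quantity changes."""
    n = len(q_b)
    x_b = sum(q_b[i] / 100.0 * p_b[i] for i in range(n))
    dp = [p_a[j] / p_b[j] - 1.0 for j in range(n)]
    dq_pe = [sum(dp[j] * eps[i][j] for j in range(n)) for i in range(n)]
    x_pe = sum((1.0 + dq_pe[i]) * q_b[i] / 100.0 * p_a[i] for i in range(n))
    return [x_b / x_pe * (1.0 + dq_pe[i]) - 1.0 for i in range(n)]


def oracle_lifetable(pop, diseases, pifs, horizon, intervention):
    """Cycle-by-cycle scalar recomputation of one lifetable run's HALYs."""
    total = 0.0
    for cohort in pop.cohorts:
        alive = cohort.count
        prev = [0.0] * len(diseases)
        for t in range(horizon):
            age = cohort.age + t
            mort_arr = pop.mortality[cohort.sex]
            morb_arr = pop.morbidity[cohort.sex]
            a = min(age, len(mort_arr) - 1)
            morb = float(morb_arr[min(age, len(morb_arr) - 1)])
            mort = float(mort_arr[a])
            for d, dis in enumerate(diseases):
                cf = dis.case_fatality[cohort.sex]
                cf_val = float(cf[min(age, len(cf) - 1)])
                morb += dis.disability_weight * prev[d]
                mort += cf_val * prev[d]
            morb = min(morb, 1.0)
            mort = min(mort, 1.0)
            total += alive * (1.0 - morb) / (1.0 + pop.discount_rate) ** t
            for d, dis in enumerate(diseases):
                inc_arr = dis.incidence[cohort.sex]
                inc = float(inc_arr[min(age, len(inc_arr) - 1)])
                if intervention and t >= dis.lag_years:
                    inc *= 1.0 - pifs.get(dis.name, 0.0)
                cf = dis.case_fatality[cohort.sex]
                rem = dis.remission[cohort.sex]
                cf_val = float(cf[min(age, len(cf) - 1)])
                rem_val = float(rem[min(age, len(rem) - 1)])
                nxt = prev[d] + inc * (1.0 - prev[d]) - (rem_val + cf_val) * prev[d]
                prev[d] = min(max(nxt, 0.0), 1.0)
            alive *= 1.0 - mort
    return total
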