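"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: linear programs are
rebuilt from the raw stoichiometric matrix and solved with scipy's HiGHS
interior-point/simplex, so agreement with the GLPK-backed implementation is
a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def arrays(model, objective=None):
    """(S, lb, ub, c) arrays for a cobra model; ``objective`` may override
    the model's objective as a reaction-id -> weight mapping."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    S = np.zeros((len(met_index), n))
    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        if objective is None:
            c[j] = rxn.objective_coefficient
        elif rxn.id in objective:
            c[j] = objective[rxn.id]
    return S, lb, ub, c


def oracle_fba(model, objective=None, sense="max"):
    """Objective value and flux vector of the FBA LP via scipy HiGHS."""
    S, lb, ub, c = arrays(model, objective)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return None, None
    return float(c @ res.x), res.x


def oracle_pfba_l1(model, objective=None, growth_fraction=1.0):
    """Minimal total absolute flux at the FBA optimum, by explicit variable
    splitting (v = p - q, p,q >= 0, minimize sum p + q)."""
    opt, _ = oracle_fba(model, objective)
    if opt is None:
        return None
    S, lb, ub, c = arrays(model, objective)
    n = S.shape[1]
    # variables [p, q]; v = p - q
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    target = growth_fraction * opt
    A_growth = np.hstack([c, -c]).reshape(1, -1)
    A_eq = np.vstack([A_eq, A_growth])
    b_eq = np.append(b_eq, target)
    bounds = []
    for j in range(n):
        bounds.append((max(lb[j], 0.0), max(ub[j], 0.0)))
    for j in range(n):
        bounds.append((max(-ub[j], 0.0), max(-lb[j], 0.0)))
    cost = np.ones(2 * n)
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return float(res.fun)


def oracle_oxygen(model, o2_exchange="EX_o2_e"):
    """Two-stage (mu_max, r_max) via scipy: max growth with oxygen open,
    then minimal oxygen import magnitude at that growth."""
    S, lb, ub, c = arrays(model)
    j_o2 = [j for j, r in enumerate(model.reactions) if r.id == o2_exchange][0]
    lb = lb.copy()
    lb[j_o2] = -1000.0
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    mu_max = float(c @ res.x)
    if mu_max <= 1e-6:
        return mu_max, 0.0
    A_ub = -c.reshape(1, -1)  # growth >= mu_max (1 - 1e-9)
    b_ub = np.array([-mu_max * (1 - 1e-9)])
    c2 = np.zeros_like(c)
    c2[j_o2] = -1.0  # maximize v_o2 (imports are negative)
    res2 = linprog(c2, A_eq=S, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
                   bounds=list(zip(lb, ub)), method="highs")
    return mu_max, max(0.0, -float(res2.x[j_o2]))


def oracle_feasible(model) -> bool:
    """Pure feasibility of the model's current constraint set."""
    S, lb, ub, _ = arrays(model)
    res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    return res.status == 0
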