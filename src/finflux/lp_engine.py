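"""Linear-programming core: FBA, parsimonious FBA, and the oxygen reference.

All solves go through the model's optlang/GLPK problem. Results are frozen
into :class:`FluxSolution` records carrying fluxes, reduced costs, status and
the tolerances under which they were produced.

Reduced costs follow cobra's convention: the derivative of the objective
value with respect to the flux variable at its active bound (for a
maximization, positive means raising the upper bound would increase the
objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cobra import Model

__all__ = [
    "LP_TOLERANCE",
    "VALIDATION_TOLERANCE",
    "FluxSolution",
    "OxygenReference",
    "InfeasibleError",
    "fba",
    "pfba",
    "oxygen_reference",
]

LP_TOLERANCE = 1e-9
VALIDATION_TOLERANCE = 1e-6


class InfeasibleError(RuntimeError):
    """Raised when an operation requires an optimal solution but none exists."""


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    reduced_costs: dict[str, float]
    status: str  # "optimal", "infeasible", or "unbounded"
    tolerance: float = VALIDATION_TOLERANCE

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def total_absolute_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


@dataclass
class OxygenReference:
    """Growth ceiling and minimal oxygen demand of a model in a medium.

    ``mu_max`` is the FBA optimum with unconstrained oxygen import; ``r_max``
    is the smallest oxygen uptake magnitude that still supports ``mu_max``.
    """

    mu_max: float
    r_max: float
    zero_growth: bool = False


def _configure(model: Model) -> None:
    model.tolerance = LP_TOLERANCE


def _extract(model: Model, status: str, objective_value: float | None) -> FluxSolution:
    if status != "optimal":
        return FluxSolution(
            objective_value=float("nan"), fluxes={}, reduced_costs={}, status=status
        )
    fluxes = {}
    reduced = {}
    for rxn in model.reactions:
        fluxes[rxn.id] = rxn.forward_variable.primal - rxn.reverse_variable.primal
        try:
            reduced[rxn.id] = rxn.forward_variable.dual - rxn.reverse_variable.dual
        except Exception:
            reduced[rxn.id] = float("nan")
    return FluxSolution(
        objective_value=float(objective_value),
        fluxes=fluxes,
        reduced_costs=reduced,
        status="optimal",
    )


def _solve(model: Model) -> FluxSolution:
    _configure(model)
    model.solver.optimize()
    status = model.solver.status
    if status not in ("optimal", "infeasible", "unbounded"):
        status = "infeasible" if status is None else str(status)
    value = model.solver.objective.value if status == "optimal" else None
    return _extract(model, status, value)


def fba(
    model: Model,
    objective: dict[str, float] | str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize a linear flux objective at steady state.

    ``objective`` may be a reaction id, a mapping reaction id -> weight, or
    ``None`` to use the model's current objective. Infeasibility and
    unboundedness are reported in ``status``, never raised silently.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    with model as m:
        if isinstance(objective, str):
            m.objective = objective
        elif isinstance(objective, dict):
            if not objective:
                raise ValueError("objective mapping is empty")
            m.objective = {
                m.reactions.get_by_id(rid): w for rid, w in objective.items()
            }
        m.objective_direction = sense
        return _solve(m)


def pfba(
    model: Model,
    growth_fraction: float = 1.0,
    objective: dict[str, float] | str | None = None,
) -> FluxSolution:
    """Parsimonious FBA: fix growth at ``growth_fraction`` of the FBA optimum
    and minimize total absolute flux.

    The L1 norm is exact: optlang already represents every flux as the
    difference of two non-negative split variables, and the second LP
    minimizes their sum. The returned record carries the parsimonious fluxes
    and reduced costs; ``objective_value`` is the growth rate attained.
    """
    if not 0 < growth_fraction <= 1:
        raise ValueError(f"growth_fraction must be in (0, 1], got {growth_fraction}")
    first = fba(model, objective=objective)
    if not first.optimal:
        return first
    target = growth_fraction * first.objective_value
    with model as m:
        if isinstance(objective, str):
            m.objective = objective
        elif isinstance(objective, dict):
            m.objective = {
                m.reactions.get_by_id(rid): w for rid, w in objective.items()
            }
        # fix the growth objective as a constraint, then minimize sum |v|
        expr = m.objective.expression
        slack = max(abs(target), 1.0) * 1e-9
        growth_cst = m.problem.Constraint(expr, lb=target - slack, ub=target + slack)
        m.add_cons_vars([growth_cst])
        l1_vars = []
        for rxn in m.reactions:
            l1_vars.append(rxn.forward_variable)
            l1_vars.append(rxn.reverse_variable)
        m.objective = m.problem.Objective(sum(l1_vars), direction="min")
        sol = _solve(m)
    if not sol.optimal:
        return sol
    growth = sum(
        w * sol.fluxes[rid]
        for rid, w in _objective_weights(model, objective).items()
    )
    sol.objective_value = float(growth)
    return sol


def _objective_weights(
    model: Model, objective: dict[str, float] | str | None
) -> dict[str, float]:
    if isinstance(objective, str):
        return {objective: 1.0}
    if isinstance(objective, dict):
        return dict(objective)
    weights = {}
    for rxn in model.reactions:
        coef = rxn.objective_coefficient
        if coef:
            weights[rxn.id] = float(coef)
    return weights


def oxygen_reference(model: Model, o2_exchange: str = "EX_o2_e") -> OxygenReference:
    """Maximal growth with unlimited oxygen and the minimal oxygen uptake
    magnitude sustaining it (two-stage LP)."""
    if o2_exchange not in model.reactions:
        raise KeyError(f"no oxygen exchange reaction {o2_exchange!r} in model")
    with model as m:
        ex = m.reactions.get_by_id(o2_exchange)
        ex.lower_bound = -1000.0
        sol = fba(m)
        if not sol.optimal:
            raise InfeasibleError(f"growth FBA is {sol.status}")
        mu_max = sol.objective_value
        if mu_max <= VALIDATION_TOLERANCE:
            return OxygenReference(mu_max=float(mu_max), r_max=0.0, zero_growth=True)
        growth_rxn = [r.id for r, w in _model_objective_items(m)]
        for rid in growth_rxn:
            rxn = m.reactions.get_by_id(rid)
            rxn.lower_bound = mu_max * (1.0 - 1e-9)
        # import is negative flux: maximizing v(EX_o2) minimizes its magnitude
        min_sol = fba(m, objective=o2_exchange, sense="max")
        if not min_sol.optimal:
            raise InfeasibleError(f"oxygen minimization is {min_sol.status}")
        r_max = max(0.0, -min_sol.fluxes[o2_exchange])
    return OxygenReference(mu_max=float(mu_max), r_max=float(r_max))


def _model_objective_items(model: Model):
    return [
        (rxn, rxn.objective_coefficient)
        for rxn in model.reactions
        if rxn.objective_coefficient
    ]
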