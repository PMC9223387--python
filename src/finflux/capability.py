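"""Metabolic capability screens: nutrient essentiality, task evaluation, and
enumeration of minimal growth-supporting uptake/secretion sets.

Essentiality follows the classic knock-out-the-uptake protocol: with all
boundary reactions open, each nutrient's import is disabled in turn and the
growth optimum recomputed; a nutrient is essential when growth collapses
below ``GROWTH_ZERO_THRESHOLD``.

Minimal-set enumeration is a MILP over indicator variables: uptake (or
secretion) of a boundary metabolite is allowed only when its binary
indicator is on, the number of active indicators is minimized, and exclusion
cuts enumerate successive support-minimal sets. Water is treated as a free
metabolite (always exchangeable, never reported in a set), as is standard in
medium formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cobra import Model, Reaction

from .lp_engine import fba
from .model_core import ModelValidationError

__all__ = [
    "GROWTH_ZERO_THRESHOLD",
    "MetabolicTask",
    "TaskResult",
    "MinimalSetProblem",
    "essentiality_screen",
    "evaluate_task",
    "load_tasks",
    "minimal_uptake_sets",
    "minimal_secretion_sets",
]

GROWTH_ZERO_THRESHOLD = 1e-6
_BIG = 1000.0
FREE_METABOLITES = frozenset({"h2o"})


# ---------------------------------------------------------------- essentiality

def _open_all_boundaries(model: Model) -> None:
    for rxn in model.boundary:
        rxn.bounds = (-_BIG, _BIG)


def essentiality_screen(
    model: Model, nutrients: list[str]
) -> dict[str, str]:
    """Classify each nutrient exchange as ``essential`` or ``non_essential``.

    ``nutrients`` are exchange-reaction ids. All boundary reactions are
    opened for both uptake and secretion; each listed uptake is then disabled
    alone and growth re-maximized. Order of the screen does not matter.
    """
    with model as m:
        _open_all_boundaries(m)
        baseline = fba(m)
        if not baseline.optimal or baseline.objective_value <= GROWTH_ZERO_THRESHOLD:
            raise ModelValidationError(
                "essentiality screen undefined: zero baseline growth"
            )
        result: dict[str, str] = {}
        for rid in nutrients:
            rxn = m.reactions.get_by_id(rid)
            old = rxn.lower_bound
            rxn.lower_bound = 0.0
            sol = fba(m)
            growth = sol.objective_value if sol.optimal else 0.0
            result[rid] = (
                "essential" if growth <= GROWTH_ZERO_THRESHOLD else "non_essential"
            )
            rxn.lower_bound = old
    return result


# ----------------------------------------------------------------------- tasks

@dataclass
class MetabolicTask:
    """A should-happen / should-fail test of metabolic capability.

    Uptakes and secretions reference metabolites by base id (compartment
    suffixes are tolerated); metabolites from compartments absent in the
    model are remapped to the cytosol.
    """

    id: str
    system: str
    required_uptakes: list[tuple[str, float]] = field(default_factory=list)
    required_secretions: list[tuple[str, float]] = field(default_factory=list)
    expected: str = "feasible"  # or "infeasible"


@dataclass
class TaskResult:
    task_id: str
    observed: str  # "feasible", "infeasible", or "unmappable"
    passed: bool
    detail: str = ""


def load_tasks(path=None) -> list[MetabolicTask]:
    """Load a task library from JSON (a list of objects with id, system,
    uptakes, secretions, expected). Without a path, the bundled toy-scale
    library (~20 tasks matched to the synthetic core model) is returned."""
    import importlib.resources
    import json
    from pathlib import Path

    if path is None:
        ref = importlib.resources.files("finflux.data") / "toy_tasks.json"
        with importlib.resources.as_file(ref) as p:
            raw = json.loads(Path(p).read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return [
        MetabolicTask(
            id=item["id"], system=item.get("system", ""),
            required_uptakes=[(m, float(r)) for m, r in item.get("uptakes", [])],
            required_secretions=[
                (m, float(r)) for m, r in item.get("secretions", [])
            ],
            expected=item.get("expected", "feasible"),
        )
        for item in raw
    ]


def _resolve_task_metabolite(model: Model, ref: str):
    """Map a task metabolite reference onto a model metabolite.

    Tries exact id, then extracellular, then cytosol (the remap-to-cytosol
    rule for compartments the model lacks). Returns None when the metabolite
    is entirely absent.
    """
    if ref in model.metabolites:
        return model.metabolites.get_by_id(ref)
    base = ref.rsplit("_", 1)[0] if "_" in ref else ref
    for candidate in (f"{ref}_e", f"{ref}_c", f"{base}_e", f"{base}_c"):
        if candidate in model.metabolites:
            return model.metabolites.get_by_id(candidate)
    return None


def _boundary_for(model: Model, met) -> Reaction:
    """Existing single-metabolite boundary reaction for ``met``, or a fresh
    temporary one (used for cytosolic remaps)."""
    for rxn in met.reactions:
        if len(rxn.metabolites) == 1:
            return rxn
    rxn = Reaction(f"TASK_BOUNDARY_{met.id}")
    rxn.add_metabolites({met: -1.0})
    rxn.bounds = (0.0, 0.0)
    model.add_reactions([rxn])
    return rxn


def evaluate_task(model: Model, task: MetabolicTask) -> TaskResult:
    """Evaluate one metabolic task.

    All regular boundary reactions are closed; the task's uptakes are opened
    (import up to the stated rate) and its secretions are demanded (export at
    least the stated rate). The task passes when LP feasibility matches
    ``task.expected``.
    """
    with model as m:
        for rxn in m.boundary:
            rxn.bounds = (0.0, 0.0)
        for base in FREE_METABOLITES:
            try:
                _exchange_of(m, base).bounds = (-_BIG, _BIG)
            except KeyError:
                pass
        for ref, rate in task.required_uptakes:
            met = _resolve_task_metabolite(m, ref)
            if met is None:
                return TaskResult(task.id, "unmappable", False,
                                  f"uptake metabolite {ref!r} absent from model")
            rxn = _boundary_for(m, met)
            rxn.lower_bound = -abs(rate)
        demands = []
        for ref, rate in task.required_secretions:
            met = _resolve_task_metabolite(m, ref)
            if met is None:
                return TaskResult(task.id, "unmappable", False,
                                  f"secretion metabolite {ref!r} absent from model")
            rxn = _boundary_for(m, met)
            rxn.upper_bound = _BIG
            rxn.lower_bound = max(rxn.lower_bound, abs(rate))
            demands.append(rxn.id)
        sol = fba(m, objective={d: 1.0 for d in demands} if demands else None)
        observed = "feasible" if sol.optimal else "infeasible"
    passed = observed == task.expected
    return TaskResult(task.id, observed, passed,
                      "" if passed else f"expected {task.expected}, got {observed}")


# ---------------------------------------------------------------- minimal sets

@dataclass
class MinimalSetProblem:
    """Constraints for minimal uptake/secretion set enumeration.

    ``forced_uptakes``/``forced_secretions`` are base metabolite ids whose
    exchange must stay active; ``alternatives`` lists groups where at least
    one member must be secreted; ``min_growth`` is the growth rate every
    returned set must support.
    """

    forced_uptakes: set[str] = field(default_factory=set)
    forced_secretions: set[str] = field(default_factory=set)
    alternatives: list[set[str]] = field(default_factory=list)
    min_growth: float = 1.0

    def validate(self) -> None:
        if self.min_growth <= 0:
            raise ModelValidationError("min_growth must be positive")


def _exchange_of(model: Model, base: str) -> Reaction:
    rid = f"EX_{base}_e"
    if rid in model.reactions:
        return model.reactions.get_by_id(rid)
    for rxn in model.boundary:
        if base in {m.id.rsplit("_", 1)[0] for m in rxn.metabolites}:
            return rxn
    raise KeyError(f"no exchange reaction for metabolite {base!r}")


def _growth_reaction(model: Model) -> Reaction:
    objs = [r for r in model.reactions if r.objective_coefficient]
    if len(objs) != 1:
        raise ModelValidationError("expected exactly one objective (growth) reaction")
    return objs[0]


def _boundary_bases(model: Model) -> list[str]:
    bases = []
    for rxn in model.boundary:
        (met,) = rxn.metabolites
        base = met.id.rsplit("_", 1)[0]
        if base not in FREE_METABOLITES:
            bases.append(base)
    return sorted(set(bases))


def _enumerate_minimal_sets(
    model: Model,
    problem: MinimalSetProblem,
    role: str,
    candidates: list[str] | None,
    allowed_uptakes: set[str] | None,
    max_sets: int,
    secretion_rate: float = 1e-3,
) -> list[frozenset[str]]:
    """Shared MILP enumeration for uptake ('uptake') or secretion ('secretion')
    roles. Returns support-minimal sets of base metabolite ids."""
    problem.validate()
    if candidates is None:
        candidates = _boundary_bases(model)
    # operate on a private copy: binary variables and exclusion cuts do not
    # roll back cleanly through the GLPK backend's context history
    m = model.copy()
    with m:
        growth = _growth_reaction(m)
        growth.lower_bound = problem.min_growth
        # baseline: close everything, then free water
        for rxn in m.boundary:
            rxn.bounds = (0.0, 0.0)
        for base in FREE_METABOLITES:
            try:
                _exchange_of(m, base).bounds = (-_BIG, _BIG)
            except KeyError:
                pass
        for base in problem.forced_uptakes:
            _exchange_of(m, base).lower_bound = -_BIG
        for base in problem.forced_secretions:
            ex = _exchange_of(m, base)
            ex.bounds = (secretion_rate, _BIG)  # must actually be secreted
        if role == "secretion" and allowed_uptakes:
            for base in allowed_uptakes:
                _exchange_of(m, base).lower_bound = -_BIG

        if role == "uptake":
            # secretions are unrestricted while enumerating uptakes, except
            # the alternative groups which impose their own disjunction
            for rxn in m.boundary:
                rxn.upper_bound = _BIG

        indicator = {}
        cons = []
        if role == "uptake":
            excluded = set(problem.forced_uptakes)
        else:
            # metabolites open for uptake cannot carry a secretion indicator
            # (the efflux-forcing constraint would forbid their import)
            excluded = set(problem.forced_secretions) | set(problem.forced_uptakes)
            excluded |= set(allowed_uptakes or ())
        pool = [b for b in candidates if b not in excluded]
        for base in pool:
            ex = _exchange_of(m, base)
            y = m.problem.Variable(f"y_{role}_{base}", type="binary")
            indicator[base] = y
            if role == "uptake":
                ex.lower_bound = -_BIG
                # v >= -BIG * y  (import only when indicator on)
                cons.append(
                    m.problem.Constraint(ex.flux_expression + _BIG * y, lb=0.0)
                )
            else:
                ex.upper_bound = _BIG
                # v <= BIG * y and v >= rate * y (secretion means real efflux)
                cons.append(
                    m.problem.Constraint(ex.flux_expression - _BIG * y, ub=0.0)
                )
                cons.append(
                    m.problem.Constraint(
                        ex.flux_expression - secretion_rate * y, lb=0.0
                    )
                )
        # alternative secretion groups (at least one member secreted)
        for group in problem.alternatives:
            terms = []
            for base in group:
                ex = _exchange_of(m, base)
                ex.upper_bound = _BIG
                z = m.problem.Variable(f"z_alt_{base}", type="binary")
                cons.append(
                    m.problem.Constraint(
                        ex.flux_expression - secretion_rate * z, lb=0.0
                    )
                )
                terms.append(z)
            cons.append(m.problem.Constraint(sum(terms), lb=1.0))
        m.add_cons_vars(list(indicator.values()) + cons)
        m.objective = m.problem.Objective(sum(indicator.values()), direction="min")

        found: list[frozenset[str]] = []
        while len(found) < max_sets:
            m.solver.optimize()
            if m.solver.status != "optimal":
                break
            active = frozenset(
                b for b, y in indicator.items() if y.primal > 0.5
            )
            found.append(active)
            if not active:
                break  # forced set alone suffices; nothing smaller exists
            cut = m.problem.Constraint(
                sum(indicator[b] for b in active), ub=len(active) - 1
            )
            m.add_cons_vars([cut])
    return found


def _feasible_with(
    model: Model,
    problem: MinimalSetProblem,
    role: str,
    members: frozenset[str],
    allowed_uptakes: set[str] | None,
) -> bool:
    """Feasibility re-check with exactly ``members`` active in ``role``."""
    with model as m:
        growth = _growth_reaction(m)
        growth.lower_bound = problem.min_growth
        for rxn in m.boundary:
            rxn.bounds = (0.0, 0.0)
        for base in FREE_METABOLITES:
            try:
                _exchange_of(m, base).bounds = (-_BIG, _BIG)
            except KeyError:
                pass
        open_uptakes = set(problem.forced_uptakes)
        if role == "uptake":
            open_uptakes |= members
            for rxn in m.boundary:
                rxn.upper_bound = _BIG
        else:
            if allowed_uptakes:
                open_uptakes |= allowed_uptakes
            for base in members:
                _exchange_of(m, base).upper_bound = _BIG
        for base in problem.forced_secretions:
            _exchange_of(m, base).bounds = (1e-3, _BIG)
        for base in open_uptakes:
            _exchange_of(m, base).lower_bound = -_BIG
        sol = fba(m)
        return sol.optimal and sol.objective_value >= problem.min_growth - 1e-9


def _prune_to_support_minimal(
    model: Model,
    problem: MinimalSetProblem,
    role: str,
    sets: list[frozenset[str]],
    allowed_uptakes: set[str] | None,
) -> list[frozenset[str]]:
    minimal = []
    for s in sets:
        ok = True
        for member in s:
            if _feasible_with(model, problem, role, s - {member}, allowed_uptakes):
                ok = False
                break
        if ok and _feasible_with(model, problem, role, s, allowed_uptakes):
            minimal.append(s)
    return minimal


def minimal_uptake_sets(
    model: Model,
    problem: MinimalSetProblem,
    max_sets: int = 10,
    candidates: list[str] | None = None,
) -> list[frozenset[str]]:
    """Enumerate support-minimal sets of boundary metabolites whose uptake
    (beyond the forced ones) supports ``problem.min_growth``.

    Returns base metabolite ids, smallest sets first; empty list when the
    problem is infeasible even with every candidate open.
    """
    sets = _enumerate_minimal_sets(
        model, problem, "uptake", candidates, None, max_sets
    )
    return _prune_to_support_minimal(model, problem, "uptake", sets, None)


def minimal_secretion_sets(
    model: Model,
    problem: MinimalSetProblem,
    allowed_uptakes: set[str],
    max_sets: int = 10,
    candidates: list[str] | None = None,
) -> list[frozenset[str]]:
    """Enumerate support-minimal secretion sets given the allowed uptakes
    (typically the union of metabolites found in minimal uptake sets)."""
    sets = _enumerate_minimal_sets(
        model, problem, "secretion", candidates, allowed_uptakes, max_sets
    )
    return _prune_to_support_minimal(
        model, problem, "secretion", sets, allowed_uptakes
    )
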