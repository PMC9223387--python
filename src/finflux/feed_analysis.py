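"""Feed-uptake reactions, limiting-amino-acid identification, and iterative
supplementation.

A feed is represented as one boundary reaction that delivers amino acids in
the feed's mass ratios, scaled so that one unit of feed flux supplies exactly
1 g of amino-acid mass. With growth fixed and total consumed mass minimized,
the reduced costs of the amino-acid exchange reactions — weighted by molar
mass so that large residues are not favored — rank amino acids by how much
growth is limited by their supply. The most limiting amino acid is opened
for import with a mass-priced penalty, and the procedure repeats until no
amino acid is limiting, yielding a supplementation trace with the feed
efficiency after each step.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
from cobra import Model, Reaction

from .chem import AMINO_ACIDS, molar_mass
from .lp_engine import FluxSolution, fba
from .model_core import ModelValidationError

__all__ = [
    "FeedComposition",
    "SupplementationTrace",
    "load_feed_table",
    "feed_from_table",
    "balanced_feed",
    "build_feed_reaction",
    "limiting_amino_acid",
    "supplement_iteratively",
    "feed_efficiency",
]

_BIG = 1000.0
PERCENT_TOL = 0.5
#: score threshold below which no amino acid is called limiting (g-weighted
#: reduced cost; scores scale with the mass-minimization objective, so this
#: is a pure numerical-noise cutoff)
LIMITING_SCORE_TOL = 1e-6


@dataclass
class FeedComposition:
    """Amino-acid mass composition of a feed ingredient.

    ``mass_percent`` maps amino acids to percent of total amino-acid mass;
    combined entries (``asn/asp``, ``gln/glu``) are split half/half by mass.
    """

    name: str
    mass_percent: dict[str, float]
    molar_masses: dict[str, float] = field(
        default_factory=lambda: {aa: molar_mass(aa) for aa in AMINO_ACIDS}
    )

    def validate(self) -> None:
        total = sum(self.mass_percent.values())
        if abs(total - 100.0) > PERCENT_TOL:
            raise ModelValidationError(
                f"feed {self.name!r} percentages sum to {total}, expected 100"
            )
        for key in self._split_keys():
            if key not in self.molar_masses:
                raise ModelValidationError(f"unknown amino acid {key!r} in feed")
        for aa, mass in self.molar_masses.items():
            if mass <= 0:
                raise ModelValidationError(f"non-positive molar mass for {aa!r}")

    def _split_keys(self):
        for key in self.mass_percent:
            for part in key.split("/"):
                yield part.strip().lower()

    def mass_fractions(self) -> dict[str, float]:
        """Per-amino-acid mass fractions, combined entries split equally and
        the whole renormalized to sum to exactly 1."""
        self.validate()
        split: dict[str, float] = {}
        for key, percent in self.mass_percent.items():
            parts = [p.strip().lower() for p in key.split("/")]
            for part in parts:
                split[part] = split.get(part, 0.0) + percent / len(parts)
        total = sum(split.values())
        return {aa: w / total for aa, w in split.items()}


def load_feed_table() -> pd.DataFrame:
    """Bundled feed-ingredient table (mass % of total amino-acid mass),
    indexed by amino acid with one column per ingredient."""
    ref = importlib.resources.files("finflux.data") / "feed_ingredients.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="amino_acid")


def feed_from_table(name: str) -> FeedComposition:
    """A named feed (``fish_meal``, ``soybean_meal``, ``insect_meal``) from
    the bundled table."""
    table = load_feed_table()
    if name not in table.columns:
        raise KeyError(f"unknown feed {name!r}; available: {list(table.columns)}")
    return FeedComposition(name=name, mass_percent=table[name].to_dict())


def balanced_feed(
    model: Model, name: str = "balanced", fixed_growth: float = 1.0
) -> FeedComposition:
    """A feed whose amino-acid mass ratios match the model's cheapest
    amino-acid diet at the given growth rate, so that no amino acid is
    limiting.

    The mix is computed by a mass-minimization LP with every amino-acid
    exchange open for import (no feed reaction): the optimal import fluxes,
    mass-weighted, give the ratios. This accounts for all amino-acid sinks
    (protein plus nitrogen for nucleotide and non-essential amino-acid
    synthesis), not just the protein stoichiometry; a feed proportional to
    protein demand alone would be slightly nitrogen-short.
    """
    with model as m:
        growth = m.reactions.get_by_id("BIOMASS")
        growth.bounds = (fixed_growth, fixed_growth)
        for base in ("glc", "o2", "pi", "chol", "h2o"):
            rid = f"EX_{base}_e"
            if rid in m.reactions:
                m.reactions.get_by_id(rid).lower_bound = -_BIG
        coeffs = {}
        for aa in AMINO_ACIDS:
            rid = f"EX_{aa}_e"
            if rid not in m.reactions:
                continue
            ex = m.reactions.get_by_id(rid)
            ex.bounds = (-_BIG, 0.0)
            coeffs[ex] = -molar_mass(aa) / 1000.0
        m.objective = coeffs
        m.objective_direction = "min"
        sol = fba(m, sense="min")
        if not sol.optimal:
            raise ModelValidationError("balanced-feed LP did not solve")
        demand_mass = {
            aa: -sol.fluxes[f"EX_{aa}_e"] * molar_mass(aa)
            for aa in AMINO_ACIDS
            if f"EX_{aa}_e" in sol.fluxes and sol.fluxes[f"EX_{aa}_e"] < -1e-9
        }
    total = sum(demand_mass.values())
    return FeedComposition(
        name=name,
        mass_percent={aa: 100.0 * mm / total for aa, mm in demand_mass.items()},
    )


def build_feed_reaction(feed: FeedComposition, model: Model | None = None) -> Reaction:
    """Boundary reaction delivering the feed's amino acids.

    Coefficient of amino acid ``i`` is ``1000 * w_i / M_i`` mmol per unit
    flux (``w_i`` normalized mass fraction, ``M_i`` free molar mass), so one
    unit of feed flux supplies exactly 1 g of amino-acid mass. Metabolites
    are the extracellular species when a model is given.
    """
    fractions = feed.mass_fractions()
    rxn = Reaction(f"FEED_{feed.name}", name=f"feed uptake ({feed.name})")
    stoich = {}
    for aa, w in fractions.items():
        coeff = 1000.0 * w / feed.molar_masses[aa]
        if model is not None:
            met = model.metabolites.get_by_id(f"{aa}_e")
        else:
            from cobra import Metabolite

            met = Metabolite(f"{aa}_e", name=aa, compartment="e")
        stoich[met] = coeff
    rxn.add_metabolites(stoich)
    rxn.bounds = (0.0, _BIG)
    return rxn


def _prepare_feed_lp(
    model: Model,
    feed_rxn_id: str,
    fixed_growth: float,
    supplemented: dict[str, float],
    penalty_scale: float,
) -> None:
    """Configure the feed-minimization LP in-place (inside a model context).

    Growth is fixed, glucose/oxygen/phosphate/choline/water uptake is
    unlimited, amino-acid import through regular exchanges is disabled
    (surplus export stays open), and supplemented amino acids are re-opened
    import-only. The minimization objective prices one unit of feed flux as
    1 g and supplement imports at ``penalty_scale`` times their mass.
    """
    growth = model.reactions.get_by_id("BIOMASS")
    growth.bounds = (fixed_growth, fixed_growth)
    for base in ("glc", "o2", "pi", "chol", "h2o"):
        rid = f"EX_{base}_e"
        if rid in model.reactions:
            model.reactions.get_by_id(rid).lower_bound = -_BIG
    coeffs = {model.reactions.get_by_id(feed_rxn_id): 1.0}
    for aa in AMINO_ACIDS:
        rid = f"EX_{aa}_e"
        if rid not in model.reactions:
            continue
        ex = model.reactions.get_by_id(rid)
        if aa in supplemented:
            ex.bounds = (-_BIG, 0.0)  # import only
            # mass-priced penalty in g: M/1000 per mmol imported
            coeffs[ex] = -penalty_scale * molar_mass(aa) / 1000.0
        else:
            ex.bounds = (0.0, _BIG)  # surplus export allowed, import blocked
    model.objective = coeffs
    model.objective_direction = "min"


def _limiting_scores(solution: FluxSolution, supplemented: set[str]) -> dict[str, float]:
    """Mass-weighted reduced costs of closed amino-acid exchanges.

    A positive score means that allowing import of that amino acid would
    reduce the mass-minimization objective (it is growth limiting); the
    returned scores are comparable across amino acids because the molar mass
    converts the per-mmol reduced cost to a per-gram basis... of benefit per
    unit uptake.
    """
    scores = {}
    for aa in AMINO_ACIDS:
        rid = f"EX_{aa}_e"
        if rid in solution.reduced_costs and aa not in supplemented:
            scores[aa] = molar_mass(aa) * solution.reduced_costs[rid] / 1000.0
    return scores


def limiting_amino_acid(
    model: Model,
    feed: FeedComposition | str,
    fixed_growth: float = 1.0,
    supplemented: dict[str, float] | None = None,
    penalty_scale: float = 1.0,
) -> tuple[str | None, FluxSolution]:
    """Identify the growth-limiting amino acid of a feed.

    Returns ``(amino_acid, solution)``; the amino acid is ``None`` when no
    closed exchange has a limiting mass-weighted reduced cost ("none
    limiting", e.g. for a perfectly balanced feed). Ties break
    lexicographically.
    """
    if isinstance(feed, str):
        feed = feed_from_table(feed)
    supplemented = dict(supplemented or {})
    with model as m:
        feed_rxn = build_feed_reaction(feed, m)
        m.add_reactions([feed_rxn])
        _prepare_feed_lp(m, feed_rxn.id, fixed_growth, supplemented, penalty_scale)
        sol = fba(m, objective=None, sense="min")
        if not sol.optimal:
            raise ModelValidationError(
                f"feed LP for {feed.name!r} is {sol.status} at growth {fixed_growth}"
            )
        scores = _limiting_scores(sol, set(supplemented))
        base_cost = _objective_cost(sol, feed_rxn.id, supplemented, penalty_scale)
        # Reduced costs rank the candidates, but at degenerate optima (ties
        # between simultaneously binding amino acids) the dual is not unique
        # and can flag an amino acid whose true marginal value is zero.
        # Confirm the winner with one perturbation solve: supplementing a
        # truly limiting amino acid at mass parity must lower the total cost.
        for aa in sorted(scores, key=lambda a: (-scores[a], a)):
            if scores[aa] <= LIMITING_SCORE_TOL:
                break
            trial = dict(supplemented)
            trial[aa] = molar_mass(aa)
            _prepare_feed_lp(m, feed_rxn.id, fixed_growth, trial, penalty_scale)
            trial_sol = fba(m, objective=None, sense="min")
            if not trial_sol.optimal:
                continue
            trial_cost = _objective_cost(trial_sol, feed_rxn.id, trial, penalty_scale)
            if base_cost - trial_cost > 1e-7 * max(1.0, abs(base_cost)):
                return aa, sol
    return None, sol


def _objective_cost(
    solution: FluxSolution,
    feed_rxn_id: str,
    supplemented: dict[str, float],
    penalty_scale: float,
) -> float:
    """Value of the mass-priced objective: feed mass plus penalized
    supplement mass (g/gDW/h)."""
    cost = solution.fluxes.get(feed_rxn_id, 0.0)
    for aa in supplemented:
        v = solution.fluxes.get(f"EX_{aa}_e", 0.0)
        if v < 0:
            cost += -v * penalty_scale * molar_mass(aa) / 1000.0
    return float(cost)


@dataclass
class SupplementationTrace:
    """Ordered record of supplementation steps and feed efficiencies.

    Efficiencies are gDW biomass per g total consumed mass (feed plus
    supplements); ``inverse`` views are mg consumed per gDW produced.
    """

    feed_name: str
    baseline_efficiency: float
    steps: list[tuple[str, float]] = field(default_factory=list)

    @property
    def supplemented(self) -> list[str]:
        return [aa for aa, _ in self.steps]

    @property
    def efficiencies(self) -> list[float]:
        return [self.baseline_efficiency] + [eff for _, eff in self.steps]

    @property
    def inverse_efficiencies_mg(self) -> list[float]:
        return [1000.0 / e for e in self.efficiencies]


def consumed_mass_flux(solution: FluxSolution, feed_rxn_id: str) -> float:
    """Total consumed mass in g/gDW/h: feed flux (1 g per unit) plus
    mass-weighted supplement imports."""
    total = solution.fluxes.get(feed_rxn_id, 0.0)
    for aa in AMINO_ACIDS:
        v = solution.fluxes.get(f"EX_{aa}_e", 0.0)
        if v < 0:
            total += -v * molar_mass(aa) / 1000.0
    return float(total)


def feed_efficiency(
    solution: FluxSolution, fixed_growth: float, feed_rxn_id: str
) -> tuple[float, float]:
    """Feed efficiency pair: (gDW biomass per g consumed, mg consumed per
    gDW biomass)."""
    mass = consumed_mass_flux(solution, feed_rxn_id)
    if mass <= 0:
        raise ModelValidationError("no mass consumed; efficiency undefined")
    eff = fixed_growth / mass
    return float(eff), float(1000.0 / eff)


def supplement_iteratively(
    model: Model,
    feed: FeedComposition | str,
    fixed_growth: float = 1.0,
    penalty_scale: float = 1.0,
) -> SupplementationTrace:
    """Repeatedly supplement the most limiting amino acid until none remains.

    Each step re-solves the mass-minimization LP with the supplement's
    exchange opened import-only and priced at ``penalty_scale`` times its
    mass, and records the feed efficiency after the step. Guards against
    non-termination at one step per amino acid.
    """
    if isinstance(feed, str):
        feed = feed_from_table(feed)
    feed_rxn_id = f"FEED_{feed.name}"
    supplemented: dict[str, float] = {}
    aa_id, sol = limiting_amino_acid(model, feed, fixed_growth, supplemented,
                                     penalty_scale)
    baseline = fixed_growth / consumed_mass_flux(sol, feed_rxn_id)
    trace = SupplementationTrace(feed_name=feed.name, baseline_efficiency=baseline)
    n_guard = len(AMINO_ACIDS)
    while aa_id is not None:
        if len(supplemented) >= n_guard:
            raise ModelValidationError(
                "supplementation failed to terminate within one step per amino acid"
            )
        supplemented[aa_id] = molar_mass(aa_id)
        aa_next, sol = limiting_amino_acid(
            model, feed, fixed_growth, supplemented, penalty_scale
        )
        eff, _ = feed_efficiency(sol, fixed_growth, feed_rxn_id)
        trace.steps.append((aa_id, eff))
        aa_id = aa_next
    return trace
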