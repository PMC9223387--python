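"""Model container, SBML/JSON IO, summary statistics, and biomass assembly.

The in-memory container is :class:`cobra.Model`; this module wraps reading,
writing, validation, and the two model-level computations that the rest of
the toolkit relies on: content summaries (gene/reaction/metabolite counts,
transport and boundary classification, degree distributions) and assembly of
a mass-normalized biomass reaction from a macromolecule recipe.

Sign convention for boundary reactions: negative flux is import into the
system, positive flux is export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import cobra
import pandas as pd
from cobra import Metabolite, Reaction

__all__ = [
    "BiomassRecipe",
    "ModelValidationError",
    "read_model",
    "write_model",
    "validate_model",
    "base_metabolite_id",
    "metabolite_molar_mass",
    "summarize_model",
    "degree_distributions",
    "build_biomass_reaction",
]

FRACTION_TOL = 1e-9
MASS_TOL = 1e-6


class ModelValidationError(ValueError):
    """A structural invariant of a metabolic model does not hold."""


def read_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a metabolic model from SBML (Level 3 + FBC) or community JSON.

    ``format`` is inferred from the file suffix when not given. Malformed
    files raise :class:`ModelValidationError` with the parser's context.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("sbml", "json"):
        raise ValueError(f"unknown model format {format!r}")
    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # libsbml / json parse failures
        raise ModelValidationError(f"could not parse {path}: {exc}") from exc
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    """Write a model to SBML L3+FBC or community JSON (by suffix or ``format``)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif format == "json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants; raise :class:`ModelValidationError` if violated."""
    compartments = set(model.compartments) | {m.compartment for m in model.metabolites}
    for met in model.metabolites:
        if met.compartment is None or met.compartment not in compartments:
            raise ModelValidationError(
                f"metabolite {met.id!r} has unknown compartment {met.compartment!r}"
            )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lower bound above upper bound"
            )
        if not rxn.metabolites:
            raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
    if not model.reactions:
        raise ModelValidationError("model has no reactions")


def base_metabolite_id(met: Metabolite) -> str:
    """Metabolite id with its compartment suffix stripped (``glc_c`` -> ``glc``)."""
    suffix = f"_{met.compartment}"
    if met.compartment and met.id.endswith(suffix):
        return met.id[: -len(suffix)]
    return met.id


def metabolite_molar_mass(met: Metabolite) -> float | None:
    """Molar mass in g/mol, from ``notes['molar_mass']`` or the chemical formula."""
    mass = met.notes.get("molar_mass") if met.notes else None
    if mass is not None:
        return float(mass)
    if met.formula:
        try:
            return float(met.formula_weight)
        except Exception:
            return None
    return None


def _is_boundary(rxn: Reaction) -> bool:
    return len(rxn.metabolites) == 1


def _is_transport(rxn: Reaction) -> bool:
    return len({m.compartment for m in rxn.metabolites}) >= 2


def summarize_model(model: cobra.Model) -> pd.Series:
    """Content summary of a model as a pandas Series.

    Counts genes, reactions, metabolites, compartment-collapsed unique
    metabolites, transport reactions (touching >= 2 compartments), and
    boundary reactions (single-metabolite exchanges, sinks, and demands),
    plus per-compartment metabolite counts. Invariant to reaction order.
    """
    unique = {base_metabolite_id(m) for m in model.metabolites}
    counts = {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "unique_metabolites": len(unique),
        "transport_reactions": sum(_is_transport(r) for r in model.reactions),
        "boundary_reactions": sum(_is_boundary(r) for r in model.reactions),
        "compartments": len(set(m.compartment for m in model.metabolites)),
    }
    for comp in sorted({m.compartment for m in model.metabolites}):
        counts[f"metabolites_{comp}"] = sum(
            m.compartment == comp for m in model.metabolites
        )
    return pd.Series(counts, name=model.id or "model")


def degree_distributions(model: cobra.Model) -> dict[str, pd.Series]:
    """Network degree distributions: metabolites/genes per reaction and
    reactions per metabolite/gene."""
    return {
        "metabolites_per_reaction": pd.Series(
            {r.id: len(r.metabolites) for r in model.reactions}
        ),
        "genes_per_reaction": pd.Series(
            {r.id: len(r.genes) for r in model.reactions}
        ),
        "reactions_per_metabolite": pd.Series(
            {m.id: len(m.reactions) for m in model.metabolites}
        ),
        "reactions_per_gene": pd.Series(
            {g.id: len(g.reactions) for g in model.genes}
        ),
    }


@dataclass
class BiomassRecipe:
    """Macromolecular composition of 1 gDW of biomass.

    ``macromolecule_fractions`` maps macromolecule name to its mass fraction
    of dry weight; ``monomer_fractions`` maps each macromolecule to the mass
    fractions of its monomers. Both mappings must sum to 1. ``energy_cost``
    is the ATP demand of polymer synthesis in mmol ATP per g protein.
    """

    macromolecule_fractions: dict[str, float]
    monomer_fractions: dict[str, dict[str, float]]
    energy_cost: float = 30.0

    def validate(self) -> None:
        total = sum(self.macromolecule_fractions.values())
        if abs(total - 1.0) > FRACTION_TOL:
            raise ModelValidationError(
                f"macromolecule_fractions sum to {total!r}, expected 1"
            )
        for macro, fractions in self.monomer_fractions.items():
            sub = sum(fractions.values())
            if abs(sub - 1.0) > FRACTION_TOL:
                raise ModelValidationError(
                    f"monomer fractions of {macro!r} sum to {sub!r}, expected 1"
                )
        missing = set(self.macromolecule_fractions) - set(self.monomer_fractions)
        if missing:
            raise ModelValidationError(
                f"no monomer composition for macromolecules {sorted(missing)}"
            )


def build_biomass_reaction(
    recipe: BiomassRecipe,
    monomer_masses: dict[str, float],
    metabolites: dict[str, Metabolite] | None = None,
    energy_pair: tuple[Metabolite, Metabolite] | None = None,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Assemble a biomass reaction consuming exactly 1 g of precursors per
    unit flux.

    The coefficient of monomer ``m`` belonging to macromolecule ``M`` is
    ``1000 * fraction(M) * mass_fraction(m | M) / molar_mass(m)`` in
    mmol/gDW, so that one unit of biomass flux drains one gram of monomer
    mass. If ``energy_pair = (atp, adp)`` is given, an ATP hydrolysis term of
    ``energy_cost * fraction(protein)`` mmol is added (ATP consumed, ADP
    produced); energy terms are not part of the 1 g normalization.
    """
    recipe.validate()
    coefficients: dict[str, float] = {}
    for macro, macro_frac in recipe.macromolecule_fractions.items():
        for monomer, w in recipe.monomer_fractions[macro].items():
            if monomer not in monomer_masses:
                raise ModelValidationError(f"missing molar mass for monomer {monomer!r}")
            coeff = 1000.0 * macro_frac * w / monomer_masses[monomer]
            coefficients[monomer] = coefficients.get(monomer, 0.0) + coeff

    total_mass = sum(c * monomer_masses[m] for m, c in coefficients.items()) / 1000.0
    if abs(total_mass - 1.0) > MASS_TOL:
        raise ModelValidationError(
            f"biomass precursor mass is {total_mass} g per unit flux, expected 1"
        )

    if metabolites is None:
        metabolites = {
            m: Metabolite(f"{m}_c", name=m, compartment="c") for m in coefficients
        }
    rxn = Reaction(reaction_id, name="biomass")
    rxn.add_metabolites({metabolites[m]: -c for m, c in coefficients.items()})
    if energy_pair is not None and recipe.energy_cost > 0:
        protein_frac = recipe.macromolecule_fractions.get("protein", 0.0)
        atp_demand = recipe.energy_cost * protein_frac
        if atp_demand > 0:
            atp, adp = energy_pair
            rxn.add_metabolites({atp: -atp_demand, adp: atp_demand})
    rxn.bounds = (0.0, 1000.0)
    return rxn
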