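"""Synthetic "salmon-like" core metabolic model and randomized conditions.

The generator emits a small (~70 reaction) flux-consistent model that mimics
the metabolic traits the downstream analyses depend on:

* three compartments (extracellular ``e``, cytosol ``c``, mitochondrion ``m``);
* exchange + transport reactions for glucose, O2, CO2, NH3, urea, phosphate,
  choline, water, lactate, and the 20 proteinogenic amino acids;
* ten dietary-essential amino acids (Arg, His, Ile, Leu, Lys, Met, Phe, Thr,
  Trp, Val) with no internal synthesis route, the rest synthesizable from
  pyruvate + NH3 + ATP;
* lumped aerobic energy metabolism (glycolysis, mitochondrial respiration)
  and an optional anaerobic lactate route;
* ATP-free ammonia disposal and an ATP-costly, capacity-limited urea route,
  reflecting the low ureotelic capacity of teleost fish;
* a biomass reaction draining exactly 1 g of monomer mass per unit flux.

Lumped reactions are mass-closed with a water makeweight (coefficients are
chosen so that stoichiometry times molar mass sums to zero); elemental
balance is not enforced for lumped conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cobra import Metabolite, Model, Reaction

from .chem import (
    AMINO_ACIDS,
    ESSENTIAL_AA,
    NONESSENTIAL_AA,
    WATER_MASS,
    metabolite_mass,
)
from .model_core import BiomassRecipe, ModelValidationError, build_biomass_reaction

__all__ = [
    "ToyModelSpec",
    "ConditionSample",
    "generate_toy_model",
    "sample_condition",
    "sample_conditions",
    "minimal_feed_nutrients",
    "toy_pathways",
    "conditions_to_frames",
]

DEFAULT_BIOMASS_FRACTIONS = {
    "protein": 0.55,
    "lipid": 0.35,
    "carbohydrate": 0.04,
    "nucleic_acid": 0.06,
}

_ESSENTIAL_ORDER = tuple(sorted(ESSENTIAL_AA))
_BIG = 1000.0


@dataclass
class ToyModelSpec:
    """Parameters of the synthetic core model.

    ``urea_capacity`` caps urea-cycle flux (mmol/gDW/h); teleosts excrete
    most nitrogen as ammonia, and the cap makes urea-only disposal unable to
    support appreciable growth.
    """

    n_essential_aa: int = 10
    n_nonessential_aa: int = 10
    include_urea_route: bool = True
    include_anaerobic_route: bool = True
    biomass_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS_FRACTIONS)
    )
    energy_cost: float = 30.0  # mmol ATP per g protein
    urea_capacity: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_essential_aa <= len(_ESSENTIAL_ORDER):
            raise ModelValidationError(
                f"n_essential_aa must be in [1, {len(_ESSENTIAL_ORDER)}], "
                f"got {self.n_essential_aa}"
            )
        if not 0 <= self.n_nonessential_aa <= len(NONESSENTIAL_AA):
            raise ModelValidationError(
                f"n_nonessential_aa must be in [0, {len(NONESSENTIAL_AA)}], "
                f"got {self.n_nonessential_aa}"
            )
        total_aa = self.n_essential_aa + self.n_nonessential_aa
        if not 2 <= total_aa <= 20:
            raise ModelValidationError(
                f"n_essential_aa + n_nonessential_aa must be in [2, 20], got {total_aa}"
            )
        frac_sum = sum(self.biomass_fractions.values())
        if abs(frac_sum - 1.0) > 1e-9:
            raise ModelValidationError(
                f"biomass_fractions must sum to 1, got {frac_sum!r}"
            )
        if self.urea_capacity < 0:
            raise ModelValidationError("urea_capacity must be non-negative")

    @property
    def essential_aa(self) -> tuple[str, ...]:
        return _ESSENTIAL_ORDER[: self.n_essential_aa]

    @property
    def nonessential_aa(self) -> tuple[str, ...]:
        return NONESSENTIAL_AA[: self.n_nonessential_aa]

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.essential_aa + self.nonessential_aa))


def _met(model: Model, base: str, comp: str) -> Metabolite:
    mid = f"{base}_{comp}"
    if mid in model.metabolites:
        return model.metabolites.get_by_id(mid)
    met = Metabolite(mid, name=base, compartment=comp)
    met.notes["molar_mass"] = metabolite_mass(base)
    model.add_metabolites([met])
    return met


def _mass_closed(stoich: dict[Metabolite, float], water: Metabolite) -> dict[Metabolite, float]:
    """Add a water makeweight so that sum(coeff * molar_mass) == 0."""
    residual = sum(
        coeff * float(met.notes["molar_mass"]) for met, coeff in stoich.items()
    )
    out = dict(stoich)
    if abs(residual) > 1e-12:
        out[water] = out.get(water, 0.0) - residual / WATER_MASS
    return out


def _reaction(
    model: Model,
    rid: str,
    stoich: dict[Metabolite, float],
    bounds: tuple[float, float],
    gpr: str = "",
    mass_close: bool = True,
) -> Reaction:
    rxn = Reaction(rid)
    water = _met(model, "h2o", "c")
    rxn.add_metabolites(_mass_closed(stoich, water) if mass_close else stoich)
    rxn.bounds = bounds
    model.add_reactions([rxn])
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def generate_toy_model(spec: ToyModelSpec | None = None) -> Model:
    """Build the synthetic core model described in the module docstring.

    The returned model carries a reference medium: glucose, phosphate and
    choline uptake at 10 mmol/gDW/h, each amino acid at 1, oxygen and water
    unlimited, and export-only bounds for CO2, NH3, urea and lactate. The
    biomass reaction is the objective.
    """
    spec = spec or ToyModelSpec()
    spec.validate()

    model = Model("toy_salmonid_core")
    model.compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}

    externals = ["glc", "o2", "co2", "nh3", "urea", "pi", "chol", "h2o"]
    if spec.include_anaerobic_route:
        externals.append("lac")
    externals += list(spec.amino_acids)

    uptake_limits = {"glc": 10.0, "o2": _BIG, "pi": 10.0, "chol": 10.0, "h2o": _BIG}
    export_only = {"co2", "nh3", "urea", "lac"}

    for base in externals:
        met_e = _met(model, base, "e")
        met_c = _met(model, base, "c")
        if base in export_only:
            ex_bounds = (0.0, _BIG)
        elif base in uptake_limits:
            ex_bounds = (-uptake_limits[base], _BIG)
        else:  # amino acids
            ex_bounds = (-1.0, _BIG)
        _reaction(model, f"EX_{base}_e", {met_e: -1.0}, ex_bounds, mass_close=False)
        # amino-acid transport is import-only: fish retain or catabolize amino
        # acids rather than excreting them, so nitrogen leaves as NH3/urea
        t_bounds = (0.0, _BIG) if base in AMINO_ACIDS else (-_BIG, _BIG)
        _reaction(model, f"T_{base}", {met_e: -1.0, met_c: 1.0}, t_bounds,
                  mass_close=False)

    atp = _met(model, "atp", "c")
    adp = _met(model, "adp", "c")
    pyr = _met(model, "pyr", "c")
    glc = _met(model, "glc", "c")
    nh3 = _met(model, "nh3", "c")
    co2 = _met(model, "co2", "c")
    pi = _met(model, "pi", "c")
    chol = _met(model, "chol", "c")
    pc = _met(model, "pc", "c")
    glycg = _met(model, "glycg", "c")
    ntp = _met(model, "ntp", "c")
    pyr_m = _met(model, "pyr", "m")
    o2_m = _met(model, "o2", "m")
    co2_m = _met(model, "co2", "m")
    o2_c = _met(model, "o2", "c")

    # mitochondrial transports
    _reaction(model, "T_pyr_m", {pyr: -1.0, pyr_m: 1.0}, (0.0, _BIG), mass_close=False)
    _reaction(model, "T_o2_m", {o2_c: -1.0, o2_m: 1.0}, (0.0, _BIG), mass_close=False)
    _reaction(model, "T_co2_m", {co2_m: -1.0, co2: 1.0}, (0.0, _BIG), mass_close=False)

    # lumped energy and carbon metabolism
    _reaction(model, "GLYC", {glc: -1.0, adp: -2.0, pyr: 2.0, atp: 2.0},
              (0.0, _BIG), gpr="gGLYC1 or gGLYC2")
    _reaction(model, "RESP",
              {pyr_m: -1.0, o2_m: -2.5, adp: -12.5, co2_m: 3.0, atp: 12.5},
              (0.0, _BIG), gpr="gRESP1 and gRESP2")
    _reaction(model, "GNG", {pyr: -2.0, atp: -6.0, glc: 1.0, adp: 6.0},
              (0.0, _BIG), gpr="gGNG")
    if spec.include_anaerobic_route:
        lac = _met(model, "lac", "c")
        _reaction(model, "LDH", {pyr: -1.0, lac: 1.0}, (0.0, _BIG), gpr="gLDH")
    if spec.include_urea_route:
        urea = _met(model, "urea", "c")
        _reaction(model, "UREACYC",
                  {nh3: -2.0, co2: -1.0, atp: -2.0, urea: 1.0, adp: 2.0},
                  (0.0, spec.urea_capacity), gpr="gUREACYC")

    # macromolecule precursor synthesis
    _reaction(model, "GLYCOGENS", {glc: -1.0, atp: -1.0, glycg: 1.0, adp: 1.0},
              (0.0, _BIG), gpr="gGLYCOGENS")
    _reaction(model, "PCSYN",
              {chol: -1.0, glc: -35.0 / 6.0, pi: -1.0, atp: -4.0, pc: 1.0, adp: 4.0},
              (0.0, _BIG), gpr="gPCSYN")
    _reaction(model, "NTPSYN",
              {glc: -10.0 / 6.0, nh3: -5.0, pi: -3.0, atp: -2.0, ntp: 1.0, adp: 2.0},
              (0.0, _BIG), gpr="gNTPSYN")

    # oxidative choline catabolism (lumped betaine/glycine route): without
    # it, surplus choline from a ratio-skewed feed bundle would block growth
    _reaction(model, "DEG_chol",
              {chol: -1.0, o2_c: -1.0, nh3: 1.0, pyr: 5.0 / 3.0},
              (0.0, _BIG), gpr="gDEGCHOL")

    # amino acid degradation (all) and synthesis (non-essential only)
    for aa in spec.amino_acids:
        _, n_atoms, c_atoms = AMINO_ACIDS[aa]
        aa_c = model.metabolites.get_by_id(f"{aa}_c")
        _reaction(model, f"DEG_{aa}",
                  {aa_c: -1.0, nh3: float(n_atoms), pyr: c_atoms / 3.0},
                  (0.0, _BIG), gpr=f"gDEG{aa.upper()}")
    for aa in spec.nonessential_aa:
        _, n_atoms, c_atoms = AMINO_ACIDS[aa]
        aa_c = model.metabolites.get_by_id(f"{aa}_c")
        _reaction(model, f"SYN_{aa}",
                  {pyr: -c_atoms / 3.0, nh3: -float(n_atoms), atp: -2.0,
                   aa_c: 1.0, adp: 2.0},
                  (0.0, _BIG), gpr=f"gSYN{aa.upper()}")

    # biomass
    n_aa = len(spec.amino_acids)
    recipe = BiomassRecipe(
        macromolecule_fractions=dict(spec.biomass_fractions),
        monomer_fractions={
            "protein": {aa: 1.0 / n_aa for aa in spec.amino_acids},
            "lipid": {"pc": 1.0},
            "carbohydrate": {"glycg": 1.0},
            "nucleic_acid": {"ntp": 1.0},
        },
        energy_cost=spec.energy_cost,
    )
    monomer_masses = {aa: AMINO_ACIDS[aa][0] - WATER_MASS for aa in spec.amino_acids}
    monomer_masses.update(
        pc=metabolite_mass("pc"),
        glycg=metabolite_mass("glycg"),
        ntp=metabolite_mass("ntp"),
    )
    monomer_mets = {aa: model.metabolites.get_by_id(f"{aa}_c") for aa in spec.amino_acids}
    monomer_mets.update(pc=pc, glycg=glycg, ntp=ntp)
    biomass = build_biomass_reaction(
        recipe, monomer_masses, metabolites=monomer_mets, energy_pair=(atp, adp)
    )
    model.add_reactions([biomass])
    model.objective = "BIOMASS"
    return model


def minimal_feed_nutrients(spec: ToyModelSpec | None = None) -> tuple[str, ...]:
    """Nutrients of the minimal feed: the essential amino acids plus choline."""
    spec = spec or ToyModelSpec()
    return spec.essential_aa + ("chol",)


@dataclass
class ConditionSample:
    """One randomized environment for the oxygen-limited growth experiment.

    ``feed_ratios`` are uniform ratios in [1, 100] per minimal-feed nutrient;
    ``bound_samples`` maps ``(reaction_id, direction)`` to a strictly positive
    lognormal flux-bound sample, one per direction a reaction admits.
    """

    feed_ratios: dict[str, float]
    bound_samples: dict[tuple[str, str], float]
    seed: int

    def validate(self) -> None:
        for nutrient, ratio in self.feed_ratios.items():
            if not 1.0 <= ratio <= 100.0:
                raise ModelValidationError(
                    f"feed ratio for {nutrient!r} outside [1, 100]: {ratio}"
                )
        for key, bound in self.bound_samples.items():
            if bound <= 0:
                raise ModelValidationError(f"non-positive sampled bound for {key}")


def _sampled_reactions(model: Model):
    """Reactions whose capacity bounds are randomized: internal and transport
    reactions, excluding boundary (single-metabolite) and biomass reactions.

    Directions with a curated capacity below the default big bound (e.g. the
    urea-cycle cap) are structural knowledge, not uncertainty, and yield only
    their default-bound directions for sampling.
    """
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1 or rxn.id == "BIOMASS":
            continue
        yield rxn


def sample_condition(
    model: Model,
    rng_seed: int,
    sigma_ln: float = 2.0,
    feed_nutrients: tuple[str, ...] | None = None,
) -> ConditionSample:
    """Draw one condition: uniform feed ratios and lognormal flux bounds.

    ``ln(b) ~ Normal(0, sigma_ln**2)`` independently per reaction direction;
    reversibilities of the template model are preserved.
    """
    if sigma_ln <= 0:
        raise ModelValidationError(f"sigma_ln must be positive, got {sigma_ln}")
    if feed_nutrients is None:
        feed_nutrients = minimal_feed_nutrients()
        feed_nutrients = tuple(
            n for n in feed_nutrients if f"EX_{n}_e" in model.reactions
        )
    rng = np.random.default_rng(rng_seed)
    feed_ratios = {
        nutrient: float(rng.uniform(1.0, 100.0)) for nutrient in feed_nutrients
    }
    bound_samples: dict[tuple[str, str], float] = {}
    for rxn in _sampled_reactions(model):
        if rxn.upper_bound >= _BIG:
            bound_samples[(rxn.id, "forward")] = float(rng.lognormal(0.0, sigma_ln))
        if rxn.lower_bound <= -_BIG:
            bound_samples[(rxn.id, "reverse")] = float(rng.lognormal(0.0, sigma_ln))
    return ConditionSample(feed_ratios=feed_ratios, bound_samples=bound_samples,
                           seed=int(rng_seed))


def sample_conditions(
    model: Model, n: int, master_seed: int, sigma_ln: float = 2.0
) -> list[ConditionSample]:
    """Spawn ``n`` reproducible conditions from one master seed."""
    rng = np.random.default_rng(master_seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [sample_condition(model, int(s), sigma_ln) for s in child_seeds]


def toy_pathways(model: Model) -> dict[str, set[str]]:
    """Toy pathway -> gene-set mapping for enrichment analysis."""
    groups = {
        "glycolysis_gluconeogenesis": ("GLYC", "GNG", "LDH", "GLYCOGENS"),
        "oxidative_phosphorylation": ("RESP",),
        "amino_acid_degradation": tuple(
            r.id for r in model.reactions if r.id.startswith("DEG_")
        ),
        "amino_acid_biosynthesis": tuple(
            r.id for r in model.reactions if r.id.startswith("SYN_")
        ),
        "nitrogen_disposal": ("UREACYC",),
        "lipid_and_nucleotide_synthesis": ("PCSYN", "NTPSYN"),
    }
    pathways: dict[str, set[str]] = {}
    for name, rids in groups.items():
        genes: set[str] = set()
        for rid in rids:
            if rid in model.reactions:
                genes |= {g.id for g in model.reactions.get_by_id(rid).genes}
        if genes:
            pathways[name] = genes
    return pathways


def conditions_to_frames(conditions: list[ConditionSample]):
    """Long-form DataFrames (feed ratios; sampled bounds) for CSV export."""
    import pandas as pd

    feed_rows = [
        {"condition_id": i, "nutrient": n, "ratio": r}
        for i, cond in enumerate(conditions)
        for n, r in cond.feed_ratios.items()
    ]
    bound_rows = [
        {"condition_id": i, "reaction": rid, "direction": d, "bound": b}
        for i, cond in enumerate(conditions)
        for (rid, d), b in cond.bound_samples.items()
    ]
    return pd.DataFrame(feed_rows), pd.DataFrame(bound_rows)
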