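"""Amino-acid and small-molecule reference data used across the toolkit.

Molar masses are free (hydrolysate) masses in g/mol; protein-bound residue
masses are the free mass minus one water. Essentiality follows the ten amino
acids that teleost fish cannot synthesize (Arg, His, Ile, Leu, Lys, Met, Phe,
Thr, Trp, Val).
"""

from __future__ import annotations

WATER_MASS = 18.015

#: id -> (free molar mass g/mol, nitrogen atoms, carbon atoms)
AMINO_ACIDS: dict[str, tuple[float, int, int]] = {
    "ala": (89.09, 1, 3),
    "arg": (174.20, 4, 6),
    "asn": (132.12, 2, 4),
    "asp": (133.10, 1, 4),
    "cys": (121.16, 1, 3),
    "gln": (146.15, 2, 5),
    "glu": (147.13, 1, 5),
    "gly": (75.07, 1, 2),
    "his": (155.15, 3, 6),
    "ile": (131.17, 1, 6),
    "leu": (131.17, 1, 6),
    "lys": (146.19, 2, 6),
    "met": (149.21, 1, 5),
    "phe": (165.19, 1, 9),
    "pro": (115.13, 1, 5),
    "ser": (105.09, 1, 3),
    "thr": (119.12, 1, 4),
    "trp": (204.23, 2, 11),
    "tyr": (181.19, 1, 9),
    "val": (117.15, 1, 5),
}

#: Amino acids that fish must obtain from the diet.
ESSENTIAL_AA: frozenset[str] = frozenset(
    {"arg", "his", "ile", "leu", "lys", "met", "phe", "thr", "trp", "val"}
)

NONESSENTIAL_AA: tuple[str, ...] = tuple(
    sorted(set(AMINO_ACIDS) - ESSENTIAL_AA)
)


def molar_mass(aa: str) -> float:
    """Free molar mass of an amino acid in g/mol."""
    return AMINO_ACIDS[aa][0]


def residue_mass(aa: str) -> float:
    """Protein-bound residue mass (free mass minus one water) in g/mol."""
    return AMINO_ACIDS[aa][0] - WATER_MASS


#: Other metabolites of the core network: id -> molar mass (g/mol).
SMALL_MOLECULES: dict[str, float] = {
    "glc": 180.16,   # glucose
    "o2": 32.00,
    "co2": 44.01,
    "nh3": 17.03,
    "urea": 60.06,
    "pi": 97.99,     # phosphate (as H3PO4)
    "chol": 104.17,  # choline
    "h2o": WATER_MASS,
    "lac": 90.08,    # lactate
    "pyr": 88.06,    # pyruvate
    "atp": 507.18,
    "adp": 427.20,
    "pc": 734.04,    # phosphatidylcholine (dipalmitoyl)
    "glycg": 162.14, # glycogen glucosyl unit
    "ntp": 507.18,   # generic nucleoside triphosphate
}


def metabolite_mass(base_id: str) -> float:
    """Molar mass for any metabolite base id known to the toolkit."""
    if base_id in SMALL_MOLECULES:
        return SMALL_MOLECULES[base_id]
    if base_id in AMINO_ACIDS:
        return AMINO_ACIDS[base_id][0]
    raise KeyError(f"no molar mass registered for metabolite {base_id!r}")
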