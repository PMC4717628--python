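"""Desk-scale test inputs: the cyanobacterial core model and toy databases.

The core model is a carbon-skeleton reduction of *Synechocystis* sp. 6803
central metabolism under glycogen catabolism: glycogen (as glucose
units) enters glycolysis, PEP carboxylase feeds an incomplete TCA arm,
and — because the organism lacks both 2-oxoglutarate dehydrogenase and
fumarate reductase — succinate is reached only through the GABA shunt
(2OG -> Glu -> GABA -> SsA -> Suc).  The glyoxylate-to-glycerate route
(glyoxylate carboligase, tartronate-semialdehyde reductase, glycerate
kinase) is present but carries no flux until something supplies
glyoxylate.  Cofactors (ATP/NAD(P)H) and nitrogen are deliberately not
tracked: the yields of interest are carbon-stoichiometric, and free NH3
exchange makes the lumped (de)aminations exact.  This is a fixture
simplification, not a claim about any genome-scale reconstruction.

Glycogen is modeled in glucose-equivalent units, so an uptake bound of
100 reads as 100 glucose units and yields are per mol glucose.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional

import numpy as np

from .model import MetabolicModel, Metabolite, Reaction
from .reactions import ReactionEquation, parse_equation

__all__ = [
    "build_core_model",
    "build_toy_db",
    "random_toy_model",
    "CORE_CARBON",
    "CORE_EXCHANGES",
    "LINKER12_HOST_COMPOUNDS",
    "LINKER12_CURRENCY_IDS",
]

#: carbon atoms per core-model metabolite (used by the carbon audit)
CORE_CARBON = {
    "glycogen": 6,  # one glucose unit
    "G6P": 6,
    "PGA": 3,
    "PEP": 3,
    "Pyr": 3,
    "AcCoA": 2,  # the acetyl moiety; CoA itself is not tracked
    "Cit": 6,
    "Icit": 6,
    "2OG": 5,
    "Glu": 5,
    "GABA": 4,
    "SsA": 4,
    "Suc": 4,
    "OAA": 4,
    "Mal": 4,
    "Fum": 4,
    "Glx": 2,
    "2h3opan": 3,
    "GlycR": 3,
    "CO2": 1,
}

_UNIVERSAL = {
    "glycogen": "C00182",
    "G6P": "C00092",
    "PGA": "C00197",
    "PEP": "C00074",
    "Pyr": "C00022",
    "AcCoA": "C00024",
    "Cit": "C00158",
    "Icit": "C00311",
    "2OG": "C00026",
    "Glu": "C00025",
    "GABA": "C00334",
    "SsA": "C00232",
    "Suc": "C00042",
    "OAA": "C00036",
    "Mal": "C00149",
    "Fum": "C00122",
    "Glx": "C00048",
    "2h3opan": "C01146",
    "GlycR": "C00258",
    "CO2": "C00011",
}

# (id, stoichiometry, lb, ub, name, universal_id)
_CORE_REACTIONS = [
    ("GLGP", {"glycogen": -1, "G6P": 1}, 0, 1000, "glycogen phosphorylase (lumped)", None),
    ("PGI_EMP", {"G6P": -1, "PGA": 2}, 0, 1000, "upper glycolysis (lumped)", None),
    ("ENO", {"PGA": -1, "PEP": 1}, 0, 1000, "enolase (lumped)", None),
    ("PPC", {"PEP": -1, "CO2": -1, "OAA": 1}, 0, 1000, "PEP carboxylase", None),
    ("PYK", {"PEP": -1, "Pyr": 1}, 0, 1000, "pyruvate kinase", None),
    ("PDH", {"Pyr": -1, "AcCoA": 1, "CO2": 1}, 0, 1000, "pyruvate dehydrogenase", None),
    ("CS", {"OAA": -1, "AcCoA": -1, "Cit": 1}, 0, 1000, "citrate synthase", None),
    ("ACN", {"Cit": -1, "Icit": 1}, -1000, 1000, "aconitase", None),
    ("ICD", {"Icit": -1, "2OG": 1, "CO2": 1}, 0, 1000, "isocitrate dehydrogenase", None),
    ("GDH", {"2OG": -1, "Glu": 1}, 0, 1000, "glutamate dehydrogenase (lumped amination)", None),
    ("GAD", {"Glu": -1, "GABA": 1, "CO2": 1}, 0, 1000, "glutamate decarboxylase", None),
    ("ABAT", {"GABA": -1, "SsA": 1}, 0, 1000, "GABA aminotransferase (lumped)", None),
    ("SSADH", {"SsA": -1, "Suc": 1}, 0, 1000, "succinate-semialdehyde dehydrogenase", None),
    ("MDH", {"OAA": -1, "Mal": 1}, -1000, 1000, "malate dehydrogenase", None),
    ("FUM", {"Mal": -1, "Fum": 1}, -1000, 1000, "fumarase", None),
    ("GCL", {"Glx": -2, "2h3opan": 1, "CO2": 1}, 0, 1000, "glyoxylate carboligase", "R00013"),
    ("TSR", {"2h3opan": -1, "GlycR": 1}, 0, 1000, "tartronate-semialdehyde reductase", None),
    ("GLYK", {"GlycR": -1, "PGA": 1}, 0, 1000, "glycerate kinase", None),
    # exchanges: flux > 0 secretes, lb < 0 permits uptake
    ("EX_glyc", {"glycogen": -1}, -100, 0, "glycogen source", None),
    ("EX_suc", {"Suc": -1}, 0, float("inf"), "succinate sink", None),
    ("EX_co2", {"CO2": -1}, 0, float("inf"), "CO2 efflux", None),
]

#: exchange-reaction ids of the core model, keyed by role
CORE_EXCHANGES = {"source": "EX_glyc", "target": "EX_suc", "co2": "EX_co2"}


def build_core_model() -> MetabolicModel:
    """The carbon-skeleton core model, ready for succinate maximization.

    Ships with the photomixotrophic constraints already in place: glycogen
    uptake capped at 100 glucose units, CO2 efflux-only, objective =
    succinate exchange.  There is no O2 exchange because no tracked
    reaction consumes or produces O2.
    """
    mets = [
        Metabolite(id=mid, name=mid, compartment="c", universal_id=_UNIVERSAL[mid])
        for mid in CORE_CARBON
    ]
    rxns = [
        Reaction(
            id=rid,
            stoichiometry={m: Fraction(k) for m, k in stoich.items()},
            lower_bound=float(lb),
            upper_bound=float(ub),
            name=name,
            source="host",
            universal_id=uid,
        )
        for rid, stoich, lb, ub, name, uid in _CORE_REACTIONS
    ]
    return MetabolicModel(
        id="synechocystis_core",
        metabolites=mets,
        reactions=rxns,
        objective=("EX_suc", "max"),
    )


# -- toy universal databases ----------------------------------------------

# The four reactions discussed in the succinate case study.  R10179's
# stoichiometry is a synthetic stand-in (written here as an acetylating
# acetaldehyde dehydrogenase, the enzyme consistent with its use next to
# threonine aldolase); it is excluded from any quantitative check.
_PAPER4 = [
    ("R00479", "C00311 <=> C00042 + C00048"),  # isocitrate lyase
    ("R00751", "C00188 <=> C00037 + C00084"),  # threonine aldolase
    ("R01867", "C00337 + C00122 <=> C00295 + C00042"),  # dihydroorotate:fumarate
    ("R10179", "C00084 + C00010 + C00006 <=> C00024 + C00005 + C00080"),  # stand-in
]

# Twelve hand-written reactions over a synthetic compound alphabet
# (C9xxxx) exercising singleton links, 2- and 3-chains, dead ends,
# currency-only contacts and an isolated island.  Host compounds are
# C90001-C90003; currency is H2O + CO2.
_LINKER12 = [
    ("R001", "C90001 <=> C91001"),
    ("R002", "C91001 <=> C91002"),
    ("R003", "C91002 <=> C90002"),
    ("R004", "C90001 <=> C90002"),
    ("R005", "C91008 <=> C91009"),            # island: never linkable
    ("R006", "C00001 <=> C91007"),            # touches host only via currency
    ("R007", "C90003 <=> C91003"),
    ("R008", "C91003 <=> C91004"),            # dangling far end
    ("R009", "C90002 + C90003 <=> C90001"),
    ("R010", "C90001 + C00001 <=> C91005 + C90002"),
    ("R011", "C91005 <=> C90003"),
    ("R012", "2 C91006 <=> C90003 + C00011"),  # coefficient 2, currency product
]

LINKER12_HOST_COMPOUNDS = frozenset({"C90001", "C90002", "C90003"})
LINKER12_CURRENCY_IDS = frozenset({"C00001", "C00011"})


def build_toy_db(
    kind: str, seed: Optional[int] = None, size: int = 20
) -> list[ReactionEquation]:
    """Build one of the shipped toy universal databases.

    ``paper4``   the four case-study reactions;
    ``linker12`` twelve reactions exercising the chain enumerator;
    ``random``   a seeded synthetic database of ``size`` reactions.
    """
    if kind == "paper4":
        rows = _PAPER4
    elif kind == "linker12":
        rows = _LINKER12
    elif kind == "random":
        if seed is None:
            raise ValueError("random toy db requires a seed")
        return _random_db(seed, size)
    else:
        raise ValueError(f"unknown toy db kind {kind!r}")
    return [parse_equation(eq, rid) for rid, eq in rows]


def _random_db(seed: int, size: int) -> list[ReactionEquation]:
    """Seeded random database over a synthetic compound alphabet.

    Each reaction involves 2-4 compounds with unit or double
    coefficients; 30% of entries are forward-only.  Compound reuse across
    reactions gives the link density needed to exercise the enumerator.
    """
    rng = np.random.default_rng(seed)
    alphabet = [f"C8{i:04d}" for i in range(max(6, size))]
    out = []
    for i in range(size):
        k = int(rng.integers(2, 5))
        compounds = list(rng.choice(alphabet, size=k, replace=False))
        split = int(rng.integers(1, k))
        coef = lambda: Fraction(int(rng.integers(1, 3)))
        eq = ReactionEquation(
            reaction_id=f"R8{i:04d}",
            substrates=tuple((coef(), c) for c in compounds[:split]),
            products=tuple((coef(), c) for c in compounds[split:]),
            reversible=bool(rng.random() >= 0.3),
        )
        out.append(eq)
    return out


def random_toy_model(
    seed: int, n_mets: int = 4, n_rxns: int = 6, bound: float = 10.0
) -> MetabolicModel:
    """A small random model for property tests.

    One uptake exchange feeds the first metabolite, one secretion drains
    the last and serves as the objective; internal reactions have sparse
    small-integer stoichiometry.  All bounds are finite and straddle or
    touch zero, so v = 0 is always feasible and the LP is always bounded.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"M{i}") for i in range(n_mets)]
    rxns = [
        Reaction(id="EX_src", stoichiometry={"M0": Fraction(-1)},
                 lower_bound=-bound, upper_bound=0.0),
        Reaction(id="EX_prod", stoichiometry={f"M{n_mets-1}": Fraction(-1)},
                 lower_bound=0.0, upper_bound=bound),
    ]
    for j in range(n_rxns):
        k = int(rng.integers(2, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {}
        for pos, i in enumerate(chosen):
            sign = -1 if pos < k // 2 or pos == 0 else 1
            stoich[f"M{i}"] = Fraction(sign * int(rng.integers(1, 3)))
        reversible = bool(rng.random() < 0.5)
        rxns.append(
            Reaction(
                id=f"V{j}",
                stoichiometry=stoich,
                lower_bound=-bound if reversible else 0.0,
                upper_bound=bound,
            )
        )
    return MetabolicModel(
        id=f"toy{seed}", metabolites=mets, reactions=rxns, objective=("EX_prod", "max")
    )
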