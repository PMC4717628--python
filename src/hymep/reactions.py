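"""Universal reaction database: equation grammar, currency filtering, exogenous set.

A universal reaction database is a flat list of KEGG-style reaction
equations written over compound identifiers (``C00042`` etc.).  Reactions
drawn from it are candidates for heterologous addition to a host model.
Connectivity between reactions is judged on *carbon-skeleton* compounds
only: ubiquitous cofactors and inorganics ("currency metabolites") are
excluded so that a shared ATP does not count as a metabolic link.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "EquationParseError",
    "ReactionEquation",
    "CurrencyList",
    "parse_equation",
    "format_equation",
    "linkable_compounds",
    "exogenous_set",
]

#: default pattern for a well-formed universal compound identifier
COMPOUND_ID_RE = re.compile(r"^C\d{5}$")

_COEF_RE = re.compile(r"^\d+(\.\d+)?(/\d+)?$")
_POLYMER_RE = re.compile(r"^\(?n([+-]\d+)?\)?$|^n$")


class EquationParseError(ValueError):
    """Raised when an equation string does not conform to the grammar."""

    def __init__(self, message: str, reaction_id: str = "", token: str = ""):
        self.reaction_id = reaction_id
        self.token = token
        prefix = f"[{reaction_id}] " if reaction_id else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class ReactionEquation:
    """A parsed universal-database entry.

    ``substrates`` and ``products`` are tuples of ``(coefficient,
    compound_id)`` with positive rational coefficients.  ``reversible``
    mirrors the ``<=>`` / ``=>`` arrow of the source equation.
    """

    reaction_id: str
    substrates: tuple[tuple[Fraction, str], ...]
    products: tuple[tuple[Fraction, str], ...]
    reversible: bool = True

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise EquationParseError("both sides must be non-empty", self.reaction_id)
        for coef, _ in self.substrates + self.products:
            if coef <= 0:
                raise EquationParseError("coefficients must be positive", self.reaction_id)

    @property
    def compounds(self) -> frozenset[str]:
        """All compound ids appearing on either side."""
        return frozenset(c for _, c in self.substrates + self.products)

    @property
    def transport_like(self) -> bool:
        """True when a compound appears on both sides with the same coefficient."""
        subs = {c: k for k, c in self.substrates}
        return any(subs.get(c) == k for k, c in self.products)

    def format(self) -> str:
        return format_equation(self)


def _format_side(side: Sequence[tuple[Fraction, str]]) -> str:
    parts = []
    for coef, cid in side:
        if coef == 1:
            parts.append(cid)
        elif coef.denominator == 1:
            parts.append(f"{coef.numerator} {cid}")
        else:
            parts.append(f"{coef.numerator}/{coef.denominator} {cid}")
    return " + ".join(parts)


def format_equation(eq: ReactionEquation) -> str:
    arrow = "<=>" if eq.reversible else "=>"
    return f"{_format_side(eq.substrates)} {arrow} {_format_side(eq.products)}"


def _parse_side(
    text: str, reaction_id: str, allow_empty: bool
) -> tuple[tuple[Fraction, str], ...]:
    text = text.strip()
    if not text:
        if allow_empty:
            return ()
        raise EquationParseError("empty equation side", reaction_id)
    terms: list[tuple[Fraction, str]] = []
    for raw in re.split(r"\s+\+\s+", text):
        tokens = raw.split()
        if not tokens:
            raise EquationParseError("empty term", reaction_id)
        if len(tokens) == 1:
            coef, cid = Fraction(1), tokens[0]
        elif len(tokens) == 2 and _COEF_RE.match(tokens[0]):
            coef, cid = Fraction(tokens[0]), tokens[1]
        else:
            raise EquationParseError(f"cannot parse term {raw!r}", reaction_id, raw)
        if _POLYMER_RE.match(cid) or _POLYMER_RE.match(tokens[0]):
            raise EquationParseError(
                f"polymer-style term {raw!r} is not representable", reaction_id, raw
            )
        if _COEF_RE.match(cid):
            raise EquationParseError(f"term {raw!r} has no compound id", reaction_id, raw)
        if coef == 0:
            raise EquationParseError(f"zero coefficient in {raw!r}", reaction_id, raw)
        terms.append((coef, cid))
    return tuple(terms)


def parse_equation(text: str, reaction_id: str = "") -> ReactionEquation:
    """Parse a KEGG-style equation string.

    Grammar: terms ``[coef] compound_id`` joined by ``" + "``; the two
    sides joined by ``<=>`` (reversible) or ``=>`` (forward only).
    Coefficients default to 1 and may be integers, decimals or ``p/q``
    fractions.  Both sides must be non-empty.
    """
    if "<=>" in text:
        left, right = text.split("<=>", 1)
        reversible = True
    elif "=>" in text:
        left, right = text.split("=>", 1)
        reversible = False
    else:
        raise EquationParseError("no reaction arrow ('<=>' or '=>') found", reaction_id)
    return ReactionEquation(
        reaction_id=reaction_id,
        substrates=_parse_side(left, reaction_id, allow_empty=False),
        products=_parse_side(right, reaction_id, allow_empty=False),
        reversible=reversible,
    )


@dataclass(frozen=True)
class CurrencyList:
    """Compound ids excluded from network linking.

    The shipped default covers water, the adenylate pool, phosphate,
    nicotinamide and flavin cofactors, CoA, protons, O2, NH3 and CO2 —
    the species whose ubiquity would otherwise connect almost every pair
    of reactions.  CO2 membership only affects linking, never
    stoichiometry: excluded compounds still appear in the added
    reactions' stoichiometries.
    """

    excluded_ids: frozenset[str]
    source: str = ""

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.excluded_ids

    def __len__(self) -> int:
        return len(self.excluded_ids)

    @classmethod
    def from_ids(cls, ids: Iterable[str], source: str = "inline") -> "CurrencyList":
        return cls(frozenset(ids), source)

    @classmethod
    def from_file(cls, path) -> "CurrencyList":
        ids = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    ids.add(line)
        return cls(frozenset(ids), str(path))

    @classmethod
    def default(cls) -> "CurrencyList":
        text = resources.files("hymep.data").joinpath("currency_default.txt").read_text()
        ids = set()
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
        return cls(frozenset(ids), "hymep default")


def linkable_compounds(eq: ReactionEquation, currency: CurrencyList) -> frozenset[str]:
    """Compounds of ``eq`` through which a metabolic link may be made."""
    return frozenset(c for c in eq.compounds if c not in currency)


def exogenous_set(host, db: Sequence[ReactionEquation]) -> list[ReactionEquation]:
    """Reactions of the universal database absent from the host model.

    Exogeneity is judged by reaction-id match against the host reactions'
    ``universal_id`` annotations (list subtraction), not by stoichiometric
    equivalence.  A host with no annotations yields the whole database and
    a warning.
    """
    import warnings

    host_ids = {
        r.universal_id for r in host.reactions.values() if r.universal_id is not None
    }
    if not host_ids:
        warnings.warn(
            "host model carries no universal reaction annotations; "
            "the whole database is treated as exogenous",
            stacklevel=2,
        )
    return [eq for eq in db if eq.reaction_id not in host_ids]
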