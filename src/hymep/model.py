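"""In-memory constraint-based metabolic model and structural edit operations.

A :class:`MetabolicModel` is the FBA substrate: metabolites, reactions with
signed rational stoichiometry and flux bounds, and a single objective
reaction.  Exchange reactions are single-sided (``{met: -1}`` with nothing
on the other side): positive flux is secretion, a negative lower bound
permits uptake.

All public edit operations are pure — they return an edited copy and leave
the input model untouched, so screening many candidate additions can never
corrupt the baseline.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Optional

import numpy as np

__all__ = [
    "ModelError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "add_reaction",
    "remove_reaction",
    "set_bounds",
    "stoichiometric_matrix",
]

#: default magnitude for "unconstrained" internal fluxes
DEFAULT_BOUND = 1000.0

_UNIVERSAL_MET_RE = re.compile(r"^C\d{5}$")


class ModelError(ValueError):
    """Violation of a model invariant or precondition."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    universal_id: Optional[str] = None
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.universal_id is not None and not _UNIVERSAL_MET_RE.match(self.universal_id):
            raise ModelError(
                f"metabolite {self.id}: malformed universal id {self.universal_id!r}"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient
    (negative = consumed).  ``source`` records whether the reaction belongs
    to the host reconstruction or was added heterologously.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    source: Literal["host", "exogenous"] = "host"
    universal_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        self.stoichiometry = {m: Fraction(k) for m, k in self.stoichiometry.items()}
        if any(k == 0 for k in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id}: zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """Single-sided reactions cross the system boundary."""
        signs = {k > 0 for k in self.stoichiometry.values()}
        return len(signs) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class MetabolicModel:
    """Metabolites, reactions and an objective; insertion order preserved."""

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective: Optional[tuple[str, str]] = None,
    ):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {m.id}")
            self.metabolites[m.id] = m
        for r in reactions:
            self._insert(r)
        self.objective = objective  # (reaction_id, "max"|"min") or None
        if objective is not None:
            rid, direction = objective
            if rid not in self.reactions:
                raise ModelError(f"objective reaction {rid} not in model")
            if direction not in ("max", "min"):
                raise ModelError(f"objective direction must be max/min, got {direction}")

    def _insert(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(f"reaction {rxn.id}: unknown metabolites {missing}")
        self.reactions[rxn.id] = rxn

    # -- queries ---------------------------------------------------------

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_boundary]

    def host_compound_ids(self) -> frozenset[str]:
        """Universal compound ids carried by the model's metabolites."""
        return frozenset(
            m.universal_id for m in self.metabolites.values() if m.universal_id
        )

    def metabolites_by_compound(self) -> dict[str, list[str]]:
        """Inverse universal-id map: compound id -> sorted host metabolite ids."""
        inv: dict[str, list[str]] = {}
        for m in self.metabolites.values():
            if m.universal_id:
                inv.setdefault(m.universal_id, []).append(m.id)
        return {c: sorted(ids) for c, ids in inv.items()}

    def copy(self) -> "MetabolicModel":
        clone = MetabolicModel(id=self.id)
        clone.metabolites = {k: replace(v) for k, v in self.metabolites.items()}
        clone.reactions = {k: v.copy() for k, v in self.reactions.items()}
        clone.objective = self.objective
        return clone

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.objective == other.objective
        )

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# -- pure edit operations ------------------------------------------------


def add_reaction(
    model: MetabolicModel, rxn: Reaction, create_missing: bool = False
) -> MetabolicModel:
    """Return a copy of ``model`` with ``rxn`` added.

    Metabolites referenced by ``rxn`` but absent from the model are created
    as new cytosolic internal metabolites when ``create_missing`` is true
    (their id doubles as the universal id when it is well-formed);
    otherwise the addition is rejected.
    """
    if rxn.id in model.reactions:
        raise ModelError(f"reaction id {rxn.id} already present")
    out = model.copy()
    for mid in rxn.stoichiometry:
        if mid not in out.metabolites:
            if not create_missing:
                raise ModelError(f"reaction {rxn.id}: unknown metabolite {mid}")
            out.metabolites[mid] = Metabolite(
                id=mid,
                compartment="c",
                universal_id=mid if _UNIVERSAL_MET_RE.match(mid) else None,
            )
    out._insert(rxn.copy())
    return out


def remove_reaction(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Return a copy without ``reaction_id``; orphaned metabolites are dropped."""
    if reaction_id not in model.reactions:
        raise ModelError(f"unknown reaction {reaction_id}")
    out = model.copy()
    removed = out.reactions.pop(reaction_id)
    still_used = {m for r in out.reactions.values() for m in r.stoichiometry}
    for mid in removed.stoichiometry:
        if mid not in still_used:
            del out.metabolites[mid]
    if out.objective and out.objective[0] == reaction_id:
        out.objective = None
    return out


def set_bounds(
    model: MetabolicModel, reaction_id: str, lb: float, ub: float
) -> MetabolicModel:
    """Return a copy with the bounds of ``reaction_id`` replaced."""
    if reaction_id not in model.reactions:
        raise ModelError(f"unknown reaction {reaction_id}")
    if lb > ub:
        raise ModelError(f"lower bound {lb} exceeds upper bound {ub}")
    out = model.copy()
    rxn = out.reactions[reaction_id]
    rxn.lower_bound = float(lb)
    rxn.upper_bound = float(ub)
    return out


def stoichiometric_matrix(
    model: MetabolicModel, exact: bool = False
) -> tuple[np.ndarray, list[str], list[str]]:
    """The matrix S (rows: internal metabolites, columns: reactions).

    Returns ``(S, metabolite_ids, reaction_ids)``.  With ``exact=True`` the
    entries are :class:`fractions.Fraction` in an object array; otherwise
    float64.
    """
    met_ids = model.internal_metabolite_ids
    rxn_ids = list(model.reactions)
    row = {m: i for i, m in enumerate(met_ids)}
    if exact:
        S = np.full((len(met_ids), len(rxn_ids)), Fraction(0), dtype=object)
    else:
        S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            i = row.get(mid)
            if i is not None:
                S[i, j] = coef if exact else float(coef)
    return S, met_ids, rxn_ids
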