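"""Screen candidate reaction additions by FBA and report yield increases.

Each candidate set is realized on a disposable copy of the host model,
the target flux is re-maximized, and the result is expressed as a *rate
of increase* on a scale where the host-only optimum is 100.  The
comparison that decides "improved" runs on raw LP optima with a relative
tolerance; rounding to the printed integer happens last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Optional, Sequence

from .fba import IMPROVEMENT_TOL, FluxSolution, maximize_target, parsimonious_fluxes
from .linker import CandidateSet
from .model import DEFAULT_BOUND, MetabolicModel, Reaction, add_reaction
from .reactions import ReactionEquation

__all__ = [
    "ScreenResult",
    "rate_of_increase",
    "realize_equation",
    "augment_model",
    "activated_reactions",
    "screen",
]

#: flux magnitude below which a reaction counts as inactive
ACTIVATION_TOL = 1e-6


def rate_of_increase(baseline: float, augmented: float) -> int:
    """100 x augmented / baseline, rounded half-up to an integer."""
    if baseline <= 0:
        raise ValueError("rate of increase undefined for non-positive baseline")
    return math.floor(100.0 * augmented / baseline + 0.5)


def realize_equation(
    eq: ReactionEquation,
    model: MetabolicModel,
    default_bound: float = DEFAULT_BOUND,
) -> Reaction:
    """Translate a universal-database equation into a model reaction.

    Compounds mapped by the model's metabolites (via their universal ids)
    are wired to the existing species — the lexicographically first when
    several compartmentalized metabolites share a compound id.  Unmapped
    compounds keep their compound id and will be created as new cytosolic
    metabolites on addition.  Reversible equations get symmetric bounds,
    forward-only ones are irreversible.
    """
    inverse = model.metabolites_by_compound()
    stoich: dict[str, Fraction] = {}
    for coef, cid in eq.substrates:
        mid = inverse.get(cid, [cid])[0]
        stoich[mid] = stoich.get(mid, Fraction(0)) - coef
    for coef, cid in eq.products:
        mid = inverse.get(cid, [cid])[0]
        stoich[mid] = stoich.get(mid, Fraction(0)) + coef
    stoich = {m: k for m, k in stoich.items() if k != 0}
    if not stoich:
        raise ValueError(f"{eq.reaction_id}: stoichiometry cancels entirely")
    lb = -default_bound if eq.reversible else 0.0
    return Reaction(
        id=eq.reaction_id,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=default_bound,
        source="exogenous",
        universal_id=eq.reaction_id,
    )


def augment_model(
    model: MetabolicModel,
    candidate: CandidateSet,
    default_bound: float = DEFAULT_BOUND,
) -> MetabolicModel:
    """A copy of ``model`` with every reaction of the candidate added."""
    out = model
    for eq in candidate.reactions:
        out = add_reaction(out, realize_equation(eq, model, default_bound), create_missing=True)
    return out


@dataclass
class ScreenResult:
    candidate: CandidateSet
    baseline_objective: float
    augmented_objective: Optional[float]
    rate_of_increase: Optional[int]
    activated_host_reactions: list[str] = field(default_factory=list)
    status: Literal["improved", "neutral", "infeasible", "unbounded"] = "neutral"

    @property
    def n(self) -> int:
        return self.candidate.n

    @property
    def m(self) -> int:
        return self.candidate.m

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return self.candidate.reaction_ids

    @property
    def n_activated(self) -> int:
        return len(self.activated_host_reactions)


def activated_reactions(
    model: MetabolicModel,
    candidate: CandidateSet,
    target_reaction_id: str,
    abs_tol: float = ACTIVATION_TOL,
    backend: str = "scipy",
) -> list[str]:
    """Host reactions switched on by the candidate.

    Both the baseline and the augmented model are solved parsimoniously
    (minimum total |flux| at the fixed optimum) so that the comparison is
    between stable supports.  Returned are host reactions whose absolute
    flux rises from <= abs_tol to > abs_tol, sorted by flux increase
    (largest first, reaction id breaking ties).
    """
    base = parsimonious_fluxes(model, target_reaction_id, backend=backend)
    aug = parsimonious_fluxes(
        augment_model(model, candidate), target_reaction_id, backend=backend
    )
    if not (base.optimal and aug.optimal):
        raise RuntimeError("activated-reaction comparison requires optimal solutions")
    out = []
    for rid, rxn in model.reactions.items():
        if rxn.source != "host":
            continue
        v0, v1 = abs(base.fluxes.get(rid, 0.0)), abs(aug.fluxes.get(rid, 0.0))
        if v0 <= abs_tol < v1:
            out.append((v1 - v0, rid))
    return [rid for _, rid in sorted(out, key=lambda t: (-t[0], t[1]))]


def screen(
    model: MetabolicModel,
    candidates: Sequence[CandidateSet],
    target_reaction_id: str,
    compute_activated: bool = True,
    abs_tol: float = ACTIVATION_TOL,
    backend: str = "scipy",
    default_bound: float = DEFAULT_BOUND,
) -> list[ScreenResult]:
    """Screen every candidate against the host baseline.

    The baseline optimum is computed once, each candidate on its own
    disposable augmented copy.  An infeasible baseline aborts the screen;
    an unbounded or infeasible augmented problem only flags that result.
    Results are ordered by rate descending, then by reaction ids.
    """
    base = maximize_target(model, target_reaction_id, backend=backend)
    if not base.optimal:
        raise RuntimeError(f"baseline FBA is {base.status}; cannot screen")
    b = base.objective_value
    results: list[ScreenResult] = []
    for cand in candidates:
        aug_model = augment_model(model, cand, default_bound)
        sol = maximize_target(aug_model, target_reaction_id, backend=backend)
        if not sol.optimal:
            results.append(
                ScreenResult(cand, b, None, None, [], status=sol.status)
            )
            continue
        a = sol.objective_value
        improved = a > b * (1.0 + IMPROVEMENT_TOL)
        activated: list[str] = []
        if compute_activated and improved:
            activated = activated_reactions(
                model, cand, target_reaction_id, abs_tol, backend
            )
        results.append(
            ScreenResult(
                candidate=cand,
                baseline_objective=b,
                augmented_objective=a,
                rate_of_increase=rate_of_increase(b, a),
                activated_host_reactions=activated,
                status="improved" if improved else "neutral",
            )
        )
    results.sort(
        key=lambda r: (-(r.rate_of_increase if r.rate_of_increase is not None else -1),
                       r.reaction_ids)
    )
    return results
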