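"""Enumerate heterologous pathway candidates.

A *chain* is an ordered series of exogenous reactions: the first reaction
touches a host metabolite (its anchor), and consecutive reactions are
joined through a *link* compound that is neither currency nor present in
the host.  With ``anchored_both_ends=True`` (default) the last reaction of
a multi-reaction chain must also touch the host — a chain whose far end
dangles cannot carry steady-state flux, so it can never change an FBA
optimum.  The permissive mode keeps such outward-growing chains anyway.

A *candidate set* bundles m reaction-disjoint chains totalling n reactions
(n, m are the row labels of the screening report).  The same reaction set
may appear once as two singleton chains and once as a two-chain when its
reactions share a novel compound; these are distinct candidates (they
differ in m) but identical LP problems.

Because reversible database reactions can run either way, linking ignores
which side of an equation a shared compound sits on; the LP decides net
direction later.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import MetabolicModel
from .reactions import CurrencyList, ReactionEquation

__all__ = [
    "PathwayChain",
    "CandidateSet",
    "EnumerationResult",
    "find_linkable",
    "extend_chains",
    "enumerate_chains",
    "enumerate_candidates",
    "count_linkable_by_n",
]

#: hard cap on emitted candidate sets in exhaustive mode
DEFAULT_CANDIDATE_BUDGET = 10**6


def _host_ids(host: Union[MetabolicModel, Iterable[str]]) -> frozenset[str]:
    if isinstance(host, MetabolicModel):
        return host.host_compound_ids()
    return frozenset(host)


@dataclass(frozen=True)
class PathwayChain:
    """An ordered series of linked exogenous reactions."""

    reactions: tuple[ReactionEquation, ...]
    anchor_compounds: frozenset[str]
    link_compounds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.link_compounds) != len(self.reactions) - 1:
            raise ValueError("need exactly len(reactions)-1 link compounds")
        if not self.anchor_compounds:
            raise ValueError("a chain must anchor to at least one host compound")
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction in chain")
        if len(set(self.link_compounds)) != len(self.link_compounds):
            raise ValueError("a link compound may be traversed only once")

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.reaction_id for r in self.reactions)

    @property
    def canonical_key(self) -> tuple[str, ...]:
        """Order-independent identity of the chain."""
        return tuple(sorted(self.reaction_ids))

    def validate(self, host_compound_ids: frozenset[str], currency: CurrencyList) -> None:
        """Machine-check the chain invariants against a host and currency list."""
        for c in self.link_compounds:
            if c in currency:
                raise ValueError(f"link compound {c} is currency")
            if c in host_compound_ids:
                raise ValueError(f"link compound {c} is a host compound")
        for i, c in enumerate(self.link_compounds):
            if c not in self.reactions[i].compounds or c not in self.reactions[i + 1].compounds:
                raise ValueError(f"link compound {c} not shared by reactions {i},{i+1}")
        for a in self.anchor_compounds:
            if a not in host_compound_ids or a in currency:
                raise ValueError(f"bad anchor compound {a}")


@dataclass(frozen=True)
class CandidateSet:
    """m reaction-disjoint chains, n reactions total, screened in one shot."""

    chains: tuple[PathwayChain, ...]

    def __post_init__(self) -> None:
        ids = [rid for ch in self.chains for rid in ch.reaction_ids]
        if len(set(ids)) != len(ids):
            raise ValueError("a reaction may not appear in two chains")

    @property
    def n(self) -> int:
        return sum(ch.n for ch in self.chains)

    @property
    def m(self) -> int:
        return len(self.chains)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(sorted(rid for ch in self.chains for rid in ch.reaction_ids))

    @property
    def reactions(self) -> tuple[ReactionEquation, ...]:
        seen = {}
        for ch in self.chains:
            for r in ch.reactions:
                seen[r.reaction_id] = r
        return tuple(seen[rid] for rid in sorted(seen))

    @property
    def canonical_key(self) -> tuple[tuple[str, ...], ...]:
        return tuple(sorted(ch.canonical_key for ch in self.chains))

    @classmethod
    def empty(cls) -> "CandidateSet":
        return cls(chains=())


@dataclass
class EnumerationResult:
    candidates: list[CandidateSet]
    truncated: bool = False


def _anchors(eq: ReactionEquation, host: frozenset[str], currency: CurrencyList) -> frozenset[str]:
    return frozenset(c for c in eq.compounds if c in host and c not in currency)


def _open_compounds(
    eq: ReactionEquation, host: frozenset[str], currency: CurrencyList
) -> frozenset[str]:
    """Compounds through which a chain may grow: novel, non-currency."""
    return frozenset(c for c in eq.compounds if c not in host and c not in currency)


def find_linkable(
    db_exogenous: Sequence[ReactionEquation],
    host: Union[MetabolicModel, Iterable[str]],
    currency: CurrencyList,
) -> list[ReactionEquation]:
    """Exogenous reactions with at least one non-currency host compound."""
    host_ids = _host_ids(host)
    return [eq for eq in db_exogenous if _anchors(eq, host_ids, currency)]


def _singleton_chains(
    db_exogenous: Sequence[ReactionEquation],
    host_ids: frozenset[str],
    currency: CurrencyList,
) -> list[PathwayChain]:
    return [
        PathwayChain((eq,), _anchors(eq, host_ids, currency), ())
        for eq in find_linkable(db_exogenous, host_ids, currency)
    ]


def extend_chains(
    frontier: Sequence[PathwayChain],
    db_exogenous: Sequence[ReactionEquation],
    host: Union[MetabolicModel, Iterable[str]],
    currency: CurrencyList,
    max_len: int,
) -> list[PathwayChain]:
    """Grow each frontier chain by one reaction through its open-end compounds.

    The open end of a chain is the set of novel, non-currency compounds of
    its last reaction that were not already traversed as links.  Exact
    duplicates (same ordered reactions, same links) are removed; chains
    over the same reaction set with different growth states are all kept,
    since they extend differently.
    """
    host_ids = _host_ids(host)
    by_compound: dict[str, list[ReactionEquation]] = {}
    for eq in db_exogenous:
        for c in _open_compounds(eq, host_ids, currency):
            by_compound.setdefault(c, []).append(eq)
    out: dict[tuple, PathwayChain] = {}
    for chain in frontier:
        if chain.n >= max_len:
            continue
        last = chain.reactions[-1]
        used = set(chain.link_compounds)
        for c in sorted(_open_compounds(last, host_ids, currency) - used):
            for eq in by_compound.get(c, ()):
                if eq.reaction_id in chain.reaction_ids:
                    continue
                new = PathwayChain(
                    reactions=chain.reactions + (eq,),
                    anchor_compounds=chain.anchor_compounds
                    | _anchors(eq, host_ids, currency),
                    link_compounds=chain.link_compounds + (c,),
                )
                out.setdefault((new.reaction_ids, new.link_compounds), new)
    return [out[k] for k in sorted(out)]


def enumerate_chains(
    db_exogenous: Sequence[ReactionEquation],
    host: Union[MetabolicModel, Iterable[str]],
    currency: CurrencyList,
    max_len: int,
    anchored_both_ends: bool = True,
) -> list[PathwayChain]:
    """All chains of 1..max_len reactions, canonical and deduplicated."""
    host_ids = _host_ids(host)
    frontier = _singleton_chains(db_exogenous, host_ids, currency)
    accepted: dict[tuple[str, ...], PathwayChain] = {
        ch.canonical_key: ch for ch in frontier
    }
    for _ in range(1, max_len):
        frontier = extend_chains(frontier, db_exogenous, host_ids, currency, max_len)
        for ch in frontier:
            if anchored_both_ends and not _anchors(ch.reactions[-1], host_ids, currency):
                continue
            accepted.setdefault(ch.canonical_key, ch)
    chains = [accepted[k] for k in sorted(accepted)]
    for ch in chains:
        ch.validate(host_ids, currency)
    return chains


def enumerate_candidates(
    db_exogenous: Sequence[ReactionEquation],
    host: Union[MetabolicModel, Iterable[str]],
    currency: CurrencyList,
    n_max: int,
    anchored_both_ends: bool = True,
    budget: int = DEFAULT_CANDIDATE_BUDGET,
) -> EnumerationResult:
    """All candidate sets with n <= n_max reactions.

    Candidates are formed by combining reaction-disjoint chains; the
    emitted order is lexicographic on the canonical chain keys.  When the
    number of candidates exceeds ``budget`` enumeration stops and the
    result is flagged truncated.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    chains = enumerate_chains(db_exogenous, host, currency, n_max, anchored_both_ends)
    candidates: list[CandidateSet] = []
    truncated = False

    def recurse(start: int, chosen: list[PathwayChain], used: set[str], n: int) -> bool:
        nonlocal truncated
        if chosen:
            if len(candidates) >= budget:
                truncated = True
                return False
            candidates.append(CandidateSet(tuple(chosen)))
        for i in range(start, len(chains)):
            ch = chains[i]
            if n + ch.n > n_max or used & set(ch.reaction_ids):
                continue
            chosen.append(ch)
            used |= set(ch.reaction_ids)
            ok = recurse(i + 1, chosen, used, n + ch.n)
            used -= set(ch.reaction_ids)
            chosen.pop()
            if not ok:
                return False
        return True

    recurse(0, [], set(), 0)
    return EnumerationResult(candidates, truncated)


def count_linkable_by_n(
    db_exogenous: Sequence[ReactionEquation],
    host: Union[MetabolicModel, Iterable[str]],
    currency: CurrencyList,
    n_max: int,
    anchored_both_ends: bool = True,
) -> dict[int, int]:
    """Number of distinct linkable reaction combinations for each total n.

    Distinctness is on the combined reaction-id set, so a pair of
    singletons and the two-chain over the same two reactions count once.
    """
    result = enumerate_candidates(
        db_exogenous, host, currency, n_max, anchored_both_ends
    )
    seen: dict[int, set[tuple[str, ...]]] = {n: set() for n in range(1, n_max + 1)}
    for cand in result.candidates:
        seen[cand.n].add(cand.reaction_ids)
    return {n: len(seen[n]) for n in range(1, n_max + 1)}
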