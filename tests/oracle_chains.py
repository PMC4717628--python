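"""Independent brute-force oracle for chain and candidate enumeration.

Chains are checked straight from their definition: try every ordering of
every reaction subset, requiring an anchored first reaction, pairwise
distinct novel link compounds between consecutive reactions, and (in
both-ends mode) an anchored last reaction.  Candidates are every set
partition of every reaction subset into valid chains.  Exponential, but
exact — meant for toy databases only.
"""

from __future__ import annotations

from itertools import combinations, permutations


def _anchors(eq, host, currency):
    return {c for c in eq.compounds if c in host and c not in currency}


def _novel_shared(a, b, host, currency):
    return {
        c for c in a.compounds & b.compounds
        if c not in host and c not in currency
    }


def is_valid_chain(seq, host, currency, anchored_both_ends):
    """Can ``seq`` (an ordered reaction tuple) be walked as a chain?"""
    if not _anchors(seq[0], host, currency):
        return False
    if anchored_both_ends and len(seq) > 1 and not _anchors(seq[-1], host, currency):
        return False

    def assign(i, used):
        if i == len(seq) - 1:
            return True
        options = _novel_shared(seq[i], seq[i + 1], host, currency) - used
        return any(assign(i + 1, used | {c}) for c in sorted(options))

    return assign(0, frozenset())


def chain_keys(db, host, currency, max_len, anchored_both_ends=True):
    """Canonical keys (sorted reaction-id tuples) of all valid chains."""
    keys = set()
    for k in range(1, max_len + 1):
        for subset in combinations(db, k):
            if any(
                is_valid_chain(perm, host, currency, anchored_both_ends)
                for perm in permutations(subset)
            ):
                keys.add(tuple(sorted(eq.reaction_id for eq in subset)))
    return keys


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def candidate_keys(db, host, currency, n_max, anchored_both_ends=True):
    """Canonical keys of all valid candidate sets with n <= n_max.

    A key is the sorted tuple of per-chain canonical keys; the same
    reaction set partitioned differently yields distinct keys.
    """
    keys = set()
    for k in range(1, n_max + 1):
        for subset in combinations(db, k):
            for part in _partitions(list(subset)):
                if all(
                    any(
                        is_valid_chain(perm, host, currency, anchored_both_ends)
                        for perm in permutations(block)
                    )
                    for block in part
                ):
                    keys.add(
                        tuple(sorted(
                            tuple(sorted(eq.reaction_id for eq in block))
                            for block in part
                        ))
                    )
    return keys
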