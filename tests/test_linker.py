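"""Chain and candidate enumeration against an exhaustive brute-force oracle."""

import pytest

from hymep import (
    CurrencyList,
    enumerate_candidates,
    enumerate_chains,
    extend_chains,
    find_linkable,
    count_linkable_by_n,
)
from hymep.fixtures import build_toy_db
from hymep.linker import PathwayChain

from .oracle_chains import candidate_keys, chain_keys


class TestFindLinkable:
    def test_linker12_anchored_reactions(self, linker12_db, linker12_host, linker12_currency):
        got = {e.reaction_id for e in
               find_linkable(linker12_db, linker12_host, linker12_currency)}
        # by inspection: R002/R008 touch only novel compounds, R005 is an
        # island, R006 touches the host set through nothing but currency
        assert got == {"R001", "R003", "R004", "R007", "R009", "R010", "R011", "R012"}

    def test_empty_host_set(self, linker12_db, linker12_currency):
        assert find_linkable(linker12_db, frozenset(), linker12_currency) == []

    def test_currency_contact_does_not_anchor(self, linker12_db, linker12_currency):
        linked = find_linkable(linker12_db, {"C00001"}, linker12_currency)
        assert all(e.reaction_id != "R006" for e in linked)


class TestChains:
    def test_unique_three_chain_both_ends(self, linker12_db, linker12_host, linker12_currency):
        chains = enumerate_chains(linker12_db, linker12_host, linker12_currency, 3)
        three = [c for c in chains if c.n == 3]
        assert [c.canonical_key for c in three] == [("R001", "R002", "R003")]

    def test_two_chains_both_ends(self, linker12_db, linker12_host, linker12_currency):
        chains = enumerate_chains(linker12_db, linker12_host, linker12_currency, 2)
        two = {c.canonical_key for c in chains if c.n == 2}
        assert two == {("R010", "R011")}

    def test_permissive_superset_of_both_ends(self, linker12_db, linker12_host, linker12_currency):
        strict = {c.canonical_key for c in
                  enumerate_chains(linker12_db, linker12_host, linker12_currency, 3, True)}
        loose = {c.canonical_key for c in
                 enumerate_chains(linker12_db, linker12_host, linker12_currency, 3, False)}
        assert strict <= loose
        assert ("R007", "R008") in loose - strict  # dangling far end

    @pytest.mark.parametrize("both_ends", [True, False])
    @pytest.mark.parametrize("max_len", [1, 2, 3])
    def test_matches_oracle_on_linker12(
        self, linker12_db, linker12_host, linker12_currency, max_len, both_ends
    ):
        got = {c.canonical_key for c in enumerate_chains(
            linker12_db, linker12_host, linker12_currency, max_len, both_ends)}
        want = chain_keys(linker12_db, linker12_host, linker12_currency, max_len, both_ends)
        assert got == want

    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_matches_oracle_on_random_dbs(self, seed):
        db = build_toy_db("random", seed=seed, size=10)
        compounds = sorted({c for eq in db for c in eq.compounds})
        host = frozenset(compounds[: max(2, len(compounds) // 4)])
        currency = CurrencyList.from_ids(compounds[-2:])
        for both_ends in (True, False):
            got = {c.canonical_key for c in
                   enumerate_chains(db, host, currency, 3, both_ends)}
            want = chain_keys(db, host, currency, 3, both_ends)
            assert got == want

    def test_extension_respects_max_len(self, linker12_db, linker12_host, linker12_currency):
        chains = [c for c in
                  enumerate_chains(linker12_db, linker12_host, linker12_currency, 2)
                  if c.n == 2]
        assert chains  # the frontier is non-trivial
        assert extend_chains(chains, linker12_db, linker12_host, linker12_currency, 2) == []

    def test_invariants_machine_checked(self, linker12_db, linker12_host, linker12_currency):
        for chain in enumerate_chains(linker12_db, linker12_host, linker12_currency, 3, False):
            chain.validate(linker12_host, linker12_currency)
            assert len(chain.link_compounds) == chain.n - 1

    def test_chain_requires_anchor(self, linker12_db):
        with pytest.raises(ValueError, match="anchor"):
            PathwayChain((linker12_db[1],), frozenset(), ())


class TestCandidates:
    @pytest.mark.parametrize("both_ends", [True, False])
    @pytest.mark.parametrize("n_max", [1, 2, 3])
    def test_matches_oracle(self, linker12_db, linker12_host, linker12_currency, n_max, both_ends):
        enum = enumerate_candidates(
            linker12_db, linker12_host, linker12_currency, n_max, both_ends)
        assert not enum.truncated
        got = {c.canonical_key for c in enum.candidates}
        want = candidate_keys(linker12_db, linker12_host, linker12_currency, n_max, both_ends)
        assert got == want
        # canonicalization: no candidate reported twice
        assert len(got) == len(enum.candidates)

    def test_n2_is_pattern1_union_pattern2(self, linker12_db, linker12_host, linker12_currency):
        """n=2 candidates are exactly pairs of singleton links plus 2-chains."""
        enum = enumerate_candidates(linker12_db, linker12_host, linker12_currency, 2)
        n2 = [c for c in enum.candidates if c.n == 2]
        shapes = {c.canonical_key: c.m for c in n2}
        singles = {e.reaction_id for e in
                   find_linkable(linker12_db, linker12_host, linker12_currency)}
        import itertools
        pattern1 = {tuple((a,), ) + ((b,),) for a, b in
                    itertools.combinations(sorted(singles), 2)}
        pattern1 = {tuple(sorted(((a,), (b,)))) for a, b in
                    itertools.combinations(sorted(singles), 2)}
        pattern2 = {(("R010", "R011"),)}
        assert set(shapes) == pattern1 | pattern2
        assert all(m == 2 for key, m in shapes.items() if len(key) == 2)

    def test_n1_only_singletons(self, linker12_db, linker12_host, linker12_currency):
        enum = enumerate_candidates(linker12_db, linker12_host, linker12_currency, 1)
        assert all(c.n == 1 and c.m == 1 for c in enum.candidates)
        assert len(enum.candidates) == 8

    def test_budget_truncation_flagged(self, linker12_db, linker12_host, linker12_currency):
        enum = enumerate_candidates(
            linker12_db, linker12_host, linker12_currency, 3, budget=5)
        assert enum.truncated and len(enum.candidates) == 5

    def test_deterministic_order(self, linker12_db, linker12_host, linker12_currency):
        a = enumerate_candidates(linker12_db, linker12_host, linker12_currency, 2)
        b = enumerate_candidates(linker12_db, linker12_host, linker12_currency, 2)
        assert [c.canonical_key for c in a.candidates] == \
            [c.canonical_key for c in b.candidates]


class TestCounts:
    def test_counts_match_bruteforce(self, linker12_db, linker12_host, linker12_currency):
        counts = count_linkable_by_n(linker12_db, linker12_host, linker12_currency, 3)
        want = candidate_keys(linker12_db, linker12_host, linker12_currency, 3)
        by_n = {}
        for key in want:
            ids = {r for block in key for r in block}
            by_n.setdefault(len(ids), set()).add(frozenset(ids))
        assert counts == {n: len(by_n.get(n, set())) for n in (1, 2, 3)}

    def test_zero_beyond_reachable_n(self, linker12_currency):
        db = build_toy_db("paper4")
        counts = count_linkable_by_n(db, {"C00311"}, CurrencyList.from_ids(set()), 3)
        assert counts[1] == 1 and counts[2] == 0 and counts[3] == 0

    def test_monotone_in_currency(self, linker12_db, linker12_host):
        small = CurrencyList.from_ids({"C00001"})
        large = CurrencyList.from_ids({"C00001", "C00011", "C91005"})
        a = count_linkable_by_n(linker12_db, linker12_host, small, 2)
        b = count_linkable_by_n(linker12_db, linker12_host, large, 2)
        assert all(b[n] <= a[n] for n in a)
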