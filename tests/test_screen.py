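"""Yield screening: rates, activated reactions, monotonicity, statelessness."""

from fractions import Fraction

import pytest

from hymep import (
    CandidateSet,
    CurrencyList,
    PathwayChain,
    Reaction,
    activated_reactions,
    augment_model,
    enumerate_candidates,
    exogenous_set,
    maximize_target,
    parse_equation,
    rate_of_increase,
    realize_equation,
    screen,
)
from hymep.fixtures import build_core_model, build_toy_db, random_toy_model


def singleton(eq):
    """Wrap one equation as a single-reaction candidate (anchors unchecked)."""
    return CandidateSet((PathwayChain((eq,), frozenset({"_"}) | eq.compounds, ()),))


@pytest.fixture(scope="module")
def paper4_candidates(core_model, paper4_db, default_currency):
    exo = exogenous_set(core_model, paper4_db)
    return enumerate_candidates(exo, core_model, default_currency, 2).candidates


class TestRateOfIncrease:
    @pytest.mark.parametrize(
        "baseline, augmented, expected",
        [(100.0, 400.0 / 3.0, 133), (100.0, 100.0, 100), (100.0, 155.4, 155),
         (100.0, 133.5, 134)],  # half-up, not banker's
    )
    def test_rounding(self, baseline, augmented, expected):
        assert rate_of_increase(baseline, augmented) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            rate_of_increase(0.0, 10.0)


class TestRealizeEquation:
    def test_maps_compounds_to_host_metabolites(self, core_model, paper4_db):
        rxn = realize_equation(paper4_db[0], core_model)  # isocitrate lyase
        assert rxn.stoichiometry == {
            "Icit": Fraction(-1), "Suc": Fraction(1), "Glx": Fraction(1)}
        assert rxn.source == "exogenous" and rxn.universal_id == "R00479"
        assert (rxn.lower_bound, rxn.upper_bound) == (-1000.0, 1000.0)

    def test_forward_only_equation_gets_irreversible_bounds(self, core_model):
        eq = parse_equation("C00311 => C00042 + C00048", "RFWD")
        rxn = realize_equation(eq, core_model)
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)

    def test_unmapped_compounds_keep_compound_ids(self, core_model, paper4_db):
        r01867 = next(e for e in paper4_db if e.reaction_id == "R01867")
        rxn = realize_equation(r01867, core_model)
        assert "C00337" in rxn.stoichiometry and "Fum" in rxn.stoichiometry


class TestScreenOnCore:
    def test_isocitrate_lyase_rate_133(self, core_model, paper4_candidates):
        results = screen(core_model, paper4_candidates, "EX_suc")
        icl = next(r for r in results if r.reaction_ids == ("R00479",))
        assert icl.rate_of_increase == 133
        assert icl.status == "improved"
        assert icl.baseline_objective == pytest.approx(100.0)
        assert icl.augmented_objective == pytest.approx(400.0 / 3.0, rel=1e-7)

    def test_empty_candidate_is_neutral_100(self, core_model):
        res = screen(core_model, [CandidateSet.empty()], "EX_suc")
        assert res[0].rate_of_increase == 100 and res[0].status == "neutral"

    def test_top_single_candidate_is_isocitrate_lyase(self, core_model, paper4_candidates):
        singles = [c for c in paper4_candidates if c.n == 1]
        results = screen(core_model, singles, "EX_suc")
        assert results[0].reaction_ids == ("R00479",)
        assert all(r.rate_of_increase == 100 for r in results[1:])

    def test_no_two_reaction_candidate_beats_isocitrate_lyase(
        self, core_model, paper4_candidates
    ):
        results = screen(core_model, paper4_candidates, "EX_suc")
        assert max(r.rate_of_increase for r in results) == 133

    def test_activated_reactions_are_the_glycerate_route(self, core_model, paper4_db):
        cand = singleton(paper4_db[0])
        assert sorted(
            activated_reactions(core_model, cand, "EX_suc")
        ) == ["GCL", "GLYK", "TSR"]

    def test_activation_threshold_semantics(self, core_model, paper4_db):
        cand = singleton(paper4_db[0])
        assert activated_reactions(core_model, cand, "EX_suc",
                                   abs_tol=float("inf")) == []

    def test_dangling_reaction_is_neutral(self, core_model):
        eq = parse_equation("C00042 <=> C99999", "RDANGLE")
        res = screen(core_model, [singleton(eq)], "EX_suc")[0]
        assert res.rate_of_increase == 100 and res.status == "neutral"

    def test_duplicate_of_host_reaction_is_exactly_neutral(self, core_model):
        # same stoichiometry as the host GABA-shunt exit, different id
        eq = parse_equation("C00232 <=> C00042", "RDUP")
        res = screen(core_model, [singleton(eq)], "EX_suc")[0]
        assert res.rate_of_increase == 100

    def test_screen_is_stateless(self, core_model, paper4_db):
        cand = singleton(paper4_db[0])
        a = screen(core_model, [cand], "EX_suc")[0]
        b = screen(core_model, [cand], "EX_suc")[0]
        assert (a.rate_of_increase, a.augmented_objective,
                a.activated_host_reactions) == \
               (b.rate_of_increase, b.augmented_objective,
                b.activated_host_reactions)

    def test_results_sorted_by_rate_then_ids(self, core_model, paper4_candidates):
        results = screen(core_model, paper4_candidates, "EX_suc")
        keys = [(-r.rate_of_increase, r.reaction_ids) for r in results]
        assert keys == sorted(keys)

    def test_unbounded_candidate_flagged_and_screen_continues(self, core_model):
        # a reversible free lunch: creates succinate from nothing
        eq = parse_equation("C00011 <=> C00042 + C00011", "RFREE")
        cand_bad = CandidateSet((PathwayChain((eq,), frozenset({"C00042"}), ()),))
        results = screen(build_core_model(), [cand_bad, CandidateSet.empty()],
                         "EX_suc", default_bound=float("inf"))
        by_ids = {r.reaction_ids: r for r in results}
        assert by_ids[("RFREE",)].status == "unbounded"
        assert by_ids[()].rate_of_increase == 100

    def test_infeasible_baseline_aborts(self, core_model):
        from hymep import set_bounds
        bad = set_bounds(core_model, "PDH", 500.0, 1000.0)  # forced overflow
        with pytest.raises(RuntimeError, match="baseline"):
            screen(bad, [CandidateSet.empty()], "EX_suc")


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(20))
    def test_superset_never_lowers_optimum(self, seed):
        """Adding reactions can only keep or raise the LP optimum."""
        import numpy as np

        model = random_toy_model(seed, n_mets=5, n_rxns=6)
        base = maximize_target(model, "EX_prod").objective_value
        rng = np.random.default_rng(1000 + seed)
        compounds = [m.id for m in model.metabolites.values()]
        for trial in range(10):
            k = int(rng.integers(2, 4))
            chosen = list(rng.choice(compounds, size=k, replace=False))
            stoich = {}
            for pos, mid in enumerate(chosen):
                stoich[mid] = Fraction(int(rng.integers(1, 3)) * (-1 if pos == 0 else 1))
            rxn = Reaction(id=f"ADD{trial}", stoichiometry=stoich,
                           lower_bound=-10.0, upper_bound=10.0, source="exogenous")
            from hymep import add_reaction
            aug = add_reaction(model, rxn, create_missing=True)
            out = maximize_target(aug, "EX_prod")
            assert out.optimal
            assert out.objective_value >= base - 1e-7
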