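"""Phenotype screens: media, essentiality, rescue, synthetic lethality."""

import pytest

from farm import fixtures as fx
from farm.media import Media, build_media, vogels_minimal
from farm.phenotype import (
    classify_sl_pair,
    predict_essentiality,
    predict_rescue,
    simulate_knockout,
    synthetic_lethal_screen,
)
from farm.model import GprRule, ReactionRecord


class TestMedia:
    def test_supplement_capped_at_three(self, linear_chain):
        media = build_media(linear_chain.media, ["M2[e]"],
                            model=linear_chain.model)
        assert media.uptakes["M2[e]"] == 3.0
        assert media.uptakes["S[e]"] == 1.5  # base untouched

    def test_unknown_supplement_named_in_error(self, linear_chain):
        with pytest.raises(KeyError, match="NOPE"):
            build_media(linear_chain.media, ["NOPE[e]"],
                        model=linear_chain.model)

    def test_empty_supplement_list_is_identity(self, linear_chain):
        assert build_media(linear_chain.media, []) is linear_chain.media

    def test_vogels_preset_caps_sucrose(self):
        media = vogels_minimal()
        assert media.uptakes["SUCROSE[e]"] == 1.5
        assert media.uptakes["AMMONIUM[e]"] == 1000.0


class TestEssentiality:
    def test_chain_genes_essential(self, linear_chain):
        truth = {g: "inviable" for g in linear_chain.truth["essential_genes"]}
        results, summary = predict_essentiality(
            linear_chain.model, linear_chain.media, truth=truth)
        calls = {next(iter(r.genes)): r.viable for r in results}
        for g in linear_chain.truth["essential_genes"]:
            assert not calls[g]
        assert summary.specificity == 1.0

    def test_cycle_input_essential_only_under_dilution(self, input_cycle):
        model, media = input_cycle.model, input_cycle.media
        limed = simulate_knockout(model, {"g_input"}, media, method="limed")
        plain = simulate_knockout(model, {"g_input"}, media, method="fba")
        assert not limed.viable
        assert plain.viable

    def test_summary_counts_are_consistent(self, linear_chain):
        model = linear_chain.model
        truth = {g: "inviable" for g in linear_chain.truth["essential_genes"]}
        truth["g_ghost"] = "viable"  # not in model: must be skipped
        results, summary = predict_essentiality(model, linear_chain.media,
                                                truth=truth)
        assert summary.total == len(linear_chain.truth["essential_genes"])
        # sensitivity * experimentally-viable-count is the integer TP
        if summary.tp + summary.fn:
            assert summary.sensitivity * (summary.tp + summary.fn) == \
                pytest.approx(summary.tp)

    def test_threshold_monotonicity(self, linear_chain):
        """Lowering the threshold to 0 never turns viable into inviable."""
        model, media = linear_chain.model, linear_chain.media
        for gene in sorted(model.genes):
            strict = simulate_knockout(model, {gene}, media, threshold=0.02)
            loose = simulate_knockout(model, {gene}, media, threshold=0.0)
            if strict.viable:
                assert loose.viable


class TestRescue:
    def test_downstream_supplements_rescue_upstream_do_not(self, linear_chain):
        fix = linear_chain
        for gene, expected in fix.truth["rescues"].items():
            out = predict_rescue(fix.model, fix.media, gene,
                                 fix.truth["supplements"])
            rescued = {next(iter(s)) for s, res, implied in out
                       if implied or res.viable}
            assert rescued == expected, gene

    def test_rescue_of_viable_gene_is_undefined(self, linear_chain):
        model = linear_chain.model.copy()
        model.add_reaction(ReactionRecord(
            id="SHORTCUT", stoichiometry={"S[e]": -1, "M4[c]": 1}))
        with pytest.raises(ValueError, match="not inviable"):
            predict_rescue(model, linear_chain.media, "g1", ["M2[e]"])

    def test_superset_of_rescuing_single_is_implied(self, linear_chain):
        out = predict_rescue(linear_chain.model, linear_chain.media, "g1",
                             ["M2[e]", ("M2[e]", "M1[e]")])
        by_set = {s: (res, implied) for s, res, implied in out}
        assert by_set[frozenset({"M2[e]"})][0].viable
        assert by_set[frozenset({"M2[e]", "M1[e]"})][1] is True

    def test_reported_rescues_resimulate_consistently(self, linear_chain):
        fix = linear_chain
        out = predict_rescue(fix.model, fix.media, "g2",
                             fix.truth["supplements"])
        for supset, res, implied in out:
            if implied:
                continue
            media = build_media(fix.media, sorted(supset), model=fix.model)
            again = simulate_knockout(fix.model, {"g2"}, media)
            assert again.viable == res.viable


class TestSyntheticLethality:
    def test_dual_route_pair_recovered_and_classified(self, dual_route):
        pairs = synthetic_lethal_screen(dual_route.model, dual_route.media,
                                        dual_route.truth["nonessential"])
        assert len(pairs) == 1
        assert pairs[0].genes == dual_route.truth["sl_pair"]
        assert pairs[0].classification == dual_route.truth["classification"]

    def test_planted_supplement_rescues_double_mutant(self, dual_route):
        fix = dual_route
        double = simulate_knockout(fix.model, fix.truth["sl_pair"], fix.media)
        assert not double.viable
        media = build_media(fix.media, [fix.truth["rescue_supplement"]],
                            model=fix.model)
        rescued = simulate_knockout(fix.model, fix.truth["sl_pair"], media)
        assert rescued.viable

    def test_isozyme_pair_detected(self):
        fix = fx.isozyme_sl()
        pairs = synthetic_lethal_screen(fix.model, fix.media,
                                        fix.truth["nonessential"])
        assert len(pairs) == 1
        assert pairs[0].classification == "isozyme"

    def test_interacting_pathways_classification(self):
        fix = fx.dual_route_sl(shared_pathway=False)
        pairs = synthetic_lethal_screen(fix.model, fix.media,
                                        fix.truth["nonessential"])
        assert pairs[0].classification == "interacting_pathways"

    def test_triple_redundancy_yields_no_pair(self):
        fix = fx.dual_route_sl()
        model = fix.model.copy()
        model.add_reaction(ReactionRecord(
            id="R_third", stoichiometry={"K[c]": -1, "G[c]": 1},
            gpr=GprRule.parse("gC")))
        model.genes.add("gC")
        pairs = synthetic_lethal_screen(model, fix.media, ["gA", "gB", "gC"])
        assert pairs == []

    def test_screen_is_symmetric_in_gene_order(self, dual_route):
        fwd = synthetic_lethal_screen(dual_route.model, dual_route.media,
                                      ["gA", "gB"])
        rev = synthetic_lethal_screen(dual_route.model, dual_route.media,
                                      ["gB", "gA"])
        assert [p.genes for p in fwd] == [p.genes for p in rev]

    def test_shortcut_matches_exhaustive_screen(self, dual_route):
        fix = dual_route
        exhaustive = synthetic_lethal_screen(fix.model, fix.media,
                                             fix.truth["nonessential"],
                                             exhaustive=True)
        shortcut = synthetic_lethal_screen(fix.model, fix.media,
                                           fix.truth["nonessential"],
                                           exhaustive=False)
        assert [p.genes for p in exhaustive] == [p.genes for p in shortcut]

    def test_individually_lethal_gene_rejected(self, dual_route):
        with pytest.raises(ValueError, match="individually inviable"):
            synthetic_lethal_screen(dual_route.model, dual_route.media,
                                    ["gA", "g_synth"])
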