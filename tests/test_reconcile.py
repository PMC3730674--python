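"""Reconciliation: weights, minimal repairs, minimal cuts, flip contract."""

import itertools
import math

import pytest

from farm import fixtures as fx
from farm.model import EvidenceRecord, MetabolicModel, ReactionRecord
from farm.reconcile import (
    Phenotype,
    apply_reconciliation,
    default_weights,
    reaction_weight,
    restore_growth,
    suppress_growth,
)
from farm.phenotype import simulate_knockout
from farm.solve import limed_fba

THRESHOLD = 0.02


class TestReactionWeight:
    def test_fully_supported_reaction_costs_nothing(self):
        assert reaction_weight(EvidenceRecord()) == 0.0

    def test_half_probability_costs_ln2(self):
        ev = EvidenceRecord(p_biochem=0.5)
        assert reaction_weight(ev) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("which", ["p_biochem", "p_thermo", "pathway_support"])
    def test_log_additivity_over_evidence_channels(self, which):
        """Halving any one probability adds exactly ln 2 to the weight."""
        base = EvidenceRecord(p_biochem=0.7, p_thermo=0.9, pathway_support=0.8)
        halved = EvidenceRecord(**{**base.__dict__, which: getattr(base, which) / 2})
        assert reaction_weight(halved) - reaction_weight(base) == \
            pytest.approx(math.log(2))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_probability_rejected(self, bad):
        with pytest.raises(ValueError):
            reaction_weight(EvidenceRecord(p_biochem=bad))

    def test_missing_evidence_defaults_to_uninformative_pathway_prior(self):
        rxn = ReactionRecord(id="R", stoichiometry={})
        w = default_weights([rxn])["R"]
        assert w == pytest.approx(math.log(2))  # pathway_support = 0.5


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def grows(model, media):
    return limed_fba(model, media).objective_value > THRESHOLD


def brute_force_additions(model, db, pheno, weights, max_size=3):
    """Minimum-weight addition set by exhaustive subset enumeration."""
    from farm.model import apply_knockout
    best, best_w = None, math.inf
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(db, size):
            trial = apply_knockout(model, pheno.genes).copy()
            for cand in combo:
                trial.add_reaction(cand)
                trial.genes |= cand.gpr.genes()
            trial = apply_knockout(trial, pheno.genes)
            if grows(trial, pheno.media):
                w = sum(weights[c.id] for c in combo)
                if w < best_w - 1e-12:
                    best, best_w = frozenset(c.id for c in combo), w
    return best, best_w


def brute_force_removals(model, pheno, weights, removable, max_size=3):
    best, best_w = None, math.inf
    from farm.model import apply_knockout
    base = apply_knockout(model, pheno.genes)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(removable, size):
            trial = base.copy()
            for rid in combo:
                rxn = trial.reaction(rid)
                rxn.lower_bound = rxn.upper_bound = 0.0
            if not grows(trial, pheno.media):
                w = sum(weights[r] for r in combo)
                if w < best_w - 1e-12:
                    best, best_w = frozenset(combo), w
    return best, best_w


# ---------------------------------------------------------------------------
# restore growth
# ---------------------------------------------------------------------------

def chain_pheno(genes, media):
    return Phenotype(genes=frozenset(genes), media=media, observed="viable")


class TestRestoreGrowth:
    def test_unique_minimal_repair_found(self):
        fix = fx.linear_chain(n=3)
        db = [ReactionRecord(id="DB_fix",
                             stoichiometry={"M1[c]": -1, "M2[c]": 1})]
        rec = restore_growth(fix.model, db, chain_pheno({"g1"}, fix.media))
        assert rec.resolved
        assert [r for r, _ in rec.suggestions] == ["DB_fix"]

    def test_cheaper_alternative_wins(self):
        fix = fx.linear_chain(n=3)
        db = [
            ReactionRecord(id="DB_a", stoichiometry={"M1[c]": -1, "M2[c]": 1},
                           evidence=EvidenceRecord(p_biochem=0.905)),
            ReactionRecord(id="DB_b", stoichiometry={"M1[c]": -1, "M2[c]": 1},
                           evidence=EvidenceRecord(p_biochem=0.135)),
        ]
        weights = default_weights(db)
        pheno = chain_pheno({"g1"}, fix.media)
        rec = restore_growth(fix.model, db, pheno, weights=weights)
        oracle, oracle_w = brute_force_additions(fix.model, db, pheno, weights)
        assert rec.resolved
        assert {r for r, _ in rec.suggestions} == oracle == {"DB_a"}
        assert sum(w for _, w in rec.suggestions) == pytest.approx(oracle_w)

    def test_two_reaction_repair_matches_subset_enumeration(self):
        fix = fx.linear_chain(n=4)
        db = [
            ReactionRecord(id="DB_12", stoichiometry={"M1[c]": -1, "M2[c]": 1}),
            ReactionRecord(id="DB_23", stoichiometry={"M2[c]": -1, "M3[c]": 1}),
            ReactionRecord(id="DB_dud", stoichiometry={"M4[c]": -1, "M1[c]": 1}),
        ]
        weights = default_weights(db)
        pheno = chain_pheno({"g1", "g2"}, fix.media)
        rec = restore_growth(fix.model, db, pheno, weights=weights)
        oracle, oracle_w = brute_force_additions(fix.model, db, pheno, weights)
        assert rec.resolved
        assert {r for r, _ in rec.suggestions} == oracle == {"DB_12", "DB_23"}
        assert sum(w for _, w in rec.suggestions) == pytest.approx(oracle_w)

    def test_no_feasible_addition_reported_unresolvable(self):
        fix = fx.linear_chain(n=3)
        db = [ReactionRecord(id="DB_dud",
                             stoichiometry={"M2[c]": -1, "M1[c]": 1})]
        rec = restore_growth(fix.model, db, chain_pheno({"g1"}, fix.media))
        assert not rec.resolved and rec.suggestions == []

    def test_every_suggestion_flips_the_growth_call(self):
        fix = fx.linear_chain(n=3)
        db = [ReactionRecord(id="DB_fix",
                             stoichiometry={"M1[c]": -1, "M2[c]": 1})]
        pheno = chain_pheno({"g1"}, fix.media)
        rec = restore_growth(fix.model, db, pheno)
        patched = apply_reconciliation(fix.model, rec, database=db)
        res = simulate_knockout(patched, pheno.genes, pheno.media)
        assert res.viable

    def test_weight_monotonicity(self):
        """Raising a candidate's weight never pulls it into the optimum."""
        fix = fx.linear_chain(n=3)
        db = [
            ReactionRecord(id="DB_a", stoichiometry={"M1[c]": -1, "M2[c]": 1}),
            ReactionRecord(id="DB_b", stoichiometry={"M1[c]": -1, "M2[c]": 1}),
        ]
        pheno = chain_pheno({"g1"}, fix.media)
        low = restore_growth(fix.model, db, pheno,
                             weights={"DB_a": 0.1, "DB_b": 1.0})
        high = restore_growth(fix.model, db, pheno,
                              weights={"DB_a": 0.1, "DB_b": 5.0})
        assert {r for r, _ in low.suggestions} == {"DB_a"}
        assert "DB_b" not in {r for r, _ in high.suggestions}

    def test_precondition_growing_model_rejected(self):
        fix = fx.linear_chain(n=3)
        with pytest.raises(ValueError, match="already"):
            restore_growth(fix.model, [], chain_pheno(set(), fix.media))


# ---------------------------------------------------------------------------
# suppress growth
# ---------------------------------------------------------------------------

def curate(model, except_ids=()):
    for rxn in model.reactions:
        if rxn.id not in except_ids:
            rxn.evidence = EvidenceRecord(curated=True)


class TestSuppressGrowth:
    def leaky_model(self, n_bypasses=1):
        fix = fx.linear_chain(n=3)
        m = fix.model
        bypasses = []
        for i in range(n_bypasses):
            rid = f"LEAK{i}"
            m.add_reaction(ReactionRecord(
                id=rid, stoichiometry={"S[e]": -1, "M3[c]": 1},
                evidence=EvidenceRecord(p_biochem=0.2)))
            bypasses.append(rid)
        curate(m, except_ids=bypasses)
        return m, fix.media, bypasses

    def test_single_low_evidence_bypass_cut(self):
        m, media, bypasses = self.leaky_model(1)
        pheno = Phenotype(frozenset({"g1"}), media, "inviable")
        rec = suppress_growth(m, pheno)
        assert rec.resolved
        assert [r for r, _ in rec.suggestions] == bypasses
        assert rec.post_change_biomass <= THRESHOLD

    def test_parallel_bypasses_both_cut_minimally(self):
        m, media, bypasses = self.leaky_model(2)
        pheno = Phenotype(frozenset({"g1"}), media, "inviable")
        rec = suppress_growth(m, pheno)
        weights = default_weights([m.reaction(r) for r in bypasses])
        oracle, oracle_w = brute_force_removals(m, pheno, weights, bypasses)
        assert rec.resolved
        assert {r for r, _ in rec.suggestions} == oracle == set(bypasses)
        assert sum(w for _, w in rec.suggestions) == pytest.approx(oracle_w)

    def test_curated_core_is_unresolvable(self):
        fix = fx.linear_chain(n=3)
        curate(fix.model)
        # observed inviable, but the model grows through curated reactions only
        pheno = Phenotype(frozenset(), fix.media, "inviable")
        rec = suppress_growth(fix.model, pheno)
        assert not rec.resolved

    def test_curated_reactions_never_suggested(self):
        m, media, bypasses = self.leaky_model(1)
        pheno = Phenotype(frozenset({"g1"}), media, "inviable")
        rec = suppress_growth(m, pheno)
        curated = {r.id for r in m.reactions
                   if r.evidence is not None and r.evidence.curated}
        assert not curated & {r for r, _ in rec.suggestions}

    def test_removal_flips_the_growth_call(self):
        m, media, _ = self.leaky_model(1)
        pheno = Phenotype(frozenset({"g1"}), media, "inviable")
        rec = suppress_growth(m, pheno)
        patched = apply_reconciliation(m, rec)
        res = simulate_knockout(patched, pheno.genes, pheno.media)
        assert not res.viable
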