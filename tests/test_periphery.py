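"""Peripheral checks: attacks, IFN-γ-gated P-MHC updates, rendezvous
detection, antibody production, the response decision table, and patrol."""

from __future__ import annotations

import pytest

from gtais.immune_world import (
    KnownRegistry,
    build_registry,
    genome_sentinel,
    make_negator,
)
from gtais.machine_core import NEG, Status, StepBudget, compose, pair, run
from gtais.periphery import (
    AttackError,
    IntegrityError,
    MisroutedResponseError,
    OutcomeKind,
    autoimmune_patrol,
    detect,
    make_world,
    online_attack,
    pmhc_default,
    pmhc_update,
    produce_antibody,
    respond,
)
from gtais.recursion_theory import enumerate_we, smn_sigma
from gtais.thymus import MotifForm, TCRMotif, train_repertoire

from conftest import BUDGET


def diagonal_motif(antigen, gene) -> TCRMotif:
    fg = compose(antigen.code, gene.code)
    return TCRMotif(left=fg.gn, right=fg.gn, sigma=smn_sigma(fg.gn, fg.gn),
                    form=MotifForm.DIAGONAL, source_f=antigen.gn, source_g=gene.gn)


def program_change_motif(antigen, gene) -> TCRMotif:
    fg = compose(antigen.code, gene.code)
    return TCRMotif(left=fg.gn, right=gene.gn, sigma=smn_sigma(fg.gn, gene.gn),
                    form=MotifForm.PROGRAM_CHANGE, source_f=antigen.gn, source_g=gene.gn)


@pytest.fixture()
def world(genome8):
    return make_world(genome8, BUDGET)


@pytest.fixture()
def released(genome8):
    repertoire, _ = train_repertoire(genome8, [NEG], 100, seed=21, budget=BUDGET)
    return list(repertoire.released)


class TestOnlineAttack:
    def test_attack_negates_baseline(self, world, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        event = online_attack(world, antigen, gene, BUDGET)
        assert event.observed == world.baseline[gene.tissue].negate()
        assert world.phenotypes[gene.tissue].polarity == "-"

    def test_observed_matches_direct_oracle(self, world, genome8):
        gene = genome8.genes[2]
        antigen = make_negator(gene, 13, budget=BUDGET)
        event = online_attack(world, antigen, gene, BUDGET)
        oracle = run(compose(antigen.code, gene.code), gene.gn, BUDGET)
        assert event.observed.token() == oracle.output

    def test_double_attack_rejected(self, world, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        online_attack(world, antigen, gene, BUDGET)
        with pytest.raises(AttackError):
            online_attack(world, antigen, gene, BUDGET)

    def test_no_attack_leaves_world_unchanged(self, world):
        assert world.phenotypes == world.baseline
        assert world.events == []


class TestPmhcUpdate:
    def test_ifn_on_updates_to_sentence_index(self, world, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        state = pmhc_default(genome8, ifn_gamma=True)
        event = online_attack(world, antigen, gene, BUDGET)
        updated = pmhc_update(state, event)
        fg = compose(antigen.code, gene.code)
        assert updated.indices[gene.tissue] == pair(fg.gn, fg.gn)

    def test_ifn_off_is_blind(self, world, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        state = pmhc_default(genome8, ifn_gamma=False)
        event = online_attack(world, antigen, gene, BUDGET)
        updated = pmhc_update(state, event)
        assert updated.indices == state.benign

    def test_independent_updates_commute(self, genome8):
        g1, g2 = genome8.genes[1], genome8.genes[2]
        a1 = make_negator(g1, 13, budget=BUDGET)
        a2 = make_negator(g2, 14, budget=BUDGET)

        def final_state(order):
            w = make_world(genome8, BUDGET)
            s = pmhc_default(genome8, ifn_gamma=True)
            for antigen, gene in order:
                s = pmhc_update(s, online_attack(w, antigen, gene, BUDGET))
            return s.indices

        assert final_state([(a1, g1), (a2, g2)]) == final_state([(a2, g2), (a1, g1)])


class TestDetect:
    def test_rendezvous_requires_update_and_motif(self, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        m = diagonal_motif(antigen, gene)

        for ifn, present, expect in [
            (True, True, True), (True, False, False),
            (False, True, False), (False, False, False),
        ]:
            w = make_world(genome8, BUDGET)
            s = pmhc_default(genome8, ifn_gamma=ifn)
            s = pmhc_update(s, online_attack(w, antigen, gene, BUDGET))
            hit = detect([m] if present else [], s)
            assert (hit is not None) is expect

    def test_benign_index_never_fires(self, genome8):
        state = pmhc_default(genome8, ifn_gamma=True)
        g = genome8.genes[0]
        benign = TCRMotif(left=g.gn, right=g.gn, sigma=smn_sigma(g.gn, g.gn),
                          form=MotifForm.SELF, source_f=0, source_g=g.gn)
        assert detect([benign], state) is None


class TestProduceAntibody:
    def test_neutralization_and_productivity(self, world, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        online_attack(world, antigen, gene, BUDGET)
        registry = KnownRegistry(bound=100)
        fg = compose(antigen.code, gene.code)
        sentence = pair(fg.gn, fg.gn)
        ab = produce_antibody(sentence, antigen, gene, genome_sentinel(genome8),
                              registry, 1000, budget=BUDGET, genome=genome8)
        restored = run(ab.code, world.phenotypes[gene.tissue].token(), BUDGET)
        assert restored.output == world.baseline[gene.tissue].token()
        # productivity surrogate: outside both enumerated surrogate sets and
        # outside the exact finite sets themselves
        genome_prefix = enumerate_we(genome_sentinel(genome8), 1000, StepBudget(256))
        assert ab.gn not in set(genome_prefix.members)
        assert ab.gn not in set(genome8.gene_gns())
        assert ab.gn not in registry.entries

    def test_registry_listed_sentence_is_misrouted(self, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        registry = build_registry([(antigen, gene)], 100, budget=BUDGET)
        sentence = next(iter(registry.entries))
        with pytest.raises(MisroutedResponseError):
            produce_antibody(sentence, antigen, gene, genome_sentinel(genome8),
                             registry, 100, budget=BUDGET)


class TestRespond:
    def _attack_setup(self, genome8, *, ifn=True, registry=None):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        world = make_world(genome8, BUDGET)
        state = pmhc_default(genome8, ifn_gamma=ifn)
        event = online_attack(world, antigen, gene, BUDGET)
        state = pmhc_update(state, event)
        registry = registry if registry is not None else KnownRegistry(bound=100)
        return world, state, antigen, gene, registry

    def test_novel_antibody_path_restores_tissue(self, genome8):
        world, state, antigen, gene, registry = self._attack_setup(genome8)
        outcome = respond(world, [diagonal_motif(antigen, gene)], state, registry,
                          budget=BUDGET)
        assert outcome.kind is OutcomeKind.NOVEL_ANTIBODY
        assert outcome.antibody is not None
        assert world.phenotypes[gene.tissue] == world.baseline[gene.tissue]

    def test_ifn_knockout_gives_cytokine_storm(self, genome8):
        world, state, antigen, gene, registry = self._attack_setup(genome8, ifn=False)
        outcome = respond(world, [diagonal_motif(antigen, gene)], state, registry,
                          budget=BUDGET)
        assert outcome.kind is OutcomeKind.CYTOKINE_STORM
        assert world.phenotypes[gene.tissue].polarity == "-"  # not restored

    def test_missing_motif_gives_cytokine_storm(self, genome8):
        world, state, antigen, gene, registry = self._attack_setup(genome8)
        outcome = respond(world, [], state, registry, budget=BUDGET)
        assert outcome.kind is OutcomeKind.CYTOKINE_STORM

    def test_known_antigen_uses_stock_antibody(self, genome8):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        registry = build_registry([(antigen, gene)], 100, budget=BUDGET)
        world, state, antigen, gene, registry = self._attack_setup(
            genome8, registry=registry
        )
        outcome = respond(world, [], state, registry, budget=BUDGET)
        assert outcome.kind is OutcomeKind.KNOWN_ANTIBODY
        assert world.phenotypes[gene.tissue] == world.baseline[gene.tissue]

    def test_reattack_after_novel_response_is_known(self, genome8):
        """Membership growth: the novel sentence joins the listable set."""
        world, state, antigen, gene, registry = self._attack_setup(genome8)
        first = respond(world, [diagonal_motif(antigen, gene)], state, registry,
                        budget=BUDGET)
        assert first.kind is OutcomeKind.NOVEL_ANTIBODY
        # same antigen attacks again, fresh world
        world2 = make_world(world.genome, BUDGET)
        state2 = pmhc_default(world.genome, ifn_gamma=True)
        state2 = pmhc_update(state2, online_attack(world2, antigen, gene, BUDGET))
        second = respond(world2, [diagonal_motif(antigen, gene)], state2, registry,
                         budget=BUDGET)
        assert second.kind is OutcomeKind.KNOWN_ANTIBODY

    def test_attack_on_undeveloped_tissue_undetected(self, genome8):
        world = make_world(genome8, BUDGET)
        gene = genome8.genes[3]
        del world.baseline[gene.tissue]
        del world.phenotypes[gene.tissue]
        antigen = make_negator(gene, 13, budget=BUDGET)
        state = pmhc_default(genome8, ifn_gamma=True)
        state = pmhc_update(state, online_attack(world, antigen, gene, BUDGET))
        outcome = respond(world, [], state, KnownRegistry(bound=10), budget=BUDGET)
        assert outcome.kind is OutcomeKind.UNDETECTED

    def test_integrity_error_on_phantom_update(self, genome8, released):
        world = make_world(genome8, BUDGET)
        state = pmhc_default(genome8, ifn_gamma=True)
        state.indices["t4"] = 12345  # update with no event
        with pytest.raises(IntegrityError):
            respond(world, released, state, KnownRegistry(bound=10), budget=BUDGET)

    def test_benign_world_is_benign(self, genome8, released):
        world = make_world(genome8, BUDGET)
        state = pmhc_default(genome8, ifn_gamma=True)
        outcome = respond(world, released, state, KnownRegistry(bound=10),
                          budget=BUDGET, patrol_steps=50)
        assert outcome.kind is OutcomeKind.BENIGN
        assert outcome.events == []


class TestPatrol:
    def test_fully_selected_repertoire_is_safe(self, genome8, released):
        world = make_world(genome8, BUDGET)
        events = autoimmune_patrol(released, world, 1000, BUDGET)
        assert events == []
        assert world.phenotypes == world.baseline

    def test_forced_escape_flips_at_step_one(self, genome8):
        gene = genome8.genes[0]
        antigen = make_negator(gene, 13, budget=BUDGET)
        world = make_world(genome8, BUDGET)
        events = autoimmune_patrol([program_change_motif(antigen, gene)], world, 10, BUDGET)
        assert events and events[0]["time"] == 1
        assert events[0]["tissue"] == gene.tissue
        assert world.phenotypes[gene.tissue].polarity == "-"

    def test_aire_escape_is_attack_equivalent(self, genome8):
        repertoire, _ = train_repertoire(
            genome8, [NEG], 100, seed=21, aire_dropout={"t2"}, budget=BUDGET
        )
        world = make_world(genome8, BUDGET)
        events = autoimmune_patrol(repertoire.released, world, 5, BUDGET)
        assert any(ev["tissue"] == "t2" for ev in events)
        assert all(ev["tissue"] == "t2" for ev in events)

    def test_conservation_of_untouched_tissues(self, genome8, released):
        gene = genome8.genes[1]
        antigen = make_negator(gene, 13, budget=BUDGET)
        world = make_world(genome8, BUDGET)
        state = pmhc_default(genome8, ifn_gamma=True)
        state = pmhc_update(state, online_attack(world, antigen, gene, BUDGET))
        respond(world, released + [diagonal_motif(antigen, gene)], state,
                KnownRegistry(bound=10), budget=BUDGET)
        for g in world.genome:
            if g.tissue == gene.tissue:
                continue
            assert world.phenotypes[g.tissue].polarity == "+"
            assert state.indices[g.tissue] == state.benign[g.tissue]
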