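"""Online periphery: antigen attacks, IFN-γ-gated peripheral-MHC updates,
Gödel-sentence rendezvous detection, novel-antibody production, and
autoimmune patrol.

The peripheral MHC keeps one meta-index per tissue.  In basal health the
index is the benign default σ(g, g) (as a composite integer pair(g, g)).
When an antigen attack succeeds online and the IFN-γ circuitry is intact,
the index is updated to σ(g¬, g¬) for the conflicted code g¬ = f¬∘g.
Detection is a rendezvous: a released (thymus-trained) DIAGONAL motif whose
composite index equals a tissue's updated peripheral index — an exact
integer match, no tolerance.  With IFN-γ knocked out the update never
happens and the host has a blind spot regarding the other: damage is sensed
but no code-specific response forms (a cytokine storm).

A detected novel attack triggers the productive surprise response: a fresh
antibody code that restores the attacked tissue (negation is an involution)
and whose Gödel number lies outside the enumerated surrogates of the known
genomic and forbidden sets.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .immune_world import (
    Antigen,
    Gene,
    Genome,
    KnownRegistry,
    Phenotype,
    develop,
    genome_sentinel,
    parse_phenotype,
)
from .machine_core import (
    Budgetish,
    DEFAULT_STATE,
    ProgramCode,
    Status,
    StepBudget,
    compose,
    encode_program,
    pair,
    run,
)
from .recursion_theory import DEFAULT_MAX_CANDIDATES, enumerate_we
from .thymus import MotifForm, Repertoire, TCRMotif

DEFAULT_ENUM_BOUND = 10_000
DEFAULT_ENUM_BUDGET = StepBudget(256)


class OutcomeKind(str, Enum):
    NOVEL_ANTIBODY = "NOVEL_ANTIBODY"
    KNOWN_ANTIBODY = "KNOWN_ANTIBODY"
    CYTOKINE_STORM = "CYTOKINE_STORM"
    AUTOIMMUNE = "AUTOIMMUNE"
    UNDETECTED = "UNDETECTED"
    BENIGN = "BENIGN"


class AttackError(RuntimeError):
    """Raised for an attack on a tissue that is already negated."""


class IntegrityError(RuntimeError):
    """World/state inconsistency: a P-MHC index updated with no attack event."""


class MisroutedResponseError(RuntimeError):
    """Novel-antibody production requested for a registry-listed sentence."""


@dataclass(frozen=True)
class AttackEvent:
    antigen: Antigen
    gene: Gene
    time: int
    observed: Phenotype

    def to_json(self) -> dict:
        return {
            "time": self.time,
            "type": "ATTACK",
            "tissue": self.gene.tissue,
            "antigen_gn": self.antigen.gn,
            "gene_gn": self.gene.gn,
            "observed": self.observed.token(),
        }


@dataclass(frozen=True)
class PMHCState:
    """Per-tissue peripheral meta-indexes plus the IFN-γ flag."""

    indices: dict[str, int]
    benign: dict[str, int]
    ifn_gamma: bool = True


@dataclass
class World:
    """The online world: a genome, its developed phenotypes, and event log."""

    genome: Genome
    baseline: dict[str, Phenotype]
    phenotypes: dict[str, Phenotype]
    events: list[AttackEvent] = field(default_factory=list)
    time: int = 0


def make_world(genome: Genome, budget: Budgetish = StepBudget()) -> World:
    baseline = develop(genome, budget)
    return World(genome=genome, baseline=baseline, phenotypes=dict(baseline))


def pmhc_default(genome: Genome, ifn_gamma: bool = True) -> PMHCState:
    benign = {g.tissue: pair(g.gn, g.gn) for g in genome}
    return PMHCState(indices=dict(benign), benign=benign, ifn_gamma=ifn_gamma)


def online_attack(
    world: World,
    antigen: Antigen,
    gene: Gene,
    budget: Budgetish = StepBudget(),
) -> AttackEvent:
    """Execute a negator attack on one gene's tissue.

    The observed phenotype is the actual output of the conflicted code
    f¬∘g run online; for a successful negator attack it is the negation of
    the baseline.  A second attack on an already-negated tissue is rejected.
    """
    current = world.phenotypes.get(gene.tissue)
    if current is not None and current.polarity == "-":
        raise AttackError(f"tissue {gene.tissue} is already negated")
    conflicted = compose(antigen.code, gene.code)
    out = run(conflicted, gene.gn, budget)
    observed = parse_phenotype(out.output) if out.status is Status.HALTED else None
    if observed is None:
        raise AttackError(
            f"antigen gn={antigen.gn} did not produce a phenotype on {gene.tissue}"
        )
    world.time += 1
    world.phenotypes[gene.tissue] = observed
    event = AttackEvent(antigen=antigen, gene=gene, time=world.time, observed=observed)
    world.events.append(event)
    return event


def pmhc_update(state: PMHCState, event: AttackEvent) -> PMHCState:
    """Record the attack in the peripheral MHC — gated by IFN-γ.

    With IFN-γ on, the attacked tissue's index becomes pair(g¬, g¬), the
    same composite the liar fixed point assigns to the sentence σ(g¬, g¬).
    With IFN-γ off the index is left at its benign default: the blind spot.
    """
    if not state.ifn_gamma:
        return state
    conflicted = compose(event.antigen.code, event.gene.code)
    indices = dict(state.indices)
    indices[event.gene.tissue] = pair(conflicted.gn, conflicted.gn)
    return replace(state, indices=indices)


def detect(released: Sequence[TCRMotif], state: PMHCState) -> TCRMotif | None:
    """Gödel-sentence rendezvous: exact composite-index match.

    Returns a released motif whose σ composite equals some tissue's current
    peripheral index, provided that index differs from the tissue's benign
    default (a benign σ(g, g) match never fires).
    """
    for tissue, idx in state.indices.items():
        if idx == state.benign.get(tissue):
            continue
        for m in released:
            if m.sigma.composite_gn == idx:
                return m
    return None


@dataclass(frozen=True)
class Antibody:
    code: ProgramCode
    gn: int
    target_sentence: int


@functools.lru_cache(maxsize=4096)
def _cached_run(code_text: str, input_value: str, T: int):
    return run(encode_program(code_text), input_value, StepBudget(T))


def produce_antibody(
    sentence: int,
    antigen: Antigen,
    gene: Gene,
    genome_set_index: int | ProgramCode,
    registry: KnownRegistry,
    N: int = DEFAULT_ENUM_BOUND,
    *,
    budget: Budgetish = StepBudget(),
    enum_budget: Budgetish = DEFAULT_ENUM_BUDGET,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    genome: Genome | None = None,
) -> Antibody:
    """Post's productive surprise response: a fresh neutralizing code.

    The antibody reapplies the negation to the attacked tissue's output —
    negation is an involution, so application restores polarity +.  Its
    Gödel number is canonically padded until it avoids the first-N
    dovetail-enumerated members of the genome-set and registry-set
    surrogates, and (a strictly stronger direct check on the same finite
    sets) every gene gn, registry sentence gn and stock-antibody gn.
    """
    if sentence in registry:
        raise MisroutedResponseError(
            f"sentence {sentence} is registry-listed; use the stock antibody"
        )
    genome_prefix = enumerate_we(
        genome_set_index, N, enum_budget, max_candidates=max_candidates
    )
    registry_prefix = enumerate_we(
        registry.sentinel, N, enum_budget, max_candidates=max_candidates
    )
    forbidden = set(genome_prefix.members) | set(registry_prefix.members)
    forbidden |= set(registry.entries)
    forbidden |= {code.gn for code in registry.entries.values()}
    if genome is not None:
        forbidden |= set(genome.gene_gns())
    text = "~"
    while encode_program(text).gn in forbidden:
        text += "."
    code = encode_program(text)
    return Antibody(code=code, gn=code.gn, target_sentence=sentence)


def _apply_antibody(world: World, tissue: str, antibody_code: ProgramCode, budget: Budgetish) -> Phenotype:
    out = run(antibody_code, world.phenotypes[tissue].token(), budget)
    restored = parse_phenotype(out.output) if out.status is Status.HALTED else None
    if restored is None:  # pragma: no cover - involution guarantees a phenotype
        raise RuntimeError("antibody failed to produce a phenotype")
    world.phenotypes[tissue] = restored
    return restored


def autoimmune_patrol(
    released: Sequence[TCRMotif],
    world: World,
    steps: int,
    budget: Budgetish = StepBudget(),
    *,
    state_input: str = DEFAULT_STATE,
) -> list[dict]:
    """Patrol the world with the released repertoire.

    Each step executes every released motif's σ-code against the standard
    state (executions are deterministic, so outcomes are cached); a halting
    outcome that negates a currently-healthy tissue flips that tissue and is
    logged as an AUTOIMMUNE event naming the motif.
    """
    T = budget.T if isinstance(budget, StepBudget) else int(budget)
    events: list[dict] = []
    for step in range(1, steps + 1):
        for m in released:
            out = _cached_run(m.sigma.code.text, state_input, T)
            phen = parse_phenotype(out.output) if out.status is Status.HALTED else None
            if phen is None or phen.polarity != "-":
                continue
            current = world.phenotypes.get(phen.tissue)
            if current is not None and current.polarity == "+":
                world.phenotypes[phen.tissue] = phen
                events.append(
                    {
                        "time": step,
                        "type": "AUTOIMMUNE",
                        "tissue": phen.tissue,
                        "motif_composite_gn": m.sigma.composite_gn,
                        "f_gn": m.source_f,
                        "g_gn": m.source_g,
                    }
                )
    return events


@dataclass
class ImmuneOutcome:
    kind: OutcomeKind
    antibody: Antibody | None
    events: list[dict]
    matched_motif: TCRMotif | None = None

    def to_json(self) -> dict:
        return {
            "kind": self.kind.value,
            "antibody_gn": self.antibody.gn if self.antibody else None,
            "events": self.events,
        }


def respond(
    world: World,
    released: Sequence[TCRMotif],
    state: PMHCState,
    registry: KnownRegistry,
    *,
    budget: Budgetish = StepBudget(),
    patrol_steps: int = 1000,
    enum_bound: int = DEFAULT_ENUM_BOUND,
    enum_budget: Budgetish = DEFAULT_ENUM_BUDGET,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> ImmuneOutcome:
    """Classify the world's situation per the adaptive-immune decision table.

    (a) attack whose sentence is registry-listed -> KNOWN_ANTIBODY (stock
    antibody applied, tissue restored); (b) attack + rendezvous match +
    novel sentence -> NOVEL_ANTIBODY (produced, applied, then registered);
    (c) attack without rendezvous (IFN-γ off or diagonal motif missing) ->
    CYTOKINE_STORM (damage sensed, no code-specific response, phenotype not
    restored); (d) no attack, but patrol finds a released motif negating a
    healthy tissue -> AUTOIMMUNE; (e) attack on a never-developed tissue ->
    UNDETECTED.  A benign run with an empty event list is BENIGN.
    """
    for tissue, idx in state.indices.items():
        if idx != state.benign.get(tissue) and not any(
            ev.gene.tissue == tissue for ev in world.events
        ):
            raise IntegrityError(f"P-MHC index for {tissue} updated with no event")

    log: list[dict] = [ev.to_json() for ev in world.events]

    if world.events:
        event = world.events[-1]
        tissue = event.gene.tissue
        if tissue not in world.baseline:
            return ImmuneOutcome(OutcomeKind.UNDETECTED, None, log)
        conflicted = compose(event.antigen.code, event.gene.code)
        sentence = pair(conflicted.gn, conflicted.gn)
        if sentence in registry:
            stock = registry.entries[sentence]
            restored = _apply_antibody(world, tissue, stock, budget)
            log.append(
                {
                    "time": event.time,
                    "type": "KNOWN_ANTIBODY",
                    "tissue": tissue,
                    "antibody_gn": stock.gn,
                    "restored": restored.token(),
                }
            )
            return ImmuneOutcome(OutcomeKind.KNOWN_ANTIBODY, None, log)
        match = detect(released, state)
        if match is not None and event.antigen.novel:
            antibody = produce_antibody(
                sentence,
                event.antigen,
                event.gene,
                genome_sentinel(world.genome),
                registry,
                enum_bound,
                budget=budget,
                enum_budget=enum_budget,
                max_candidates=max_candidates,
                genome=world.genome,
            )
            restored = _apply_antibody(world, tissue, antibody.code, budget)
            registry.add(sentence, antibody.code)
            log.append(
                {
                    "time": event.time,
                    "type": "NOVEL_ANTIBODY",
                    "tissue": tissue,
                    "antibody_gn": antibody.gn,
                    "restored": restored.token(),
                }
            )
            return ImmuneOutcome(
                OutcomeKind.NOVEL_ANTIBODY, antibody, log, matched_motif=match
            )
        log.append(
            {
                "time": event.time,
                "type": "CYTOKINE_STORM",
                "tissue": tissue,
                "detail": "damage sensed; no code-specific detection",
            }
        )
        return ImmuneOutcome(OutcomeKind.CYTOKINE_STORM, None, log)

    patrol_events = autoimmune_patrol(released, world, patrol_steps, budget)
    log.extend(patrol_events)
    if patrol_events:
        return ImmuneOutcome(OutcomeKind.AUTOIMMUNE, None, log)
    return ImmuneOutcome(OutcomeKind.BENIGN, None, log)
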