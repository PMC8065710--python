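"""Scenario runner: reproducible end-to-end experiments over the immune world.

Each named scenario wires the synthetic genome, thymic training, and the
peripheral response into one deterministic run.  Under default configuration
the outcome truth table is:

=================  =================  =====================================
scenario           outcome            mechanism
=================  =================  =====================================
baseline_novel     NOVEL_ANTIBODY     attack, IFN-γ on, diagonal motif hit
known_antigen      KNOWN_ANTIBODY     attack sentence is registry-listed
ifn_knockout       CYTOKINE_STORM     attack recorded nowhere: blind spot
aire_knockout      AUTOIMMUNE         untestable σ(g¬, g) escapes, patrols
forced_escape      AUTOIMMUNE         σ(g¬, g) injected into the released set
no_attack          BENIGN             empty event list
=================  =================  =====================================

Outcome kinds are seed-invariant; Gödel numbers and counts vary with seeds.
Reports are byte-stable for equal seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

from .immune_world import (
    Antigen,
    Genome,
    KnownRegistry,
    build_registry,
    make_negator,
    synth_genome,
)
from .machine_core import StepBudget, compose, pair
from .periphery import (
    ImmuneOutcome,
    OutcomeKind,
    make_world,
    online_attack,
    pmhc_default,
    pmhc_update,
    respond,
)
from .recursion_theory import smn_sigma
from .thymus import MotifForm, Repertoire, TCRMotif, repertoire_to_tsv, train_repertoire

SCENARIOS = (
    "baseline_novel",
    "known_antigen",
    "ifn_knockout",
    "aire_knockout",
    "forced_escape",
    "no_attack",
)

_ATTACK_SCENARIOS = frozenset({"baseline_novel", "known_antigen", "ifn_knockout"})


class ScenarioConfig(BaseModel):
    """Validated configuration for one scenario run."""

    scenario: Literal[
        "baseline_novel",
        "known_antigen",
        "ifn_knockout",
        "aire_knockout",
        "forced_escape",
        "no_attack",
    ]
    n_genes: int = 8
    vdj_n: int = 500
    seed: int = 42
    budget_t: int = 10_000
    bound_n: int = 10_000
    patrol_steps: int = 1000
    attack_gene_index: int = 1
    rescue: bool = True
    ifn_gamma: Optional[bool] = None  # None: scenario default
    aire_dropout: tuple[str, ...] = ()
    enum_budget: int = 256
    max_candidates: int = 256

    @field_validator(
        "n_genes", "vdj_n", "budget_t", "bound_n", "patrol_steps",
        "enum_budget", "max_candidates",
    )
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be positive")
        return v

    @field_validator("attack_gene_index", "seed")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("must be non-negative")
        return v


class ScenarioReport(BaseModel):
    config: dict
    outcome_kind: str
    antibody_gn: Optional[int]
    counts: dict[str, int]
    released_forms: dict[str, int]
    rescued: bool
    injected: bool
    events: list[dict]
    repertoire_tsv: str
    budget_t: int
    invariants: dict[str, bool]

    def summary_json(self) -> str:
        payload = self.model_dump(exclude={"repertoire_tsv", "events"})
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    def events_jsonl(self) -> str:
        return "".join(json.dumps(ev, sort_keys=True) + "\n" for ev in self.events)


def _resolve_config(config: ScenarioConfig) -> ScenarioConfig:
    updates: dict = {}
    if config.ifn_gamma is None:
        updates["ifn_gamma"] = config.scenario != "ifn_knockout"
    if config.scenario == "aire_knockout" and not config.aire_dropout:
        updates["aire_dropout"] = (f"t{config.attack_gene_index}",)
    return config.model_copy(update=updates) if updates else config


def run_scenario(config: ScenarioConfig | dict) -> ScenarioReport:
    """Execute one named scenario deterministically under its seed."""
    if isinstance(config, dict):
        config = ScenarioConfig(**config)
    if config.attack_gene_index >= config.n_genes:
        raise ValueError("attack_gene_index out of range")
    config = _resolve_config(config)
    budget = StepBudget(config.budget_t)

    genome = synth_genome(config.n_genes, config.seed, budget=budget)
    target = genome.genes[config.attack_gene_index]
    antigen = make_negator(target, config.seed + 2, budget=budget)
    pool = [antigen.code]

    repertoire, records = train_repertoire(
        genome,
        pool,
        config.vdj_n,
        config.seed + 1,
        aire_dropout=config.aire_dropout,
        budget=budget,
    )

    conflicted = compose(antigen.code, target.code)
    needed_composite = pair(conflicted.gn, conflicted.gn)
    released = list(repertoire.released)

    rescued = False
    if (
        config.scenario in _ATTACK_SCENARIOS
        and config.rescue
        and not any(m.sigma.composite_gn == needed_composite for m in released)
    ):
        # Guarantee the diagonal motif so the scenario exercises detection
        # logic rather than sampling luck; flagged in the report.
        released.append(
            TCRMotif(
                left=conflicted.gn,
                right=conflicted.gn,
                sigma=smn_sigma(conflicted.gn, conflicted.gn),
                form=MotifForm.DIAGONAL,
                source_f=antigen.gn,
                source_g=target.gn,
            )
        )
        rescued = True

    injected = False
    if config.scenario == "forced_escape":
        released.append(
            TCRMotif(
                left=conflicted.gn,
                right=target.gn,
                sigma=smn_sigma(conflicted.gn, target.gn),
                form=MotifForm.PROGRAM_CHANGE,
                source_f=antigen.gn,
                source_g=target.gn,
            )
        )
        injected = True

    if config.scenario == "known_antigen":
        antigen = dataclasses.replace(antigen, novel=False)
        registry = build_registry([(antigen, target)], config.bound_n, budget=budget)
    else:
        registry = KnownRegistry(bound=config.bound_n)

    world = make_world(genome, budget)
    state = pmhc_default(genome, ifn_gamma=bool(config.ifn_gamma))

    if config.scenario in _ATTACK_SCENARIOS:
        event = online_attack(world, antigen, target, budget)
        state = pmhc_update(state, event)

    outcome: ImmuneOutcome = respond(
        world,
        released,
        state,
        registry,
        budget=budget,
        patrol_steps=config.patrol_steps,
        enum_bound=config.bound_n,
        enum_budget=StepBudget(config.enum_budget),
        max_candidates=config.max_candidates,
    )

    final_repertoire = Repertoire(
        generated=repertoire.generated,
        post_positive=repertoire.post_positive,
        released=tuple(released),
    )
    released_forms: dict[str, int] = {}
    for m in released:
        released_forms[m.form.value] = released_forms.get(m.form.value, 0) + 1

    invariants = {
        "stage_containment": {m.sigma.composite_gn for m in repertoire.released}
        <= {m.sigma.composite_gn for m in repertoire.post_positive}
        and {m.sigma.composite_gn for m in repertoire.post_positive}
        <= {m.sigma.composite_gn for m in repertoire.generated},
        "released_all_diagonal_or_escape": all(
            m.form in (MotifForm.DIAGONAL, MotifForm.PROGRAM_CHANGE) for m in released
        ),
        "untouched_tissues_healthy": all(
            world.phenotypes[t].polarity == "+"
            for t in world.baseline
            if t != target.tissue
            and all(ev.get("tissue") != t for ev in outcome.events)
        ),
    }

    return ScenarioReport(
        config=json.loads(config.model_dump_json()),
        outcome_kind=outcome.kind.value,
        antibody_gn=outcome.antibody.gn if outcome.antibody else None,
        counts=final_repertoire.counts,
        released_forms=released_forms,
        rescued=rescued,
        injected=injected,
        events=outcome.events,
        repertoire_tsv=repertoire_to_tsv(final_repertoire),
        budget_t=config.budget_t,
        invariants=invariants,
    )


def report_write(report: ScenarioReport, outdir: str | Path) -> dict[str, Path]:
    """Write summary.json, events.jsonl and repertoire.tsv; byte-stable."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "summary.json",
        "events": out / "events.jsonl",
        "repertoire": out / "repertoire.tsv",
    }
    paths["summary"].write_text(report.summary_json())
    paths["events"].write_text(report.events_jsonl())
    paths["repertoire"].write_text(report.repertoire_tsv)
    return paths
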