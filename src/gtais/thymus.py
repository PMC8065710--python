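"""Offline thymic mirror: Self-Rep records, V(D)J motif generation, and the
two-stage positive/negative selection of T-cell receptor motifs.

The thymus never touches the online world.  It holds the offline
self-representation σ(g, g) of every mirrored gene (the thymic-MHC display)
and generates candidate receptor motifs by applying total transformers f to
genes, in the three forms the combinatorial machinery can produce:

==============  ===================  =========================================
form            index pair           reading
==============  ===================  =========================================
INPUT_CHANGE    σ(g,   f∘g)          change in the input of Diag(g)
PROGRAM_CHANGE  σ(f∘g, g)            change in the program — halting, and
                                     guaranteed to alter the basal output
DIAGONAL        σ(f∘g, f∘g)          change in both: Diag(f∘g), the only
                                     self-consistent anticipation of an attack
==============  ===================  =========================================

Positive selection rejects INPUT_CHANGE (untenable: ϕ_g(f∘g) is not a Diag
operation) and SELF (no diversity).  Negative selection simulates each
PROGRAM_CHANGE motif against the recorded self-phenotypes and eliminates
those whose action negates a record — the motifs that would cause autoimmune
pathology if released.  Only DIAGONAL motifs survive a fully mirrored
training; PROGRAM_CHANGE motifs for genes missing from the mirror (AIRE
dropout) cannot be tested and escape.

Reactivity is decided by computation, not by an affinity score: a motif's
danger is established by actually running its σ-code.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .immune_world import Gene, Genome, Phenotype, parse_phenotype
from .machine_core import (
    Budgetish,
    DEFAULT_STATE,
    Inputish,
    ProgramCode,
    Status,
    StepBudget,
    STANDARD_BATTERY,
    compose,
    extensionally_equal,
    is_total_on_battery,
    run,
)
from .recursion_theory import SigmaIndex, diag, smn_sigma


class MotifForm(str, Enum):
    SELF = "SELF"
    INPUT_CHANGE = "INPUT_CHANGE"
    PROGRAM_CHANGE = "PROGRAM_CHANGE"
    DIAGONAL = "DIAGONAL"


@dataclass(frozen=True)
class SelfRepRecord:
    """One thymic-MHC mirror entry: σ(g, g) plus the recorded phenotype q."""

    gene_gn: int
    sigma: SigmaIndex
    phenotype: Phenotype


@dataclass(frozen=True)
class TCRMotif:
    left: int
    right: int
    sigma: SigmaIndex
    form: MotifForm
    source_f: int
    source_g: int

    def row(self, stage: str) -> dict:
        return {
            "stage": stage,
            "form": self.form.value,
            "f_gn": self.source_f,
            "g_gn": self.source_g,
            "left": self.left,
            "right": self.right,
            "composite_gn": self.sigma.composite_gn,
        }


@dataclass(frozen=True)
class Repertoire:
    generated: tuple[TCRMotif, ...]
    post_positive: tuple[TCRMotif, ...]
    released: tuple[TCRMotif, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "generated": len(self.generated),
            "post_positive": len(self.post_positive),
            "released": len(self.released),
        }


def self_rep(
    genome: Genome,
    aire_dropout: Iterable[str] = (),
    budget: Budgetish = StepBudget(),
) -> tuple[SelfRepRecord, ...]:
    """Mirror the genome into offline Self-Rep records.

    Genes whose tissue is in ``aire_dropout`` (or flagged not self-repped)
    produce no record; these records are the only self-knowledge visible to
    negative selection, so dropout opens an escape route.
    """
    dropped = frozenset(aire_dropout)
    records = []
    for gene in genome:
        if not gene.self_repped or gene.tissue in dropped:
            continue
        out = diag(gene.code, budget)
        phen = parse_phenotype(out.output)
        if phen is None:  # pragma: no cover - genome invariant guards this
            raise RuntimeError(f"gene {gene.tissue} has no recordable phenotype")
        records.append(
            SelfRepRecord(gene_gn=gene.gn, sigma=smn_sigma(gene.gn, gene.gn), phenotype=phen)
        )
    return tuple(records)


_GENERATIVE_FORMS = (MotifForm.INPUT_CHANGE, MotifForm.PROGRAM_CHANGE, MotifForm.DIAGONAL)


def _build_motif(
    form: MotifForm,
    f: ProgramCode,
    gene: Gene,
    fg: ProgramCode,
    selfish: bool,
) -> TCRMotif:
    if selfish:
        left = right = gene.gn
        form = MotifForm.SELF
    elif form is MotifForm.INPUT_CHANGE:
        left, right = gene.gn, fg.gn
    elif form is MotifForm.PROGRAM_CHANGE:
        left, right = fg.gn, gene.gn
    else:
        left = right = fg.gn
    return TCRMotif(
        left=left,
        right=right,
        sigma=smn_sigma(left, right),
        form=form,
        source_f=f.gn,
        source_g=gene.gn,
    )


def vdj_generate(
    genome: Genome,
    transformer_pool: Sequence[ProgramCode],
    n: int,
    seed: int,
    *,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> tuple[TCRMotif, ...]:
    """Generate ``n`` motifs over the space form × transformer × gene.

    Sampling is uniform via per-epoch shuffles of the full combination space
    (so any n at least the size of the space covers it exhaustively, while
    marginals stay uniform), reproducible under the seed.  Transformers are
    only ever applied to genome genes — non-biotic targets are ruled out a
    priori.  A combination whose f acts extensionally as the identity on its
    gene degenerates to a SELF motif regardless of the requested form.
    """
    if not transformer_pool:
        raise ValueError("transformer pool must be nonempty")
    if n < 1:
        raise ValueError("n must be >= 1")
    for f in transformer_pool:
        if not is_total_on_battery(f, battery, budget):
            raise ValueError(f"transformer gn={f.gn} is not total on the battery")

    combos = [
        (form, f, gene)
        for form in _GENERATIVE_FORMS
        for f in transformer_pool
        for gene in genome
    ]
    rng = np.random.default_rng(seed)
    fg_cache: dict[tuple[int, int], tuple[ProgramCode, bool]] = {}
    motifs: list[TCRMotif] = []
    while len(motifs) < n:
        order = rng.permutation(len(combos))
        for idx in order:
            if len(motifs) >= n:
                break
            form, f, gene = combos[idx]
            key = (f.gn, gene.gn)
            if key not in fg_cache:
                fg = compose(f, gene.code)
                fg_cache[key] = (fg, extensionally_equal(fg, gene.code, battery, budget))
            fg, selfish = fg_cache[key]
            motifs.append(_build_motif(form, f, gene, fg, selfish))
    return tuple(motifs)


def positive_select(motifs: Sequence[TCRMotif]) -> tuple[TCRMotif, ...]:
    """Retain PROGRAM_CHANGE and DIAGONAL motifs; reject INPUT_CHANGE and SELF.

    Order-preserving.  Off-diagonal motifs in rows indexed by a gene itself
    (σ(g, f∘g)) are untenable, and σ(g, g) offers no diversity from self.
    """
    return tuple(
        m for m in motifs if m.form in (MotifForm.PROGRAM_CHANGE, MotifForm.DIAGONAL)
    )


def negative_select(
    motifs: Sequence[TCRMotif],
    records: Sequence[SelfRepRecord],
    budget: Budgetish = StepBudget(),
    *,
    state_input: str = DEFAULT_STATE,
    escape_on_missing_record: bool = True,
    generated: Sequence[TCRMotif] | None = None,
) -> Repertoire:
    """Train post-positive motifs against the Self-Rep records.

    Each PROGRAM_CHANGE motif with a mirrored record for its gene is
    *simulated*: its σ-code is run on the standard state input, and a halting
    outcome that negates the recorded phenotype eliminates the motif.
    DIAGONAL motifs are retained — their simulated action either diverges
    (the liar fixed point; divergence is not negation of a record) or leaves
    recorded phenotypes intact.  PROGRAM_CHANGE motifs whose gene has no
    record (AIRE dropout) cannot be tested and escape into the released
    repertoire when ``escape_on_missing_record`` is set.
    """
    by_gene: Mapping[int, SelfRepRecord] = {r.gene_gn: r for r in records}
    released: list[TCRMotif] = []
    for m in motifs:
        if m.form is MotifForm.DIAGONAL:
            released.append(m)
            continue
        if m.form is not MotifForm.PROGRAM_CHANGE:
            continue  # defensively drop anything positive selection missed
        record = by_gene.get(m.right)
        if record is None:
            if escape_on_missing_record:
                released.append(m)
            continue
        out = run(m.sigma.code, state_input, budget)
        phen = parse_phenotype(out.output) if out.status is Status.HALTED else None
        if phen == record.phenotype.negate():
            continue  # autoimmune capacity confirmed by simulation: eliminate
        released.append(m)
    return Repertoire(
        generated=tuple(generated) if generated is not None else tuple(motifs),
        post_positive=tuple(motifs),
        released=tuple(released),
    )


def train_repertoire(
    genome: Genome,
    transformer_pool: Sequence[ProgramCode],
    n: int,
    seed: int,
    *,
    aire_dropout: Iterable[str] = (),
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
    state_input: str = DEFAULT_STATE,
    escape_on_missing_record: bool = True,
) -> tuple[Repertoire, tuple[SelfRepRecord, ...]]:
    """Full thymic pipeline: mirror, generate, positively and negatively select."""
    records = self_rep(genome, aire_dropout, budget)
    generated = vdj_generate(
        genome, transformer_pool, n, seed, battery=battery, budget=budget
    )
    post_positive = positive_select(generated)
    repertoire = negative_select(
        post_positive,
        records,
        budget,
        state_input=state_input,
        escape_on_missing_record=escape_on_missing_record,
        generated=generated,
    )
    return repertoire, records


def repertoire_to_tsv(repertoire: Repertoire) -> str:
    header = "stage\tform\tf_gn\tg_gn\tcomposite_gn"
    rows = [header]
    for stage, motifs in (
        ("generated", repertoire.generated),
        ("post_positive", repertoire.post_positive),
        ("released", repertoire.released),
    ):
        for m in motifs:
            rows.append(
                f"{stage}\t{m.form.value}\t{m.source_f}\t{m.source_g}\t{m.sigma.composite_gn}"
            )
    return "\n".join(rows) + "\n"
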