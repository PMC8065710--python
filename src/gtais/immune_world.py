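"""Synthetic world: genomes of halting self-assembly genes, negator
antigens, and the known-antigen registry.

The world emulated here is the stated model world of the simulator: a finite
set G of gene programs whose self-application halts and emits a
tissue-labeled phenotype of positive polarity (the "theorems" of the genomic
formal system); total negator transformers that compose with genes to invert
their phenotype polarity (the "forbidden codes" / non-theorems); and a
finite registry of known antigen–gene sentences, the bounded surrogate of
the machine-listable set of forbidden codes.

Phenotypes are code-level, not sequence-level: a phenotype is the token
``tissue:polarity`` and a negator flips only the polarity field, never the
tissue label — the negated output is antithetical to, but of the same tissue
as, the healthy one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .machine_core import (
    Budgetish,
    DATA_CHARS,
    Inputish,
    ProgramCode,
    Status,
    StepBudget,
    STANDARD_BATTERY,
    compose,
    encode_program,
    is_total_on_battery,
    program_from_gn,
    quote_literal,
    run,
)
from .recursion_theory import LiarFixedPoint, liar_fixed_point

POSITIVE = "+"
NEGATIVE = "-"

#: Base text of every negator antigen: flip polarity, then the liar guard.
NEGATOR_BASE = "~N"

DEFAULT_GENE_PAD_MAX = 8


class GenomeInvariantError(RuntimeError):
    """A synthesized gene violated the halting-self-assembly invariant."""


class DuplicateRegistryEntryError(ValueError):
    """Two known antigen–gene pairs derived the same sentence index."""


@dataclass(frozen=True)
class Phenotype:
    """Tissue-labeled output with polarity; negation is an involution."""

    tissue: str
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError("polarity must be '+' or '-'")

    def negate(self) -> "Phenotype":
        other = NEGATIVE if self.polarity == POSITIVE else POSITIVE
        return Phenotype(self.tissue, other)

    def token(self) -> str:
        return f"{self.tissue}:{self.polarity}"


def parse_phenotype(token: str | None) -> Phenotype | None:
    """Parse a ``tissue:polarity`` token; None when the token is not one."""
    if not token or ":" not in token:
        return None
    tissue, _, polarity = token.rpartition(":")
    if polarity not in (POSITIVE, NEGATIVE) or not tissue:
        return None
    if not all(c in DATA_CHARS for c in tissue):
        return None
    return Phenotype(tissue, polarity)


@dataclass(frozen=True)
class Gene:
    """A self-assembly program: Diag(g) halts with phenotype (tissue, +)."""

    code: ProgramCode
    tissue: str
    self_repped: bool = True

    @property
    def gn(self) -> int:
        return self.code.gn


@dataclass(frozen=True)
class Genome:
    genes: tuple[Gene, ...]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_tissue(self, tissue: str) -> Gene:
        for g in self.genes:
            if g.tissue == tissue:
                return g
        raise KeyError(tissue)

    def gene_gns(self) -> tuple[int, ...]:
        return tuple(g.gn for g in self.genes)

    def gene_texts(self) -> tuple[str, ...]:
        return tuple(g.code.text for g in self.genes)


@dataclass(frozen=True)
class Antigen:
    """A total negator transformer f¬ targeting specific tissues.

    Composing the antigen onto a gene yields the forbidden code g¬ whose
    output is the negated phenotype; applying it twice restores the original
    (negation is an involution).
    """

    code: ProgramCode
    target_tissues: tuple[str, ...]
    novel: bool = True

    @property
    def gn(self) -> int:
        return self.code.gn


def synth_genome(
    n_genes: int,
    seed: int,
    *,
    pad_max: int = DEFAULT_GENE_PAD_MAX,
    budget: Budgetish = StepBudget(),
) -> Genome:
    """Generate a genome of ``n_genes`` halting self-assembly genes.

    Gene i emits the phenotype token ``t{i}:+``; seed-dependent no-op padding
    varies the Gödel numbers across seeds and gives V(D)J a nontrivial code
    space.  Every gene is verified against the halting invariant at the
    given budget before the genome is returned.
    """
    if n_genes < 1:
        raise ValueError("a genome has at least one gene")
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        pad = int(rng.integers(0, pad_max + 1))
        tissue = f"t{i}"
        code = encode_program(f"{tissue}:{POSITIVE}" + "." * pad)
        gene = Gene(code=code, tissue=tissue)
        _check_gene(gene, budget)
        genes.append(gene)
    return Genome(genes=tuple(genes))


def _check_gene(gene: Gene, budget: Budgetish) -> Phenotype:
    from .recursion_theory import diag

    out = diag(gene.code, budget)
    phen = parse_phenotype(out.output) if out.status is Status.HALTED else None
    if phen is None or phen != Phenotype(gene.tissue, POSITIVE):
        raise GenomeInvariantError(
            f"gene {gene.tissue} (gn={gene.gn}) failed halting self-assembly: "
            f"{out.status.value} output={out.output!r}"
        )
    return phen


def develop(genome: Genome, budget: Budgetish = StepBudget()) -> dict[str, Phenotype]:
    """Run Diag on every gene: the benign baseline world state, all polarity +.

    Idempotent — the map depends only on the genome and the budget.
    """
    return {g.tissue: _check_gene(g, budget) for g in genome}


def make_negator(
    target: Gene,
    seed: int,
    *,
    pad_max: int = 5,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> Antigen:
    """Build a negator antigen for ``target``: a total polarity-flip
    postprocessor with seed-dependent padding (distinct antigen identities
    across seeds)."""
    rng = np.random.default_rng(seed)
    pad = int(rng.integers(0, pad_max + 1))
    code = encode_program(NEGATOR_BASE + "." * pad)
    antigen = Antigen(code=code, target_tissues=(target.tissue,))
    if not is_total_on_battery(code, battery, budget):  # pragma: no cover
        raise GenomeInvariantError("negator construction is not total on battery")
    return antigen


# ---------------------------------------------------------------------------
# Sentinel programs: finite-domain membership machines realizing W-sets
# ---------------------------------------------------------------------------

def sentinel_program(member_texts: Iterable[str]) -> ProgramCode:
    """A program that halts exactly on the given member texts.

    For each member m: duplicate the input, push m, compare, and halt on
    equality; fall through to an unconditional loop otherwise.  Its halting
    domain W is therefore exactly {gn(m)} — the bounded-surrogate realization
    of a machine-listable set.
    """
    checks = "".join("D" + quote_literal(m) + "EBH" for m in member_texts)
    return encode_program(checks + "L")


def genome_sentinel(genome: Genome) -> ProgramCode:
    """Sentinel whose domain is the genome's gene codes (the set G surrogate)."""
    return sentinel_program(genome.gene_texts())


@dataclass
class KnownRegistry:
    """Known antigen–gene sentences mapped to stock antibodies.

    The registry is the bounded surrogate of the machine-listable set of
    forbidden codes: entries key on the sentence composite_gn derived by the
    liar fixed point, and the registry sentinel's halting domain is exactly
    the set of entry keys.
    """

    bound: int
    entries: dict[int, ProgramCode] = field(default_factory=dict)

    @property
    def sentinel(self) -> ProgramCode:
        return sentinel_program(program_from_gn(k).text for k in self.entries)

    @property
    def sentinel_index(self) -> int:
        return self.sentinel.gn

    def __contains__(self, sentence_cgn: int) -> bool:
        return sentence_cgn in self.entries

    def add(self, sentence_cgn: int, antibody: ProgramCode) -> None:
        if sentence_cgn in self.entries:
            raise DuplicateRegistryEntryError(
                f"sentence {sentence_cgn} already registered"
            )
        if len(self.entries) >= self.bound:
            raise ValueError("registry bound exceeded")
        self.entries[sentence_cgn] = antibody

    def to_json(self) -> dict:
        return {
            "bound": self.bound,
            "sentinel_index": self.sentinel_index,
            "entries": {str(k): v.gn for k, v in self.entries.items()},
        }


def build_registry(
    known_antigens: Sequence[tuple[Antigen, Gene]],
    bound: int,
    *,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> KnownRegistry:
    """Derive the registry from a finite known-antigen list.

    Each (antigen, gene) pair contributes its liar-fixed-point sentence as
    key and the antigen's own code as the stock antibody — negation is an
    involution, so the inverse transformer is the negator itself.  Duplicate
    sentence indexes are rejected.
    """
    registry = KnownRegistry(bound=bound)
    for antigen, gene in known_antigens:
        lf: LiarFixedPoint = liar_fixed_point(antigen.code, gene.code, battery, budget)
        registry.add(lf.sentence.composite_gn, antigen.code)
    return registry


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def genome_to_tsv(genome: Genome) -> str:
    lines = ["tissue\tgn"]
    lines += [f"{g.tissue}\t{g.gn}" for g in genome]
    return "\n".join(lines) + "\n"


def genome_to_json(genome: Genome) -> str:
    payload = [
        {"tissue": g.tissue, "gn": g.gn, "text": g.code.text, "self_repped": g.self_repped}
        for g in genome
    ]
    return json.dumps(payload, sort_keys=True)
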