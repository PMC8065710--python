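"""Recursion-theoretic core: Diag, the s-m-n substitution σ, dovetailed
enumeration of W-sets, the Rogers fixed-point construction, and the Liar
(Gödel-sentence) construction.

The two-place substitution index σ(x, y) names, in the offline meta system,
the program that *simulates* the online two-stage execution: first evaluate
ϕ_x(y); if that halts with output e, treat e as a program and evaluate
ϕ_e(s) on the actual state input s.  σ(x, y) exists for every pair — the
meta representation is always available even when the simulated execution
diverges — and is injective in (x, y).

Self-application Diag(g) = ϕ_g(g) models gene-code self-assembly; its
offline record σ(g, g) is the "mirror" entry displayed on thymic MHC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .machine_core import (
    Budgetish,
    ExecutionOutcome,
    Inputish,
    Machine,
    ProgramCode,
    Status,
    StepBudget,
    STANDARD_BATTERY,
    compose,
    encode_program,
    first_divergent_input,
    pair,
    program_from_gn,
    quote_literal,
    run,
)

#: Step quantum allotted to each candidate per dovetail round.
DOVETAIL_QUANTUM = 64

#: Default size of the candidate universe examined by bounded enumeration.
DEFAULT_MAX_CANDIDATES = 256


class TotalityError(ValueError):
    """A transformer required to be total diverged on a battery input."""


@dataclass(frozen=True)
class SigmaIndex:
    """The canonical σ(left, right) meta-index.

    ``code`` is the program realizing the two-stage semantics; ``composite_gn``
    is the Cantor pairing of the two places, carried for exact (intensional)
    matching — Gödel-sentence rendezvous compares these integers exactly.
    """

    left: int
    right: int
    code: ProgramCode
    composite_gn: int

    def to_json(self) -> dict:
        return {
            "left": self.left,
            "right": self.right,
            "code_gn": self.code.gn,
            "code_text": self.code.text,
            "composite_gn": self.composite_gn,
        }


@dataclass(frozen=True)
class FixedPointResult:
    """A program v with ϕ_{f(v)} ≡ ϕ_v (extensionally, on the battery)."""

    v: ProgramCode
    transformer_gn: int


@dataclass(frozen=True)
class EnumerablePrefix:
    """First members of W_x = {y : ϕ_x(y)↓} found by bounded dovetailing.

    ``members`` is monotone in the bound (prefix property) for a fixed
    schedule; every member re-verifies by a direct run at the budget.
    """

    index: int
    bound: int
    members: tuple[int, ...]
    budget_T: int
    max_candidates: int

    def to_json(self) -> dict:
        return {
            "index": self.index,
            "bound": self.bound,
            "members": list(self.members),
            "budget_T": self.budget_T,
            "max_candidates": self.max_candidates,
        }


@dataclass(frozen=True)
class LiarFixedPoint:
    """The negated code g¬ = f¬∘g and its Gödel sentence σ(g¬, g¬)."""

    g_neg: int
    sentence: SigmaIndex


def smn_sigma(x: int | ProgramCode, y: int | ProgramCode) -> SigmaIndex:
    """Effective two-place substitution: the index of the offline simulator.

    The constructed code pushes the texts of y and x as literals, calls x on
    y, then calls the result on the state input — realizing
    ϕ_{σ(x,y)}(s) ≅ ϕ_{ϕ_x(y)}(s).  Construction never fails, even when
    ϕ_x(y) diverges.
    """
    xg = x.gn if isinstance(x, ProgramCode) else int(x)
    yg = y.gn if isinstance(y, ProgramCode) else int(y)
    if xg < 0 or yg < 0:
        raise ValueError("σ is defined on non-negative Gödel numbers")
    xt = program_from_gn(xg).text
    yt = program_from_gn(yg).text
    code = encode_program(quote_literal(yt) + quote_literal(xt) + "!!")
    return SigmaIndex(left=xg, right=yg, code=code, composite_gn=pair(xg, yg))


def diag(g: int | ProgramCode, budget: Budgetish = StepBudget()) -> ExecutionOutcome:
    """Self-Ref: run program g on its own Gödel number, Diag(g) = ϕ_g(g)."""
    code = g if isinstance(g, ProgramCode) else program_from_gn(g)
    return run(code, code.gn, budget)


def sigma_two_stage_oracle(
    x: int | ProgramCode,
    y: int | ProgramCode,
    s: Inputish,
    budget: Budgetish = StepBudget(),
) -> ExecutionOutcome:
    """Independent two-stage evaluation of the σ(x, y) semantics.

    Evaluates ϕ_x(y) directly; on halting, evaluates the output as a program
    on s.  Used as the oracle against which σ-indexed execution is checked;
    deliberately does not share any code path with :func:`smn_sigma`.
    """
    code = x if isinstance(x, ProgramCode) else program_from_gn(x)
    first = run(code, y if isinstance(y, int) else y.gn, budget)
    if first.status is not Status.HALTED:
        return first
    assert first.output is not None
    second = run(encode_program(first.output), s, budget)
    if second.status is not Status.HALTED:
        return second
    return ExecutionOutcome(Status.HALTED, second.output, first.steps + second.steps)


# Rogers fixed-point construction.  For a total transformer f, the auxiliary
# program e computes x ↦ f(text of σ(x, x)); the fixed point is v = σ(e, e):
#   ϕ_v = ϕ_{ϕ_e(e)} = ϕ_{f(σ(e,e))} = ϕ_{f(v)}.
_SIGMA_SELF_BUILDER = "DQxQ,'!'!"  # x ↦ text of σ(x, x).code


def fixed_point(
    f: ProgramCode,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> FixedPointResult:
    """Rogers fixed point of a (battery-)total code transformer f.

    Returns v with ϕ_{f(v)} ≡ ϕ_v extensionally on the battery; the
    construction is the standard diagonal/quine argument expressed through
    smn_sigma and self-application.
    """
    bad = first_divergent_input(f, battery, budget)
    if bad is not None:
        raise TotalityError(
            f"transformer gn={f.gn} is not total on the battery: "
            f"diverges on input {bad!r}"
        )
    e = encode_program(_SIGMA_SELF_BUILDER + quote_literal(f.text) + "!")
    v = smn_sigma(e.gn, e.gn).code
    return FixedPointResult(v=v, transformer_gn=f.gn)


def enumerate_we(
    x: int | ProgramCode,
    bound: int,
    budget: Budgetish = StepBudget(),
    *,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> EnumerablePrefix:
    """Bounded dovetailed enumeration of W_x (inputs on which ϕ_x halts).

    Schedule: candidate i enters at round i+1; each round every active
    candidate advances one quantum of 64 steps, candidates swept in
    ascending order.  A candidate is retired when it halts (appended to the
    members, in discovery order) or exhausts the per-candidate budget.
    Deterministic; members at a smaller bound are a prefix of members at a
    larger bound under the same schedule parameters.

    This is an explicitly bounded surrogate: only Gödel numbers below
    ``max_candidates`` are examined and "does not halt" means "not within
    the budget".
    """
    if bound < 0:
        raise ValueError("bound must be >= 0")
    code = x if isinstance(x, ProgramCode) else program_from_gn(x)
    T = budget.T if isinstance(budget, StepBudget) else int(budget)
    members: list[int] = []
    machines: dict[int, Machine] = {}
    retired: set[int] = set()
    round_no = 0
    while len(members) < bound and len(retired) < max_candidates:
        round_no += 1
        active_limit = min(round_no, max_candidates)
        for i in range(active_limit):
            if i in retired or len(members) >= bound:
                continue
            m = machines.get(i)
            if m is None:
                m = Machine(code.text, program_from_gn(i).text)
                machines[i] = m
            status = m.advance(min(m.steps + DOVETAIL_QUANTUM, T))
            if status is Status.HALTED:
                members.append(i)
                retired.add(i)
                del machines[i]
            elif m.steps >= T:
                retired.add(i)
                del machines[i]
    return EnumerablePrefix(
        index=code.gn,
        bound=bound,
        members=tuple(members),
        budget_T=T,
        max_candidates=max_candidates,
    )


def liar_fixed_point(
    negator: ProgramCode,
    g: int | ProgramCode,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> LiarFixedPoint:
    """Gödel sentence for a negator antigen attacking gene g.

    g¬ = negator∘g is the conflicted ("forbidden") code; the sentence
    σ(g¬, g¬) is its self-applied meta-index, whose composite_gn canonically
    identifies the antigen–tissue pair.  Direct evaluation of the sentence
    code exhausts any step budget: the negator re-invokes the conflicted
    code on itself, so the rendezvous point is a non-halting computation.
    """
    bad = first_divergent_input(negator, battery, budget)
    if bad is not None:
        raise TotalityError(
            f"negator gn={negator.gn} is not total on the battery: "
            f"diverges on input {bad!r}"
        )
    gene_code = g if isinstance(g, ProgramCode) else program_from_gn(g)
    g_neg = compose(negator, gene_code)
    sentence = smn_sigma(g_neg.gn, g_neg.gn)
    return LiarFixedPoint(g_neg=g_neg.gn, sentence=sentence)
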