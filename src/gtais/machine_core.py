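"""Minimal concatenative stack machine with bijective Gödel numbering.

This is the computational substrate for the whole simulator: a tiny
Turing-complete language whose programs are strings over a fixed 29-character
alphabet.  Every string over the alphabet is syntactically valid, so the
canonical length-then-lexicographic enumeration of programs is exactly
bijective base-29 numeration and the Gödel number (gn) of a program is its
rank in that enumeration.

The language is concatenative: values are strings held on a stack, program
composition is concatenation (with a no-op separator), and partial
application — the effective s-m-n operation — is "prepend a quoted literal".

Instruction set
---------------
``.``        no-op (also the composition separator / padding character)
``'c``       append character *c* to the string on top of the stack
``(``        push a fresh empty string (starts a quoted literal)
``,``        concat: pop a, pop b, push b+a
``!``        call: pop code, pop argument, run code on the argument, push output
``~``        flip the polarity suffix ``:+`` / ``:-`` of the top value
``D``        duplicate the top value
``x``        swap the two top values
``Q``        quote: pop v, push the literal-building code for v
``N``        liar guard: if this frame's own input carries the negation marker
             ``N``, re-invoke that input on itself (recursive self-application)
``L``        loop forever (consumes one step per transition, never advances)
``E``        equality test: pop a, pop b, push ``+`` if a == b else ``-``
``B``        branch: pop flag, skip the next instruction when flag is ``-``
``H``        halt the current frame immediately (output = top of stack)
data chars   ``s t : + -`` and digits; a maximal run of data characters is one
             push-literal instruction, so phenotype tokens such as ``t3:+``
             are self-reproducing programs: ϕ_q(s) = q.

Halting is undecidable; every execution here is bounded by a step budget and
"halts" always means "halts within the budget" (the operational surrogate
used throughout the package).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

ALPHABET = ".'(,!~DxQNLEBHst:+-0123456789"
_BASE = len(ALPHABET)
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}
DATA_CHARS = frozenset("st:+-0123456789")

#: Negation marker character; programs containing it are "negator-tainted"
#: and trigger the recursive liar guard ``N`` when self-applied.
NEG_MARK = "N"

#: Default state battery: the declared finite state set on which extensional
#: equality and totality surrogates are evaluated.
STANDARD_BATTERY: tuple[str, ...] = tuple(f"s{i}" for i in range(50))
DEFAULT_STATE = "s0"

DEFAULT_BUDGET_STEPS = 10_000


class ProgramSyntaxError(ValueError):
    """Raised when a program text contains a character outside the alphabet."""


class Status(str, Enum):
    HALTED = "HALTED"
    BUDGET_EXHAUSTED = "BUDGET_EXHAUSTED"
    RUNNING = "RUNNING"


@dataclass(frozen=True)
class ProgramCode:
    """A program together with its Gödel number.

    ``gn`` is the rank of ``text`` in the canonical length-then-lexicographic
    enumeration of all programs; ``encode_program``/``program_from_gn`` are
    mutually inverse bijections.
    """

    gn: int
    text: str

    def __post_init__(self) -> None:
        if self.gn < 0:
            raise ValueError("Gödel numbers are non-negative")


@dataclass(frozen=True)
class StateInput:
    """A token drawn from a declared finite, nonempty state set."""

    value: str
    states: tuple[str, ...] = STANDARD_BATTERY

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("state set must be nonempty")
        if self.value not in self.states:
            raise ValueError(f"state {self.value!r} not in declared state set")


@dataclass(frozen=True)
class StepBudget:
    """Maximum number of interpreter transitions for one execution."""

    T: int = DEFAULT_BUDGET_STEPS

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("step budget must be >= 1")


@dataclass(frozen=True)
class ExecutionOutcome:
    status: Status
    output: str | None
    steps: int

    def __post_init__(self) -> None:
        if (self.output is not None) != (self.status is Status.HALTED):
            raise ValueError("output is present iff status is HALTED")


Inputish = Union[str, int, StateInput, ProgramCode]
Budgetish = Union[StepBudget, int]


# ---------------------------------------------------------------------------
# Gödel numbering
# ---------------------------------------------------------------------------

def _validate_text(text: str) -> None:
    for ch in text:
        if ch not in _CHAR_INDEX:
            raise ProgramSyntaxError(
                f"invalid instruction {ch!r}; alphabet is {ALPHABET!r}"
            )


def encode_program(text: str) -> ProgramCode:
    """Encode a program text as its canonical Gödel number (bijective base-29)."""
    _validate_text(text)
    gn = 0
    for ch in text:
        gn = gn * _BASE + _CHAR_INDEX[ch] + 1
    return ProgramCode(gn=gn, text=text)


def program_from_gn(gn: int) -> ProgramCode:
    """Decode a Gödel number back to the unique program text with that rank."""
    if gn < 0:
        raise ValueError("Gödel numbers are non-negative")
    n = gn
    chars: list[str] = []
    while n > 0:
        n, r = divmod(n - 1, _BASE)
        chars.append(ALPHABET[r])
    return ProgramCode(gn=gn, text="".join(reversed(chars)))


def is_valid_text(text: str) -> bool:
    return all(ch in _CHAR_INDEX for ch in text)


def quote_literal(text: str) -> str:
    """Code that pushes ``text`` onto the stack: ``(`` then one ``'c`` per char."""
    _validate_text(text)
    return "(" + "".join("'" + c for c in text)


# ---------------------------------------------------------------------------
# Cantor pairing (used to fold two-place σ indexes into single integers)
# ---------------------------------------------------------------------------

def pair(x: int, y: int) -> int:
    if x < 0 or y < 0:
        raise ValueError("pairing is defined on non-negative integers")
    s = x + y
    return s * (s + 1) // 2 + y


def unpair(n: int) -> tuple[int, int]:
    if n < 0:
        raise ValueError("pairing is defined on non-negative integers")
    w = (math.isqrt(8 * n + 1) - 1) // 2
    y = n - w * (w + 1) // 2
    return w - y, y


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_OP, _LIT, _QCH = 0, 1, 2


@functools.lru_cache(maxsize=16384)
def _tokenize(text: str) -> tuple[tuple[int, str], ...]:
    tokens: list[tuple[int, str]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in DATA_CHARS:
            j = i
            while j < n and text[j] in DATA_CHARS:
                j += 1
            tokens.append((_LIT, text[i:j]))
            i = j
        elif ch == "'":
            if i + 1 < n:
                tokens.append((_QCH, text[i + 1]))
                i += 2
            else:  # dangling quote: benign no-op, keeps every string valid
                tokens.append((_QCH, ""))
                i += 1
        else:
            tokens.append((_OP, ch))
            i += 1
    return tuple(tokens)


# ---------------------------------------------------------------------------
# Interpreter
# ---------------------------------------------------------------------------

class _Frame:
    __slots__ = ("tokens", "pc", "stack", "input")

    def __init__(self, tokens: tuple[tuple[int, str], ...], stack: list[str], inp: str):
        self.tokens = tokens
        self.pc = 0
        self.stack = stack
        self.input = inp


def _coerce_input(value: Inputish) -> str:
    if isinstance(value, StateInput):
        return value.value
    if isinstance(value, ProgramCode):
        return value.text
    if isinstance(value, int):
        return program_from_gn(value).text
    return value


def _coerce_budget(budget: Budgetish) -> int:
    return budget.T if isinstance(budget, StepBudget) else int(budget)


class Machine:
    """A resumable execution of one program on one input.

    ``advance(limit)`` runs until the machine halts or the cumulative step
    count reaches ``limit``; dovetailed enumeration drives machines in fixed
    step quanta through this interface.  One interpreter transition is one
    step, including transitions of nested applied code.
    """

    __slots__ = ("steps", "status", "output", "_frames")

    def __init__(self, code_text: str, input_value: str):
        _validate_text(code_text)
        self.steps = 0
        self.status = Status.RUNNING
        self.output: str | None = None
        self._frames: list[_Frame] = [
            _Frame(_tokenize(code_text), [input_value], input_value)
        ]

    def advance(self, limit: int) -> Status:
        frames = self._frames
        while self.status is Status.RUNNING:
            if not frames:
                self.status = Status.HALTED
                break
            fr = frames[-1]
            if fr.pc >= len(fr.tokens):
                out = fr.stack[-1] if fr.stack else ""
                frames.pop()
                if frames:
                    frames[-1].stack.append(out)
                else:
                    self.status = Status.HALTED
                    self.output = out
                continue
            if self.steps >= limit:
                break
            self.steps += 1
            kind, arg = fr.tokens[fr.pc]
            fr.pc += 1
            stack = fr.stack
            if kind == _LIT:
                stack.append(arg)
            elif kind == _QCH:
                if arg:
                    if stack:
                        stack[-1] = stack[-1] + arg
                    else:
                        stack.append(arg)
            else:
                op = arg
                if op == ".":
                    pass
                elif op == "!":
                    code = stack.pop() if stack else ""
                    argv = stack.pop() if stack else ""
                    if is_valid_text(code):
                        frames.append(_Frame(_tokenize(code), [argv], argv))
                    else:  # inert value applied as code: leave the argument
                        stack.append(argv)
                elif op == "~":
                    v = stack.pop() if stack else ""
                    if v.endswith(":+"):
                        v = v[:-1] + "-"
                    elif v.endswith(":-"):
                        v = v[:-1] + "+"
                    stack.append(v)
                elif op == "D":
                    v = stack.pop() if stack else ""
                    stack.append(v)
                    stack.append(v)
                elif op == "x":
                    a = stack.pop() if stack else ""
                    b = stack.pop() if stack else ""
                    stack.append(a)
                    stack.append(b)
                elif op == ",":
                    a = stack.pop() if stack else ""
                    b = stack.pop() if stack else ""
                    stack.append(b + a)
                elif op == "(":
                    stack.append("")
                elif op == "Q":
                    v = stack.pop() if stack else ""
                    stack.append(quote_literal(v) if is_valid_text(v) else v)
                elif op == "N":
                    # Liar guard: conflicted (negator-marked) inputs are
                    # re-invoked on themselves, making self-application of a
                    # negated code recursive and hence non-halting.
                    v = fr.input
                    if NEG_MARK in v and is_valid_text(v):
                        frames.append(_Frame(_tokenize(v), [v], v))
                elif op == "L":
                    fr.pc -= 1
                elif op == "E":
                    a = stack.pop() if stack else ""
                    b = stack.pop() if stack else ""
                    stack.append("+" if a == b else "-")
                elif op == "B":
                    flag = stack.pop() if stack else ""
                    if flag == "-":
                        fr.pc += 1
                elif op == "H":
                    fr.pc = len(fr.tokens)
                else:  # pragma: no cover - alphabet is closed
                    raise AssertionError(f"unhandled instruction {op!r}")
        return self.status


def run(code: ProgramCode | str, input: Inputish, budget: Budgetish = StepBudget()) -> ExecutionOutcome:
    """Execute ``code`` on ``input`` under a step budget.

    Deterministic in its arguments.  Monotone in the budget: an execution
    that halts within ``T`` steps halts with the identical output under any
    larger budget.  Non-halting within the budget is a status, not an error.
    """
    text = code.text if isinstance(code, ProgramCode) else code
    T = _coerce_budget(budget)
    if T < 1:
        raise ValueError("step budget must be >= 1")
    m = Machine(text, _coerce_input(input))
    status = m.advance(T)
    if status is Status.HALTED:
        return ExecutionOutcome(Status.HALTED, m.output, m.steps)
    return ExecutionOutcome(Status.BUDGET_EXHAUSTED, None, T)


# ---------------------------------------------------------------------------
# Effective operations on programs
# ---------------------------------------------------------------------------

def compose(f: ProgramCode, g: ProgramCode) -> ProgramCode:
    """Effective composition: ϕ_{compose(f,g)}(x) ≅ ϕ_f(ϕ_g(x)).

    In a concatenative language composition is concatenation; a no-op
    separator keeps adjacent literal runs from merging, so the encoding is
    canonical and the composite's gn is stable and comparable.
    """
    return encode_program(g.text + "." + f.text)


def is_total_on_battery(
    f: ProgramCode,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> bool:
    """Operational totality surrogate: halts on every battery input.

    True totality is undecidable (the set of total computable functions is
    not recursively enumerable); "total" in every report produced by this
    package means exactly this bounded check at the recorded budget.
    """
    if not battery:
        raise ValueError("battery must be nonempty")
    return first_divergent_input(f, battery, budget) is None


def first_divergent_input(
    f: ProgramCode,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> Inputish | None:
    for b in battery:
        if run(f, b, budget).status is not Status.HALTED:
            return b
    return None


def extensionally_equal(
    a: ProgramCode,
    b: ProgramCode,
    battery: Sequence[Inputish] = STANDARD_BATTERY,
    budget: Budgetish = StepBudget(),
) -> bool:
    """Agreement of (status, output) on a declared finite battery at budget T."""
    for x in battery:
        ra, rb = run(a, x, budget), run(b, x, budget)
        if (ra.status, ra.output) != (rb.status, rb.output):
            return False
    return True


#: Canonical named programs.
ID = encode_program("")           # identity: empty program, gn 0
NOOP = encode_program(".")
LOOP = encode_program("L")        # one-instruction infinite loop
NEG = encode_program("~N")        # the canonical negator / "Liar" transformer
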