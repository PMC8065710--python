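"""Shared fixtures: small worlds, program pools, and batteries."""

from __future__ import annotations

import numpy as np
import pytest

from gtais.immune_world import make_negator, synth_genome
from gtais.machine_core import (
    ID,
    NEG,
    NOOP,
    ProgramCode,
    StepBudget,
    STANDARD_BATTERY,
    compose,
    encode_program,
    quote_literal,
)

BUDGET = StepBudget(10_000)


@pytest.fixture(scope="session")
def budget() -> StepBudget:
    return BUDGET


@pytest.fixture(scope="session")
def battery() -> tuple[str, ...]:
    return STANDARD_BATTERY


@pytest.fixture(scope="session")
def genome8():
    return synth_genome(8, 42, budget=BUDGET)


@pytest.fixture(scope="session")
def genome2():
    return synth_genome(2, 7, budget=BUDGET)


@pytest.fixture(scope="session")
def attacker(genome8):
    return make_negator(genome8.genes[1], 44, budget=BUDGET)


#: Base transformers for fixed-point checks.  All are total on every string
#: input, code texts included (the guarded negator "~N" is deliberately not
#: here: it diverges on negator-marked codes, which is its defining liar
#: property, so it is not a lawful Rogers-fixed-point transformer).
BASE_TRANSFORMERS = (
    "",        # identity
    ".",       # no-op
    "~",       # plain polarity flip
    "('.,",    # append a no-op to the value
    "D,",      # duplicate-and-concat
)


def make_transformer_pool(rng: np.random.Generator, size: int) -> list[ProgramCode]:
    """Random total transformers: compositions of the base transformers."""
    pool = []
    for _ in range(size):
        depth = int(rng.integers(1, 4))
        parts = [BASE_TRANSFORMERS[int(rng.integers(len(BASE_TRANSFORMERS)))] for _ in range(depth)]
        code = encode_program(parts[0])
        for p in parts[1:]:
            code = compose(encode_program(p), code)
        pool.append(code)
    return pool


def make_program_pool(genome) -> list[ProgramCode]:
    """A mixed pool of halting and non-halting programs for oracle checks."""
    pool = [ID, NOOP, NEG, encode_program("L")]
    for gene in genome:
        pool.append(gene.code)
        pool.append(compose(NEG, gene.code))
    pool.append(encode_program(quote_literal("t0:+")))
    pool.append(compose(encode_program("('.,"), genome.genes[0].code))
    return pool
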