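"""Shared fixtures: deterministic random read generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from selexkit.seqio import Read

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def make_reads(
    rng: np.random.Generator,
    n: int,
    length: int,
    with_qual: bool = True,
    alphabet: str = BASES,
) -> list[Read]:
    reads = []
    for i in range(n):
        qual = list(rng.integers(0, 41, length)) if with_qual else None
        reads.append(Read(f"r{i}", random_seq(rng, length, alphabet), qual))
    return reads


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240615)
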