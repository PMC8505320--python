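"""Shared fixtures and random-census helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from indbeta import Census, worked_example_fixtures


def random_census(rng: np.random.Generator, *, n_units: int | None = None,
                  max_individuals: int = 30, max_species: int = 6,
                  contiguous: bool = False) -> Census:
    """A small random census: arbitrary (or contiguous) 0/1 lifespans.

    Every individual gets at least one presence. Used for algebraic and
    oracle-equivalence checks where no particular ecology is assumed.
    """
    T = int(n_units) if n_units is not None else int(rng.integers(2, 7))
    n = int(rng.integers(1, max_individuals + 1))
    occ = np.zeros((n, T), dtype=np.int8)
    for i in range(n):
        if contiguous:
            a = int(rng.integers(0, T))
            b = int(rng.integers(a, T))
            occ[i, a:b + 1] = 1
        else:
            occ[i] = rng.integers(0, 2, size=T)
            if not occ[i].any():
                occ[i, rng.integers(0, T)] = 1
    species = tuple(f"s{rng.integers(1, max_species + 1)}" for _ in range(n))
    ids = tuple(f"i{j}" for j in range(n))
    return Census(tuple(range(1, T + 1)), ids, species, occ)


@pytest.fixture
def five_individual_census() -> Census:
    """Two units, three species, five individuals; the hand-worked example.

    i1 (s1) persists; i2 (s1) dies; i3 (s2) dies; i4 (s1) and i5 (s3)
    recruit. Abundance matrix: s1 (2,2), s2 (1,0), s3 (0,1).
    """
    occ = np.array(
        [[1, 1], [1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
    return Census((1, 2), ("i1", "i2", "i3", "i4", "i5"),
                  ("s1", "s1", "s2", "s1", "s3"), occ)


@pytest.fixture
def worked_case_i() -> Census:
    return worked_example_fixtures()[0]


@pytest.fixture
def worked_case_ii() -> Census:
    return worked_example_fixtures()[1]


@pytest.fixture
def three_unit_abundance() -> Census:
    """Census realizing counts s1: (2,1,0), s2: (0,1,2) over three units."""
    occ = np.array([
        [1, 1, 0],   # s1, spans units 1-2
        [1, 0, 0],   # s1, unit 1 only
        [0, 1, 1],   # s2, spans units 2-3
        [0, 0, 1],   # s2, unit 3 only
    ], dtype=np.int8)
    return Census((1, 2, 3), ("i1", "i2", "i3", "i4"),
                  ("s1", "s1", "s2", "s2"), occ)
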