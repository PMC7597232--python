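"""Seeded random molecule specs and interaction tables for property tests."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .molecules import InteractionTable, MoleculeSpec

__all__ = ["random_molecule", "random_table", "fixture_generator"]


def random_molecule(
    rng: np.random.Generator, component_id: int, n_classes: int = 3
) -> MoleculeSpec:
    """A molecule with faces drawn uniformly from classes 1..n_classes."""
    if not 1 <= n_classes <= 3:
        raise ValueError("between one and three classes are supported")
    faces = tuple(int(c) for c in rng.integers(1, n_classes + 1, size=6))
    return MoleculeSpec(component_id, faces, f"Random{component_id}")


def random_table(
    rng: np.random.Generator, classes: frozenset[int] | set[int], bound: float = 2.0
) -> InteractionTable:
    """A bounded random symmetric table, complete for the classes in use;
    class 0 stays inert."""
    cls = sorted(set(classes) | {0})
    eps: dict[tuple[int, int], float] = {}
    for i in cls:
        for j in cls:
            if j < i:
                continue
            v = 0.0 if (i == 0 or j == 0) else float(rng.uniform(-bound, bound))
            eps[(i, j)] = v
            eps[(j, i)] = v
    return InteractionTable(eps)


def fixture_generator(
    seed: int, n: int = 10, bound: float = 2.0
) -> Iterator[tuple[MoleculeSpec, MoleculeSpec, InteractionTable]]:
    """Yield n seeded random (component1, component2, table) triples."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        k1 = int(rng.integers(1, 4))
        k2 = int(rng.integers(1, 4))
        m1 = random_molecule(rng, 1, k1)
        m2 = random_molecule(rng, 2, k2)
        table = random_table(rng, m1.classes | m2.classes, bound)
        yield m1, m2, table
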