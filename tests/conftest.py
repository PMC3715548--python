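"""Shared fixtures: tiny analytic structures and synthetic generators."""

from __future__ import annotations

import numpy as np
import pytest

from enmswitch import CalphaStructure, ResidueKey


def structure_from_coords(coords, chain="A", start=1) -> CalphaStructure:
    coords = np.asarray(coords, dtype=float)
    residues = [ResidueKey(chain, start + i) for i in range(coords.shape[0])]
    return CalphaStructure(residues, coords)


@pytest.fixture
def triangle() -> CalphaStructure:
    """Equilateral triangle, side 3.8 A: the complete graph K3 at cutoff 10."""
    return structure_from_coords(
        [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [1.9, 3.8 * np.sqrt(3) / 2, 0.0]]
    )


@pytest.fixture
def path3() -> CalphaStructure:
    """Three collinear points spaced 3.8 A: a path graph at cutoff 5."""
    return structure_from_coords([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0]])


def rand_index(a, b) -> float:
    """Pair-counting Rand index between two labelings."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))
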