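"""Slow-mode shapes and hinge detection.

The square of a GNM eigenvector gives the distribution of residue mobility
along that mode ("mode shape").  Two complementary hinge definitions are
implemented:

* minima of an averaged slow-mode shape — residues that barely move while
  coordinating the cooperative motion around them;
* crossover points of an individual slow mode — residues where the
  displacement changes sign along the chain, i.e. the pivot between
  anticorrelated blocks.

Both are sign-flip invariant (the shape squares the eigenvector; the
crossover detector re-fixes the sign internally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import ContractError
from .gnm import GNMModes, ModeRange
from .structure_io import ResidueKey

__all__ = [
    "ModeShape",
    "HingeSet",
    "slow_mode_shape",
    "detect_hinges_minima",
    "detect_hinges_crossover",
]


@dataclass
class ModeShape:
    """Per-residue squared eigenvector entries averaged over a mode set.

    Each individual mode shape sums to 1 (unit eigenvectors), so the
    average does too.
    """

    values: np.ndarray
    residues: list[ResidueKey]
    mode_range: ModeRange


@dataclass
class HingeSet:
    """Residues identified as hinge sites, grouped into contiguous segments."""

    hinge_residues: list[ResidueKey]
    method: Literal["minima", "crossover"]
    mode_range: ModeRange
    segments: list[list[ResidueKey]]

    def indices(self, residues: list[ResidueKey]) -> list[int]:
        """Positions of the hinge residues in a reference residue list."""
        pos = {r: i for i, r in enumerate(residues)}
        return [pos[r] for r in self.hinge_residues if r in pos]


def slow_mode_shape(modes: GNMModes, mode_range: ModeRange) -> ModeShape:
    """Average squared-eigenvector shape over the given nonzero modes."""
    cols = mode_range.indices(modes)
    u = modes.eigenvectors[:, cols]
    values = np.mean(u * u, axis=1)
    return ModeShape(values, list(modes.residues), mode_range)


def _segments(residues: list[ResidueKey], flags: np.ndarray) -> list[list[ResidueKey]]:
    """Group flagged residues into runs contiguous in the residue list."""
    segs: list[list[ResidueKey]] = []
    current: list[ResidueKey] = []
    for i, on in enumerate(flags):
        if on:
            if current and residues[i].chain_id != current[-1].chain_id:
                segs.append(current)
                current = []
            current.append(residues[i])
        elif current:
            segs.append(current)
            current = []
    if current:
        segs.append(current)
    return segs


def detect_hinges_minima(
    shape: ModeShape, window: int = 5, floor_quantile: float = 0.25
) -> HingeSet:
    """Hinges as low-lying local minima of a slow-mode shape.

    A residue qualifies when it is a minimum of the shape within a sliding
    window of odd width ``window`` and its value lies at or below the
    ``floor_quantile`` quantile of the whole shape (guards against
    spurious minima on high plateaus).  Contiguous qualifiers merge into
    one hinge segment.  May return an empty set.
    """
    if window % 2 != 1 or window < 1:
        raise ContractError("window must be a positive odd integer")
    v = np.asarray(shape.values, dtype=float)
    n = v.size
    if n < window:
        raise ContractError(f"structure of {n} residues smaller than window {window}")
    half = window // 2
    floor = np.quantile(v, floor_quantile)
    flags = np.zeros(n, dtype=bool)
    # only interior residues can be local minima: a monotone run ending at
    # a terminus is not a hinge
    for i in range(half, n - half):
        if v[i] <= v[i - half : i + half + 1].min() and v[i] <= floor:
            flags[i] = True
    segs = _segments(shape.residues, flags)
    return HingeSet(
        [r for seg in segs for r in seg], "minima", shape.mode_range, segs
    )


def detect_hinges_crossover(modes: GNMModes, mode_index: int = 1) -> HingeSet:
    """Hinges as sign-crossover sites of one slow mode.

    Walks each chain in residue order; wherever the eigenvector changes
    sign between consecutive (nonzero) entries, both flanking residues are
    reported, along with any exactly-zero residues lying between them.
    Crossovers are never detected across chain boundaries, where sequence
    adjacency is meaningless.  For a connected network every nonzero mode
    is orthogonal to the uniform vector, so at least one crossover exists
    somewhere in the structure.
    """
    lam, u = modes.nonzero_mode(mode_index)
    del lam
    tol = 1e-10 * np.abs(u).max()
    sign = np.where(np.abs(u) <= tol, 0, np.sign(u)).astype(int)
    residues = modes.residues
    n = len(residues)
    flags = np.zeros(n, dtype=bool)
    for chain in {r.chain_id for r in residues}:
        idx = [i for i, r in enumerate(residues) if r.chain_id == chain]
        nz = [i for i in idx if sign[i] != 0]
        for a, b in zip(nz, nz[1:]):
            if sign[a] * sign[b] < 0:
                flags[a] = flags[b] = True
                for j in idx:
                    if a < j < b and sign[j] == 0:
                        flags[j] = True
    segs = _segments(residues, flags)
    mr = ModeRange(mode_index, mode_index, label=f"mode {mode_index} crossover")
    return HingeSet([r for seg in segs for r in seg], "crossover", mr, segs)
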