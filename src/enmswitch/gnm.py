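"""Gaussian Network Model: Kirchhoff matrix, modes, fluctuations, correlations.

The GNM treats a structure as a network of C-alpha nodes joined by identical
harmonic springs whenever two nodes lie within a cutoff distance (10 A by
default).  The contact topology is encoded in the Kirchhoff (connectivity)
matrix Gamma — the graph Laplacian: -1 off-diagonal for contacting pairs,
node degree on the diagonal.  Residue fluctuations and their couplings
follow from the spectral decomposition of Gamma,

    <dR_i . dR_j>  ∝  sum_k  (1/lambda_k) u_ki u_kj ,

the sum running over the N-1 nonzero modes (or any chosen subset: the
low-lambda "slow" modes carry the cooperative, global motions).  The
physical prefactor 3 k_B T / gamma is set to 1: everything is reported in
these reduced units, which cancel in normalized correlations.

The normalized cross-correlation map

    C_ij = <dR_i . dR_j> / sqrt(<dR_i^2><dR_j^2>)

lies in [-1, 1]; its diagonal gives 1 and the same-mode-range raw diagonal
is exactly the mean-square fluctuation (MSF) profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ContractError, DisconnectedStructureError, NumericalError
from .structure_io import CalphaStructure, ResidueKey

__all__ = [
    "DEFAULT_CUTOFF",
    "DEFAULT_ZERO_TOL",
    "KirchhoffMatrix",
    "GNMModes",
    "ModeRange",
    "MSFProfile",
    "CorrelationMap",
    "build_kirchhoff",
    "decompose",
    "cross_correlations",
    "mean_square_fluctuations",
    "slowest_modes",
    "gnm_correlation_map",
]

#: Contact cutoff used throughout unless overridden (Angstrom).
DEFAULT_CUTOFF = 10.0
#: Relative eigenvalue threshold below which a mode counts as zero.
DEFAULT_ZERO_TOL = 1e-8


@dataclass
class KirchhoffMatrix:
    """Contact Laplacian Gamma of a C-alpha network."""

    gamma: np.ndarray
    cutoff: float
    structure: CalphaStructure

    @property
    def n(self) -> int:
        return self.gamma.shape[0]


@dataclass
class GNMModes:
    """Eigendecomposition of a Kirchhoff matrix.

    Eigenvalues ascend; eigenvector columns are orthonormal, sign-fixed so
    each column's largest-magnitude entry is positive.  ``n_zero`` counts
    numerically zero eigenvalues: 1 for a connected contact graph, more for
    a disconnected one (carried as a property rather than an error so
    callers can decide).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    residues: list[ResidueKey]

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_nonzero(self) -> int:
        return self.n - self.n_zero

    @property
    def connected(self) -> bool:
        return self.n_zero == 1

    def nonzero_mode(self, k: int) -> tuple[float, np.ndarray]:
        """Eigenpair of the k-th nonzero mode (k = 1 is the slowest)."""
        if not 1 <= k <= self.n_nonzero:
            raise ContractError(f"mode index {k} outside 1..{self.n_nonzero}")
        j = self.n_zero + k - 1
        return float(self.eigenvalues[j]), self.eigenvectors[:, j]


@dataclass(frozen=True)
class ModeRange:
    """Inclusive 1-based range over the nonzero modes (1 = slowest)."""

    first: int = 1
    last: int = 10
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.first <= self.last:
            raise ContractError(f"invalid mode range {self.first}:{self.last}")

    def indices(self, modes: GNMModes) -> np.ndarray:
        """Absolute column indices into the eigenvector matrix."""
        if self.last > modes.n_nonzero:
            raise ContractError(
                f"mode range {self.first}:{self.last} exceeds the "
                f"{modes.n_nonzero} available nonzero modes"
            )
        return np.arange(modes.n_zero + self.first - 1, modes.n_zero + self.last)

    @property
    def n_modes(self) -> int:
        return self.last - self.first + 1

    def describe(self) -> str:
        return self.label or f"modes {self.first}:{self.last}"


def slowest_modes(modes_or_n: GNMModes | int, k: int = 10) -> ModeRange:
    """Range over the k slowest nonzero modes, truncated for tiny systems.

    When fewer than k nonzero modes exist, all of them are used and the
    truncation is recorded in the label.
    """
    avail = modes_or_n.n_nonzero if isinstance(modes_or_n, GNMModes) else int(modes_or_n)
    if avail < 1:
        raise ContractError("no nonzero modes available")
    if avail < k:
        return ModeRange(1, avail, label=f"modes 1:{avail} (truncated from 1:{k})")
    return ModeRange(1, k)


@dataclass
class MSFProfile:
    """Per-residue mean-square fluctuations.

    Units are 3 k_B T / gamma for GNM-derived profiles and A^2 for
    trajectory-derived ones; ``mode_range`` is None in the latter case.
    """

    values: np.ndarray
    residues: list[ResidueKey]
    mode_range: ModeRange | None = None
    label: str = ""


@dataclass
class CorrelationMap:
    """Raw and normalized residue-fluctuation cross-correlations."""

    raw: np.ndarray
    normalized: np.ndarray
    residues: list[ResidueKey]
    mode_range: ModeRange | None = None
    label: str = ""

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    def msf(self) -> MSFProfile:
        """MSF profile for the same mode subset (raw diagonal)."""
        return MSFProfile(
            np.diag(self.raw).copy(), list(self.residues), self.mode_range, self.label
        )


# ---------------------------------------------------------------------------
# construction and decomposition


def build_kirchhoff(
    structure: CalphaStructure, cutoff: float = DEFAULT_CUTOFF
) -> KirchhoffMatrix:
    """Build the Kirchhoff (connectivity) matrix at the given cutoff.

    Gamma_ij = -1 for i != j within `cutoff` (Euclidean, Angstrom), else 0;
    diagonal entries make every row sum to zero.
    """
    if cutoff <= 0:
        raise ContractError("cutoff must be positive")
    coords = structure.coordinates
    contacts = squareform(pdist(coords) <= cutoff).astype(float)
    gamma = -contacts
    np.fill_diagonal(gamma, contacts.sum(axis=1))
    return KirchhoffMatrix(gamma, float(cutoff), structure)


def decompose(
    kirchhoff: KirchhoffMatrix, zero_tol: float = DEFAULT_ZERO_TOL
) -> GNMModes:
    """Full symmetric eigendecomposition of Gamma.

    Eigenvalues below ``zero_tol * max(eigenvalue)`` are classified as zero
    modes.  A connected graph has exactly one (the uniform vector); extra
    zero modes signal a disconnected structure, recorded in ``n_zero``.
    """
    gamma = kirchhoff.gamma
    eigenvalues, eigenvectors = np.linalg.eigh(gamma)
    # sign convention: largest-magnitude entry of each eigenvector positive
    idx = np.abs(eigenvectors).argmax(axis=0)
    signs = np.sign(eigenvectors[idx, np.arange(eigenvectors.shape[1])])
    signs[signs == 0] = 1.0
    eigenvectors = eigenvectors * signs
    n_zero = int(np.sum(eigenvalues < zero_tol * max(eigenvalues[-1], zero_tol)))
    n_zero = max(n_zero, 1)  # the uniform vector is always in the kernel
    return GNMModes(eigenvalues, eigenvectors, n_zero, list(kirchhoff.structure.residues))


def _raw_map(modes: GNMModes, mode_range: ModeRange) -> np.ndarray:
    cols = mode_range.indices(modes)
    lam = modes.eigenvalues[cols]
    u = modes.eigenvectors[:, cols]
    raw = (u / lam) @ u.T
    return (raw + raw.T) / 2.0


def cross_correlations(modes: GNMModes, mode_range: ModeRange) -> CorrelationMap:
    """Cross-correlation map restricted to a mode subset.

    raw_ij = sum_{k in range} u_ki u_kj / lambda_k (reduced units); the
    normalized map divides by sqrt(raw_ii raw_jj) and lies in [-1, 1].
    Over the full nonzero range the raw map is the Moore-Penrose
    pseudo-inverse of Gamma.
    """
    if not modes.connected:
        raise DisconnectedStructureError(
            f"contact graph has {modes.n_zero} components; correlations need 1"
        )
    raw = _raw_map(modes, mode_range)
    diag = np.diag(raw)
    if np.any(diag <= 0):
        raise NumericalError("non-positive fluctuation on the diagonal")
    scale = np.sqrt(diag)
    normalized = raw / np.outer(scale, scale)
    np.fill_diagonal(normalized, 1.0)
    return CorrelationMap(raw, normalized, list(modes.residues), mode_range)


def mean_square_fluctuations(modes: GNMModes, mode_range: ModeRange) -> MSFProfile:
    """Per-residue MSF over a mode subset: sum_k u_ki^2 / lambda_k.

    Identical (bit-for-bit) to the diagonal of the same-range raw map.
    """
    return cross_correlations(modes, mode_range).msf()


def gnm_correlation_map(
    structure: CalphaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    mode_range: ModeRange | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> CorrelationMap:
    """Convenience: Kirchhoff -> modes -> correlation map in one call.

    ``mode_range=None`` selects the ten slowest nonzero modes (truncated
    for tiny structures).
    """
    modes = decompose(build_kirchhoff(structure, cutoff), zero_tol)
    if mode_range is None:
        mode_range = slowest_modes(modes)
    elif mode_range.last > modes.n_nonzero:
        # tiny structure: clip to the available modes and record it
        clipped_last = modes.n_nonzero
        mode_range = ModeRange(
            min(mode_range.first, clipped_last),
            clipped_last,
            label=f"modes {mode_range.first}:{clipped_last} "
            f"(truncated from {mode_range.first}:{mode_range.last})",
        )
    return cross_correlations(modes, mode_range)
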