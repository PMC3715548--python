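"""Conformer-series analysis: superposition, clustering, essential dynamics.

A trajectory here is an ordered list of C-alpha conformers sharing one
topology (plain multi-model PDB stands in for binary trajectory formats).
Frames before ``equilibration_frames`` are discarded as equilibration.

Three analyses mirror the standard MD post-processing workflow:

* RMSD of every frame from a fixed reference after optimal rigid-body
  (Kabsch) superposition;
* radius-controlled conformer clustering in the style of the MMTSB
  ``kclust`` tool — the cluster count is an *output* of the chosen radius,
  not an input, and each cluster is represented by its "best member", the
  frame nearest the centroid;
* essential dynamics — PCA of the superposed C-alpha fluctuation matrix
  via singular value decomposition, with cross-correlations rebuilt from
  the leading essential modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, NumericalError
from .gnm import CorrelationMap, ModeRange, MSFProfile
from .structure_io import CalphaStructure, ResidueKey

__all__ = [
    "Trajectory",
    "ClusterResult",
    "EssentialModes",
    "kabsch_superpose",
    "rmsd_series",
    "radius_cluster",
    "essential_modes",
    "essential_correlations",
    "msf_from_trajectory",
]


@dataclass
class Trajectory:
    """Ordered conformer series with shared topology.

    ``frame_interval`` is the time per saved frame in arbitrary units;
    ``equilibration_frames`` frames are dropped from the front before any
    analysis (0 by default, appropriate for synthetic series).
    """

    frames: list[CalphaStructure]
    frame_interval: float = 1.0
    equilibration_frames: int = 0

    def __post_init__(self) -> None:
        if len(self.production_frames) < 2:
            raise ContractError("need at least 2 frames after equilibration discard")
        first = self.frames[0].topology_keys()
        for f in self.frames[1:]:
            if f.topology_keys() != first:
                raise ContractError("trajectory frames differ in residue topology")

    @property
    def production_frames(self) -> list[CalphaStructure]:
        return self.frames[self.equilibration_frames :]

    @property
    def residues(self) -> list[ResidueKey]:
        return self.frames[0].residues

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    def coordinate_array(self) -> np.ndarray:
        """(T, N, 3) array of the production frames."""
        return np.array([f.coordinates for f in self.production_frames])


@dataclass
class ClusterResult:
    """Partition of frames at a given radius, with best members."""

    radius: float
    assignments: np.ndarray  # frame -> cluster index, production frames
    centroids: list[np.ndarray]  # (N, 3) mean coordinates per cluster
    populations: np.ndarray
    best_members: list[int]  # production-frame index nearest each centroid
    residues: list[ResidueKey] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


@dataclass
class EssentialModes:
    """PCA of the superposed C-alpha fluctuation matrix.

    ``eigenvalues`` are positional variances (A^2) in descending order over
    the full nonzero spectrum; their sum equals the total C-alpha variance.
    ``eigenvectors`` columns are orthonormal 3N-vectors.  ``n_modes_kept``
    records how many leading modes the caller asked for.
    """

    mean_structure: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_modes_kept: int
    residues: list[ResidueKey]
    truncated: bool = False


# ---------------------------------------------------------------------------
# superposition


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (no reflections) mapping mobile onto ref."""
    h = mobile_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def kabsch_superpose(
    mobile: CalphaStructure, reference: CalphaStructure
) -> tuple[CalphaStructure, float]:
    """Least-squares rigid-body superposition of mobile onto reference.

    Returns the superposed copy and the minimized C-alpha RMSD (A).  Only
    proper rotations are allowed, so mirror-image pairs retain a positive
    RMSD.
    """
    if mobile.topology_keys() != reference.topology_keys():
        raise ContractError("superposition requires identical residue lists")
    p = mobile.coordinates
    q = reference.coordinates
    if np.array_equal(p, q):
        return mobile.with_coordinates(p.copy()), 0.0
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    rot = _kabsch_rotation(pc, qc)
    moved = pc @ rot.T + q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return mobile.with_coordinates(moved), rmsd


def rmsd_series(
    traj: Trajectory, reference: CalphaStructure | None = None
) -> np.ndarray:
    """Per-frame Kabsch RMSD from a fixed reference.

    The default reference is the first production frame, matching the
    convention of measuring drift from the initial structure.
    """
    frames = traj.production_frames
    ref = reference if reference is not None else frames[0]
    return np.array([kabsch_superpose(f, ref)[1] for f in frames])


def _superposed_coords(traj: Trajectory) -> np.ndarray:
    """(T, N, 3) production coordinates superposed onto the first frame."""
    frames = traj.production_frames
    ref = frames[0]
    return np.array([kabsch_superpose(f, ref)[0].coordinates for f in frames])


# ---------------------------------------------------------------------------
# radius-controlled clustering


def _pair_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets (Kabsch, proper rotations)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot = _kabsch_rotation(pc, qc)
    return float(np.sqrt(np.mean(np.sum((pc @ rot.T - qc) ** 2, axis=1))))


def _cluster_mean(coords: np.ndarray, members: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Mean of member coordinates after superposing each onto the centroid."""
    cc = centroid - centroid.mean(axis=0)
    acc = np.zeros_like(centroid)
    for i in members:
        pc = coords[i] - coords[i].mean(axis=0)
        rot = _kabsch_rotation(pc, cc)
        acc += pc @ rot.T
    return acc / members.size


def radius_cluster(
    traj: Trajectory, radius: float, max_iter: int = 100, seed: int = 0
) -> ClusterResult:
    """Cluster frames so members stay within ~radius of their centroid.

    Distances are pairwise Kabsch RMSDs between a frame and a cluster
    centroid, so the partition does not depend on any fixed reference
    orientation.  Pass 1 walks the frames in order, seeding a new cluster
    whenever the nearest existing centroid is farther than ``radius``;
    subsequent passes reassign frames to their nearest centroid and
    recompute each centroid as the mean of its members after superposing
    them onto it, until the partition is stable (or ``max_iter``).  The
    number of clusters is therefore an output of the radius.  The radius
    is honoured approximately, as in k-means-style clustering: at
    convergence members are near, but not guaranteed within, ``radius``
    of their centroid.

    ``seed`` only breaks exact distance ties and does not otherwise affect
    the deterministic pass order.
    """
    if radius <= 0:
        raise ContractError("cluster radius must be positive")
    coords = np.array([f.coordinates for f in traj.production_frames])
    t = coords.shape[0]
    rng = np.random.default_rng(seed)

    centroids: list[np.ndarray] = []
    assignments = np.zeros(t, dtype=int)
    for i in range(t):
        if centroids:
            d = np.array([_pair_rmsd(coords[i], c) for c in centroids])
            j = int(d.argmin())
            ties = np.flatnonzero(d == d[j])
            if ties.size > 1:
                j = int(rng.choice(ties))
        else:
            d, j = None, -1
        if j < 0 or d[j] > radius:
            centroids.append(coords[i].copy())
            assignments[i] = len(centroids) - 1
        else:
            assignments[i] = j

    for _ in range(max_iter):
        centroids = [
            _cluster_mean(coords, np.flatnonzero(assignments == k), centroids[k])
            for k in range(len(centroids))
        ]
        new = np.array(
            [
                int(np.argmin([_pair_rmsd(coords[i], c) for c in centroids]))
                for i in range(t)
            ]
        )
        # drop clusters emptied by reassignment, compacting indices
        kept = sorted(set(new.tolist()))
        remap = {old: k for k, old in enumerate(kept)}
        new = np.array([remap[a] for a in new])
        centroids = [centroids[old] for old in kept]
        if np.array_equal(new, assignments):
            break
        assignments = new

    centroids = [
        _cluster_mean(coords, np.flatnonzero(assignments == k), centroids[k])
        for k in range(len(centroids))
    ]
    populations = np.bincount(assignments, minlength=len(centroids))
    best_members = [
        int(
            np.flatnonzero(assignments == k)[
                np.argmin(
                    [
                        _pair_rmsd(coords[i], centroids[k])
                        for i in np.flatnonzero(assignments == k)
                    ]
                )
            ]
        )
        for k in range(len(centroids))
    ]
    return ClusterResult(
        float(radius),
        assignments,
        centroids,
        populations,
        best_members,
        list(traj.residues),
    )


def best_member_ensemble(traj: Trajectory, result: ClusterResult):
    """The best-member frames as a shared-topology ensemble (cluster order)."""
    from .structure_io import StructureEnsemble

    frames = traj.production_frames
    return StructureEnsemble([frames[i] for i in result.best_members], True)


# ---------------------------------------------------------------------------
# essential dynamics


def essential_modes(traj: Trajectory, n_modes: int = 10) -> EssentialModes:
    """Essential modes by SVD of the C-alpha fluctuation matrix.

    Frames are superposed onto the first production frame; the fluctuation
    matrix holds each frame's 3N deviation from the time-mean structure.
    Its SVD yields the eigenvectors of the positional covariance with
    variances s^2 / T.  The full nonzero spectrum is stored (so the trace
    identity with the total variance holds); ``n_modes`` records the
    requested leading count, truncated with a warning if it exceeds the
    available rank.
    """
    if n_modes < 1:
        raise ContractError("n_modes must be >= 1")
    coords = _superposed_coords(traj)
    t, n, _ = coords.shape
    mean = coords.mean(axis=0)
    dev = (coords - mean).reshape(t, 3 * n)
    _, s, vt = np.linalg.svd(dev, full_matrices=False)
    eigenvalues = s**2 / t
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    eigenvalues = eigenvalues[: max(rank, 1)]
    eigenvectors = vt[: max(rank, 1)].T
    truncated = n_modes > eigenvalues.size
    if truncated:
        warnings.warn(
            f"requested {n_modes} essential modes but covariance rank is "
            f"{eigenvalues.size}; keeping {eigenvalues.size}",
            stacklevel=2,
        )
        n_modes = eigenvalues.size
    return EssentialModes(
        mean, eigenvalues, eigenvectors, n_modes, list(traj.residues), truncated
    )


def essential_correlations(
    modes: EssentialModes, n_modes: int | None = None
) -> CorrelationMap:
    """Residue cross-correlations rebuilt from the leading essential modes.

    raw_ij contracts the per-residue 3-vector blocks of each kept
    eigenvector, weighted by its variance; normalization as in the GNM
    maps.  With all modes this equals the correlation matrix of the full
    positional covariance.
    """
    k = n_modes if n_modes is not None else modes.n_modes_kept
    if k < 1 or k > modes.eigenvalues.size:
        raise ContractError(
            f"n_modes {k} outside 1..{modes.eigenvalues.size} available modes"
        )
    n = len(modes.residues)
    v = modes.eigenvectors[:, :k].reshape(n, 3, k)
    lam = modes.eigenvalues[:k]
    raw = np.einsum("iak,jak->ij", v * lam, v)
    raw = (raw + raw.T) / 2.0
    diag = np.diag(raw)
    if np.any(diag <= 0):
        raise NumericalError(
            "a residue has zero fluctuation in the kept essential modes"
        )
    scale = np.sqrt(diag)
    normalized = raw / np.outer(scale, scale)
    np.fill_diagonal(normalized, 1.0)
    mr = ModeRange(1, k, label=f"essential modes 1:{k}")
    return CorrelationMap(raw, normalized, list(modes.residues), mr, "essential dynamics")


def msf_from_trajectory(traj: Trajectory) -> MSFProfile:
    """Per-residue mean-square fluctuation about the superposed time mean (A^2)."""
    coords = _superposed_coords(traj)
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    return MSFProfile(msf, list(traj.residues), None, "trajectory MSF")
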