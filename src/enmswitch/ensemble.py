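"""Ensemble-level GNM analysis, difference maps, and the switch score.

A conformer ensemble (NMR models, cluster best members) is analysed by
running the GNM on every member and averaging the *normalized* maps —
members may differ in overall stiffness, and the displayed quantity of
interest is the normalized correlation, so averaging happens on that scale.

Functional states are compared on the residue intersection of two maps
(difference-correlation map, difference-MSF), and a hinge-mediated switch
is scored from mean correlations between named regions: an inter-domain
hinge that couples to the partner subunit's hinge and ligand-binding site
marks the "on" state of the allosteric switch; a hinge that only talks to
its own subunit marks "off".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError, DisconnectedStructureError, EmptySelectionError
from .gnm import (
    DEFAULT_CUTOFF,
    DEFAULT_ZERO_TOL,
    CorrelationMap,
    ModeRange,
    MSFProfile,
    build_kirchhoff,
    cross_correlations,
    decompose,
    slowest_modes,
)
from .structure_io import ResidueKey, StructureEnsemble

__all__ = [
    "RegionSpec",
    "SubunitRegions",
    "RegionProfile",
    "DifferenceMap",
    "DifferenceProfile",
    "SwitchReport",
    "ensemble_correlation_map",
    "region_profile",
    "difference_correlation_map",
    "difference_msf",
    "switch_score",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named chain + inclusive residue-number range, e.g. the L134-D138 hinge."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContractError(f"region {self.name}: start {self.start} > end {self.end}")

    def member_indices(self, residues: list[ResidueKey]) -> list[int]:
        idx = [
            i
            for i, r in enumerate(residues)
            if r.chain_id == self.chain_id and self.start <= r.residue_number <= self.end
        ]
        if not idx:
            raise EmptySelectionError(
                f"region {self.name} ({self.chain_id}:{self.start}-{self.end}) "
                "matches no resolved residues"
            )
        return idx

    @classmethod
    def parse(cls, name: str, text: str) -> "RegionSpec":
        """Parse the ``chain:start-end`` config notation."""
        try:
            chain, _, span = text.strip().partition(":")
            lo, _, hi = span.partition("-")
            return cls(name, chain.strip(), int(lo), int(hi))
        except ValueError as exc:
            raise ContractError(f"cannot parse region '{name} = {text}'") from exc


@dataclass(frozen=True)
class SubunitRegions:
    """The functional regions of one subunit used by the switch score."""

    hinge: RegionSpec
    camp_site: RegionSpec
    dna_site: RegionSpec
    dna_domain: RegionSpec


@dataclass
class RegionProfile:
    """Mean normalized correlation of a region with every residue."""

    values: np.ndarray
    region: RegionSpec
    residues: list[ResidueKey]


@dataclass
class DifferenceMap:
    """Normalized-correlation difference A - B on the shared residues."""

    values: np.ndarray
    residues: list[ResidueKey]
    state_labels: tuple[str, str]


@dataclass
class DifferenceProfile:
    """Per-residue profile difference A - B on the shared residues."""

    values: np.ndarray
    residues: list[ResidueKey]
    state_labels: tuple[str, str]


@dataclass
class SwitchReport:
    """Region-region couplings and on/off labels, one entry per subunit.

    couplings[subunit] maps coupling names (e.g. ``hinge_other_hinge``,
    ``hinge_camp_other``) to mean normalized correlations in [-1, 1]; the
    label is "on" when the hinge couples across the interface (other-hinge
    coupling >= theta1 and other-subunit cAMP-site coupling >= theta2),
    otherwise "off".  Raw couplings are always reported so conclusions do
    not hinge on the thresholds.
    """

    couplings: dict[str, dict[str, float]]
    state_label: dict[str, str]
    thresholds: tuple[float, float]


# ---------------------------------------------------------------------------


def ensemble_correlation_map(
    ensemble: StructureEnsemble,
    cutoff: float = DEFAULT_CUTOFF,
    mode_range: ModeRange | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> CorrelationMap:
    """Average the per-member normalized GNM maps of an ensemble.

    Every member must share the residue topology and have a connected
    contact graph; a disconnected member aborts with its model id.
    """
    if not ensemble.shared_topology:
        raise ContractError("ensemble members must share one residue topology")
    if len(ensemble) == 0:
        raise ContractError("empty ensemble")
    first = ensemble.members[0]
    if all(np.array_equal(m.coordinates, first.coordinates) for m in ensemble.members[1:]):
        # degenerate ensemble: averaging identical maps is the identity,
        # so compute once (this also keeps the result bit-exact)
        single = StructureEnsemble([first], shared_topology=True)
        if len(ensemble) > 1:
            cmap = ensemble_correlation_map(single, cutoff, mode_range, zero_tol)
            cmap.label = f"ensemble average of {len(ensemble)} members"
            return cmap
    raw_sum = norm_sum = None
    used_range: ModeRange | None = None
    for member in ensemble:
        modes = decompose(build_kirchhoff(member, cutoff), zero_tol)
        if not modes.connected:
            raise DisconnectedStructureError(
                f"ensemble member model {member.model_id} has a disconnected "
                f"contact graph ({modes.n_zero} components)"
            )
        mr = mode_range if mode_range is not None else slowest_modes(modes)
        cmap = cross_correlations(modes, mr)
        used_range = cmap.mode_range
        if raw_sum is None:
            raw_sum = cmap.raw.copy()
            norm_sum = cmap.normalized.copy()
        else:
            raw_sum += cmap.raw
            norm_sum += cmap.normalized
    n = len(ensemble)
    normalized = norm_sum / n
    np.fill_diagonal(normalized, 1.0)
    return CorrelationMap(
        raw_sum / n,
        normalized,
        list(ensemble.members[0].residues),
        used_range,
        label=f"ensemble average of {n} members",
    )


def region_profile(cmap: CorrelationMap, region: RegionSpec) -> RegionProfile:
    """Mean normalized correlation of the region's residues with all residues."""
    idx = region.member_indices(cmap.residues)
    values = cmap.normalized[idx, :].mean(axis=0)
    return RegionProfile(values, region, list(cmap.residues))


def _intersect(
    a: list[ResidueKey], b: list[ResidueKey]
) -> tuple[list[int], list[int], list[ResidueKey]]:
    """Align two residue lists on (chain, number, icode); order follows A."""
    pos_b = {(r.chain_id, r.residue_number, r.insertion_code): j for j, r in enumerate(b)}
    ia: list[int] = []
    ib: list[int] = []
    shared: list[ResidueKey] = []
    for i, r in enumerate(a):
        j = pos_b.get((r.chain_id, r.residue_number, r.insertion_code))
        if j is not None:
            ia.append(i)
            ib.append(j)
            shared.append(r)
    return ia, ib, shared


def difference_correlation_map(
    map_a: CorrelationMap,
    map_b: CorrelationMap,
    state_labels: tuple[str, str] = ("A", "B"),
) -> DifferenceMap:
    """Normalized map of state A minus state B on their shared residues.

    Residues align by (chain, residue number); the result is antisymmetric
    under swapping the two states.
    """
    ia, ib, shared = _intersect(map_a.residues, map_b.residues)
    if len(shared) < 2:
        raise ContractError("fewer than 2 shared residues between the two maps")
    values = map_a.normalized[np.ix_(ia, ia)] - map_b.normalized[np.ix_(ib, ib)]
    return DifferenceMap(values, shared, state_labels)


def difference_msf(
    profile_a: MSFProfile,
    profile_b: MSFProfile,
    state_labels: tuple[str, str] = ("A", "B"),
) -> DifferenceProfile:
    """Per-residue MSF difference A - B on the shared residues."""
    ia, ib, shared = _intersect(profile_a.residues, profile_b.residues)
    if len(shared) < 2:
        raise ContractError("fewer than 2 shared residues between the two profiles")
    values = np.asarray(profile_a.values)[ia] - np.asarray(profile_b.values)[ib]
    return DifferenceProfile(values, shared, state_labels)


def region_pair_coupling(
    cmap: CorrelationMap, region_a: RegionSpec, region_b: RegionSpec
) -> float:
    """Mean normalized correlation over the product of two residue sets."""
    ia = region_a.member_indices(cmap.residues)
    ib = region_b.member_indices(cmap.residues)
    return float(cmap.normalized[np.ix_(ia, ib)].mean())


def switch_score(
    cmap: CorrelationMap,
    subunits: dict[str, SubunitRegions],
    theta1: float = 0.2,
    theta2: float = 0.2,
) -> SwitchReport:
    """Score the hinge-mediated on/off switch from a correlation map.

    For each subunit the report carries mean couplings of the inter-domain
    hinge with: its own DNA-binding domain, the partner subunit's hinge,
    the cAMP-site and DNA-site regions of both subunits, plus the
    cAMP-site <-> DNA-site coupling within the subunit.  A subunit is
    labeled "on" iff hinge <-> other-hinge >= theta1 AND hinge <->
    other-subunit cAMP site >= theta2; the hinge then acts as a global
    hinge coordinating both subunits.  Otherwise "off": the hinge couples
    only within its own subunit.
    """
    if len(subunits) != 2:
        raise ContractError("switch_score expects exactly two subunits")
    names = list(subunits)
    couplings: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    for s in names:
        o = names[0] if s == names[1] else names[1]
        rs, ro = subunits[s], subunits[o]
        c = {
            "hinge_dna_domain_own": region_pair_coupling(cmap, rs.hinge, rs.dna_domain),
            "hinge_other_hinge": region_pair_coupling(cmap, rs.hinge, ro.hinge),
            "hinge_camp_own": region_pair_coupling(cmap, rs.hinge, rs.camp_site),
            "hinge_camp_other": region_pair_coupling(cmap, rs.hinge, ro.camp_site),
            "hinge_dna_site_own": region_pair_coupling(cmap, rs.hinge, rs.dna_site),
            "hinge_dna_site_other": region_pair_coupling(cmap, rs.hinge, ro.dna_site),
            "camp_dna_site_own": region_pair_coupling(cmap, rs.camp_site, rs.dna_site),
        }
        couplings[s] = c
        labels[s] = (
            "on"
            if c["hinge_other_hinge"] >= theta1 and c["hinge_camp_other"] >= theta2
            else "off"
        )
    return SwitchReport(couplings, labels, (theta1, theta2))
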