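"""End-to-end workflow orchestration and reporting.

``run_state_analysis`` reproduces the standard workflow for one functional
state: read a conformer series or ensemble, optionally discard
equilibration frames, superpose and cluster at a fixed radius, run the GNM
on each cluster best member (or ensemble member), average the normalized
maps, extract region profiles and the switch report, and write everything
as CSV next to a JSON run manifest.  ``run_comparison`` diffs two states on
their shared residues.

Outputs are a pure function of (inputs, config, seed); the manifest records
the full parameter set so a run can be reproduced from it alone.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    RegionSpec,
    SubunitRegions,
    SwitchReport,
    difference_correlation_map,
    difference_msf,
    ensemble_correlation_map,
    region_profile,
    switch_score,
)
from .exceptions import ContractError, InputError
from .gnm import CorrelationMap, ModeRange, MSFProfile
from .structure_io import (
    read_pdb_models,
    write_calpha_pdb,
    write_matrix_csv,
    write_profile_csv,
)
from .trajectory import (
    ClusterResult,
    Trajectory,
    best_member_ensemble,
    essential_correlations,
    essential_modes,
    msf_from_trajectory,
    radius_cluster,
    rmsd_series,
)

__all__ = [
    "PipelineConfig",
    "StateReport",
    "ComparisonReport",
    "DEFAULT_REGIONS",
    "load_config",
    "parse_regions_text",
    "subunits_from_regions",
    "run_state_analysis",
    "run_comparison",
]

log = logging.getLogger("enmswitch")

#: Default CRP region definitions (author numbering), instantiated for the
#: two subunit chains A and B: inter-domain hinge L134-D138, cAMP-domain
#: flexible site K52-E58, DNA-domain sites G173-V176 and P154-A156, DNA
#: domain V139-R209, cAMP domain V1-N133.
DEFAULT_REGIONS: dict[str, str] = {}
for _chain in ("A", "B"):
    DEFAULT_REGIONS.update(
        {
            f"hinge_{_chain}": f"{_chain}:134-138",
            f"camp_site_{_chain}": f"{_chain}:52-58",
            f"dna_site_{_chain}": f"{_chain}:173-176",
            f"dna_flex_{_chain}": f"{_chain}:154-156",
            f"dna_domain_{_chain}": f"{_chain}:139-209",
            f"camp_domain_{_chain}": f"{_chain}:1-133",
        }
    )


@dataclass
class PipelineConfig:
    """All knobs of one analysis run (defaults follow the study conventions)."""

    structure: str | None = None  # single/multi-model PDB for the GNM path
    trajectory: str | None = None  # multi-model PDB conformer series
    chains: list[str] | None = None
    cutoff: float = 10.0
    mode_first: int = 1
    mode_last: int = 10
    pca_modes: int = 10
    cluster_radius: float = 3.5
    equilibration_frames: int = 0
    regions: dict[str, RegionSpec] = field(default_factory=dict)
    theta1: float = 0.2
    theta2: float = 0.2
    outdir: str = "enmswitch_out"
    seed: int = 0
    log_level: str = "info"
    label: str = "state"

    def __post_init__(self) -> None:
        for name, value in [
            ("cutoff", self.cutoff),
            ("cluster_radius", self.cluster_radius),
            ("pca_modes", self.pca_modes),
            ("mode_first", self.mode_first),
            ("mode_last", self.mode_last),
        ]:
            if value <= 0:
                raise ContractError(f"{name} must be positive")

    @property
    def mode_range(self) -> ModeRange:
        return ModeRange(self.mode_first, self.mode_last)


def parse_regions_text(text: str) -> dict[str, RegionSpec]:
    """Parse ``name = chain:start-end`` lines (``#`` starts a comment)."""
    regions: dict[str, RegionSpec] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ContractError(f"bad region line: {line!r}")
        name, _, value = line.partition("=")
        name = name.strip()
        regions[name] = RegionSpec.parse(name, value)
    return regions


def default_regions() -> dict[str, RegionSpec]:
    return {n: RegionSpec.parse(n, v) for n, v in DEFAULT_REGIONS.items()}


def default_regions_path() -> Path:
    """Path of the shipped CRP region-definition config file."""
    return Path(__file__).parent / "data" / "crp_regions.cfg"


_CONFIG_KEYS = {
    "structure": str,
    "trajectory": str,
    "cutoff": float,
    "mode_first": int,
    "mode_last": int,
    "pca_modes": int,
    "cluster_radius": float,
    "equilibration_frames": int,
    "theta1": float,
    "theta2": float,
    "outdir": str,
    "seed": int,
    "log_level": str,
    "label": str,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` config file.

    ``regions = FILE`` includes a region-definition file (path relative to
    the config file); ``chains = A,B`` selects chains.  Unset keys keep
    their defaults.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such config file: {path}")
    kwargs: dict = {}
    regions = default_regions()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "regions":
            region_path = (path.parent / value).resolve()
            if not region_path.exists():
                raise InputError(f"region file not found: {region_path}")
            regions = parse_regions_text(region_path.read_text())
        elif key == "chains":
            kwargs["chains"] = [c.strip() for c in value.split(",") if c.strip()]
        elif key in _CONFIG_KEYS:
            kwargs[key] = _CONFIG_KEYS[key](value)
        else:
            raise InputError(f"unknown config key: {key}")
    return PipelineConfig(regions=regions, **kwargs)


def subunits_from_regions(regions: dict[str, RegionSpec]) -> dict[str, SubunitRegions]:
    """Group ``<role>_<subunit>`` regions into per-subunit switch inputs.

    Needs hinge/camp_site/dna_site/dna_domain for exactly two subunits;
    returns an empty dict when the regions do not describe a dimer.
    """
    roles = ("hinge", "camp_site", "dna_site", "dna_domain")
    by_subunit: dict[str, dict[str, RegionSpec]] = {}
    for name, region in regions.items():
        base, _, subunit = name.rpartition("_")
        if base in roles and subunit:
            by_subunit.setdefault(subunit, {})[base] = region
    complete = {
        s: d for s, d in by_subunit.items() if all(r in d for r in roles)
    }
    if len(complete) != 2:
        return {}
    return {
        s: SubunitRegions(d["hinge"], d["camp_site"], d["dna_site"], d["dna_domain"])
        for s, d in complete.items()
    }


# ---------------------------------------------------------------------------
# reporting helpers


@dataclass
class StateReport:
    """Everything one state analysis produced, plus where it was written."""

    config: PipelineConfig
    correlation_map: CorrelationMap
    msf: MSFProfile
    cluster_result: ClusterResult | None
    switch_report: SwitchReport | None
    outputs: list[Path]
    manifest: dict


@dataclass
class ComparisonReport:
    state_a: StateReport
    state_b: StateReport
    outputs: list[Path]
    manifest: dict


def _setup_logging(config: PipelineConfig, outdir: Path) -> None:
    level = {"debug": logging.DEBUG, "info": logging.INFO, "warning": logging.WARNING}[
        config.log_level.lower()
    ]
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    file_handler = logging.FileHandler(outdir / "run.log", mode="w")
    file_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(file_handler)


def _switch_frame(report: SwitchReport) -> pd.DataFrame:
    rows = []
    for subunit, couplings in report.couplings.items():
        row = {"subunit": subunit, **couplings, "state": report.state_label[subunit]}
        rows.append(row)
    return pd.DataFrame(rows)


def _resolvable(regions: dict[str, RegionSpec], cmap: CorrelationMap) -> dict[str, RegionSpec]:
    out = {}
    for name, region in regions.items():
        try:
            region.member_indices(cmap.residues)
        except Exception:
            continue
        out[name] = region
    return out


# ---------------------------------------------------------------------------
# main entry points


def run_state_analysis(config: PipelineConfig) -> StateReport:
    """Run the full single-state workflow and write its report bundle.

    Trajectory path: discard equilibration, superpose, cluster at the
    configured radius, GNM on every cluster best member, average the
    normalized maps.  Ensemble/single-structure path: GNM per model,
    averaged.  Partial outputs are removed if any stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    written: list[Path] = []

    def emit(name: str, writer, *args) -> Path:
        target = outdir / name
        writer(*args, target)
        written.append(target)
        return target

    manifest: dict = {
        "tool": "enmswitch",
        "version": __version__,
        "numpy": np.__version__,
        "label": config.label,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
            if k != "regions"
        },
        "regions": {
            n: f"{r.chain_id}:{r.start}-{r.end}" for n, r in config.regions.items()
        },
    }
    cluster_result: ClusterResult | None = None
    try:
        if config.trajectory:
            log.info("reading trajectory %s", config.trajectory)
            raw = read_pdb_models(config.trajectory, config.chains)
            traj = Trajectory(
                list(raw.members), equilibration_frames=config.equilibration_frames
            )
            series = rmsd_series(traj)
            emit(
                "rmsd_series.csv",
                lambda s, p: pd.DataFrame(
                    {"frame": np.arange(len(s)), "rmsd": s}
                ).to_csv(p, index=False),
                series,
            )
            log.info("clustering %d frames at radius %.2f", len(series), config.cluster_radius)
            cluster_result = radius_cluster(
                traj, config.cluster_radius, seed=config.seed
            )
            manifest["n_clusters"] = cluster_result.n_clusters
            manifest["cluster_populations"] = cluster_result.populations.tolist()
            manifest["best_members"] = cluster_result.best_members
            emit(
                "cluster_evolution.csv",
                lambda r, p: pd.DataFrame(
                    {
                        "frame": np.arange(r.assignments.size),
                        "cluster": r.assignments,
                    }
                ).to_csv(p, index=False),
                cluster_result,
            )
            emit(
                "cluster_populations.csv",
                lambda r, p: pd.DataFrame(
                    {
                        "cluster": np.arange(r.n_clusters),
                        "population": r.populations,
                        "best_member_frame": r.best_members,
                    }
                ).to_csv(p, index=False),
                cluster_result,
            )
            best = best_member_ensemble(traj, cluster_result)
            emit("best_members.pdb", write_calpha_pdb, best)
            log.info("GNM on %d cluster best members", len(best))
            cmap = ensemble_correlation_map(best, config.cutoff, config.mode_range)
            msf = msf_from_trajectory(traj)
            emit("trajectory_msf.csv", write_profile_csv, msf.values, msf.residues)
            ess = essential_modes(traj, config.pca_modes)
            ecmap = essential_correlations(ess)
            emit(
                "essential_correlations.csv",
                write_matrix_csv,
                ecmap.normalized,
                ecmap.residues,
            )
            manifest["essential_eigenvalues"] = ess.eigenvalues[
                : ess.n_modes_kept
            ].tolist()
        else:
            if not config.structure:
                raise InputError("config needs a structure or a trajectory path")
            log.info("reading structure %s", config.structure)
            members = read_pdb_models(config.structure, config.chains)
            cmap = ensemble_correlation_map(members, config.cutoff, config.mode_range)
            msf = cmap.msf()
            manifest["n_models"] = len(members)

        emit("correlation_map.csv", write_matrix_csv, cmap.normalized, cmap.residues)
        emit("raw_correlation_map.csv", write_matrix_csv, cmap.raw, cmap.residues)
        emit("msf.csv", write_profile_csv, msf.values, msf.residues)
        manifest["mode_range"] = cmap.mode_range.describe() if cmap.mode_range else ""
        manifest["n_residues"] = cmap.n

        for name, region in _resolvable(config.regions, cmap).items():
            profile = region_profile(cmap, region)
            emit(f"profile_{name}.csv", write_profile_csv, profile.values, profile.residues)

        switch_report: SwitchReport | None = None
        subunits = subunits_from_regions(_resolvable(config.regions, cmap))
        if subunits:
            switch_report = switch_score(cmap, subunits, config.theta1, config.theta2)
            emit(
                "switch_report.csv",
                lambda r, p: _switch_frame(r).to_csv(p, index=False),
                switch_report,
            )
            manifest["switch_labels"] = switch_report.state_label
            log.info("switch labels: %s", switch_report.state_label)

        manifest["outputs"] = [p.name for p in written]
        target = outdir / "manifest.json"
        target.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(target)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return StateReport(config, cmap, msf, cluster_result, switch_report, written, manifest)


def run_comparison(
    config_a: PipelineConfig, config_b: PipelineConfig, outdir: str | Path | None = None
) -> ComparisonReport:
    """Analyse two states and difference them on the shared residues.

    Writes the difference-correlation map (A - B), the difference-MSF, and
    the two switch reports side by side.
    """
    report_a = run_state_analysis(config_a)
    report_b = run_state_analysis(config_b)
    outdir = Path(outdir) if outdir else Path(config_a.outdir).parent / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    labels = (config_a.label, config_b.label)
    try:
        diff = difference_correlation_map(
            report_a.correlation_map, report_b.correlation_map, labels
        )
        target = outdir / "difference_correlation_map.csv"
        write_matrix_csv(diff.values, diff.residues, target)
        written.append(target)

        dmsf = difference_msf(report_a.msf, report_b.msf, labels)
        target = outdir / "difference_msf.csv"
        write_profile_csv(dmsf.values, dmsf.residues, target)
        written.append(target)

        manifest = {
            "states": list(labels),
            "shared_residues": len(diff.residues),
            "difference_order": f"{labels[0]} - {labels[1]}",
        }
        if report_a.switch_report and report_b.switch_report:
            frame = pd.concat(
                [
                    _switch_frame(report_a.switch_report).assign(state_label=labels[0]),
                    _switch_frame(report_b.switch_report).assign(state_label=labels[1]),
                ]
            )
            target = outdir / "switch_reports.csv"
            frame.to_csv(target, index=False)
            written.append(target)
            manifest["switch_labels"] = {
                labels[0]: report_a.switch_report.state_label,
                labels[1]: report_b.switch_report.state_label,
            }
        target = outdir / "manifest.json"
        target.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(target)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return ComparisonReport(report_a, report_b, written, manifest)
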