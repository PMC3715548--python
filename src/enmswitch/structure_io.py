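"""Read and write C-alpha level structure data.

Structures are reduced to one node per residue (the C-alpha atom), which is
the resolution at which the elastic-network and essential-dynamics analyses
operate.  Multi-model PDB files map to conformer ensembles: one
:class:`CalphaStructure` per MODEL record.  Author residue numbering is kept
verbatim (no renumbering), insertion codes are carried in the residue key,
and unresolved residues are simply absent — never imputed.

Matrices (correlation maps) and per-residue profiles are exchanged as plain
CSV with ``chain:resnum`` column labels so results stay inspectable with
ordinary tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .exceptions import ContractError, EmptySelectionError, PDBParseError

__all__ = [
    "ResidueKey",
    "CalphaStructure",
    "StructureEnsemble",
    "read_pdb_models",
    "write_calpha_pdb",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_profile_csv",
    "read_profile_csv",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author number, insertion code, name.

    ``(chain_id, residue_number, insertion_code)`` is unique within a
    conformer; the 3-letter ``residue_name`` is carried for reporting only
    and does not participate in equality across states.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = field(default="GLY", compare=False)

    @property
    def label(self) -> str:
        """Compact ``chain:resnum[icode]`` label used in CSV headers."""
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"

    @classmethod
    def from_label(cls, label: str, residue_name: str = "GLY") -> "ResidueKey":
        chain, _, rest = label.partition(":")
        num = rest
        icode = ""
        if rest and not rest.lstrip("-").isdigit():
            # trailing non-digit characters are the insertion code
            i = len(rest)
            while i > 0 and not rest[i - 1].isdigit():
                i -= 1
            num, icode = rest[:i], rest[i:]
        return cls(chain, int(num), icode, residue_name)


@dataclass
class CalphaStructure:
    """One conformer reduced to C-alpha nodes.

    coordinates are an (N, 3) float array in Angstrom, row i belonging to
    ``residues[i]``.
    """

    residues: list[ResidueKey]
    coordinates: np.ndarray
    model_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ContractError("coordinates must be an (N, 3) array")
        if len(self.residues) != self.coordinates.shape[0]:
            raise ContractError(
                f"{len(self.residues)} residues but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if self.n_residues < 2:
            raise ContractError("a structure needs at least 2 residues")
        if not np.all(np.isfinite(self.coordinates)):
            raise ContractError("coordinates must be finite")
        keys = [(r.chain_id, r.residue_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ContractError("duplicate (chain, residue number) in structure")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def topology_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple((r.chain_id, r.residue_number, r.insertion_code) for r in self.residues)

    def select_chains(self, chains: Iterable[str]) -> "CalphaStructure":
        wanted = set(chains)
        idx = [i for i, r in enumerate(self.residues) if r.chain_id in wanted]
        if not idx:
            raise EmptySelectionError(f"no residues in chains {sorted(wanted)}")
        return CalphaStructure(
            [self.residues[i] for i in idx], self.coordinates[idx], self.model_id
        )

    def with_coordinates(self, coords: np.ndarray) -> "CalphaStructure":
        return CalphaStructure(list(self.residues), np.array(coords, dtype=float), self.model_id)


@dataclass
class StructureEnsemble:
    """A list of conformers, optionally sharing one residue topology."""

    members: list[CalphaStructure]
    shared_topology: bool = True

    def __post_init__(self) -> None:
        if self.shared_topology and self.members:
            first = self.members[0].topology_keys()
            for m in self.members[1:]:
                if m.topology_keys() != first:
                    raise ContractError(
                        "shared_topology=True but members differ in residue lists"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# PDB reading


def _calpha_coord(residue) -> np.ndarray | None:
    """C-alpha coordinate of a Bio.PDB residue, resolving altlocs.

    Disordered C-alphas keep altloc 'A' when present, else the first listed.
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        ids = atom.disordered_get_id_list()
        pick = "A" if "A" in ids else ids[0]
        atom = atom.disordered_get(pick)
    return np.asarray(atom.get_coord(), dtype=float)


def read_pdb_models(
    path: str | Path, chains: Sequence[str] | None = None
) -> StructureEnsemble:
    """Read a (multi-model) PDB file into a C-alpha conformer ensemble.

    One :class:`CalphaStructure` per MODEL record (exactly one if the file
    has no MODEL records).  Only amino-acid C-alpha atoms are retained;
    heteroatom records (ligands, waters, nucleic acids) are excluded from
    the network.  Residues are ordered by chain then author residue number.

    Parameters
    ----------
    path:
        PDB file path.
    chains:
        Optional chain filter; ``None`` keeps all chains.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such structure file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises assorted exceptions
            raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    wanted = set(chains) if chains else None
    members: list[CalphaStructure] = []
    any_calpha = False
    for model in structure:
        rows: list[tuple[ResidueKey, np.ndarray]] = []
        for chain in model:
            for residue in chain:
                hetflag, resnum, icode = residue.get_id()
                if hetflag.strip():
                    continue  # HETATM / water: not a network node
                coord = _calpha_coord(residue)
                if coord is None:
                    continue
                any_calpha = True
                cid = chain.get_id()
                if wanted is not None and cid not in wanted:
                    continue
                key = ResidueKey(cid, resnum, icode.strip(), residue.get_resname())
                rows.append((key, coord))
        if not rows:
            continue
        rows.sort(key=lambda t: (t[0].chain_id, t[0].residue_number, t[0].insertion_code))
        members.append(
            CalphaStructure(
                [k for k, _ in rows],
                np.array([c for _, c in rows]),
                model_id=model.get_id() + 1 if isinstance(model.get_id(), int) else 1,
            )
        )

    if not any_calpha:
        raise PDBParseError(f"{path} contains no C-alpha atoms")
    if not members:
        raise EmptySelectionError(
            f"chain filter {sorted(wanted)} matched no residues in {path}"
        )
    shared = len({m.topology_keys() for m in members}) == 1
    return StructureEnsemble(members, shared_topology=shared)


# ---------------------------------------------------------------------------
# PDB writing

_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  {resname:>3s} {chain:1s}{resnum:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
)


def write_calpha_pdb(ensemble: StructureEnsemble | CalphaStructure, path: str | Path) -> None:
    """Write an ensemble as a standard multi-model C-alpha PDB file.

    Coordinates use the fixed 3-decimal PDB fields, so a read/write round
    trip is the identity to 3 decimals.
    """
    if isinstance(ensemble, CalphaStructure):
        ensemble = StructureEnsemble([ensemble], shared_topology=True)
    if len(ensemble) == 0:
        raise ContractError("cannot write an empty ensemble")
    lines: list[str] = []
    multi = len(ensemble) > 1
    for i, member in enumerate(ensemble, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        serial = 1
        for key, (x, y, z) in zip(member.residues, member.coordinates):
            lines.append(
                _ATOM_FMT.format(
                    serial=serial,
                    resname=key.residue_name,
                    chain=key.chain_id,
                    resnum=key.residue_number,
                    icode=key.insertion_code or " ",
                    x=x,
                    y=y,
                    z=z,
                )
            )
            serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV matrices and profiles


def _check_labels(n: int, labels: Sequence[ResidueKey]) -> list[str]:
    if len(labels) != n:
        raise ContractError(f"{n} rows but {len(labels)} labels")
    return [k.label for k in labels]


def write_matrix_csv(
    matrix: np.ndarray, labels: Sequence[ResidueKey], path: str | Path
) -> None:
    """Write an N x N residue matrix as CSV with ``chain:resnum`` headers."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ContractError("matrix must be square")
    cols = _check_labels(matrix.shape[0], labels)
    df = pd.DataFrame(matrix, index=cols, columns=cols)
    df.to_csv(path, index_label="residue", float_format="%.10g")


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[ResidueKey]]:
    df = pd.read_csv(path, index_col=0)
    keys = [ResidueKey.from_label(c) for c in df.columns]
    return df.to_numpy(dtype=float), keys


def write_profile_csv(
    values: np.ndarray, labels: Sequence[ResidueKey], path: str | Path
) -> None:
    """Write a per-residue profile (MSF, mode shape, region correlation)."""
    values = np.asarray(values, dtype=float).ravel()
    cols = _check_labels(values.shape[0], labels)
    df = pd.DataFrame({"residue": cols, "value": values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_profile_csv(path: str | Path) -> tuple[np.ndarray, list[ResidueKey]]:
    df = pd.read_csv(path)
    keys = [ResidueKey.from_label(str(c)) for c in df["residue"]]
    return df["value"].to_numpy(dtype=float), keys
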