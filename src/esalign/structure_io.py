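"""Reading, selecting, validating and writing protein backbone chains.

PDB parsing is delegated to Bio.PDB; the results are converted into small
plain dataclasses (:class:`Atom`, :class:`Residue`, :class:`ChainModel`)
that the rest of the package consumes.  Only ``ATOM`` records are kept
(waters, ligands and other HETATM entries are ignored) and alternate
locations are resolved to the highest-occupancy conformer.
"""
from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .errors import (
    ContractError,
    DegenerateChainError,
    EmptyStructureError,
    InputError,
    SelectionError,
)

logger = logging.getLogger(__name__)

#: backbone atom names required for a residue to be usable
BACKBONE_NAMES = ("N", "CA", "C")

#: Cα–Cα separation beyond which a chain break is logged (Å)
CHAIN_BREAK_CUTOFF = 4.5

#: common nonstandard residues mapped to their parent standard residue
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "CME": "CYS",
    "KCX": "LYS",
    "MLY": "LYS",
    "M3L": "LYS",
    "FME": "MET",
}

STANDARD_CODES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class Atom:
    """A single atom: name (e.g. ``"CA"``), Cartesian coordinates in Å, element."""

    name: str
    coords: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ContractError(f"atom {self.name!r}: coords must be a finite 3-vector")


@dataclass
class Residue:
    """One amino-acid residue with its backbone atoms.

    ``index`` is the 1-based ordinal position in the chain as read from the
    file; ``resseq`` keeps the author residue number.  ``sidechain_atom_count``
    counts heavy atoms observed beyond N, Cα, C, O (and OXT).
    """

    index: int
    code3: str
    backbone: dict[str, Atom]
    sidechain_atom_count: int = 0
    resseq: int = 0
    icode: str = " "

    @property
    def is_standard(self) -> bool:
        return self.code3 in STANDARD_CODES

    @property
    def standard_code(self) -> str | None:
        """Three-letter code after nonstandard→parent mapping, or None."""
        if self.code3 in STANDARD_CODES:
            return self.code3
        return NONSTANDARD_PARENT.get(self.code3)

    def has_complete_backbone(self) -> bool:
        return all(name in self.backbone for name in BACKBONE_NAMES)

    def atom_coords(self, name: str) -> np.ndarray:
        return self.backbone[name].coords


@dataclass
class ValidationReport:
    dropped_indices: list[int] = field(default_factory=list)
    chain_breaks: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ChainModel:
    """An ordered residue sequence for one model/chain of one structure."""

    pdb_id: str
    model_id: int
    chain_id: str
    residues: list[Residue]
    validation: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coordinates(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        return np.array([r.atom_coords("CA") for r in self.residues])


@dataclass
class ProteinStructure:
    """All models/chains of one parsed PDB entry, in file order."""

    pdb_id: str
    models: dict[int, dict[str, ChainModel]]  # model serial -> chain id -> chain

    @property
    def model_ids(self) -> list[int]:
        return list(self.models)

    def chain_ids(self, model_id: int) -> list[str]:
        return list(self.models[model_id])


def _as_handle(source: str | Path) -> tuple[io.TextIOBase, str]:
    """Return a text handle and an id string for a path or raw PDB text."""
    if isinstance(source, Path):
        if not source.is_file():
            raise InputError(f"no such file: {source}")
        return open(source), source.stem
    if not isinstance(source, str):
        raise InputError(f"unsupported PDB source type: {type(source)!r}")
    if "\n" in source:
        return io.StringIO(source), "inline"
    if os.path.isfile(source):
        return open(source), Path(source).stem
    raise InputError(f"no such file: {source}")


def parse_pdb(source: str | Path, pdb_id: str | None = None) -> ProteinStructure:
    """Parse a PDB file path or raw PDB text into a :class:`ProteinStructure`.

    Every model and chain is returned, residues in file order.  HETATM
    records are ignored; disordered atoms keep the highest-occupancy
    alternate location (ties: first seen).
    """
    handle, inferred_id = _as_handle(source)
    parser = PDBParser(QUIET=True)
    try:
        with handle:
            bio_structure = parser.get_structure(pdb_id or inferred_id, handle)
    except InputError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise InputError(f"cannot parse PDB source: {exc}") from exc

    models: dict[int, dict[str, ChainModel]] = {}
    n_residues_total = 0
    for position, bio_model in enumerate(bio_structure, start=1):
        serial = bio_model.serial_num if bio_model.serial_num else position
        chains: dict[str, ChainModel] = {}
        for bio_chain in bio_model:
            residues: list[Residue] = []
            for bio_res in bio_chain:
                hetflag, resseq, icode = bio_res.id
                if hetflag != " ":
                    continue  # HETATM (waters, ligands, modified-residue HET entries)
                backbone: dict[str, Atom] = {}
                sidechain = 0
                for bio_atom in bio_res:
                    # DisorderedAtom resolves to highest-occupancy child here
                    name = bio_atom.get_name()
                    element = (bio_atom.element or "").strip()
                    if element in ("H", "D"):
                        continue
                    if name in BACKBONE_NAMES:
                        backbone[name] = Atom(name, np.array(bio_atom.get_coord(), dtype=float), element)
                    elif name not in ("O", "OXT"):
                        sidechain += 1
                residues.append(
                    Residue(
                        index=len(residues) + 1,
                        code3=bio_res.get_resname().strip(),
                        backbone=backbone,
                        sidechain_atom_count=sidechain,
                        resseq=resseq,
                        icode=icode,
                    )
                )
            if residues:
                n_residues_total += len(residues)
                chains[bio_chain.id] = ChainModel(
                    pdb_id=bio_structure.id,
                    model_id=serial,
                    chain_id=bio_chain.id,
                    residues=residues,
                )
        if chains:
            models[serial] = chains

    if n_residues_total == 0:
        raise EmptyStructureError(f"{bio_structure.id}: no ATOM records")
    return ProteinStructure(pdb_id=bio_structure.id, models=models)


def select_chain(
    structure: ProteinStructure, model_id: int | None = None, chain_id: str | None = None
) -> ChainModel:
    """Pick one model and chain; defaults to the first of each.

    Raises :class:`SelectionError` naming the available ids when the request
    cannot be satisfied.
    """
    if model_id is None:
        model_key = next(iter(structure.models))
    elif model_id in structure.models:
        model_key = model_id
    else:
        # fall back to 1-based ordinal position among models
        ids = structure.model_ids
        if 1 <= model_id <= len(ids):
            model_key = ids[model_id - 1]
        else:
            raise SelectionError(
                f"{structure.pdb_id}: model {model_id} not found; available models: {ids}"
            )
    chains = structure.models[model_key]
    if chain_id is None:
        return next(iter(chains.values()))
    if chain_id not in chains:
        raise SelectionError(
            f"{structure.pdb_id}: chain {chain_id!r} not found in model {model_key}; "
            f"available chains: {list(chains)}"
        )
    return chains[chain_id]


def validate_chain(chain: ChainModel) -> ChainModel:
    """Drop residues missing any of N, Cα, C and log chain breaks.

    The returned chain keeps the surviving residues (original ``index``
    values preserved) and carries a :class:`ValidationReport`.  Idempotent.
    Raises :class:`DegenerateChainError` if fewer than 2 residues survive.
    """
    report = ValidationReport()
    kept: list[Residue] = []
    for res in chain.residues:
        if res.has_complete_backbone():
            kept.append(res)
        else:
            report.dropped_indices.append(res.index)
    if len(kept) < 2:
        raise DegenerateChainError(
            f"{chain.pdb_id}/{chain.chain_id}: only {len(kept)} residue(s) with a "
            f"complete N,CA,C backbone (need ≥ 2)"
        )
    if report.dropped_indices:
        logger.warning(
            "%s/%s: dropped %d residue(s) with incomplete backbone: %s",
            chain.pdb_id, chain.chain_id, len(report.dropped_indices), report.dropped_indices,
        )
    for a, b in zip(kept[:-1], kept[1:]):
        d = float(np.linalg.norm(a.atom_coords("CA") - b.atom_coords("CA")))
        if d > CHAIN_BREAK_CUTOFF:
            report.chain_breaks.append((a.index, d))
            logger.warning(
                "%s/%s: chain break after residue %d (Cα–Cα %.2f Å); curve kept continuous",
                chain.pdb_id, chain.chain_id, a.index, d,
            )
    return ChainModel(
        pdb_id=chain.pdb_id,
        model_id=chain.model_id,
        chain_id=chain.chain_id,
        residues=kept,
        validation=report,
    )


# ---------------------------------------------------------------------------
# writer (fixed-width wwPDB v3.3 ATOM records) — used by the fixture generator
# and for round-trip tests


def _atom_record(serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    name = atom.name
    # short names start in column 14 (space-padded), 4-char names fill 13-16
    name_field = f" {name:<3s}" if len(name) < 4 else name
    element = atom.element or name[0]
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:5d} {name_field:4s} {res.code3:>3s} {chain_id:1s}"
        f"{res.resseq:4d}{res.icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def chain_to_pdb(chain: ChainModel, include_model: bool = True) -> str:
    """Serialize a chain as standard PDB ATOM records (3-decimal precision)."""
    lines: list[str] = []
    if include_model:
        lines.append(f"MODEL     {chain.model_id:4d}")
    serial = 0
    for res in chain.residues:
        for name in BACKBONE_NAMES:
            if name in res.backbone:
                serial += 1
                lines.append(_atom_record(serial, res.backbone[name], res, chain.chain_id))
    lines.append("TER")
    if include_model:
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def chains_to_pdb(chains: Sequence[ChainModel]) -> str:
    """Serialize several chains as successive MODEL blocks."""
    return "".join(chain_to_pdb(c) for c in chains)
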