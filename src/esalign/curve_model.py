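"""Composite input curves: backbone geometry plus residue-level channels.

A protein chain is turned into a ``(3 + k) × n`` matrix **P** whose first
three rows are Cartesian coordinates derived from the backbone under one of
three criteria:

* ``ESA-BB``    — the N, Cα, C atoms themselves (n = 3 · residues),
* ``ESA-CA``    — Cα atoms only (n = residues),
* ``ESA-MC-BB`` — the unweighted centroid of N, Cα, C per residue.

The remaining *k* rows carry auxiliary information: backbone dihedral
angles (φ, ψ, ω — mandatory for ``ESA-CA`` and ``ESA-MC-BB``) and a
configurable subset of per-residue molecular properties (hydrophobicity,
polarity, residue mass, functional-group class, side-chain heavy-atom
count).  Glycine contributes backbone geometry only: its side-chain atom
count is 0 and no side-chain-derived geometry is used anywhere.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError, PropertyLookupError
from .structure_io import ChainModel, NONSTANDARD_PARENT, STANDARD_CODES, Residue

logger = logging.getLogger(__name__)

CRITERIA = ("ESA-BB", "ESA-CA", "ESA-MC-BB")

#: feature code -> property-table channel, in the declared channel order
FEATURE_CHANNELS = {
    "HP": "hydrophobicity",
    "POL": "polarity",
    "MASS": "mass",
    "GROUP": "group_class",
    "SC-ATOMS": "sidechain_atoms",
}

DIHEDRAL_LABELS = ("phi", "psi", "omega")

# --- default property scales -------------------------------------------------
# Kyte–Doolittle hydropathy index
_HYDROPHOBICITY = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9, "TYR": -1.3,
    "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5, "ASP": -3.5, "ASN": -3.5,
    "LYS": -3.9, "ARG": -4.5,
}
# Grantham (1974) polarity
_POLARITY = {
    "ALA": 8.1, "ARG": 10.5, "ASN": 11.6, "ASP": 13.0, "CYS": 5.5, "GLN": 10.5,
    "GLU": 12.3, "GLY": 9.0, "HIS": 10.4, "ILE": 5.2, "LEU": 4.9, "LYS": 11.3,
    "MET": 5.7, "PHE": 5.2, "PRO": 8.0, "SER": 9.2, "THR": 8.6, "TRP": 5.4,
    "TYR": 6.2, "VAL": 5.9,
}
# monoisotopic residue (amino-acid minus water) masses, Da
_MASS = {
    "GLY": 57.02146, "ALA": 71.03711, "SER": 87.03203, "PRO": 97.05276,
    "VAL": 99.06841, "THR": 101.04768, "CYS": 103.00919, "LEU": 113.08406,
    "ILE": 113.08406, "ASN": 114.04293, "ASP": 115.02694, "GLN": 128.05858,
    "LYS": 128.09496, "GLU": 129.04259, "MET": 131.04049, "HIS": 137.05891,
    "PHE": 147.06841, "ARG": 156.10111, "TYR": 163.06333, "TRP": 186.07931,
}
# functional-group class: 1 aliphatic, 2 acyclic (non-cyclic polar/charged),
# 3 hydroxyl/sulphur-containing, 4 aromatic
_GROUP_CLASS = {
    "ALA": 1, "GLY": 1, "ILE": 1, "LEU": 1, "PRO": 1, "VAL": 1,
    "ARG": 2, "ASN": 2, "ASP": 2, "GLN": 2, "GLU": 2, "LYS": 2,
    "CYS": 3, "MET": 3, "SER": 3, "THR": 3,
    "HIS": 4, "PHE": 4, "TRP": 4, "TYR": 4,
}
# side-chain heavy atoms (beyond N, Cα, C, O); glycine has none
_SIDECHAIN_ATOMS = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "PRO": 3, "VAL": 3,
    "ASP": 4, "ASN": 4, "ILE": 4, "LEU": 4, "MET": 4, "GLU": 5, "GLN": 5,
    "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7, "TYR": 8, "TRP": 10,
}


@dataclass
class PropertyTable:
    """Per-residue molecular property values, one dict per channel.

    ``strict`` controls what happens for a residue code that cannot be
    mapped to a standard amino acid: raise (default) or substitute
    ``neutral_value`` with a log message.
    """

    values: dict[str, dict[str, float]]
    strict: bool = True
    neutral_value: float = 0.0

    @classmethod
    def default(cls, strict: bool = True) -> "PropertyTable":
        values: dict[str, dict[str, float]] = {}
        for code in STANDARD_CODES:
            values[code] = {
                "hydrophobicity": _HYDROPHOBICITY[code],
                "polarity": _POLARITY[code],
                "mass": _MASS[code],
                "group_class": float(_GROUP_CLASS[code]),
                "sidechain_atoms": float(_SIDECHAIN_ATOMS[code]),
            }
        return cls(values=values, strict=strict)

    @classmethod
    def from_files(cls, channel_files: Mapping[str, str | Path], strict: bool = True) -> "PropertyTable":
        """Override default channels from two-column ``code value`` text files."""
        table = cls.default(strict=strict)
        for channel, path in channel_files.items():
            if channel not in next(iter(table.values.values())):
                raise PropertyLookupError(f"unknown property channel {channel!r}")
            for line in Path(path).read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                code, value = line.replace(",", " ").split()[:2]
                table.values.setdefault(code.upper(), {})[channel] = float(value)
        return table

    def lookup(self, code3: str, channel: str) -> float:
        code = code3.upper()
        if code not in self.values:
            code = NONSTANDARD_PARENT.get(code, code)
        entry = self.values.get(code)
        if entry is None or channel not in entry:
            if self.strict:
                raise PropertyLookupError(
                    f"no {channel!r} value for residue {code3!r} (not a standard residue)"
                )
            logger.warning("residue %s: no %s value, using neutral %g", code3, channel, self.neutral_value)
            return self.neutral_value
        return entry[channel]


def residue_properties(
    code3: str,
    table: PropertyTable | None = None,
    feature_set: Sequence[str] = ("HP",),
) -> np.ndarray:
    """Selected property values for one residue, in declared feature order."""
    table = table or PropertyTable.default()
    unknown = [f for f in feature_set if f not in FEATURE_CHANNELS]
    if unknown:
        raise PropertyLookupError(f"unknown feature code(s) {unknown}; valid: {list(FEATURE_CHANNELS)}")
    return np.array([table.lookup(code3, FEATURE_CHANNELS[f]) for f in feature_set], dtype=float)


# --- dihedral angles ---------------------------------------------------------

#: sentinel for an undefined torsion angle
UNDEFINED = float("nan")


@dataclass(frozen=True)
class DihedralTriple:
    """Backbone torsions of one residue in radians; NaN marks undefined."""

    phi: float
    psi: float
    omega: float

    def as_array(self) -> np.ndarray:
        return np.array([self.phi, self.psi, self.omega])


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion of the p0–p1–p2–p3 quadruple (IUPAC convention).

    Returns NaN for collinear or zero-length configurations.
    """
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return UNDEFINED
    m1 = np.cross(n1, b1 / nb1)
    # sign flipped so the convention matches the field standard (the value
    # reported for an α-helix φ is ≈ −60°), as implemented e.g. in Bio.PDB
    angle = -float(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    # exactly-planar trans configurations sit on the ±π branch cut, where
    # rounding noise flips the sign; snap them to +π for a stable value
    if math.pi - abs(angle) < 1e-9:
        return math.pi
    return angle


def compute_dihedrals(chain: ChainModel) -> list[DihedralTriple]:
    """φ, ψ, ω per residue of a validated chain.

    φ(i) = torsion(C(i−1), N(i), Cα(i), C(i)) — undefined for the first residue;
    ψ(i) = torsion(N(i), Cα(i), C(i), N(i+1)) and
    ω(i) = torsion(Cα(i), C(i), N(i+1), Cα(i+1)) — undefined for the last.
    Degenerate (collinear) quadruples yield NaN with a log message.
    """
    res = chain.residues
    out: list[DihedralTriple] = []
    n_degenerate = 0
    for i, r in enumerate(res):
        phi = psi = omega = UNDEFINED
        if i > 0:
            phi = dihedral_angle(
                res[i - 1].atom_coords("C"), r.atom_coords("N"),
                r.atom_coords("CA"), r.atom_coords("C"),
            )
        if i < len(res) - 1:
            nxt = res[i + 1]
            psi = dihedral_angle(
                r.atom_coords("N"), r.atom_coords("CA"),
                r.atom_coords("C"), nxt.atom_coords("N"),
            )
            omega = dihedral_angle(
                r.atom_coords("CA"), r.atom_coords("C"),
                nxt.atom_coords("N"), nxt.atom_coords("CA"),
            )
        interior_undefined = (
            (i > 0 and math.isnan(phi))
            or (i < len(res) - 1 and (math.isnan(psi) or math.isnan(omega)))
        )
        if interior_undefined:
            n_degenerate += 1
        out.append(DihedralTriple(phi, psi, omega))
    if n_degenerate:
        logger.info(
            "%s/%s: %d residue(s) with degenerate (collinear) torsion quadruples",
            chain.pdb_id, chain.chain_id, n_degenerate,
        )
    return out


# --- geometry and curve assembly --------------------------------------------


def geometric_coordinates(chain: ChainModel, criterion: str) -> np.ndarray:
    """3 × n spatial coordinate matrix for a validated chain.

    ``ESA-BB`` interleaves N, Cα, C per residue (n = 3·m); ``ESA-CA`` keeps
    Cα only; ``ESA-MC-BB`` uses the N/Cα/C centroid.
    """
    if criterion not in CRITERIA:
        raise ContractError(f"unknown criterion {criterion!r}; valid: {CRITERIA}")
    if criterion == "ESA-BB":
        cols = [r.atom_coords(name) for r in chain.residues for name in ("N", "CA", "C")]
    elif criterion == "ESA-CA":
        cols = [r.atom_coords("CA") for r in chain.residues]
    else:  # ESA-MC-BB
        cols = [
            (r.atom_coords("N") + r.atom_coords("CA") + r.atom_coords("C")) / 3.0
            for r in chain.residues
        ]
    return np.array(cols, dtype=float).T


@dataclass
class ScalingConfig:
    """How auxiliary rows are balanced against Å-scale geometry.

    ``mode="standardize"`` rescales each property row to mean 0, sd 1
    (constant rows become zero); ``mode="none"`` keeps raw values.
    Dihedral rows are kept in raw radians in both modes.  Every auxiliary
    row is finally multiplied by its per-channel weight (default 1.0).
    """

    mode: str = "standardize"
    weights: dict[str, float] = field(default_factory=dict)

    def weight(self, label: str) -> float:
        w = self.weights.get(label, 1.0)
        if w < 0:
            raise ContractError(f"channel weight for {label!r} must be ≥ 0")
        return w


@dataclass
class CompositeCurve:
    """The (3 + k) × n composite input matrix **P** for one structure."""

    values: np.ndarray
    row_labels: list[str]
    criterion: str
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_labels):
            raise ContractError("curve matrix and row labels disagree")
        if self.values.shape[0] != 3 + self.k:
            raise ContractError(f"expected {3 + self.k} rows, got {self.values.shape[0]}")
        if self.values.shape[1] < 2:
            raise ContractError("a curve needs at least 2 columns")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("curve contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def spatial(self) -> np.ndarray:
        return self.values[:3]


def build_curve(
    chain: ChainModel,
    criterion: str = "ESA-CA",
    feature_set: Sequence[str] = (),
    table: PropertyTable | None = None,
    scaling: ScalingConfig | None = None,
    include_dihedrals: bool | None = None,
) -> CompositeCurve:
    """Assemble the composite curve for a validated chain.

    Rows are stacked as geometry (3), dihedrals (φ, ψ, ω; mandatory for
    ``ESA-CA``/``ESA-MC-BB``, opt-in for ``ESA-BB``), then the requested
    property channels.  Undefined dihedrals become 0 after logging.  For
    ``ESA-BB`` each residue's auxiliary values repeat across its three atom
    columns so the matrix stays rectangular.
    """
    if criterion not in CRITERIA:
        raise ContractError(f"unknown criterion {criterion!r}; valid: {CRITERIA}")
    table = table or PropertyTable.default()
    scaling = scaling or ScalingConfig()
    if include_dihedrals is None:
        include_dihedrals = criterion in ("ESA-CA", "ESA-MC-BB")
    if criterion in ("ESA-CA", "ESA-MC-BB") and not include_dihedrals:
        raise ContractError(f"dihedral rows are mandatory for criterion {criterion}")

    geometry = geometric_coordinates(chain, criterion)
    m = len(chain.residues)
    aux_rows: list[np.ndarray] = []
    labels = ["x", "y", "z"]

    if include_dihedrals:
        tri = np.array([d.as_array() for d in compute_dihedrals(chain)]).T  # 3 × m
        n_undefined = int(np.isnan(tri).sum())
        if n_undefined:
            logger.info("%s/%s: %d undefined dihedral value(s) set to 0",
                        chain.pdb_id, chain.chain_id, n_undefined)
        tri = np.nan_to_num(tri, nan=0.0)
        for label, row in zip(DIHEDRAL_LABELS, tri):
            aux_rows.append(row * scaling.weight(label))
            labels.append(label)

    for feat in feature_set:
        row = np.array(
            [residue_properties(r.code3, table, (feat,))[0] for r in chain.residues]
        )
        if scaling.mode == "standardize":
            sd = row.std()
            row = (row - row.mean()) / sd if sd > 0 else np.zeros_like(row)
        elif scaling.mode != "none":
            raise ContractError(f"unknown scaling mode {scaling.mode!r}")
        aux_rows.append(row * scaling.weight(feat))
        labels.append(feat)

    if aux_rows:
        aux = np.vstack(aux_rows)
        if criterion == "ESA-BB":
            aux = np.repeat(aux, 3, axis=1)
        values = np.vstack([geometry, aux])
    else:
        values = geometry
    return CompositeCurve(values=values, row_labels=labels, criterion=criterion, k=len(aux_rows))
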