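"""Deterministic synthetic protein backbones for testing and benchmarks.

Chains are built from stylized geometry — an ideal α-helix-like spiral
(Cα radius 2.3 Å, rise 1.5 Å, 100°/residue), an extended zigzag strand
(3.5 Å Cα spacing, ±1 Å zigzag) or a persistent random coil — with N and
C atoms placed ±0.75 Å along the local Cα tangent so each residue has
three distinct ordered backbone atoms.  Geometry is stylized rather than
Ramachandran-accurate: the comparison pipeline consumes only coordinates
and residue identities, which these fixtures provide deterministically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .curve_model import _SIDECHAIN_ATOMS
from .errors import ContractError
from .structure_io import Atom, ChainModel, Residue, chain_to_pdb

logger = logging.getLogger(__name__)

FAMILIES = ("helix", "strand", "random-coil")

STANDARD_20 = sorted(_SIDECHAIN_ATOMS)

HELIX_RADIUS = 2.3        # Å
HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = np.deg2rad(100.0)
STRAND_SPACING = 3.5      # Å along the axis
STRAND_ZIGZAG = 1.0       # Å lateral offset
TANGENT_OFFSET = 0.75     # Å from Cα to N and C along the local tangent
NORMAL_OFFSET = 0.35      # Å off-tangent shift so N, Cα, C are not collinear
COIL_STEP = 3.8           # Å Cα–Cα
COIL_PERSISTENCE = 0.6    # direction perturbation scale


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain."""

    n_residues: int = 40
    family: str = "helix"
    sequence: tuple[str, ...] | None = None  # default poly-ALA
    noise_sigma: float = 0.0  # Å, per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ContractError("need at least 2 residues")
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        if self.noise_sigma < 0:
            raise ContractError("noise sigma must be ≥ 0")


def _ca_positions(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    i = np.arange(n)
    if spec.family == "helix":
        return np.column_stack([
            HELIX_RADIUS * np.cos(i * HELIX_TWIST),
            HELIX_RADIUS * np.sin(i * HELIX_TWIST),
            HELIX_RISE * i,
        ])
    if spec.family == "strand":
        return np.column_stack([
            STRAND_SPACING * i,
            STRAND_ZIGZAG * np.where(i % 2 == 0, 1.0, -1.0),
            np.zeros(n),
        ])
    # random coil: persistent random walk
    points = np.zeros((n, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for step in range(1, n):
        points[step] = points[step - 1] + COIL_STEP * direction
        direction = direction + COIL_PERSISTENCE * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
    return points


def _tangents(ca: np.ndarray) -> np.ndarray:
    t = np.gradient(ca, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _normals(tangent: np.ndarray) -> np.ndarray:
    """Unit vectors perpendicular to each tangent (deterministic choice).

    Gram–Schmidt of a fixed reference axis against the tangent; the
    reference flips from z to x where the tangent is nearly axial.
    """
    ref = np.tile([0.0, 0.0, 1.0], (tangent.shape[0], 1))
    ref[np.abs(tangent[:, 2]) > 0.9] = [1.0, 0.0, 0.0]
    n = ref - (np.einsum("ij,ij->i", ref, tangent))[:, None] * tangent
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def make_chain(spec: FixtureSpec, pdb_id: str | None = None) -> ChainModel:
    """Generate a deterministic synthetic chain from its spec."""
    rng = np.random.default_rng(spec.seed)
    sequence = list(spec.sequence) if spec.sequence else ["ALA"] * spec.n_residues
    if len(sequence) != spec.n_residues:
        raise ContractError("sequence length must equal n_residues")
    ca = _ca_positions(spec, rng)
    tangent = _tangents(ca)
    # N and C sit ±0.75 Å along the tangent plus a fixed off-tangent shift:
    # exactly collinear N, Cα, C would make every backbone torsion degenerate
    offset = NORMAL_OFFSET * _normals(tangent)
    coords = np.stack([
        ca - TANGENT_OFFSET * tangent + offset,  # N
        ca,                                      # CA
        ca + TANGENT_OFFSET * tangent + offset,  # C
    ], axis=1)  # (n, 3 atoms, 3)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    residues = []
    for idx, code in enumerate(sequence):
        backbone = {
            name: Atom(name, coords[idx, a], element=name[0])
            for a, name in enumerate(("N", "CA", "C"))
        }
        residues.append(
            Residue(
                index=idx + 1,
                code3=code,
                backbone=backbone,
                sidechain_atom_count=_SIDECHAIN_ATOMS.get(code, 0),
                resseq=idx + 1,
            )
        )
    return ChainModel(
        pdb_id=pdb_id or f"{spec.family[:4]}{spec.seed}",
        model_id=1,
        chain_id="A",
        residues=residues,
    )


def rigid_motion(chain: ChainModel, rotation: np.ndarray, translation: np.ndarray) -> ChainModel:
    """Apply x ↦ Rx + t to every atom; residue identities unchanged."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R.T @ R, np.eye(3), atol=1e-8) \
            or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ContractError("rotation must be orthogonal with det +1")
    residues = []
    for res in chain.residues:
        backbone = {
            name: Atom(atom.name, R @ atom.coords + t, atom.element)
            for name, atom in res.backbone.items()
        }
        residues.append(replace(res, backbone=backbone))
    return ChainModel(chain.pdb_id, chain.model_id, chain.chain_id, residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_sequence(n: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Uniform random sequence over the 20 standard residues."""
    return tuple(rng.choice(STANDARD_20, size=n))


def make_dataset(
    n_classes: int,
    per_class: int,
    base_specs: Sequence[FixtureSpec] | None = None,
    seed: int = 0,
    noise_sigma: float | None = None,
    out_dir: str | Path | None = None,
    random_sequences: bool = False,
) -> tuple[list[ChainModel], list[tuple[str, str]]]:
    """Noisy per-family variants emulating a labelled benchmark set.

    Returns the chains and an (id, class-label) table; if ``out_dir`` is
    given, one PDB file per chain plus a ``labels.tsv`` are written.
    Byte-identical output for a fixed seed.
    """
    if base_specs is None:
        base_specs = [FixtureSpec(family=f) for f in FAMILIES[:n_classes]]
    if len(base_specs) != n_classes:
        raise ContractError("base_specs length must equal n_classes")
    chains: list[ChainModel] = []
    labels: list[tuple[str, str]] = []
    for c, base in enumerate(base_specs):
        for i in range(per_class):
            derived_seed = int((seed * 1000003 + c * 1009 + i) % (2**31 - 1))
            spec = replace(
                base,
                seed=derived_seed,
                noise_sigma=base.noise_sigma if noise_sigma is None else noise_sigma,
            )
            if random_sequences:
                seq_rng = np.random.default_rng(derived_seed + 7)
                spec = replace(spec, sequence=random_sequence(spec.n_residues, seq_rng))
            chain_id = f"{base.family}_{c}_{i}"
            chains.append(make_chain(spec, pdb_id=chain_id))
            labels.append((chain_id, base.family))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for chain in chains:
            (out / f"{chain.pdb_id}.pdb").write_text(chain_to_pdb(chain))
        (out / "labels.tsv").write_text(
            "".join(f"{name}\t{label}\n" for name, label in labels)
        )
    return chains, labels
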