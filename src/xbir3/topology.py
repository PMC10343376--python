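"""Atomistic containers: atoms, complexes, trajectories, and selections.

A :class:`ComplexTopology` holds the physical system — receptor plus bound
ligand — with per-atom partial charges, Lennard-Jones parameters, and the
dielectric-boundary radii used by the Poisson–Boltzmann solver.  Residue
numbering is always kept verbatim from the input (XIAP-BIR3 constructs use
author numbering 248–352); no internal renumbering ever occurs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Residue names assigned to the receptor segment by default: the 20
#: standard amino acids plus the CHARMM protonation/deprotonation variants
#: used for XIAP-BIR3 (HSD/HSE histidines, CYM zinc-coordinating cysteine).
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "CYM",
}

#: Atom names forming the peptide backbone.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

HBOND_ROLES = ("donor_heavy", "acceptor", "polar_h", "none")
SEGMENTS = ("receptor", "ligand")


@dataclass
class AtomRecord:
    """One atom with coordinates and force-field/PB parameters.

    ``charge`` is in elementary charges, ``lj_epsilon`` (well depth) in
    kcal/mol, ``lj_rmin_half`` (half the pair distance at the LJ minimum)
    and ``pb_radius`` in Å, ``mass`` in amu.
    """

    atom_index: int
    atom_name: str
    residue_name: str
    residue_id: int
    segment: str = "receptor"
    group_id: str | None = None
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    charge: float = math.nan
    lj_epsilon: float = math.nan
    lj_rmin_half: float = math.nan
    pb_radius: float = math.nan
    mass: float = math.nan
    is_hydrogen: bool = False
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        if self.atom_index < 1:
            raise ValueError(f"atom_index must be >= 1, got {self.atom_index}")
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        if self.hbond_role not in HBOND_ROLES:
            raise ValueError(f"hbond_role must be one of {HBOND_ROLES}")
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)

    @property
    def parameterized(self) -> bool:
        vals = (self.charge, self.lj_epsilon, self.lj_rmin_half, self.pb_radius, self.mass)
        return all(math.isfinite(v) for v in vals)

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


class ComplexTopology:
    """Ordered atom collection with residue index and provenance tag.

    ``provenance`` is free text describing where the coordinates/ensemble
    came from (e.g. the force-field parametrization tag of an MD run such
    as "HMR" or "WYF", or "synthetic").
    """

    def __init__(self, atoms: Sequence[AtomRecord], provenance: str = "synthetic"):
        self.atoms: list[AtomRecord] = list(atoms)
        self.provenance = provenance
        seen: set[int] = set()
        for a in self.atoms:
            if a.atom_index in seen:
                raise ValueError(f"duplicate atom_index {a.atom_index}")
            seen.add(a.atom_index)
        self.residue_index: dict[int, list[int]] = {}
        for pos, a in enumerate(self.atoms):
            self.residue_index.setdefault(a.residue_id, []).append(pos)

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, topology order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, frame: np.ndarray) -> None:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (self.n_atoms, 3):
            raise ValueError(f"frame shape {frame.shape} != ({self.n_atoms}, 3)")
        for a, xyz in zip(self.atoms, frame):
            a.coords = xyz.copy()

    def segment_positions(self, segment: str) -> list[int]:
        if segment not in SEGMENTS:
            raise ValueError(f"unknown segment {segment!r}")
        return [i for i, a in enumerate(self.atoms) if a.segment == segment]

    def require_complex(self) -> None:
        """Raise unless both a receptor and a ligand segment are present."""
        have = {a.segment for a in self.atoms}
        if have != set(SEGMENTS):
            missing = set(SEGMENTS) - have
            raise ValueError(f"topology is not a complex: missing segment(s) {sorted(missing)}")

    def require_parameterized(self) -> None:
        bad = [a.atom_index for a in self.atoms if not a.parameterized]
        if bad:
            raise ValueError(f"unparameterized atoms (indices): {bad[:10]}"
                             + ("..." if len(bad) > 10 else ""))

    def net_charge(self, segment: str | None = None) -> float:
        atoms = self.atoms if segment is None else [self.atoms[i] for i in self.segment_positions(segment)]
        return float(sum(a.charge for a in atoms))

    def subset(self, positions: Iterable[int]) -> "ComplexTopology":
        """New topology with the given atom positions (order preserved)."""
        return ComplexTopology([self.atoms[i].copy() for i in positions], provenance=self.provenance)

    def copy(self) -> "ComplexTopology":
        return ComplexTopology([a.copy() for a in self.atoms], provenance=self.provenance)


@dataclass
class SelectionSpec:
    """Declarative atom selection: segment, residue ranges, atom-name class.

    ``residue_ranges`` are inclusive (lo, hi) pairs in the topology's own
    (verbatim) numbering; ``atom_names`` restricts to a name class such as
    the backbone; hydrogens are excluded unless ``include_hydrogens``.
    """

    segment: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] = ()
    include_hydrogens: bool = False

    def resolve(self, top: ComplexTopology) -> list[int]:
        """Deterministic, index-ordered atom positions; raises if empty."""
        out: list[int] = []
        for pos, a in enumerate(top.atoms):
            if self.segment is not None and a.segment != self.segment:
                continue
            if self.residue_ranges and not any(lo <= a.residue_id <= hi for lo, hi in self.residue_ranges):
                continue
            if self.atom_names and a.atom_name not in self.atom_names:
                continue
            if a.is_hydrogen and not self.include_hydrogens:
                continue
            out.append(pos)
        if not out:
            raise ValueError(f"selection resolved to an empty atom set: {self}")
        return out


def backbone_selection(lo: int, hi: int) -> SelectionSpec:
    """Backbone (N, CA, C, O) of receptor residues lo..hi inclusive."""
    return SelectionSpec(segment="receptor", residue_ranges=((lo, hi),), atom_names=BACKBONE_ATOMS)


#: Named selections for the XIAP-BIR3 construct (residues 248–352): the
#: flexible termini are excluded from core alignment.
XIAP_CORE = backbone_selection(259, 335)
XIAP_N_TERM = SelectionSpec(segment="receptor", residue_ranges=((248, 258),))
XIAP_C_TERM = SelectionSpec(segment="receptor", residue_ranges=((336, 352),))


def split_complex(top: ComplexTopology, frame: np.ndarray | None = None):
    """Partition a complex into (receptor, ligand) sub-topologies.

    This implements the single-trajectory convention: free-species
    coordinates are obtained from the complex snapshot by deleting the
    other segment's atoms, so receptor ∪ ligand reproduces the complex
    exactly (atom count, order and coordinates conserved).

    Returns ``(receptor_top, ligand_top, receptor_positions, ligand_positions)``.
    """
    top.require_complex()
    work = top if frame is None else None
    if frame is not None:
        work = top.copy()
        work.set_coords(frame)
    rec_pos = work.segment_positions("receptor")
    lig_pos = work.segment_positions("ligand")
    return work.subset(rec_pos), work.subset(lig_pos), rec_pos, lig_pos


class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    Stands in for an MD production ensemble (frames saved on a fixed
    ``frame_interval`` in ps at a given ``temperature``).
    """

    def __init__(self, topology: ComplexTopology, frames: Sequence[np.ndarray],
                 frame_interval: float = 20.0, temperature: float = 303.15):
        if frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        if len(frames) == 0:
            raise ValueError("trajectory must have at least one frame")
        self.topology = topology
        self.frames: list[np.ndarray] = []
        for k, f in enumerate(frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (topology.n_atoms, 3):
                raise ValueError(f"frame {k} shape {f.shape} != ({topology.n_atoms}, 3)")
            self.frames.append(f)
        self.frame_interval = float(frame_interval)
        self.temperature = float(temperature)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)
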