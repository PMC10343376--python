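"""Structural ensemble analyses: superposition/RMSD, H-bonds, contact maps.

Binding-site stability is judged on the backbone RMSD of the protein core
(XIAP-BIR3 residues 259–335, i.e. excluding the flexible 248–258 and
336–352 termini) after least-squares superposition; ligand RMSD uses that
same core alignment, with a mean above 2 Å flagged as unstable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import (ComplexTopology, SelectionSpec, Trajectory,
                       backbone_selection)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition (Kabsch) and its residual RMSD."""

    rotation: np.ndarray     # (3,3), orthonormal, det=+1
    translation: np.ndarray  # Å; maps mobile → reference
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(ref_coords: np.ndarray, mobile_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mobile onto reference."""
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match (n,3): {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 points for superposition")
    rc = ref.mean(axis=0)
    mc = mob.mean(axis=0)
    p = mob - mc
    q = ref - rc
    if ref.shape[0] == 2:
        # two points: align the segment direction through the centroids
        from .pharmacophore import _rotation_between
        rot = _rotation_between(p[1] - p[0], q[1] - q[0])
        trans = rc - rot @ mc
        moved = mob @ rot.T + trans
        rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
        return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)
    if np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _resolve_core(top: ComplexTopology, core_selection: SelectionSpec | None) -> list[int]:
    sel = core_selection or backbone_selection(259, 335)
    try:
        return sel.resolve(top)
    except ValueError as exc:
        raise ValueError(f"core selection failed: {exc}") from exc


def core_rmsd_series(traj: Trajectory, core_selection: SelectionSpec | None = None,
                     reference: np.ndarray | None = None) -> np.ndarray:
    """Backbone RMSD of the protein core per frame, after core alignment.

    The reference is frame 0 unless an explicit reference coordinate set
    (full topology shape) is supplied.
    """
    pos = _resolve_core(traj.topology, core_selection)
    ref = (traj.frames[0] if reference is None else np.asarray(reference, float))[pos]
    return np.array([kabsch_superpose(ref, frame[pos]).rmsd for frame in traj.frames])


def ligand_rmsd_series(traj: Trajectory, core_selection: SelectionSpec | None = None,
                       reference: np.ndarray | None = None,
                       unstable_threshold: float = 2.0):
    """Ligand heavy-atom RMSD per frame after protein-core alignment.

    The superposition is computed on the core backbone only and then
    applied to the ligand.  Returns ``(rmsd_array, unstable)`` where
    ``unstable`` flags a mean RMSD above the threshold (default 2 Å, the
    customary ligand-stability reading).
    """
    top = traj.topology
    core = _resolve_core(top, core_selection)
    lig = [i for i in top.segment_positions("ligand") if not top.atoms[i].is_hydrogen]
    if not lig:
        raise ValueError("no ligand heavy atoms")
    ref_full = traj.frames[0] if reference is None else np.asarray(reference, float)
    out = []
    for frame in traj.frames:
        sup = kabsch_superpose(ref_full[core], frame[core])
        moved = sup.apply(frame[lig])
        out.append(float(np.sqrt(np.mean(np.sum((moved - ref_full[lig]) ** 2, axis=1)))))
    arr = np.array(out)
    return arr, bool(arr.mean() > unstable_threshold)


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    ``donor`` and ``acceptor`` are atom_index values (topology numbering);
    ``hydrogen`` is optional — the D–H···A angle test applies only when it
    is given.  Defaults: donor–acceptor ≤ 3.5 Å, angle ≥ 120°.
    """

    donor: int
    acceptor: int
    hydrogen: int | None = None
    max_distance: float = 3.5
    min_angle: float = 120.0

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if not 0.0 <= self.min_angle <= 180.0:
            raise ValueError("min_angle must be in [0, 180]")


def _atom_position(top: ComplexTopology, atom_index: int) -> int:
    for pos, a in enumerate(top.atoms):
        if a.atom_index == atom_index:
            return pos
    raise ValueError(f"atom_index {atom_index} not found in topology")


def hbond_satisfied(frame: np.ndarray, d_pos: int, a_pos: int,
                    h_pos: int | None, crit: HBondCriterion) -> bool:
    d = float(np.linalg.norm(frame[d_pos] - frame[a_pos]))
    if d > crit.max_distance:
        return False
    if h_pos is not None:
        u = frame[d_pos] - frame[h_pos]
        v = frame[a_pos] - frame[h_pos]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
        if angle < crit.min_angle:
            return False
    return True


def hbond_occupancy(traj: Trajectory, criterion: HBondCriterion) -> float:
    """Fraction of frames in which the H-bond criterion is satisfied."""
    top = traj.topology
    d_pos = _atom_position(top, criterion.donor)
    a_pos = _atom_position(top, criterion.acceptor)
    h_pos = _atom_position(top, criterion.hydrogen) if criterion.hydrogen is not None else None
    hits = sum(hbond_satisfied(f, d_pos, a_pos, h_pos, criterion) for f in traj.frames)
    return hits / traj.n_frames


@dataclass
class ContactMap:
    """Residue × ligand-atom contact frequencies over an ensemble."""

    frequencies: np.ndarray        # (n_residues, n_ligand_atoms), values in [0,1]
    residue_ids: list[int]
    ligand_atom_indices: list[int]
    cutoff: float


def contact_map(traj: Trajectory, cutoff: float = 4.0) -> ContactMap:
    """Fraction of frames with any residue heavy atom within ``cutoff`` of
    each ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    top = traj.topology
    top.require_complex()
    rec = [i for i in top.segment_positions("receptor") if not top.atoms[i].is_hydrogen]
    lig = [i for i in top.segment_positions("ligand") if not top.atoms[i].is_hydrogen]
    residues = sorted({top.atoms[i].residue_id for i in rec})
    res_rows = {r: k for k, r in enumerate(residues)}
    counts = np.zeros((len(residues), len(lig)))
    for frame in traj.frames:
        d = np.linalg.norm(frame[rec][:, None, :] - frame[lig][None, :, :], axis=-1)
        close = d < cutoff
        per_res = np.zeros((len(residues), len(lig)), dtype=bool)
        for ri, i in enumerate(rec):
            per_res[res_rows[top.atoms[i].residue_id]] |= close[ri]
        counts += per_res
    return ContactMap(frequencies=counts / traj.n_frames, residue_ids=residues,
                      ligand_atom_indices=[top.atoms[i].atom_index for i in lig],
                      cutoff=cutoff)
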