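"""MM-PBSA assembly: per-frame energies, ensemble estimates, decomposition.

The binding free energy of each ensemble snapshot is

    ΔG = E_inte + ΔG_polar + ΔG_nonpolar − TΔS

under the single-trajectory convention: receptor and ligand conformations
are taken from the complex frame by deleting the other segment's atoms, so
each species' internal MM energy cancels and only the inter-segment
interaction energy E_inte survives.  The ensemble estimate is reported as
mean ± population standard deviation over frames; the entropy term (if
any) is a single ensemble-level number added to the mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import (EnergyComponents, SolvationBindingTerms,
                         interaction_energy, solvation_binding_terms)
from .topology import ComplexTopology, Trajectory


@dataclass
class FrameEnergies:
    """Energy terms of one snapshot (all kcal/mol)."""

    frame_index: int
    e_inte: EnergyComponents
    g_polar: float
    g_nonpolar: float

    @property
    def total(self) -> float:
        return self.e_inte.e_inte + self.g_polar + self.g_nonpolar


@dataclass
class BindingEstimate:
    """Ensemble MM-PBSA estimate: mean ΔG ± sd plus component means.

    ``sd`` is the population standard deviation (divide by n) of the
    per-frame totals, matching the ± convention of MM-PBSA tables;
    ``entropy_term`` is −TΔS (kcal/mol) with its method tag.
    """

    mean_dg: float
    sd: float
    mean_elec: float
    mean_vdw: float
    mean_polar: float
    mean_nonpolar: float
    entropy_term: float = 0.0
    entropy_method: str = "none"
    n_frames: int = 0
    sd_convention: str = "population"

    def components(self) -> dict[str, float]:
        return {"elec": self.mean_elec, "vdw": self.mean_vdw,
                "polar": self.mean_polar, "nonpolar": self.mean_nonpolar,
                "entropy": self.entropy_term}


def frame_energy_series(traj: Trajectory, stride: int = 1, pb_spec=None,
                        n_sphere_points: int = 240) -> list[FrameEnergies]:
    """E_inte + solvation terms for every ``stride``-th frame (0-based)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    top.require_complex()
    top.require_parameterized()
    out: list[FrameEnergies] = []
    for k in range(0, traj.n_frames, stride):
        frame = traj.frames[k]
        mm = interaction_energy(top, frame)
        solv = solvation_binding_terms(top, frame, pb_spec=pb_spec,
                                       n_sphere_points=n_sphere_points)
        out.append(FrameEnergies(frame_index=k, e_inte=mm,
                                 g_polar=solv.dg_polar, g_nonpolar=solv.dg_nonpolar))
    if not out:
        raise ValueError("no frames selected")
    return out


def estimate_binding(series: list[FrameEnergies], entropy=None) -> BindingEstimate:
    """Combine per-frame energies (and an optional entropy term) into ΔG.

    ``entropy`` is an :class:`xbir3.entropy.EntropyEstimate` or None.
    """
    if not series:
        raise ValueError("empty frame-energy series")
    totals = np.array([f.total for f in series])
    ent_term = 0.0
    ent_method = "none"
    if entropy is not None:
        ent_term = float(entropy.minus_t_ds)
        ent_method = entropy.method
    return BindingEstimate(
        mean_dg=float(totals.mean() + ent_term),
        sd=float(totals.std()),  # population (ddof=0)
        mean_elec=float(np.mean([f.e_inte.elec for f in series])),
        mean_vdw=float(np.mean([f.e_inte.vdw for f in series])),
        mean_polar=float(np.mean([f.g_polar for f in series])),
        mean_nonpolar=float(np.mean([f.g_nonpolar for f in series])),
        entropy_term=ent_term, entropy_method=ent_method,
        n_frames=len(series))


def _pair_matrices(top: ComplexTopology, frame: np.ndarray):
    """Per-pair Coulomb and LJ energy matrices, receptor × ligand."""
    from .constants import COULOMB_CONSTANT
    rec = top.segment_positions("receptor")
    lig = top.segment_positions("ligand")
    q = np.array([a.charge for a in top.atoms])
    eps = np.array([a.lj_epsilon for a in top.atoms])
    rmh = np.array([a.lj_rmin_half for a in top.atoms])
    d = np.linalg.norm(frame[rec][:, None, :] - frame[lig][None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise ValueError("overlapping receptor/ligand atoms")
    elec = COULOMB_CONSTANT * np.outer(q[rec], q[lig]) / d
    s6 = ((rmh[rec][:, None] + rmh[lig][None, :]) / d) ** 6
    vdw = np.sqrt(np.outer(eps[rec], eps[lig])) * (s6 * s6 - 2.0 * s6)
    return rec, lig, elec, vdw


@dataclass
class DecompositionTable:
    """Per-residue or per-group contributions, kcal/mol, with metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def per_residue_decomposition(traj: Trajectory, stride: int = 1,
                              include_solvation: bool = True, pb_spec=None,
                              n_sphere_points: int = 240) -> DecompositionTable:
    """Mean polar/non-polar binding contribution of each receptor residue.

    Per frame, the interaction energy is attributed exactly: every
    receptor–ligand atom pair's Coulomb (LJ) energy goes to the receptor
    atom's residue.  With ``include_solvation`` the PB reaction-field
    attribution ½·q·Δφ_rf and the per-atom SASA differences ×0.00542 are
    added; ligand-atom solvation attribution is reported on a ``ligand``
    row and the intercept convention on an ``offset`` row, so the polar
    column sums exactly to ΔG_polar and the non-polar column to
    ΔG_nonpolar on every frame.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    top.require_complex()
    top.require_parameterized()
    residues = sorted({top.atoms[i].residue_id for i in top.segment_positions("receptor")})
    rows = [str(r) for r in residues] + (["ligand", "offset"] if include_solvation else [])
    polar_acc: dict[str, list[float]] = {r: [] for r in rows}
    nonpolar_acc: dict[str, list[float]] = {r: [] for r in rows}
    for k in range(0, traj.n_frames, stride):
        frame = traj.frames[k]
        rec, lig, elec, vdw = _pair_matrices(top, frame)
        res_of = np.array([top.atoms[i].residue_id for i in rec])
        pol = {str(r): float(elec[res_of == r].sum()) for r in residues}
        npl = {str(r): float(vdw[res_of == r].sum()) for r in residues}
        if include_solvation:
            solv = solvation_binding_terms(top, frame, pb_spec=pb_spec,
                                           n_sphere_points=n_sphere_points)
            for r in residues:
                pos = [i for i in rec if top.atoms[i].residue_id == r]
                pol[str(r)] += float(solv.per_atom_polar[pos].sum())
                npl[str(r)] += float(solv.per_atom_nonpolar[pos].sum())
            pol["ligand"] = float(solv.per_atom_polar[lig].sum())
            npl["ligand"] = float(solv.per_atom_nonpolar[lig].sum())
            pol["offset"] = 0.0
            npl["offset"] = solv.nonpolar_offset
        for r in rows:
            polar_acc[r].append(pol[r])
            nonpolar_acc[r].append(npl[r])
    data = []
    for r in rows:
        p = np.array(polar_acc[r])
        n = np.array(nonpolar_acc[r])
        tot = p + n
        data.append({"row": r, "polar": p.mean(), "nonpolar": n.mean(),
                     "total": tot.mean(), "sd": tot.std()})
    meta = {"attribution": "pairwise MM + half-charge reaction-field + per-atom SASA"
            if include_solvation else "pairwise MM interaction energy only",
            "sd_convention": "population", "stride": stride}
    return DecompositionTable(pd.DataFrame(data).set_index("row"), meta)


def per_group_decomposition(traj: Trajectory, stride: int = 1,
                            residue_list: list[int] | None = None):
    """Interaction-energy decomposition by ligand group (elec+vdw only).

    Returns ``(DecompositionTable, cross)`` where ``cross`` is the
    group × residue interaction-energy matrix (mean over frames) for the
    caller-supplied residue list (all receptor residues when omitted).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    top.require_complex()
    top.require_parameterized()
    lig_positions = top.segment_positions("ligand")
    untagged = [top.atoms[i].atom_index for i in lig_positions if top.atoms[i].group_id is None]
    if untagged:
        raise ValueError(f"ligand atoms without group_id: {untagged}")
    groups = sorted({top.atoms[i].group_id for i in lig_positions})
    all_residues = sorted({top.atoms[i].residue_id for i in top.segment_positions("receptor")})
    residue_list = residue_list if residue_list is not None else all_residues
    missing = [r for r in residue_list if r not in all_residues]
    if missing:
        raise ValueError(f"residues not in receptor: {missing}")
    acc = {g: [] for g in groups}
    cross_acc = np.zeros((len(groups), len(residue_list)))
    n_used = 0
    for k in range(0, traj.n_frames, stride):
        frame = traj.frames[k]
        rec, lig, elec, vdw = _pair_matrices(top, frame)
        total = elec + vdw
        grp_of = np.array([top.atoms[i].group_id for i in lig])
        res_of = np.array([top.atoms[i].residue_id for i in rec])
        for gi, g in enumerate(groups):
            gmask = grp_of == g
            acc[g].append(float(total[:, gmask].sum()))
            for ri, r in enumerate(residue_list):
                cross_acc[gi, ri] += float(total[res_of == r][:, gmask].sum())
        n_used += 1
    data = []
    for g in groups:
        v = np.array(acc[g])
        data.append({"row": g, "polar": np.nan, "nonpolar": np.nan,
                     "total": v.mean(), "sd": v.std()})
    cross = pd.DataFrame(cross_acc / n_used, index=groups, columns=residue_list)
    meta = {"attribution": "pairwise MM interaction energy only",
            "sd_convention": "population", "stride": stride}
    return DecompositionTable(pd.DataFrame(data).set_index("row"), meta), cross
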