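"""Synthetic study inputs: toy complexes, ensembles, series, libraries.

Every generator is a pure function of its recipe and seed, so planted
ground truth (hydrogen-bond occupancies, library confusion counts, energy
moments) is exactly recoverable by the corresponding analysis operation.
The ensembles emulate the statistical features the analyses consume —
isotropic Gaussian positional fluctuation around a reference structure
and scheduled intermittent hydrogen bonds — not real force-field dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pharmacophore import (DEFAULT_TOLERANCE, ExclusionVolume, Feature,
                            LibraryEntry, PharmacophoreModel, _autolabel)
from .topology import AtomRecord, ComplexTopology, Trajectory

# CHARMM-like backbone parameters: (name, charge, eps, rmin/2, pb_radius, mass,
# hbond_role); charges sum to zero per residue.
_BACKBONE_PARAMS = [
    ("N", -0.30, 0.20, 1.85, 1.55, 14.007, "donor_heavy"),
    ("CA", 0.10, 0.11, 2.00, 1.70, 12.011, "none"),
    ("C", 0.51, 0.11, 2.00, 1.70, 12.011, "none"),
    ("O", -0.31, 0.12, 1.70, 1.52, 15.999, "acceptor"),
]


def default_ligand_spec() -> list[dict]:
    """Two-group toy ligand: a charged donor group and a polar tail.

    Mirrors the chemistry the pipeline cares about: G1 carries a
    protonated donor nitrogen (net +1), G2 a carbonyl-like acceptor.
    """
    return [
        {"group_id": "G1", "atoms": [
            {"name": "N1", "charge": 0.60, "lj_epsilon": 0.20, "lj_rmin_half": 1.85,
             "pb_radius": 1.55, "mass": 14.007, "hbond_role": "donor_heavy",
             "offset": (0.0, 0.0, 0.0)},
            {"name": "C1", "charge": 0.40, "lj_epsilon": 0.11, "lj_rmin_half": 2.0,
             "pb_radius": 1.70, "mass": 12.011, "hbond_role": "none",
             "offset": (1.5, 0.0, 0.0)},
        ]},
        {"group_id": "G2", "atoms": [
            {"name": "C2", "charge": 0.45, "lj_epsilon": 0.11, "lj_rmin_half": 2.0,
             "pb_radius": 1.70, "mass": 12.011, "hbond_role": "none",
             "offset": (3.0, 0.0, 0.0)},
            {"name": "O1", "charge": -0.45, "lj_epsilon": 0.12, "lj_rmin_half": 1.7,
             "pb_radius": 1.52, "mass": 15.999, "hbond_role": "acceptor",
             "offset": (3.0, 1.2, 0.0)},
        ]},
    ]


def make_toy_complex(n_residues: int, ligand_spec: list[dict] | None = None,
                     seed: int = 0, start_residue: int = 1) -> ComplexTopology:
    """Fully parameterized toy receptor–ligand complex.

    The receptor is an arc of ``n_residues`` four-atom backbone residues
    curving around a binding site; ligand atoms (grouped G1…Gk per the
    spec) sit at fixed offsets from the arc centre.  Deterministic for a
    fixed seed; residue numbering starts at ``start_residue``.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    ligand_spec = ligand_spec if ligand_spec is not None else default_ligand_spec()
    if not ligand_spec or not any(g.get("atoms") for g in ligand_spec):
        raise ValueError("ligand_spec must define at least one atom")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    idx = 1
    radius = max(8.0, n_residues * 3.8 / np.pi)
    # per-residue offsets in a local (tangential, inward, z) frame so the
    # backbone carbonyl oxygens line the binding groove
    offsets = [(-1.2, -0.2, 0.4), (0.0, 0.0, 0.0), (1.2, 0.2, 0.0), (1.5, 1.3, 0.2)]
    for r in range(n_residues):
        theta = np.pi * (r + 0.5) / max(n_residues, 1)
        base = np.array([radius * np.cos(theta), radius * np.sin(theta),
                         0.8 * np.sin(3 * theta)])
        inward = -base / np.linalg.norm(base)
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        for (name, q, eps, rmh, rad, mass, role), off in zip(_BACKBONE_PARAMS, offsets):
            coords = (base + off[0] * tangent + off[1] * inward
                      + np.array([0.0, 0.0, off[2]]) + rng.normal(0.0, 0.05, 3))
            atoms.append(AtomRecord(
                atom_index=idx, atom_name=name, residue_name="GLY",
                residue_id=start_residue + r, segment="receptor",
                coords=coords, charge=q, lj_epsilon=eps, lj_rmin_half=rmh,
                pb_radius=rad, mass=mass, is_hydrogen=False, hbond_role=role))
            idx += 1
    lig_resid = start_residue + n_residues + 1
    lig_origin = np.array([0.0, radius - 5.0, 0.0])  # inside the arc, groove-distance
    for g in ligand_spec:
        for spec_atom in g["atoms"]:
            coords = lig_origin + np.asarray(spec_atom.get("offset", (0, 0, 0)), float)
            atoms.append(AtomRecord(
                atom_index=idx, atom_name=spec_atom["name"], residue_name="LIG",
                residue_id=lig_resid, segment="ligand", group_id=g["group_id"],
                coords=coords, charge=spec_atom["charge"],
                lj_epsilon=spec_atom["lj_epsilon"],
                lj_rmin_half=spec_atom["lj_rmin_half"],
                pb_radius=spec_atom["pb_radius"], mass=spec_atom["mass"],
                is_hydrogen=bool(spec_atom.get("is_hydrogen", False)),
                hbond_role=spec_atom.get("hbond_role", "none")))
            idx += 1
    return ComplexTopology(atoms, provenance="synthetic")


@dataclass
class EnsembleRecipe:
    """Recipe for a fluctuating ensemble with plantable H-bond schedules.

    ``hbond_schedules`` lists (donor atom_index, acceptor atom_index,
    target occupancy); the planted occupancy is met exactly (to 1/n_frames)
    by explicit frame assignment, not sampling.
    """

    topology: ComplexTopology
    sigma: float = 0.3            # Å, isotropic per-atom fluctuation
    n_frames: int = 100
    hbond_schedules: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0
    frame_interval: float = 20.0  # ps
    temperature: float = 303.15
    bonded_distance: float = 2.9  # Å, planted donor–acceptor distance when bonded
    unbonded_distance: float = 6.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for d, a, occ in self.hbond_schedules:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} outside [0, 1]")


def make_ensemble(recipe: EnsembleRecipe) -> Trajectory:
    """Gaussian-fluctuation ensemble honouring the planted H-bond schedules.

    In a scheduled "bonded" frame the acceptor atom is placed at the
    planted bonded distance from the (fluctuating) donor; in the other
    frames at the unbonded distance, so a 3.5 Å donor–acceptor criterion
    (and a 4 Å contact criterion) recovers the occupancy exactly.
    """
    top = recipe.topology
    pos_of = {a.atom_index: i for i, a in enumerate(top.atoms)}
    for d, a, _ in recipe.hbond_schedules:
        for atom_index in (d, a):
            if atom_index not in pos_of:
                raise ValueError(f"schedule references unknown atom_index {atom_index}")
    rng = np.random.default_rng(recipe.seed)
    base = top.coords()
    n = recipe.n_frames
    frames = [base + (rng.normal(0.0, recipe.sigma, base.shape) if recipe.sigma > 0
                      else 0.0) for _ in range(n)]
    for d, a, occ in recipe.hbond_schedules:
        k = int(round(occ * n))
        bonded = set(rng.permutation(n)[:k].tolist())
        dp, ap = pos_of[d], pos_of[a]
        for f in range(n):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            dist = recipe.bonded_distance if f in bonded else recipe.unbonded_distance
            frames[f][ap] = frames[f][dp] + dist * u
    return Trajectory(top, frames, frame_interval=recipe.frame_interval,
                      temperature=recipe.temperature)


def make_energy_series(mean: float, sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Seeded i.i.d. Gaussian interaction-energy series, kcal/mol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, float(mean))
    return rng.normal(mean, sigma, n)


def make_born_system(q: float, a: float) -> ComplexTopology:
    """Single-ion system at the origin (closed-form PB oracle)."""
    if a <= 0:
        raise ValueError("Born radius must be > 0")
    atom = AtomRecord(atom_index=1, atom_name="Q", residue_name="ION", residue_id=1,
                      segment="ligand", coords=np.zeros(3), charge=float(q),
                      lj_epsilon=0.1, lj_rmin_half=a, pb_radius=float(a), mass=20.0)
    return ComplexTopology([atom], provenance="synthetic")


def make_reference_pharmacophore(seed: int = 0, kind_counts: dict[str, int] | None = None,
                                 tolerance: float = DEFAULT_TOLERANCE,
                                 n_exclusions: int = 6) -> PharmacophoreModel:
    """Deterministic reference model for library generation.

    Default composition mirrors a merged structure+ensemble model of a
    BIR3 groove binder: 2 HBD, 1 HBA, 4 H, 1 HAr (8 features), with
    exclusion volumes placed well away from all feature spheres.
    """
    kind_counts = kind_counts or {"HBD": 2, "HBA": 1, "H": 4, "HAr": 1}
    rng = np.random.default_rng(seed)
    feats = []
    for kind in ("HBD", "HBA", "H", "HAr"):
        for _ in range(kind_counts.get(kind, 0)):
            feats.append(Feature(kind, tuple(rng.uniform(-6.0, 6.0, 3)),
                                 tolerance=tolerance))
    if not feats:
        raise ValueError("kind_counts produced no features")
    centers = np.array([f.center for f in feats])
    exclusions = []
    attempts = 0
    while len(exclusions) < n_exclusions and attempts < 1000:
        attempts += 1
        c = rng.uniform(-10.0, 10.0, 3)
        if np.min(np.linalg.norm(centers - c, axis=1)) > tolerance + 3.0:
            exclusions.append(ExclusionVolume(tuple(c)))
    return PharmacophoreModel(_autolabel(feats), exclusions, name="reference")


@dataclass
class LibraryRecipe:
    """Recipe for a labeled screening library planted on a reference model.

    Actives reproduce every feature of the reference (jitter below the
    matching tolerance) and carry pIC50 > 6; decoys violate
    ``decoy_violations`` features by construction (the corresponding
    feature points are absent) and carry pIC50 < 4.5.  A fraction
    ``corrupt_active_fraction`` of actives violate exactly one feature —
    they then fail a 0-omission screen but pass a 1-omission screen.
    """

    n_active: int = 173
    n_inactive: int = 5417
    reference: PharmacophoreModel | None = None
    jitter_sigma: float = 0.25          # Å
    decoy_violations: int = 2
    corrupt_active_fraction: float = 0.0
    n_excluded: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("library counts must be >= 0")
        if self.decoy_violations < 1:
            raise ValueError("decoys must violate at least one feature")


def make_screening_library(recipe: LibraryRecipe) -> list[LibraryEntry]:
    """Generate the labeled library; planted confusion counts are exact."""
    model = recipe.reference or make_reference_pharmacophore(recipe.seed)
    tol = min(f.tolerance for f in model.features)
    if recipe.jitter_sigma >= tol:
        raise ValueError(f"jitter σ={recipe.jitter_sigma} must stay below the "
                         f"matching tolerance {tol} to keep the planted truth")
    if recipe.decoy_violations > len(model.features):
        raise ValueError("cannot violate more features than the model has")
    rng = np.random.default_rng(recipe.seed)
    feats = model.features
    entries: list[LibraryEntry] = []
    n_corrupt = int(round(recipe.corrupt_active_fraction * recipe.n_active))
    for i in range(recipe.n_active):
        pts = [(f.kind, np.array(f.center) + rng.normal(0.0, recipe.jitter_sigma, 3))
               for f in feats]
        if i < n_corrupt:                       # violate exactly one feature
            drop = rng.integers(len(pts))
            pts = [p for k, p in enumerate(pts) if k != drop]
        heavy = np.array([c for _, c in pts])
        entries.append(LibraryEntry(id=f"ACT{i:05d}", label="active",
                                    feature_points=pts, heavy_coords=heavy,
                                    pic50=float(rng.uniform(6.0, 9.0)) + 1e-9))
    for i in range(recipe.n_inactive):
        drops = set(rng.choice(len(feats), size=recipe.decoy_violations,
                               replace=False).tolist())
        pts = [(f.kind, np.array(f.center) + rng.normal(0.0, recipe.jitter_sigma, 3))
               for k, f in enumerate(feats) if k not in drops]
        heavy = np.array([c for _, c in pts])
        entries.append(LibraryEntry(id=f"DEC{i:05d}", label="inactive",
                                    feature_points=pts, heavy_coords=heavy,
                                    pic50=float(rng.uniform(3.0, 4.5 - 1e-9))))
    for i in range(recipe.n_excluded):
        pts = [(f.kind, np.array(f.center) + rng.normal(0.0, recipe.jitter_sigma, 3))
               for f in feats]
        heavy = np.array([c for _, c in pts])
        entries.append(LibraryEntry(id=f"EXC{i:05d}", label="excluded",
                                    feature_points=pts, heavy_coords=heavy,
                                    pic50=float(rng.uniform(4.5, 6.0))))
    return entries


# ---------------------------------------------------------------------------
# library serialization: manifest table + per-entry structured text records
# ---------------------------------------------------------------------------

def write_library(entries: list[LibraryEntry], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in entries:
        rows.append({"id": e.id, "label": e.label, "pic50": e.pic50})
        with open(directory / f"{e.id}.txt", "w") as fh:
            for kind, c in e.feature_points:
                fh.write(f"POINT {kind} {c[0]:.4f} {c[1]:.4f} {c[2]:.4f}\n")
            for c in e.heavy_coords:
                fh.write(f"ATOM {c[0]:.4f} {c[1]:.4f} {c[2]:.4f}\n")
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_library(directory) -> list[LibraryEntry]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    entries = []
    for _, row in manifest.iterrows():
        pts, heavy = [], []
        with open(directory / f"{row['id']}.txt") as fh:
            for line in fh:
                parts = line.split()
                if parts[0] == "POINT":
                    pts.append((parts[1], np.array(list(map(float, parts[2:5])))))
                elif parts[0] == "ATOM":
                    heavy.append(list(map(float, parts[1:4])))
        entries.append(LibraryEntry(id=row["id"], label=row["label"],
                                    feature_points=pts, heavy_coords=np.array(heavy),
                                    pic50=None if pd.isna(row["pic50"]) else float(row["pic50"])))
    return entries
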