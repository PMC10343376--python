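"""Structure-based 3D pharmacophores: build, merge, edit, screen, evaluate.

A pharmacophore is a set of typed interaction features — hydrogen-bond
donor (HBD), acceptor (HBA), hydrophobic (H), aromatic-hydrophobic (HAr) —
each a point with a tolerance sphere, plus exclusion volumes marking
receptor-occupied space.  Matching is a deterministic exhaustive
kind-respecting assignment of model features to a ligand's feature points
followed by least-squares superposition; screening may allow the omission
of one feature, enumerated exhaustively (a deterministic superset of a
"randomly discard one feature" screen).  Performance is summarized by

    sensitivity = TP/A,  specificity = TN/I,  EF = (TP/Htot)/(A/D)

with A/I/D the active/inactive/total library sizes and Htot the hit-list
size, plus full and early-recognition ROC AUC.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

FEATURE_KINDS = ("HBD", "HBA", "H", "HAr")

DEFAULT_TOLERANCE = 1.5      # Å, feature tolerance sphere
DEFAULT_EXCLUSION_RADIUS = 1.0  # Å
MAX_ASSIGNMENTS = 10 ** 6


@dataclass(frozen=True)
class Feature:
    kind: str
    center: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE
    label: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class ExclusionVolume:
    center: tuple[float, float, float]
    radius: float = DEFAULT_EXCLUSION_RADIUS

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("exclusion radius must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass
class PharmacophoreModel:
    features: list[Feature]
    exclusions: list[ExclusionVolume] = field(default_factory=list)
    name: str = "model"
    provenance: str = "crystal"   # crystal | ensemble | merged | edited

    def __post_init__(self):
        if not self.features:
            raise ValueError("empty model: no features")
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate feature labels: {labels}")

    def feature_by_label(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features])


def _autolabel(features: list[Feature]) -> list[Feature]:
    counts: dict[str, int] = {}
    out = []
    for f in features:
        counts[f.kind] = counts.get(f.kind, 0) + 1
        out.append(replace(f, label=f"{f.kind}{counts[f.kind]}"))
    return out


# ---------------------------------------------------------------------------
# feature perception on typed ligand atoms
# ---------------------------------------------------------------------------

@dataclass
class TypedAtom:
    """Ligand atom with the chemical typing feature perception needs."""

    index: int
    coords: np.ndarray
    element: str = "C"
    hbond_role: str = "none"
    ring_id: int | None = None
    bonded_to: tuple[int, ...] = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not self.element:
            raise ValueError(f"atom {self.index}: untyped (no element)")
        if self.hbond_role not in ("donor_heavy", "acceptor", "polar_h", "none"):
            raise ValueError(f"atom {self.index}: untyped hbond_role {self.hbond_role!r}")

    @property
    def is_carbon(self) -> bool:
        return self.element.upper() == "C"

    @property
    def in_ring(self) -> bool:
        return self.ring_id is not None


def perceive_features(atoms: list[TypedAtom]) -> list[tuple[str, np.ndarray, tuple[int, ...]]]:
    """Candidate (kind, center, source-atom-indices) feature points.

    HBD at donor heavy atoms, HBA at acceptors, HAr at ring centroids,
    H at centroids of bonded clusters of ≥ 3 non-ring carbons.
    """
    by_index = {a.index: a for a in atoms}
    out: list[tuple[str, np.ndarray, tuple[int, ...]]] = []
    for a in atoms:
        if a.hbond_role == "donor_heavy":
            out.append(("HBD", a.coords.copy(), (a.index,)))
        if a.hbond_role == "acceptor":
            out.append(("HBA", a.coords.copy(), (a.index,)))
    rings: dict[int, list[TypedAtom]] = {}
    for a in atoms:
        if a.in_ring:
            rings.setdefault(a.ring_id, []).append(a)
    for rid in sorted(rings):
        members = rings[rid]
        centroid = np.mean([m.coords for m in members], axis=0)
        out.append(("HAr", centroid, tuple(sorted(m.index for m in members))))
    # connected clusters of non-ring carbons
    chain_carbons = {a.index for a in atoms if a.is_carbon and not a.in_ring}
    unvisited = set(chain_carbons)
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in by_index[cur].bonded_to:
                if nb in chain_carbons and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        unvisited -= comp
        if len(comp) >= 3:
            centroid = np.mean([by_index[i].coords for i in sorted(comp)], axis=0)
            out.append(("H", centroid, tuple(sorted(comp))))
    return out


# ---------------------------------------------------------------------------
# model construction from a complex or an ensemble
# ---------------------------------------------------------------------------

def build_model(top, frames, ligand_typing: dict[int, TypedAtom],
                frequency_threshold: float = 0.5, hbond_distance: float = 3.5,
                hydrophobic_distance: float = 4.0, exclusion_distance: float = 6.0,
                tolerance: float = DEFAULT_TOLERANCE,
                exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
                name: str = "model") -> PharmacophoreModel:
    """Structure-based model from a complex frame or a conformational ensemble.

    A candidate ligand feature is retained when its complementary protein
    condition holds — HBD needs a protein acceptor (HBA a protein donor)
    within the H-bond distance; H/HAr need a protein heavy atom within the
    hydrophobic distance of the centroid — in ≥ ``frequency_threshold`` of
    frames; retained centers are frame averages.  Exclusion volumes sit on
    protein heavy atoms within ``exclusion_distance`` of any ligand atom
    (frame-averaged coordinates).
    """
    frames = [np.asarray(f, float) for f in (frames if isinstance(frames, (list, tuple)) else [frames])]
    top.require_complex()
    rec_pos = top.segment_positions("receptor")
    lig_pos = top.segment_positions("ligand")
    missing = [top.atoms[i].atom_index for i in lig_pos
               if top.atoms[i].atom_index not in ligand_typing]
    if missing:
        raise ValueError(f"ligand atoms without typing: {missing}")
    rec_heavy = [i for i in rec_pos if not top.atoms[i].is_hydrogen]
    rec_acceptors = [i for i in rec_pos if top.atoms[i].hbond_role == "acceptor"]
    rec_donors = [i for i in rec_pos if top.atoms[i].hbond_role == "donor_heavy"]
    pos_of = {top.atoms[i].atom_index: i for i in lig_pos}

    hits: dict[tuple, list[np.ndarray]] = {}
    satisfied: dict[tuple, int] = {}
    for frame in frames:
        atoms = [replace(ligand_typing[top.atoms[i].atom_index],
                         coords=frame[pos_of[top.atoms[i].atom_index]]) for i in lig_pos]
        for kind, center, src in perceive_features(atoms):
            key = (kind, src)
            hits.setdefault(key, []).append(center)
            if kind == "HBD":
                partners = frame[rec_acceptors] if rec_acceptors else np.empty((0, 3))
                ok = partners.size and np.min(np.linalg.norm(partners - center, axis=1)) <= hbond_distance
            elif kind == "HBA":
                partners = frame[rec_donors] if rec_donors else np.empty((0, 3))
                ok = partners.size and np.min(np.linalg.norm(partners - center, axis=1)) <= hbond_distance
            else:
                partners = frame[rec_heavy]
                ok = partners.size and np.min(np.linalg.norm(partners - center, axis=1)) <= hydrophobic_distance
            satisfied[key] = satisfied.get(key, 0) + bool(ok)
    n = len(frames)
    feats = []
    for key in sorted(hits, key=lambda k: (FEATURE_KINDS.index(k[0]), k[1])):
        if satisfied.get(key, 0) / n >= frequency_threshold:
            center = np.mean(hits[key], axis=0)
            feats.append(Feature(kind=key[0], center=tuple(center), tolerance=tolerance))
    if not feats:
        raise ValueError("empty model: no feature satisfied its protein-partner "
                         "condition at the requested frequency")
    mean_frame = np.mean(frames, axis=0)
    lig_coords = mean_frame[lig_pos]
    exclusions = []
    for i in rec_heavy:
        d = np.min(np.linalg.norm(lig_coords - mean_frame[i], axis=1))
        if d <= exclusion_distance:
            exclusions.append(ExclusionVolume(center=tuple(mean_frame[i]),
                                              radius=exclusion_radius))
    return PharmacophoreModel(_autolabel(feats), exclusions, name=name,
                              provenance="crystal" if n == 1 else "ensemble")


def merge_models(a: PharmacophoreModel, b: PharmacophoreModel,
                 merge_distance: float = 1.5) -> PharmacophoreModel:
    """Fuse same-kind features within ``merge_distance`` to their midpoint;
    carry everything else over; union exclusion volumes with the same rule."""
    feats: list[Feature] = []
    used_b: set[int] = set()
    for fa in a.features:
        partner = None
        for k, fb in enumerate(b.features):
            if k in used_b or fb.kind != fa.kind:
                continue
            d = np.linalg.norm(np.array(fa.center) - np.array(fb.center))
            if d <= merge_distance and (partner is None or d < partner[0]):
                partner = (d, k)
        if partner is not None:
            used_b.add(partner[1])
            fb = b.features[partner[1]]
            mid = tuple((np.array(fa.center) + np.array(fb.center)) / 2.0)
            feats.append(Feature(fa.kind, mid, min(fa.tolerance, fb.tolerance)))
        else:
            feats.append(replace(fa, label=""))
    feats.extend(replace(fb, label="") for k, fb in enumerate(b.features) if k not in used_b)
    excl: list[ExclusionVolume] = []
    used_b2: set[int] = set()
    for ea in a.exclusions:
        partner = None
        for k, eb in enumerate(b.exclusions):
            if k in used_b2:
                continue
            d = np.linalg.norm(np.array(ea.center) - np.array(eb.center))
            if d <= merge_distance and (partner is None or d < partner[0]):
                partner = (d, k)
        if partner is not None:
            used_b2.add(partner[1])
            eb = b.exclusions[partner[1]]
            excl.append(ExclusionVolume(tuple((np.array(ea.center) + np.array(eb.center)) / 2.0),
                                        min(ea.radius, eb.radius)))
        else:
            excl.append(ea)
    excl.extend(eb for k, eb in enumerate(b.exclusions) if k not in used_b2)
    return PharmacophoreModel(_autolabel(feats), excl,
                              name=f"{a.name}+{b.name}", provenance="merged")


def edit_model(model: PharmacophoreModel, drop_labels: list[str]) -> PharmacophoreModel:
    """Copy of the model without the named features (provenance 'edited')."""
    known = {f.label for f in model.features}
    unknown = [lab for lab in drop_labels if lab not in known]
    if unknown:
        raise KeyError(f"unknown feature labels: {unknown}")
    kept = [f for f in model.features if f.label not in drop_labels]
    if not kept:
        raise ValueError("empty model: all features dropped")
    return PharmacophoreModel(kept, list(model.exclusions), name=model.name,
                              provenance="edited")


# ---------------------------------------------------------------------------
# matching and screening
# ---------------------------------------------------------------------------

@dataclass
class LibraryEntry:
    """One screening-library conformer: feature points + heavy atoms.

    ``label`` ∈ {active, inactive, excluded}; entries in the pIC50 band
    [4.5, 6] carry "excluded" and are skipped during screening.
    """

    id: str
    label: str
    feature_points: list[tuple[str, np.ndarray]]
    heavy_coords: np.ndarray
    pic50: float | None = None

    def __post_init__(self):
        self.feature_points = [(k, np.asarray(c, float).reshape(3))
                               for k, c in self.feature_points]
        self.heavy_coords = np.asarray(self.heavy_coords, float).reshape(-1, 3)
        if self.label not in ("active", "inactive", "excluded"):
            raise ValueError(f"bad label {self.label!r}")
        if self.pic50 is not None:
            in_band = 4.5 <= self.pic50 <= 6.0
            if in_band != (self.label == "excluded"):
                raise ValueError(f"entry {self.id}: label {self.label!r} inconsistent "
                                 f"with pIC50 {self.pic50}")


@dataclass
class MatchResult:
    matched: bool
    omitted_label: str | None = None
    rmsd: float = float("nan")


def _fit_transform(model_pts: np.ndarray, entry_pts: np.ndarray):
    """Rigid transform mapping entry points onto model points (least squares).

    Falls back to centroid translation (plus a vector-aligning rotation for
    two points) when fewer than three non-degenerate pairs are available.
    """
    n = len(model_pts)
    mc = model_pts.mean(axis=0)
    ec = entry_pts.mean(axis=0)
    if n == 1:
        return np.eye(3), mc - ec
    p = entry_pts - ec
    q = model_pts - mc
    if n == 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        u = p[1] - p[0]
        v = q[1] - q[0]
        rot = _rotation_between(u, v)
    else:
        h = p.T @ q
        u_, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u_.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u_.T
    return rot, mc - rot @ ec


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return np.eye(3)
    a = u / nu
    b = v / nv
    c = np.cross(a, b)
    cos = float(np.dot(a, b))
    if np.linalg.norm(c) < 1e-12:
        if cos > 0:
            return np.eye(3)
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    k = np.array([[0, -c[2], c[1]], [c[2], 0, -c[0]], [-c[1], c[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + cos)


def match_entry(model: PharmacophoreModel, entry: LibraryEntry,
                max_omitted: int = 0) -> MatchResult:
    """Deterministic exhaustive feature matching with optional omission.

    For the empty omission set (and, if allowed, each single omitted
    feature) every kind-respecting assignment of model features to entry
    feature points is tried: the entry is rigidly superposed onto the
    model on the assigned pairs, and the pose is accepted when every
    assigned pair falls within its tolerance sphere and no entry heavy
    atom lies inside an exclusion volume.  Of all acceptances the lowest
    alignment RMSD wins; ties prefer fewer omissions, then the
    lexicographically smallest omitted label.
    """
    if max_omitted not in (0, 1):
        raise ValueError("max_omitted must be 0 or 1")
    omission_sets: list[str | None] = [None]
    if max_omitted == 1 and len(model.features) > 1:
        omission_sets += [f.label for f in model.features]
    entry_by_kind: dict[str, list[np.ndarray]] = {}
    for kind, c in entry.feature_points:
        entry_by_kind.setdefault(kind, []).append(c)
    excl_centers = np.array([e.center for e in model.exclusions]).reshape(-1, 3)
    excl_radii = np.array([e.radius for e in model.exclusions])

    best: tuple[float, int, str] | None = None  # (rmsd, n_omit, label)
    best_label: str | None = None
    for omitted in omission_sets:
        feats = [f for f in model.features if f.label != omitted]
        by_kind: dict[str, list[Feature]] = {}
        for f in feats:
            by_kind.setdefault(f.kind, []).append(f)
        n_assign = 1
        feasible = True
        for kind, fl in by_kind.items():
            avail = len(entry_by_kind.get(kind, []))
            if avail < len(fl):
                feasible = False
                break
            n_assign *= int(np.prod([avail - t for t in range(len(fl))]))
        if not feasible:
            continue
        if n_assign > MAX_ASSIGNMENTS:
            raise RuntimeError(f"assignment enumeration too large ({n_assign} > "
                               f"{MAX_ASSIGNMENTS}); reduce per-kind feature counts")
        kind_list = sorted(by_kind)
        pools = [list(itertools.permutations(range(len(entry_by_kind[k])), len(by_kind[k])))
                 for k in kind_list]
        for combo in itertools.product(*pools):
            model_pts, entry_pts, tols = [], [], []
            for k, perm in zip(kind_list, combo):
                for f, e_idx in zip(by_kind[k], perm):
                    model_pts.append(f.center)
                    entry_pts.append(entry_by_kind[k][e_idx])
                    tols.append(f.tolerance)
            mp = np.array(model_pts)
            ep = np.array(entry_pts)
            rot, trans = _fit_transform(mp, ep)
            moved = ep @ rot.T + trans
            dev = np.linalg.norm(moved - mp, axis=1)
            if np.any(dev > np.array(tols)):
                continue
            if len(excl_centers):
                heavy = entry.heavy_coords @ rot.T + trans
                d = np.linalg.norm(heavy[:, None, :] - excl_centers[None, :, :], axis=-1)
                if np.any(d < excl_radii[None, :]):
                    continue
            rmsd = float(np.sqrt(np.mean(dev ** 2)))
            n_omit = 0 if omitted is None else 1
            key = (rmsd, n_omit, omitted or "")
            if best is None or key < best:
                best = key
                best_label = omitted
    if best is None:
        return MatchResult(False)
    return MatchResult(True, omitted_label=best_label, rmsd=best[0])


@dataclass
class ScreeningOutcome:
    """Confusion counts plus per-entry scores for ROC ranking."""

    tp: int
    fp: int
    tn: int
    fn: int
    matched_ids: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)  # −rmsd; non-matches lowest
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def a(self) -> int:
        return self.tp + self.fn

    @property
    def i(self) -> int:
        return self.tn + self.fp

    @property
    def d(self) -> int:
        return self.a + self.i

    @property
    def htot(self) -> int:
        return self.tp + self.fp


NO_MATCH_SCORE = -1e9


def screen_library(model: PharmacophoreModel, library: list[LibraryEntry],
                   max_omitted: int = 0) -> ScreeningOutcome:
    """Match every (non-excluded) entry and tally the confusion counts."""
    if not library:
        raise ValueError("empty library")
    tp = fp = tn = fn = 0
    matched_ids, scores, labels = [], {}, {}
    for entry in library:
        if entry.label == "excluded":
            continue
        res = match_entry(model, entry, max_omitted=max_omitted)
        labels[entry.id] = entry.label
        scores[entry.id] = -res.rmsd if res.matched else NO_MATCH_SCORE
        if res.matched:
            matched_ids.append(entry.id)
            if entry.label == "active":
                tp += 1
            else:
                fp += 1
        else:
            if entry.label == "active":
                fn += 1
            else:
                tn += 1
    return ScreeningOutcome(tp, fp, tn, fn, matched_ids, scores, labels)


def screening_metrics(outcome: ScreeningOutcome) -> dict:
    """Sensitivity, specificity and enrichment factor from the counts.

    EF uses D = A + I (the full labeled dataset size) and is None for an
    empty hit list.
    """
    if outcome.a == 0 or outcome.i == 0:
        raise ValueError("both actives (A) and inactives (I) must be present")
    sens = outcome.tp / outcome.a
    spec = outcome.tn / outcome.i
    ef = None
    if outcome.htot > 0:
        ef = (outcome.tp / outcome.htot) / (outcome.a / outcome.d)
    return {"sensitivity": sens, "specificity": spec, "EF": ef,
            "TP": outcome.tp, "FP": outcome.fp, "TN": outcome.tn, "FN": outcome.fn,
            "A": outcome.a, "I": outcome.i, "D": outcome.d, "Htot": outcome.htot}


def metrics_from_counts(tp: int, tn: int, n_active: int, n_inactive: int) -> dict:
    """Metrics from published confusion counts (replay without screening)."""
    out = ScreeningOutcome(tp=tp, fp=n_inactive - tn, tn=tn, fn=n_active - tp)
    return screening_metrics(out)


def roc_auc(scores, labels, fraction: float = 1.0) -> float:
    """ROC AUC by Mann–Whitney pair counting (ties credited ½).

    With ``fraction`` < 1 the area is computed over the top fraction of
    the ranked library only (early recognition) and normalized to [0, 1]
    by the false-positive rate reached at the cutoff; a prefix containing
    no inactives scores 1.0 if it holds any active, else 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (1, True, "active") else 0 for l in labels])
    if s.shape != y.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        ranks = rankdata(s)                       # average ranks handle ties
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        return float(auc)
    # early-recognition partial AUC over the top ceil(fraction·n) entries
    k = int(np.ceil(fraction * len(y)))
    order = np.argsort(-s, kind="stable")
    area = 0.0
    tp = fp = 0
    taken = 0
    idx = 0
    while idx < len(y) and taken < k:
        # process one tie group (possibly truncated at the cutoff)
        j = idx
        while j < len(y) and s[order[j]] == s[order[idx]]:
            j += 1
        group = order[idx:j]
        g_pos = int(y[group].sum())
        g_neg = len(group) - g_pos
        frac_used = min(1.0, (k - taken) / len(group))
        d_tp = g_pos * frac_used
        d_fp = g_neg * frac_used
        area += d_fp * (tp + d_tp / 2.0)          # trapezoid on the tie diagonal
        tp += d_tp
        fp += d_fp
        taken += len(group)
        idx = j
    if fp == 0:
        return 1.0 if tp > 0 else 0.5
    return float(area / (fp * n_pos))


# ---------------------------------------------------------------------------
# model serialization (structured text)
# ---------------------------------------------------------------------------

def write_model(model: PharmacophoreModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pharmacophore {model.name} provenance={model.provenance}\n")
        for f in model.features:
            fh.write(f"FEATURE {f.kind} {f.label} "
                     f"{f.center[0]:.4f} {f.center[1]:.4f} {f.center[2]:.4f} "
                     f"{f.tolerance:.3f}\n")
        for e in model.exclusions:
            fh.write(f"EXCLUSION {e.center[0]:.4f} {e.center[1]:.4f} "
                     f"{e.center[2]:.4f} {e.radius:.3f}\n")


def read_model(path) -> PharmacophoreModel:
    features, exclusions = [], []
    name, provenance = "model", "crystal"
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#":
                if len(parts) >= 3:
                    name = parts[2]
                for p in parts:
                    if p.startswith("provenance="):
                        provenance = p.split("=", 1)[1]
            elif parts[0] == "FEATURE":
                features.append(Feature(kind=parts[1], label=parts[2],
                                        center=tuple(map(float, parts[3:6])),
                                        tolerance=float(parts[6])))
            elif parts[0] == "EXCLUSION":
                exclusions.append(ExclusionVolume(center=tuple(map(float, parts[1:4])),
                                                  radius=float(parts[4])))
            else:
                raise ValueError(f"unknown record {parts[0]!r} in {path}")
    return PharmacophoreModel(features, exclusions, name=name, provenance=provenance)
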