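"""Feature perception, model building/merging, matching and screening math."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xbir3.pharmacophore import (ExclusionVolume, Feature, LibraryEntry,
                                 PharmacophoreModel, TypedAtom, build_model,
                                 edit_model, match_entry, merge_models,
                                 metrics_from_counts, perceive_features,
                                 read_model, roc_auc, screen_library,
                                 screening_metrics, write_model)
from xbir3.synthetic import (LibraryRecipe, make_reference_pharmacophore,
                             make_screening_library, make_toy_complex)


class TestPerception:
    def test_hydroxyl_like_oxygen_is_donor_and_acceptor(self):
        atoms = [TypedAtom(1, [0, 0, 0], element="O", hbond_role="donor_heavy"),
                 TypedAtom(2, [0, 0, 0], element="O", hbond_role="acceptor")]
        kinds = sorted(k for k, _, _ in perceive_features(atoms))
        assert kinds == ["HBA", "HBD"]

    def test_six_carbon_ring_gives_har_at_centroid(self):
        ring = [TypedAtom(i, [np.cos(i * np.pi / 3), np.sin(i * np.pi / 3), 0],
                          element="C", ring_id=1) for i in range(6)]
        feats = perceive_features(ring)
        assert len(feats) == 1
        kind, center, src = feats[0]
        assert kind == "HAr"
        np.testing.assert_allclose(center, [0, 0, 0], atol=1e-12)

    def test_four_carbon_chain_gives_one_hydrophobic(self):
        chain = [TypedAtom(i, [1.5 * i, 0, 0], element="C",
                           bonded_to=tuple(j for j in (i - 1, i + 1) if 0 <= j < 4))
                 for i in range(4)]
        feats = perceive_features(chain)
        assert [k for k, _, _ in feats] == ["H"]
        np.testing.assert_allclose(feats[0][1], [2.25, 0, 0])

    def test_two_carbon_fragment_below_cluster_floor(self):
        pair = [TypedAtom(0, [0, 0, 0], element="C", bonded_to=(1,)),
                TypedAtom(1, [1.5, 0, 0], element="C", bonded_to=(0,))]
        assert perceive_features(pair) == []


def _planted_complex():
    """Toy complex whose ligand donates one H-bond and packs one 3-carbon chain."""
    spec = [{"group_id": "G1", "atoms": [
        {"name": "N1", "charge": 0.5, "lj_epsilon": 0.2, "lj_rmin_half": 1.85,
         "pb_radius": 1.55, "mass": 14.0, "hbond_role": "donor_heavy",
         "offset": (0.0, 0.0, 0.0)},
        {"name": "C1", "charge": 0.17, "lj_epsilon": 0.11, "lj_rmin_half": 2.0,
         "pb_radius": 1.7, "mass": 12.0, "hbond_role": "none", "offset": (1.5, 0.0, 0.0)},
        {"name": "C2", "charge": 0.17, "lj_epsilon": 0.11, "lj_rmin_half": 2.0,
         "pb_radius": 1.7, "mass": 12.0, "hbond_role": "none", "offset": (3.0, 0.0, 0.0)},
        {"name": "C3", "charge": 0.16, "lj_epsilon": 0.11, "lj_rmin_half": 2.0,
         "pb_radius": 1.7, "mass": 12.0, "hbond_role": "none", "offset": (4.5, 0.0, 0.0)},
    ]}]
    top = make_toy_complex(4, ligand_spec=spec, seed=7)
    # place the ligand so the donor nitrogen sits at H-bond distance (2.9 Å)
    # from the nearest receptor carbonyl oxygen
    coords = top.coords()
    lig_pos = top.segment_positions("ligand")
    don = next(i for i in lig_pos if top.atoms[i].hbond_role == "donor_heavy")
    accs = [i for i in top.segment_positions("receptor")
            if top.atoms[i].hbond_role == "acceptor"]
    acc = min(accs, key=lambda i: np.linalg.norm(coords[don] - coords[i]))
    direction = coords[don] - coords[acc]
    direction /= np.linalg.norm(direction)
    shift = (coords[acc] + 2.9 * direction) - coords[don]
    coords[lig_pos] += shift
    top.set_coords(coords)
    typing = {}
    lig = [top.atoms[i] for i in top.segment_positions("ligand")]
    idx = {a.atom_name: a.atom_index for a in lig}
    typing[idx["N1"]] = TypedAtom(idx["N1"], [0, 0, 0], element="N",
                                  hbond_role="donor_heavy")
    typing[idx["C1"]] = TypedAtom(idx["C1"], [0, 0, 0], element="C",
                                  bonded_to=(idx["C2"],))
    typing[idx["C2"]] = TypedAtom(idx["C2"], [0, 0, 0], element="C",
                                  bonded_to=(idx["C1"], idx["C3"]))
    typing[idx["C3"]] = TypedAtom(idx["C3"], [0, 0, 0], element="C",
                                  bonded_to=(idx["C2"],))
    return top, typing


class TestBuildModel:
    def test_planted_features_recovered(self):
        top, typing = _planted_complex()
        model = build_model(top, top.coords(), typing)
        kinds = sorted(f.kind for f in model.features)
        assert kinds == ["H", "HBD"]
        assert model.provenance == "crystal"
        assert len(model.exclusions) > 0

    def test_frozen_trajectory_equals_single_frame(self):
        top, typing = _planted_complex()
        single = build_model(top, top.coords(), typing)
        frozen = build_model(top, [top.coords()] * 4, typing)
        assert frozen.provenance == "ensemble"
        assert [f.kind for f in frozen.features] == [f.kind for f in single.features]
        np.testing.assert_allclose(frozen.centers(), single.centers(), atol=1e-12)

    def test_frequency_threshold_gates_intermittent_feature(self):
        top, typing = _planted_complex()
        base = top.coords()
        # break the H-bond in 3 of 5 frames by moving the donor far away
        donor_pos = next(i for i in top.segment_positions("ligand")
                         if top.atoms[i].hbond_role == "donor_heavy")
        frames = []
        for k in range(5):
            f = base.copy()
            if k >= 2:
                f[donor_pos] += [0.0, -40.0, 0.0]
            frames.append(f)
        kinds_50 = [f.kind for f in build_model(top, frames, typing,
                                                frequency_threshold=0.5).features]
        kinds_30 = [f.kind for f in build_model(top, frames, typing,
                                                frequency_threshold=0.3).features]
        assert "HBD" not in kinds_50   # holds in 40% of frames only
        assert "HBD" in kinds_30

    def test_no_retained_features_errors(self):
        top, typing = _planted_complex()
        far = top.coords()
        for i in top.segment_positions("ligand"):
            far[i] += 200.0
        with pytest.raises(ValueError, match="empty model"):
            build_model(top, far, typing)


class TestMergeEdit:
    def test_merge_idempotent(self):
        m = make_reference_pharmacophore(3)
        merged = merge_models(m, m)
        assert len(merged.features) == len(m.features)
        np.testing.assert_allclose(merged.centers(), m.centers(), atol=1e-12)
        assert merged.provenance == "merged"

    def test_merge_disjoint_is_union(self):
        a = PharmacophoreModel([Feature("HBD", (0, 0, 0), label="HBD1")])
        b = PharmacophoreModel([Feature("HBD", (30, 0, 0), label="HBD1")])
        assert len(merge_models(a, b).features) == 2

    def test_merge_counts_mirror_shared_features(self):
        # 5-feature and 6-feature models sharing 3 fusable -> 8 features
        rng = np.random.default_rng(0)
        shared = [Feature(k, tuple(rng.uniform(-5, 5, 3))) for k in ("HBD", "HBA", "H")]
        only_a = [Feature("H", (20, 0, 0)), Feature("HAr", (25, 0, 0))]
        only_b = [Feature("H", (-20, 0, 0)), Feature("HBD", (-25, 0, 0)),
                  Feature("H", (-30, 0, 0))]
        from xbir3.pharmacophore import _autolabel
        a = PharmacophoreModel(_autolabel(shared + only_a))
        jittered = [Feature(f.kind, tuple(np.array(f.center) + 0.3)) for f in shared]
        b = PharmacophoreModel(_autolabel(jittered + only_b))
        assert len(merge_models(a, b, merge_distance=1.5).features) == 8

    def test_edit_drop_and_errors(self):
        m = make_reference_pharmacophore(1)  # default 8 features incl. H4
        edited = edit_model(m, ["H4"])
        assert len(edited.features) == len(m.features) - 1
        assert edited.provenance == "edited"
        assert edit_model(m, []).features == m.features
        with pytest.raises(KeyError):
            edit_model(m, ["NOPE"])
        with pytest.raises(ValueError, match="empty"):
            edit_model(m, [f.label for f in m.features])


class TestMatching:
    def test_planted_entry_matches_exactly(self):
        m = make_reference_pharmacophore(2)
        entry = LibraryEntry("e", "active",
                             [(f.kind, np.array(f.center)) for f in m.features],
                             np.array([f.center for f in m.features]))
        res = match_entry(m, entry)
        assert res.matched and res.omitted_label is None
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_displaced_feature_needs_omission(self):
        m = make_reference_pharmacophore(2)
        pts = [(f.kind, np.array(f.center)) for f in m.features]
        k = 0
        pts[k] = (pts[k][0], pts[k][1] + np.array([2 * m.features[k].tolerance + 8.0, 0, 0]))
        entry = LibraryEntry("e", "active", pts, np.array([c for _, c in pts]))
        assert not match_entry(m, entry, max_omitted=0).matched
        res = match_entry(m, entry, max_omitted=1)
        assert res.matched and res.omitted_label == m.features[k].label

    def test_exclusion_volume_vetoes_regardless_of_omission(self):
        feats = [Feature("HBD", (0, 0, 0), label="HBD1"),
                 Feature("HBA", (4, 0, 0), label="HBA1"),
                 Feature("H", (0, 4, 0), label="H1")]
        m = PharmacophoreModel(feats, [ExclusionVolume((2, 2, 0), radius=1.0)])
        pts = [(f.kind, np.array(f.center)) for f in feats]
        heavy = np.vstack([np.array([c for _, c in pts]), [[2.0, 2.0, 0.0]]])
        entry = LibraryEntry("e", "active", pts, heavy)
        assert not match_entry(m, entry, max_omitted=0).matched
        assert not match_entry(m, entry, max_omitted=1).matched

    def test_rigid_motion_invariance(self, rng):
        m = make_reference_pharmacophore(5)
        theta = 1.2
        rot = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        pts = [(f.kind, rot @ np.array(f.center) + [11, -7, 3]) for f in m.features]
        entry = LibraryEntry("e", "active", pts, np.array([c for _, c in pts]))
        res = match_entry(m, entry)
        assert res.matched
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)


class TestScreening:
    def test_planted_library_perfect_recovery(self):
        model = make_reference_pharmacophore(0)
        lib = make_screening_library(LibraryRecipe(n_active=20, n_inactive=60,
                                                   reference=model, seed=1))
        out = screen_library(model, lib, max_omitted=0)
        m = screening_metrics(out)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["EF"] == pytest.approx(out.d / out.a)

    def test_corrupted_actives_recovered_by_omission(self):
        model = make_reference_pharmacophore(0)
        lib = make_screening_library(LibraryRecipe(n_active=20, n_inactive=50,
                                                   reference=model,
                                                   corrupt_active_fraction=0.2, seed=2))
        m0 = screening_metrics(screen_library(model, lib, max_omitted=0))
        m1 = screening_metrics(screen_library(model, lib, max_omitted=1))
        assert m0["sensitivity"] == pytest.approx(0.8)
        assert m1["sensitivity"] == pytest.approx(1.0)

    def test_always_violated_extra_feature_kills_sensitivity(self):
        model = make_reference_pharmacophore(0)
        lib = make_screening_library(LibraryRecipe(n_active=10, n_inactive=10,
                                                   reference=model, seed=3))
        stricter = PharmacophoreModel(
            model.features + [Feature("HBA", (500, 0, 0), label="HBA99")],
            model.exclusions, name="strict")
        out = screen_library(stricter, lib, max_omitted=0)
        assert out.tp == 0

    def test_excluded_entries_skipped(self):
        model = make_reference_pharmacophore(0)
        lib = make_screening_library(LibraryRecipe(n_active=5, n_inactive=5,
                                                   n_excluded=7, reference=model, seed=4))
        out = screen_library(model, lib, max_omitted=0)
        assert out.d == 10

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_omission_only_relaxes_matching(self, seed):
        model = make_reference_pharmacophore(seed)
        lib = make_screening_library(LibraryRecipe(
            n_active=12, n_inactive=25, reference=model,
            corrupt_active_fraction=0.3, seed=seed))
        s0 = screening_metrics(screen_library(model, lib, 0))["sensitivity"]
        s1 = screening_metrics(screen_library(model, lib, 1))["sensitivity"]
        assert s1 >= s0

    @pytest.mark.parametrize("seed", [21, 22])
    def test_dropping_a_feature_is_a_relaxation(self, seed):
        model = make_reference_pharmacophore(seed)
        lib = make_screening_library(LibraryRecipe(
            n_active=10, n_inactive=20, reference=model,
            corrupt_active_fraction=0.3, seed=seed))
        m_full = screening_metrics(screen_library(model, lib, 0))
        smaller = edit_model(model, [model.features[0].label])
        m_small = screening_metrics(screen_library(smaller, lib, 0))
        assert m_small["sensitivity"] >= m_full["sensitivity"]
        assert m_small["specificity"] <= m_full["specificity"]


class TestMetrics:
    def test_published_count_arithmetic(self):
        # 0-omission screen of the first model: TP=5 of 173 -> 2.9%, EF 32.3
        m1 = metrics_from_counts(tp=5, tn=5417, n_active=173, n_inactive=5417)
        assert 100 * m1["sensitivity"] == pytest.approx(2.9, abs=0.05)
        assert m1["EF"] == pytest.approx(32.3, abs=0.05)
        # 1-omission screen of the fourth model: TP=134 -> 77.5%
        m4 = metrics_from_counts(tp=134, tn=5056, n_active=173, n_inactive=5417)
        assert 100 * m4["sensitivity"] == pytest.approx(77.5, abs=0.05)
        # final 5-feature model: TP=136, TN=5338 -> EF 20.4
        m5 = metrics_from_counts(tp=136, tn=5338, n_active=173, n_inactive=5417)
        assert m5["EF"] == pytest.approx(20.4, abs=0.05)

    def test_perfect_retrieval(self):
        m = metrics_from_counts(tp=173, tn=5417, n_active=173, n_inactive=5417)
        assert m["sensitivity"] == 1.0
        assert m["EF"] == pytest.approx(5590 / 173)

    def test_empty_hit_list_ef_undefined(self):
        m = metrics_from_counts(tp=0, tn=5417, n_active=173, n_inactive=5417)
        assert m["EF"] is None

    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 200), tn=st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_identities_on_random_outcomes(self, tp, fn, fp, tn):
        from xbir3.pharmacophore import ScreeningOutcome
        if tp + fn == 0 or fp + tn == 0:
            return
        out = ScreeningOutcome(tp=tp, fp=fp, tn=tn, fn=fn)
        m = screening_metrics(out)
        assert m["TP"] + m["FN"] == m["A"]
        assert m["TN"] + m["FP"] == m["I"]
        if m["EF"] is not None:
            assert m["EF"] == pytest.approx(
                m["sensitivity"] * m["D"] / m["Htot"], rel=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([5, 4, 3, 2, 1], ["active", "active", "inactive",
                                         "inactive", "inactive"]) == 1.0

    def test_worked_four_entry_set(self):
        # scores 4,3,2,1 with labels +,-,+,-: pairs (4>3),(4>1),(2>1) win,
        # (2<3) loses -> 3/4
        assert roc_auc([4, 3, 2, 1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_random_scores_near_half(self, rng):
        n = 10 ** 5
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.01)

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 20, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            wins = ties = 0
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            for sp in pos:
                for sn in neg:
                    wins += sp > sn
                    ties += sp == sn
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_partial_auc_conventions(self, rng):
        scores = [10, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 1, 0]
        # top 30% holds only actives -> early AUC 1.0
        assert roc_auc(scores, labels, fraction=0.3) == 1.0
        full = roc_auc(scores, labels, fraction=1.0)
        assert 0.0 <= roc_auc(scores, labels, fraction=0.6) <= 1.0
        assert 0.0 < full < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        m = make_reference_pharmacophore(9)
        p = tmp_path / "model.txt"
        write_model(m, p)
        back = read_model(p)
        assert [f.label for f in back.features] == [f.label for f in m.features]
        np.testing.assert_allclose(back.centers(), m.centers(), atol=1e-3)
        assert len(back.exclusions) == len(m.exclusions)
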