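"""Duplicate selection, rounds, duplicated filters, comprehensive mode."""

import numpy as np
import pandas as pd
import pytest

from duster.align2d import Align2DParams
from duster.duster_core import (DecoyLoopResult, EmptyRunError,
                                comprehensive_select, decoy_filter,
                                duplicate_select, duster_round,
                                iterative_decoy_filter, probability_filter,
                                run_duster, stack_subset)
from duster.align2d import ParticleStack, extract_particles
from duster.pickio import CurationConfig, RecenteredPickSet
from duster.synthgen import SimConfig, simulate_dataset

from conftest import recentered_from_points


def random_recentered(rng, n, run, n_mics=3, size=200.0, pixel_size=1.0):
    df = pd.DataFrame({
        "pick_id": [f"{run}:{i}" for i in range(n)],
        "micrograph_id": [f"mic_{rng.integers(n_mics):03d}"
                          for _ in range(n)],
        "x_ref": rng.uniform(0, size, n),
        "y_ref": rng.uniform(0, size, n),
        "dx": 0.0, "dy": 0.0, "class_id": 0, "class_prob": 1.0,
    })
    return RecenteredPickSet(df, pixel_size, source_run=run)


def brute_force_select(rA, rB, d_th, mode):
    """All-pairs O(n^2) oracle for duplicate_select kept sets."""
    keptA, keptB = set(), set()
    A, B = rA.df, rB.df

    def close(a, b):
        if a.micrograph_id != b.micrograph_id:
            return False
        d = np.hypot(a.x_ref - b.x_ref, a.y_ref - b.y_ref) * rA.pixel_size
        return d < d_th

    for a in A.itertuples(index=False):
        for b in B.itertuples(index=False):
            if close(a, b):
                keptA.add(a.pick_id)
                keptB.add(b.pick_id)
    if mode == "union":
        for df, kept in ((A, keptA), (B, keptB)):
            rows = list(df.itertuples(index=False))
            for i, a in enumerate(rows):
                for j, b in enumerate(rows):
                    if i != j and close(a, b):
                        kept.add(a.pick_id)
    return keptA, keptB


class TestDuplicateSelect:
    def test_identical_sets_all_kept(self):
        pts = [(10.0, 10.0), (50.0, 50.0)]
        rA = recentered_from_points(pts, run=1)
        rB = recentered_from_points(pts, run=2)
        m = duplicate_select(rA, rB, d_th_angstrom=1.0)
        assert m.kept_run1 == set(rA.pick_ids)
        assert m.kept_run2 == set(rB.pick_ids)
        assert not m.rejected_run1 and not m.rejected_run2

    def test_strict_inequality_boundary(self):
        rA = recentered_from_points([(0.0, 0.0)], run=1)
        kept = duplicate_select(
            rA, recentered_from_points([(0.0, 19.0)], run=2), 20.0)
        assert kept.kept_run1 == {"1:0"} and kept.kept_run2 == {"2:0"}
        rej = duplicate_select(
            rA, recentered_from_points([(0.0, 20.0)], run=2), 20.0)
        assert not rej.kept_run1 and not rej.kept_run2
        assert rej.rejected_run1 == {"1:0"}

    def test_threshold_in_angstrom_not_pixels(self):
        # 15 px apart at 2 A/px = 30 A: rejected at 20 A, kept at 31 A
        rA = recentered_from_points([(0.0, 0.0)], run=1, pixel_size=2.0)
        rB = recentered_from_points([(15.0, 0.0)], run=2, pixel_size=2.0)
        assert not duplicate_select(rA, rB, 20.0).kept_run1
        assert duplicate_select(rA, rB, 31.0).kept_run1 == {"1:0"}

    def test_singletons_always_rejected(self, rng):
        rA = random_recentered(rng, 30, run=1)
        rB = random_recentered(rng, 0, run=2)
        m = duplicate_select(rA, rB, 1e9)
        assert not m.kept_run1
        assert m.rejected_run1 == set(rA.pick_ids)

    def test_different_micrographs_never_match(self):
        rA = recentered_from_points([(10.0, 10.0)], run=1, mic="mic_000")
        rB = recentered_from_points([(10.0, 10.0)], run=2, mic="mic_001")
        m = duplicate_select(rA, rB, 1e6)
        assert not m.kept_run1 and not m.kept_run2

    def test_symmetry_mirrored_kept_sets(self, rng):
        rA = random_recentered(rng, 80, run=1)
        rB = random_recentered(rng, 80, run=2)
        m1 = duplicate_select(rA, rB, 15.0)
        m2 = duplicate_select(rB, rA, 15.0)
        assert m1.kept_run1 == m2.kept_run2
        assert m1.kept_run2 == m2.kept_run1

    def test_monotone_in_threshold(self, rng):
        rA = random_recentered(rng, 100, run=1)
        rB = random_recentered(rng, 100, run=2)
        prev1, prev2 = set(), set()
        for d_th in np.linspace(1.0, 60.0, 10):
            m = duplicate_select(rA, rB, float(d_th))
            assert prev1 <= m.kept_run1 and prev2 <= m.kept_run2
            prev1, prev2 = m.kept_run1, m.kept_run2

    def test_union_mode_keeps_same_run_neighbors(self):
        # two close picks of run 1, nothing in run 2 nearby
        rA = recentered_from_points([(10.0, 10.0), (12.0, 10.0)], run=1)
        rB = recentered_from_points([(150.0, 150.0)], run=2)
        cross = duplicate_select(rA, rB, 20.0, mode="cross_run")
        assert not cross.kept_run1
        union = duplicate_select(rA, rB, 20.0, mode="union")
        assert union.kept_run1 == set(rA.pick_ids)
        assert not union.kept_run2  # still a singleton

    @pytest.mark.parametrize("mode", ["cross_run", "union"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        for trial in range(25):
            rA = random_recentered(rng, int(rng.integers(0, 80)), run=1)
            rB = random_recentered(rng, int(rng.integers(1, 80)), run=2)
            d_th = float(rng.uniform(1.0, 40.0))
            m = duplicate_select(rA, rB, d_th, mode=mode)
            oA, oB = brute_force_select(rA, rB, d_th, mode)
            assert m.kept_run1 == oA and m.kept_run2 == oB
            # kept/rejected partition the inputs
            assert m.kept_run1 | m.rejected_run1 == set(rA.pick_ids)
            assert not m.kept_run1 & m.rejected_run1

    def test_pair_distances_below_threshold(self, rng):
        rA = random_recentered(rng, 100, run=1)
        rB = random_recentered(rng, 100, run=2)
        m = duplicate_select(rA, rB, 25.0)
        assert all(0.0 <= d < 25.0 for d in m.pair_distances)

    def test_pixel_size_mismatch_rejected(self):
        rA = recentered_from_points([(0.0, 0.0)], run=1, pixel_size=1.0)
        rB = recentered_from_points([(0.0, 0.0)], run=2, pixel_size=1.5)
        with pytest.raises(ValueError, match="pixel_size"):
            duplicate_select(rA, rB, 20.0)

    def test_unknown_mode_rejected(self):
        rA = recentered_from_points([(0.0, 0.0)], run=1)
        with pytest.raises(ValueError, match="mode"):
            duplicate_select(rA, rA, 20.0, mode="both")


@pytest.fixture(scope="module")
def small_scene():
    cfg = SimConfig(n_micrographs=3, mic_shape=(512, 512),
                    n_targets_per_mic=10, n_junk_picks_per_mic=10,
                    seed=17)
    return cfg, *simulate_dataset(cfg)


class TestRounds:
    params = Align2DParams(box_px=96, n_classes=4, max_shift_px=24,
                           n_iter=6)

    def test_counts_non_increasing_and_survivors_recentered(
            self, small_scene):
        cfg, mics, truth, psA, psB = small_scene
        res = duster_round(psA, psB, mics, self.params,
                           d_th_angstrom=20.0, seed=3)
        assert len(res.psA) <= len(psA) and len(res.psB) <= len(psB)
        # survivors carry the recentered coordinates
        merged = res.psA.df.merge(res.rpsA.df, on="pick_id")
        np.testing.assert_allclose(merged["x"], merged["x_ref"])
        np.testing.assert_allclose(merged["y"], merged["y_ref"])
        # and keep their original run/provenance metadata
        assert (res.psA.df["run_id"] == 1).all()
        assert set(res.psA.df["pick_id"]) == res.match.kept_run1

    def test_noise_free_round_keeps_every_true_pair(self):
        cfg = SimConfig(n_micrographs=2, mic_shape=(512, 512),
                        n_targets_per_mic=8, n_junk_picks_per_mic=0,
                        pick_jitter_sigma_px=0.0, noise_sigma=1e-3,
                        seed=29)
        mics, truth, psA, psB = simulate_dataset(cfg)
        res = duster_round(psA, psB, mics, self.params,
                           d_th_angstrom=20.0, seed=1)
        assert set(res.psA.pick_ids) == set(psA.pick_ids)
        assert set(res.psB.pick_ids) == set(psB.pick_ids)

    def test_round_improves_purity(self, small_scene):
        cfg, mics, truth, psA, psB = small_scene

        def purity(ps):
            return float((ps.df["source"] >= 0).mean())

        res = duster_round(psA, psB, mics, self.params,
                           d_th_angstrom=20.0, seed=3)
        assert purity(res.psA) > purity(psA)
        assert purity(res.psB) > purity(psB)

    def test_empty_input_rejected(self, small_scene):
        cfg, mics, truth, psA, psB = small_scene
        empty = psA.subset([])
        with pytest.raises(EmptyRunError, match="nonempty"):
            duster_round(empty, psB, mics, self.params, 20.0)

    def test_run_duster_one_round_equals_duster_round(self, small_scene):
        cfg, mics, truth, psA, psB = small_scene
        ccfg = CurationConfig(d_th_angstrom=20.0, n_rounds=1, seed=3)
        keptA, keptB, hist = run_duster(psA, psB, mics, ccfg, self.params)
        res = duster_round(psA, psB, mics, self.params, 20.0,
                           mode=ccfg.match_mode, seed=3, round_index=0)
        assert set(keptA.pick_ids) == set(res.psA.pick_ids)
        assert set(keptB.pick_ids) == set(res.psB.pick_ids)
        assert len(hist.rounds) == 1

    def test_run_duster_history_monotone_and_deterministic(
            self, small_scene):
        cfg, mics, truth, psA, psB = small_scene
        ccfg = CurationConfig(d_th_angstrom=20.0, n_rounds=2, seed=5)
        kA1, kB1, h1 = run_duster(psA, psB, mics, ccfg, self.params)
        kA2, kB2, h2 = run_duster(psA, psB, mics, ccfg, self.params)
        assert [r.n_out for r in h1.rounds] == [r.n_out for r in h2.rounds]
        assert kA1.pick_ids == kA2.pick_ids
        outs = [r.n_out for r in h1.rounds]
        ins = [r.n_in for r in h1.rounds]
        assert all(o <= i for o, i in zip(outs, ins))
        assert ins[1] == outs[0]


class TestDuplicatedFilters:
    def test_probability_filter_duplicated_rule(self):
        probsA = {"p": 0.25, "q": 0.25, "r": 0.30}
        probsB = {"p": 0.28, "q": 0.35, "r": 0.29}
        kept = probability_filter(probsA, probsB, threshold=0.3)
        assert kept == {"q", "r"}  # p removed; 0.30 not < 0.3

    def test_probability_filter_single_replicate_kept(self):
        kept = probability_filter({"a": 0.01}, {"b": 0.01}, 0.3)
        assert kept == {"a", "b"}

    def test_decoy_filter_duplicated_rule(self):
        kept = decoy_filter({"p": "decoy", "q": "decoy"},
                            {"p": "decoy", "q": "target"}, {"decoy"})
        assert kept == {"q"}

    def test_decoy_filter_empty_labels_identity(self):
        kept = decoy_filter({"p": "decoy"}, {"p": "decoy"}, set())
        assert kept == {"p"}

    def test_probability_filter_matches_brute_force(self):
        rng = np.random.default_rng(8)
        ids = [f"id{i}" for i in range(1000)]
        pA = {i: float(rng.uniform()) for i in ids}
        pB = {i: float(rng.uniform()) for i in ids}
        kept = probability_filter(pA, pB, 0.3)
        expected = {i for i in ids
                    if not (pA[i] < 0.3 and pB[i] < 0.3)}
        assert kept == expected

    def test_decoy_filter_matches_brute_force(self):
        rng = np.random.default_rng(9)
        labels = ["target", "decoy1", "decoy2"]
        ids = [f"id{i}" for i in range(500)]
        aA = {i: labels[rng.integers(3)] for i in ids}
        aB = {i: labels[rng.integers(3)] for i in ids}
        decoys = {"decoy1", "decoy2"}
        kept = decoy_filter(aA, aB, decoys)
        expected = {i for i in ids
                    if not (aA[i] in decoys and aB[i] in decoys)}
        assert kept == expected


class TestIterativeDecoyFilter:
    def make_stack(self, rng, n_target, n_junk, box=48):
        yy, xx = np.mgrid[0:box, 0:box]
        t = np.clip(6.5 - np.hypot(yy - box // 2, xx - box // 2), 0, 1)
        images = [6.0 * t + rng.normal(size=(box, box))
                  for _ in range(n_target)]
        images += [rng.normal(size=(box, box)) for _ in range(n_junk)]
        arr = np.asarray(images)
        return ParticleStack(arr, [f"1:{i}" for i in range(len(arr))],
                             1.0, box), t

    def test_already_pure_stops_after_one_round(self, rng):
        stack, ref = self.make_stack(rng, 60, 2)
        res = iterative_decoy_filter(stack, K_decoy=2, max_shift_px=8,
                                     seed=1, target_fraction=0.9,
                                     target_reference=ref)
        assert res.converged
        assert len(res.fractions) == 1
        assert res.kept_ids == list(stack.pick_ids)

    def test_max_rounds_zero_identity_not_converged(self, rng):
        stack, _ = self.make_stack(rng, 10, 10)
        res = iterative_decoy_filter(stack, K_decoy=2, max_shift_px=8,
                                     seed=1, max_rounds=0)
        assert res.kept_ids == list(stack.pick_ids)
        assert not res.converged and res.fractions == []

    def test_fractions_non_decreasing_on_mixture(self, rng):
        stack, ref = self.make_stack(rng, 60, 40)
        res = iterative_decoy_filter(stack, K_decoy=3, max_shift_px=8,
                                     seed=2, target_fraction=0.9,
                                     target_reference=ref)
        assert all(b >= a - 1e-12
                   for a, b in zip(res.fractions, res.fractions[1:]))
        assert res.converged

    def test_invalid_target_fraction_rejected(self, rng):
        stack, _ = self.make_stack(rng, 4, 0)
        with pytest.raises(ValueError, match="target_fraction"):
            iterative_decoy_filter(stack, 1, 8, 0, target_fraction=0.0)


class TestComprehensiveSelect:
    def jittered_replicas(self, rng, base_points, run, sigma=2.0):
        return [recentered_from_points(
            [(x + rng.normal(0, sigma), y + rng.normal(0, sigma))
             for x, y in base_points], run=run) for _ in range(3)]

    def test_identical_replicas_equal_single_select(self, rng):
        rA = random_recentered(rng, 50, run=1)
        rB = random_recentered(rng, 50, run=2)
        single = duplicate_select(rA, rB, 15.0)
        for rule in ("all", "any", "majority"):
            out = comprehensive_select([rA] * 3, [rB] * 3, 15.0, rule=rule)
            assert out["run1"] == single.kept_run1
            assert out["run2"] == single.kept_run2

    def test_inclusion_chain(self, rng):
        base = [(rng.uniform(30, 170), rng.uniform(30, 170))
                for _ in range(40)]
        for _ in range(10):
            setsA = self.jittered_replicas(rng, base, run=1)
            setsB = self.jittered_replicas(rng, base, run=2)
            kept = {rule: comprehensive_select(setsA, setsB, 8.0,
                                               rule=rule)
                    for rule in ("all", "majority", "any")}
            for run in ("run1", "run2"):
                assert kept["all"][run] <= kept["majority"][run]
                assert kept["majority"][run] <= kept["any"][run]

    def test_wrong_replica_count_rejected(self, rng):
        rA = random_recentered(rng, 5, run=1)
        rB = random_recentered(rng, 5, run=2)
        with pytest.raises(ValueError, match="3 replicate"):
            comprehensive_select([rA] * 2, [rB] * 3, 10.0)
        out = comprehensive_select([rA] * 2, [rB] * 2, 10.0,
                                   allow_general=True)
        assert set(out) == {"run1", "run2"}
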