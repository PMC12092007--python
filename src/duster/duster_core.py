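"""Reproducibility-based particle curation.

The curation rests on one observation: particles with enough signal are
recentered to the same place no matter which picking run they entered
classification from, while picks sitting on background noise recenter to
essentially random offsets.  Measuring the distance D between the
recentered points of the two independent picking runs and keeping only
points with D strictly below a threshold D_TH therefore separates real
particles from rubbish without requiring interpretable class averages.

This module implements that selection (single-shot and iterated rounds),
plus the companion duplicated filters: class-probability filtering
(removed only when below the cutoff in both replicate classifications),
duplicated decoy removal, the iterative decoy loop with its >90%
stopping rule, and the comprehensive mode that aggregates the selection
over all nine combinations of three replicate runs per picking set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pickio import (CurationConfig, CurationHistory, PickSet,
                     RecenteredPickSet, RoundRecord)
from .align2d import (Align2DParams, Classification, ParticleStack,
                      classify2d, extract_particles, recenter,
                      select_classes)

__all__ = [
    "MatchResult",
    "RoundResult",
    "DecoyLoopResult",
    "EmptyRunError",
    "duplicate_select",
    "duster_round",
    "run_duster",
    "probability_filter",
    "decoy_filter",
    "iterative_decoy_filter",
    "comprehensive_select",
    "stack_subset",
]


class EmptyRunError(RuntimeError):
    """A picking run lost all its picks during curation."""


@dataclass
class MatchResult:
    """Outcome of one cross-run duplicate selection.

    ``pairs`` lists every qualifying cross-run pair as
    ``(id_run1, id_run2, distance_angstrom)`` with distance strictly below
    the threshold; kept/rejected partition the input ids of each run.
    """

    kept_run1: set[str]
    kept_run2: set[str]
    pairs: list[tuple[str, str, float]]
    rejected_run1: set[str]
    rejected_run2: set[str]

    @property
    def pair_distances(self) -> list[float]:
        return [d for _, _, d in self.pairs]


def _per_micrograph(df: pd.DataFrame):
    for mic_id, grp in df.groupby("micrograph_id", sort=True):
        yield mic_id, grp


def duplicate_select(rA: RecenteredPickSet, rB: RecenteredPickSet,
                     d_th_angstrom: float,
                     mode: str = "cross_run") -> MatchResult:
    """Keep recentered points that are reproduced by the other run.

    A point passes in ``cross_run`` mode iff some point of the *other* run
    on the same micrograph lies at Euclidean distance (in angstrom)
    strictly below ``d_th_angstrom``; ``union`` mode keeps a point iff
    *any* other point of either run does, reproducing the behaviour of a
    duplicate-removal tool that cannot distinguish runs.  Points with no
    counterpart (singletons) are always rejected.  Points on different
    micrographs never match.
    """
    if mode not in ("cross_run", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    if rA.pixel_size != rB.pixel_size:
        raise ValueError(
            f"pixel_size mismatch: {rA.pixel_size} vs {rB.pixel_size}")
    d_th_px = d_th_angstrom / rA.pixel_size

    idsA = rA.df["pick_id"].to_numpy()
    idsB = rB.df["pick_id"].to_numpy()
    keptA: set[str] = set()
    keptB: set[str] = set()
    pairs: list[tuple[str, str, float]] = []

    groupsA = {m: g for m, g in _per_micrograph(rA.df)}
    groupsB = {m: g for m, g in _per_micrograph(rB.df)}
    for mic_id in sorted(set(groupsA) | set(groupsB)):
        gA = groupsA.get(mic_id)
        gB = groupsB.get(mic_id)
        xyA = (gA[["x_ref", "y_ref"]].to_numpy(float)
               if gA is not None else np.empty((0, 2)))
        xyB = (gB[["x_ref", "y_ref"]].to_numpy(float)
               if gB is not None else np.empty((0, 2)))
        aids = gA["pick_id"].to_numpy() if gA is not None else np.empty(0, object)
        bids = gB["pick_id"].to_numpy() if gB is not None else np.empty(0, object)

        # cross-run pairs (reported in both modes)
        mic_pairs: list[tuple[str, str, float]] = []
        if len(xyA) and len(xyB):
            tree = cKDTree(xyB)
            for i, neighbors in enumerate(
                    tree.query_ball_point(xyA, r=d_th_px)):
                for j in sorted(neighbors):
                    d_px = float(np.hypot(*(xyA[i] - xyB[j])))
                    if d_px * rA.pixel_size < d_th_angstrom:  # strict
                        mic_pairs.append((aids[i], bids[j],
                                          d_px * rA.pixel_size))
        pairs.extend(mic_pairs)
        if mode == "cross_run":
            keptA.update(p[0] for p in mic_pairs)
            keptB.update(p[1] for p in mic_pairs)
        else:  # union: any other point of either run within the threshold
            xy = np.vstack([xyA, xyB])
            ids = np.concatenate([aids, bids])
            if len(xy) >= 2:
                tree = cKDTree(xy)
                for i, j in tree.query_pairs(r=d_th_px):
                    d_px = float(np.hypot(*(xy[i] - xy[j])))
                    if d_px * rA.pixel_size < d_th_angstrom:
                        for k in (i, j):
                            (keptA if k < len(xyA) else keptB).add(ids[k])
    return MatchResult(
        kept_run1=keptA, kept_run2=keptB, pairs=pairs,
        rejected_run1=set(idsA) - keptA, rejected_run2=set(idsB) - keptB)


# ---------------------------------------------------------------------------
# Rounds
# ---------------------------------------------------------------------------

@dataclass
class RoundResult:
    """One curation round: surviving picks (carrying recentered
    coordinates), the match outcome, and the per-run classifications."""

    psA: PickSet
    psB: PickSet
    match: MatchResult
    clsA: Classification
    clsB: Classification
    rpsA: RecenteredPickSet
    rpsB: RecenteredPickSet
    n_in: int

    def __iter__(self):  # allow (psA, psB, match) unpacking
        return iter((self.psA, self.psB, self.match))


def _survivors(ps: PickSet, rps: RecenteredPickSet,
               kept_ids: set[str]) -> PickSet:
    """Build the next round's PickSet from survivors, replacing the
    original coordinates with the recentered ones."""
    keep = rps.df[rps.df["pick_id"].isin(kept_ids)]
    base = ps.df.set_index("pick_id").loc[keep["pick_id"]]
    df = pd.DataFrame({
        "pick_id": keep["pick_id"].to_numpy(),
        "micrograph_id": keep["micrograph_id"].to_numpy(),
        "run_id": base["run_id"].to_numpy(),
        "x": keep["x_ref"].to_numpy(float),
        "y": keep["y_ref"].to_numpy(float),
    })
    if "source" in ps.df.columns:
        df["source"] = base["source"].to_numpy()
    return PickSet(df, ps.pixel_size, ps.provenance)


def duster_round(psA: PickSet, psB: PickSet,
                 micrographs: Mapping[str, np.ndarray],
                 params: Align2DParams, d_th_angstrom: float,
                 mode: str = "cross_run", seed: int = 0,
                 round_index: int = 0,
                 class_select: Callable | None = None) -> RoundResult:
    """One full curation round.

    Each run is independently classified and recentered (per-run seeds
    derived as ``seed + round_index * 2 + run_index``), then the cross-run
    duplicate selection is applied; survivors carry their recentered
    coordinates into the next round.  Counts are non-increasing.
    """
    if len(psA) == 0 or len(psB) == 0:
        raise EmptyRunError("both picking runs must be nonempty")
    n_in = len(psA) + len(psB)
    recentered = []
    classifications = []
    for run_index, ps in enumerate((psA, psB)):
        stack = extract_particles(micrographs, ps, params.box_px,
                                  normalize=params.normalize)
        if len(stack) == 0:
            raise EmptyRunError(
                f"run {run_index + 1}: every pick was dropped at extraction")
        cls = classify2d(stack, K=params.n_classes,
                         max_shift_px=params.max_shift_px,
                         n_iter=params.n_iter,
                         seed=seed + round_index * 2 + run_index)
        rps = recenter(ps, cls)
        if class_select is not None:
            keep_classes = class_select(round_index=round_index,
                                        run_id=run_index + 1, cls=cls,
                                        rps=rps)
            if keep_classes is not None:
                rps = select_classes(rps, cls, set(keep_classes))
        recentered.append(rps)
        classifications.append(cls)
    rpsA, rpsB = recentered
    match = duplicate_select(rpsA, rpsB, d_th_angstrom, mode)
    psA2 = _survivors(psA, rpsA, match.kept_run1)
    psB2 = _survivors(psB, rpsB, match.kept_run2)
    if len(psA2) == 0 or len(psB2) == 0:
        raise EmptyRunError(
            "a picking run became empty during duplicate selection; "
            "consider relaxing d_th_angstrom")
    return RoundResult(psA2, psB2, match, classifications[0],
                       classifications[1], rpsA, rpsB, n_in)


def run_duster(psA: PickSet, psB: PickSet,
               micrographs: Mapping[str, np.ndarray],
               cfg: CurationConfig, params: Align2DParams,
               class_select: Callable | None = None
               ) -> tuple[PickSet, PickSet, CurationHistory]:
    """Run ``cfg.n_rounds`` curation rounds and record the history.

    Deterministic under ``cfg.seed``; each round classifies both runs
    afresh on the survivors of the previous round.
    """
    history = CurationHistory()
    curA, curB = psA, psB
    for round_index in range(cfg.n_rounds):
        result = duster_round(curA, curB, micrographs, params,
                              cfg.d_th_angstrom, cfg.match_mode,
                              seed=cfg.seed, round_index=round_index,
                              class_select=class_select)
        curA, curB = result.psA, result.psB
        history.append(RoundRecord(
            kept_ids_run1=sorted(result.match.kept_run1),
            kept_ids_run2=sorted(result.match.kept_run2),
            pair_distances=sorted(result.match.pair_distances),
            n_in=result.n_in,
            n_out=len(curA) + len(curB)))
    return curA, curB, history


# ---------------------------------------------------------------------------
# Duplicated filters
# ---------------------------------------------------------------------------

def probability_filter(probsA: Mapping[str, float],
                       probsB: Mapping[str, float],
                       threshold: float = 0.3) -> set[str]:
    """Duplicated class-probability filter.

    A particle is removed iff its class probability is strictly below the
    threshold in *both* replicate classifications; an id present in only
    one replicate cannot satisfy the condition and is kept.
    """
    kept = set()
    for pid in set(probsA) | set(probsB):
        if pid in probsA and pid in probsB \
                and probsA[pid] < threshold and probsB[pid] < threshold:
            continue
        kept.add(pid)
    return kept


def decoy_filter(assignA: Mapping[str, object],
                 assignB: Mapping[str, object],
                 decoy_labels: set) -> set[str]:
    """Duplicated decoy removal: an id is removed only when it is assigned
    to a decoy class in *both* replicate runs (a single-run decoy call
    never removes a particle)."""
    kept = set()
    for pid in set(assignA) | set(assignB):
        if pid in assignA and pid in assignB \
                and assignA[pid] in decoy_labels \
                and assignB[pid] in decoy_labels:
            continue
        kept.add(pid)
    return kept


# ---------------------------------------------------------------------------
# Iterative decoy loop
# ---------------------------------------------------------------------------

@dataclass
class DecoyLoopResult:
    kept_ids: list[str]
    fractions: list[float]  # target-class fraction per round
    converged: bool


def stack_subset(stack: ParticleStack, keep_ids) -> ParticleStack:
    keep = set(keep_ids)
    mask = np.array([pid in keep for pid in stack.pick_ids], dtype=bool)
    return ParticleStack(stack.images[mask],
                         [p for p, m in zip(stack.pick_ids, mask) if m],
                         stack.pixel_size, stack.box_px)


def iterative_decoy_filter(stack: ParticleStack, K_decoy: int,
                           max_shift_px: int, seed: int,
                           target_fraction: float = 0.9,
                           max_rounds: int = 10,
                           target_reference: np.ndarray | None = None
                           ) -> DecoyLoopResult:
    """Iterated decoy classification with a stopping rule.

    Each round classifies the survivors against one target reference plus
    ``K_decoy`` decoy references — deliberately wrong references, drawn
    as seeded Gaussian noise images, so that only particles genuinely
    resembling the target stay in the target class — and removes the
    decoy-assigned particles.  Each round is a single-pass reference
    classification: the deliberately wrong references are not refined
    toward the data.  The loop stops once the target-class fraction
    exceeds ``target_fraction`` (the classic "more than 90% of
    particles" rule) or after ``max_rounds``.  The target reference is
    ``target_reference`` when given, else the mean of the surviving
    particles (the dominant motif).
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in (0, 1]")
    if K_decoy < 1:
        raise ValueError("K_decoy must be >= 1")
    box = stack.box_px
    current = stack
    fractions: list[float] = []
    converged = False
    for rnd in range(max_rounds):
        if len(current) == 0:
            break
        rng = np.random.default_rng([seed, rnd])
        ref = (np.asarray(target_reference, dtype=np.float64)
               if target_reference is not None
               else current.images.mean(axis=0))
        decoys = rng.normal(size=(K_decoy, box, box))
        init = np.concatenate([ref[None], decoys], axis=0)
        K = min(1 + K_decoy, len(current))
        cls = classify2d(current, K=K,
                         max_shift_px=max_shift_px, n_iter=1,
                         seed=seed + rnd, init_averages=init[:K])
        in_target = cls.class_ids == 0  # class 0 is the target reference
        fraction = float(in_target.mean())
        fractions.append(fraction)
        if fraction > target_fraction:
            converged = True
            break
        keep_ids = [pid for pid, m in zip(cls.pick_ids, in_target) if m]
        current = stack_subset(current, keep_ids)
    return DecoyLoopResult(kept_ids=list(current.pick_ids),
                           fractions=fractions, converged=converged)


# ---------------------------------------------------------------------------
# Comprehensive (nine-combination) mode
# ---------------------------------------------------------------------------

def comprehensive_select(setsA: Sequence[RecenteredPickSet],
                         setsB: Sequence[RecenteredPickSet],
                         d_th_angstrom: float, rule: str = "all",
                         mode: str = "cross_run",
                         allow_general: bool = False
                         ) -> dict[str, set[str]]:
    """Aggregate the duplicate selection over all replicate combinations.

    With three replicate recentered sets per run, the selection is
    evaluated on each of the nine (A_i, B_j) pairs and a pick is kept per
    ``rule``: ``all`` (kept in every pair, the strictest reading),
    ``any`` (kept in at least one), or ``majority`` (kept in more than
    half, i.e. >= 5 of 9).  Returns ``{"run1": kept_ids, "run2": kept_ids}``.
    """
    if rule not in ("all", "any", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    if not allow_general and (len(setsA) != 3 or len(setsB) != 3):
        raise ValueError(
            "expected 3 replicate sets per run (pass allow_general=True "
            "for other shapes)")
    n_pairs = len(setsA) * len(setsB)
    countsA: dict[str, int] = {}
    countsB: dict[str, int] = {}
    for sA in setsA:
        for sB in setsB:
            match = duplicate_select(sA, sB, d_th_angstrom, mode)
            for pid in match.kept_run1:
                countsA[pid] = countsA.get(pid, 0) + 1
            for pid in match.kept_run2:
                countsB[pid] = countsB.get(pid, 0) + 1
    need = {"all": n_pairs, "any": 1,
            "majority": n_pairs // 2 + 1}[rule]
    return {
        "run1": {pid for pid, c in countsA.items() if c >= need},
        "run2": {pid for pid, c in countsB.items() if c >= need},
    }
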