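"""Multi-reference translational 2D classification.

A deliberately small alignment engine: K class averages, integer-pixel
translational search by FFT cross-correlation, soft class assignment via a
fixed-temperature softmax over the per-class correlation scores.  Its job
is to supply the two things the downstream curation consumes — recentering
shifts and class probabilities — not to be a full single-particle
classification stack (no rotation search by default, no CTF).

Sign convention: a particle's best shift is its offset from the extraction
window center, so adding the shift to the pick coordinate moves the pick
onto the particle center.  A pick displaced (+3, -2) px from the true
particle center therefore gets shift (-3, +2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pickio import PickSet, RecenteredPickSet

__all__ = [
    "ParticleStack",
    "Classification",
    "Align2DParams",
    "extract_particles",
    "classify2d",
    "recenter",
    "select_classes",
]


@dataclass
class ParticleStack:
    """Windowed particle images extracted around picks."""

    images: np.ndarray  # (N, box, box) float
    pick_ids: list[str]
    pixel_size: float
    box_px: int
    dropped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.pick_ids)
        if self.images.shape != (n, self.box_px, self.box_px):
            raise ValueError(
                f"images shape {self.images.shape} inconsistent with "
                f"{n} picks of box {self.box_px}")

    def __len__(self) -> int:
        return len(self.pick_ids)


@dataclass
class Classification:
    """Result of one classification run.

    ``shifts`` are integer window shifts (dy applied to rows, dx to
    columns) bounded by the search radius; ``probs`` rows sum to one and
    ``class_ids`` is the row argmax (ties to the lowest index).
    """

    K: int
    class_averages: np.ndarray  # (K, box, box)
    shifts: np.ndarray          # (N, 2) as (dx, dy), integer-valued
    class_ids: np.ndarray       # (N,) int in [0, K)
    probs: np.ndarray           # (N, K)
    pick_ids: list[str]
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        row_sums = self.probs.sum(axis=1)
        if len(row_sums) and np.abs(row_sums - 1.0).max() > 1e-9:
            raise ValueError("probability rows must sum to 1")

    def max_probs(self) -> np.ndarray:
        return self.probs[np.arange(len(self.class_ids)), self.class_ids]


@dataclass
class Align2DParams:
    """Engine knobs shared by the round-based curation driver."""

    box_px: int = 96
    n_classes: int = 6
    max_shift_px: int = 24
    n_iter: int = 8
    normalize: bool = True


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_particles(micrographs: Mapping[str, np.ndarray], ps: PickSet,
                      box_px: int, normalize: bool = True) -> ParticleStack:
    """Extract ``box_px`` windows centered on the rounded pick coordinates.

    Picks whose window would cross a micrograph edge are dropped and
    reported in ``dropped_ids``.  With ``normalize`` each window is scaled
    to zero mean and unit variance (a zero-variance window is left at
    zero, with a warning).
    """
    if box_px % 2 != 0:
        raise ValueError("box_px must be even")
    half = box_px // 2
    for mic_id, img in micrographs.items():
        if box_px > min(img.shape):
            raise ValueError(
                f"box_px={box_px} exceeds micrograph {mic_id} "
                f"shape {img.shape}")
    images, kept_ids, dropped = [], [], []
    for row in ps.df.itertuples(index=False):
        img = micrographs[row.micrograph_id]
        h, w = img.shape
        cy, cx = int(round(row.y)), int(round(row.x))
        if cy - half < 0 or cy + half > h or cx - half < 0 or cx + half > w:
            dropped.append(row.pick_id)
            continue
        win = np.asarray(img[cy - half:cy + half, cx - half:cx + half],
                         dtype=np.float64)
        if normalize:
            sd = win.std()
            if sd == 0:
                import warnings
                warnings.warn(f"zero-variance window for pick {row.pick_id}",
                              stacklevel=2)
                win = np.zeros_like(win)
            else:
                win = (win - win.mean()) / sd
        images.append(win)
        kept_ids.append(row.pick_id)
    stack = (np.stack(images) if images
             else np.empty((0, box_px, box_px)))
    return ParticleStack(stack, kept_ids, ps.pixel_size, box_px,
                         dropped_ids=dropped)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _shift_window_indices(box: int, max_shift: int):
    """Index grids selecting the (2m+1)^2 shift window from a circular
    correlation map, ordered so ties resolve to the lexicographically
    smallest (dy, dx)."""
    offsets = np.arange(-max_shift, max_shift + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    return dy.ravel(), dx.ravel(), (dy % box).ravel(), (dx % box).ravel()


def _correlate_all(stack_fts: np.ndarray, avg: np.ndarray,
                   box: int, idx_y, idx_x) -> np.ndarray:
    """Circular cross-correlation of every particle with one average,
    evaluated on the shift window only.  Entry s of the returned (N, S)
    array is sum_p image[p + s] * avg[p]."""
    avg_ft = np.conj(np.fft.rfft2(avg))
    corr = np.fft.irfft2(stack_fts * avg_ft[None, :, :], s=(box, box))
    return corr[:, idx_y, idx_x]


def _normalize_avg(avg: np.ndarray) -> np.ndarray:
    a = avg - avg.mean()
    norm = np.linalg.norm(a)
    return a / norm if norm > 0 else a


def _center_average(avg: np.ndarray) -> np.ndarray:
    """Roll a class average so its energy centroid sits at the zero-shift
    reference (box // 2, box // 2).

    Without this the alignment reference is only defined up to an
    arbitrary common offset, which would bias recovered centers (and
    therefore cross-run distances) by a constant per classification run.
    Energy (squared intensity) is used because windows are zero-mean.
    """
    box = avg.shape[0]
    e = avg ** 2
    mass = e.sum()
    if mass <= 0:
        return avg
    yy, xx = np.mgrid[0:box, 0:box]
    cy = (e * yy).sum() / mass
    cx = (e * xx).sum() / mass
    ref = box // 2
    return np.roll(avg, (int(round(ref - cy)), int(round(ref - cx))),
                   axis=(0, 1))


def classify2d(stack: ParticleStack, K: int, max_shift_px: int,
               n_iter: int, seed: int,
               init_averages: np.ndarray | None = None) -> Classification:
    """Iterative multi-reference translational alignment.

    Starts from a seeded random partition; each iteration scores every
    particle against every class average by best integer-shift normalized
    cross-correlation over a ``(2*max_shift+1)^2`` window (via FFT),
    soft-assigns classes with ``softmax(score / T)`` at fixed temperature
    ``T = 1 / box_px``, takes each particle's shift as the best shift of
    its argmax class, and rebuilds averages as probability-weighted
    means of the recentered particles.  Stops early once fewer than 0.1%
    of class assignments change.  Deterministic for a fixed seed.

    ``init_averages`` (K x box x box) replaces the random-partition
    initialization with fixed starting references; with ``n_iter=1`` this
    is a single-pass reference classification (used for decoy
    classification against deliberately wrong references).
    """
    N, box = len(stack), stack.box_px
    if K < 1 or K > N:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    if max_shift_px > box // 4:
        raise ValueError("max_shift_px must be <= box_px / 4")
    images = np.asarray(stack.images, dtype=np.float64)
    norms = np.linalg.norm(images.reshape(N, -1), axis=1)
    if np.all(norms == 0):
        raise ValueError("degenerate input: all-zero particle stack")
    safe_norms = np.where(norms > 0, norms, 1.0)
    unit = images / safe_norms[:, None, None]
    stack_fts = np.fft.rfft2(unit)

    dy_off, dx_off, idx_y, idx_x = _shift_window_indices(box, max_shift_px)
    temperature = 1.0 / box

    rng = np.random.default_rng(seed)
    if init_averages is not None:
        init_averages = np.asarray(init_averages, dtype=np.float64)
        if init_averages.shape != (K, box, box):
            raise ValueError(
                f"init_averages must have shape {(K, box, box)}, "
                f"got {init_averages.shape}")
        averages = np.stack([_center_average(a) for a in init_averages])
        class_ids = np.zeros(N, dtype=int)
    else:
        labels = rng.permutation(np.arange(N) % K)  # random partition
        averages = np.stack([
            _center_average(images[labels == k].mean(axis=0))
            if np.any(labels == k) else np.zeros((box, box))
            for k in range(K)])
        class_ids = labels.copy()
    best_shift_flat = np.zeros(N, dtype=int)
    scores = np.zeros((N, K))
    iterations_run = 0
    for it in range(max(n_iter, 1)):
        iterations_run = it + 1
        best_flat_per_class = np.empty((N, K), dtype=int)
        for k in range(K):
            corr = _correlate_all(stack_fts, _normalize_avg(averages[k]),
                                  box, idx_y, idx_x)
            # first-maximum argmax => lexicographically smallest (dy, dx)
            best_flat_per_class[:, k] = np.argmax(corr, axis=1)
            scores[:, k] = corr[np.arange(N), best_flat_per_class[:, k]]
        new_ids = np.argmax(scores, axis=1)  # ties -> lowest class index

        # soft assignment at fixed temperature
        logits = scores / temperature
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)

        best_shift_flat = best_flat_per_class[np.arange(N), new_ids]

        # M-step: probability-weighted mean of recentered particles
        dy = dy_off[best_shift_flat]
        dx = dx_off[best_shift_flat]
        recentered = np.empty_like(images)
        for i in range(N):
            recentered[i] = np.roll(images[i], (-dy[i], -dx[i]),
                                    axis=(0, 1))
        new_averages = np.einsum("nk,nij->kij", probs, recentered)
        weights = probs.sum(axis=0)
        for k in range(K):
            if weights[k] > 1e-12:
                new_averages[k] /= weights[k]
            else:
                # empty-class repair: re-seed with the worst-matched particle
                worst = int(np.argmin(scores.max(axis=1)))
                new_averages[k] = recentered[worst]
            new_averages[k] = _center_average(new_averages[k])
        averages = new_averages

        n_changed = int(np.sum(new_ids != class_ids))
        class_ids = new_ids
        if it > 0 and n_changed < max(1, 0.001 * N):
            break

    shifts = np.stack([dx_off[best_shift_flat],
                       dy_off[best_shift_flat]], axis=1)
    return Classification(K=K, class_averages=averages, shifts=shifts,
                          class_ids=class_ids, probs=probs,
                          pick_ids=list(stack.pick_ids),
                          n_iter=iterations_run, seed=seed)


# ---------------------------------------------------------------------------
# Recentering and class selection
# ---------------------------------------------------------------------------

def recenter(ps: PickSet, cls: Classification) -> RecenteredPickSet:
    """Apply classification shifts to the picks.

    The refined center is ``round(pick) + integer_shift`` (extraction
    windows are centered on the rounded pick), so the stored per-pick
    offset ``dx = x_ref - x`` folds in the rounding residual and
    ``x_ref = x + dx`` holds exactly.  Picks dropped at extraction are
    absent from the output.
    """
    ps_ids = set(ps.pick_ids)
    unknown = [i for i in cls.pick_ids if i not in ps_ids]
    if unknown:
        raise ValueError(
            f"classification refers to picks absent from the pick set: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    rows = ps.df.set_index("pick_id").loc[cls.pick_ids]
    x = rows["x"].to_numpy(float)
    y = rows["y"].to_numpy(float)
    x_ref = np.round(x) + cls.shifts[:, 0]
    y_ref = np.round(y) + cls.shifts[:, 1]
    df = {
        "pick_id": cls.pick_ids,
        "micrograph_id": rows["micrograph_id"].to_numpy(),
        "x_ref": x_ref,
        "y_ref": y_ref,
        "dx": x_ref - x,
        "dy": y_ref - y,
        "class_id": cls.class_ids.astype(int),
        "class_prob": cls.max_probs(),
    }
    out = pd.DataFrame(df)
    if "source" in ps.df.columns:
        out["source"] = rows["source"].to_numpy()
    run = int(rows["run_id"].iloc[0]) if len(rows) else 0
    return RecenteredPickSet(out, ps.pixel_size, source_run=run)


def select_classes(rps: RecenteredPickSet, cls: Classification,
                   keep_classes: set[int]) -> RecenteredPickSet:
    """Keep only picks assigned to the given classes (order preserved)."""
    if not keep_classes:
        raise ValueError("keep_classes must name at least one class")
    bad = [k for k in keep_classes if not 0 <= k < cls.K]
    if bad:
        raise ValueError(f"class ids out of range [0, {cls.K}): {bad}")
    keep = rps.df["class_id"].isin(keep_classes)
    return RecenteredPickSet(rps.df[keep].copy(), rps.pixel_size,
                             rps.source_run)
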