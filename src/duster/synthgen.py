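"""Synthetic micrograph and picking simulator.

Generates the statistical structure the reproducibility-based curation
assumes: micrographs of Gaussian background noise containing radially
structured target particles of controlled contrast, and two independent
picking runs.  Each run picks every true particle with Gaussian jitter
and additionally hallucinates its own false picks on empty background.

Two properties of real independent pickers are modelled explicitly:

* **Independent false positives.**  Two pickers built from different
  templates or models agree on real particles but their false positives
  are artifacts of each picker and land at uncorrelated locations.
* **Non-maximum suppression.**  A picker emits at most one pick per
  particle-sized neighbourhood, so false picks never sit within a
  particle diameter of a true pick (a pick that close to a particle *is*
  a pick of that particle).

High-contrast targets recenter reproducibly during alignment; false
picks on background noise do not — that contrast in recentering
reproducibility is exactly what the curation exploits, so the generator
is the benchmark for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pickio import PickSet, write_truth_csv
from .mrcio import write_mrc

__all__ = [
    "SimConfig",
    "PlacementError",
    "make_template",
    "simulate_micrographs",
    "simulate_picking",
    "simulate_dataset",
    "render_scene",
    "write_dataset",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of particles at the requested
    minimum separation within the retry budget."""


@dataclass
class SimConfig:
    """Parameters of the synthetic scene.

    ``target_amplitude`` is the mean peak contrast of a target relative to
    the noise standard deviation ``noise_sigma`` (so amplitude 6 on sigma 1
    is a peak S/N of about 6 for a flat disc template); individual target
    amplitudes are drawn uniformly in ``target_amplitude +/-
    target_amplitude_spread`` so that contrast-stratified diagnostics are
    non-degenerate.

    Junk is modelled in two selectable regimes via ``junk_amplitude``:

    * ``junk_amplitude == 0`` (default, "pure-noise picks"): junk picks
      are hallucinations of each picker, not scene objects.  Each run
      places ``n_junk_picks_per_mic`` of its own false picks per
      micrograph, independently, on background noise at least
      ``min_separation_px`` from every true particle (the picker's
      non-maximum-suppression radius) and from its other false picks.
    * ``junk_amplitude > 0`` ("faint particles"): junk rows are real
      faint particles rendered into the scene, which both runs then
      pick like targets.
    """

    n_micrographs: int = 20
    mic_shape: tuple[int, int] = (1024, 1024)  # (height, width) px
    pixel_size: float = 1.0  # angstrom / px
    n_targets_per_mic: int = 30
    n_junk_picks_per_mic: int = 30
    template_kind: str = "disc"  # disc | annulus | pentamer
    template_radius_px: float = 8.0
    target_amplitude: float = 6.0
    target_amplitude_spread: float = 1.0
    junk_amplitude: float = 0.0
    noise_sigma: float = 1.0
    pick_jitter_sigma_px: float = 3.0
    min_separation_px: float = 48.0
    edge_margin_px: float = 56.0  # keep particles extractable at box 96
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_micrographs < 1:
            raise ValueError("n_micrographs must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        for name in ("target_amplitude", "junk_amplitude",
                     "pick_jitter_sigma_px", "target_amplitude_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_separation_px < 2 * self.template_radius_px:
            import warnings
            warnings.warn(
                "min_separation_px below twice the template radius: "
                "particles may overlap", stacklevel=2)

    def micrograph_ids(self) -> list[str]:
        return [f"mic_{i:03d}" for i in range(self.n_micrographs)]


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_template(kind: str, radius_px: float, box_px: int) -> np.ndarray:
    """Render a zero-background, unit-peak particle template.

    The template is centered at ``((box_px - 1) / 2, (box_px - 1) / 2)``
    (so a 32-px box centers at 15.5).  ``pentamer`` is five Gaussian blobs
    at 72-degree spacing on a ring of radius ``0.6 * radius_px``, the
    shape of a pentameric complex seen along its symmetry axis.
    """
    if box_px < 2 * radius_px + 1:
        raise ValueError(
            f"box_px={box_px} too small for radius {radius_px} "
            f"(need >= {2 * radius_px + 1:.0f})")
    c = (box_px - 1) / 2.0
    yy, xx = np.mgrid[0:box_px, 0:box_px]
    r = np.hypot(yy - c, xx - c)
    if kind == "disc":
        img = np.clip(radius_px + 0.5 - r, 0.0, 1.0)
    elif kind == "annulus":
        thickness = max(1.5, radius_px / 3.0)
        img = np.clip(1.0 - np.abs(r - radius_px) / thickness, 0.0, 1.0)
        img /= img.max()  # grid sampling can miss the continuous peak
    elif kind == "pentamer":
        ring = 0.6 * radius_px
        sigma = max(1.0, 0.2 * radius_px)
        img = np.zeros((box_px, box_px))
        for k in range(5):
            ang = np.deg2rad(90.0 + 72.0 * k)
            by = c - ring * np.sin(ang)  # row axis points down
            bx = c + ring * np.cos(ang)
            img += np.exp(-((yy - by) ** 2 + (xx - bx) ** 2)
                          / (2.0 * sigma ** 2))
        img /= img.max()
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return img.astype(np.float64)


def _template_box(radius_px: float) -> int:
    # generous odd box: pentamer blobs extend past the nominal radius
    return 2 * int(np.ceil(1.5 * radius_px)) + 5


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _splat(image: np.ndarray, template: np.ndarray,
           x: float, y: float, amplitude: float) -> None:
    """Add ``amplitude * template`` centered at (x, y) with bilinear
    sub-pixel placement; contributions outside the image are clipped."""
    if amplitude == 0.0:
        return
    tb = template.shape[0]
    ctr = (tb - 1) / 2.0
    cy, cx = y - ctr, x - ctr  # float top-left corner
    i0, j0 = int(np.floor(cy)), int(np.floor(cx))
    fy, fx = cy - i0, cx - j0
    pad = np.zeros((tb + 1, tb + 1))
    pad[:-1, :-1] += (1 - fy) * (1 - fx) * template
    pad[1:, :-1] += fy * (1 - fx) * template
    pad[:-1, 1:] += (1 - fy) * fx * template
    pad[1:, 1:] += fy * fx * template
    h, w = image.shape
    y_lo, y_hi = max(i0, 0), min(i0 + tb + 1, h)
    x_lo, x_hi = max(j0, 0), min(j0 + tb + 1, w)
    if y_lo >= y_hi or x_lo >= x_hi:
        return
    image[y_lo:y_hi, x_lo:x_hi] += amplitude * pad[
        y_lo - i0:y_hi - i0, x_lo - j0:x_hi - j0]


def render_scene(shape: tuple[int, int], truth_rows: pd.DataFrame,
                 template: np.ndarray) -> np.ndarray:
    """Render the noise-free scene for one micrograph from truth rows."""
    image = np.zeros(shape, dtype=np.float64)
    for row in truth_rows.itertuples(index=False):
        _splat(image, template, float(row.x), float(row.y),
               float(row.amplitude))
    return image


def _place_positions(rng: np.random.Generator, n: int,
                     shape: tuple[int, int], margin: float,
                     min_sep: float, existing: list[tuple[float, float]],
                     max_tries_per_point: int = 2000) -> list[tuple[float, float]]:
    h, w = shape
    placed: list[tuple[float, float]] = []
    all_pts = list(existing)
    for _ in range(n):
        for _try in range(max_tries_per_point):
            x = rng.uniform(margin, w - 1 - margin)
            y = rng.uniform(margin, h - 1 - margin)
            if all(np.hypot(x - px, y - py) >= min_sep
                   for px, py in all_pts):
                placed.append((x, y))
                all_pts.append((x, y))
                break
        else:
            raise PlacementError(
                f"placed only {len(placed)} of {n} points at "
                f"min_separation_px={min_sep}")
    return placed


def simulate_micrographs(
        cfg: SimConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Generate micrographs and the ground-truth particle table.

    Each micrograph is Gaussian noise (mean 0, sd ``noise_sigma``) plus
    the rendered targets.  In the faint-particle junk regime
    (``junk_amplitude > 0``) the truth additionally contains junk rows
    rendered at ``junk_amplitude``; in the pure-noise regime (default)
    junk picks belong to the picking runs, not the scene, so the truth
    holds targets only.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    template = make_template(cfg.template_kind, cfg.template_radius_px,
                             _template_box(cfg.template_radius_px))
    margin = max(cfg.template_radius_px, cfg.edge_margin_px, 1.0)
    micrographs: dict[str, np.ndarray] = {}
    rows = []
    for mic_id in cfg.micrograph_ids():
        targets = _place_positions(rng, cfg.n_targets_per_mic,
                                   cfg.mic_shape, margin,
                                   cfg.min_separation_px, [])
        n_scene_junk = (cfg.n_junk_picks_per_mic
                        if cfg.junk_amplitude > 0 else 0)
        junk = _place_positions(rng, n_scene_junk, cfg.mic_shape, margin,
                                cfg.min_separation_px, targets)
        lo = cfg.target_amplitude - cfg.target_amplitude_spread
        hi = cfg.target_amplitude + cfg.target_amplitude_spread
        amps = rng.uniform(lo, hi, size=len(targets))
        for (x, y), a in zip(targets, amps):
            rows.append((mic_id, x, y, float(a), "target"))
        for x, y in junk:
            rows.append((mic_id, x, y, float(cfg.junk_amplitude), "junk"))
        n_mic = len(targets) + len(junk)
        truth_mic = pd.DataFrame(
            rows[-n_mic:] if n_mic else [],
            columns=["micrograph_id", "x", "y", "amplitude", "label"])
        scene = render_scene(cfg.mic_shape, truth_mic, template)
        noise = rng.normal(0.0, cfg.noise_sigma, size=cfg.mic_shape)
        micrographs[mic_id] = (scene + noise).astype(np.float32)
    truth = pd.DataFrame(
        rows, columns=["micrograph_id", "x", "y", "amplitude", "label"])
    return micrographs, truth


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------

def simulate_picking(truth: pd.DataFrame, run_id: int,
                     jitter_sigma_px: float, miss_rate: float = 0.0,
                     n_false_per_mic: int = 0, seed: int = 0, *,
                     mic_shape: tuple[int, int],
                     pixel_size: float = 1.0,
                     false_min_sep_px: float = 0.0,
                     false_margin_px: float = 0.0) -> PickSet:
    """Simulate one picking run over the ground truth.

    Every truth row is picked with probability ``1 - miss_rate`` at its
    position plus isotropic Gaussian jitter, and ``n_false_per_mic``
    false picks are added per micrograph at uniform background locations
    at least ``false_min_sep_px`` from every true particle and from each
    other (the picker's non-maximum-suppression radius) and at least
    ``false_margin_px`` from the micrograph edge.  Different
    ``run_id``/``seed`` combinations give independent streams.  The
    hidden ``source`` column records the truth row index (-1 for false
    picks) and is used only by the evaluation layer.
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must lie in [0, 1]")
    rng = np.random.default_rng([seed, run_id])
    h, w = mic_shape
    recs = []
    for idx, row in truth.reset_index().iterrows():
        if rng.uniform() < miss_rate:
            continue
        x = row["x"] + rng.normal(0.0, jitter_sigma_px)
        y = row["y"] + rng.normal(0.0, jitter_sigma_px)
        recs.append((row["micrograph_id"],
                     float(np.clip(x, 0, w - 1)),
                     float(np.clip(y, 0, h - 1)),
                     int(row["index"])))
    if n_false_per_mic > 0:
        by_mic = truth.groupby("micrograph_id", sort=False)
        for mic_id in truth["micrograph_id"].unique():
            grp = by_mic.get_group(mic_id)
            existing = list(zip(grp["x"], grp["y"]))
            false_pts = _place_positions(
                rng, n_false_per_mic, mic_shape, false_margin_px,
                false_min_sep_px, existing)
            for x, y in false_pts:
                recs.append((mic_id, float(x), float(y), -1))
    df = pd.DataFrame(recs, columns=["micrograph_id", "x", "y", "source"])
    df.insert(0, "run_id", run_id)
    df.insert(0, "pick_id", [f"{run_id}:{i}" for i in range(len(df))])
    return PickSet(df, pixel_size,
                   provenance=f"simulated picking run {run_id}")


def simulate_dataset(cfg: SimConfig, miss_rate: float = 0.0
                     ) -> tuple[dict[str, np.ndarray], pd.DataFrame,
                                PickSet, PickSet]:
    """Full study setup: micrographs, truth, and two independent pickings.

    In the pure-noise junk regime each run contributes
    ``cfg.n_junk_picks_per_mic`` of its own false picks per micrograph,
    placed at least ``cfg.min_separation_px`` from every true particle
    and kept ``cfg.edge_margin_px`` from the edge so they stay
    extractable.  In the faint-particle regime the junk rows are part of
    the truth and are picked by both runs like targets.
    """
    micrographs, truth = simulate_micrographs(cfg)
    margin = max(cfg.template_radius_px, cfg.edge_margin_px, 1.0)
    n_false = (cfg.n_junk_picks_per_mic
               if cfg.junk_amplitude == 0 else 0)
    kwargs = dict(jitter_sigma_px=cfg.pick_jitter_sigma_px,
                  miss_rate=miss_rate,
                  n_false_per_mic=n_false,
                  seed=cfg.seed, mic_shape=cfg.mic_shape,
                  pixel_size=cfg.pixel_size,
                  false_min_sep_px=cfg.min_separation_px,
                  false_margin_px=margin)
    ps1 = simulate_picking(truth, run_id=1, **kwargs)
    ps2 = simulate_picking(truth, run_id=2, **kwargs)
    return micrographs, truth, ps1, ps2


def write_dataset(out_dir: str | Path, micrographs: Mapping[str, np.ndarray],
                  truth: pd.DataFrame, pixel_size: float) -> None:
    """Persist micrographs as MRC mode-2 files and the truth table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for mic_id, image in micrographs.items():
        write_mrc(image, out_dir / f"{mic_id}.mrc", pixel_size)
    write_truth_csv(truth, out_dir / "truth.csv")
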