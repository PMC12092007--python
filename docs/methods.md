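# Methods

This note documents the model behind `duster`, the meaning and defaults of
every parameter, the numerical choices, and the known limitations.

## Coordinates, units, formats

* Pick coordinates are **0-based pixels**, `x` = column, `y` = row, origin
  at the top-left of the micrograph.  Sub-pixel positions are allowed.
* Physical distances (the duplicate threshold `D_TH`, box sizes given in
  Å) are specified in **ångström** and converted once through
  `pixel_size` (Å/px).
* Pick tables are STAR files (`_rlnCoordinateX/Y`, `_rlnMicrographName`);
  recentered tables additionally carry `_rlnClassNumber` (1-based on
  disk), `_rlnMaxValueProbDistribution`, and `_rlnOriginX/YAngst`
  (the applied shift in Å).  Coordinates are written with 6 decimals.
* Micrographs and class-average stacks are MRC mode 2 (float32) with the
  pixel size stored in the cell dimensions.

## The curation algorithm

Two picking runs of the same micrographs are classified and recentered
**independently**, then compared:

* `duplicate_select(rA, rB, d_th_angstrom, mode)` — in the default
  `cross_run` mode a recentered point is kept iff some point of the
  *other* run on the same micrograph lies at Euclidean distance strictly
  below `d_th_angstrom`.  `union` mode keeps a point if *any* other point
  (either run) is that close, emulating duplicate-removal tools that
  cannot distinguish runs.  Singletons are always rejected.  Matching is
  any-neighbor (≥ 1 counterpart), per micrograph, via a k-d tree; the
  strict `<` at the boundary is fixed for determinism.
* `duster_round` — classify + recenter each run (per-run seeds
  `seed + 2·round + run`), select duplicates, and carry the **recentered**
  coordinates into the next round, so rounds are self-improving.
* `run_duster` — iterate `n_rounds` (default 3) and record per-round
  kept ids and pair distances.

Companion duplicated filters (a particle is removed only when *both*
replicates condemn it): `probability_filter` (removed iff class
probability strictly < 0.3 in both), `decoy_filter` (removed iff
decoy-assigned in both), and `iterative_decoy_filter` — each round
classifies survivors against the target reference plus `K_decoy`
deliberately wrong references (seeded Gaussian-noise images, never
refined toward the data) and removes decoy-assigned particles until the
target-class fraction exceeds 0.9.  `comprehensive_select` aggregates
`duplicate_select` over the nine (A_i, B_j) combinations of 3 × 3
replicate sets under an `all` / `majority` (≥ 5 of 9) / `any` rule;
`all` is the default (strictest) reading.

## The 2D classification engine

`classify2d` is a minimal multi-reference **translational** aligner:

1. Init: seeded random partition into K classes; averages = group means
   (or caller-supplied `init_averages` for reference classification).
2. E-step: for every particle and class, best integer-shift normalized
   cross-correlation over the `(2·max_shift+1)²` window, computed with
   FFTs; class scores are the per-class best correlations; probabilities
   are `softmax(score / T)` with fixed temperature `T = 1/box_px`; each
   particle's shift is the best shift of its argmax class.  Ties break to
   the lowest class index, then the lexicographically smallest `(dy, dx)`.
3. M-step: averages = probability-weighted means of the recentered
   particles; an emptied class is re-seeded with the worst-matched
   particle; every average is re-centered by rolling its energy
   (intensity²) centroid to `box/2`, which pins the translational gauge
   freedom so that recentering is unbiased across iterations.
4. Stop after `n_iter` iterations or when < 0.1 % of assignments change.

`recenter` replaces each pick by `round(pick) + shift` (windows are
extracted at the rounded pick), storing the exact applied offset so that
`x_ref = x + dx` holds to machine precision.

Numerical choices: integer shift grid (no sub-pixel refinement — `D_TH`
is 15–20 Å ≈ 15–20 px here, far above 1 px); fixed softmax temperature
(the probability model is a stand-in — only the 0.3 threshold consumes
it); normalized extraction windows (zero mean, unit variance).

## The synthetic generator

`simulate_micrographs` renders Gaussian background noise (sd
`noise_sigma`) plus disc / annulus / pentamer templates at uniformly
placed positions (pairwise separation ≥ `min_separation_px`, margin
`edge_margin_px`), with bilinear sub-pixel placement so recentering can
be tested below 1 px.  `simulate_picking` picks every truth row with
probability `1 − miss_rate` plus isotropic Gaussian jitter, and adds
per-run false picks.  A hidden `source` column links each pick to its
truth row (−1 for false picks) and is consumed only by the evaluation
layer.

Junk is modelled in two selectable regimes:

* **Pure-noise picks** (`junk_amplitude = 0`, default): junk picks are
  hallucinations of each *picker*, not objects in the scene.  Each run
  places its own false picks, independently, at least
  `min_separation_px` from every true particle — real pickers apply
  non-maximum suppression, so a false pick a particle-radius away from a
  particle would simply be a pick *of* that particle.  This independence
  matters: if both runs hallucinated the same empty location, both
  extraction windows would contain the same background noise, any
  blob-like reference would peak at the same noise fluctuation in both
  runs, and the "two" recentered points would agree spuriously — a
  correlated-noise artifact with no physical counterpart, since
  independent pickers do not share hallucinations.
* **Faint particles** (`junk_amplitude > 0`): junk rows are real, weak
  particles rendered into the scene and picked by both runs.  Here
  shared windows are physically correct; curation performance then
  depends on the contrast gap between targets and junk.

### Parameters (defaults = the benchmark scenario)

| parameter | default | units | rationale |
|---|---|---|---|
| `n_micrographs` | 20 | – | enough statistics (600 targets) in ~1 min |
| `mic_shape` | 1024×1024 | px | realistic field with ~60 picks/run |
| `pixel_size` | 1.0 | Å/px | makes Å and px thresholds legible |
| `n_targets_per_mic` | 30 | – | 50 % of picks are targets |
| `n_junk_picks_per_mic` | 30 | per run | 50 % junk: the curation must double purity |
| `template_radius_px` | 8 | px | particle diameter 16 px ≪ box 96 |
| `target_amplitude` | 6 ± 1 | ×noise sd | peak S/N ≈ 5–7: strong enough to recenter, spread makes contrast strata non-degenerate |
| `noise_sigma` | 1.0 | – | reference scale |
| `pick_jitter_sigma_px` | 3.0 | px | recentering must beat this |
| `min_separation_px` | 48 | px | no two particles inside one search window; also the picker's non-maximum-suppression radius |
| `edge_margin_px` | 56 | px | every pick extractable at box 96 |
| `seed` | 7 | – | all randomness is seeded |

Engine defaults (`Align2DParams`): `box_px = 96` (6× particle radius, so
the full ±24 px search fits), `n_classes = 6`, `max_shift_px = 24`
(**must exceed `D_TH` in pixels** — 24 px > 20 px — so that
irreproducibly recentered junk can disperse beyond the threshold),
`n_iter = 8`.  Curation defaults (`CurationConfig`):
`d_th_angstrom = 20`, `n_rounds = 3`, `prob_threshold = 0.3`.

## Evaluation

`report` computes purity (kept targets / kept), recall (kept targets /
picked true targets), mean recentering error, a cross-run distance
histogram, mean amplitude of kept vs rejected picks (false picks count
as amplitude 0, the contrast of empty background), and the retention of
true targets per target-amplitude quartile.  The amplitude strata are
the desk-scale analog of defocus strata on real data: a reproducibility
selection must retain targets at a similar rate in every stratum,
whereas a brightness filter would not.  Truth matching uses the hidden
provenance column when present and falls back to greedy nearest-first
one-to-one positional matching within a tolerance.

## Limitations

* Translational alignment only; in-plane rotation is not searched.  The
  rotationally structured templates are handled by class multiplicity,
  not rotation — adequate because recentering is the only output the
  curation consumes.
* No CTF, envelope, or radiation-damage model; amplitude is the stand-in
  for defocus-dependent contrast.
* The class probability is a fixed-temperature softmax over correlation
  scores — a monotone stand-in, not a generative posterior; only its
  0.3-threshold behaviour is relied upon.
* Integer-pixel shifts bound recentering accuracy at ~0.3–0.5 px; this
  is two orders of magnitude below `D_TH` and does not affect selection.
* In the faint-particle junk regime both runs extract the same
  micrograph noise around a junk row; at very low junk contrast the
  shared-noise agreement between replicates sets a floor on achievable
  purity for any deterministic aligner.  The pure-noise (per-picker)
  regime is the default benchmark for exactly this reason.
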