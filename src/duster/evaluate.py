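"""Evaluation of curation outcomes against synthetic ground truth.

Reports purity (kept targets / kept), recall (kept targets / true targets
picked), recentering error, a distance histogram, and the retention of
true targets stratified by target amplitude.  The amplitude strata play
the role that defocus strata play on real data: if the curation were a
mere brightness filter, retention would climb steeply with amplitude,
whereas a reproducibility-based selection should retain targets at a
similar rate in every stratum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CurationReport",
    "match_to_truth",
    "stratified_retention",
    "report",
    "plot_report",
]


@dataclass
class CurationReport:
    n_input: dict  # per run
    n_kept: dict   # per run
    purity: float | None          # kept targets / kept (None if kept empty)
    recall: float | None          # kept targets / true targets picked
    mean_center_error_px: float | None
    retention_by_amplitude_quartile: list  # 4 values in [0, 1] (or None)
    distance_histogram: dict      # {"bin_edges_angstrom": [...], "counts": [...]}
    mean_amplitude_kept: float | None = None
    mean_amplitude_rejected: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _pick_table(ps) -> pd.DataFrame:
    df = ps.df
    if "x" in df.columns:
        return df[["pick_id", "micrograph_id", "x", "y"]].assign(
            source=df["source"] if "source" in df.columns else -2)
    # recentered set
    out = df[["pick_id", "micrograph_id"]].copy()
    out["x"] = df["x_ref"]
    out["y"] = df["y_ref"]
    out["source"] = df["source"] if "source" in df.columns else -2
    return out


def match_to_truth(kept, truth: pd.DataFrame, tol_px: float) -> pd.Series:
    """Label each kept pick ``target`` or ``junk`` against the truth table.

    When the hidden provenance column is present, the label is that of the
    originating truth row.  Otherwise targets are matched greedily by
    distance: candidate (pick, truth-target) pairs within ``tol_px`` are
    assigned nearest-first with each truth row used at most once; unmatched
    picks are labeled junk.  Returns a Series indexed by pick_id.
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be > 0")
    picks = _pick_table(kept)
    labels = pd.Series("junk", index=picks["pick_id"], dtype=object)
    have_provenance = (picks["source"] >= -1).all() and len(picks)
    if have_provenance:
        src = picks["source"].to_numpy(int)
        is_target = np.zeros(len(picks), dtype=bool)
        valid = src >= 0
        is_target[valid] = (
            truth.iloc[src[valid]]["label"].to_numpy() == "target")
        labels[:] = np.where(is_target, "target", "junk")
        return labels

    targets = truth[truth["label"] == "target"]
    for mic_id, grp in picks.groupby("micrograph_id"):
        t = targets[targets["micrograph_id"] == mic_id]
        if not len(t):
            continue
        txy = t[["x", "y"]].to_numpy(float)
        pxy = grp[["x", "y"]].to_numpy(float)
        tree = cKDTree(txy)
        candidates = []
        for i, neighbors in enumerate(tree.query_ball_point(pxy, r=tol_px)):
            for j in neighbors:
                candidates.append(
                    (float(np.hypot(*(pxy[i] - txy[j]))), i, j))
        used_t: set[int] = set()
        used_p: set[int] = set()
        for d, i, j in sorted(candidates):
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            labels[grp["pick_id"].iloc[i]] = "target"
    return labels


def stratified_retention(kept, all_picked, truth: pd.DataFrame,
                         n_strata: int = 4) -> list:
    """Retention of true target picks per target-amplitude stratum.

    Strata are amplitude quantile bins over the picked true targets;
    retention is the fraction of each stratum's picks that survived.
    Requires the provenance column (synthetic data).
    """
    pk = _pick_table(all_picked)
    pk = pk[pk["source"] >= 0]
    src = pk["source"].to_numpy(int)
    is_target = truth.iloc[src]["label"].to_numpy() == "target"
    pk = pk[is_target]
    if not len(pk):
        return [None] * n_strata
    amps = truth.iloc[pk["source"].to_numpy(int)]["amplitude"].to_numpy(float)
    kept_ids = set(_pick_table(kept)["pick_id"])
    survived = pk["pick_id"].isin(kept_ids).to_numpy()
    edges = np.quantile(amps, np.linspace(0, 1, n_strata + 1))
    out = []
    for q in range(n_strata):
        lo, hi = edges[q], edges[q + 1]
        in_bin = ((amps >= lo) & (amps <= hi)) if q == n_strata - 1 \
            else ((amps >= lo) & (amps < hi))
        out.append(float(survived[in_bin].mean()) if in_bin.any() else None)
    return out


def report(kept, rejected, truth: pd.DataFrame, tol_px: float,
           pair_distances=None, all_picked=None,
           n_histogram_bins: int = 20) -> CurationReport:
    """Compute the full curation report.

    ``kept``/``rejected`` are PickSets or RecenteredPickSets of one run
    (or concatenations); ``pair_distances`` (angstrom) feeds the distance
    histogram; ``all_picked`` (defaults to kept+rejected via provenance)
    is the denominator for recall and the stratified retention.
    """
    kept_tab = _pick_table(kept)
    rej_tab = _pick_table(rejected)
    labels_kept = match_to_truth(kept, truth, tol_px) if len(kept_tab) \
        else pd.Series(dtype=object)
    n_kept_targets = int((labels_kept == "target").sum())

    purity = (n_kept_targets / len(kept_tab)) if len(kept_tab) else None

    # recall denominator: distinct true-target picks among kept + rejected
    def _target_mask(tab):
        src = tab["source"].to_numpy(int)
        mask = np.zeros(len(tab), dtype=bool)
        valid = src >= 0
        if valid.any():
            mask[valid] = truth.iloc[src[valid]]["label"].to_numpy() == "target"
        return mask

    have_prov = ((kept_tab["source"] >= -1).all()
                 and (rej_tab["source"] >= -1).all())
    if have_prov:
        n_true_picked = int(_target_mask(kept_tab).sum()
                            + _target_mask(rej_tab).sum())
    else:
        labels_rej = match_to_truth(rejected, truth, tol_px) if len(rej_tab) \
            else pd.Series(dtype=object)
        n_true_picked = n_kept_targets + int((labels_rej == "target").sum())
    recall = (n_kept_targets / n_true_picked) if n_true_picked else None

    # recentering / picking error of kept true targets against truth
    err = None
    if have_prov and len(kept_tab):
        mask = _target_mask(kept_tab)
        if mask.any():
            src = kept_tab["source"].to_numpy(int)[mask]
            txy = truth.iloc[src][["x", "y"]].to_numpy(float)
            pxy = kept_tab[["x", "y"]].to_numpy(float)[mask]
            err = float(np.hypot(*(pxy - txy).T).mean())

    # amplitude contrast between kept and rejected (junk amplitude counts
    # as its truth value, false picks as 0)
    def _mean_amp(tab):
        if not len(tab) or not have_prov:
            return None
        src = tab["source"].to_numpy(int)
        amps = np.zeros(len(tab))
        valid = src >= 0
        amps[valid] = truth.iloc[src[valid]]["amplitude"].to_numpy(float)
        return float(amps.mean())

    if pair_distances is not None and len(pair_distances):
        counts, edges = np.histogram(np.asarray(pair_distances, float),
                                     bins=n_histogram_bins)
        hist = {"bin_edges_angstrom": edges.tolist(),
                "counts": counts.tolist()}
    else:
        hist = {"bin_edges_angstrom": [], "counts": []}

    if all_picked is None:
        both = pd.concat([kept_tab, rej_tab], ignore_index=True)
        both = both.drop_duplicates("pick_id")

        class _Wrap:  # minimal duck-typed pick container
            df = both.rename(columns={})
        all_for_strata = _Wrap()
    else:
        all_for_strata = all_picked
    retention = (stratified_retention(kept, all_for_strata, truth)
                 if have_prov else [None] * 4)

    def _count_by_run(tab):
        runs = [pid.split(":", 1)[0] for pid in tab["pick_id"]]
        out: dict[str, int] = {}
        for r in runs:
            out[f"run{r}"] = out.get(f"run{r}", 0) + 1
        return out

    return CurationReport(
        n_input=_count_by_run(pd.concat([kept_tab, rej_tab],
                                        ignore_index=True)
                              .drop_duplicates("pick_id")),
        n_kept=_count_by_run(kept_tab),
        purity=purity,
        recall=recall,
        mean_center_error_px=err,
        retention_by_amplitude_quartile=retention,
        distance_histogram=hist,
        mean_amplitude_kept=_mean_amp(kept_tab),
        mean_amplitude_rejected=_mean_amp(rej_tab),
    )


def plot_report(rep: CurationReport, history=None,
                out_path: str | Path = "report.png") -> None:
    """Diagnostic panel: distance histogram, per-round counts, and
    amplitude-stratified retention."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    edges = rep.distance_histogram["bin_edges_angstrom"]
    counts = rep.distance_histogram["counts"]
    if edges:
        axes[0].stairs(counts, edges, fill=True)
    axes[0].set_xlabel("pair distance D (Å)")
    axes[0].set_ylabel("pairs")
    axes[0].set_title("cross-run distances")

    if history is not None:
        axes[1].plot(range(1, len(history.rounds) + 1),
                     [r.n_out for r in history.rounds], marker="o")
    axes[1].set_xlabel("round")
    axes[1].set_ylabel("picks kept")
    axes[1].set_title("survivors per round")

    vals = [v if v is not None else np.nan
            for v in rep.retention_by_amplitude_quartile]
    axes[2].bar(range(1, len(vals) + 1), vals)
    axes[2].set_ylim(0, 1.05)
    axes[2].set_xlabel("amplitude quartile")
    axes[2].set_ylabel("target retention")
    axes[2].set_title("contrast-stratified retention")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
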