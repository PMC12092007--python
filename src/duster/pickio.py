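"""Domain types and coordinate/metadata file I/O.

Coordinate convention used throughout the package: 0-based pixel
coordinates with ``x`` the column index and ``y`` the row index, origin at
the top-left of the array (so ``image[round(y), round(x)]`` is the pixel
under a pick).  Distance thresholds are configured in angstroms and
converted to pixels once via the pixel size; all internal geometry is in
pixels, while curation histories report angstroms.

Coordinate files use the RELION-3.1 STAR dialect: ``_rlnMicrographName``,
``_rlnCoordinateX``, ``_rlnCoordinateY`` (pixels), with recentered particle
files adding ``_rlnClassNumber`` (1-based on disk),
``_rlnMaxValueProbDistribution`` and angstrom-valued origin shifts
``_rlnOriginXAngst`` / ``_rlnOriginYAngst``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Pick",
    "PickSet",
    "RecenteredPick",
    "RecenteredPickSet",
    "CurationConfig",
    "CurationHistory",
    "RoundRecord",
    "StarFormatError",
    "read_star_table",
    "write_star_table",
    "read_picks_star",
    "read_recentered_star",
    "write_picks_star",
    "split_by_run",
]

# Decimal places used when writing coordinates/probabilities; round-trips
# are exact at this precision.
STAR_PRECISION = 6

COORD_COLUMNS = ("_rlnMicrographName", "_rlnCoordinateX", "_rlnCoordinateY")
EXTENDED_COLUMNS = COORD_COLUMNS + (
    "_rlnClassNumber",
    "_rlnMaxValueProbDistribution",
    "_rlnOriginXAngst",
    "_rlnOriginYAngst",
)


class StarFormatError(ValueError):
    """Raised for malformed STAR input (missing column, bad value)."""


@dataclass(frozen=True)
class Pick:
    """A single picked coordinate from one picking run."""

    pick_id: str
    micrograph_id: str
    run_id: int
    x: float  # column, pixels
    y: float  # row, pixels


@dataclass(frozen=True)
class RecenteredPick:
    """A pick after alignment: refined center, class id, class probability."""

    pick_id: str
    micrograph_id: str
    x_ref: float
    y_ref: float
    dx: float
    dy: float
    class_id: int
    class_prob: float


@dataclass
class PickSet:
    """Picked coordinates for one picking run, the unit the curation acts on.

    Stored as a DataFrame with columns ``pick_id, micrograph_id, run_id,
    x, y`` plus an optional hidden provenance column ``source`` (index of
    the ground-truth row a pick derives from, -1 for false picks) used
    only by the evaluation layer.
    """

    df: pd.DataFrame
    pixel_size: float  # angstrom per pixel
    provenance: str = ""

    REQUIRED = ("pick_id", "micrograph_id", "run_id", "x", "y")

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"PickSet missing columns: {missing}")
        if self.df["pick_id"].duplicated().any():
            raise ValueError("pick_id values must be unique within a PickSet")
        xy = self.df[["x", "y"]].to_numpy(float)
        if len(xy) and (~np.isfinite(xy)).any():
            raise ValueError("pick coordinates must be finite")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pick_ids(self) -> list[str]:
        return self.df["pick_id"].tolist()

    @property
    def picks(self) -> Iterator[Pick]:
        for row in self.df.itertuples(index=False):
            yield Pick(row.pick_id, row.micrograph_id, int(row.run_id),
                       float(row.x), float(row.y))

    @classmethod
    def from_picks(cls, picks: list[Pick], pixel_size: float,
                   provenance: str = "") -> "PickSet":
        df = pd.DataFrame(
            [dataclasses.asdict(p) for p in picks],
            columns=list(cls.REQUIRED),
        )
        return cls(df, pixel_size, provenance)

    def subset(self, pick_ids) -> "PickSet":
        """Return the picks whose ids are in ``pick_ids``, order preserved."""
        keep = self.df["pick_id"].isin(set(pick_ids))
        return PickSet(self.df[keep].copy(), self.pixel_size, self.provenance)


@dataclass
class RecenteredPickSet:
    """Picks after recentering, with class assignment and probability.

    DataFrame columns: ``pick_id, micrograph_id, x_ref, y_ref, dx, dy,
    class_id, class_prob`` (plus optional ``source`` provenance).
    """

    df: pd.DataFrame
    pixel_size: float
    source_run: int

    REQUIRED = ("pick_id", "micrograph_id", "x_ref", "y_ref",
                "dx", "dy", "class_id", "class_prob")

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"RecenteredPickSet missing columns: {missing}")
        if self.df["pick_id"].duplicated().any():
            raise ValueError("pick_id values must be unique")
        probs = self.df["class_prob"].to_numpy(float)
        if len(probs) and ((probs < 0) | (probs > 1)).any():
            raise ValueError("class_prob must lie in [0, 1]")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pick_ids(self) -> list[str]:
        return self.df["pick_id"].tolist()

    @property
    def items(self) -> Iterator[RecenteredPick]:
        for row in self.df.itertuples(index=False):
            yield RecenteredPick(row.pick_id, row.micrograph_id,
                                 float(row.x_ref), float(row.y_ref),
                                 float(row.dx), float(row.dy),
                                 int(row.class_id), float(row.class_prob))

    def subset(self, pick_ids) -> "RecenteredPickSet":
        keep = self.df["pick_id"].isin(set(pick_ids))
        return RecenteredPickSet(self.df[keep].copy(), self.pixel_size,
                                 self.source_run)


@dataclass
class CurationConfig:
    """Configuration of the distance-based curation.

    ``d_th_angstrom`` is the distance threshold D_TH between the recentered
    points of the two picking runs (20 A for 2D rounds, 15 A for the 3D
    pathway in typical use); a particle passes when D < D_TH strictly.
    ``prob_threshold`` is the duplicated class-probability cutoff (a pick is
    removed only when its class probability is below the cutoff in *both*
    replicate classifications).
    """

    d_th_angstrom: float
    n_rounds: int = 1
    match_mode: str = "cross_run"  # or "union"
    prob_threshold: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_th_angstrom <= 0:
            raise ValueError("d_th_angstrom must be > 0")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.match_mode not in ("cross_run", "union"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "CurationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        data = {k: v for k, v in data.items() if k in known}
        data.update(overrides)
        return cls(**data)


@dataclass
class RoundRecord:
    """Per-round curation outcome: survivors, pair distances (angstrom)."""

    kept_ids_run1: list[str]
    kept_ids_run2: list[str]
    pair_distances: list[float]
    n_in: int
    n_out: int


@dataclass
class CurationHistory:
    rounds: list[RoundRecord] = field(default_factory=list)

    def append(self, record: RoundRecord) -> None:
        if record.n_out > record.n_in:
            raise ValueError("n_out may not exceed n_in")
        self.rounds.append(record)

    def kept_counts(self) -> list[int]:
        return [r.n_out for r in self.rounds]

    def to_json_dict(self) -> dict:
        return {
            "rounds": [
                {
                    "n_in": r.n_in,
                    "n_out": r.n_out,
                    "n_kept_run1": len(r.kept_ids_run1),
                    "n_kept_run2": len(r.kept_ids_run2),
                    "n_pairs": len(r.pair_distances),
                    "pair_distance_angstrom": {
                        "mean": float(np.mean(r.pair_distances)) if r.pair_distances else None,
                        "median": float(np.median(r.pair_distances)) if r.pair_distances else None,
                        "max": float(np.max(r.pair_distances)) if r.pair_distances else None,
                    },
                }
                for r in self.rounds
            ]
        }


# ---------------------------------------------------------------------------
# STAR I/O (minimal RELION loop dialect)
# ---------------------------------------------------------------------------

def read_star_table(path: str | Path) -> pd.DataFrame:
    """Parse the first ``loop_`` block of a STAR file into a DataFrame.

    Column names are taken from the ``_rln...`` tags; values stay strings
    so callers control numeric conversion and error reporting.
    """
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    header_done = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith("data_"):
                continue
            if stripped == "loop_":
                if header_done:
                    break  # only the first loop block
                in_loop = True
                continue
            if in_loop and stripped.startswith("_"):
                if header_done:
                    break
                columns.append(stripped.split()[0])
                continue
            if in_loop and columns:
                header_done = True
                fields = stripped.split()
                if len(fields) != len(columns):
                    raise StarFormatError(
                        f"{path}: row has {len(fields)} fields, "
                        f"expected {len(columns)}: {stripped!r}")
                rows.append(fields)
    if not columns:
        raise StarFormatError(f"{path}: no loop_ block with column tags found")
    return pd.DataFrame(rows, columns=columns)


def write_star_table(df: pd.DataFrame, path: str | Path,
                     block_name: str = "particles") -> None:
    """Write a DataFrame as a single-loop STAR file (values pre-formatted)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block_name}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"{col} #{i}\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(str(v) for v in row) + "\n")


def _parse_float_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError:
        for i, v in enumerate(df[col]):
            try:
                float(v)
            except ValueError:
                raise StarFormatError(
                    f"{path}: non-numeric value {v!r} in column {col}, "
                    f"data row {i}") from None
        raise  # pragma: no cover


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StarFormatError(f"{path}: missing required column(s) {missing}")


def read_picks_star(path: str | Path, run_id: int,
                    pixel_size: float) -> PickSet:
    """Read a coordinate STAR file into a PickSet.

    One pick per data row, in file order; ``pick_id`` is assigned
    deterministically as ``"{run_id}:{row_index}"``.  Class/probability/
    origin columns, if present, are ignored at this stage.
    """
    raw = read_star_table(path)
    _require_columns(raw, COORD_COLUMNS, path)
    df = pd.DataFrame({
        "pick_id": [f"{run_id}:{i}" for i in range(len(raw))],
        "micrograph_id": raw["_rlnMicrographName"].tolist(),
        "run_id": run_id,
        "x": _parse_float_column(raw, "_rlnCoordinateX", path),
        "y": _parse_float_column(raw, "_rlnCoordinateY", path),
    })
    return PickSet(df, pixel_size, provenance=f"read from {path}")


def read_recentered_star(path: str | Path, pixel_size: float,
                         source_run: int) -> RecenteredPickSet:
    """Read an extended particle STAR file into a RecenteredPickSet.

    Origin shifts are converted from angstrom back to pixels; coordinates
    on disk are the original (pre-shift) picks, so ``x_ref = x + dx``.
    """
    raw = read_star_table(path)
    _require_columns(raw, EXTENDED_COLUMNS, path)
    x = _parse_float_column(raw, "_rlnCoordinateX", path)
    y = _parse_float_column(raw, "_rlnCoordinateY", path)
    dx = _parse_float_column(raw, "_rlnOriginXAngst", path) / pixel_size
    dy = _parse_float_column(raw, "_rlnOriginYAngst", path) / pixel_size
    df = pd.DataFrame({
        "pick_id": [f"{source_run}:{i}" for i in range(len(raw))],
        "micrograph_id": raw["_rlnMicrographName"].tolist(),
        "x_ref": x + dx,
        "y_ref": y + dy,
        "dx": dx,
        "dy": dy,
        "class_id": raw["_rlnClassNumber"].astype(int).to_numpy() - 1,
        "class_prob": _parse_float_column(
            raw, "_rlnMaxValueProbDistribution", path),
    })
    return RecenteredPickSet(df, pixel_size, source_run)


def _fmt(v: float) -> str:
    return f"{v:.{STAR_PRECISION}f}"


def write_picks_star(ps: PickSet | RecenteredPickSet,
                     path: str | Path) -> None:
    """Write a PickSet or RecenteredPickSet as a STAR particle file.

    A RecenteredPickSet additionally emits class number (1-based), class
    probability and angstrom-valued origin shifts; the coordinate columns
    then hold the original (pre-shift) pick so readers recover
    ``x_ref = x + dx``.  Values are printed with 6 decimals and round-trip
    exactly at that precision.
    """
    if isinstance(ps, PickSet):
        out = pd.DataFrame({
            "_rlnMicrographName": ps.df["micrograph_id"],
            "_rlnCoordinateX": ps.df["x"].map(_fmt),
            "_rlnCoordinateY": ps.df["y"].map(_fmt),
        })
    elif isinstance(ps, RecenteredPickSet):
        d = ps.df
        out = pd.DataFrame({
            "_rlnMicrographName": d["micrograph_id"],
            "_rlnCoordinateX": (d["x_ref"] - d["dx"]).map(_fmt),
            "_rlnCoordinateY": (d["y_ref"] - d["dy"]).map(_fmt),
            "_rlnClassNumber": (d["class_id"].astype(int) + 1).astype(str),
            "_rlnMaxValueProbDistribution": d["class_prob"].map(_fmt),
            "_rlnOriginXAngst": (d["dx"] * ps.pixel_size).map(_fmt),
            "_rlnOriginYAngst": (d["dy"] * ps.pixel_size).map(_fmt),
        })
    else:
        raise TypeError(f"cannot write object of type {type(ps).__name__}")
    write_star_table(out, path)


def split_by_run(merged) -> dict[int, PickSet]:
    """Partition picks by picking run.

    Accepts a PickSet or an iterable of Pick; returns ``{run_id: PickSet}``.
    The union of the outputs equals the input and no pick appears twice.
    """
    if isinstance(merged, PickSet):
        df, pixel_size, prov = merged.df, merged.pixel_size, merged.provenance
    else:
        picks = list(merged)
        if not picks:
            return {}
        df = pd.DataFrame([dataclasses.asdict(p) for p in picks])
        pixel_size, prov = 1.0, "split_by_run on raw picks"
    out: dict[int, PickSet] = {}
    for run_id, group in df.groupby("run_id", sort=True):
        out[int(run_id)] = PickSet(group.copy(), pixel_size, prov)
    return out


# ---------------------------------------------------------------------------
# Ground-truth table I/O (CSV: micrograph_id,x,y,amplitude,label)
# ---------------------------------------------------------------------------

def read_truth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["micrograph_id", "x", "y", "amplitude", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StarFormatError(f"{path}: truth table missing columns {missing}")
    bad = set(df["label"]) - {"target", "junk"}
    if bad:
        raise StarFormatError(f"{path}: unknown truth labels {sorted(bad)}")
    return df


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    cols = ["micrograph_id", "x", "y", "amplitude", "label"]
    truth[cols].to_csv(path, index=False, float_format=f"%.{STAR_PRECISION}f")
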