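"""Data model and I/O for 3D multi-animal trajectories.

The canonical on-disk trajectory format is a CSV table with columns
``frame,id,x,y,z`` (positions in mm, ``frame`` a 0-based integer) preceded
by ``#``-comment metadata lines carrying at least the frame rate, e.g.::

    # shoalkit trajectory v1
    # fps=15.0
    # units=mm
    frame,id,x,y,z
    0,0,12.0,3.5,40.1
    ...

A JSON dialect mirrors the same content (keys ``fps``, ``columns``,
``rows``).  Velocities are forward differences assigned to the earlier
frame: ``v(t, i) = (x(t+1, i) - x(t, i)) * fps``; tracking gaps simply
produce no velocity row, no interpolation is performed at this layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

POSITION_COLUMNS = ["frame", "id", "x", "y", "z"]


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory data."""


@dataclass
class TrajectorySet:
    """Per-frame 3D positions of identified individuals at a fixed frame rate.

    Parameters
    ----------
    positions : pandas.DataFrame
        Columns ``frame, id, x, y, z``; one row per detection, positions in mm.
    fps : float
        Recording frame rate in Hz.
    """

    positions: pd.DataFrame
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise TrajectoryError(f"fps must be positive, got {self.fps}")
        df = pd.DataFrame(self.positions)[POSITION_COLUMNS].copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["id"] = df["id"].astype(np.int64)
        for c in "xyz":
            df[c] = df[c].astype(float)
        if (df["frame"] < 0).any():
            raise TrajectoryError("frame indices must be non-negative")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise TrajectoryError("positions must be finite")
        dup = df.duplicated(subset=["frame", "id"])
        if dup.any():
            pairs = df.loc[dup, ["frame", "id"]].to_records(index=False).tolist()
            raise TrajectoryError(f"duplicate (frame, id) pairs: {pairs[:5]}")
        df = df.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
        self.positions = df

    @property
    def n_individuals(self) -> int:
        return int(self.positions["id"].nunique())

    @property
    def n_frames(self) -> int:
        """Nominal frame count: last frame index + 1."""
        if len(self.positions) == 0:
            return 0
        return int(self.positions["frame"].max()) + 1

    @property
    def duration(self) -> float:
        """Recording length in seconds (nominal frame count / fps)."""
        return self.n_frames / self.fps

    def frame(self, frame: int) -> pd.DataFrame:
        return self.positions[self.positions["frame"] == frame]

    def coords(self, frame: int) -> np.ndarray:
        """(n, 3) array of positions present at `frame`, sorted by id."""
        return self.frame(frame)[["x", "y", "z"]].to_numpy()


@dataclass
class VelocityField:
    """Forward-difference velocities aligned with a :class:`TrajectorySet`.

    ``velocities`` has columns ``frame, id, vx, vy, vz`` in mm/s; a row
    exists for (frame, id) iff positions exist at both (frame, id) and
    (frame+1, id).
    """

    velocities: pd.DataFrame
    fps: float

    def frame(self, frame: int) -> pd.DataFrame:
        return self.velocities[self.velocities["frame"] == frame]

    def vectors(self, frame: int) -> np.ndarray:
        return self.frame(frame)[["vx", "vy", "vz"]].to_numpy()


@dataclass
class WindowSegmentation:
    """Disjoint, consecutive, equal-length frame windows; tail discarded.

    ``windows`` is a list of half-open ``(start_frame, end_frame)`` intervals.
    """

    window_length: float  # seconds
    fps: float
    windows: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def derive_velocities(t: TrajectorySet) -> VelocityField:
    """Forward-difference velocities, assigned to the earlier frame.

    Individuals absent from the successor frame contribute no velocity row,
    so tracking gaps silently truncate tracks rather than being interpolated.
    """
    df = t.positions
    nxt = df.copy()
    nxt["frame"] -= 1  # row at (frame, id) now means "position at frame+1"
    merged = df.merge(nxt, on=["frame", "id"], suffixes=("", "_next"))
    out = merged[["frame", "id"]].copy()
    for c in "xyz":
        out["v" + c] = (merged[c + "_next"] - merged[c]) * t.fps
    return VelocityField(out.reset_index(drop=True), fps=t.fps)


def segment_windows(t: TrajectorySet, window_length: float = 120.0) -> WindowSegmentation:
    """Cut the recording into consecutive windows of `window_length` seconds.

    The number of windows is floor(duration / window_length); a shorter tail
    is discarded.  Each collective state is treated as steady within a window.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    frames_per_window = int(round(window_length * t.fps))
    n_windows = t.n_frames // frames_per_window
    if n_windows == 0:
        warnings.warn(
            f"recording ({t.duration:.1f} s) shorter than window "
            f"({window_length:.1f} s); empty segmentation",
            stacklevel=2,
        )
    windows = [
        (k * frames_per_window, (k + 1) * frames_per_window) for k in range(n_windows)
    ]
    return WindowSegmentation(window_length=window_length, fps=t.fps, windows=windows)


# ---------------------------------------------------------------------------
# trajectory I/O


def _metadata_header(fps: float, **extra) -> str:
    lines = [f"# shoalkit trajectory v1 (shoalkit {__version__})", f"# fps={fps}", "# units=mm"]
    lines += [f"# {k}={v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"


def write_trajectories(t: TrajectorySet, path, dialect: str = "csv") -> None:
    """Write a TrajectorySet in the canonical CSV or JSON dialect."""
    if dialect == "csv":
        with open(path, "w") as fh:
            fh.write(_metadata_header(t.fps, **t.meta))
            t.positions.to_csv(fh, index=False, float_format="%.17g")
    elif dialect == "json":
        payload = {
            "format": "shoalkit trajectory v1",
            "version": __version__,
            "fps": t.fps,
            "units": "mm",
            "columns": POSITION_COLUMNS,
            "rows": t.positions.to_numpy().tolist(),
            **t.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trajectories(path, dialect: str = "csv", fps: float | None = None) -> TrajectorySet:
    """Read a trajectory table written in the canonical CSV or JSON dialect.

    ``fps`` overrides (or supplies, if the file lacks it) the frame rate.
    """
    if dialect == "csv":
        meta: dict = {}
        with open(path) as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                c = line[1:].strip()
                if "=" in c:
                    k, _, v = c.partition("=")
                    meta[k.strip()] = v.strip()
            try:
                df = pd.read_csv(fh)
            except Exception as exc:  # surface the offending file, keep cause
                raise TrajectoryError(f"cannot parse {path}: {exc}") from exc
        file_fps = float(meta.pop("fps")) if "fps" in meta else None
    elif dialect == "json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise TrajectoryError(f"cannot parse {path}: {exc}") from exc
        df = pd.DataFrame(payload["rows"], columns=payload.get("columns", POSITION_COLUMNS))
        file_fps = payload.get("fps")
        meta = {
            k: v
            for k, v in payload.items()
            if k not in {"rows", "columns", "fps", "format", "version", "units"}
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing required columns {missing}")
    use_fps = fps if fps is not None else file_fps
    if use_fps is None:
        raise TrajectoryError(f"{path}: no fps in metadata and none supplied")
    meta.pop("units", None)
    return TrajectorySet(df, fps=float(use_fps), meta=meta)


# ---------------------------------------------------------------------------
# behavioural-quantity JSON (windowed shoal descriptors)

#: Synonyms accepted for each behavioural quantity when reading external
#: JSON files whose exact key names vary.  First entry is canonical.
BEHAVIOURAL_KEY_SYNONYMS: dict[str, tuple[str, ...]] = {
    "v0": ("v0", "speed", "mean_speed", "v_0", "average_speed"),
    "phi": ("phi", "polarisation", "polarization", "order_parameter"),
    "lnn": ("lnn", "l_nn", "nn_dist", "nearest_neighbour_distance", "nearest_neighbor_distance"),
    "tau": ("tau", "relaxation_time", "t_relax", "tau_relax"),
    "epsilon": ("epsilon", "attraction", "effective_attraction", "eps"),
    "lp": ("lp", "l_p", "persistence_length"),
    "kappa": ("kappa", "reduced_persistence_length", "k"),
}

_MANDATORY = ("v0", "phi", "lnn", "tau")


def _canonicalise_record(rec: dict) -> dict:
    out = dict(rec)  # unknown keys are preserved, not dropped
    lowered = {str(k).lower(): k for k in rec}
    for canon, synonyms in BEHAVIOURAL_KEY_SYNONYMS.items():
        for syn in synonyms:
            if syn in lowered:
                out[canon] = rec[lowered[syn]]
                break
    return out


def read_behavioural_dataset(path) -> pd.DataFrame:
    """Read per-window behavioural quantities from a JSON file.

    Accepts either ``{"groups": {label: [record, ...]}}``, a flat mapping
    ``{label: [record, ...]}``, or a flat list of records carrying a
    ``group`` key.  Key synonyms (e.g. ``phi`` / ``polarisation``) are
    mapped onto canonical names; unknown keys are kept as extra columns.
    """
    with open(path) as fh:
        payload = json.load(fh)

    if isinstance(payload, dict) and "groups" in payload:
        groups = payload["groups"]
    elif isinstance(payload, list):
        groups = {"all": payload}
    else:
        groups = {
            k: v for k, v in payload.items() if isinstance(v, list)
        }
        if not groups:
            raise TrajectoryError(f"{path}: unrecognised behavioural-dataset layout")

    records = []
    for label, recs in groups.items():
        for w, rec in enumerate(recs):
            out = _canonicalise_record(rec)
            out.setdefault("group", label if "group" not in rec else rec["group"])
            out.setdefault("window", w)
            records.append(out)

    df = pd.DataFrame.from_records(records)
    for key in _MANDATORY:
        if key not in df.columns or df[key].isna().all():
            raise TrajectoryError(
                f"{path}: behavioural dataset lacks mandatory quantity {key!r} "
                f"(accepted names: {BEHAVIOURAL_KEY_SYNONYMS[key]})"
            )
    if "lp" not in df.columns:
        df["lp"] = df["v0"] * df["tau"]
    if "kappa" not in df.columns:
        df["kappa"] = df["lp"] / df["lnn"]
    return df


def write_behavioural_dataset(states, path, **meta) -> None:
    """Write BehaviouralState records as grouped JSON (round-trips with the reader)."""
    groups: dict[str, list] = {}
    for s in states:
        rec = s.to_record() if hasattr(s, "to_record") else dict(s)
        groups.setdefault(rec.get("group", "all"), []).append(rec)
    payload = {"format": "shoalkit behavioural v1", "version": __version__, **meta,
               "groups": groups}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
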