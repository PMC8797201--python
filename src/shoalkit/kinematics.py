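"""Scalar behavioural quantities of a swimming group and their temporal statistics.

Per-frame descriptors
---------------------
* mean speed            v0  = (1/N) sum_i |v_i|              [mm/s]
* polarisation          Phi = (1/N) |sum_i v_i / |v_i||      [0, 1]
* nearest-neighbour
  distance              l_nn = mean_i min_{j != i} |x_i - x_j|   [mm]

Temporal statistics
-------------------
* autocorrelation of scalar series (mean-subtracted, normalised at lag 0),
* orientation autocorrelation <o_i(t) . o_i(t+lag)> averaged over
  individuals and time origins (not mean-subtracted),
* exponential relaxation time tau fitted to the orientation ACF,
* persistence length l_p = <v0><tau> and its reduced form
  kappa = l_p / <l_nn>.

Per-window averages of these quantities form a :class:`BehaviouralState`;
a sequence of windows describes how the collective state of the group
drifts between schooling (high Phi) and shoaling (low Phi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.tsa.stattools import acf as _sm_acf

from .trajectory import TrajectorySet, VelocityField

logger = logging.getLogger(__name__)


class UndefinedValueError(ValueError):
    """The requested quantity is undefined on the given data (e.g. empty frame)."""


@dataclass
class AcfCurve:
    """A normalised autocorrelation function on a grid of time lags.

    ``lags`` are in seconds, strictly increasing, starting at 0 where
    ``values[0] == 1``; ``n_pairs[k]`` counts the (origin, origin+lag)
    products averaged into ``values[k]``.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)


@dataclass
class BehaviouralState:
    """Window-averaged description of the collective state of a group.

    All brackets are 120 s (or `window`-long) time averages.  `epsilon`
    (effective attraction, from the RDF peak) is filled in by the
    spatial-correlation layer and may be None.
    """

    v0_mean: float          # <v0>, mm/s
    phi_mean: float         # <Phi>, dimensionless
    lnn_mean: float         # <l_nn>, mm
    tau: float              # <tau>, s
    lp: float               # <l_p> = <v0><tau>, mm
    kappa: float            # <l_p>/<l_nn>, dimensionless
    window: tuple[float, float]  # (start, end) seconds
    group_label: str = ""
    epsilon: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-1e-9 <= self.phi_mean <= 1 + 1e-9):
            raise ValueError(f"phi_mean out of [0,1]: {self.phi_mean}")
        if self.v0_mean < 0 or self.lnn_mean <= 0 or self.tau <= 0:
            raise ValueError("v0_mean must be >= 0; lnn_mean and tau must be > 0")
        if not np.isclose(self.lp, self.v0_mean * self.tau, rtol=1e-9):
            raise ValueError("lp must equal v0_mean * tau")
        if not np.isclose(self.kappa, self.lp / self.lnn_mean, rtol=1e-9):
            raise ValueError("kappa must equal lp / lnn_mean")

    def to_record(self) -> dict:
        rec = {
            "group": self.group_label,
            "window_start": self.window[0],
            "window_end": self.window[1],
            "v0": self.v0_mean,
            "phi": self.phi_mean,
            "lnn": self.lnn_mean,
            "tau": self.tau,
            "lp": self.lp,
            "kappa": self.kappa,
        }
        if self.epsilon is not None:
            rec["epsilon"] = self.epsilon
        rec.update(self.extras)
        return rec


# ---------------------------------------------------------------------------
# per-frame quantities


def speed_magnitudes(v: VelocityField, frame: int) -> np.ndarray:
    vecs = v.vectors(frame)
    if len(vecs) == 0:
        raise UndefinedValueError(f"no velocities at frame {frame}")
    return np.linalg.norm(vecs, axis=1)


def frame_speed(v: VelocityField, frame: int) -> float:
    """Mean speed v0 over individuals tracked at `frame` (mm/s)."""
    return float(speed_magnitudes(v, frame).mean())


def polarisation(vectors: np.ndarray) -> float:
    """Modulus of the mean unit vector of `vectors` (rows with |v|=0 dropped)."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    nonzero = norms > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.debug("polarisation: excluding %d zero-magnitude velocities", n_dropped)
    if not nonzero.any():
        raise UndefinedValueError("all velocities have zero magnitude")
    units = vectors[nonzero] / norms[nonzero, None]
    return float(np.linalg.norm(units.mean(axis=0)))


def frame_polarisation(v: VelocityField, frame: int) -> float:
    """Polarisation Phi of the group at `frame`; 1 = parallel, ~0 = isotropic."""
    vecs = v.vectors(frame)
    if len(vecs) == 0:
        raise UndefinedValueError(f"no velocities at frame {frame}")
    return polarisation(vecs)


def nearest_neighbour_distances(points: np.ndarray, box: float | None = None) -> np.ndarray:
    """Per-point distance to the closest other point.

    `box` enables periodic minimum-image distances in a cubic box of that
    edge (used when the same code path analyses periodic simulations).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise UndefinedValueError("need at least 2 individuals for l_nn")
    tree = cKDTree(np.mod(points, box) if box else points, boxsize=box)
    dists, _ = tree.query(np.mod(points, box) if box else points, k=2)
    return dists[:, 1]


def frame_nearest_neighbour_distance(t: TrajectorySet, frame: int) -> float:
    """Mean nearest-neighbour distance l_nn at `frame` (mm)."""
    return float(nearest_neighbour_distances(t.coords(frame)).mean())


# ---------------------------------------------------------------------------
# autocorrelation functions


def scalar_acf(series: np.ndarray, fps: float, max_lag: float) -> AcfCurve:
    """ACF of a scalar time series, mean-subtracted, normalised to 1 at lag 0.

    Uses the biased (1/T) estimator; lags run 0 .. `max_lag` seconds on the
    frame grid.
    """
    series = np.asarray(series, dtype=float)
    n_lags = int(round(max_lag * fps))
    if len(series) <= 2 * n_lags:
        warnings.warn(
            f"series length {len(series)} < 2 x max lag {n_lags} frames; "
            "ACF tail will be noisy",
            stacklevel=2,
        )
    if np.ptp(series) == 0:
        raise UndefinedValueError("constant series has undefined ACF (zero variance)")
    n_lags = min(n_lags, len(series) - 1)
    values = _sm_acf(series, nlags=n_lags, fft=True)
    lags = np.arange(n_lags + 1) / fps
    n_pairs = len(series) - np.arange(n_lags + 1)
    return AcfCurve(lags=lags, values=values, n_pairs=n_pairs)


def _unit_orientation_array(v: VelocityField) -> np.ndarray:
    """(n_frames, n_ids, 3) array of unit velocities, NaN where untracked."""
    df = v.velocities
    frames = df["frame"].to_numpy()
    ids_all = np.unique(df["id"].to_numpy())
    id_index = {i: k for k, i in enumerate(ids_all)}
    T = int(frames.max()) + 1 if len(frames) else 0
    arr = np.full((T, len(ids_all), 3), np.nan)
    cols = df[["vx", "vy", "vz"]].to_numpy()
    norms = np.linalg.norm(cols, axis=1)
    ok = norms > 0
    rows = frames[ok]
    col_idx = np.array([id_index[i] for i in df["id"].to_numpy()[ok]])
    arr[rows, col_idx] = cols[ok] / norms[ok, None]
    return arr


def unit_vector_acf(U: np.ndarray, fps: float, max_lag: float) -> AcfCurve:
    """Orientation ACF of a (n_frames, n_tracks, 3) unit-vector array.

    Averages o_i(t) . o_i(t + lag) over tracks and time origins; NaN rows
    (missing detections) are skipped.  Not mean-subtracted — perfect
    persistence gives 1 at every lag; value at lag 0 is exactly 1.
    """
    U = np.asarray(U, dtype=float)
    T = U.shape[0]
    n_lags = min(int(round(max_lag * fps)), T - 1)
    if T < 2:
        raise UndefinedValueError("no track long enough for an orientation ACF")
    if not np.isnan(U).any():
        # gap-free: FFT autocorrelation per agent/component
        M = U.reshape(T, -1)
        nfft = 1 << int(np.ceil(np.log2(2 * T)))
        F = np.fft.rfft(M, n=nfft, axis=0)
        corr = np.fft.irfft((F * F.conj()).real, n=nfft, axis=0)[: n_lags + 1]
        # sum x,y,z components per agent, then over agents
        total = corr.reshape(n_lags + 1, U.shape[1], 3).sum(axis=(1, 2))
        counts = (T - np.arange(n_lags + 1)) * U.shape[1]
    else:
        total = np.zeros(n_lags + 1)
        counts = np.zeros(n_lags + 1, dtype=np.int64)
        for k in range(n_lags + 1):
            dots = np.einsum("tij,tij->ti", U[: T - k], U[k:])
            valid = np.isfinite(dots)
            total[k] = np.nansum(np.where(valid, dots, 0.0))
            counts[k] = valid.sum()
    if counts[0] == 0 or (counts[1:] == 0).all():
        raise UndefinedValueError("no track long enough for an orientation ACF")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    lags = np.arange(n_lags + 1) / fps
    values = values / values[0]  # exact 1 at lag 0 (guards rounding)
    return AcfCurve(lags=lags, values=values, n_pairs=counts)


def orientation_acf(v: VelocityField, max_lag: float) -> AcfCurve:
    """Orientation ACF of tracked individuals (see :func:`unit_vector_acf`)."""
    return unit_vector_acf(_unit_orientation_array(v), fps=v.fps, max_lag=max_lag)


def fit_relaxation_time(
    acf: AcfCurve, floor: float = 0.2, plateau: float | str | None = "auto"
) -> float:
    """Relaxation time tau (s) of the fast exponential decay of an ACF.

    Fits a straight line to log of the plateau-corrected ACF,
    (C - p) / (1 - p), over the leading lags where that quantity stays
    above `floor`; at least 3 points are required.  In an ordered group
    the orientation ACF does not decay to zero but to a plateau near the
    squared polarisation (the collective direction persists far longer
    than any individual heading); `plateau="auto"` estimates p from the
    mean of the last quarter of lags and applies it only when it is
    appreciable (> 0.05), so a plain exponential is fitted exactly.
    Pass a float to fix p, or None to force p = 0.
    """
    vals = np.asarray(acf.values, dtype=float)
    lags = np.asarray(acf.lags, dtype=float)
    if plateau == "auto":
        tail = vals[3 * len(vals) // 4 :]
        p = float(np.nanmean(tail)) if len(tail) else 0.0
        if not np.isfinite(p) or p <= 0.05:
            p = 0.0
        p = min(p, 0.95)
    else:
        p = float(plateau) if plateau is not None else 0.0
    with np.errstate(invalid="ignore"):
        vals = (vals - p) / (1.0 - p)
    above = vals > floor
    # leading run of above-floor lags
    stop = int(np.argmin(above)) if not above.all() else len(vals)
    if stop < 3:
        raise ValueError(
            f"fewer than 3 ACF points above the fit floor {floor}; "
            "decrease the floor or sample finer lags"
        )
    x, y = lags[:stop], np.log(vals[:stop])
    slope, _ = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError(
            "orientation ACF does not decay over the fitted range; "
            "increase max_lag or add noise to the dynamics"
        )
    return float(-1.0 / slope)


# ---------------------------------------------------------------------------
# windowed behavioural state


def window_state(
    t: TrajectorySet,
    v: VelocityField,
    window: tuple[int, int],
    group_label: str = "",
    acf_max_lag: float | None = None,
    acf_floor: float = 0.2,
) -> BehaviouralState:
    """Average v0, Phi and l_nn over a frame window and fit tau within it.

    `window` is a half-open (start_frame, end_frame) interval.  The
    orientation ACF is computed from the window's velocities only (each
    window treated as a steady state); `acf_max_lag` defaults to a quarter
    of the window length.
    """
    start, end = window
    vel = v.velocities
    vel_w = vel[(vel["frame"] >= start) & (vel["frame"] < end)]
    pos = t.positions
    pos_w = pos[(pos["frame"] >= start) & (pos["frame"] < end)]
    if len(vel_w) == 0 or len(pos_w) == 0:
        raise UndefinedValueError(f"window {window}: no tracked data")

    speeds = np.linalg.norm(vel_w[["vx", "vy", "vz"]].to_numpy(), axis=1)
    v0_mean = float(pd.Series(speeds).groupby(vel_w["frame"].to_numpy()).mean().mean())

    phis = []
    for _, grp in vel_w.groupby("frame"):
        try:
            phis.append(polarisation(grp[["vx", "vy", "vz"]].to_numpy()))
        except UndefinedValueError:
            continue
    if not phis:
        raise UndefinedValueError(f"window {window}: polarisation undefined in every frame")
    phi_mean = float(np.mean(phis))

    lnns = []
    for _, grp in pos_w.groupby("frame"):
        if len(grp) >= 2:
            lnns.append(nearest_neighbour_distances(grp[["x", "y", "z"]].to_numpy()).mean())
    if not lnns:
        raise UndefinedValueError(f"window {window}: <2 individuals in every frame")
    lnn_mean = float(np.mean(lnns))

    # tau from the window's own orientation ACF (frames re-based to 0)
    vel_local = vel_w.copy()
    vel_local["frame"] -= start
    if acf_max_lag is None:
        acf_max_lag = (end - start) / t.fps / 4
    acf = orientation_acf(VelocityField(vel_local, fps=t.fps), max_lag=acf_max_lag)
    tau = fit_relaxation_time(acf, floor=acf_floor)

    lp = v0_mean * tau
    return BehaviouralState(
        v0_mean=v0_mean,
        phi_mean=phi_mean,
        lnn_mean=lnn_mean,
        tau=tau,
        lp=lp,
        kappa=lp / lnn_mean,
        window=(start / t.fps, end / t.fps),
        group_label=group_label,
    )
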