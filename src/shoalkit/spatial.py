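"""Pair-correlation statistics of a confined group.

Radial distribution function (RDF)
----------------------------------
g(r) is the histogram of observed pair distances divided by the pair-distance
histogram of uniform, non-interacting configurations of the same number of
individuals drawn in the same arena (Monte-Carlo ideal-gas normalisation —
the arena is irregular and non-periodic, so no analytic shell volume
exists).  The peak height of g beyond the first bin measures cohesion, and
its negative logarithm is the "effective attraction"

    epsilon = -ln(max_r g)        (more cohesive -> higher peak -> lower epsilon),

by analogy with potentials of mean force in liquids.

Velocity-fluctuation correlation
--------------------------------
C(r) averages, over frames and over pairs at distance ~r, the dot product
of velocity fluctuations (each frame's mean velocity subtracted):

    C(r) = < sum_{i<j} dv_i . dv_j delta(r - r_ij) / sum_{i<j} delta(r - r_ij) >

with the Dirac delta realised as fixed-width distance bins.  Sums over
pairs are accumulated over all frames before dividing by the accumulated
pair counts (time-averaged estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .arena import Arena
from .trajectory import TrajectorySet, VelocityField


@dataclass
class RdfCurve:
    """Binned radial distribution function with its cohesion summary."""

    bin_edges: np.ndarray   # mm
    g_values: np.ndarray    # dimensionless, NaN where the reference is empty
    pair_counts: np.ndarray  # observed pairs per bin (summed over frames)
    peak_height: float
    peak_location: float    # mm, bin centre of the peak

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class VelocityCorrelationCurve:
    """Binned spatial correlation of velocity fluctuations.

    Bins with no pairs hold NaN in ``C_values`` (explicitly empty, not 0).
    ``rescaled_by_lnn`` flags whether ``bin_centers`` are in units of the
    window's mean nearest-neighbour distance instead of mm.
    """

    bin_centers: np.ndarray
    C_values: np.ndarray       # (mm/s)^2
    pair_counts: np.ndarray
    rescaled_by_lnn: bool = False
    lnn_scale: float | None = None

    def normalised(self) -> np.ndarray:
        """C divided by its first occupied bin (display variant; raw values kept)."""
        occ = np.flatnonzero(self.pair_counts > 0)
        if len(occ) == 0:
            raise ValueError("no occupied bins")
        return self.C_values / self.C_values[occ[0]]


def _pair_distance_histogram(points: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(pdist(points), bins=bin_edges)
    return counts


def rdf(
    t: TrajectorySet,
    frames,
    arena: Arena,
    n_reference: int = 50,
    bin_width: float = 5.0,
    r_max: float | None = None,
    seed: int | np.random.Generator = 0,
) -> RdfCurve:
    """Radial distribution function of the group over a set of frames.

    Observed pair-distance counts (summed over `frames`) are divided by the
    mean pair-distance histogram of `n_reference` uniform configurations of
    the same N drawn in `arena`.  The peak is searched beyond the first bin
    (short-range depletion from body size makes r -> 0 unreliable).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")

    configs = [t.coords(f) for f in frames]
    for f, pts in zip(frames, configs):
        if len(pts) < 2:
            raise ValueError(f"frame {f}: fewer than 2 individuals")
        outside = ~arena.contains(pts)
        if outside.any():
            raise ValueError(
                f"frame {f}: {int(outside.sum())} positions outside the arena, "
                f"e.g. {pts[outside][:3].tolist()}"
            )

    if r_max is None:
        r_max = max(pdist(pts).max() for pts in configs) * 1.05
    bin_edges = np.arange(0.0, r_max + bin_width, bin_width)

    obs = np.zeros(len(bin_edges) - 1)
    for pts in configs:
        obs += _pair_distance_histogram(pts, bin_edges)
    obs_mean = obs / len(configs)

    n_typical = int(round(np.mean([len(p) for p in configs])))
    ref = np.zeros_like(obs_mean)
    for _ in range(n_reference):
        ref += _pair_distance_histogram(arena.sample(n_typical, rng), bin_edges)
    ref_mean = ref / n_reference

    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ref_mean > 0, obs_mean / ref_mean, np.nan)

    interior = g[1:]
    if np.all(np.isnan(interior)):
        raise ValueError("reference histogram empty beyond the first bin")
    k = int(np.nanargmax(interior)) + 1
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return RdfCurve(
        bin_edges=bin_edges,
        g_values=g,
        pair_counts=obs.astype(np.int64),
        peak_height=float(g[k]),
        peak_location=float(centers[k]),
    )


def effective_attraction(curve: RdfCurve) -> float:
    """epsilon = -ln(RDF peak height); lower (more negative) = more cohesive."""
    if not np.isfinite(curve.peak_height) or curve.peak_height <= 0:
        raise ValueError(f"RDF peak height must be positive, got {curve.peak_height}")
    return float(-np.log(curve.peak_height))


def rdf_time_sequence(
    t: TrajectorySet,
    windows,
    arena: Arena,
    frame_step: int = 1,
    **kwargs,
) -> list[RdfCurve]:
    """One RdfCurve per frame window (enables the epsilon-over-time series).

    `windows` holds half-open (start_frame, end_frame) intervals;
    `frame_step` subsamples frames inside each window to bound cost.
    """
    present = np.unique(t.positions["frame"].to_numpy())
    curves = []
    for start, end in windows:
        frames = [f for f in range(start, end, frame_step) if f in set(present)]
        curves.append(rdf(t, frames, arena, **kwargs))
    return curves


def velocity_correlation(
    t: TrajectorySet,
    v: VelocityField,
    frames,
    bin_width: float = 5.0,
    r_max: float | None = None,
    rescale_by_lnn: float | None = None,
) -> VelocityCorrelationCurve:
    """Spatial correlation C(r) of velocity fluctuations, time-averaged.

    For each frame the frame's mean velocity is subtracted; fluctuation dot
    products are accumulated into distance bins over all `frames` and each
    bin is divided by its accumulated pair count.  Pass the window's mean
    nearest-neighbour distance as `rescale_by_lnn` to express distances in
    units of l_nn (bin_width is then also in those units).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")

    per_frame = []
    for f in frames:
        pos_df = t.frame(f)
        vel_df = v.frame(f)
        merged = pos_df.merge(vel_df, on=["frame", "id"])
        if len(merged) < 2:
            continue
        pts = merged[["x", "y", "z"]].to_numpy()
        vel = merged[["vx", "vy", "vz"]].to_numpy()
        dv = vel - vel.mean(axis=0)
        d = pdist(pts)
        if rescale_by_lnn:
            d = d / rescale_by_lnn
        iu, ju = np.triu_indices(len(merged), k=1)
        dots = np.einsum("ij,ij->i", dv[iu], dv[ju])
        per_frame.append((d, dots))
    if not per_frame:
        raise ValueError("no frame has >= 2 individuals with velocities")

    if r_max is None:
        r_max = max(d.max() for d, _ in per_frame) * 1.05
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    num = np.zeros(len(edges) - 1)
    cnt = np.zeros(len(edges) - 1, dtype=np.int64)
    for d, dots in per_frame:
        which = np.digitize(d, edges) - 1
        ok = (which >= 0) & (which < len(cnt))
        np.add.at(num, which[ok], dots[ok])
        np.add.at(cnt, which[ok], 1)
    with np.errstate(invalid="ignore"):
        C = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VelocityCorrelationCurve(
        bin_centers=centers,
        C_values=C,
        pair_counts=cnt,
        rescaled_by_lnn=rescale_by_lnn is not None,
        lnn_scale=rescale_by_lnn,
    )
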