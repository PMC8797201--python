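"""3D inertial Vicsek model with scalar (spherical-cap) noise.

Agents are point particles moving at constant speed v0 in a periodic cube.
Each time step every agent takes the normalised velocity sum of its metric
neighbours (all agents within the interaction range xi, itself included),
perturbs it by a random rotation drawn uniformly from a spherical cap of
area 4*pi*eta centred on it, and mixes the result with its own previous
velocity with inertia weight alpha:

    v_i(t+1) = v0 * N[ (1-alpha) * v0 * R_eta[ N( sum_{j in S_i} v_j(t) ) ]
                       + alpha * v_i(t) ]

where N is vector normalisation.  alpha = 0 recovers the standard Vicsek
model; alpha = 1 gives straight-line motion.  eta = 0 is noiseless; eta = 1
redraws directions uniformly on the whole sphere.

Units: interaction range xi = 1 and time step dt = 1 set the simulation
units; density rho is in xi^-3 and speed in xi/dt.

Observables mirror the fish analysis: polarisation Phi(t), susceptibility
chi = N * var(Phi), orientational relaxation time tau from the orientation
ACF, nearest-neighbour distance (minimum image), and the reduced
persistence length kappa = v0 * tau / l_nn — measured from simulated
trajectories through the same kinematics code paths used for fish data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import kinematics
from .trajectory import TrajectorySet


@dataclass
class SimConfig:
    """Parameters of the inertial Vicsek simulation (Eq. units xi = dt = 1)."""

    n: int = 50             # matches the observed group size; Phi is N-dependent
    rho: float = 1.0        # number density, xi^-3
    xi: float = 1.0         # interaction range (length unit)
    dt: float = 1.0         # time step (time unit)
    v0: float = 0.1         # speed, xi/dt
    alpha: float = 0.63     # inertia fraction in [0, 1]
    eta: float = 0.65       # noise: cap area fraction in [0, 1]
    n_steps: int = 5000
    n_equilibration: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0,1], got {self.eta}")
        if self.v0 <= 0 or self.rho <= 0 or self.n < 1:
            raise ValueError("v0 and rho must be positive, n >= 1")

    @property
    def box_length(self) -> float:
        return float((self.n / self.rho) ** (1.0 / 3.0) * self.xi)


@dataclass
class SimState:
    """Positions in [0, L)^3 and velocities of magnitude v0; one time step."""

    positions: np.ndarray   # (n, 3)
    velocities: np.ndarray  # (n, 3), |v_i| = v0
    step: int = 0


@dataclass
class RunResult:
    """Observable series and (optionally) state snapshots of one run."""

    config: SimConfig
    phi: np.ndarray                       # polarisation per measured step
    positions: np.ndarray | None = None   # (n_snapshots, n, 3), wrapped
    velocities: np.ndarray | None = None  # (n_snapshots, n, 3)
    snapshot_stride: int = 1

    @property
    def phi_mean(self) -> float:
        return float(self.phi.mean())

    def phi_standard_error(self, n_blocks: int = 10) -> float:
        """Blocked standard error of <Phi> (guards serial correlation)."""
        m = len(self.phi) // n_blocks
        if m < 1:
            return float(self.phi.std(ddof=1) / np.sqrt(len(self.phi)))
        blocks = self.phi[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
        return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def normalise(vec: np.ndarray) -> np.ndarray:
    """vec / |vec|; raises on zero vectors.  Works on (..., 3) arrays."""
    vec = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot normalise a zero vector")
    return vec / norm


def _orthonormal_frame(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to each row of `directions`."""
    d = directions
    helper = np.zeros_like(d)
    use_x = np.abs(d[:, 2]) > 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 2] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def cap_rotate(
    directions: np.ndarray, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Redraw each direction uniformly from the spherical cap of area 4*pi*eta
    centred on it.

    The cap is {u : u . d >= 1 - 2*eta}: cos(theta) is drawn uniformly on
    [1 - 2*eta, 1] and the azimuth uniformly on [0, 2*pi).  eta = 0 returns
    the input exactly; eta = 1 is a uniform redraw on the whole sphere.
    Draw order (one uniform array for cos(theta), then one for the azimuth)
    is part of the reproducibility contract.
    """
    single = np.ndim(directions) == 1
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if eta == 0.0:
        out = d.copy()
        return out[0] if single else out
    n = len(d)
    cos_t = rng.uniform(1.0 - 2.0 * eta, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    e1, e2 = _orthonormal_frame(d)
    out = (
        cos_t[:, None] * d
        + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    return out[0] if single else out


def neighbours(positions: np.ndarray, xi: float, box_length: float) -> list[np.ndarray]:
    """Metric neighbour sets S_i = {j : min-image dist(i,j) <= xi}, self included."""
    pos = np.mod(positions, box_length)
    tree = cKDTree(pos, boxsize=box_length)
    pairs = tree.query_pairs(r=xi, output_type="ndarray")
    sets: list[list[int]] = [[i] for i in range(len(pos))]
    for i, j in pairs:
        sets[i].append(j)
        sets[j].append(i)
    return [np.sort(np.array(s)) for s in sets]


def _neighbour_velocity_sums(
    positions: np.ndarray, velocities: np.ndarray, xi: float, box_length: float
) -> np.ndarray:
    tree = cKDTree(positions, boxsize=box_length)
    pairs = tree.query_pairs(r=xi, output_type="ndarray")
    sums = velocities.copy()  # self term
    if len(pairs):
        np.add.at(sums, pairs[:, 0], velocities[pairs[:, 1]])
        np.add.at(sums, pairs[:, 1], velocities[pairs[:, 0]])
    return sums


def _safe_unit(vectors: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Normalise rows; rows with zero norm take the corresponding fallback row."""
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    out = np.where(zero[:, None], fallback, vectors / np.where(norms == 0, 1.0, norms))
    return out


def initial_state(config: SimConfig, rng: np.random.Generator) -> SimState:
    """Uniform random positions; isotropic random headings at speed v0."""
    L = config.box_length
    pos = rng.uniform(0.0, L, size=(config.n, 3))
    u = rng.normal(size=(config.n, 3))
    u = normalise(u)
    return SimState(positions=pos, velocities=config.v0 * u, step=0)


def step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """One synchronous update of every agent, then forward streaming.

    An exactly cancelling neighbour-velocity sum (measure-zero) falls back
    to the agent's own current heading, both inside the alignment term and
    after the inertia mixture.
    """
    L = config.box_length
    own_u = state.velocities / config.v0
    sums = _neighbour_velocity_sums(state.positions, state.velocities, config.xi, L)
    align_u = _safe_unit(sums, own_u)
    noisy_u = cap_rotate(align_u, config.eta, rng)
    mixed = (1.0 - config.alpha) * noisy_u + config.alpha * own_u
    new_u = _safe_unit(mixed, own_u)
    new_v = config.v0 * new_u
    new_pos = np.mod(state.positions + new_v * config.dt, L)
    return SimState(positions=new_pos, velocities=new_v, step=state.step + 1)


def polarisation_of(velocities: np.ndarray) -> float:
    return float(np.linalg.norm(normalise(velocities).mean(axis=0)))


def run(
    config: SimConfig,
    store_snapshots: bool = False,
    snapshot_stride: int = 1,
    max_snapshots: int = 5000,
) -> RunResult:
    """Equilibrate, then measure Phi each step; optionally keep state snapshots.

    Snapshots (wrapped positions + velocities, float32) are taken every
    `snapshot_stride` steps over the last `max_snapshots * snapshot_stride`
    measurement steps — enough to measure tau and l_nn without holding the
    whole trajectory.
    """
    rng = np.random.default_rng(config.seed)
    state = initial_state(config, rng)
    for _ in range(config.n_equilibration):
        state = step(state, config, rng)

    phi = np.empty(config.n_steps)
    pos_snaps: list[np.ndarray] = []
    vel_snaps: list[np.ndarray] = []
    snap_start = max(0, config.n_steps - max_snapshots * snapshot_stride)
    for k in range(config.n_steps):
        state = step(state, config, rng)
        phi[k] = polarisation_of(state.velocities)
        if store_snapshots and k >= snap_start and (k - snap_start) % snapshot_stride == 0:
            pos_snaps.append(state.positions.astype(np.float32))
            vel_snaps.append(state.velocities.astype(np.float32))

    return RunResult(
        config=config,
        phi=phi,
        positions=np.array(pos_snaps) if pos_snaps else None,
        velocities=np.array(vel_snaps) if vel_snaps else None,
        snapshot_stride=snapshot_stride,
    )


def to_trajectory_set(result: RunResult, fps: float | None = None) -> TrajectorySet:
    """Unwrapped simulation snapshots as a TrajectorySet (fish code path).

    Positions are unwrapped by accumulating the recorded velocities, so the
    forward differences computed by `derive_velocities` reproduce the
    simulated velocities exactly (up to snapshot precision).  Requires
    snapshot_stride == 1.
    """
    if result.positions is None:
        raise ValueError("run was executed without snapshots")
    if result.snapshot_stride != 1:
        raise ValueError("unwrapping requires snapshot_stride == 1")
    cfg = result.config
    if fps is None:
        fps = 1.0 / cfg.dt
    vel = result.velocities.astype(float)
    pos0 = result.positions[0].astype(float)
    # x(k+1) = x(k) + v(k+1) dt; snapshots store v at each recorded step
    disp = np.cumsum(vel[1:] * cfg.dt, axis=0)
    pos = np.concatenate([pos0[None], pos0[None] + disp], axis=0)
    T, n, _ = pos.shape
    frames = np.repeat(np.arange(T), n)
    ids = np.tile(np.arange(n), T)
    df = pd.DataFrame(
        {
            "frame": frames,
            "id": ids,
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
            "z": pos[:, :, 2].ravel(),
        }
    )
    return TrajectorySet(df, fps=fps, meta={"source": "inertial_vicsek", "seed": cfg.seed})


def susceptibility(phi_series: np.ndarray, n_agents: int) -> float:
    """chi = N * (<Phi^2> - <Phi>^2); peaks near the order-disorder transition."""
    phi_series = np.asarray(phi_series, dtype=float)
    return float(n_agents * phi_series.var())


def measure_kappa(
    result: RunResult,
    acf_max_lag: float | None = None,
    acf_floor: float = 0.2,
    lnn_stride: int = 10,
    plateau: float | str | None = "auto",
) -> dict:
    """Measure tau, l_nn and kappa = v0*tau/l_nn on a finished run.

    Uses the same kinematics code paths as the fish analysis: the
    orientation ACF (per-agent unit velocities, averaged over agents and
    time origins) fitted with an exponential above `acf_floor`, and
    minimum-image nearest-neighbour distances averaged over snapshots.
    In deeply ordered states the slow wandering of the collective
    direction dominates the tail of the ACF; the auto plateau estimate in
    :func:`shoalkit.kinematics.fit_relaxation_time` keeps the fit on the
    decaying part.
    """
    if result.velocities is None:
        raise ValueError("run was executed without snapshots")
    cfg = result.config
    if cfg.eta == 0.0:
        raise ValueError(
            "orientation ACF does not decay in the noiseless (eta = 0) model; "
            "use eta > 0 to measure a relaxation time"
        )
    fps = 1.0 / cfg.dt / result.snapshot_stride  # snapshots per time unit
    U = normalise(result.velocities.astype(float))
    T = U.shape[0]
    if acf_max_lag is None:
        acf_max_lag = (T - 1) / fps / 4
    acf = kinematics.unit_vector_acf(U, fps=fps, max_lag=acf_max_lag)
    tau = kinematics.fit_relaxation_time(acf, floor=acf_floor, plateau=plateau)

    L = cfg.box_length
    lnn_vals = [
        kinematics.nearest_neighbour_distances(p.astype(float), box=L).mean()
        for p in result.positions[::lnn_stride]
    ]
    lnn = float(np.mean(lnn_vals))
    v0_measured = float(np.linalg.norm(result.velocities.astype(float), axis=2).mean())
    lp = v0_measured * tau
    return {
        "v0": v0_measured,
        "tau": tau,
        "lnn": lnn,
        "lp": lp,
        "kappa": lp / lnn,
    }


def sweep(
    template: SimConfig,
    eta_values=None,
    alpha_values=None,
    seed: int | None = None,
    n_replicates: int = 1,
    measure_kappa_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Independent runs over a noise (or inertia) grid; the model kappa-Phi curve.

    Each grid point gets `n_replicates` independent runs with their own
    child seeds; observables are averaged across replicates (kappa's slow
    collective component is noisy in a single run).  Per-point failures
    are recorded in the `error` column and the sweep continues.  Returns
    a DataFrame with columns alpha, eta, phi_mean, phi_se, chi, tau, lnn,
    kappa, seed, error.
    """
    if (eta_values is None) == (alpha_values is None):
        raise ValueError("give exactly one of eta_values or alpha_values")
    grid = [("eta", e) for e in eta_values] if eta_values is not None else [
        ("alpha", a) for a in alpha_values
    ]
    root = np.random.SeedSequence(template.seed if seed is None else seed)
    children = root.spawn(len(grid) * n_replicates)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children]
    rows = []
    for k, (param, value) in enumerate(grid):
        seeds = child_seeds[k * n_replicates : (k + 1) * n_replicates]
        reps = []
        errors = []
        for child_seed in seeds:
            cfg = replace(template, **{param: value}, seed=child_seed)
            try:
                result = run(cfg, store_snapshots=True)
                rep = {
                    "phi_mean": result.phi_mean,
                    "phi_se": result.phi_standard_error(),
                    "chi": susceptibility(result.phi, cfg.n),
                }
                rep.update(measure_kappa(result, **(measure_kappa_kwargs or {})))
                reps.append(rep)
            except Exception as exc:  # keep sweeping; report per-point failure
                errors.append(str(exc))
        row = {"alpha": cfg.alpha, "eta": cfg.eta, "seed": seeds[0],
               "n_replicates": len(reps), "error": "; ".join(errors)}
        if reps:
            agg = pd.DataFrame(reps).mean()
            row.update(agg.to_dict())
            row["phi_se"] = float(agg["phi_se"] / np.sqrt(len(reps)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dilute (non-interacting) limit: persistence-length scaling


def free_agent_relaxation(
    cap_half_angle: float,
    n_agents: int = 200,
    n_steps: int = 20000,
    seed: int = 0,
    acf_floor: float = 0.2,
) -> float:
    """Relaxation time (steps) of independent cap-noise walkers.

    Each agent redraws its heading every step from the spherical cap of
    opening half-angle `cap_half_angle` (radians) centred on its current
    heading — the standard Vicsek update in the dilute limit where the
    neighbour set is the agent itself.  tau is fitted from the orientation
    ACF exactly as for interacting runs.
    """
    eta_area = 0.5 * (1.0 - np.cos(cap_half_angle))  # cap area fraction
    rng = np.random.default_rng(seed)
    u = normalise(rng.normal(size=(n_agents, 3)))
    U = np.empty((n_steps, n_agents, 3))
    for t in range(n_steps):
        u = cap_rotate(u, eta_area, rng)
        U[t] = u
    # expected tau ~ 4/theta^2 steps; fit over ~5 tau of lags
    max_lag = min(n_steps - 1, int(20.0 / cap_half_angle**2))
    acf = kinematics.unit_vector_acf(U, fps=1.0, max_lag=max_lag)
    return kinematics.fit_relaxation_time(acf, floor=acf_floor)


def persistence_length_scaling(
    amplitudes=(0.05, 0.08, 0.12, 0.19, 0.3),
    v0: float = 0.1,
    n_agents: int = 200,
    n_steps: int = 20000,
    seed: int = 0,
) -> dict:
    """Log-log slope of the persistence length vs the noise amplitude.

    The noise amplitude is the cap opening half-angle (radians).  For the
    standard (zero-inertia) Vicsek dynamics the persistence length
    l = v0 * tau scales as v0 / amplitude^2, i.e. slope -2: a cap of
    half-angle theta has area fraction ~ theta^2/4 and per-step mean cosine
    1 - theta^2/4, so tau ~ 4/theta^2 steps.
    """
    root = np.random.SeedSequence(seed)
    taus = []
    for amp, child in zip(amplitudes, root.spawn(len(amplitudes))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        taus.append(
            free_agent_relaxation(amp, n_agents=n_agents, n_steps=n_steps, seed=child_seed)
        )
    taus = np.asarray(taus)
    lengths = v0 * taus
    slope, intercept = np.polyfit(np.log(np.asarray(amplitudes)), np.log(lengths), 1)
    return {
        "amplitudes": np.asarray(amplitudes),
        "tau": taus,
        "persistence_length": lengths,
        "slope": float(slope),
        "intercept": float(intercept),
    }
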