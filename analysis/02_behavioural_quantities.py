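#!/usr/bin/env python
"""Windowed behavioural quantities of each recording.

For every 120 s window: mean speed <v0>, polarisation <Phi>,
nearest-neighbour distance <l_nn>, orientational relaxation time <tau>
from the exponential fit of the orientation autocorrelation, the
persistence length <l_p> = <v0><tau>, the reduced persistence length
kappa = <l_p>/<l_nn>, and the effective attraction <epsilon> from the
windowed radial distribution function.  Results go to one JSON per run
(schema shared with the behavioural-dataset reader).
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shoalkit import kinematics, spatial  # noqa: E402
from shoalkit.arena import ParaboloidArena  # noqa: E402
from shoalkit.trajectory import (  # noqa: E402
    derive_velocities,
    read_trajectories,
    segment_windows,
    write_behavioural_dataset,
)


def analyse(csv_path: Path, label: str, window: float, seed: int):
    traj = read_trajectories(csv_path)
    vel = derive_velocities(traj)
    arena = ParaboloidArena()
    states = []
    for i, (s, e) in enumerate(segment_windows(traj, window)):
        st = kinematics.window_state(traj, vel, (s, e), group_label=label)
        curve = spatial.rdf(
            traj, range(s, e, 5), arena, n_reference=30, bin_width=10.0, seed=seed + i
        )
        st.epsilon = spatial.effective_attraction(curve)
        states.append(st)
    return states


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--window", type=float, default=120.0)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/behavioural_states.json"))
    args = ap.parse_args()

    recordings = sorted(args.in_dir.glob("*.csv"))
    if not recordings:
        ap.error(f"no recordings in {args.in_dir}; run 01_synthesise_recordings.py first")

    all_states = []
    for path in recordings:
        label = path.stem
        states = analyse(path, label, args.window, args.seed)
        all_states.extend(states)
        print(f"\n{label}: {len(states)} windows of {args.window:.0f} s")
        print(f"{'window':>8} {'<v0>':>7} {'<Phi>':>7} {'<lnn>':>7} "
              f"{'<tau>':>7} {'<lp>':>7} {'kappa':>7} {'<eps>':>7}")
        for st in states:
            print(
                f"{st.window[0]:8.0f} {st.v0_mean:7.1f} {st.phi_mean:7.3f} "
                f"{st.lnn_mean:7.1f} {st.tau:7.2f} {st.lp:7.1f} "
                f"{st.kappa:7.2f} {st.epsilon:7.2f}"
            )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_behavioural_dataset(all_states, args.out)
    print(f"\nwrote {len(all_states)} window states -> {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
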