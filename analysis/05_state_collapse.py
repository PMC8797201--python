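#!/usr/bin/env python
"""Macroscopic-state reduction: planar regression and the kappa-Phi collapse.

Pools the windowed behavioural states of all recordings, fits the planar
model Phi = a * l_p + b * l_nn + c by ordinary least squares, and then
collapses the same windows onto the single variable kappa = l_p / l_nn,
comparing them against the inertial Vicsek noise-sweep curve and the
finite-group isotropic baseline.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shoalkit import state  # noqa: E402
from shoalkit.trajectory import read_behavioural_dataset  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--states", type=Path, default=Path("results/behavioural_states.json"))
    ap.add_argument("--sweep", type=Path, default=Path("results/model_sweep.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/state_collapse.json"))
    args = ap.parse_args()

    if not args.states.exists():
        ap.error(f"{args.states} missing; run 02_behavioural_quantities.py first")
    df = read_behavioural_dataset(args.states)
    fit = state.fit_plane(df)
    print(
        f"planar fit over {fit.n_points} windows:\n"
        f"  Phi = {fit.coef_lp:.4f} * l_p {fit.coef_lnn:+.4f} * l_nn "
        f"{fit.intercept:+.4f}   (R^2 = {fit.r_squared:.3f})"
    )
    for g, sub in df.groupby("group"):
        print(f"  group {g}: <Phi> = {sub['phi'].mean():.3f}, "
              f"<l_p> = {sub['lp'].mean():.1f} mm, <l_nn> = {sub['lnn'].mean():.1f} mm, "
              f"kappa in [{sub['kappa'].min():.2f}, {sub['kappa'].max():.2f}]")

    report = {
        "regression": {
            "coef_lp": fit.coef_lp, "coef_lnn": fit.coef_lnn,
            "intercept": fit.intercept, "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        }
    }

    if args.sweep.exists():
        sweep = pd.read_csv(args.sweep)
        cc = state.collapse(df, sweep)
        n_agents = 50
        base_mean, base_sd = state.isotropic_baseline(n_agents, rng=args.seed)
        print(f"\nkappa-Phi collapse against the model sweep: RMS vertical "
              f"deviation = {cc.rms_deviation}")
        print(f"isotropic baseline for N={n_agents}: Phi = {base_mean:.3f} "
              f"+- {base_sd:.3f} (disorder floor)")
        report["collapse"] = {
            "rms_deviation": cc.rms_deviation,
            "model_kappa": None if cc.model_kappa is None else cc.model_kappa.tolist(),
            "model_phi": None if cc.model_phi is None else cc.model_phi.tolist(),
            "points": cc.points.to_dict(orient="records"),
            "isotropic_baseline": {"n": n_agents, "mean": base_mean, "sd": base_sd},
        }
    else:
        print(f"\n{args.sweep} missing; skipping model comparison "
              "(run 04_vicsek_sweep.py for the collapse)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
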