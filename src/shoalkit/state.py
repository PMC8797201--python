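"""Macroscopic-state description: the Phi-(l_p, l_nn) plane and the kappa collapse.

Across 120 s windows the collective state of a shoal is summarised by the
persistence length l_p = <v0><tau> and the nearest-neighbour distance
l_nn.  Two reductions are provided:

* a multilinear (planar) regression Phi = a * l_p + b * l_nn + c fitted by
  ordinary least squares with unstandardised, unit-bearing coefficients
  (per mm), and
* the one-parameter collapse of Phi onto the reduced persistence length
  kappa = l_p / l_nn, compared against the inertial Vicsek model's noise
  sweep by interpolating the model curve in kappa.

The isotropic baseline — the polarisation of N independent uniformly
random unit vectors — gives the floor that a finite disordered group
cannot fall below (it scales as N^{-1/2}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionFit:
    """OLS fit of Phi on (l_p, l_nn) with intercept."""

    coef_lp: float       # per mm
    coef_lnn: float      # per mm
    intercept: float     # dimensionless
    r_squared: float
    n_points: int

    def predict(self, lp, lnn):
        return self.coef_lp * np.asarray(lp) + self.coef_lnn * np.asarray(lnn) + self.intercept


@dataclass
class CollapseCurve:
    """Empirical (kappa, Phi) points overlaid on a model sweep curve."""

    points: pd.DataFrame          # columns kappa, phi, group
    model_kappa: np.ndarray | None = None
    model_phi: np.ndarray | None = None
    rms_deviation: float | None = None  # RMS vertical distance data - model


def _states_frame(states) -> pd.DataFrame:
    if isinstance(states, pd.DataFrame):
        return states
    return pd.DataFrame([s.to_record() for s in states])


def fit_plane(states, condition_limit: float = 1e8) -> RegressionFit:
    """Planar OLS of window polarisation on the two length scales.

    `states` is a list of BehaviouralState or a DataFrame with columns
    phi, lp, lnn.  Coefficients are unstandardised (units 1/mm), matching
    a regression written directly in mm.
    """
    df = _states_frame(states)
    df = df[np.isfinite(df[["phi", "lp", "lnn"]]).all(axis=1)]
    if len(df) < 4:
        raise ValueError(f"need >= 4 finite states to fit a plane, got {len(df)}")
    X = sm.add_constant(df[["lp", "lnn"]].to_numpy())
    cond = np.linalg.cond(X)
    if cond > condition_limit:
        raise ValueError(
            f"predictors are collinear (design-matrix condition number {cond:.3g})"
        )
    model = sm.OLS(df["phi"].to_numpy(), X).fit()
    const, c_lp, c_lnn = model.params
    return RegressionFit(
        coef_lp=float(c_lp),
        coef_lnn=float(c_lnn),
        intercept=float(const),
        r_squared=float(model.rsquared),
        n_points=len(df),
    )


def isotropic_baseline(
    n: int, n_draws: int = 10000, rng: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of Phi for `n` i.i.d. uniform unit vectors.

    This is the expected polarisation of a completely disordered group of
    finite size; for n = 1 it is exactly 1, and it decays as n^{-1/2}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 1.0, 0.0
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = rng.normal(size=(n_draws, n, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    phi = np.linalg.norm(v.mean(axis=1), axis=1)
    return float(phi.mean()), float(phi.std(ddof=1))


def collapse(states, model_sweep: pd.DataFrame | None = None) -> CollapseCurve:
    """Overlay empirical (kappa, Phi) windows with the model sweep curve.

    The model curve (columns kappa, phi_mean from :func:`shoalkit.vicsek.sweep`)
    is interpolated piecewise-linearly in kappa; the report's figure of
    merit is the RMS vertical deviation of the data from that curve over
    the overlapping kappa range.  No per-group refitting is performed.
    """
    df = _states_frame(states)
    pts = df[["kappa", "phi"]].copy()
    pts["group"] = df["group"] if "group" in df else ""

    if model_sweep is None:
        return CollapseCurve(points=pts)

    ms = model_sweep.dropna(subset=["kappa", "phi_mean"]).sort_values("kappa")
    mk = ms["kappa"].to_numpy()
    mp = ms["phi_mean"].to_numpy()
    lo, hi = mk.min(), mk.max()
    inside = (pts["kappa"] >= lo) & (pts["kappa"] <= hi)
    if not inside.any():
        warnings.warn(
            f"data kappa range [{pts['kappa'].min():.3g}, {pts['kappa'].max():.3g}] "
            f"is disjoint from model range [{lo:.3g}, {hi:.3g}]; no comparison",
            stacklevel=2,
        )
        return CollapseCurve(points=pts, model_kappa=mk, model_phi=mp)
    pred = np.interp(pts.loc[inside, "kappa"], mk, mp)
    rms = float(np.sqrt(np.mean((pts.loc[inside, "phi"].to_numpy() - pred) ** 2)))
    return CollapseCurve(points=pts, model_kappa=mk, model_phi=mp, rms_deviation=rms)
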