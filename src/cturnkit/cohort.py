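"""Cohort-level statistics for repeated C-maneuver trials.

Three population analyses over a trials table (one row per maneuver):

* :func:`fit_alpha_phi` — the bending-amplitude law: ordinary least squares
  of alpha_max on phi over the linear window (yaws of 60-220 deg by
  default) plus the flat-band mean/SD below the split;
* :func:`kappa_invariance` — is the per-trial maximum curvature constant
  across yaw angles (a physiological ceiling)?  Coefficient of variation
  and a seeded permutation test on the kappa_max-vs-phi slope;
* :func:`velocity_regimes` — initial-speed contrast between moderate and
  large turns at the 140 deg boundary, with a seeded bootstrap CI.

Resampling is used for inference throughout (no parametric test assumed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "fit_alpha_phi",
    "kappa_invariance",
    "velocity_regimes",
]


@dataclass
class RegressionResult:
    """Piecewise alpha_max(phi) fit: linear band + flat band."""

    slope: float            # deg alpha per deg phi
    intercept: float        # deg
    r_squared: float
    stderr: float           # standard error of the slope
    n: int                  # trials in the linear window
    phi_window: Tuple[float, float]
    flat_mean: float        # mean alpha_max below the split
    flat_sd: float
    n_flat: int


def fit_alpha_phi(table: pd.DataFrame, split: float = 60.0,
                  window: Tuple[float, float] = (60.0, 220.0)
                  ) -> RegressionResult:
    """OLS of alpha_max on phi in ``window``; flat-band stats below ``split``.

    Raises if either band holds fewer than 3 trials.
    """
    lin = table[(table.phi >= window[0]) & (table.phi <= window[1])]
    flat = table[table.phi < split]
    if len(lin) < 3 or len(flat) < 3:
        raise ValueError(
            f"insufficient trials: {len(lin)} in linear window {window}, "
            f"{len(flat)} below split {split} (need >= 3 each)"
        )
    fit = stats.linregress(lin.phi.to_numpy(), lin.alpha_max.to_numpy())
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr),
        n=len(lin),
        phi_window=window,
        flat_mean=float(flat.alpha_max.mean()),
        flat_sd=float(flat.alpha_max.std(ddof=1)),
        n_flat=len(flat),
    )


def kappa_invariance(table: pd.DataFrame,
                     window: Tuple[float, float] = (60.0, 220.0),
                     n_perm: int = 10_000, seed: int = 0) -> dict:
    """Constancy of the per-trial curvature ceiling across yaw angles.

    Returns the mean and coefficient of variation of kappa_max in the
    window, the OLS slope of kappa_max vs phi, and a two-sided permutation
    p-value for that slope (phi labels permuted, seeded).
    """
    sub = table[(table.phi >= window[0]) & (table.phi <= window[1])]
    if len(sub) < 5:
        raise ValueError(f"need >= 5 trials in window, found {len(sub)}")
    phi = sub.phi.to_numpy()
    kap = sub.kappa_max.to_numpy()
    mean = kap.mean()
    cv = kap.std(ddof=1) / mean if mean != 0 else 0.0
    xc = phi - phi.mean()
    denom = (xc**2).sum()
    slope = float((xc * (kap - kap.mean())).sum() / denom)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(kap, (n_perm, kap.size)).copy(), axis=1)
    null = (perm - kap.mean()) @ xc / denom
    p = float((np.abs(null) >= abs(slope)).mean())
    return {"mean": float(mean), "cv": float(cv), "slope": slope,
            "p_value": p, "n": len(sub)}


def velocity_regimes(table: pd.DataFrame, threshold: float = 140.0,
                     n_boot: int = 10_000, seed: int = 0,
                     ci_level: float = 0.95) -> dict:
    """Speed contrast between moderate (phi < threshold) and large turns.

    Per-regime means of u0/um/ue, the u0 mean difference (large - moderate),
    and a seeded percentile bootstrap CI for that difference.
    """
    small = table[table.phi < threshold]
    large = table[table.phi >= threshold]
    if len(small) == 0 or len(large) == 0:
        raise ValueError(
            f"empty regime at threshold {threshold} "
            f"(moderate n={len(small)}, large n={len(large)})"
        )
    rng = np.random.default_rng(seed)
    u_s = small.u0.to_numpy()
    u_l = large.u0.to_numpy()
    diff = u_l.mean() - u_s.mean()
    bs = (u_l[rng.integers(0, u_l.size, (n_boot, u_l.size))].mean(axis=1)
          - u_s[rng.integers(0, u_s.size, (n_boot, u_s.size))].mean(axis=1))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(bs, [alpha / 2, 1 - alpha / 2])
    out = {"u0_diff": float(diff), "u0_ci": (float(lo), float(hi)),
           "n_moderate": len(small), "n_large": len(large)}
    for col in ("u0", "um", "ue"):
        out[f"{col}_moderate"] = float(small[col].mean())
        out[f"{col}_large"] = float(large[col].mean())
    return out
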