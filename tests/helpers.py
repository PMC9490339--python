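"""Independent oracles and small builders shared across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import iv

from membud.dataset import DatasetTable, R_COLS, Z_COLS
from membud.mechanics import MembraneState, make_profiles


def clamped_disc_deflection(rr, R, kappa, lam, p):
    """Closed-form small deflection of a clamped circular membrane.

    Linearizing the Helfrich equilibrium about the flat state (W = kappa H^2,
    H = lap(z)/2) gives (kappa/2) lap^2 z - lam lap z = p with z(R) = 0 and
    z'(R) = 0. The regular axisymmetric solution is a quadratic plus a
    modified Bessel boundary layer:

        z(r) = A - p r^2 / (4 lam) + (B / k^2) I0(k r),  k^2 = 2 lam / kappa.
    """
    kb = kappa / 2.0
    k = np.sqrt(lam / kb)
    B = p * R * k / (2.0 * lam * iv(1, k * R))
    A = p * R**2 / (4.0 * lam) - (B / k**2) * iv(0, k * R)
    return A - p * np.asarray(rr) ** 2 / (4.0 * lam) + (B / k**2) * iv(0, k * np.asarray(rr))


def normal_balance_residual(state: MembraneState, params, norm: str = "rms") -> float:
    """Finite-difference check of the normal force balance.

    Rebuilds Delta[kappa (H - C)] = (1/r) d/ds (r d[kappa(H-C)]/ds) by
    centred differences along the mesh (d/ds = 2 pi r d/da) and compares it
    with p + 2 lam H - 2 kappa (H-C)(2H^2 - K) + 2 kappa H (H-C)^2,
    independently of the solver's own L variable. Returns the interior
    residual normalized by the peak magnitude of the right-hand side.
    """
    profiles = make_profiles(params, state.C_value)
    a = state.mesh
    kap = profiles.kappa(a)
    C = profiles.curvature(a)
    p = profiles.pressure(a)
    flux = 2.0 * np.pi * state.r**2 * np.gradient(kap * (state.H - C), a)
    lap = 2.0 * np.pi * np.gradient(flux, a)
    K = state.gaussian_curvature()
    rhs = (p + 2.0 * state.lam * state.H
           - 2.0 * kap * (state.H - C) * (2.0 * state.H**2 - K)
           + 2.0 * kap * state.H * (state.H - C) ** 2)
    resid = (lap - rhs)[5:-5]
    scale = np.max(np.abs(rhs)) + 1e-300
    if norm == "max":
        return float(np.max(np.abs(resid)) / scale)
    return float(np.sqrt(np.mean(resid**2)) / scale)


def average_precision_brute(scores, labels) -> float:
    """Brute-force step-wise AUPRC: iterate thresholds at every distinct
    score, accumulate sum of (delta recall) * precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    area = 0.0
    r_prev = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        prec = tp / int(pred.sum())
        rec = tp / n_pos
        area += (rec - r_prev) * prec
        r_prev = rec
    return area


def make_table(X, y, curves=None, feature_columns=("curvature", "tension",
               "patch_radius", "pressure"), ranges=None) -> DatasetTable:
    """Assemble a DatasetTable directly from arrays (synthetic test data)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if curves is None:
        curves = np.zeros((n, 50, 2))
        curves[:, :, 0] = np.linspace(0.0, 1.0, 50)
    cols = {c: X[:, i] for i, c in enumerate(feature_columns)}
    cols["label"] = y
    cols["direction"] = np.full(n, "ascending")
    cols["sweep_id"] = np.zeros(n, int)
    cols.update({c: curves[:, i, 0] for i, c in enumerate(R_COLS)})
    cols.update({c: curves[:, i, 1] for i, c in enumerate(Z_COLS)})
    df = pd.DataFrame(cols)
    if ranges is None:
        ranges = {c: (float(X[:, i].min()), float(max(X[:, i].max(), X[:, i].min() + 1)))
                  for i, c in enumerate(feature_columns)}
    meta = {
        "space": "synthetic",
        "features": list(feature_columns),
        "ranges": {k: list(v) for k, v in ranges.items()},
        "seed": 0,
        "class_counts": {"hill": int((y == 0).sum()), "omega": int((y == 1).sum())},
    }
    return DatasetTable(df=df, metadata=meta)
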