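"""Dataset generation: parameter sampling, labeling, curve downsampling, IO.

Each converged continuation record becomes one labeled row: four
mechanical features (curvature, tension, patch radius, and pressure or
rigidity multiplier depending on the space), a binary omega/hill label
from the tangent-angle criterion, and the equilibrium profile curve
downsampled to 50 (r, z) points. Tables round-trip through CSV with a
JSON metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from membud.parameters import MechanicalParameters, SPACES, InvalidParameterError
from membud.mechanics import MembraneState, SolverConfig
from membud.continuation import (
    ContinuationRecord,
    curvature_sweep,
    DEFAULT_C_STEP,
    DEFAULT_C_MAX,
)

__all__ = [
    "Sample",
    "DatasetTable",
    "sample_parameter_space",
    "label_shape",
    "downsample_curve",
    "assemble_dataset",
    "split_dataset",
    "normalized_l1_distance",
    "generate_dataset",
    "N_CURVE_POINTS",
]

N_CURVE_POINTS = 50
R_COLS = [f"r{i:02d}" for i in range(N_CURVE_POINTS)]
Z_COLS = [f"z{i:02d}" for i in range(N_CURVE_POINTS)]


@dataclass(frozen=True)
class Sample:
    """One labeled record: features, omega label and 50-point curve."""

    features: Dict[str, float]
    label: str  # "omega" | "hill"
    curve: np.ndarray  # (50, 2) array of (r, z), nm
    direction: str
    sweep_id: int


def sample_parameter_space(
    space: str, n_sweeps: int, seed: int
) -> List[MechanicalParameters]:
    """Draw ``n_sweeps`` parameter sets uniformly from one of the two spaces.

    The pressure space varies (tension, patch radius, patch pressure) with
    the rigidity multiplier fixed at 1; the rigidity space varies (tension,
    patch radius, rigidity multiplier) with pressure fixed at 0. Curvature
    is not drawn: the continuation sweep scans it.
    """
    if space not in SPACES:
        raise InvalidParameterError(f"unknown space {space!r}; expected one of {sorted(SPACES)}")
    if n_sweeps < 1:
        raise InvalidParameterError("n_sweeps must be >= 1")
    spec = SPACES[space]
    rng = np.random.default_rng(seed)
    lo_t, hi_t = spec["ranges"]["tension"]
    lo_r, hi_r = spec["ranges"]["patch_radius"]
    tensions = rng.uniform(lo_t, hi_t, n_sweeps)
    radii = rng.uniform(lo_r, hi_r, n_sweeps)
    out = []
    if space == "pressure":
        lo_p, hi_p = spec["ranges"]["pressure"]
        pressures = rng.uniform(lo_p, hi_p, n_sweeps)
        for t, r, p in zip(tensions, radii, pressures):
            out.append(MechanicalParameters(
                patch_radius=float(r), edge_tension=float(t),
                patch_pressure=float(p), rigidity_multiplier=1.0))
    else:
        lo_d, hi_d = spec["ranges"]["rigidity_multiplier"]
        deltas = rng.uniform(lo_d, hi_d, n_sweeps)
        for t, r, d in zip(tensions, radii, deltas):
            out.append(MechanicalParameters(
                patch_radius=float(r), edge_tension=float(t),
                patch_pressure=0.0, rigidity_multiplier=float(d)))
    return out


def label_shape(state: MembraneState) -> str:
    """Label a converged shape: omega iff the tangent angle exceeds 90 deg.

    An omega-shaped bud has formed a neck — somewhere along the profile the
    tangent has rotated past vertical (psi > pi/2, strictly); anything else
    (flat, hill-shaped) is "hill".
    """
    if not state.converged:
        raise ValueError("cannot label a non-convergent state")
    return "omega" if state.max_psi > np.pi / 2 else "hill"


def downsample_curve(state_or_curve, n: int = N_CURVE_POINTS) -> np.ndarray:
    """Interpolate the (r, z) profile at ``n`` equal arclength fractions.

    Endpoints are preserved; interior points are linear interpolants of the
    polyline at fractions i/(n-1) of its total chord length.
    """
    if isinstance(state_or_curve, MembraneState):
        curve = state_or_curve.curve()
    else:
        curve = np.asarray(state_or_curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise ValueError("curve must be an (m, 2) array")
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate zero-length curve")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n)
    return np.column_stack([
        np.interp(targets, arc, curve[:, 0]),
        np.interp(targets, arc, curve[:, 1]),
    ])


@dataclass
class DatasetTable:
    """Columnar dataset of labeled membrane shapes plus its metadata.

    ``df`` columns: the feature columns of the space, ``label`` (0 = hill,
    1 = omega), ``direction``, ``sweep_id``, and the 100 curve columns
    r00..r49, z00..z49. ``metadata`` records the space, sampling ranges,
    seed, per-class counts and a hash of the generating configuration.
    """

    df: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> List[str]:
        return list(self.metadata["features"])

    @property
    def ranges(self) -> Dict[str, Tuple[float, float]]:
        return {k: tuple(v) for k, v in self.metadata["ranges"].items()}

    def features(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def curves(self) -> np.ndarray:
        """(n_rows, 50, 2) array of curves."""
        r = self.df[R_COLS].to_numpy(dtype=float)
        z = self.df[Z_COLS].to_numpy(dtype=float)
        return np.stack([r, z], axis=-1)

    def class_counts(self) -> Dict[str, int]:
        y = self.labels()
        return {"hill": int((y == 0).sum()), "omega": int((y == 1).sum())}

    def validate(self) -> None:
        counts = self.class_counts()
        meta_counts = self.metadata.get("class_counts")
        if meta_counts is not None and {k: int(v) for k, v in meta_counts.items()} != counts:
            raise ValueError("metadata class counts do not match table")
        if counts["hill"] + counts["omega"] != len(self.df):
            raise ValueError("class counts do not sum to row count")
        missing = [c for c in self.feature_columns + R_COLS + Z_COLS
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing[:5]}...")

    def to_csv(self, path) -> None:
        """Write the table as CSV with a JSON metadata sidecar (.meta.json)."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        side = path.with_suffix(path.suffix + ".meta.json")
        side.write_text(json.dumps(self.metadata, indent=1, default=str))

    @classmethod
    def from_csv(cls, path) -> "DatasetTable":
        path = Path(path)
        df = pd.read_csv(path)
        side = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(side.read_text())
        table = cls(df=df, metadata=metadata)
        table.validate()
        return table


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def assemble_dataset(
    sweep_outputs: Sequence[Tuple[MechanicalParameters, Sequence[ContinuationRecord]]],
    space: str,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> DatasetTable:
    """Flatten sweep outputs into one labeled table (one row per record)."""
    spec = SPACES[space]
    feature_names = list(spec["features"])
    rows = []
    for sweep_id, (params, records) in enumerate(sweep_outputs):
        for rec in records:
            st = rec.state
            feats = {
                "curvature": rec.C_value,
                "tension": params.edge_tension,
                "patch_radius": params.patch_radius,
                "pressure": params.patch_pressure,
                "rigidity_multiplier": params.rigidity_multiplier,
            }
            row = {name: feats[name] for name in feature_names}
            row["label"] = 1 if label_shape(st) == "omega" else 0
            row["direction"] = rec.direction
            row["sweep_id"] = sweep_id
            pts = downsample_curve(st)
            row.update({c: pts[i, 0] for i, c in enumerate(R_COLS)})
            row.update({c: pts[i, 1] for i, c in enumerate(Z_COLS)})
            rows.append(row)
    if not rows:
        raise ValueError("no convergent records to assemble")
    df = pd.DataFrame(rows)
    metadata = {
        "space": space,
        "features": feature_names,
        "ranges": {k: list(v) for k, v in spec["ranges"].items()},
        "seed": seed,
        "n_sweeps": len(sweep_outputs),
        "class_counts": {},
        "config_hash": _config_hash(config or {}),
    }
    table = DatasetTable(df=df, metadata=metadata)
    metadata["class_counts"] = table.class_counts()
    return table


def split_dataset(
    table: DatasetTable, test_fraction: float = 0.15, seed: int = 0
) -> Tuple[DatasetTable, DatasetTable]:
    """Seeded random row partition into (train, test); no row in both."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(table.df)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])

    def _sub(idx, part):
        meta = dict(table.metadata)
        sub = DatasetTable(df=table.df.iloc[idx].reset_index(drop=True),
                           metadata=meta)
        meta = dict(meta)
        meta["part"] = part
        meta["class_counts"] = sub.class_counts()
        sub.metadata = meta
        return sub

    return _sub(train_idx, "train"), _sub(test_idx, "test")


def normalized_l1_distance(x, y, ranges) -> float:
    """Manhattan distance after mapping each feature range onto [0, 1].

    ``ranges`` is an ordered sequence of (lo, hi) pairs (or a mapping whose
    values are such pairs) matching the feature order of x and y.
    """
    if isinstance(ranges, dict):
        ranges = list(ranges.values())
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = np.array([r[0] for r in ranges], dtype=float)
    hi = np.array([r[1] for r in ranges], dtype=float)
    width = hi - lo
    if np.any(width <= 0):
        raise ValueError("zero-width feature range")
    return float(np.sum(np.abs((x - y) / width)))


def generate_dataset(
    space: str,
    n_sweeps: int,
    seed: int,
    solver_cfg: Optional[SolverConfig] = None,
    step: float = DEFAULT_C_STEP,
    C_max: float = DEFAULT_C_MAX,
    progress: bool = False,
) -> DatasetTable:
    """Sample the space, run all continuation sweeps, assemble the table.

    The full run is a pure function of (space, n_sweeps, seed, solver
    settings): repeated calls reproduce the dataset exactly.
    """
    cfg = solver_cfg or SolverConfig()
    params_list = sample_parameter_space(space, n_sweeps, seed)
    outputs = []
    for i, params in enumerate(params_list):
        records = curvature_sweep(params, step=step, C_max=C_max, solver_cfg=cfg)
        outputs.append((params, records))
        if progress:
            n_asc = sum(1 for r in records if r.direction == "ascending")
            print(f"sweep {i + 1}/{n_sweeps}: radius={params.patch_radius:.1f} nm "
                  f"tension={params.edge_tension:.4f} -> {n_asc} ascending / "
                  f"{len(records) - n_asc} descending records", flush=True)
    config = {
        "space": space, "n_sweeps": n_sweeps, "seed": seed, "step": step,
        "C_max": C_max, "tolerance": cfg.tolerance,
        "mesh_points": cfg.mesh_points,
        "max_node_multiplier": cfg.max_node_multiplier,
        "transition_width_frac": cfg.transition_width_frac,
    }
    table = assemble_dataset(
        [o for o in outputs if o[1]], space, seed=seed, config=config
    )
    table.metadata["generation_config"] = config
    return table
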