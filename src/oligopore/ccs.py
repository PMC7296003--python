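"""Theoretical collision cross sections by the Projection Approximation (PA).

The PA estimates an ion's CCS as the orientation-averaged area of the union
of its atoms' projected disks. Orientations are drawn uniformly over SO(3)
(random quaternions); per orientation the union area is estimated by Monte
Carlo rejection sampling over the padded projected bounding box. Batches of
orientations are accumulated until the running mean changes by less than a
convergence threshold (default 1%), and the whole calculation is repeated
for a configured number of independent replicates (default 3) whose mean and
standard deviation are reported.

Absolute PA values depend on the projection radii table; the shipped default
is the hard-sphere set commonly used by PA implementations (H 2.2 Å, C/N/O
2.7 Å, S/P 3.1 Å) and can be overridden from file.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Structure, strip_heteroatoms

__all__ = [
    "DEFAULT_RADII",
    "load_radii_table",
    "PAConfig",
    "CCSResult",
    "projected_area",
    "pa_ccs",
    "compare_models_to_ccs",
    "vacuum_compact",
    "EngineNotFoundError",
]

# Element -> projection radius (Å). Hard-sphere radii typical of PA codes.
DEFAULT_RADII: dict[str, float] = {
    "H": 2.2, "D": 2.2, "C": 2.7, "N": 2.7, "O": 2.7, "S": 3.1, "P": 3.1,
    "SE": 3.1,
}


def load_radii_table(path: str) -> dict[str, float]:
    """Load an element→radius table from a two-column CSV (element, radius_A)."""
    df = pd.read_csv(path)
    table = {str(r.element).upper(): float(r.radius_A) for r in df.itertuples()}
    if any(v <= 0 for v in table.values()):
        raise ValueError("radii must be positive")
    return table


@dataclass
class PAConfig:
    orientations_per_batch: int = 64
    mc_points: int = 4000
    convergence: float = 0.01          # relative change of the running mean
    replicates: int = 3
    max_batches: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.orientations_per_batch, self.mc_points,
               self.replicates, self.max_batches) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.convergence < 1.0):
            raise ValueError("convergence threshold must be in (0, 1)")


@dataclass
class CCSResult:
    mean: float                       # Å²
    replicates: list[float]
    sd: float
    orientations_used: list[int]
    mc_points: int

    def __repr__(self):
        return f"CCSResult(mean={self.mean:.1f} Å², sd={self.sd:.1f}, n={len(self.replicates)})"


def _radii_for(s: Structure, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(s))
    for i, a in enumerate(s.atoms):
        r = radii.get(a.element.upper())
        if r is None:
            raise KeyError(f"no projection radius for element {a.element!r}")
        out[i] = r
    return out


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n rotation matrices uniform over SO(3) via unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _union_area_mc(xy: np.ndarray, radii: np.ndarray, mc_points: int,
                   rng: np.random.Generator) -> float:
    """MC estimate of the area of a union of disks (centers xy, radii)."""
    pad = radii.max()
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    box_area = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(mc_points, 2))
    # chunked all-pairs test: inside if within any disk
    hit = np.zeros(mc_points, dtype=bool)
    r2 = radii ** 2
    chunk = max(1, int(2e6) // max(len(xy), 1))
    for s in range(0, mc_points, chunk):
        d2 = ((pts[s:s + chunk, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        hit[s:s + chunk] = (d2 <= r2[None, :]).any(axis=1)
    return box_area * hit.mean()


def _orientation_matrix(orientation: np.ndarray) -> np.ndarray:
    """Rotation taking ``orientation`` (unit 3-vector) to the z axis."""
    v = np.asarray(orientation, dtype=float)
    v = v / np.linalg.norm(v)
    zaxis = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, zaxis)
    s = np.linalg.norm(axis)
    c = float(v @ zaxis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def projected_area(s: Structure, orientation: np.ndarray,
                   radii: dict[str, float] | None = None,
                   mc_points: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Area (Å²) of the atom-disk union projected along ``orientation``.

    ``orientation`` is either a unit 3-vector (projection direction) or a 3×3
    rotation matrix whose z row defines the direction. Returns
    ``(area, standard_error)``.
    """
    if len(s) == 0:
        raise ValueError("structure has no atoms")
    radii = radii if radii is not None else DEFAULT_RADII
    rvec = _radii_for(s, radii)
    orientation = np.asarray(orientation, dtype=float)
    R = orientation if orientation.shape == (3, 3) else _orientation_matrix(orientation)
    rng = np.random.default_rng(seed)
    xy = (s.coords() @ R.T)[:, :2]
    pad = rvec.max()
    lo = xy.min(axis=0) - pad
    hi = xy.max(axis=0) + pad
    box_area = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(mc_points, 2))
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    hit = (d2 <= (rvec ** 2)[None, :]).any(axis=1)
    p = hit.mean()
    area = box_area * p
    se = box_area * float(np.sqrt(max(p * (1 - p), 0.0) / mc_points))
    return area, se


def pa_ccs(s: Structure, radii: dict[str, float] | None = None,
           cfg: PAConfig | None = None, strip: bool = True) -> CCSResult:
    """Orientation-averaged projected area with the 1%-convergence protocol.

    Heteroatoms/solvent are stripped first (``strip=False`` to skip). Batches
    of orientations are added until the running mean moves by less than
    ``cfg.convergence`` relative; the calculation is repeated
    ``cfg.replicates`` times and the replicate mean and sd are reported.
    """
    cfg = cfg or PAConfig()
    radii = radii if radii is not None else DEFAULT_RADII
    if strip:
        s = strip_heteroatoms(s)
    if len(s) == 0:
        raise ValueError("no atoms after heteroatom stripping")
    rvec = _radii_for(s, radii)
    coords = s.coords()
    values, counts = [], []
    for rep in range(cfg.replicates):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, rep]))
        total, n_used = 0.0, 0
        running = None
        for batch in range(cfg.max_batches):
            Rs = _random_rotations(rng, cfg.orientations_per_batch)
            for R in Rs:
                xy = (coords @ R.T)[:, :2]
                total += _union_area_mc(xy, rvec, cfg.mc_points, rng)
            n_used += cfg.orientations_per_batch
            new_mean = total / n_used
            if running is not None and abs(new_mean - running) <= cfg.convergence * running:
                running = new_mean
                break
            running = new_mean
        else:
            raise RuntimeError(
                f"PA did not converge within {cfg.max_batches} batches "
                f"(last mean {running:.1f} Å²)")
        values.append(running)
        counts.append(n_used)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return CCSResult(mean, [float(v) for v in values], sd, counts, cfg.mc_points)


def compare_models_to_ccs(models: dict[str, CCSResult | float],
                          experimental: float) -> pd.DataFrame:
    """Rank candidate models by |signed fractional deviation| from experiment.

    ``deviation = (model − experimental)/experimental``. Returns a DataFrame
    sorted by absolute deviation with the best-matching model first.
    """
    if experimental <= 0:
        raise ValueError("experimental CCS must be positive")
    if not models:
        raise ValueError("no models to compare")
    rows = []
    for name, res in models.items():
        value = res.mean if isinstance(res, CCSResult) else float(res)
        rows.append({"model": name, "ccs_A2": value,
                     "deviation": (value - experimental) / experimental})
    df = pd.DataFrame(rows)
    df["rank"] = df["deviation"].abs().rank(method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


class EngineNotFoundError(RuntimeError):
    """No external MD engine is available for gas-phase compaction."""


def vacuum_compact(s: Structure, engine: str = "namd3", ns: float = 100.0,
                   workdir: str | None = None) -> Structure:
    """Shim for gas-phase (in vacuo) compaction via an external MD engine.

    Ions compact in the gas phase before mobility measurement; matching a
    theoretical CCS to experiment therefore requires a short vacuum MD
    relaxation of the solution structure. This package never integrates
    equations of motion itself: this shim documents the external call and
    raises :class:`EngineNotFoundError` when no engine binary is on PATH.
    """
    exe = shutil.which(engine)
    if exe is None:
        raise EngineNotFoundError(
            f"external MD engine {engine!r} not found on PATH; gas-phase "
            "compaction requires an external engine (e.g. NAMD with a "
            "CHARMM force field, vacuum ensemble, ~100 ns)")
    raise NotImplementedError(
        f"engine {exe} found, but driving input generation for arbitrary "
        "engines is out of scope; run the vacuum simulation externally and "
        "load the compacted frame with read_structure()")
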