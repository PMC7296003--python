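"""Trajectory and ensemble analytics for membrane-bound oligomer simulations.

Implements the per-frame metrics used to characterise oligomer stability and
membrane disruption: best-fit Cα RMSD time series, per-residue RMSF,
ensemble RMSD to the mean conformer, mass-weighted radius of gyration,
Kabsch–Sander secondary-structure content, lipid-probe contact profiles
within a 9 Å cutoff of backbone amide nitrogens, water-permeation histograms
along the membrane normal (z), and Shrake–Rupley solvent-accessible surface
area.

Replicate spread follows the convention of reporting ±SD divided by the
number of independent samples (``spread="sd_over_n"``), with the more common
standard error (``"sd_over_sqrt_n"``) available as a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Ensemble, Selection, Structure, kabsch

__all__ = [
    "Trajectory",
    "load_trajectory",
    "rmsd_series",
    "ensemble_rmsd",
    "rmsf",
    "radius_of_gyration",
    "beta_content",
    "SSContent",
    "ContactSpec",
    "ContactProfile",
    "contact_profile",
    "PermeationProfile",
    "water_permeation",
    "sasa",
    "VDW_RADII",
]


@dataclass
class Trajectory:
    """Coordinate frames (Å) over a fixed topology; membrane normal = z."""

    topology: Structure
    frames: np.ndarray                       # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None            # (n_frames, 3) orthorhombic lengths
    times: np.ndarray | None = None          # ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("frames must be (n_frames, n_atoms, 3) matching topology")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        elif np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be monotone")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_ensemble(cls, ens: Ensemble) -> "Trajectory":
        return cls(ens.models[0].copy(), ens.coords())


def load_trajectory(topology_path: str, trajectory_path: str | None = None) -> Trajectory:
    """Load a trajectory from standard formats.

    A multi-model PDB alone, or a topology PDB plus a DCD/XTC/TRR read
    through MDAnalysis.
    """
    from . import structio

    if trajectory_path is None:
        obj = structio.read_structure(topology_path)
        if isinstance(obj, Ensemble):
            return Trajectory.from_ensemble(obj)
        return Trajectory(obj, obj.coords()[None, :, :])

    import MDAnalysis as mda

    top = structio.read_structure(topology_path)
    if isinstance(top, Ensemble):
        top = top.models[0]
    u = mda.Universe(topology_path, trajectory_path)
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    box = np.array([ts.dimensions[:3] for ts in u.trajectory], dtype=float) \
        if u.trajectory[0].dimensions is not None else None
    times = np.array([ts.time for ts in u.trajectory], dtype=float)
    return Trajectory(top, frames, box=box, times=times)


# ---------------------------------------------------------------------------
# RMSD family


def rmsd_series(traj: Trajectory, ref: Structure,
                sel: Selection | str | None = None) -> np.ndarray:
    """Per-frame best-fit RMSD (Å) over a selection after superposition on it."""
    sel = sel if sel is not None else Selection(names="calpha")
    ti = traj.topology.select(sel)
    ri = ref.select(sel)
    if len(ti) != len(ri) or len(ti) == 0:
        raise ValueError("selection resolves differently in trajectory and reference")
    refc = ref.coords()[ri]
    out = np.empty(len(traj))
    for f in range(len(traj)):
        _, _, out[f] = kabsch(traj.frames[f, ti], refc)
    return out


def ensemble_rmsd(ens: Ensemble, sel: Selection | str | None = None,
                  tol: float = 1e-6, max_iter: int = 100) -> float:
    """Mean RMSD of ensemble models to their mean coordinates over a selection.

    All models are iteratively superposed on the evolving mean conformation
    until the mean moves by less than ``tol`` Å RMS, then the mean over
    models of the RMSD-to-mean is returned.
    """
    if len(ens) < 2:
        raise ValueError("ensemble RMSD needs >= 2 models")
    sel = sel if sel is not None else Selection(names="backbone")
    idx = sel if isinstance(sel, np.ndarray) else ens.models[0].select(sel)
    if len(idx) < 3:
        raise ValueError("selection too small")
    X = ens.coords()[:, idx, :].copy()
    mean = X[0].copy()
    for _ in range(max_iter):
        for m in range(len(X)):
            R, t, _ = kabsch(X[m], mean)
            X[m] = X[m] @ R.T + t
        new_mean = X.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            break
    rmsds = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=1))
    return float(rmsds.mean())


def rmsf(traj: Trajectory, sel: Selection | str | None = None) -> pd.DataFrame:
    """Per-residue fluctuation (Å) about the time-mean after superposition.

    Frames are superposed on the selection, the per-atom RMS fluctuation
    about the mean structure is computed, and atoms are averaged per
    (chain, residue).
    """
    sel = sel if sel is not None else Selection(names="calpha")
    idx = traj.topology.select(sel)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if len(traj) < 2:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
        flucts = np.zeros(len(idx))
    else:
        X = traj.frames[:, idx, :].copy()
        refc = X[0]
        for f in range(len(X)):
            R, t, _ = kabsch(X[f], refc)
            X[f] = X[f] @ R.T + t
        mean = X.mean(axis=0)
        flucts = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    rows = []
    for k, i in enumerate(idx):
        a = traj.topology.atoms[i]
        rows.append({"chain": a.chain_id, "residue": a.residue_number,
                     "rmsf_A": flucts[k]})
    return (pd.DataFrame(rows)
            .groupby(["chain", "residue"], as_index=False)["rmsf_A"].mean())


def radius_of_gyration(obj: Structure | np.ndarray,
                       masses: np.ndarray | None = None,
                       sel: Selection | str | None = None) -> float:
    """Mass-weighted radius of gyration (Å) of a structure or coordinate set."""
    if isinstance(obj, Structure):
        idx = obj.select(sel) if sel is not None else np.arange(len(obj))
        coords = obj.coords()[idx]
        masses = obj.masses()[idx]
    else:
        coords = np.asarray(obj, dtype=float)
        masses = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    if len(coords) == 0:
        raise ValueError("no atoms selected")
    M = masses.sum()
    if M <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / M
    return float(np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / M))


# ---------------------------------------------------------------------------
# Kabsch–Sander secondary structure

_Q1Q2_F = 27.888  # kcal/mol·Å : 0.084 e² · 332 Å·kcal/(mol·e²)
_HBOND_CUTOFF = -0.5


@dataclass
class SSContent:
    """Per-frame secondary-structure fractions (of scored residues)."""

    beta: np.ndarray
    helix: np.ndarray
    n_residues: int

    def __post_init__(self):
        if np.any((self.beta < 0) | (self.beta > 1)) or \
           np.any((self.helix < 0) | (self.helix > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def _backbone_tables(top: Structure):
    """Residue list [(chain, resnum, {N, CA, C, O} atom indices)] in order."""
    residues = []
    for chain, resmap in top.residue_index.items():
        for resnum in sorted(resmap):
            names = {}
            for i in resmap[resnum]:
                nm = top.atoms[i].name.upper()
                if nm in {"N", "CA", "C", "O"}:
                    names[nm] = i
            if {"N", "CA", "C", "O"} <= names.keys():
                residues.append((chain, resnum, names))
    return residues


def _ks_assign(coords: np.ndarray, residues) -> np.ndarray:
    """Kabsch–Sander assignment for one frame → array of '', 'E', 'H'."""
    n = len(residues)
    N = np.array([coords[r[2]["N"]] for r in residues])
    CA = np.array([coords[r[2]["CA"]] for r in residues])
    C = np.array([coords[r[2]["C"]] for r in residues])
    O = np.array([coords[r[2]["O"]] for r in residues])

    # amide H from the bisector of CA->N and C(prev)->N at 1.01 Å
    H = np.full((n, 3), np.nan)
    for i in range(n):
        prev_ok = i > 0 and residues[i - 1][0] == residues[i][0] \
            and residues[i - 1][1] == residues[i][1] - 1
        if not prev_ok:
            continue
        v1 = N[i] - C[i - 1]
        v2 = N[i] - CA[i]
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        d = v1 + v2
        nrm = np.linalg.norm(d)
        if nrm > 1e-8:
            H[i] = N[i] + 1.01 * d / nrm

    # Hbond(i, j): C=O of residue i accepts N-H of residue j
    hbond = np.zeros((n, n), dtype=bool)
    valid_j = ~np.isnan(H[:, 0])
    for j in range(n):
        if not valid_j[j]:
            continue
        r_on = np.linalg.norm(O - N[j], axis=1)
        r_ch = np.linalg.norm(C - H[j], axis=1)
        r_oh = np.linalg.norm(O - H[j], axis=1)
        r_cn = np.linalg.norm(C - N[j], axis=1)
        with np.errstate(divide="ignore"):
            E = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        for i in range(n):
            if i == j:
                continue
            same_chain = residues[i][0] == residues[j][0]
            if same_chain and abs(residues[i][1] - residues[j][1]) < 2:
                continue
            if E[i] < _HBOND_CUTOFF:
                hbond[i, j] = True

    ss = np.array([""] * n, dtype=object)

    # β-bridges (parallel and antiparallel); both partners marked strand
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = residues[i][0] == residues[j][0]
            if same_chain and abs(residues[i][1] - residues[j][1]) < 3:
                continue
            anti = (hbond[i, j] and hbond[j, i]) or (
                i > 0 and j + 1 < n and i + 1 < n and
                hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            para = (i > 0 and i + 1 < n and hbond[i - 1, j] and hbond[j, i + 1]) or (
                j > 0 and j + 1 < n and hbond[j - 1, i] and hbond[i, j + 1])
            if anti or para:
                ss[i] = "E"
                ss[j] = "E"

    # α-helix: two consecutive (i, i+4) turns mark residues i+1..i+4
    for i in range(1, n - 4):
        contig = all(residues[k][0] == residues[i][0] and
                     residues[k][1] == residues[i][1] + (k - i)
                     for k in range(i - 1, i + 5))
        if contig and hbond[i - 1, i + 3] and hbond[i, i + 4]:
            for k in range(i + 1, i + 5):
                if ss[k] != "E":
                    ss[k] = "H"
    return ss


def beta_content(obj: Trajectory | Structure) -> SSContent:
    """Kabsch–Sander β-strand and α-helix fractions per frame.

    Hydrogen bonds use the electrostatic energy
    E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a −0.5
    kcal/mol cutoff; β counts residues in parallel/antiparallel bridges,
    helix the 4-turn pattern. Residues lacking backbone N/CA/C/O are
    excluded.
    """
    traj = obj if isinstance(obj, Trajectory) else \
        Trajectory(obj, obj.coords()[None, :, :])
    residues = _backbone_tables(traj.topology)
    if not residues:
        raise ValueError("no residues with complete backbone")
    beta = np.empty(len(traj))
    helix = np.empty(len(traj))
    for f in range(len(traj)):
        ss = _ks_assign(traj.frames[f], residues)
        beta[f] = np.mean(ss == "E")
        helix[f] = np.mean(ss == "H")
    return SSContent(beta, helix, len(residues))


# ---------------------------------------------------------------------------
# Contacts and permeation


@dataclass
class ContactSpec:
    """Probe-contact counting around backbone amide nitrogens."""

    target: Selection | str = field(default_factory=lambda: Selection(names="amide_n"))
    probe: Selection | str | np.ndarray = None          # selection or explicit indices
    cutoff: float = 9.0
    spread: str = "sd_over_n"                            # or "sd_over_sqrt_n"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactProfile:
    residues: np.ndarray          # residue numbers (summed over symmetric chains)
    mean: np.ndarray
    spread: np.ndarray
    n_replicates: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "mean_contacts": self.mean,
                             "spread": self.spread})


def _min_image_dists(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sqrt((diff ** 2).sum(axis=2))


def _contact_counts_one(traj: Trajectory, spec: ContactSpec):
    """Per-residue contact count averaged over frames, summed over chains."""
    top = traj.topology
    ti = top.select(spec.target) if not isinstance(spec.target, np.ndarray) else spec.target
    if isinstance(spec.probe, np.ndarray):
        pi = spec.probe
    elif spec.probe is None:
        raise ValueError("probe selection is required")
    else:
        pi = top.select(spec.probe)
    if len(pi) == 0:
        raise ValueError("empty probe selection")
    if set(ti.tolist()) & set(pi.tolist()):
        raise ValueError("probe and target selections must be disjoint")
    resnums = np.array([top.atoms[i].residue_number for i in ti])
    uniq = np.unique(resnums)
    acc = np.zeros(len(uniq))
    for f in range(len(traj)):
        box = traj.box[f] if traj.box is not None else None
        d = _min_image_dists(traj.frames[f, ti], traj.frames[f, pi], box)
        counts = (d <= spec.cutoff).sum(axis=1)
        for u, r in enumerate(uniq):
            acc[u] += counts[resnums == r].sum()    # sum over symmetric chains
    return uniq, acc / len(traj)


def contact_profile(traj: Trajectory | None, spec: ContactSpec,
                    replicates: list[Trajectory] | None = None) -> ContactProfile:
    """Probe-site contacts within ``spec.cutoff`` of each residue's amide N.

    Counts are evaluated per frame, summed over symmetric chains, averaged
    over frames, and the across-replicate spread is reported as SD divided
    by the number of independent samples (or SD/√n with
    ``spread="sd_over_sqrt_n"``).
    """
    trajs = list(replicates) if replicates else []
    if traj is not None:
        trajs = [traj] + trajs
    if not trajs:
        raise ValueError("need at least one trajectory")
    uniq = None
    profiles = []
    for t in trajs:
        u, prof = _contact_counts_one(t, spec)
        if uniq is None:
            uniq = u
        elif not np.array_equal(uniq, u):
            raise ValueError("replicates disagree on the residue set")
        profiles.append(prof)
    P = np.vstack(profiles)
    mean = P.mean(axis=0)
    n = len(trajs)
    if n > 1:
        sd = P.std(axis=0, ddof=1)
        spread_v = sd / n if spec.spread == "sd_over_n" else sd / np.sqrt(n)
    else:
        spread_v = np.zeros_like(mean)
    return ContactProfile(uniq, mean, spread_v, n)


@dataclass
class PermeationProfile:
    bin_edges: np.ndarray
    mean_counts: np.ndarray
    membrane_span: tuple[float, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"z_center_A": centers, "mean_waters": self.mean_counts})


def water_permeation(traj: Trajectory, water: Selection | str | np.ndarray,
                     bin_width: float = 1.0,
                     membrane_span: tuple[float, float] | None = None) -> PermeationProfile:
    """Frame-averaged histogram of water-oxygen z coordinates.

    Bin edges are uniform with ``bin_width`` covering the full z range of the
    water selection across frames; per frame the bin sums equal the number of
    selected waters.
    """
    wi = water if isinstance(water, np.ndarray) else traj.topology.select(water)
    if len(wi) == 0:
        raise ValueError("no water atoms selected")
    zs = traj.frames[:, wi, 2]
    lo = np.floor(zs.min() / bin_width) * bin_width
    hi = np.ceil(zs.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts = np.stack([np.histogram(zs[f], bins=edges)[0] for f in range(len(traj))])
    return PermeationProfile(edges, counts.mean(axis=0), membrane_span)


# ---------------------------------------------------------------------------
# SASA

# van der Waals radii (Å) for solvent accessibility (distinct from PA radii).
VDW_RADII = {"H": 1.2, "D": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8,
             "P": 1.8, "SE": 1.9}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(s: Structure, probe: float = 1.4, points_per_atom: int = 960,
         radii: dict[str, float] | None = None) -> tuple[float, pd.DataFrame]:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Test points on each atom's solvent-expanded sphere are kept if they fall
    inside no other expanded sphere. Returns total SASA and a per-residue
    table.
    """
    radii = radii if radii is not None else VDW_RADII
    coords = s.coords()
    try:
        rads = np.array([radii[a.element.upper()] for a in s.atoms]) + probe
    except KeyError as exc:
        raise KeyError(f"no vdW radius for element {exc.args[0]!r}") from None
    pts = _sphere_points(points_per_atom)
    n = len(s)
    areas = np.zeros(n)
    # neighbour lists by cutoff on centre distance
    maxr = rads.max()
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbr = np.where((d < rads[i] + maxr) & (np.arange(n) != i))[0]
        nbr = nbr[d[nbr] < rads[i] + rads[nbr]]
        test = coords[i] + rads[i] * pts
        if len(nbr):
            d2 = ((test[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (rads[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * rads[i] ** 2 * frac
    rows = [{"chain": a.chain_id, "residue": a.residue_number, "sasa_A2": areas[i]}
            for i, a in enumerate(s.atoms)]
    per_res = (pd.DataFrame(rows)
               .groupby(["chain", "residue"], as_index=False)["sasa_A2"].sum())
    return float(areas.sum()), per_res
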