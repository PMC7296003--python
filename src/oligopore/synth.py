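"""Synthetic-data generators with machine-readable ground truth.

Every analysis stage in the package has a generator here producing its input
under known truth: an idealized six-stranded antiparallel β-sheet tetramer
(the 42-residue amyloid-β peptide arranged as two hairpin "red" subunits and
two single-strand "green" subunits), jittered NMR-style ensembles, mixed
tetramer/octamer native mass spectra with charge-state envelopes, power-law
mobility calibrant tables, chemical-shift tables painted from a known
secondary structure, membrane-slab pseudo-trajectories with probe sites and
pore waters, and single-channel current traces of the three pore behaviours.

Fixed seeds give identical output. The generators' default parameters are
the study conditions (sample concentrations, micelle arithmetic constants,
pore-type occurrence mixes); they are inputs to the analyses, not knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nmr
from .native_ms import (GasParameters, MassSpectrum, PROTON_MASS_DA,
                        reduced_mass, theoretical_mz)
from .ephys import CurrentTrace
from .structio import AtomRecord, Ensemble, Structure, TopologySpec
from .traj import Trajectory

__all__ = [
    "AB42_SEQUENCE",
    "SampleComposition",
    "micelle_ratio",
    "make_tetramer_coords",
    "make_ensemble",
    "make_membrane_traj",
    "make_mass_spectrum",
    "make_calibrant_table",
    "make_shift_table",
    "make_current_trace",
    "make_trace_batch",
    "OCCURRENCE_PRESETS",
]

# Aβ(1-42) sequence, 1-letter
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# Sample-composition arithmetic


@dataclass
class SampleComposition:
    """Peptide/detergent preparation with micelle-molarity arithmetic.

    The micelle concentration is ``[M] = (D − CMC)/aggregation_number`` with
    the detergent concentration D and critical micellar concentration CMC in
    mM; the peptide:micelle ratio is ``peptide/[M]`` with the peptide
    concentration converted to mM.
    """

    peptide_uM: float
    detergent_mM: float
    cmc_mM: float = 1.5                 # dodecylphosphocholine
    aggregation_number: float = 54.0

    def __post_init__(self):
        if self.peptide_uM < 0 or self.detergent_mM < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def micelle_mM(self) -> float:
        if self.detergent_mM <= self.cmc_mM:
            raise ValueError("detergent below CMC: micelle concentration undefined")
        return (self.detergent_mM - self.cmc_mM) / self.aggregation_number

    @property
    def ratio(self) -> float:
        return (self.peptide_uM / 1000.0) / self.micelle_mM


def micelle_ratio(sc: SampleComposition) -> tuple[float, str]:
    """Peptide-per-micelle ratio and its rounded ``"n:1"`` label."""
    r = sc.ratio
    return r, f"{round(r)}:1"


# ---------------------------------------------------------------------------
# Idealized tetramer geometry

# extended-backbone internal geometry (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_RISE = 3.63          # per-residue rise of a fully extended chain


def _extended_backbone(n_res: int) -> dict[str, np.ndarray]:
    """Planar fully-extended backbone along +x (zigzag in xy, carbonyls ±y).

    Ideal-geometry chain with all-trans torsions: N/CA/C alternate above and
    below the axis, C=O and N-H point alternately along ∓y so two antiparallel
    copies can hydrogen-bond in the plane.
    """
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    # template residue pair built from ideal bond geometry, zigzag amplitude
    amp = 0.45
    for i in range(n_res):
        x0 = i * _RISE
        s = 1.0 if i % 2 == 0 else -1.0
        N[i] = (x0, -s * amp, 0.0)
        CA[i] = (x0 + _RISE * 0.27, s * amp, 0.0)
        C[i] = (x0 + _RISE * 0.63, -s * amp * 0.4, 0.0)
        O[i] = C[i] + (0.0, -s * _B_C_O, 0.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _rot_z(coords: np.ndarray) -> np.ndarray:
    out = coords.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


def _strand(n_res: int, reverse: bool) -> dict[str, np.ndarray]:
    bb = _extended_backbone(n_res)
    if reverse:
        bb = {k: _rot_z(v) for k, v in bb.items()}
    return bb


def _ks_pair_energy(row_a: dict, row_b: dict) -> int:
    """Count inter-strand Kabsch–Sander H-bonds (both donor directions)."""
    count = 0
    for don, acc in ((row_a, row_b), (row_b, row_a)):
        nd = len(don["N"])
        for j in range(1, nd):
            v1 = don["N"][j] - don["C"][j - 1]
            v2 = don["N"][j] - don["CA"][j]
            d = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
            H = don["N"][j] + 1.01 * d / np.linalg.norm(d)
            r_on = np.linalg.norm(acc["O"] - don["N"][j], axis=1)
            r_ch = np.linalg.norm(acc["C"] - H, axis=1)
            r_oh = np.linalg.norm(acc["O"] - H, axis=1)
            r_cn = np.linalg.norm(acc["C"] - don["N"][j], axis=1)
            E = 27.888 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            count += int((E < -0.5).sum())
    return count


def _optimal_registry(row_a: dict, n_b: int, reverse_b: bool) -> tuple[dict, float, float]:
    """Place strand B against strand A maximising inter-strand H-bonds."""
    base = _strand(n_b, reverse_b)
    xa = row_a["CA"][:, 0]
    atoms_a = np.concatenate([row_a[k] for k in ("N", "CA", "C", "O")])
    best, best_score = None, -1
    for dy in np.arange(4.6, 5.4, 0.1):
        for dx in np.arange(xa.min() - 2.0, xa.min() + 2.0 * _RISE, 0.25):
            cand = {k: v + np.array([dx - base["CA"][:, 0].min(),
                                     row_a["CA"][0, 1] + dy - base["CA"][0, 1], 0.0])
                    for k, v in base.items()}
            atoms_b = np.concatenate([cand[k] for k in ("N", "CA", "C", "O")])
            dmin = np.sqrt(((atoms_a[:, None] - atoms_b[None, :]) ** 2).sum(-1)).min()
            if dmin < 2.3:          # reject sterically clashing registries
                continue
            score = _ks_pair_energy(row_a, cand)
            if score > best_score:
                best, best_score = cand, score
    return best, best_score


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +x onto ``direction``."""
    d = direction / np.linalg.norm(direction)
    x = np.array([1.0, 0.0, 0.0])
    axis = np.cross(x, d)
    s = np.linalg.norm(axis)
    c = float(x @ d)
    if s < 1e-9:
        return np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _coil_extension(attach_point: np.ndarray, direction: np.ndarray,
                    n_res: int, reverse: bool, bend_deg: float = 50.0,
                    segment_len: int = 8, bend_axis: str = "y") -> dict[str, np.ndarray]:
    """Compact coil run fanned out from ``attach_point``.

    Built as straight extended segments of up to ``segment_len`` residues,
    each successive segment turned by ``bend_deg`` about the sheet's in-plane
    y axis so long termini curl instead of running straight (flexible tails
    are compact in practice; the ideal local geometry is kept within each
    segment).
    """
    d0 = np.asarray(direction, float)
    d0 = d0 / np.linalg.norm(d0)
    bend = np.deg2rad(bend_deg)
    cb, sb = np.cos(bend), np.sin(bend)

    def turn(d):
        if bend_axis == "y":
            d = np.array([cb * d[0] + sb * d[2], d[1], -sb * d[0] + cb * d[2]])
        else:  # bend about z: curl within the sheet plane
            d = np.array([cb * d[0] - sb * d[1], sb * d[0] + cb * d[1], d[2]])
        return d / np.linalg.norm(d)

    # per-segment walk directions, outward from the attach point
    seg_lens = []
    remaining = n_res
    while remaining > 0:
        seg_lens.append(min(segment_len, remaining))
        remaining -= seg_lens[-1]
    dirs = [d0]
    for _ in seg_lens[1:]:
        dirs.append(turn(dirs[-1]))

    if reverse:
        # N-terminal coil: residues run in natural N→C order TOWARD the
        # attach point, so build forward along the reversed direction list
        seg_lens = seg_lens[::-1]
        dirs = [-dd for dd in dirs[::-1]]

    pieces: list[dict[str, np.ndarray]] = []
    start = None
    for n_seg, d in zip(seg_lens, dirs):
        bb = _strand(n_seg, reverse=False)
        R = _rotation_to(d)
        seg = {k: v @ R.T for k, v in bb.items()}
        anchor = (attach_point + 3.8 * d) if start is None else (start + 3.8 * d)
        seg = {k: v + (anchor - seg["N"][0]) for k, v in seg.items()}
        pieces.append(seg)
        start = seg["C"][-1]
    out = {k: np.concatenate([p[k] for p in pieces]) for k in ("N", "CA", "C", "O")}
    if reverse:
        # translate so the final C sits one peptide-bond length before attach
        shift = (attach_point - 1.33 * dirs[-1]) - out["C"][-1]
        out = {k: v + shift for k, v in out.items()}
    return out


@dataclass
class _ChainPlan:
    chain_id: str
    segments: list  # (start_res, end_res, kind, row or coil params)


def make_tetramer_coords(topology: TopologySpec | None = None) -> tuple[Structure, dict]:
    """Idealized six-stranded antiparallel β-sheet tetramer with coil termini.

    Four 42-residue chains: two "red" hairpin subunits contribute strands
    β1 and β2, two "green" subunits contribute β3; sheet order is
    β1–β2–β3–β3′–β2′–β1′ with ~4.8–5 Å strand spacing and registries chosen
    (deterministically) to maximise inter-strand Kabsch–Sander hydrogen
    bonds. Loops and termini are extended coil runs fanned out of the sheet
    plane. Returns the structure and a ground-truth dict with per-residue
    secondary-structure labels per chain.
    """
    topo = topology or TopologySpec()
    b1 = (topo.beta1[0], topo.beta1[1])
    b2 = (topo.beta2[0], topo.beta2[1])
    b3 = (topo.beta3[0], topo.beta3[1])

    def length(rng):
        return rng[1] - rng[0] + 1

    # sheet rows bottom-to-top: (chain, resrange, reverse)
    rows_spec = [
        ("A", b1, False), ("A", b2, True), ("B", b3, False),
        ("D", b3, True), ("C", b2, False), ("C", b1, True),
    ]
    rows: list[dict] = []
    placed = _strand(length(rows_spec[0][1]), rows_spec[0][2])
    rows.append(placed)
    for chain, rng, rev in rows_spec[1:]:
        nxt, _ = _optimal_registry(rows[-1], length(rng), rev)
        rows.append(nxt)

    # assemble chains with coil termini/loops out of the sheet plane (±z)
    chain_bbs: dict[str, dict[int, dict[str, np.ndarray]]] = {c: {} for c in "ABCD"}
    labels: dict[str, list[str]] = {}

    def add_run(chain: str, res_range: tuple[int, int], bb: dict):
        for k, resnum in enumerate(range(res_range[0], res_range[1] + 1)):
            chain_bbs[chain][resnum] = {at: bb[at][k] for at in ("N", "CA", "C", "O")}

    for (chain, rng, rev), bb in zip(rows_spec, rows):
        add_run(chain, rng, bb)

    # all termini fan to +z so one sheet face stays clean (the membrane-facing
    # hydrophobic face of the real oligomer); builders stack on the clean side
    z_dir = {"A": +1.0, "C": +1.0, "B": +1.0, "D": +1.0}

    def coil(chain: str, res_range: tuple[int, int], attach_res: int, before: bool,
             direction: np.ndarray, bend_axis: str = "y", bend_deg: float = 50.0,
             segment_len: int = 8):
        """Coil run attached before (N-terminal) or after an existing residue."""
        if res_range[1] < res_range[0]:
            return
        n = res_range[1] - res_range[0] + 1
        anchor = chain_bbs[chain][attach_res]["N" if before else "C"]
        bb = _coil_extension(anchor, np.asarray(direction, float), n, reverse=before,
                             bend_axis=bend_axis, bend_deg=bend_deg,
                             segment_len=segment_len)
        add_run(chain, res_range, bb)

    def strand_dir(chain, rng_):
        """Unit +x direction of a placed strand (residue order)."""
        a = chain_bbs[chain][rng_[0]]["CA"]
        b = chain_bbs[chain][rng_[1]]["CA"]
        d = b - a
        return d / np.linalg.norm(d)

    for red in ("A", "C"):
        zd = z_dir[red]
        d1 = strand_dir(red, b1)
        # N-terminus fans off the sheet plane before β1; hairpin loop arcs over
        # the strand ends between β1 and β2; C-terminus exits past β2.
        coil(red, (1, b1[0] - 1), b1[0], before=True,
             direction=[-d1[0] * 0.5, 0.0, zd * 0.87])
        coil(red, (b1[1] + 1, b2[0] - 1), b1[1], before=False,
             direction=[d1[0] * 0.8, 0.3, zd * 0.5], bend_deg=70.0)
        coil(red, (b2[1] + 1, 42), b2[1], before=False,
             direction=[-d1[0] * 0.7, 0.0, zd * 0.7])
    for green in ("B", "D"):
        d3 = strand_dir(green, b3)
        yout = -1.0 if green == "B" else 1.0
        # long green termini run past the strand ends and curl gently within
        # the sheet plane (±y) so they never cross the sheet normal axis
        coil(green, (1, b3[0] - 1), b3[0], before=True,
             direction=[-d3[0] * 0.95, yout * 0.2, z_dir[green] * 0.12],
             bend_axis="z", bend_deg=42.0, segment_len=6)
        coil(green, (b3[1] + 1, 42), b3[1], before=False,
             direction=[d3[0] * 0.95, yout * 0.2, z_dir[green] * 0.12],
             bend_axis="z", bend_deg=-42.0, segment_len=6)

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in "ABCD":
        lab = ["C"] * 42
        if chain in ("A", "C"):
            for r in range(b1[0], b1[1] + 1):
                lab[r - 1] = "E"
            for r in range(b2[0], b2[1] + 1):
                lab[r - 1] = "E"
        else:
            for r in range(b3[0], b3[1] + 1):
                lab[r - 1] = "E"
        labels[chain] = lab
        for resnum in sorted(chain_bbs[chain]):
            restype = _ONE_TO_THREE[AB42_SEQUENCE[resnum - 1]]
            for at_name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                serial += 1
                x, y, z = chain_bbs[chain][resnum][at_name]
                atoms.append(AtomRecord(serial, at_name, el, restype, resnum,
                                        chain, float(x), float(y), float(z)))
    s = Structure(atoms, topology=topo, name="ideal-tetramer")
    strand_frac = float(np.mean([l == "E" for c in "ABCD" for l in labels[c]]))
    truth = {"ss_labels": labels, "strand_fraction": strand_frac,
             "n_chains": 4, "sequence": AB42_SEQUENCE}
    return s, truth


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate atom placement (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_helix_coords(n_res: int = 16, phi: float = -57.0, psi: float = -47.0,
                      chain_id: str = "A",
                      sequence: str | None = None) -> tuple[Structure, dict]:
    """Ideal α-helix backbone (N, CA, C, O) built from internal coordinates.

    Standard bond geometry with repeating (φ, ψ) and ω = 180°; carbonyl O in
    the sp² plane. Ground truth labels all interior residues helical.
    """
    seq = (sequence or ("A" * n_res))
    if len(seq) != n_res:
        raise ValueError("sequence length mismatch")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(111.2)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        if i > 0:
            N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, 117.2, psi)
            CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, 121.7, 180.0)
            C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, 111.2, phi)
        nxt = _place_atom(N[i], CA[i], C[i], _B_C_N, 117.2, psi)
        O[i] = _place_atom(N[i], CA[i], C[i], _B_C_O, 121.0, psi + 180.0)
        del nxt
    atoms = []
    serial = 0
    for i in range(n_res):
        restype = _ONE_TO_THREE[seq[i]]
        for name, el, pos in (("N", "N", N[i]), ("CA", "C", CA[i]),
                              ("C", "C", C[i]), ("O", "O", O[i])):
            serial += 1
            atoms.append(AtomRecord(serial, name, el, restype, i + 1, chain_id,
                                    float(pos[0]), float(pos[1]), float(pos[2])))
    s = Structure(atoms, name="ideal-helix")
    return s, {"n_res": n_res, "phi": phi, "psi": psi,
               "labels": ["H"] * n_res}


def make_ensemble(base: Structure, jitter_sigma: float, n_models: int = 15,
                  seed: int = 0) -> tuple[Ensemble, dict]:
    """Ensemble of ``n_models`` copies with isotropic Gaussian per-atom jitter."""
    if jitter_sigma < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    coords = base.coords()
    models = []
    for _ in range(n_models):
        m = base.copy()
        m.set_coords(coords + rng.normal(scale=jitter_sigma, size=coords.shape)
                     if jitter_sigma > 0 else coords)
        models.append(m)
    # E[RMSD to mean] for isotropic jitter: each deviation from the model mean
    # has variance σ²(1−1/n) per axis; RMSD over atoms ≈ σ·√3·√(1−1/n)
    expected = jitter_sigma * np.sqrt(3.0) * np.sqrt(1.0 - 1.0 / n_models)
    return Ensemble(models), {"sigma": jitter_sigma, "n_models": n_models,
                              "expected_rmsd_to_mean": float(expected)}


# ---------------------------------------------------------------------------
# Membrane pseudo-trajectory


def make_membrane_traj(n_frames: int = 5, half_thickness: float = 15.0,
                       box_xy: float = 60.0, box_z: float = 80.0,
                       n_waters: int = 400, pore_radius: float = 0.0,
                       pore_occupancy: int = 0, n_probes_per_leaflet: int = 40,
                       probe_near_residue: tuple[str, int, float] | None = None,
                       jitter: float = 0.0, seed: int = 0) -> tuple[Trajectory, dict]:
    """Membrane-slab pseudo-trajectory with probe sites and optional pore.

    A small protein fixture sits at the origin; headgroup-N-like probes lie
    on the two planes z = ±half_thickness and tail-carbon probes near z = 0;
    water oxygens fill the box except the slab |z| < half_thickness, apart
    from ``pore_occupancy`` waters placed inside an axial pore cylinder of
    ``pore_radius``. ``probe_near_residue = (chain, resnum, distance)``
    additionally pins three headgroup probes at exactly that distance from
    the residue's amide N. Ground truth (selection indices, in-slab water
    count) is returned alongside.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0

    # minimal protein: two short backbone runs spanning the slab
    protein_idx = []
    for chain, x0 in (("P", -5.0), ("Q", 5.0)):
        for resnum in range(1, 11):
            z = -13.5 + 3.0 * (resnum - 1)
            for at_name, el, off in (("N", "N", -0.6), ("CA", "C", 0.0),
                                     ("C", "C", 0.6), ("O", "O", 1.1)):
                serial += 1
                atoms.append(AtomRecord(serial, at_name, el, "ALA", resnum, chain,
                                        x0 + off, 0.3 * resnum, z))
                protein_idx.append(serial - 1)

    # probe sites: headgroup N on leaflet planes, terminal tail C near z=0
    head_idx, tail_idx = [], []
    for leaflet, zplane in ((1, half_thickness + 2.0), (2, -half_thickness - 2.0)):
        for k in range(n_probes_per_leaflet):
            serial += 1
            x, y = rng.uniform(-box_xy / 2, box_xy / 2, size=2)
            atoms.append(AtomRecord(serial, "N", "N", "DPC",
                                    1000 * leaflet + k, "L", x, y, zplane))
            head_idx.append(serial - 1)
            serial += 1
            atoms.append(AtomRecord(serial, "C12", "C", "DPC",
                                    1000 * leaflet + k, "L", x, y,
                                    zplane - np.sign(zplane) * (half_thickness - 1.0)))
            tail_idx.append(serial - 1)

    pinned = []
    if probe_near_residue is not None:
        chain, resnum, dist = probe_near_residue
        target = next(a for a in atoms
                      if a.chain_id == chain and a.residue_number == resnum
                      and a.name == "N")
        # directions perpendicular to the protein chain axis (z) so the
        # pinned probes stay outside the cutoff of neighbouring residues
        for k, direction in enumerate((np.array([1.0, 0.0, 0.0]),
                                       np.array([-1.0, 0.0, 0.0]),
                                       np.array([0.0, 1.0, 0.0]))):
            serial += 1
            pos = target.xyz + dist * direction
            atoms.append(AtomRecord(serial, "N", "N", "DPC", 3000 + k, "L",
                                    *pos.tolist()))
            head_idx.append(serial - 1)
            pinned.append(serial - 1)

    # waters: uniform outside the slab; optional pore waters inside
    water_idx = []
    n_out = 0
    while n_out < n_waters:
        x, y = rng.uniform(-box_xy / 2, box_xy / 2, size=2)
        z = rng.uniform(-box_z / 2, box_z / 2)
        if abs(z) < half_thickness:
            continue
        serial += 1
        atoms.append(AtomRecord(serial, "O", "O", "HOH", 5000 + n_out, "W", x, y, z))
        water_idx.append(serial - 1)
        n_out += 1
    for k in range(pore_occupancy):
        serial += 1
        r = pore_radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-half_thickness + 0.5, half_thickness - 0.5)
        atoms.append(AtomRecord(serial, "O", "O", "HOH", 7000 + k, "W",
                                r * np.cos(th), r * np.sin(th), z))
        water_idx.append(serial - 1)

    top = Structure(atoms, name="membrane-slab")
    base = top.coords()
    frames = np.stack([
        base + (rng.normal(scale=jitter, size=base.shape) if jitter > 0 else 0.0)
        for _ in range(n_frames)
    ])
    traj = Trajectory(top, frames)
    truth = {
        "protein_idx": np.array(protein_idx),
        "head_idx": np.array(head_idx), "tail_idx": np.array(tail_idx),
        "water_idx": np.array(water_idx), "pinned_probe_idx": np.array(pinned),
        "n_waters_outside": n_out, "pore_occupancy": pore_occupancy,
        "half_thickness": half_thickness,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Mass spectrometry fixtures


def make_mass_spectrum(envelopes: dict[int, dict[int, float]], monomer_mass: float,
                       mz_range: tuple[float, float] = (1000.0, 10000.0),
                       peak_sigma: float = 1.5, points: int = 40000,
                       baseline_noise: float = 0.0,
                       seed: int = 0) -> tuple[MassSpectrum, pd.DataFrame]:
    """Continuum spectrum from charge-state envelopes.

    ``envelopes`` maps oligomer order n to {charge z: abundance}. Gaussian
    peaks of width ``peak_sigma`` Th are placed at (n·M + z·m_p)/z; additive
    Gaussian baseline noise optional. Returns the spectrum and a truth table
    (n, z, mz, abundance).
    """
    rng = np.random.default_rng(seed)
    mz = np.linspace(*mz_range, points)
    intensity = np.zeros_like(mz)
    rows = []
    for n, env in envelopes.items():
        for z, abundance in env.items():
            if abundance < 0:
                raise ValueError("abundances must be non-negative")
            center = theoretical_mz(n, z, monomer_mass)
            intensity += abundance * np.exp(-0.5 * ((mz - center) / peak_sigma) ** 2)
            rows.append({"n": n, "z": z, "mz": center, "abundance": abundance})
    if baseline_noise > 0:
        intensity += np.abs(rng.normal(scale=baseline_noise, size=mz.shape))
    return MassSpectrum(mz, intensity), pd.DataFrame(rows)


def make_calibrant_table(lnA: float = 6.0, B: float = 0.45,
                         gas: GasParameters | None = None,
                         species: list[tuple[str, float, int, float]] | None = None,
                         noise_frac: float = 0.0,
                         seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Calibrant drift-time table drawn from an assumed TWIMS power law.

    ``species`` rows are (name, mass_da, z, ccs_A2); drift times follow
    t_d = (CCS·√μ/z · e^{−lnA})^{1/B} with optional multiplicative noise.
    Defaults emulate the typical native calibrant set (cytochrome c,
    β-lactoglobulin monomer/dimer, avidin).
    """
    gas = gas or GasParameters()
    rng = np.random.default_rng(seed)
    if species is None:
        species = [
            ("cytochrome_c", 12360.0, 6, 1490.0),
            ("beta_lactoglobulin_monomer", 18400.0, 8, 1960.0),
            ("beta_lactoglobulin_dimer", 36800.0, 11, 3040.0),
            ("avidin", 64000.0, 14, 4150.0),
        ]
    rows = []
    for name, mass, z, ccs in species:
        mu = reduced_mass(mass, gas.gas_mass)
        ccs_prime = ccs * np.sqrt(mu) / z
        td = (ccs_prime * np.exp(-lnA)) ** (1.0 / B)
        if noise_frac > 0:
            td *= 1.0 + rng.normal(scale=noise_frac)
        rows.append({"name": name, "mass_da": mass, "z": z, "ccs_A2": ccs,
                     "td_ms": td})
    return pd.DataFrame(rows), {"lnA": lnA, "B": B}


# ---------------------------------------------------------------------------
# NMR fixtures

DEFAULT_SS_OFFSETS = {"E": (-2.0, 2.0), "H": (2.5, -0.8), "C": (0.0, 0.0)}


def make_shift_table(ss_string: str, sequence: str = AB42_SEQUENCE,
                     offsets: dict | None = None, noise_ppm: float = 0.0,
                     nh_slopes_ppb_per_K: dict[int, float] | None = None,
                     temperatures_K: tuple[float, ...] = (303.0, 310.0, 317.0, 324.0),
                     subunit: str = "red", seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Shift table painted from a secondary-structure string.

    Cα/Cβ shifts are random-coil values plus SS-dependent offsets
    (strand: ΔCα −2, ΔCβ +2 ppm by default) plus Gaussian noise. When
    ``nh_slopes_ppb_per_K`` is given, amide-proton rows are emitted per
    temperature with those linear slopes around a 8.2 ppm intercept.
    """
    if len(ss_string) != len(sequence):
        raise ValueError("SS string and sequence lengths differ")
    if any(ch not in "EHC" for ch in ss_string):
        raise ValueError("SS string may contain only E/H/C")
    offsets = offsets if offsets is not None else DEFAULT_SS_OFFSETS
    rng = np.random.default_rng(seed)
    rows = []
    for i, (aa, ss) in enumerate(zip(sequence, ss_string), start=1):
        restype = _ONE_TO_THREE[aa]
        ca_rc, cb_rc = nmr.RANDOM_COIL_SHIFTS[restype]
        d_ca, d_cb = offsets[ss]
        rows.append({"subunit": subunit, "residue": i, "restype": restype,
                     "atom": "CA",
                     "shift_ppm": ca_rc + d_ca + rng.normal(scale=noise_ppm)
                     if noise_ppm > 0 else ca_rc + d_ca,
                     "temperature_K": temperatures_K[0]})
        if cb_rc is not None:
            rows.append({"subunit": subunit, "residue": i, "restype": restype,
                         "atom": "CB",
                         "shift_ppm": cb_rc + d_cb + rng.normal(scale=noise_ppm)
                         if noise_ppm > 0 else cb_rc + d_cb,
                         "temperature_K": temperatures_K[0]})
    if nh_slopes_ppb_per_K:
        for resnum, slope in nh_slopes_ppb_per_K.items():
            for T in temperatures_K:
                shift = 8.2 + slope * 1e-3 * (T - temperatures_K[0])
                if noise_ppm > 0:
                    shift += rng.normal(scale=noise_ppm)
                rows.append({"subunit": subunit, "residue": resnum,
                             "restype": _ONE_TO_THREE[sequence[resnum - 1]],
                             "atom": "HN", "shift_ppm": shift,
                             "temperature_K": T})
    truth = {"ss_string": ss_string, "offsets": offsets,
             "nh_slopes": nh_slopes_ppb_per_K or {}}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Current traces

# pore-type occurrence mixes observed across experiments, (type1, type2, type3) %
OCCURRENCE_PRESETS = {
    "tetramer_enriched": {"percent": (17.0, 48.0, 35.0), "N": 105},
    "octamer_enriched": {"percent": (8.5, 35.0, 56.0), "N": 71},
}


def make_current_trace(pore_type: int, G_nS: float = 0.5, potential_mV: float = 100.0,
                       noise_pA: float = 1.5, duration_s: float = 1.0,
                       sampling_rate_Hz: float = 10_000.0,
                       event_rate_Hz: float = 20.0,
                       seed: int = 0) -> CurrentTrace:
    """Synthetic single-channel trace of a given pore type.

    Type 3: one stable open level at G·V. Type 2: stepwise dwells between the
    closed and open level (≈55/45 occupancy). Type 1: fast flicker over a
    continuum of sub-levels with no level holding a stable occupancy.
    """
    if G_nS < 0:
        raise ValueError("conductance must be non-negative")
    if potential_mV == 0:
        raise ValueError("potential must be nonzero")
    rng = np.random.default_rng(seed)
    n = int(duration_s * sampling_rate_Hz)
    open_level = G_nS * potential_mV       # pA
    if pore_type == 3:
        cur = np.full(n, open_level)
    elif pore_type == 2:
        cur = np.empty(n)
        level = 0.0
        i = 0
        mean_dwell = int(sampling_rate_Hz / event_rate_Hz)
        while i < n:
            dwell = max(1, int(rng.exponential(mean_dwell)))
            cur[i:i + dwell] = level
            level = open_level if level == 0.0 else 0.0
            i += dwell
    elif pore_type == 1:
        # resample a new random sub-level every ~1 ms: broad histogram
        seg = max(1, int(sampling_rate_Hz * 0.001))
        n_seg = n // seg + 1
        levels = rng.uniform(0.0, open_level, size=n_seg)
        cur = np.repeat(levels, seg)[:n]
    else:
        raise ValueError("pore type must be 1, 2 or 3")
    if noise_pA > 0:
        cur = cur + rng.normal(scale=noise_pA, size=n)
    return CurrentTrace(cur, potential_mV, sampling_rate_Hz, label=pore_type)


def make_trace_batch(preset: str = "tetramer_enriched", n_traces: int | None = None,
                     G_nS: float = 0.5, potential_mV: float = 100.0,
                     duration_s: float = 0.5, seed: int = 0) -> list[CurrentTrace]:
    """Batch of labelled traces drawn from an occurrence-mix preset."""
    mix = OCCURRENCE_PRESETS[preset]
    n = n_traces if n_traces is not None else mix["N"]
    probs = np.array(mix["percent"]) / 100.0
    rng = np.random.default_rng(seed)
    types = rng.choice([1, 2, 3], size=n, p=probs / probs.sum())
    return [make_current_trace(int(t), G_nS=G_nS, potential_mV=potential_mV,
                               duration_s=duration_s, seed=int(rng.integers(2 ** 31)))
            for t in types]
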