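"""Candidate octamer topologies built from a tetramer building block.

Two rigid-body assemblies of two tetramer copies are considered:

* **β-sandwich** — the copies stacked face-to-face across the β-sheet plane
  (hydrophobic faces apposed), related by a 180° flip about an in-plane axis;
* **loose β-barrel** — the copies tilted and placed on opposite sides of a
  central axis so the strands enclose a solvent-accessible cavity.

Both builders are deterministic, purely rigid-body (each copy's internal
coordinates are untouched) and validated geometrically: a clash check for
the sandwich, a probe-on-axis cavity check for the barrel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Selection, Structure, AtomRecord

__all__ = ["ModelBuildSpec", "BuildError", "build_beta_sandwich", "build_beta_barrel"]


@dataclass
class ModelBuildSpec:
    mode: str = "sandwich"                  # "sandwich" | "barrel"
    separation: float = 10.0                # sheet–sheet separation (Å), sandwich
    barrel_radius: float = 11.0             # distance of each sheet to the axis (Å)
    barrel_tilt_deg: float = 25.0           # tilt of each sheet about the strand axis
    relative_rotation_deg: float = 180.0
    clash_cutoff: float = 2.5               # min inter-copy heavy-atom distance (Å)
    search_window: float = 10.0             # extra separation explored before failing
    search_step: float = 0.5

    def __post_init__(self):
        if self.separation <= 0 or self.clash_cutoff <= 0:
            raise ValueError("separation and clash cutoff must be positive")


class BuildError(RuntimeError):
    pass


def _sheet_frame(t: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis frame of the β-sheet core Cα atoms.

    Returns (centroid, axes) with axes rows = (strand axis, in-plane axis,
    sheet normal) from the PCA of core Cα coordinates; falls back to all Cα
    when no topology annotation is present.
    """
    idx = None
    if t.topology is not None:
        keep = []
        for i, a in enumerate(t.atoms):
            if a.name.upper() == "CA" and a.residue_number in \
                    t.topology.core_residues(a.chain_id):
                keep.append(i)
        if keep:
            idx = np.array(keep)
    if idx is None:
        idx = t.select(Selection(names="calpha"))
    if len(idx) < 3:
        raise BuildError("cannot resolve a β-sheet core frame (need >= 3 Cα)")
    coords = t.coords()[idx]
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    w, v = np.linalg.eigh(cov)
    axes = v[:, ::-1].T              # rows: descending variance
    # deterministic signs: strand axis toward its largest component, normal
    # toward the side carrying the flexible termini (material side)
    if axes[0][np.argmax(np.abs(axes[0]))] < 0:
        axes[0] *= -1.0
    skew = float(((t.coords() - centroid) @ axes[2]).mean())
    if skew < 0:
        axes[2] *= -1.0
    axes[1] = np.cross(axes[2], axes[0])
    return centroid, axes


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _min_heavy_distance(a: np.ndarray, b: np.ndarray) -> float:
    best = np.inf
    chunk = max(1, int(2e6) // max(len(b), 1))
    for s in range(0, len(a), chunk):
        d2 = ((a[s:s + chunk, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        best = min(best, float(np.sqrt(d2.min())))
    return best


_CHAIN_RELABEL = {"A": "E", "B": "F", "C": "G", "D": "H"}


def _assemble(t: Structure, second_coords: np.ndarray) -> Structure:
    atoms = [a for a in t.copy().atoms]
    n = len(atoms)
    for i, a in enumerate(t.atoms):
        atoms.append(AtomRecord(
            serial=n + i + 1, name=a.name, element=a.element,
            residue_name=a.residue_name, residue_number=a.residue_number,
            chain_id=_CHAIN_RELABEL.get(a.chain_id, a.chain_id + "'"),
            x=float(second_coords[i, 0]), y=float(second_coords[i, 1]),
            z=float(second_coords[i, 2]), mass=a.mass, radius=a.radius,
            het=a.het))
    return Structure(atoms, topology=t.topology, name=t.name + "-octamer")


def build_beta_sandwich(t: Structure, spec: ModelBuildSpec | None = None) -> Structure:
    """Face-to-face octamer: second copy flipped 180° and offset along the normal.

    The separation starts at ``spec.separation`` and grows in
    ``spec.search_step`` increments (up to ``spec.search_window``) until no
    inter-copy heavy-atom pair is closer than ``spec.clash_cutoff``; the
    smallest clash-free separation maximises the buried face contact.
    """
    spec = spec or ModelBuildSpec(mode="sandwich")
    centroid, axes = _sheet_frame(t)
    strand_axis, normal = axes[0], axes[2]
    coords = t.coords()
    heavy = t.select(Selection(names="heavy"))
    R = _rotation_about(strand_axis, np.deg2rad(spec.relative_rotation_deg))
    flipped = (coords - centroid) @ R.T + centroid
    # stack on the material-free face (normal points toward the termini side)
    sep = spec.separation
    while sep <= spec.separation + spec.search_window:
        second = flipped - sep * normal
        dmin = _min_heavy_distance(coords[heavy], second[heavy])
        if dmin >= spec.clash_cutoff:
            return _assemble(t, second)
        sep += spec.search_step
    raise BuildError(
        f"no clash-free separation within window (closest contact {dmin:.2f} Å)")


def build_beta_barrel(t: Structure, spec: ModelBuildSpec | None = None,
                      probe_radius: float = 2.8) -> Structure:
    """Edge-closed octamer: two tilted copies enclosing a central axis cavity.

    Each copy is tilted by ±``spec.barrel_tilt_deg`` about the strand axis
    and displaced to ±``spec.barrel_radius`` from the central axis. The build
    is accepted only if a probe sphere of ``probe_radius`` placed along the
    central axis overlaps no heavy atom.
    """
    spec = spec or ModelBuildSpec(mode="barrel")
    centroid, axes = _sheet_frame(t)
    strand_axis, normal = axes[0], axes[2]
    coords = t.coords() - centroid
    heavy = t.select(Selection(names="heavy"))

    tilt = np.deg2rad(spec.barrel_tilt_deg)
    R_up = _rotation_about(strand_axis, tilt)
    R_flip = _rotation_about(axes[1], np.pi)       # flip about in-plane axis
    R_down = _rotation_about(strand_axis, -tilt)

    first = coords @ R_up.T + spec.barrel_radius * normal + centroid
    second = (coords @ R_flip.T) @ R_down.T - spec.barrel_radius * normal + centroid

    # cavity test: probe spheres along the central (strand) axis over the
    # β-sheet-core-spanned region (the enclosed channel; termini fan outside it)
    core_idx = [i for i, a in enumerate(t.atoms)
                if a.name.upper() == "CA" and t.topology is not None
                and a.residue_number in t.topology.core_residues(a.chain_id)]
    span = (coords[core_idx] if core_idx else coords) @ strand_axis
    ts = np.linspace(span.min() * 0.6, span.max() * 0.6, 15)
    axis_pts = centroid[None, :] + ts[:, None] * strand_axis[None, :]
    allheavy = np.vstack([first[heavy], second[heavy]])
    d = np.sqrt(((axis_pts[:, None, :] - allheavy[None, :, :]) ** 2).sum(axis=2))
    if d.min() < probe_radius:
        raise BuildError(
            f"central cavity fails the {probe_radius} Å probe test "
            f"(closest heavy atom at {d.min():.2f} Å from the axis)")

    first_struct = t.copy()
    first_struct.set_coords(first)
    return _assemble(first_struct, second)
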