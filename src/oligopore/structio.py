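"""Core structural data model: atoms, structures, ensembles, selections.

Coordinates are in Å in a right-handed frame with the membrane normal along
z. Residue numbering is 1-based and ranges are inclusive. PDB and mmCIF
parsing/writing is delegated to gemmi; the in-memory model is a flat,
order-preserving list of :class:`AtomRecord` so every downstream selection
resolves to a deterministic, ordered atom subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "TopologySpec",
    "Selection",
    "ParseError",
    "TopologyError",
    "DegenerateSelectionError",
    "read_structure",
    "write_pdb",
    "superpose",
    "apply_transform",
    "strip_heteroatoms",
    "kabsch",
]

# Three-letter codes treated as standard amino acids (incl. common variants).
STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE HSD HSE HSP HID HIE HIP""".split()
)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

# Average atomic masses (Da) for the elements that occur in proteins.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "D": 2.014,
}


class ParseError(ValueError):
    """A structure file does not parse as the named standard."""


class TopologyError(ValueError):
    """Models of a multi-model file do not share one topology."""


class DegenerateSelectionError(ValueError):
    """A selection is too small or collinear for superposition."""


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Handles the common two-character cases (CL, NA, SE, FE, ZN, MG) and
    otherwise takes the first alphabetic character.
    """
    stripped = name.strip()
    two = stripped[:2].upper()
    if two in {"CL", "NA", "SE", "FE", "ZN", "MG", "BR", "MN"} and len(stripped) <= 2:
        return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    x: float
    y: float
    z: float
    mass: float = 0.0
    radius: float = 0.0
    het: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be nonempty")
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError("coordinates must be finite")
        if self.mass == 0.0:
            self.mass = ATOMIC_MASSES.get(self.element.upper(), 0.0)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class TopologySpec:
    """Secondary-structure element ranges of the tetramer building block.

    The six-stranded core pairs two hairpin subunits ("red") contributing
    strands beta1 (9-21) and beta2 (29-40) with two subunits ("green")
    contributing strand beta3 (29-41); the green subunits also carry a short
    helical turn alpha1 (17-20). Ranges are 1-based inclusive residue numbers
    within the 42-residue peptide.
    """

    beta1: tuple[int, int] = (9, 21)
    beta2: tuple[int, int] = (29, 40)
    alpha1: tuple[int, int] = (17, 20)
    beta3: tuple[int, int] = (29, 41)
    red_chains: tuple[str, ...] = ("A", "C")
    green_chains: tuple[str, ...] = ("B", "D")

    def __post_init__(self):
        for lo, hi in (self.beta1, self.beta2, self.alpha1, self.beta3):
            if not (1 <= lo <= hi <= 42):
                raise ValueError("element ranges must lie within residues 1-42")
        if self.beta1[1] >= self.beta2[0]:
            raise ValueError("beta1 and beta2 overlap within the red subunit")
        if self.alpha1[1] >= self.beta3[0]:
            raise ValueError("alpha1 and beta3 overlap within the green subunit")

    def core_residues(self, chain_id: str) -> list[int]:
        """Residues of the six-stranded β-sheet core for one chain."""
        if chain_id in self.red_chains:
            return list(range(self.beta1[0], self.beta1[1] + 1)) + list(
                range(self.beta2[0], self.beta2[1] + 1)
            )
        if chain_id in self.green_chains:
            return list(range(self.beta3[0], self.beta3[1] + 1))
        return []

    def subunit_color(self, chain_id: str) -> str | None:
        if chain_id in self.red_chains:
            return "red"
        if chain_id in self.green_chains:
            return "green"
        return None


@dataclass
class Selection:
    """Predicate over chain / residue range / atom-name class.

    ``names`` may be a set of atom names or one of the classes ``backbone``,
    ``calpha``, ``amide_n``, ``heavy``, ``all``. Resolution order follows the
    topology atom order, so repeated resolution is deterministic.
    """

    chains: tuple[str, ...] | None = None
    residues: tuple[int, int] | None = None
    residue_list: tuple[int, ...] | None = None
    names: frozenset[str] | str = "all"

    @staticmethod
    def parse(expr: str) -> "Selection":
        """Parse a config string like ``"chain A and resid 9-21 and backbone"``."""
        chains = None
        residues = None
        names: frozenset[str] | str = "all"
        for clause in [c.strip() for c in expr.split(" and ")]:
            if not clause:
                continue
            low = clause.lower()
            if low.startswith("chain "):
                chains = tuple(clause.split()[1:])
            elif low.startswith("resid "):
                spans = clause.split()[1]
                lo, _, hi = spans.partition("-")
                residues = (int(lo), int(hi or lo))
            elif low in {"backbone", "calpha", "amide_n", "heavy", "all"}:
                names = low
            elif low.startswith("name "):
                names = frozenset(n.upper() for n in clause.split()[1:])
            else:
                raise ValueError(f"cannot parse selection clause {clause!r}")
        return Selection(chains=chains, residues=residues, names=names)

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residues is not None and not (
            self.residues[0] <= atom.residue_number <= self.residues[1]
        ):
            return False
        if self.residue_list is not None and atom.residue_number not in self.residue_list:
            return False
        if isinstance(self.names, frozenset):
            return atom.name.upper() in self.names
        cls = self.names
        if cls == "all":
            return True
        if cls == "heavy":
            return atom.element.upper() not in {"H", "D"}
        if cls == "backbone":
            return atom.name.upper() in BACKBONE_NAMES
        if cls == "calpha":
            return atom.name.upper() == "CA"
        if cls == "amide_n":
            return atom.name.upper() == "N"
        raise ValueError(f"unknown atom-name class {cls!r}")


class Structure:
    """An ordered collection of atoms with a per-chain residue index."""

    def __init__(self, atoms: list[AtomRecord], topology: TopologySpec | None = None,
                 name: str = ""):
        self.atoms = list(atoms)
        self.topology = topology
        self.name = name
        self._build_index()

    def _build_index(self):
        seen = set()
        index: dict[str, dict[int, list[int]]] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            index.setdefault(a.chain_id, {}).setdefault(a.residue_number, []).append(i)
        self.residue_index = index

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.residue_index)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, (x, y, z) in zip(self.atoms, xyz):
            a.x, a.y, a.z = float(x), float(y), float(z)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def select(self, sel: Selection | str) -> np.ndarray:
        """Resolve a selection to an ordered integer index array."""
        if isinstance(sel, str):
            sel = Selection.parse(sel)
        return np.array(
            [i for i, a in enumerate(self.atoms) if sel.matches(a)], dtype=int
        )

    def subset(self, idx: np.ndarray) -> "Structure":
        return Structure([replace(self.atoms[i]) for i in idx], topology=self.topology,
                         name=self.name)

    def copy(self) -> "Structure":
        return Structure([replace(a) for a in self.atoms], topology=self.topology,
                         name=self.name)

    def signature(self) -> tuple:
        """Topology signature used to enforce identical ordering across models."""
        return tuple((a.chain_id, a.residue_number, a.name) for a in self.atoms)


@dataclass
class Ensemble:
    """Models sharing one topology (e.g. refined NMR conformers)."""

    models: list[Structure]
    model_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        sig = self.models[0].signature()
        for k, m in enumerate(self.models[1:], start=2):
            if m.signature() != sig:
                raise TopologyError(f"model {k} does not match model 1 topology")
        if not self.model_ids:
            self.model_ids = list(range(1, len(self.models) + 1))

    def __len__(self) -> int:
        return len(self.models)

    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack."""
        return np.stack([m.coords() for m in self.models])


# ---------------------------------------------------------------------------
# I/O


def _structure_from_gemmi_model(model, keep_het: bool) -> Structure:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H" or res.name not in STANDARD_RESIDUES
            if is_het and not keep_het:
                continue
            for at in res:
                serial += 1
                el = at.element.name if at.element and at.element.name != "X" else ""
                if not el:
                    el = element_from_name(at.name)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=el,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        het=is_het,
                    )
                )
    return Structure(atoms)


def read_structure(path: str, keep_het: bool = True) -> Structure | Ensemble:
    """Read a PDB or mmCIF file into a Structure (one MODEL) or Ensemble.

    Elements are taken from the file when present and inferred from atom
    names otherwise. MODEL blocks must share an identical topology.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    models = [_structure_from_gemmi_model(m, keep_het) for m in st]
    if len(models) == 1:
        return models[0]
    return Ensemble(models,
                    model_ids=[int(getattr(m, "num", i + 1)) for i, m in enumerate(st)])


def write_pdb(obj: Structure | Ensemble, path: str) -> None:
    """Write a Structure or Ensemble as a (multi-MODEL) PDB file."""
    models = obj.models if isinstance(obj, Ensemble) else [obj]
    st = gemmi.Structure()
    st.name = getattr(obj, "name", "") or "oligopore"
    for mi, m in enumerate(models, start=1):
        gm = gemmi.Model(mi)
        chains: dict[str, gemmi.Chain] = {}
        for a in m.atoms:
            ch = chains.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chains[a.chain_id] = ch
            if len(ch) == 0 or ch[-1].seqid.num != a.residue_number:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.het else "A"
                ch.add_residue(res)
            res = ch[-1]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(a.x, a.y, a.z)
            res.add_atom(ga)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T
    rmsd = float(np.sqrt((w * ((moved - Q) ** 2).sum(axis=1)).sum()))
    t = rc - mc @ R.T
    return R, t, rmsd


def _check_noncollinear(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise DegenerateSelectionError("superposition needs >= 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateSelectionError("selected atoms are (near-)collinear")


def superpose(mobile: Structure, reference: Structure,
              sel: Selection | str | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` over a selection.

    Returns ``(rotation, translation, rmsd_Å)``; the transform is not applied
    to ``mobile`` (use :func:`apply_transform`).
    """
    if sel is None:
        sel = Selection()
    mi = mobile.select(sel)
    ri = reference.select(sel)
    if len(mi) != len(ri):
        raise ValueError("selection resolves to different atom counts")
    mcoords = mobile.coords()[mi]
    rcoords = reference.coords()[ri]
    _check_noncollinear(mcoords)
    _check_noncollinear(rcoords)
    return kabsch(mcoords, rcoords)


def apply_transform(s: Structure, rotation: np.ndarray, translation: np.ndarray) -> Structure:
    out = s.copy()
    out.set_coords(s.coords() @ rotation.T + translation)
    return out


def strip_heteroatoms(s: Structure) -> Structure:
    """Keep only standard amino-acid residues (drop solvent, detergent, ions)."""
    kept = [replace(a) for a in s.atoms
            if not a.het and a.residue_name in STANDARD_RESIDUES]
    if not kept:
        warnings.warn("strip_heteroatoms produced an empty structure")
    return Structure(kept, topology=s.topology, name=s.name)
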