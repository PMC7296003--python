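"""Chemical-shift analytics for membrane-associated oligomers.

Three probes are covered:

* secondary chemical shifts — per-residue (ΔCα − ΔCβ) against a random-coil
  reference, three-residue averaged, with β-strand / α-helix element calling
  (negative runs → strand, positive runs → helix);
* amide-proton temperature coefficients Δδ_NH/ΔT in ppb/K from shift series
  measured at several temperatures (a hydrogen-bond / solvent-exposure probe);
* paramagnetic relaxation enhancement profiles ε = 1 − I/I0 from titration
  with a doxyl-labelled lipid probe.

Shift tables are plain pandas DataFrames with columns
``(subunit, residue, restype, atom, shift_ppm, temperature_K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANDOM_COIL_SHIFTS",
    "load_shift_table",
    "secondary_shifts",
    "call_elements",
    "temperature_coefficients",
    "pre_enhancement",
    "SecondaryShiftProfile",
    "PREProfile",
    "SSElement",
]

# Random-coil Cα/Cβ reference shifts (ppm). These are the widely used
# consensus random-coil values for the 20 standard residues; the table can be
# overridden with any (restype, ca_ppm, cb_ppm) CSV via ``random_coil=``.
RANDOM_COIL_SHIFTS: dict[str, tuple[float, float | None]] = {
    "ALA": (52.5, 19.1), "ARG": (56.0, 30.9), "ASN": (53.1, 38.9),
    "ASP": (54.2, 41.1), "CYS": (58.2, 28.0), "GLN": (55.7, 29.4),
    "GLU": (56.6, 29.9), "GLY": (45.1, None), "HIS": (55.0, 29.0),
    "ILE": (61.1, 38.8), "LEU": (55.1, 42.4), "LYS": (56.2, 33.1),
    "MET": (55.4, 32.9), "PHE": (57.7, 39.6), "PRO": (63.3, 32.1),
    "SER": (58.3, 63.8), "THR": (61.8, 69.8), "TRP": (57.5, 29.6),
    "TYR": (57.9, 38.8), "VAL": (62.2, 32.9),
}

SHIFT_COLUMNS = ["subunit", "residue", "restype", "atom", "shift_ppm", "temperature_K"]


def load_shift_table(path: str) -> pd.DataFrame:
    """Read a shift table CSV/TSV with the standard column set."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("residue", "restype", "atom", "shift_ppm") if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing columns: {missing}")
    if not np.isfinite(df["shift_ppm"]).all():
        raise ValueError("shift table contains non-finite shifts")
    return df


def _coil_lookup(random_coil, restype: str) -> tuple[float, float | None]:
    try:
        return random_coil[restype]
    except KeyError:
        raise KeyError(
            f"residue type {restype!r} missing from the random-coil reference table"
        ) from None


@dataclass
class SecondaryShiftProfile:
    """Per-residue secondary shifts: ΔCα, ΔCβ, combined and 3-residue smoothed."""

    residues: np.ndarray
    delta_ca: np.ndarray
    delta_cb: np.ndarray          # NaN where the residue has no Cβ (Gly)
    combined: np.ndarray          # ΔCα − ΔCβ (ΔCα for Gly)
    smoothed: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues, "delta_ca": self.delta_ca,
            "delta_cb": self.delta_cb, "combined": self.combined,
            "smoothed": self.smoothed,
        })


def secondary_shifts(shifts: pd.DataFrame,
                     random_coil: dict | None = None) -> SecondaryShiftProfile:
    """Compute (ΔCα − ΔCβ) secondary shifts with a three-residue average.

    ``combined(i) = (δCα,obs − δCα,rc) − (δCβ,obs − δCβ,rc)``; glycine, which
    has no Cβ, contributes ΔCα alone. The smoothed value at residue *i* is the
    unweighted mean of ``combined`` over the existing members of
    ``{i−1, i, i+1}`` (chain termini use the shorter window).
    """
    rc = random_coil if random_coil is not None else RANDOM_COIL_SHIFTS
    ca = shifts[shifts["atom"].str.upper().isin(["CA", "CALPHA"])]
    cb = shifts[shifts["atom"].str.upper().isin(["CB", "CBETA"])]
    cb_by_res = {int(r.residue): (r.restype, r.shift_ppm) for r in cb.itertuples()}

    residues, dca_l, dcb_l, comb = [], [], [], []
    for row in ca.sort_values("residue").itertuples():
        resnum, restype = int(row.residue), str(row.restype).upper()
        ca_rc, cb_rc = _coil_lookup(rc, restype)
        dca = row.shift_ppm - ca_rc
        if cb_rc is None:
            dcb = np.nan
            combined = dca
        else:
            if resnum not in cb_by_res:
                raise ValueError(f"residue {resnum} ({restype}) lacks a Cβ shift")
            dcb = cb_by_res[resnum][1] - cb_rc
            combined = dca - dcb
        residues.append(resnum)
        dca_l.append(dca)
        dcb_l.append(dcb)
        comb.append(combined)

    residues = np.array(residues)
    comb = np.array(comb)
    by_res = dict(zip(residues.tolist(), comb.tolist()))
    smoothed = np.array([
        np.mean([by_res[j] for j in (i - 1, i, i + 1) if j in by_res])
        for i in residues
    ])
    return SecondaryShiftProfile(residues, np.array(dca_l), np.array(dcb_l),
                                 comb, smoothed)


@dataclass
class SSElement:
    kind: str   # "beta" or "alpha"
    start: int
    end: int


def call_elements(profile: SecondaryShiftProfile, strand_thr: float = 0.7,
                  helix_thr: float = 0.7, min_len: int = 3) -> list[SSElement]:
    """Call secondary-structure elements from the smoothed profile.

    Maximal runs of consecutive residues with smoothed ≤ −strand_thr become
    β-strands; runs with smoothed ≥ +helix_thr become helices; runs shorter
    than ``min_len`` are dropped. Output is sorted and disjoint.
    """
    if strand_thr <= 0 or helix_thr <= 0:
        raise ValueError("thresholds must be positive")
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    calls: list[SSElement] = []
    run_kind, run_start, prev = None, None, None
    for resnum, val in zip(profile.residues, profile.smoothed):
        kind = "beta" if val <= -strand_thr else ("alpha" if val >= helix_thr else None)
        contiguous = prev is not None and resnum == prev + 1
        if kind != run_kind or not contiguous:
            if run_kind is not None and prev - run_start + 1 >= min_len:
                calls.append(SSElement(run_kind, run_start, prev))
            run_kind, run_start = kind, resnum
        prev = resnum
    if run_kind is not None and prev - run_start + 1 >= min_len:
        calls.append(SSElement(run_kind, run_start, prev))
    return calls


DEFAULT_COEFF_BANDS = {
    # Advisory labels: in aqueous solvents exposed amides typically show
    # gradients of −6 to −8.5 ppb/K; hydrogen-bonded protected amides > −4.
    "exposed": (-8.5, -6.0),
    "protected": (-4.0, np.inf),
}


def temperature_coefficients(series: pd.DataFrame,
                             bands: dict | None = None) -> pd.DataFrame:
    """Least-squares amide temperature coefficients Δδ_NH/ΔT in ppb/K.

    ``series`` needs columns (residue, temperature_K, shift_ppm) for the HN
    atom. Each residue must appear at ≥2 distinct temperatures. Returns a
    frame with slope (ppb/K), intercept, rms residual (ppm) and an advisory
    classification band.
    """
    bands = bands if bands is not None else DEFAULT_COEFF_BANDS
    out = []
    for resnum, grp in series.groupby("residue"):
        temps = grp["temperature_K"].to_numpy(dtype=float)
        d = grp["shift_ppm"].to_numpy(dtype=float)
        if len(np.unique(temps)) < 2:
            raise ValueError(f"residue {resnum}: slope undefined with a single temperature")
        slope_ppm, intercept = np.polyfit(temps, d, 1)
        resid = d - (slope_ppm * temps + intercept)
        slope = slope_ppm * 1e3  # ppm/K -> ppb/K
        label = ""
        for name, (lo, hi) in bands.items():
            if lo <= slope <= hi:
                label = name
                break
        out.append({"residue": int(resnum), "coeff_ppb_per_K": slope,
                    "intercept_ppm": intercept,
                    "rms_residual_ppm": float(np.sqrt(np.mean(resid ** 2))),
                    "class": label})
    return pd.DataFrame(out).sort_values("residue").reset_index(drop=True)


@dataclass
class PREProfile:
    """Paramagnetic enhancement ε per residue and titration concentration."""

    residues: np.ndarray
    concentrations: np.ndarray          # mM, ascending
    epsilon: np.ndarray                 # (n_res, n_conc), NaN where unusable
    epsilon_max: np.ndarray
    usable: np.ndarray                  # bool per residue (I0 > 0)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.epsilon,
                          columns=[f"eps_{c:g}mM" for c in self.concentrations])
        df.insert(0, "residue", self.residues)
        df["eps_max"] = self.epsilon_max
        df["usable"] = self.usable
        return df


def pre_enhancement(reference: pd.DataFrame,
                    titration: dict[float, pd.DataFrame]) -> PREProfile:
    """Paramagnetic enhancement ε(residue, c) = 1 − I(residue, c)/I0, in [0, 1].

    ``reference`` and each titration table need columns (residue, intensity).
    Residues with I0 ≤ 0 are flagged unusable and excluded.
    """
    concs = np.array(sorted(titration))
    if len(concs) != len(set(concs.tolist())):
        raise ValueError("titration concentrations must be distinct")
    i0 = dict(zip(reference["residue"].astype(int), reference["intensity"].astype(float)))
    residues = np.array(sorted(i0))
    for c in concs:
        tres = set(titration[c]["residue"].astype(int))
        if tres != set(residues.tolist()):
            raise ValueError(f"titration at {c} mM does not match the reference residue set")
    eps = np.full((len(residues), len(concs)), np.nan)
    usable = np.array([i0[r] > 0 for r in residues])
    for j, c in enumerate(concs):
        it = dict(zip(titration[c]["residue"].astype(int),
                      titration[c]["intensity"].astype(float)))
        for i, r in enumerate(residues):
            if usable[i]:
                eps[i, j] = np.clip(1.0 - it[r] / i0[r], 0.0, 1.0)
    with np.errstate(all="ignore"):
        eps_max = np.where(usable, np.nanmax(np.where(np.isnan(eps), -np.inf, eps), axis=1), np.nan)
    return PREProfile(residues, concs, eps, eps_max, usable)
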