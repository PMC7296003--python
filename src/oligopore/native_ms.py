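"""Native MS / ion-mobility analytics for oligomer stoichiometry and CCS.

A native mass spectrum of a detergent-solubilised oligomer mixture shows
charge-state envelopes whose m/z values are explained by (n, z) hypotheses:
``m/z = (n·M + z·m_p)/z`` for an n-mer carrying z protons. The (k·n, k·z)
degeneracy (a tetramer at +3 and an octamer at +6 share one m/z) cannot be
broken by m/z alone; ion mobility breaks it because the drift-time-derived
collision cross section (CCS) of a 2n-mer is far larger than that of an
n-mer. Travelling-wave (TWIMS) drift times have no closed-form mobility
relation and are converted to CCS through a power-law calibration on
reference calibrants; drift-tube style mobilities convert through the
Mason–Schamp equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS_DA",
    "N2_MASS_DA",
    "MassSpectrum",
    "Peak",
    "StoichiometryCandidate",
    "StoichiometryAssignment",
    "GasParameters",
    "MobilityRecord",
    "CalibrationFit",
    "pick_peaks",
    "theoretical_mz",
    "assign_stoichiometries",
    "resolve_with_mobility",
    "relative_abundance",
    "mason_schamp_ccs",
    "reduced_mass",
    "fit_calibration",
    "apply_calibration",
]

PROTON_MASS_DA = 1.00728          # charge carrier: protons, positive mode
N2_MASS_DA = 28.0134              # drift gas

# SI constants
_KB = 1.380649e-23                # J/K
_E = 1.602176634e-19              # C
_N0 = 2.6867811e25                # Loschmidt number, m^-3
_DA = 1.66053906660e-27           # kg


@dataclass
class MassSpectrum:
    """A continuum spectrum: m/z (Th, strictly increasing) and intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str) -> "MassSpectrum":
        df = pd.read_csv(path)
        return cls(df["mz"].to_numpy(), df["intensity"].to_numpy())

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(path, index=False)


@dataclass
class Peak:
    mz: float
    intensity: float


def pick_peaks(spec: MassSpectrum, min_rel_intensity: float = 0.01,
               window: float = 0.0) -> list[Peak]:
    """Local-maximum peak picking with 3-point parabolic apex interpolation.

    A sample is a peak if it exceeds both neighbours, clears
    ``min_rel_intensity`` × (global max), and is the largest sample within
    ±``window`` Th. Returned sorted by m/z.
    """
    if spec.mz.size == 0:
        raise ValueError("empty spectrum")
    y = spec.intensity
    x = spec.mz
    if y.size < 3:
        raise ValueError("spectrum too short for peak picking")
    thr = min_rel_intensity * y.max()
    idx = np.where((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] >= thr))[0] + 1
    peaks: list[Peak] = []
    for i in idx:
        if window > 0:
            lo = np.searchsorted(x, x[i] - window)
            hi = np.searchsorted(x, x[i] + window, side="right")
            if y[i] < y[lo:hi].max():
                continue
        # 3-point parabola through (x[i-1..i+1], y[i-1..i+1])
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom != 0:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        apex_mz = x[i] + delta * (x[min(i + 1, x.size - 1)] - x[i - 1]) / 2.0
        apex_int = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        peaks.append(Peak(float(apex_mz), float(apex_int)))
    return sorted(peaks, key=lambda p: p.mz)


@dataclass
class StoichiometryCandidate:
    n: int
    z: int
    theoretical_mz: float
    error_ppm: float


@dataclass
class StoichiometryAssignment:
    peak: Peak
    candidates: list[StoichiometryCandidate]
    resolved: bool = False
    resolved_n: int | None = None
    resolved_z: int | None = None

    def resolve(self, n: int, z: int) -> None:
        self.resolved = True
        self.resolved_n = n
        self.resolved_z = z


def theoretical_mz(n: int, z: int, monomer_mass: float) -> float:
    return (n * monomer_mass + z * PROTON_MASS_DA) / z


def assign_stoichiometries(peaks: list[Peak], monomer_mass: float,
                           max_n: int = 8, max_z: int = 12,
                           tol_ppm: float = 50.0) -> list[StoichiometryAssignment]:
    """Enumerate all (n, z) hypotheses explaining each peak within tolerance.

    Degenerate (k·n, k·z) candidates are retained on purpose; breaking the
    degeneracy is deferred to :func:`resolve_with_mobility`. Single-candidate
    peaks are resolved immediately.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    if max_n < 1 or max_z < 1:
        raise ValueError("candidate caps must be >= 1")
    out = []
    for pk in peaks:
        cands = []
        for n in range(1, max_n + 1):
            for z in range(1, max_z + 1):
                tmz = theoretical_mz(n, z, monomer_mass)
                err = (pk.mz - tmz) / tmz * 1e6
                if abs(err) <= tol_ppm:
                    cands.append(StoichiometryCandidate(n, z, tmz, err))
        cands.sort(key=lambda c: (c.n, c.z))
        a = StoichiometryAssignment(pk, cands)
        if len(cands) == 1:
            a.resolve(cands[0].n, cands[0].z)
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# Mobility and CCS


@dataclass
class GasParameters:
    """Drift-gas state for the Mason–Schamp relation (N2 by default)."""

    T: float = 298.0              # K
    p: float = 1013.25            # mbar
    T0: float = 273.15            # K
    p0: float = 1013.25           # mbar
    gas_mass: float = N2_MASS_DA  # Da
    gas: str = "N2"

    def __post_init__(self):
        if min(self.T, self.p, self.T0, self.p0, self.gas_mass) <= 0:
            raise ValueError("gas parameters must be positive")

    @property
    def number_density(self) -> float:
        """N = N0 · (p/p0) · (T0/T) in m^-3."""
        return _N0 * (self.p / self.p0) * (self.T0 / self.T)


def reduced_mass(ion_mass: float, gas_mass: float = N2_MASS_DA) -> float:
    """μ = M·m_gas/(M + m_gas), in Da."""
    return ion_mass * gas_mass / (ion_mass + gas_mass)


@dataclass
class MobilityRecord:
    species: str
    z: int
    mass: float                     # Da
    drift_time_ms: float = np.nan
    corrected_drift_time_ms: float = np.nan
    K_cm2_per_Vs: float = np.nan    # mobility at (T, p)
    K0_cm2_per_Vs: float = np.nan   # reduced mobility, if reported directly
    gas_mass: float = N2_MASS_DA

    @property
    def reduced_mass(self) -> float:
        return reduced_mass(self.mass, self.gas_mass)

    def reduced_mobility(self, gas: GasParameters) -> float:
        """K0 = K · (p/p0) · (T0/T), or the instrument-reported K0 if set."""
        if np.isfinite(self.K0_cm2_per_Vs):
            return self.K0_cm2_per_Vs
        return self.K_cm2_per_Vs * (gas.p / gas.p0) * (gas.T0 / gas.T)


def mason_schamp_ccs(rec: MobilityRecord, gas: GasParameters) -> float:
    """CCS in Å² from the Mason–Schamp equation.

    CCS = (3/16)·sqrt(2π/(μ k_B T))·(z e)/(N0 K0), evaluated in SI. The
    three equivalent forms (in K with N, or in K0 with N0) agree by the
    identity N = N0·(p/p0)·(T0/T).
    """
    K0 = rec.reduced_mobility(gas)
    if not np.isfinite(K0) or K0 <= 0:
        raise ValueError("reduced mobility must be positive")
    mu = rec.reduced_mass * _DA
    K0_si = K0 * 1e-4             # cm² V⁻¹ s⁻¹ -> m² V⁻¹ s⁻¹
    ccs_m2 = (3.0 / 16.0) * np.sqrt(2.0 * np.pi / (mu * _KB * gas.T)) \
        * (rec.z * _E) / (_N0 * K0_si)
    return float(ccs_m2 * 1e20)


@dataclass
class CalibrationFit:
    """TWIMS power-law calibration ln(CCS·√μ/z) = lnA + B·ln(t_d′)."""

    lnA: float
    B: float
    r_squared: float
    residuals: np.ndarray
    gas: GasParameters
    dead_time_ms: float = 0.0
    edc_constant: float = 0.0
    calibrants: pd.DataFrame | None = None


def _corrected_drift_time(td_ms, mz, dead_time_ms, edc_constant):
    """Enhanced-duty-cycle correction: t_d′ = t_d − dead − c·√(m/z)/1000."""
    return np.asarray(td_ms, dtype=float) - dead_time_ms \
        - edc_constant * np.sqrt(np.asarray(mz, dtype=float)) / 1000.0


def fit_calibration(calibrants: pd.DataFrame, gas: GasParameters | None = None,
                    dead_time_ms: float = 0.0,
                    edc_constant: float = 0.0) -> CalibrationFit:
    """Fit the TWIMS power law on calibrant rows (name, mass_da, z, ccs_A2, td_ms).

    The reference CCS values are reduced by charge and reduced mass
    (CCS′ = CCS·√μ/z) and regressed log-log against corrected drift time.
    """
    gas = gas or GasParameters()
    req = {"mass_da", "z", "ccs_A2", "td_ms"}
    if not req.issubset(calibrants.columns):
        raise ValueError(f"calibrant table needs columns {sorted(req)}")
    if len(calibrants) < 2:
        raise ValueError("need >= 2 calibrants")
    mz = (calibrants["mass_da"] + calibrants["z"] * PROTON_MASS_DA) / calibrants["z"]
    tdp = _corrected_drift_time(calibrants["td_ms"], mz, dead_time_ms, edc_constant)
    if np.any(tdp <= 0):
        raise ValueError("corrected drift times must be positive")
    if np.ptp(tdp) < 1e-12:
        raise ValueError("coincident drift times: calibration fit is singular")
    mu = reduced_mass(calibrants["mass_da"].to_numpy(), gas.gas_mass)
    ccs_prime = calibrants["ccs_A2"].to_numpy() * np.sqrt(mu) / calibrants["z"].to_numpy()
    x = np.log(tdp)
    y = np.log(ccs_prime)
    B, lnA = np.polyfit(x, y, 1)
    pred = lnA + B * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(float(lnA), float(B), r2, y - pred, gas,
                          dead_time_ms, edc_constant, calibrants.copy())


def apply_calibration(fit: CalibrationFit, mass_da: float, z: int,
                      td_ms: float) -> float:
    """Calibrated CCS (Å²) of a species from its drift time."""
    mz = (mass_da + z * PROTON_MASS_DA) / z
    tdp = _corrected_drift_time(td_ms, mz, fit.dead_time_ms, fit.edc_constant)
    if tdp <= 0:
        raise ValueError("corrected drift time must be positive")
    ccs_prime = np.exp(fit.lnA + fit.B * np.log(tdp))
    mu = reduced_mass(mass_da, fit.gas.gas_mass)
    return float(ccs_prime * z / np.sqrt(mu))


def resolve_with_mobility(assignments: list[StoichiometryAssignment],
                          drift_times: dict[float, float],
                          fit: CalibrationFit,
                          monomer_mass: float) -> list[StoichiometryAssignment]:
    """Break (k·n, k·z) degeneracies using calibrated CCS.

    Unambiguous (single-candidate) peaks anchor a globular n^(2/3) CCS
    scaling law, CCS(n) ≈ c·n^(2/3); each degenerate peak then resolves to
    the candidate whose calibrated CCS best matches the anchored law. Peaks
    without drift data, or when no anchor exists, stay unresolved.
    """
    anchors = []
    for a in assignments:
        if a.resolved and a.peak.mz in drift_times:
            td = drift_times[a.peak.mz]
            ccs = apply_calibration(fit, a.resolved_n * monomer_mass, a.resolved_z, td)
            anchors.append((a.resolved_n, ccs))
    if anchors:
        ns = np.array([n for n, _ in anchors], dtype=float)
        cs = np.array([c for _, c in anchors])
        scale = float(np.sum(cs * ns ** (2 / 3)) / np.sum(ns ** (4 / 3)))  # LSQ through origin
    else:
        scale = None
    for a in assignments:
        if a.resolved or not a.candidates:
            continue
        td = drift_times.get(a.peak.mz)
        if td is None or scale is None:
            continue
        best, best_err = None, np.inf
        for c in a.candidates:
            ccs = apply_calibration(fit, c.n * monomer_mass, c.z, td)
            err = abs(ccs - scale * c.n ** (2 / 3))
            if err < best_err:
                best, best_err = c, err
        if best is not None:
            a.resolve(best.n, best.z)
    return assignments


def relative_abundance(assignments: list[StoichiometryAssignment]) -> dict[int, float]:
    """Summed apex intensity per oligomer order, normalised to 1."""
    totals: dict[int, float] = {}
    for a in assignments:
        if a.resolved and a.peak.intensity > 0:
            totals[a.resolved_n] = totals.get(a.resolved_n, 0.0) + a.peak.intensity
    if not totals:
        raise ValueError("no resolved peaks with positive intensity")
    s = sum(totals.values())
    return {n: v / s for n, v in sorted(totals.items())}
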