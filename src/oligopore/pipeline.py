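"""Workflow orchestration: validated configs, staged runs, manifests.

Three demonstration workflows tie the stages together, each runnable fully
from synthetic inputs (``synth-then-analyze``) or from user-supplied files:

* ``nmr`` — shift table → secondary shifts, element calls, temperature
  coefficients;
* ``ms`` — mass spectrum + calibrants → peaks, stoichiometry assignments,
  mobility-resolved degeneracies, relative abundances;
* ``ephys`` — current-trace batch → pore-type occurrence table and open-pore
  conductances.

Every run writes a ``manifest.json`` recording package version, seed, the
full effective configuration, input digests and per-stage status, so report
tables are reproducible byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ephys, native_ms, nmr, synth

__all__ = ["PipelineConfig", "ConfigError", "run_workflow", "load_config"]

_KNOWN_WORKFLOWS = ("nmr", "ms", "ephys")

_DEFAULTS: dict = {
    "nmr": {
        "shifts_csv": None,               # None -> synthesise
        "strand_threshold_ppm": 1.0,
        "helix_threshold_ppm": 1.0,
        "min_element_length": 4,
        "noise_ppm": 0.05,
    },
    "ms": {
        "spectrum_csv": None,
        "monomer_mass_da": 4514.0,
        "max_n": 8,
        "max_z": 16,
        "tol_ppm": 50.0,
        "tetramer_fraction": 0.7,
        "peak_sigma_th": 1.5,
        "ccs_tetramer_A2": 1600.0,
        "ccs_octamer_A2": 2500.0,
    },
    "ephys": {
        "traces_dir": None,
        "preset": "tetramer_enriched",
        "n_traces": 105,
        "conductance_nS": 0.5,
        "potential_mV": 100.0,
        "duration_s": 0.5,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    workflow: str
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.workflow not in _KNOWN_WORKFLOWS:
            raise ConfigError(f"unknown workflow {self.workflow!r}; "
                              f"choose from {_KNOWN_WORKFLOWS}")
        defaults = _DEFAULTS[self.workflow]
        unknown = set(self.params) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(defaults)
        merged.update(self.params)
        self.params = merged
        for key in ("shifts_csv", "spectrum_csv", "traces_dir"):
            path = self.params.get(key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key} path does not exist: {path}")


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    top_known = {"workflow", "output_dir", "seed", "log_level", "params"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_workflow(cfg: PipelineConfig) -> dict:
    """Run a workflow; returns the manifest (also written to output_dir)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "workflow": cfg.workflow, "seed": cfg.seed,
        "parameters": cfg.params, "inputs": {}, "outputs": [], "stages": {},
    }

    def stage(name, fn):
        try:
            fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:
            manifest["stages"][name] = f"failed: {exc}"
            _finish(manifest, out, failed=True)
            raise

    if cfg.workflow == "nmr":
        _run_nmr(cfg, out, manifest, stage)
    elif cfg.workflow == "ms":
        _run_ms(cfg, out, manifest, stage)
    else:
        _run_ephys(cfg, out, manifest, stage)
    _finish(manifest, out, failed=False)
    return manifest


def _finish(manifest: dict, out: Path, failed: bool) -> None:
    manifest["status"] = "failed" if failed else "ok"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _run_nmr(cfg, out, manifest, stage):
    p = cfg.params
    state: dict = {}

    def load():
        if p["shifts_csv"]:
            manifest["inputs"]["shifts_csv"] = _digest(Path(p["shifts_csv"]))
            state["shifts"] = nmr.load_shift_table(p["shifts_csv"])
        else:
            ss = ("C" * 8 + "E" * 13 + "C" * 7 + "E" * 12 + "C" * 2)
            slopes = {r: 5.0 for r in range(9, 22)}
            state["shifts"], _ = synth.make_shift_table(
                ss, noise_ppm=p["noise_ppm"], nh_slopes_ppb_per_K=slopes,
                seed=cfg.seed)
            _write_csv(state["shifts"], out / "shifts.csv")

    def analyse():
        hn = state["shifts"][state["shifts"]["atom"].str.upper() == "HN"]
        cacb = state["shifts"][state["shifts"]["atom"].str.upper() != "HN"]
        prof = nmr.secondary_shifts(cacb)
        _write_csv(prof.as_frame(), out / "secondary_shifts.csv")
        calls = nmr.call_elements(prof, p["strand_threshold_ppm"],
                                  p["helix_threshold_ppm"],
                                  p["min_element_length"])
        _write_csv(pd.DataFrame([vars(c) for c in calls]) if calls
                   else pd.DataFrame(columns=["kind", "start", "end"]),
                   out / "elements.csv")
        if len(hn):
            coeffs = nmr.temperature_coefficients(hn)
            _write_csv(coeffs, out / "temperature_coefficients.csv")

    stage("load", load)
    stage("analyse", analyse)
    manifest["outputs"] = sorted(f.name for f in out.glob("*.csv"))


def _run_ms(cfg, out, manifest, stage):
    p = cfg.params
    state: dict = {}
    M = p["monomer_mass_da"]

    def load():
        if p["spectrum_csv"]:
            manifest["inputs"]["spectrum_csv"] = _digest(Path(p["spectrum_csv"]))
            state["spec"] = native_ms.MassSpectrum.from_csv(p["spectrum_csv"])
            state["truth"] = None
        else:
            ft = p["tetramer_fraction"]
            # octamer charges odd so only the (k·n, k·z) degeneracy (e.g.
            # tetramer +6 vs dimer +3) is left for mobility to resolve
            envelopes = {4: {5: 0.25 * ft, 6: 0.5 * ft, 7: 0.25 * ft},
                         8: {11: 0.5 * (1 - ft), 13: 0.5 * (1 - ft)}}
            state["spec"], state["truth"] = synth.make_mass_spectrum(
                envelopes, M, peak_sigma=p["peak_sigma_th"], seed=cfg.seed)
            state["spec"].to_csv(out / "spectrum.csv")

    def assign():
        peaks = native_ms.pick_peaks(state["spec"], min_rel_intensity=0.02)
        assignments = native_ms.assign_stoichiometries(
            peaks, M, p["max_n"], p["max_z"], p["tol_ppm"])
        cal, _ = synth.make_calibrant_table(seed=cfg.seed)
        _write_csv(cal, out / "calibrants.csv")
        fit = native_ms.fit_calibration(cal)
        # drift times: from the generator truth (species CCS through the
        # calibration law) when the spectrum is synthetic
        drift = {}
        if state["truth"] is not None:
            ccs_by_n = {4: p["ccs_tetramer_A2"], 8: p["ccs_octamer_A2"]}
            for a in assignments:
                row = state["truth"].iloc[
                    (state["truth"]["mz"] - a.peak.mz).abs().argmin()]
                if abs(row["mz"] - a.peak.mz) > 1.0:
                    continue
                n0, z0 = int(row["n"]), int(row["z"])
                ccs = ccs_by_n.get(n0, p["ccs_tetramer_A2"] * (n0 / 4) ** (2 / 3))
                mu = native_ms.reduced_mass(n0 * M, fit.gas.gas_mass)
                drift[a.peak.mz] = float(
                    (ccs * np.sqrt(mu) / z0 * np.exp(-fit.lnA)) ** (1 / fit.B))
        assignments = native_ms.resolve_with_mobility(assignments, drift, fit, M)
        rows = [{"mz": a.peak.mz, "intensity": a.peak.intensity,
                 "n_candidates": len(a.candidates), "resolved": a.resolved,
                 "n": a.resolved_n, "z": a.resolved_z} for a in assignments]
        _write_csv(pd.DataFrame(rows), out / "assignments.csv")
        ab = native_ms.relative_abundance(assignments)
        _write_csv(pd.DataFrame([{"n": n, "fraction": f} for n, f in ab.items()]),
                   out / "abundances.csv")

    stage("load", load)
    stage("assign", assign)
    manifest["outputs"] = sorted(f.name for f in out.glob("*.csv"))


def _run_ephys(cfg, out, manifest, stage):
    p = cfg.params
    state: dict = {}

    def load():
        if p["traces_dir"]:
            paths = sorted(Path(p["traces_dir"]).glob("*.csv"))
            manifest["inputs"]["traces"] = {x.name: _digest(x) for x in paths}
            state["traces"] = [ephys.CurrentTrace.from_csv(str(x)) for x in paths]
        else:
            state["traces"] = synth.make_trace_batch(
                p["preset"], p["n_traces"], p["conductance_nS"],
                p["potential_mV"], p["duration_s"], seed=cfg.seed)

    def analyse():
        types = [ephys.classify_pore_type(t) for t in state["traces"]]
        occ = ephys.occurrence_table(types)
        _write_csv(occ, out / "occurrence.csv")
        rows = []
        for i, t in enumerate(state["traces"]):
            est = ephys.fit_open_pore(t)
            rows.append({"trace": i, "type": types[i],
                         "true_type": t.label,
                         "G_nS": est.conductance_nS, "error_nS": est.error_nS,
                         "defined": est.defined})
        _write_csv(pd.DataFrame(rows), out / "conductances.csv")

    stage("load", load)
    stage("analyse", analyse)
    manifest["outputs"] = sorted(f.name for f in out.glob("*.csv"))
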