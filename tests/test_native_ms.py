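"""Peak picking, stoichiometry assignment, Mason–Schamp CCS, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligopore import native_ms, synth
from oligopore.native_ms import (GasParameters, MassSpectrum, MobilityRecord,
                                 Peak, PROTON_MASS_DA, apply_calibration,
                                 assign_stoichiometries, fit_calibration,
                                 mason_schamp_ccs, pick_peaks, reduced_mass,
                                 relative_abundance, resolve_with_mobility,
                                 theoretical_mz)


def brute_force_candidates(mz, M, max_n, max_z, tol_ppm):
    """Independent exhaustive enumeration over the full (n, z) grid."""
    out = []
    for n in range(1, max_n + 1):
        for z in range(1, max_z + 1):
            t = (n * M + z * PROTON_MASS_DA) / z
            if abs((mz - t) / t) * 1e6 <= tol_ppm:
                out.append((n, z))
    return sorted(out)


class TestPickPeaks:
    def test_three_gaussians_apexes(self):
        spec, truth = synth.make_mass_spectrum(
            {1: {1: 1.0}, 2: {1: 0.8}, 3: {1: 0.6}}, monomer_mass=1000.0,
            mz_range=(500.0, 4000.0), peak_sigma=2.0, points=40000)
        peaks = pick_peaks(spec, 0.05)
        assert len(peaks) == 3
        for pk, mz_true in zip(peaks, sorted(truth["mz"])):
            assert pk.mz == pytest.approx(mz_true, abs=0.1)

    def test_flat_spectrum_no_peaks(self):
        spec = MassSpectrum(np.linspace(1000, 2000, 500), np.ones(500))
        assert pick_peaks(spec, 0.01) == []

    def test_below_threshold_excluded(self):
        spec, _ = synth.make_mass_spectrum(
            {1: {1: 1.0}, 2: {1: 0.005}}, monomer_mass=1000.0,
            mz_range=(500.0, 3000.0), peak_sigma=2.0)
        peaks = pick_peaks(spec, 0.05)
        assert len(peaks) == 1

    def test_empty_spectrum_errors(self):
        with pytest.raises(ValueError):
            pick_peaks(MassSpectrum(np.array([]), np.array([])))

    def test_sorted_by_mz(self):
        spec, _ = synth.make_mass_spectrum(
            {1: {1: 0.5}, 3: {2: 1.0}, 2: {1: 0.7}}, monomer_mass=1000.0,
            mz_range=(500.0, 4000.0))
        mzs = [p.mz for p in pick_peaks(spec, 0.05)]
        assert mzs == sorted(mzs)


class TestAssignStoichiometries:
    def test_algebraic_degeneracy(self):
        """Peak at the monomer +1 position matches every (k, k)."""
        peak = Peak((1000.0 + PROTON_MASS_DA), 1.0)
        out = assign_stoichiometries([peak], 1000.0, 8, 8, 5.0)
        assert [(c.n, c.z) for c in out[0].candidates] == \
            [(k, k) for k in range(1, 9)]
        assert not out[0].resolved

    def test_unique_candidate_brute_force(self):
        """(3, 5) of a 4000 Da monomer is unique within caps (8, 8)."""
        mz = (3 * 4000.0 + 5 * PROTON_MASS_DA) / 5
        out = assign_stoichiometries([Peak(mz, 1.0)], 4000.0, 8, 8, 5.0)
        got = [(c.n, c.z) for c in out[0].candidates]
        assert got == brute_force_candidates(mz, 4000.0, 8, 8, 5.0) == [(3, 5)]
        assert out[0].resolved and (out[0].resolved_n, out[0].resolved_z) == (3, 5)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_on_random_peaks(self, seed):
        g = np.random.default_rng(seed)
        M = g.uniform(500.0, 6000.0)
        mz = g.uniform(800.0, 9000.0)
        tol = g.uniform(5.0, 200.0)
        out = assign_stoichiometries([Peak(mz, 1.0)], M, 8, 12, tol)
        assert [(c.n, c.z) for c in out[0].candidates] == \
            brute_force_candidates(mz, M, 8, 12, tol)

    def test_modal_charge_state(self):
        """A tetramer envelope peaked at +6 resolves its modal charge to +6
        once mobility breaks the (2, 3) degeneracy of that peak."""
        M = 4514.0
        spec, truth = synth.make_mass_spectrum(
            {4: {5: 0.2, 6: 0.6, 7: 0.2}}, M, peak_sigma=1.5)
        peaks = pick_peaks(spec, 0.05)
        out = assign_stoichiometries(peaks, M, 8, 8, 50.0)
        tab, tr = synth.make_calibrant_table()
        fit = fit_calibration(tab)
        drift = {}
        for a in out:
            row = truth.iloc[(truth["mz"] - a.peak.mz).abs().argmin()]
            mu = reduced_mass(row["n"] * M)
            drift[a.peak.mz] = float((1600.0 * np.sqrt(mu) / row["z"]
                                      * np.exp(-tr["lnA"])) ** (1 / tr["B"]))
        out = resolve_with_mobility(out, drift, fit, M)
        resolved = [a for a in out if a.resolved and a.resolved_n == 4]
        top = max(resolved, key=lambda a: a.peak.intensity)
        assert top.resolved_z == 6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_stoichiometries([], -1.0)
        with pytest.raises(ValueError):
            assign_stoichiometries([], 100.0, max_n=0)


class TestMasonSchamp:
    gas = GasParameters(T=298.0)

    def rec(self, z=1, M=1000.0, K0=1.0):
        return MobilityRecord("x", z, M, K0_cm2_per_Vs=K0, gas_mass=28.0134)

    def test_linear_in_charge(self):
        c1 = mason_schamp_ccs(self.rec(z=1), self.gas)
        c2 = mason_schamp_ccs(self.rec(z=2), self.gas)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_inverse_in_mobility(self):
        c1 = mason_schamp_ccs(self.rec(K0=1.0), self.gas)
        c2 = mason_schamp_ccs(self.rec(K0=2.0), self.gas)
        assert c1 == pytest.approx(2 * c2, rel=1e-12)

    def test_against_extended_precision_closed_form(self):
        """z=1, M=1000 Da, N2, 298 K, K0=1 cm²/Vs vs a sympy evaluation."""
        import sympy as sp

        mu_da = sp.Rational(1000) * sp.Float("28.0134") / (1000 + sp.Float("28.0134"))
        mu = mu_da * sp.Float("1.66053906660e-27")
        kB = sp.Float("1.380649e-23")
        e = sp.Float("1.602176634e-19")
        N0 = sp.Float("2.6867811e25")
        T = sp.Integer(298)
        K0 = sp.Float("1e-4")  # 1 cm²/Vs in SI
        expected = (sp.Rational(3, 16) * sp.sqrt(2 * sp.pi / (mu * kB * T))
                    * e / (N0 * K0)) * sp.Float("1e20")
        got = mason_schamp_ccs(self.rec(), self.gas)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_three_forms_identity(self):
        """The K-with-N and K0-with-N0 forms agree exactly (dimensional
        consistency of the reduced-pressure scaling)."""
        gas = GasParameters(T=310.0, p=900.0)
        rec = MobilityRecord("x", 3, 18000.0, K_cm2_per_Vs=0.5, gas_mass=28.0134)
        # direct K/N evaluation in SI
        mu = rec.reduced_mass * 1.66053906660e-27
        K_si = rec.K_cm2_per_Vs * 1e-4
        N = gas.number_density
        direct = (3 / 16) * np.sqrt(2 * np.pi / (mu * 1.380649e-23 * gas.T)) \
            * rec.z * 1.602176634e-19 / (N * K_si) * 1e20
        assert mason_schamp_ccs(rec, gas) == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_mobility_errors(self):
        with pytest.raises(ValueError):
            mason_schamp_ccs(self.rec(K0=0.0), self.gas)


class TestCalibration:
    def test_two_point_exact_recovery(self):
        tab, truth = synth.make_calibrant_table(
            lnA=5.5, B=0.42,
            species=[("a", 12000.0, 6, 1500.0), ("b", 36000.0, 11, 3000.0)])
        fit = fit_calibration(tab)
        assert fit.lnA == pytest.approx(truth["lnA"], abs=1e-9)
        assert fit.B == pytest.approx(truth["B"], abs=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_identity_on_own_calibrants_noise_free(self):
        tab, _ = synth.make_calibrant_table()
        fit = fit_calibration(tab)
        for row in tab.itertuples():
            back = apply_calibration(fit, row.mass_da, row.z, row.td_ms)
            assert back == pytest.approx(row.ccs_A2, rel=1e-9)

    def test_noisy_exponent_recovery(self):
        """1% multiplicative drift-time noise ⇒ B within 5%."""
        tab, truth = synth.make_calibrant_table(noise_frac=0.01, seed=8)
        fit = fit_calibration(tab)
        assert fit.B == pytest.approx(truth["B"], rel=0.05)

    def test_round_trip_held_out_species(self):
        """A held-out species generated from the same law returns its CCS
        within 2% with 1% drift noise on the calibrants."""
        tab, truth = synth.make_calibrant_table(noise_frac=0.01, seed=3)
        fit = fit_calibration(tab)
        M, z, ccs_true = 4 * 4514.0, 6, 1600.0
        mu = reduced_mass(M)
        td = (ccs_true * np.sqrt(mu) / z * np.exp(-truth["lnA"])) \
            ** (1.0 / truth["B"])
        assert apply_calibration(fit, M, z, td) == pytest.approx(ccs_true, rel=0.02)

    def test_coincident_drift_times_singular(self):
        tab = pd.DataFrame({
            "name": ["a", "b"], "mass_da": [1e4, 2e4], "z": [5, 7],
            "ccs_A2": [1500.0, 2500.0], "td_ms": [4.0, 4.0]})
        with pytest.raises(ValueError, match="singular|coincident"):
            fit_calibration(tab)

    def test_too_few_calibrants(self):
        tab = pd.DataFrame({"name": ["a"], "mass_da": [1e4], "z": [5],
                            "ccs_A2": [1500.0], "td_ms": [4.0]})
        with pytest.raises(ValueError):
            fit_calibration(tab)


class TestMobilityResolution:
    M = 4514.0

    @staticmethod
    def td_for(truth, ccs, mass, z):
        mu = reduced_mass(mass)
        return float((ccs * np.sqrt(mu) / z * np.exp(-truth["lnA"]))
                     ** (1.0 / truth["B"]))

    def test_degenerate_pair_resolved_by_ccs(self):
        """Species with CCS 1600 vs 2540 Å² sharing the m/z-degenerate peak
        resolve to (4, 6) and (8, 12) respectively from their drift times."""
        tab, truth = synth.make_calibrant_table()
        fit = fit_calibration(tab)
        anchor = Peak(theoretical_mz(8, 11, self.M), 0.3)   # unique (odd z)
        shared = Peak(theoretical_mz(4, 6, self.M), 1.0)    # ≡ (2,3), (8,12)
        anchor_td = self.td_for(truth, 2540.0, 8 * self.M, 11)
        for true_ccs, true_mass, true_z, expected in [
                (1600.0, 4 * self.M, 6, (4, 6)),
                (2540.0, 8 * self.M, 12, (8, 12))]:
            assigns = assign_stoichiometries([anchor, shared], self.M, 8, 16, 20.0)
            drift = {anchor.mz: anchor_td,
                     shared.mz: self.td_for(truth, true_ccs, true_mass, true_z)}
            out = resolve_with_mobility(assigns, drift, fit, self.M)
            assert out[1].resolved
            assert (out[1].resolved_n, out[1].resolved_z) == expected

    def test_no_drift_data_stays_unresolved(self):
        tab, _ = synth.make_calibrant_table()
        fit = fit_calibration(tab)
        shared = Peak(theoretical_mz(4, 6, self.M), 1.0)
        assigns = assign_stoichiometries([shared], self.M, 8, 16, 20.0)
        out = resolve_with_mobility(assigns, {}, fit, self.M)
        assert not out[0].resolved

    def test_single_candidate_trivially_resolved(self):
        mz = theoretical_mz(3, 5, 4000.0)
        out = assign_stoichiometries([Peak(mz, 1.0)], 4000.0, 8, 8, 5.0)
        assert out[0].resolved


class TestRelativeAbundance:
    def test_seventy_thirty_mix(self):
        """A 70:30 tetramer:octamer intensity mix is recovered within 0.02."""
        from oligopore import pipeline
        spec, truth = synth.make_mass_spectrum(
            {4: {5: 0.175, 6: 0.35, 7: 0.175}, 8: {11: 0.15, 13: 0.15}},
            monomer_mass=4514.0, peak_sigma=1.5, baseline_noise=0.002, seed=2)
        peaks = pick_peaks(spec, 0.02)
        assigns = assign_stoichiometries(peaks, 4514.0, 8, 16, 50.0)
        tab, tr = synth.make_calibrant_table()
        fit = fit_calibration(tab)
        drift = {}
        for a in assigns:
            row = truth.iloc[(truth["mz"] - a.peak.mz).abs().argmin()]
            ccs = 1600.0 if row["n"] == 4 else 2540.0
            mu = reduced_mass(row["n"] * 4514.0)
            drift[a.peak.mz] = float((ccs * np.sqrt(mu) / row["z"]
                                      * np.exp(-tr["lnA"])) ** (1 / tr["B"]))
        out = resolve_with_mobility(assigns, drift, fit, 4514.0)
        ab = relative_abundance(out)
        assert ab[4] == pytest.approx(0.70, abs=0.02)
        assert ab[8] == pytest.approx(0.30, abs=0.02)
        assert sum(ab.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_species(self):
        a = assign_stoichiometries([Peak(theoretical_mz(3, 5, 4000.0), 2.0)],
                                   4000.0, 8, 8, 5.0)
        assert relative_abundance(a) == {3: 1.0}

    def test_zero_intensity_excluded(self):
        a1 = assign_stoichiometries([Peak(theoretical_mz(3, 5, 4000.0), 0.0)],
                                    4000.0, 8, 8, 5.0)
        a2 = assign_stoichiometries([Peak(theoretical_mz(2, 5, 4000.0), 1.0)],
                                    4000.0, 8, 8, 5.0)
        ab = relative_abundance(a1 + a2)
        assert ab == {2: 1.0}

    def test_all_unresolved_errors(self):
        a = assign_stoichiometries([Peak(1000.0 + PROTON_MASS_DA, 1.0)],
                                   1000.0, 8, 8, 5.0)
        with pytest.raises(ValueError):
            relative_abundance(a)
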