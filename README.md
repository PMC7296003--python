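# oligopore

Analysis toolkit for membrane-associated amyloid-β oligomers — the
computational chain used to characterise β-sheet pore-forming Aβ(1-42)
tetramers and octamers assembled in detergent micelles and inserted into
lipid bilayers.

Aβ(1-42), the 42-residue amyloid-β variant most strongly linked to
Alzheimer's disease, forms a membrane-associated tetramer with a six-stranded
antiparallel β-sheet core (two hairpin "red" subunits contributing strands
β1 ≈ G9–A21 and β2 ≈ G29–V40, and two "green" subunits contributing
β3 ≈ G29–I41), and at higher peptide-to-micelle ratios an octamer built from
two tetramers stacked face-to-face as a β-sandwich. This package implements
the analytics that establish and exploit those structures:

* **`structio`** — PDB/mmCIF structures and NMR-style ensembles, atom
  selections, Kabsch superposition, heteroatom stripping.
* **`nmr`** — three-residue-averaged (ΔCα − ΔCβ) secondary chemical shifts
  and β/α element calling; amide temperature coefficients Δδ_NH/ΔT (ppb/K);
  paramagnetic-enhancement profiles ε = 1 − I/I₀.
* **`native_ms`** — native MS peak picking, oligomer-stoichiometry
  assignment m/z = (n·M + z·m_p)/z with explicit (k·n, k·z) degeneracy
  handling, travelling-wave ion-mobility (TWIMS) power-law calibration, and
  the Mason–Schamp relation
  CCS = (3/16)·√(2π/μk_BT)·ze/(N₀K₀).
* **`ccs`** — theoretical collision cross sections by the Projection
  Approximation: orientation-averaged Monte-Carlo area of the projected
  atom-disk union, with a 1% convergence criterion and three independent
  replicates; model-vs-experiment ranking.
* **`oligomers`** — rigid-body candidate octamers from a tetramer building
  block: face-to-face β-sandwich (clash-checked) and loose β-barrel
  (probe-tested central cavity).
* **`traj`** — trajectory/ensemble metrics: best-fit RMSD series, ensemble
  RMSD to the mean conformer, RMSF, mass-weighted radius of gyration,
  Kabsch–Sander secondary-structure content, lipid-probe contacts within
  9 Å of backbone amide nitrogens, water-permeation histograms along the
  membrane normal, Shrake–Rupley SASA.
* **`ephys`** — planar-bilayer current traces: all-point histograms,
  Gaussian open-pore conductance fits (peak centre → G, half-FWHM → error),
  pore-type classification (1 flicker / 2 stepwise / 3 stable) and
  occurrence tables.
* **`synth`** — generators for every input class with machine-readable
  ground truth, including the micelle arithmetic
  [M] = ([D] − CMC)/N_agg used to set peptide-per-micelle ratios.
* **`pipeline` / CLI** — validated configs, manifests, and an `oligopore`
  command with `synth`, `nmr`, `ms`, `ccs`, `build-octamer`, `traj`,
  `ephys` and `run` subcommands.

## Worked example

```python
from oligopore import native_ms, synth
from oligopore.synth import SampleComposition, micelle_ratio

# peptide-per-micelle arithmetic for the NMR preparation
ratio, label = micelle_ratio(SampleComposition(peptide_uM=1000.0,
                                               detergent_mM=28.5))
print(label, ratio)                     # 2:1 2.0

# a synthetic 70:30 tetramer:octamer spectrum through the full MS chain
spec, truth = synth.make_mass_spectrum(
    {4: {5: 0.175, 6: 0.35, 7: 0.175}, 8: {11: 0.15, 13: 0.15}},
    monomer_mass=4514.0, seed=2)
peaks = native_ms.pick_peaks(spec, 0.02)
assigns = native_ms.assign_stoichiometries(peaks, 4514.0, max_n=8,
                                           max_z=16, tol_ppm=50.0)
print([(a.peak.mz.__round__(1), len(a.candidates)) for a in assigns])
# [(2580.4, 2), (2778.9, 1), (3010.3, 4), (3283.9, 1), (3612.2, 2)]
```

The 3010.3 Th peak carries four (n, z) hypotheses — a tetramer at +6 is
m/z-degenerate with a dimer at +3 and an octamer at +12 — which is why ion
mobility is required: `resolve_with_mobility` converts each drift time to a
calibrated CCS and picks the candidate consistent with the n^(2/3) size
scaling anchored on the unambiguous peaks, after which
`relative_abundance` returns `{4: 0.70, 8: 0.30}` for this spectrum.

Equivalent CLI runs:

```bash
oligopore ms --seed 2 -o ms_out          # spectrum → abundances.csv
oligopore synth tetramer -o tet_out      # idealized β-sheet tetramer + truth
oligopore ccs --pdb tet_out/tetramer.pdb --convergence 0.01 --replicates 3 --seed 1
oligopore build-octamer --pdb tet_out/tetramer.pdb --mode sandwich
```

## Scope

The package analyses structures, spectra, trajectories and traces; it never
integrates equations of motion. Gas-phase compaction before CCS is delegated
to an external MD engine through a documented shim
(`oligopore.ccs.vacuum_compact`), and membrane/micelle simulation setup is
out of scope.
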