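# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Coordinate and numbering conventions

Coordinates are in Å in a right-handed frame with the membrane normal along
z; residue numbering is 1-based with inclusive ranges. The tetramer topology
annotation places strand β1 at residues 9–21 and β2 at 29–40 on the hairpin
("red") subunits and β3 at 29–41 on the single-strand ("green") subunits,
with the short helical turn α1 at 17–20 on the green subunits. The first
strand is sometimes described as starting at G10 rather than G9; 9–21 is the
default and the ranges are a plain config (`TopologySpec`). Which deposited
chain letters correspond to red vs green subunits is likewise configurable
(defaults A/C red, B/D green), since chain lettering is a deposition detail.

## Superposition and ensemble RMSD

Optimal least-squares superposition uses the Kabsch algorithm via SVD with a
determinant correction to exclude reflections. Ensemble RMSD iteratively
superposes all conformers on the evolving mean coordinate set until the mean
moves by less than 1e-6 Å RMS, then reports the mean over models of the
RMSD to the mean. For isotropic per-atom jitter of width σ over n models the
expectation is σ·√3·√(1 − 1/n), which the generators emit as ground truth.

## Secondary chemical shifts and element calling

The combined secondary shift is (δCα,obs − δCα,rc) − (δCβ,obs − δCβ,rc)
against a consensus random-coil reference table shipped with the package
(overridable by CSV; the reference set is a documented choice, not a
measurement). Glycine has no Cβ and contributes ΔCα alone. The three-residue
average is an unweighted mean over the existing members of {i−1, i, i+1};
chain termini use the shorter window. Element calling takes maximal runs of
the smoothed track at ≤ −thr (strand) or ≥ +thr (helix), dropping runs
shorter than `min_len` (default 3). Because the boundary residue adjacent to
a painted strand inherits one third of the strand signal (−4/3 for the
default −4 ppm strand offset), exact recovery of painted ranges needs a
threshold in (4/3 · offset/4, offset/2); the worked examples use 1.5 ppm.

Amide temperature coefficients are least-squares slopes of δ_NH (ppm)
against T (K), reported in ppb/K. The classification bands (exposed −6 to
−8.5 ppb/K; protected > −4 ppb/K) are advisory labels from the
hydrogen-bonding literature; positive coefficients, as seen for
micelle-shielded amides, are reported as-is.

The paramagnetic enhancement is ε = 1 − I/I₀ clipped to [0, 1], with
residues of non-positive reference intensity flagged unusable. Whether
intensities are volume- or height-based is up to the caller; the formula is
the simplest definition consistent with "enhancement upon addition of the
probe" and is stated here because it is an interpretation, not a given.

## Native MS and ion mobility

Stoichiometry hypotheses are enumerated exhaustively over the (n, z) grid:
a peak at m/z matches (n, z) when |obs − (n·M + z·1.00728)/z| is within the
ppm tolerance (default 50 ppm — native spectra of detergent-stripped
complexes are broad). Charge carriers are protons (positive mode). The
(k·n, k·z) degeneracy is retained on purpose and resolved in a separate,
auditable mobility step: unambiguous single-candidate peaks anchor a
globular CCS(n) = c·n^(2/3) scaling law (least squares through the origin),
and each degenerate peak takes the candidate whose calibrated CCS best
matches the law. With no anchor or no drift data, peaks stay unresolved
rather than being silently collapsed.

TWIMS calibration fits ln(CCS·√μ/z) = lnA + B·ln(t_d′) on calibrant rows,
with the corrected drift time t_d′ = t_d − dead_time − c·√(m/z)/1000
(enhanced-duty-cycle correction; coefficients default to zero and live in
config). The Mason–Schamp relation is evaluated in SI units with
k_B = 1.380649e−23 J/K, e = 1.602176634e−19 C and the Loschmitt number
N₀ = 2.6867811e25 m⁻³, reduced mass μ = M·m_gas/(M + m_gas) against N₂
(28.0134 Da), and the identity N = N₀·(p/p₀)(T₀/T) ties the K-with-N and
K₀-with-N₀ forms together. Mobility records may carry either a measured K
(converted through the gas state) or an instrument-reported K₀ directly.

## Projection-approximation CCS

The PA treats the CCS as the orientation-averaged area of the union of
projected atomic disks. Orientations are sampled uniformly over SO(3) by
normalised random quaternions (not axis-only sampling); per orientation the
union area is estimated by Monte-Carlo rejection over the projected bounding
box padded by the largest radius. Batches of orientations (default 64, with
4000 MC points each) accumulate until the running mean changes by less than
the convergence threshold (default 1%) between batches; the whole
calculation repeats for 3 independent replicates whose mean and sample SD
are reported. Fixed seeds give bit-identical replicate values.

The default projection radii (H 2.2, C/N/O 2.7, S/P 3.1 Å) are the
hard-sphere set commonly used by PA implementations and can be overridden
from file; absolute PA values are radii-dependent, which is why model
comparisons should quote the radii table used. Solvent and heteroatoms are
stripped before the calculation. No N₂ size scaling is applied to reported
values (a flag exists for callers that want one).

Ions compact in the gas phase before mobility measurement, so matching
theoretical to experimental CCS requires a short vacuum MD relaxation of
the solution structure. The package never integrates equations of motion:
`vacuum_compact` is a documented shim that locates an external engine and
otherwise raises, and analyses accept any compacted structure loaded from
file. PA itself is charge-blind; charge placement matters only through that
external compaction step.

## Candidate octamer builders

Both builders are deterministic rigid-body compositions — the internal
coordinates of each tetramer copy are untouched, verifiable by zero RMSD of
either copy onto the input. The β-sheet frame comes from a PCA of the core
Cα atoms, with the normal oriented toward the side carrying the flexible
termini so the builders can stack on the clean (hydrophobic) face.

* β-sandwich: the second copy is flipped 180° about the in-plane strand
  axis and offset along the sheet normal; the separation starts at the
  10 Å typical of β-sandwich inter-sheet spacing and grows in 0.5 Å steps
  until no inter-copy heavy-atom pair is closer than the 2.5 Å clash
  cutoff — the smallest clash-free separation maximises buried face
  contact. The exact inter-tetramer registry is not experimentally
  determined; CCS comparison is the published discriminator between
  topologies, so the builder aims for a representative geometry, not a
  refined one.
* loose β-barrel: the two copies are tilted ±25° about the strand axis and
  placed at ±11 Å from a central axis so the twelve strands enclose a
  channel; the build is accepted only if a 2.8 Å probe sphere along the
  axis over the core-spanned region (middle 60% of the core Cα extent —
  termini fan outside it) overlaps no heavy atom.

## Trajectory metrics

Per-frame RMSD is the best-fit value over the selection after superposition
on that selection (whether published plateau values used all-Cα or
core-only superposition is not stated; the selection is explicit here).
RMSF superposes all frames on the first, then averages per-atom fluctuation
about the time-mean per residue. The radius of gyration is mass-weighted.

Secondary structure uses the Kabsch–Sander hydrogen-bond energy
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a −0.5
kcal/mol cutoff; β counts residues in parallel/antiparallel bridges and
helix the doubled (i, i+4) turn pattern. Amide hydrogens absent from the
input (deuterated or heavy-atom-only structures) are rebuilt at 1.01 Å
along the bisector of the C(prev)→N and Cα→N directions. On idealized
fixtures this agrees with the reference DSSP implementation to within one
residue per strand end, which is the tolerance the tests assert.

Contact profiles count probe sites (lipid headgroup nitrogens, terminal
tail carbons) within 9 Å of each residue's backbone amide nitrogen per
frame, summed over symmetric chains and averaged over frames. The
across-replicate spread is reported as SD divided by the number of
independent samples — implemented literally, with SD/√n one switch away —
because that is the stated convention of the workflow this package
reproduces. Water permeation histograms bin water-oxygen z coordinates
(default 1 Å bins) and average over frames; per-frame bin sums equal the
water count exactly. Minimum-image distances are used when orthorhombic box
vectors are present.

SASA is Shrake–Rupley with a deterministic golden-spiral point set (default
960 points/atom), probe radius 1.4 Å, and a van-der-Waals radii table
(H 1.2, C 1.7, N 1.55, O 1.52, S/P 1.8 Å) distinct from the PA projection
radii.

## Current-trace analytics

The all-point histogram bins every sample at fixed width (default 1 pA).
The baseline is the peak nearest 0 pA; the dominant remaining peak is
fitted with a Gaussian whose centre over the applied potential gives the
open-pore conductance in nS and whose half-FWHM over the potential gives
the error ("width at half height" is read as an error bar, i.e. half the
FWHM; the full FWHM is one flag away). Near-noiseless levels occupying
fewer than four histogram bins are reported as the sample mean with zero
width rather than fitted. A fit is flagged undefined — the observed
behaviour of flickery pores — when no non-baseline peak resolves, when
fewer than 20% of samples dwell within the fitted FWHM, or when the fitted
width exceeds 25% of the level.

Pore types are classified heuristically (their formal definitions live in
supplementary material not restated in the text): type 3 when one
non-baseline level holds ≥70% of the dwell with σ/|level| ≤ 5%, type 1 when
no level reaches 30% occupancy, type 2 otherwise. On generator output the
defaults recover ≥90% of labels at 0.5 s records and ≈99% at 2 s records,
which is why occurrence statistics are computed from 2 s records.

## Synthetic data: what it emulates, and what it does not

Generators emit machine-readable truth beside every dataset and are
byte-reproducible under fixed seeds. Noise is Gaussian unless stated — the
simplest assumption, stated openly.

* The idealized tetramer is built from fully-extended planar strands paired
  antiparallel at 4.6–5.4 Å spacing with registries chosen (by a
  deterministic grid search) to maximise inter-strand Kabsch–Sander
  hydrogen bonds, backbone atoms only (N, Cα, C, O). Termini and loops are
  extended coil segments bent every 6–8 residues so that long tails curl
  instead of running straight, all fanned to one side of the sheet. It
  reproduces the topology, strand registry and H-bond pattern of the real
  oligomer but not side chains, twist, or realistic coil ensembles — so
  absolute SASA/CCS/Rg of the fixture are not comparable to experimental
  values, while fractions, recoveries and rigid-body properties are.
* The membrane pseudo-trajectory places probe sites on leaflet planes and
  waters uniformly outside the slab (plus optional pore waters in an axial
  cylinder). It has no lipid dynamics; it exists to give contact counting
  and permeation histograms exact expected values.
* Mass spectra are sums of Gaussian peaks at exact charge-state positions
  with optional baseline noise — no isotope structure, detergent adducts or
  peak tailing. Calibrant tables are drawn from the assumed power law, so
  calibration tests are parameter-recovery tests, not instrument models.
* Current traces: type 3 is a stable open level, type 2 alternates
  exponentially-dwelling open/closed levels, type 1 resamples a uniform
  sub-level every millisecond. Occurrence presets (17/48/35% at N = 105;
  8.5/35/56% at N = 71) reproduce the documented mixes for
  tetramer-enriched and octamer-enriched preparations.

Passing tests on these fixtures demonstrates correctness of the analytics
under known truth; they do not validate force fields, instrument physics or
real spectral complexity.

## Problem sizes

The default test and acceptance runs are desk-scale: PA uses 4000–20000 MC
points and 64-orientation batches (the 1% convergence rule typically stops
after one or two batches for globular inputs); recovery experiments use
15-conformer ensembles, 105–500 traces of 0.5–2 s at 10 kHz, and 42-residue
shift tables — sizes at which every check completes in seconds while the
statistical tolerances quoted in the tests still hold.

## Known limitations

* Analyses needing the deposited coordinates or an MD engine (ensemble
  precision of the real structure, compacted-structure CCS, compaction
  analytics, charge-placement robustness) run only when those inputs are
  supplied; the shim and tests say exactly what is missing.
* The Kabsch–Sander implementation covers strands and α-helix; 3₁₀/π
  helices, turns and bends are not assigned.
* The barrel builder produces a geometric "loose barrel" for CCS
  discrimination, not an energetically sensible pore model.
* mmCIF is read; only PDB is written.
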