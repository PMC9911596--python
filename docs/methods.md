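# Methods

`vtcfret` re-implements, as a tested pipeline, the computational chain used
to argue that InsP₆ binding docks the Vtc4 polymerase (TTM) domain onto the
VTC trans-membrane channel: diffusion smFRET burst analysis under pulsed
interleaved excitation (PIE), structure-based Förster-efficiency prediction
via accessible-volume (AV) dye modelling, HOLE-style pore profiling of the
translocation channel, and in-cell ³¹P-NMR polyP quantification.  A
synthetic photon-stream generator with known ground truth replaces the
instrument.

## The corrected-efficiency model

Per-burst FRET efficiency is computed from the three PIE photon counts —
F_DD (donor excitation / donor emission), F_DA (donor excitation / acceptor
emission), F_AA (acceptor excitation / acceptor emission) — as

    F_corr = F_DA − LK·F_DD − Di·F_AA
    E      = F_corr / (F_corr + γ·F_DD)

with the calibrated constants LK = 0.13 (donor spectral leakage), Di = 0.06
(acceptor direct excitation) and γ = 0.47 (detection-efficiency/quantum-
yield factor) as defaults.  A widely circulated rendering of this formula
subtracts LK and Di directly in the denominator, `γ·F_DD − F_DA − LK − Di`,
which is dimensionally inconsistent (dimensionless fractions subtracted
from photon counts) and non-monotone in the counts; we therefore implement
LK and Di as multiplicative fractions of F_DD and F_AA respectively, and
the denominator as `γ·F_DD + F_corr` — the standard ALEX/PIE calibration
convention.  This is the unique reading under which the generative model
below inverts exactly.  With neutral parameters (LK = Di = 0, γ = 1) E
reduces to the proximity ratio F_DA/(F_DA+F_DD).  E is never clamped;
shot-noise excursions outside [0, 1] are kept and the histogram spans
[−0.1, 1.1].

## The generative photon model

The simulator is defined as the algebraic inverse of the correction.  Each
molecular transit draws a donor-excitation photon budget B from a
log-normal law (mean `mean_burst_size` = 80 photons, log-sd
`burst_size_shape` = 0.45 — burst-size distributions of freely diffusing
molecules are heavy-tailed; the defaults are plausible for a confocal
setup, no instrument statistics being available) and an acceptor-excitation
count F_AA ~ Poisson(`aa_ratio`·B).  B is then partitioned binomially
between the DD and DA channels with expectations

    F_DD = c(1−E),  F_DA = c(γE + LK(1−E)) + Di·F_AA,
    c = (B − Di·F_AA) / ((1−E)(1+LK) + γE)

so that (i) F_DD + F_DA = B photon-for-photon in every transit and
(ii) applying the correction to the expectations returns the true E
exactly (`expected_counts` is the analytic oracle; the round-trip identity
is property-tested to 1e-9).  Transits arrive as a Poisson process
(default 20–25 s⁻¹, ~100 pM-regime occupancy) and photons are spread
uniformly over an exponential dwell (mean 1.5 ms).  Diffusion, TCSPC
lifetimes and triplet blinking are deliberately not modelled: rectangular
bursts are sufficient to exercise the 1-ms binning and threshold logic,
and the photoprotection chemistry in the original protocol has no
computational counterpart.  PIE alternation is represented by the
excitation-slot label on each photon (the 31.25 ns / 32 MHz repetition
period is carried as metadata only); timestamps serve only the binning.
All randomness flows from one integer seed through a single generator, so
streams are byte-identical across runs.

Because the generator embeds the same (LK, Di, γ) that the analysis
removes, passing pipeline tests demonstrate internal consistency of the
correction algebra and the burst logic — not the correctness of the
published calibration constants for any real instrument.

## Burst analysis

Photon streams are binned at 1 ms; (donor emission, acceptor excitation)
events carry no information and are discarded.  A burst is a maximal run of
consecutive bins whose total (DD+DA+AA) count reaches the threshold
(default 8, the midpoint of the 6–12 range in routine use; exposed as a
flag), and runs with fewer than 35 summed photons are discarded.  The
threshold applies to the per-bin total rather than any single stream,
keeping detection symmetric between donor- and acceptor-rich species; burst
boundaries are bin-resolved, matching the bin-then-threshold procedure
(not a photon-resolved sliding window).  PIE filtering removes donor-only
(F_AA < 5) and acceptor-only (F_DD < 5) molecules; the thresholds are
package defaults (no published values exist) and are configurable.  The
ALEX stoichiometry S = (γF_DD + F_corr)/(γF_DD + F_corr + F_AA) is reported
per burst as a companion diagnostic.

Corrected-E histograms use 0.025-wide bins on [−0.1, 1.1].  Population
summaries fit a 1- or 2-component Gaussian mixture by an in-module EM
(seeded quantile/k-means initialization, components reported ordered by
mean, ties broken by that ordering; sd floored at 1e-4 to avoid collapse)
and report the kernel-density mode of the raw sample alongside.  The EM is
cross-checked in the tests against a brute-force grid search over the two
means.

## Förster conversions

E = 1/(1+(R/R0)⁶) with R0 = 52 Å for Alexa488/Cy5.  R0 is always an input
(a literature value); κ² orientation effects are not modelled.  Ensemble
efficiencies over a distance distribution support two regimes: evaluating
E at the mean distance (default — the single-number prediction used when a
structure-derived average distance is quoted) and averaging per-sample
efficiencies; they differ for broad distributions and both are exposed.
At the modelled mean inter-dye distance of 42.6 Å this gives E = 0.768,
i.e. 0.77 to two decimals.

## Structural geometry

Structures are read with gemmi (PDB/mmCIF), alternate locations resolved to
highest occupancy, author residue numbering preserved.  Van der Waals radii
come from one Bondi-style table; unknown elements fall back to 1.7 Å with a
warning.  Entity stoichiometry groups protein chains by identical residue
sequence (a 3:1:1 heteropentamer yields chain-group sizes 3, 1, 1).

Superposition is the classical Kabsch SVD solution with reflections
excluded; domain RMSDs pair Cα atoms by author residue-number intersection
(the convention assumed for published domain RMSD values; the atom
selection behind such numbers is rarely stated).

Pore profiles are HOLE-style: along a user-supplied channel axis (two
points: cytoplasmic entrance and luminal exit; no axis convention is
standard), at each 0.5-Å station the in-plane point maximizing clearance to
the nearest atom surface is found by 64 seeded random starts plus a warm
start from the neighbouring station, refined with Nelder–Mead (tolerance
0.01 Å, non-convergence warned per station, never silent); the search is
confined to 12 Å of the axis so the optimizer cannot escape through the
protein wall.  On an analytic cylinder of C-atom rings (radius 8 Å) the
profile reproduces the closed form 8 − 1.7 = 6.3 Å to 1e-3.  Channel
length is the maximal contiguous run of stations with radius below an
enclosure radius (default 10 Å, an invented criterion — only "about 60 Å"
is published) containing the global constriction.  Beyond an open mouth of
bore radius R the inscribed radius grows as √(R²+dz²) − r_vdW, so the
measured length depends noticeably on the enclosure level; the flag is
exposed and results should be quoted with it.

Trans-membrane helices are detected from the Cα(i)→Cα(i+4) distance
signature (window 5.0–6.8 Å around the ideal 6.2 Å, runs of ≥6 residues)
and counted when their Cα extent spans both faces of the membrane slab.

Accessible-volume dye clouds are rejection-sampled: candidate dye-sphere
centres uniform in the reach sphere (linker length) around the attachment
atom, accepted when the linker can reach them — geodesic distance over a
1-Å obstacle grid with linker-width/2 clearance, or an unobstructed
straight path — and when the dye sphere (radius 3.5 Å) clashes with no
atom.  Dye defaults are literature-typical AV parameters for Alexa488
(linker 20 Å) and Cy5 (linker 22 Å), width 4.5 Å; they stand in for
energy-selected torsion-sampled conjugates, and the dye-sphere centre
stands in for the geometric centre of the chromophore.  Inter-dye
distances report the mean and sd over all pairwise cloud distances
(sub-sampled with a seeded generator above 2×10⁶ pairs) plus the
centroid–centroid distance, since a published "average distance between
geometric centers" admits both readings.

## ³¹P-NMR quantification

Spectra are (ppm, intensity) tables, descending axis.  The external MDP
reference (δ = 20.58 ppm, 3.3 mM, two equivalent ³¹P nuclei) converts
window integrals to phosphate-unit concentrations:
c_w = (I_w / I_ref) × 3.3 mM × 2.  Integration is trapezoidal after
subtracting a linear baseline through the median intensities of 0.5-ppm
flanking margins; the detection limit is 3× the estimated integral sd,
which includes both accumulated point noise and the coherent error of the
baseline anchors (the latter dominates for wide windows).  Windows below
the limit are reported non-detected — the readout that distinguishes
polyP-producing strains from vtc-deletion strains.  Default polyP windows
(terminal −6…−8 ppm, central −21…−23 ppm) are configurable placeholders:
peak assignments in the source experiments were made against published
shifts whose values are not printed, so the defaults must not be treated
as ground truth.  Quantification is invariant to global intensity scaling
and to ppm recalibration by construction.

## Problem sizes and determinism

The self-consistency checks simulate 150 s of acquisition at 25 transits/s
(≈3500 detected FRET bursts), comfortably above the 2000-burst floor at
which the histogram mode is stable to one 0.025 bin; unit tests use 10–60 s
streams.  Every stochastic component (simulator, pore-search starts, AV
sampling, EM initialization, mixture draws) consumes a single explicit
integer seed, and reruns reproduce reports byte-for-byte.

## Known limitations

* The deposited-structure checks (pentamer stoichiometry, 1.5 Å
  constriction lined by R31/R709/R629, ~60 Å channel, 15 TM helices,
  0.62 Å TTM superposition, 42.6 Å inter-dye distance) require the 7YTJ
  and 3G3Q coordinate files, which are too large to bundle; place them
  under `data/structures/` to run that test.  All underlying operations
  are validated on closed-form synthetic structures instead.
* The simulator's burst brightness and duration statistics are plausible
  defaults, not fits to instrument data; conclusions from passing tests
  concern the analysis chain, not detector physics.
* Pore radii and channel length depend mildly on the axis choice and the
  enclosure criterion; both are explicit inputs.
* The grid-based linker geodesic slightly over-estimates path lengths
  (26-connectivity metric); the straight-path acceptance removes the bias
  in open space but curved paths near obstacles remain conservative.
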