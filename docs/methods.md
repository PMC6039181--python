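# Methods

This note documents the models implemented in `ensemblemap`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Density model and coordinate conventions

All computations act in real space on rectangular, axis-aligned grids in
orthogonal Cartesian angstroms. Maps carry an origin and per-axis voxel
spacing; there is no crystallographic symmetry handling, because every
operation in the pipeline (background statistics, Z-scoring, event-map
algebra, footprint fitting, density scoring at atom centers) is local and
voxelwise. Sigma scaling — the affine normalization of a map to zero mean
and unit standard deviation — makes contour levels quoted "in σ"
comparable across datasets; it is monotone, idempotent, and rejected for
constant maps. Point evaluation uses trilinear interpolation, which is
exact for affine fields (a property the tests exploit as an oracle).

The synthetic forward model renders each atom as an isotropic Gaussian,

    ρ(r) = Σ_atoms occ · exp(−|r − r_atom|² / (2 σ_atom²)),
    σ_atom² = B / (8π²),

with B the atom's isotropic displacement parameter in Å². This is a
deliberate simplification of 2Fo−Fc synthesis that keeps the two properties
the pipeline actually relies on — strict linearity in occupancy
(superposition) and locality — while staying cheap enough that the whole
analysis stack runs on synthetic cohorts in seconds. Default grid spacing
is 0.5 Å, several times finer than the 1.7–2.6 Å resolutions being
emulated, so discretization error never drives any statistic. Map noise is
i.i.d. Gaussian per voxel in sigma-scaled units — the simplest model under
which Z-map statistics are exactly standard normal, which the test suite
checks with a Kolmogorov–Smirnov test on a held-out pure-noise dataset.

## Cohort background model and event detection

A cohort's background is summarized per voxel by the uniform-weight mean
μ and the population (1/n) standard deviation σ across the included
datasets. Uniform weights are a deliberate choice: combined with the
two-pass exclusion of event datasets, they reproduce the intended behavior
(the mean of apo and unbound datasets) without introducing weighting
parameters that nothing downstream constrains. The 1/n convention is
likewise fixed by design; an sd floor (default 0.05 in sigma-scaled units)
prevents division blow-ups at voxels where the cohort happens to be nearly
constant.

Events are 6-connected clusters of Z ≥ 2.5 spanning at least 27 voxels
(about one 1.5 Å-radius blob at 0.5 Å spacing), reported with
density-weighted centroid and peak Z, ordered by peak Z, then cluster size,
then centroid (lexicographic) so results are fully deterministic. Cohorts
can optionally be partitioned into resolution bins before
characterization.

## Choice of the background-subtraction fraction (BDC)

For the event map E = (ρ − BDC·μ)/(1 − BDC), the implementation scans BDC
over a 0.01 grid and picks the value minimizing |corr(E, μ)| inside the
event region, subject to E remaining faithful to μ outside it. The exact
rationale: for a two-state mixture ρ = (1−f)μ + f·b, the coefficient of μ
in E vanishes precisely at BDC = 1−f, so the inside-region correlation
crosses zero there whenever the bound-state density is uncorrelated with
the background within the region.

Two numerical choices make this estimator behave:

1. **Solvent-baseline centering.** Correlations are centered about the
   region *median* (the flat solvent level) rather than the region mean.
   Density features are nonnegative, so mean-centering makes spatially
   disjoint features — the incoming ligand and the ordered solvent it
   displaces — artificially anticorrelated, which biased the noise-free
   scan by ≈ 12% relative. About the solvent baseline, non-overlapping
   features are orthogonal and the scan recovers 1−f to its grid step for
   all f from 0.05 to 0.5 (verified to machine precision noise-free).

2. **Reliability-corrected outside constraint.** The event map amplifies
   voxel noise by 1/(1−BDC), which attenuates the observed outside-region
   correlation even when the subtraction is perfectly faithful; a raw
   corr ≥ 0.95 cutoff would cap recoverable event occupancies near 0.3
   under 0.1σ noise. The observed correlation is therefore divided by the
   square root of the reliability implied by the cohort sd map (the classic
   measurement-error disattenuation) before the 0.95 threshold is applied.
   On noise-free cohorts the correction is a no-op.

The event region used by the two-pass pipeline is a 4.0 Å ball around the
event centroid — large enough to contain both the ligand and the displaced
solvent features whose balance identifies f, small enough that bulk
protein density (which is common to both states and carries no
information about f) does not dominate the region statistics.

A dataset indistinguishable from background inside the region (peak |Z|
below the detection threshold) raises a no-event error rather than
returning an arbitrary BDC.

## Two-pass analysis

Pass 1 characterizes the background on all datasets and detects events;
pass 2 re-characterizes after excluding every pass-1 event dataset, then
re-detects and estimates BDC per event. Exclusion strictly improves
background fidelity on contaminated cohorts (asserted as an RMS test
against the known ground map) and is a no-op on clean ones. If pass 1
flags essentially every dataset, the cohort has no definable background
and the analysis aborts.

## Two-state occupancy fitting

With unit-occupancy renders A and B of the two conformers, the constrained
least-squares occupancy has the closed form occ = ⟨ρ−B, A−B⟩/‖A−B‖²,
clamped to [0, 1] (clamping is logged, not silent). The fit is restricted
to the *footprint* — the union of atom spheres of radius 2σ_atom — so
uninformative solvent voxels cannot dilute the signal. Identical conformers
make the denominator vanish and raise a degenerate-fit error. The
conformer-vs-disorder variant fits a single conformer with the remaining
occupancy interpreted as a disordered state contributing no excess
density: occ = ⟨ρ, A⟩/‖A‖² over A's footprint.

Fits assume the map is on the same scale as the renders (the raw forward
model scale). The temperature-series generator therefore leaves its maps
on that scale; its noise parameter is expressed relative to the sd of a
unit-occupancy render so that it remains comparable to sigma-scaled noise
levels.

## Minor-state density profiles

For each residue, the atoms unique to the minor state are those at least
1.0 Å (inclusive) from every major-state atom. The per-temperature score is
the sum of map values interpolated at those atom centers — computed on
sigma-scaled maps, matching the σ-contour convention in which such density
is usually judged — followed by min–max normalization to [0, 1] across
temperatures. A zero score range sets a degeneracy flag instead of
dividing by zero, and a residue with no unique atoms raises an error
rather than returning a silent zero that would masquerade as low
heterogeneity. The bimodality diagnostic for occupancy panels is the
simple edge-mass fraction (values within 0.1 of 0 or 1), with a 0.8
fraction separating "single-state-panel" from "mixed".

## Ensemble construction rules

Merging compares, per residue, the all-atom (non-hydrogen) RMSD between
the ground and bound conformers in the shared crystal frame (no
superposition): below 0.2 Å the conformers are merged into one (ground
coordinates, the reference model); from 0.2 to 0.4 Å both are kept with
per-atom restraint pairs holding their coordinates identical; above 0.4 Å
both are free. Thresholds are half-open intervals, and the RMSD test is
symmetric. Residues where either input state already carries alternate
conformations are kept free (the thresholds are defined for single
conformers), and residues present in only one state — the ligand, most
prominently — are carried as that state's conformers.

The deposited bound-state occupancy is 2.2 × the event-map occupancy
(1 − BDC), distributed evenly among the state's alternate conformers; the
ground state receives the complement. Since 2.2 × exceeds 1 for event
occupancies above 0.45, the bound total is capped at 0.95 — such cases were
resolved by manual inspection in practice, so the automated policy is to
cap and flag; any ensemble at ≥ 50% bound is flagged for inspection
regardless. Output files use the classic altloc dialect, with ground
conformers as altlocs A/B, bound as C/D, merged residues as a single
unlabeled conformer, and the state table in `REMARK 399 STATE` lines;
occupancies are written to two decimals, matching deposition practice.
Backbone RMSD between states is computed over matched N, Cα, C atoms with
no superposition.

## Quality control and site clustering

The resolution cutoff starts at 1.4 Å and steps outward by 0.05 Å until
the highest-resolution bin (the bin with the smallest edge at or beyond
the candidate cutoff) simultaneously satisfies I/σ(I) ≥ 1.0, CC½ ≥ 0.50 and
completeness ≥ 90%. The 0.05 Å step matches typical binning granularity.
The procedure is monotone: tightening any criterion can only coarsen the
selected limit.

Fragment binding sites are defined by contact residues (any heavy atom
within 4.0 Å, inclusive, of any ligand atom) and clustered by single
linkage: fragments sharing at least one contact residue belong to one
site, closed transitively, so distinct sites share no residues by
construction — an invariant the tests assert against a
connected-components oracle. The site count is an output, never a
parameter.

## Assay models

All fits are unweighted least squares on replicate means with the Hill
coefficient fixed at 1, standard errors taken from the Jacobian at the
optimum. Tethering is modeled as one pooled saturation curve
f(c) = c/(EC₅₀+c). The partial noncompetitive model
v(c) = v₀(1 − I_max·c/(K_i+c)) nests full noncompetitive inhibition
(I_max = 1) and no inhibition (I_max = 0); I_max is bounded to [0, 1], and
because flat data drive I_max toward 0 while K_i ridges to infinity (only
their ratio is identifiable), the lower-boundary flag is raised whenever
the *predicted effect over the measured dose range* is negligible, not
only when I_max itself is pinned. k_cat conversion uses Beer–Lambert with
ε = 18 000 M⁻¹cm⁻¹ and a 0.29 cm path: mAU/min → AU/min → M/min, divided
by the molar enzyme concentration.

## Synthetic study conditions

The generator defaults encode the study conditions the pipeline is meant
to handle: soak cohorts with ≈ 6% of datasets carrying a binder at 10–30%
occupancy under 0.1σ map noise (the acceptance cohort uses 100 datasets, a
desk-scale stand-in for a campaign thousands of soaks deep); a
four-temperature ladder at 100/180/240/278 K with open-state occupancies
0.33/0.45/0.55/0.65; tethering titrations at nine 3-fold dilutions from
50 µM with triplicates (generating EC₅₀ 7.8 µM); inhibition with K_i
7.1 µM and a 60% plateau; and kinetics at twelve 2-fold pNPP dilutions
from 20 mM. The binder model *displaces ordered pocket solvent* as well as
adding ligand density — as real soaking does — which is also what makes
the subtraction fraction statistically identifiable (see the BDC section).

What the generator does **not** emulate, and what passing tests therefore
do not establish: reciprocal-space effects (series termination, phase
error, solvent flattening artifacts), non-isomorphism between crystals,
B-factor heterogeneity between datasets, correlated noise, and
conformational heterogeneity of the background itself. Real campaigns also
require human triage of candidate events; the pipeline exposes ranked
events and leaves triage to the analyst.

## Known limitations

- The BDC heuristic assumes the bound-state density within the event
  region is uncorrelated (about the solvent baseline) with the background;
  binders that merely intensify existing background features would be
  mis-estimated.
- Occupancy fitting trusts the input B-factors through the atom-width
  rule; no B-factor refinement is attempted.
- The occupancy–temperature relation is reported as a curve; no
  glass-transition or other thermodynamic model is fit to it.
- Site clustering uses residue identity only; pose-level (RMSD) clustering
  within a site is out of scope.
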