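# ensemblemap

Occupancy-resolved analysis of crowded crystallographic experiments:
statistical background subtraction across cohorts of electron-density maps,
detection and quantification of rare low-occupancy binding events,
temperature-dependent two-state occupancy fitting, construction of
ground+bound multiconformer ensembles, cohort quality control with
binding-site clustering, and the biochemical dose-response models used to
validate an allosteric site.

The package is aimed at structural biologists running large fragment-soaking
campaigns or multitemperature series on one crystal system, and at method
developers who want a compact, fully synthetic, ground-truth-checked
re-implementation of that analysis stack.

## The core computations

**Cohort background subtraction.** Given *n* grid-compatible maps
ρ₁…ρₙ, the background is characterized per voxel by the uniform-weight mean
μ and population standard deviation σ. A dataset's Z-map is

    Z = (ρ − μ) / max(σ, σ_floor),

and contiguous 6-connected clusters with Z ≥ 2.5 spanning ≥ 27 voxels are
candidate binding events. For an event, the background-subtracted event map

    E_BDC = (ρ − BDC·μ) / (1 − BDC)

reconstructs the bound-state density when the background density correction
BDC equals the ground-state fraction; the **event-map occupancy is 1 − BDC**.
BDC is chosen by scanning a 0.01 grid and minimizing |corr(E, μ)| inside the
event region, subject to E remaining faithful to μ outside it. A two-pass
protocol excludes pass-1 event datasets from the background before
re-characterizing, which removes bound-state contamination from μ. For a
noise-free mixture ρ = (1−f)·ground + f·bound these formulas are exact:
E at BDC = 1−f equals the bound map to machine precision, and the scan
recovers f to its grid step.

**Two-state occupancy vs temperature.** With conformer densities A and B
rendered from a Gaussian forward model (σ_atom² = B/(8π²)), the constrained
fit min_occ ‖ρ − occ·A − (1−occ)·B‖ over the atoms' footprint has the closed
form occ = ⟨ρ−B, A−B⟩/‖A−B‖², clamped to [0, 1]. Minor-state heterogeneity
is summarized by summing σ-scaled density at the centers of atoms unique to
the minor state (≥ 1.0 Å from every major-state atom) and min-max
normalizing across temperatures.

**Ensemble deposition rules.** Ground and bound models are merged per
residue by all-atom RMSD (merge < 0.2 Å; restrain coordinates < 0.4 Å; free
otherwise); the deposited bound-state occupancy is 2.2 × the event-map
occupancy (capped at 0.95), split evenly among a state's alternate
conformers, with ensembles at ≥ 50% bound flagged for inspection.

**Assay models.** Percent tethering 100·mod/(mod+unmod); percent inhibition
100·(1 − (v_frag − v_noE)/(v_DMSO − v_noE)); saturation tethering
f(c) = c/(EC₅₀+c); partial noncompetitive inhibition
v(c) = v₀·(1 − I_max·c/(K_i+c)), which plateaus at (1−I_max)·v₀;
Michaelis–Menten v = V_max·S/(K_M+S); and k_cat from absorbance rates via
ε = 18 000 M⁻¹cm⁻¹ and a 0.29 cm path.

All inputs can be generated by the `simulate` module with known ground
truth, so the full pipeline runs and is tested without any downloads.

## Worked example

```python
import ensemblemap as em

cohort = em.simulate_soak_cohort(
    100, 0.06, (0.1, 0.3), em.SimulationConfig(seed=11, noise_sd=0.1))
background, events = em.run_two_pass_analysis(cohort)
for ds_id, evs in sorted(events.items()):
    ev = evs[0]
    truth = cohort.ground_truth["binders"][ds_id]["occupancy"]
    print(f"{ds_id}: peak Z {ev.peak_z:5.1f}  "
          f"event occupancy {ev.event_occupancy:.2f}  (true {truth:.2f})")
```

prints

```
ds_012: peak Z  27.4  event occupancy 0.17  (true 0.16)
ds_048: peak Z  23.9  event occupancy 0.16  (true 0.15)
ds_058: peak Z  43.6  event occupancy 0.30  (true 0.29)
ds_060: peak Z  26.9  event occupancy 0.17  (true 0.16)
ds_077: peak Z  36.4  event occupancy 0.24  (true 0.23)
ds_095: peak Z  37.8  event occupancy 0.23  (true 0.23)
```

— the six rare binders planted in the 100-dataset cohort are recovered with
no false positives, and their occupancies are recovered to a few percent
despite each binder contributing only 10–30% of the density in its own map
(and none being visible in a conventional map at these levels). The same
pipeline is available from the shell:

```
ensemblemap simulate cohort --n 100 --outdir scratch/cohort
ensemblemap events --map-dir scratch/cohort \
    --metadata scratch/cohort/metadata.csv --out scratch/events.csv
```

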