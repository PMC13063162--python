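# Methods

This note documents the models, conventions, and design choices behind
`pfas_screen`, in the spirit of a package's statistical/methodological
reference: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not demonstrate.

## Ion masses and formula algebra

Monoisotopic element masses are frozen constants (C 12 exact, H 1.0078250319,
F 18.9984032, O 15.9949146, N 14.0030740, S 31.9720707 Da, plus a few
halogens/alkali metals for generality), with the proton at 1.00727646 Da and
the electron at 0.00054858 Da. Two ion conventions matter:

* **Precursors** are deprotonated molecules: m/z = neutral mass − proton
  mass. The electron gained on ionisation is retained on the anion. This
  convention reproduces the reference theoretical m/z values of all eleven
  benchmark compounds to their printed decimals, which is the package's
  primary correctness anchor (and is cross-checked against an independent
  mass library in the tests).
* **Product ions** are intact anions: m/z = formula mass + electron mass.
  No proton loss is applied; diagnostic fragments such as SO₃⁻, FO₃S⁻,
  C₂F₅⁻ are written as the full anion formula.

Formula strings are Hill-style (`C4HF9O3S`), with implicit count 1 and
round-tripping text forms. One inconsistency in the source material is
resolved here: the 1H-perfluoroalkanes are carried as C₅HF₁₁ and C₇HF₁₅
(consistent with their printed m/z), not the F₁₂/F₁₆ variants that appear
once in the reference table.

## Kendrick mass defects

CF₂-normalised Kendrick mass: KM = m/z × 50/49.9968064, where 49.9968064 Da
is the exact CF₂ mass (= m(C) + 2·m(F), asserted to 1e-6 Da). The defect is
KMD = round(KM) − KM with round-half-to-even; it is computed on ion m/z
(not neutral mass) because the homolog plot displays measured m/z. Negative
KMDs are legal — the 1H-perfluoroalkane series sits at ≈ −2e-4. Homolog
invariance (KMD unchanged under ±k·CF₂) holds exactly away from rounding
boundaries and is property-tested.

## Feature detection

* **Noise**: 1.4826 × median absolute deviation from the EIC median,
  restricted to points below the median, floored at 1 count. The
  restriction makes the estimator one-sided: peaks (which live above the
  median) contribute nothing, while for pure Gaussian baseline noise the
  estimator is consistent for the standard deviation (the 0.6745σ lower
  quartile distance times 1.4826 is σ). Verified to 20% at 500 points.
* **Peaks**: local maxima with height ≥ 3 × noise; boundaries walk down
  each flank while the trace is non-increasing, stopping at a local minimum
  or on return to baseline (≤ noise); area is the trapezoid over RT between
  boundaries; the feature m/z is the intensity-weighted mean centroid m/z
  across the peak's scans. A fitted-peak-shape integrator was deliberately
  avoided: the screening thresholds (area 100,000; S/N 50) are defined on
  integrated signal, and the trapezoid reproduces the closed-form Gaussian
  area within 2% at the default sampling (scan spacing 0.01 min, peak sigma
  ≥ 0.03 min, i.e. ≥ 9 points per peak).
* Both thresholds are inclusive and applied before any blank logic.

## Screening cascade

Fixed stage order: feature thresholds → suspect match (≤ 5 ppm, signed
error kept) → blank elimination → duplicate-injection concordance →
standard RT confirmation. Design choices where the procedure description
left gaps:

* **Blank rule**: "absent in the blank" is operationalised as an
  area-fraction veto — a blank feature within 5 ppm / 0.2 min whose area is
  ≥ 10% of the sample feature's removes the hit. Strict absence would let
  noise-level blank centroids veto everything; the fraction is
  configurable.
* **Replicate rule**: the same suspect must be hit in both replicates with
  apex RTs within 0.2 min; areas need not match. Surviving hits merge the
  two features, and the reported ppm error is recomputed from the mean
  measured m/z. A sample without a duplicate injection is an error, not a
  silent pass.
* **Isomers**: suspects sharing a formula all match the same feature and
  survive screening; disambiguation happens at confidence assignment.
* Monotonicity (tightening any threshold never adds candidates) is a tested
  invariant of the cascade.

## MS² annotation and confidence

MS² spectra are pulled per candidate from its own sample's runs, requiring
the isolation window (default ±0.5 Th) to cover the measured precursor m/z
and the scan RT to fall within the peak bounds padded by 0.2 min. For each
library fragment the nearest centroid within max(5 mDa, 20 ppm) matches, at
most once per fragment, ties to the smallest absolute error; across several
spectra the best observation per fragment is kept. The tolerance is wider
than the MS¹ 5 ppm on purpose: published measured product ions for these
compounds deviate from theory by up to ~1.5 mDa (MS² resolution 17,500 vs
70,000 at MS¹), which at m/z < 200 is 10-20 ppm — a 5 ppm rule would reject
most genuine diagnostic ions (see `examples/fragment_tolerance.py`).

The confidence ladder, applied mechanically with an always-emitted
rationale string:

| Level | Condition |
|------:|-----------|
| 1 | RT within 0.1 min of an authentic standard **and** ≥ 2 matched fragments from the standard's set |
| 2 | ≥ 2 diagnostic fragments consistent with one structure (the suspect's own or class fragment set) |
| 3 | ≥ 2 isomeric suspects indistinguishable (same formula, same matched set) — emitted mechanically, override by configuration |
| 4 | formula-level support only: exactly one matched fragment, or only generic perfluoroalkyl fragments |
| 5 | accurate mass only: no MS² spectrum, or no fragment matched |

The final report includes only candidates with ≥ 1 MS² spectrum and ≥ 2
fragment matches; adding fragments to a spectrum can never lower the level
(tested). Requiring *two* fragments for Level 2 reflects the practice of
citing at least two supporting ions per proposed structure; a single ion is
treated as formula-level evidence.

## Homolog series

Single-linkage grouping with two joint conditions: |ΔKMD| ≤ 0.002 Da and
mass spacing within 5 ppm of an integer multiple (≥ 1) of exact CF₂. The
0.002 Da tolerance is this package's choice: computed within-series KMD
spreads of the benchmark set are < 1e-4 while between-series gaps exceed
0.015 (sulfonic acids ≈ +0.038, sulfonamides ≈ +0.022, telomer sulfonate
≈ +0.005, 1H-perfluoroalkanes ≈ −0.0002), so 0.002 separates cleanly with
two orders of margin for measurement error. The explicit spacing condition
prevents accidental KMD coincidences between unrelated classes. RT must
increase strictly with mass within a series; violating members (including
ties) are flagged, never auto-removed — exclusion of a flagged member is a
reviewed decision, surfaced in the report.

## Synthetic data generator

The generator emulates the acquisition design the workflow targets:
duplicate sample injections plus blanks; MS¹ centroid scans on a regular RT
grid restricted to the 0-8 min elution window that contains every benchmark
retention time (full-gradient scans would only add empty baseline); scan
spacing 0.01 min and peak sigma 0.03 min so ≥ 9 points define each peak;
Gaussian elution profiles on top of a per-channel chemical baseline
(default mean 2000, sd 800 counts) plus uniformly scattered background
centroids; measured m/z = theoretical × (1 + ppm·1e-6) with 0.1 ppm
per-scan jitter; DDA-style MS² spectra at apex scans carrying the
configured fragments displaced by a few mDa (published measured offsets
where available, otherwise seeded draws in ±2 mDa) with stepped collision
energies (15/30/50 eV) recorded as metadata. Areas are specified directly
in counts·min — the screening method is qualitative, so no
concentration-response model is pretended. Isotopologue peaks, ion
suppression, and gradient-dependent RT shifts are *not* simulated.

Each sample carries one decoy per failure mode: sub-threshold area,
sub-threshold S/N (achieved with an elevated noisy baseline on that
channel), blank contaminant (same peak in blanks), single-replicate
artifact, and an 8 ppm mass error. Decoy peaks target decoy suspect-list
entries (plausible PFAS such as PFHpS, PFOA), so a screening failure would
surface as a named false positive.

Passing the end-to-end reconstruction therefore shows that the pipeline's
rules interlock correctly under realistic mass errors, noise, and decoy
contamination — it does not demonstrate performance on real matrices, where
co-elution, in-source fragmentation, matrix suppression, and isotope
interference add failure modes outside this model.

## Determinism and numerics

All randomness flows from `numpy.random.SeedSequence(scenario seed, run
identity)`; regenerating a scenario with the same seed is byte-identical
down to the mzML files. mzML is written with uncompressed 64-bit
little-endian arrays and read back by controlled-vocabulary accession;
round-trips preserve RTs and centroids to 1e-6. Tolerance comparisons are
inclusive throughout (≤), matching how the thresholds are stated. Degenerate
inputs are defined: empty suspect lists error, unknown fragment-library
owners return empty sets, blank-only run sets screen to an empty result,
constant-zero EICs have noise 1 and no peaks, and a singleton ion is a legal
homolog series of one.
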