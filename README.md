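# pfas-screen

Accessible suspect screening for per- and polyfluoroalkyl substances (PFAS)
in LC-HRMS/MS data.

Thousands of PFAS occur in groundwater near sites where aqueous film-forming
foam (AFFF) was used, but validated targeted LC-MS/MS methods cover only a
few dozen of them. Suspect screening closes part of that gap: candidate ions
are matched by accurate mass against a large formula-based suspect list, and
confirmed — without requiring an authentic standard for every compound —
through diagnostic MS² product ions and homologous-series structure. This
package implements that workflow as an importable Python library with a thin
command-line interface, for analytical and environmental chemists who want a
transparent, scriptable alternative to vendor screening software. A seeded
synthetic-data generator stands in for instrument raw files, so the whole
pipeline is testable end to end.

## The method

For a neutral formula M, the deprotonated anion observed in negative-mode
electrospray has

    m/z([M−H]⁻) = m(M) − m(H⁺),  with m(H⁺) = 1.00727646 Da,

computed from frozen monoisotopic element masses (the ionising electron
stays on the anion). An MS¹ feature — a chromatographic peak with
intensity-weighted mean m/z, apex retention time t_R, trapezoidal area, and
signal-to-noise ratio — matches a suspect when

    |measured − theoretical| / theoretical × 10⁶ ≤ 5 ppm,

subject to area ≥ 100,000, S/N ≥ 50, detection in both duplicate
injections, and absence from ultrapure-water blanks. A candidate whose t_R
lies within 0.1 min of an authentic standard and whose MS² spectrum shows
at least two of the standard's product ions is confidence **Level 1**;
without a standard, two or more diagnostic fragments consistent with one
structure give **Level 2** (lower levels are recorded but not reported).
MS² fragments are matched at max(5 mDa, 20 ppm), since product ions from
lower-resolution MS² scans deviate from theory by ~1-1.5 mDa.

Homologous series differing by CF₂ units are found with the Kendrick mass
defect, using CF₂-normalised values:

    KM  = m/z × 50 / 49.9968064
    KMD = round(KM) − KM

Homologs share a KMD, so series appear as horizontal bands on an m/z-vs-KMD
plot; within a series, t_R must increase with chain length on a
reversed-phase gradient, and violations are flagged as suspected false
positives.

## Worked example

`examples/end_to_end_screening.py` simulates the bundled scenario — three
AFFF-impacted groundwater samples injected in duplicate, two blanks, and
one decoy peak per screening failure mode in every sample — then screens,
annotates, and groups. It prints the processing log

```
features_detected: 9663
features_after_thresholds: 47
suspect_hits: 47
after_blank_filter: 41
after_replicate_filter: 19
rt_confirmed: 9
reported: 19
unique_compounds: 11
homolog_series: 4
```

(each filter stage shrinks the candidate set; 19 sample x compound rows
remain, covering 11 unique PFAS) and a candidate table of the form

```
 sample   compound  class  theoretical_mz   rt  delta_ppm  confidence_level
Sample3       PFBS   PFSA        298.9430  3.8     0.7869                 1
Sample3      FHxSA   FASA        397.9526  5.5     0.8995                 2
...
```

Level 1 marks the five standard-confirmed compounds (PFBS, PFPeS, PFHxS,
PFOS, 6:2 FTS); the six discovery compounds (FPrSA, PFPrS, FBSA, FHxSA and
the two 1H-perfluoroalkanes) are Level 2. `examples/homolog_series.py`
groups the same 11 ions into three multi-member CF₂ series (sulfonic acids,
sulfonamides, 1H-perfluoroalkanes) plus the fluorotelomer sulfonate
singleton, all with valid retention-time trends. The other examples cover
ion-mass/KMD computation and the MS² tolerance rationale.

The same workflow is available from a shell:

```bash
pfas-screen simulate --seed 7 --out runs/
pfas-screen screen --manifest runs/manifest.csv --out results/
pfas-screen report --candidates results/candidates.csv
pfas-screen kmd --candidates results/candidates.csv --out results/kmd.csv
```

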