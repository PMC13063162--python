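"""Theoretical [M-H]- m/z and CF2 Kendrick mass defects from formulas.

For each PFAS in the bundled catalog, compute the neutral monoisotopic mass,
the deprotonated-anion m/z observed in negative-mode electrospray, and the
CF2-normalised Kendrick mass defect.  Compounds of one class share a KMD:
that is the fingerprint the homolog analysis exploits.
"""

from pfas_screen import kendrick_mass_defect, monoisotopic_mass, mz_deprotonated
from pfas_screen.catalog import COMPOUNDS

print(f"{'compound':22s} {'class':16s} {'formula':13s} "
      f"{'neutral (Da)':>12s} {'[M-H]- (Th)':>12s} {'KMD':>9s}")
for c in sorted(COMPOUNDS, key=lambda c: c.theoretical_mz):
    neutral = monoisotopic_mass(c.formula)
    mz = mz_deprotonated(neutral)
    kmd = kendrick_mass_defect(mz).kmd
    print(f"{c.name:22s} {c.pfas_class:16s} {c.formula:13s} "
          f"{neutral:12.6f} {mz:12.4f} {kmd:+9.5f}")

print("\nIons sharing a KMD (to ~1e-4) differ by whole CF2 units: homologs.")
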