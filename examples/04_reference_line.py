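"""Reference line: converting the NA cut-off back into a curve.

A scalar NA cut-off is easier to read on the critical-curve plot as a
reference line: the member tau*eta = c of the membrane curve family whose
closed-form NA equals the cut-off.  Critical curves above the line (NA
beyond the cut-off) mark rupture-prone aneurysms.
"""

from strainrisk import (REFERENCE_NA, CohortSpec, generate_cohort,
                        hyperbola_constant_from_na, hyperbola_na_closed_form,
                        reference_curve_from_na)
from strainrisk.pipeline import cohort_na_table

c = hyperbola_constant_from_na(REFERENCE_NA)
print(f"NA cut-off {REFERENCE_NA} -> hyperbola tau * eta = {c:.4f}")
print(f"closed-form NA of that curve: {hyperbola_na_closed_form(c):.6f}")

line = reference_curve_from_na(REFERENCE_NA)
verts = line.vertices()
print(f"reference line spans thickness fractions "
      f"[{verts[:, 0].min():.3f}, {verts[:, 0].max():.3f}] inside the "
      f"[0.25, 1.0]^2 design rectangle")

records = generate_cohort(CohortSpec(seed=1))
na_table = cohort_na_table(records)
flagged = na_table[na_table["na"] >= REFERENCE_NA]
print(f"\ncohort seed 1: {len(flagged)}/51 aneurysms at or above the "
      f"reference line\n({int(flagged['ruptured'].sum())} of them actually "
      f"ruptured)")
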