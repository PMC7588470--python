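"""Critical curve and normalized area for one aneurysm.

The 16 sweep strains are interpolated by the unique tensor-product bicubic
surface; the critical curve is its 0.3 (failure-strain) level set, and the
normalized area (NA) is the fraction of the design rectangle on the rupture
side — the scalar risk score in [0, 1].
"""

import numpy as np

from strainrisk import (FRACTIONS, MembraneSurface, StrainGrid,
                        extract_critical_curve, fit_surface,
                        hyperbola_na_closed_form, normalized_area)

# a ruptured-scale aneurysm: baseline strain 0.094 with membrane scaling
eps0 = 0.094
fr = np.array(FRACTIONS)
grid = StrainGrid(eps0 / np.outer(fr, fr))
surface = fit_surface(grid)

curve = extract_critical_curve(surface, level=0.3)
verts = curve.vertices()
print(f"critical curve: {len(verts)} vertices, thickness fraction spans "
      f"[{verts[:, 0].min():.3f}, {verts[:, 0].max():.3f}]")

na = normalized_area(surface, level=0.3)
na_exact = hyperbola_na_closed_form(eps0 / 0.3)
na_true_surface = normalized_area(MembraneSurface(eps0), level=0.3)
print(f"NA from the bicubic fit of the 16-point grid: {na:.4f}")
print(f"NA of the exact 1/(tau*eta) surface:          {na_true_surface:.4f}")
print(f"closed-form NA of the hyperbola family:       {na_exact:.4f}")
print("\nThe bicubic value differs from the closed form only through the "
      "interpolation\nof the hyperbolic surface from 16 nodes; on the exact "
      "surface the quadrature\nmatches the closed form to < 1e-3.  NA ~ 0.43 "
      "sits above the 0.346 reference\ncut-off: this aneurysm would be "
      "flagged as rupture-prone.")
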