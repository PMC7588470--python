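"""Reference strain statistics of a 51-aneurysm clinical FSI cohort.

These constants are the group-level summary (mean +/- SD of the highest TWA
equivalent strain per sweep condition) reported for a cohort of 27
unruptured and 24 ruptured cerebral aneurysms analysed by patient-specific
fluid-structure interaction.  They serve two purposes:

* calibration targets for the synthetic-cohort generator (the baseline
  strain distribution of each group and the group-specific condition
  amplification), and
* reference output for the per-condition group comparison.

Rows are thickness fractions (1.0, 0.75, 0.5, 0.25), columns modulus
fractions (1.0, 0.75, 0.5, 0.25), matching :class:`strainrisk.grids.StrainGrid`.
"""

from __future__ import annotations

import numpy as np

UNRUPTURED_N = 27
RUPTURED_N = 24

UNRUPTURED_MEAN = np.array([
    [0.053, 0.071, 0.105, 0.206],
    [0.078, 0.103, 0.150, 0.286],
    [0.123, 0.159, 0.230, 0.447],
    [0.252, 0.337, 0.503, 1.012],
])

UNRUPTURED_SD = np.array([
    [0.026, 0.030, 0.042, 0.088],
    [0.032, 0.040, 0.056, 0.121],
    [0.047, 0.059, 0.087, 0.190],
    [0.103, 0.135, 0.207, 0.459],
])

RUPTURED_MEAN = np.array([
    [0.094, 0.134, 0.189, 0.338],
    [0.143, 0.193, 0.267, 0.453],
    [0.258, 0.286, 0.396, 0.675],
    [0.455, 0.577, 0.824, 1.573],
])

RUPTURED_SD = np.array([
    [0.048, 0.068, 0.090, 0.140],
    [0.063, 0.092, 0.119, 0.176],
    [0.167, 0.122, 0.164, 0.281],
    [0.212, 0.276, 0.412, 0.823],
])

#: Published normalized-area cut-off separating predicted-safe from
#: predicted-rupture critical curves.  Data-dependent (it was fit on the
#: clinical cohort above); consumed here only as the input to the
#: reference-line inversion, never re-derived.
REFERENCE_NA = 0.346

#: Strain at which the cerebral arterial wall is assumed to fail.
FAILURE_STRAIN = 0.3

GROUP_MEANS = {"unruptured": UNRUPTURED_MEAN, "ruptured": RUPTURED_MEAN}
GROUP_SDS = {"unruptured": UNRUPTURED_SD, "ruptured": RUPTURED_SD}
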