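# Methods

## The risk statistic

The input per aneurysm is a 4×4 grid of highest thin-walled-area (TWA)
equivalent strains over the design rectangle of wall-thickness fraction
τ ∈ {1.0, 0.75, 0.5, 0.25} and Young's-modulus fraction η ∈ {1.0, 0.75,
0.5, 0.25}. The 16 nodes determine a unique tensor-product bicubic
polynomial ε̂(τ, η) = Σ_{i,j≤3} c_ij τ^i η^j; "polynomial interpolation on a
4×4 grid" admits exactly this one tensor-product form, which is why it was
chosen. The coefficients come from the separable Vandermonde solve
C = V_τ⁻¹ G V_η⁻ᵀ; node residuals are at machine precision (asserted at
1e-9 relative over 1000 random grids).

The **critical curve** is the level set ε̂ = ε_f with failure strain
ε_f = 0.3 — the wall-degradation combinations at which rupture is predicted.
It is extracted by marching squares (scikit-image `find_contours`) on a
256² uniform evaluation mesh with linear in-cell interpolation. When the
surface never crosses the level the curve is empty and tagged `all_below`
(no rupture predicted anywhere) or `all_above` (rupture everywhere).

The **normalized area** is defined as the exceedance measure

    NA = |{(τ, η) ∈ [0.25, 1]² : ε̂(τ, η) ≥ ε_f}| / 0.75²,

computed by midpoint counting on a 512² cell grid. For surfaces that
decrease monotonically in both τ and η — every physically sensible strain
sweep — this equals the area between the critical curve and the low-(τ, η)
axes divided by the whole rectangle, i.e. the area-under-the-curve reading
of the score; the exceedance form additionally stays well defined (and in
[0, 1]) for oscillatory bicubic interpolants whose level sets leave the
domain. Three conventions are fixed here because the score's verbal
definition leaves them open: the denominator is the design rectangle
[25%, 100%]² (area 0.75² in fraction units), not a rectangle extended to
0%; strain exactly at the failure level counts as exceedance (the wall
fails when the strain *reaches* ε_f); coordinates are fractions internally,
percent only at the plotting/CSV-polyline boundary.

**Classification.** ROC thresholds are all unique NA values plus a +∞
sentinel under the rule "predict rupture if NA ≥ cutoff" (≥ rather than >
is a fixed convention). The trapezoid AUC equals the Mann–Whitney pair
probability with ties counted ½ (asserted against brute-force pair counting
on small cohorts, and against scikit-learn). The operating point maximises
Youden's J = sensitivity + specificity − 1; ties on J break toward the
larger threshold, i.e. the more specific operating point. Group
comparisons per condition use the equal-variance (pooled) Student's t with
df = n_a + n_b − 2 (Welch available via `equal_var=False` /
`t_test = welch`); degenerate zero-variance inputs resolve explicitly to
p = 1 (equal means) or p = 0 (separated constants). Raw p-values are
reported for the 16 conditions; no multiplicity correction is applied,
matching the tabular convention the summary mirrors.

## The membrane surrogate

A full fluid–structure interaction (FSI) solve is out of scope; the
analysis only ever consumes the scalar strain per condition. The physical
stand-in is a thin-walled pressurised sphere: equibiaxial membrane strain
ε = P·R·(1−ν)/(2·t·E), which scales exactly as 1/(t·E), so the sweep grid
of an idealised aneurysm is ε₀/(τ·η). Its level sets are hyperbolas
τ·η = c with closed-form NA (piecewise in c, continuous at the branch
points c = 1/4 and c = 1), giving an analytic oracle for the numerical
quadrature (agreement < 1e-3, measured ~6e-5 at 512²) and an invertible
family for the reference line: the NA cut-off 0.346 maps by monotone
bisection (tolerance 1e-9 in NA) to the curve τ·η ≈ 0.277.

Default physical constants: nominal wall thickness 0.2 mm, Young's modulus
2.6 MPa (median of reported aneurysm moduli), Poisson's ratio 0.49, wall
density 1000 kg/m³ (informational — the quasi-static balance does not use
it), failure strain 0.3, pressure 13332 Pa (100 mmHg), sac radius 8.12 mm.
The radius default places the nominal-condition strain at the unruptured
group scale (0.0531).

## The synthetic-cohort generator

The generator emulates a 51-aneurysm labelled cohort (27 unruptured, 24
ruptured) whose per-condition group statistics match the published clinical
reference values in `calibration.py`:

- **Baseline strain** per aneurysm ~ lognormal moment-matched to the group
  nominal-condition mean/SD (0.053 ± 0.026 unruptured, 0.094 ± 0.048
  ruptured). Lognormal because strains are strictly positive and
  right-skewed; the clinical distributional family is unreported, so this
  is a modelling choice. Moment matching is exact:
  σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2.
- **Amplification** across conditions: by default the group-specific
  empirical matrices A = mean(τ, η)/mean(1, 1) from the reference table
  (componentwise ≥ 1, maximal at the thin-soft corner); the `membrane`
  mode A = 1/(τη) is available when closed-form behaviour is wanted. The
  empirical matrices capture the real sweep's departure from pure membrane
  scaling (e.g. 4.75 versus 4.0 at (25%, 100%)).
- **Condition noise**: independent mean-1 lognormal multipliers with
  CV 0.10 per cell. Real per-patient sweeps are deterministic given the
  geometry; the shared-baseline + independent-noise decomposition is a
  surrogate for unobserved geometry effects, and CV 0.10 (a free
  parameter, surfaced in the config) is of the order of the observed
  deviation from membrane scaling.

What the generator does **not** emulate: patient geometry and its
correlated, structured deviations across conditions; measurement error in
the rupture labels; any covariates. Passing tests therefore demonstrate
that the pipeline recovers the group separation implied by the reference
summary statistics under this noise model — not clinical performance on
real patients.

With this calibration the closed-form AUC of the two baseline-strain
lognormals is Φ((μ_r − μ_u)/√(σ_u² + σ_r²)) = 0.801, and the full
NA-pipeline mean AUC over 200 cohorts computes to ≈ 0.79 (the acceptance
script recomputes it), consistent with the clinical value 0.785. The
clinical NA cut-off 0.346 and the per-condition p-values are
data-dependent quantities of the private cohort and are consumed as
inputs, never re-derived.

## Numerical choices and sizes

- Contour mesh 256², NA quadrature 512² (defaults, overridable;
  ≥ 32 enforced). 512² keeps the 512-vs-1024 exceedance difference below
  5e-3 on random grids while a 200-cohort run stays in seconds.
- Reproducibility: one `numpy` Generator seeded per cohort spec; identical
  specs give bit-identical cohorts, CSVs and reports. Cohort CSVs embed
  the seed as a header comment; reports embed the config and its hash.
- Acceptance-scale problem sizes: 200 cohorts × 51 aneurysms for the mean
  AUC; 10,000 per group for calibration recovery; 1000 random grids for
  node exactness; 50 hyperbola levels for the NA oracle.

## Limitations

- The surrogate collapses all geometry into one baseline strain; it cannot
  reproduce per-patient critical-curve shapes, only their population
  statistics.
- NA's equivalence with the literal area-under-the-curve reading holds for
  monotone surfaces; for pathological non-monotone grids only the
  exceedance definition is meaningful.
- The empirical amplification matrices are group means; within-group
  variation in sweep shape enters only through the independent noise.
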