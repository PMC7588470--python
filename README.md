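# strainrisk

Rupture-risk scoring for cerebral aneurysms from wall-strain sweeps.

Whether an unruptured cerebral aneurysm should be treated hinges on an
estimate of its rupture risk. A mechanics-based route to that estimate runs a
patient-specific wall-strain analysis repeatedly while the wall thickness *t*
and Young's modulus *E* of the thin-walled area (TWA) — the locally thinned,
rupture-prone patch of the sac — are reduced in four steps (100%, 75%, 50%,
25% of nominal), recording the highest equivalent strain in the TWA for each
of the 16 conditions. `strainrisk` implements everything downstream of that
4×4 strain grid, plus a calibrated synthetic-cohort generator that stands in
for the (non-public) patient data:

1. **Surface fit.** The 16 strains ε(τ, η) over thickness fraction τ and
   modulus fraction η are interpolated by the unique tensor-product bicubic
   polynomial ε̂(τ, η) = Σ c_ij τ^i η^j.
2. **Critical curve.** The level set ε̂ = ε_f with failure strain ε_f = 0.3 —
   the wall-degradation combinations at which rupture is predicted. Curves
   near the upper-right corner (rupture predicted even with a nearly intact
   wall) mean high risk.
3. **Normalized area.** NA = (area of the rupture-predicted region
   {ε̂ ≥ ε_f}) / (area of the [0.25, 1]² design rectangle) ∈ [0, 1], the
   scalar risk score.
4. **Classification.** ROC curve of NA against rupture labels, trapezoid AUC
   (= Mann–Whitney pair probability), and the cut-off maximising Youden's
   J = sensitivity + specificity − 1.

A thin-walled-sphere membrane surrogate, ε = P·R·(1−ν)/(2·t·E), provides a
physical strain scale and exact closed-form oracles (its level sets are
hyperbolas τ·η = c with analytically known NA). The synthetic-cohort
generator draws per-aneurysm baseline strains from lognormals moment-matched
to published group statistics of a 51-aneurysm clinical cohort (27
unruptured: 0.053 ± 0.026; 24 ruptured: 0.094 ± 0.048 at the nominal
condition) and expands them across conditions with group-specific empirical
amplification and small condition-level noise.

## Worked example

`examples/03_cohort_classification.py` generates the default calibrated
cohort (seed 1) and runs the full pipeline:

```
mean NA: unruptured 0.161, ruptured 0.498
AUC of the NA score: 0.910
Youden cut-off: NA >= 0.332 (J = 0.718, sensitivity 79.2%, specificity 92.6%)
confusion: TP=19 FP=2 TN=25 FN=5
```

Mean NA separates the groups as expected (ruptured curves sit further toward
the upper-right corner). The AUC is the probability that a randomly chosen
ruptured aneurysm outscores a randomly chosen unruptured one; single
51-aneurysm cohorts scatter widely (this one drew 0.910), while the mean over
200 cohorts is ≈ 0.79. The Youden cut-off is the NA threshold with the best
sensitivity/specificity trade-off on this cohort.

The other examples show the membrane surrogate (`01`), critical-curve
extraction and the NA closed-form oracle (`02`), and the inversion of an NA
cut-off into a reference line on the curve plot (`04`).

The same pipeline is scriptable from the shell:

```sh
strainrisk simulate --seed 1 --out cohort.csv
strainrisk na cohort.csv --out na.csv
strainrisk classify na.csv --out classify.json
strainrisk report --seed 1 --out report.json   # everything in one JSON
```

## Layout

- `src/strainrisk/` — library: `membrane` (surrogate physics), `cohort`
  (generator + calibration in `calibration.py`), `surface` (bicubic fit,
  critical curves, NA), `stats` (t-tests, ROC/AUC, Youden), `io`/`pipeline`/
  `cli` (formats, reports, command line).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations.
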