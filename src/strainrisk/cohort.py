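"""Seeded generator of labeled synthetic aneurysm cohorts.

The generator emulates the structure of a clinical strain-sweep dataset:
each aneurysm carries a baseline strain (its highest TWA equivalent strain
at the nominal 100%/100% condition) drawn from a group-specific lognormal
calibrated to the reference cohort statistics, and a 4x4 grid obtained by
amplifying that baseline across the 16 sweep conditions with small
independent condition-level noise.

Two amplification models are available:

``membrane``
    A[tau, eta] = 1 / (tau * eta), the exact scaling of the thin-walled
    membrane surrogate.  Gives closed-form oracles downstream.
``empirical``
    Group-specific ratios of the reference cohort's per-condition means to
    its nominal-condition mean.  Reproduces the observed departure from
    pure membrane scaling (e.g. 0.252/0.053 = 4.75 at (25%, 100%) versus
    the membrane value 4.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import calibration
from .grids import FRACTIONS, ConditionGrid, StrainGrid

__all__ = [
    "AmplificationMatrix",
    "AneurysmRecord",
    "CohortSpec",
    "condition_sweep",
    "empirical_amplification",
    "generate_cohort",
    "lognormal_params",
    "sample_lognormal",
]


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given mean and SD.

    Moment matching: sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    """
    if not (mean > 0.0 and sd > 0.0):
        raise ValueError("mean and sd must be strictly positive")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    if not (math.isfinite(mu) and math.isfinite(sigma2)):
        raise ValueError(f"moment matching failed for mean={mean}, sd={sd}")
    return mu, math.sqrt(sigma2)


def sample_lognormal(mean: float, sd: float, size, rng: np.random.Generator):
    """Draw from the lognormal moment-matched to (mean, sd)."""
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class AmplificationMatrix:
    """Strain multipliers A[tau, eta] relative to the nominal condition.

    A is 1 at (100%, 100%) and grows as thickness and modulus shrink —
    a softer, thinner wall strains more under the same load.
    """

    values: np.ndarray
    mode: str
    conditions: ConditionGrid = field(default_factory=ConditionGrid)

    _MODES = ("membrane", "empirical-unruptured", "empirical-ruptured")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.mode not in self._MODES:
            raise ValueError(f"unknown amplification mode {self.mode!r}")
        if v.shape != (4, 4) or not np.all(np.isfinite(v)) or not np.all(v > 0):
            raise ValueError("amplification matrix must be 4x4, finite, positive")
        if v[0, 0] != 1.0:
            raise ValueError("amplification at (100%, 100%) must be exactly 1")
        # fractions are listed decreasing, so amplification must be
        # nondecreasing along each axis of the stored array
        if np.any(np.diff(v, axis=0) < 0) or np.any(np.diff(v, axis=1) < 0):
            raise ValueError("amplification must grow as thickness and "
                             "modulus fractions shrink")

    @classmethod
    def membrane(cls) -> "AmplificationMatrix":
        """Exact 1/(tau*eta) scaling of the thin-walled membrane."""
        fr = np.array(FRACTIONS)
        return cls(1.0 / np.outer(fr, fr), mode="membrane")

    @classmethod
    def empirical(cls, group: str) -> "AmplificationMatrix":
        """Reference-cohort amplification for 'unruptured' or 'ruptured'."""
        if group not in calibration.GROUP_MEANS:
            raise ValueError(f"unknown group {group!r}")
        return empirical_amplification(calibration.GROUP_MEANS[group],
                                       mode=f"empirical-{group}")


def empirical_amplification(group_means, mode: str = "empirical-unruptured"
                            ) -> AmplificationMatrix:
    """Amplification matrix from 16 per-condition group mean strains.

    ``group_means`` may be a 4x4 array (thickness-major, fractions
    decreasing) or a mapping keyed by (tau, eta).  Each entry is divided by
    the nominal-condition mean, so A[(1.0, 1.0)] = 1 exactly.
    """
    cond = ConditionGrid()
    if isinstance(group_means, dict):
        means = np.empty((4, 4))
        for tau, eta in cond.conditions():
            if (tau, eta) not in group_means:
                raise ValueError(f"missing condition ({tau}, {eta}) in group means")
            means[cond.index(tau, eta)] = group_means[(tau, eta)]
    else:
        means = np.asarray(group_means, dtype=float)
        if means.shape != (4, 4):
            raise ValueError("expected 16 per-condition means as a 4x4 array")
    if not np.all(means > 0):
        raise ValueError("per-condition means must be strictly positive")
    values = means / means[0, 0]
    values[0, 0] = 1.0
    return AmplificationMatrix(values, mode=mode)


def condition_sweep(baseline_strain: float,
                    amplification: AmplificationMatrix,
                    noise_cv: float,
                    rng: np.random.Generator) -> StrainGrid:
    """Expand a baseline strain into the 16-condition sweep grid.

    grid[tau, eta] = baseline * A[tau, eta] * m, with m drawn per condition
    from a mean-1 lognormal of coefficient of variation ``noise_cv``
    (deterministic when noise_cv = 0).  The noise models the departure of a
    real patient geometry from the shared amplification pattern.
    """
    if baseline_strain <= 0.0:
        raise ValueError("baseline strain must be strictly positive")
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be >= 0")
    grid = baseline_strain * amplification.values
    if noise_cv > 0.0:
        grid = grid * sample_lognormal(1.0, noise_cv, (4, 4), rng)
    return StrainGrid(grid, conditions=amplification.conditions)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults reproduce the reference clinical cohort: 27 unruptured and 24
    ruptured aneurysms whose baseline (nominal-condition) strains have group
    mean +/- SD of 0.053 +/- 0.026 and 0.094 +/- 0.048, group-specific
    empirical amplification, and condition-level noise with CV 0.10.
    """

    n_unruptured: int = calibration.UNRUPTURED_N
    n_ruptured: int = calibration.RUPTURED_N
    unruptured_baseline_mean: float = float(calibration.UNRUPTURED_MEAN[0, 0])
    unruptured_baseline_sd: float = float(calibration.UNRUPTURED_SD[0, 0])
    ruptured_baseline_mean: float = float(calibration.RUPTURED_MEAN[0, 0])
    ruptured_baseline_sd: float = float(calibration.RUPTURED_SD[0, 0])
    condition_noise_cv: float = 0.10
    unruptured_amplification: str = "empirical"
    ruptured_amplification: str = "empirical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unruptured < 1 or self.n_ruptured < 1:
            raise ValueError("group sizes must be >= 1")
        for name in ("unruptured_baseline_mean", "unruptured_baseline_sd",
                     "ruptured_baseline_mean", "ruptured_baseline_sd"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.condition_noise_cv < 0.0:
            raise ValueError("condition_noise_cv must be >= 0")
        for name in ("unruptured_amplification", "ruptured_amplification"):
            if getattr(self, name) not in ("empirical", "membrane"):
                raise ValueError(f"{name} must be 'empirical' or 'membrane'")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=int(seed))

    def amplification_for(self, group: str) -> AmplificationMatrix:
        mode = (self.unruptured_amplification if group == "unruptured"
                else self.ruptured_amplification)
        if mode == "membrane":
            return AmplificationMatrix.membrane()
        return AmplificationMatrix.empirical(group)


@dataclass(frozen=True)
class AneurysmRecord:
    """One synthetic aneurysm: rupture label, baseline strain, sweep grid."""

    id: str
    ruptured: bool
    baseline_strain: float
    strain_grid: StrainGrid


def generate_cohort(spec: CohortSpec) -> list[AneurysmRecord]:
    """Generate the labeled cohort described by ``spec``.

    Fully reproducible: the same spec (including seed) yields bit-identical
    records.  Unruptured records come first (ids U01..), then ruptured (R01..).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[AneurysmRecord] = []
    groups = (
        ("unruptured", "U", spec.n_unruptured,
         spec.unruptured_baseline_mean, spec.unruptured_baseline_sd),
        ("ruptured", "R", spec.n_ruptured,
         spec.ruptured_baseline_mean, spec.ruptured_baseline_sd),
    )
    for group, prefix, n, mean, sd in groups:
        amp = spec.amplification_for(group)
        baselines = sample_lognormal(mean, sd, n, rng)
        for k, baseline in enumerate(baselines, start=1):
            grid = condition_sweep(float(baseline), amp,
                                   spec.condition_noise_cv, rng)
            records.append(AneurysmRecord(
                id=f"{prefix}{k:02d}",
                ruptured=(group == "ruptured"),
                baseline_strain=float(baseline),
                strain_grid=grid,
            ))
    return records
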