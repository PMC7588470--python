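"""Thin-walled membrane surrogate for the per-condition wall strain.

A saccular aneurysm under systolic pressure is idealised as a thin-walled
sphere.  Laplace's law gives the equibiaxial membrane stress
sigma = P*R / (2*t); with a linear-elastic wall of Young's modulus E and
Poisson's ratio nu the equibiaxial strain is

    epsilon = P * R * (1 - nu) / (2 * t * E)

so the strain scales exactly as 1/(t*E): halving both wall thickness and
modulus quadruples the strain.  This closed form stands in for a full
fluid-structure interaction run whenever a physically interpretable strain
scale is wanted, and supplies exact oracles for the downstream curve and
area computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def membrane_strain(pressure, radius, thickness, modulus, poisson=0.49):
    """Equibiaxial strain of a pressurised thin-walled sphere.

    Parameters
    ----------
    pressure : float or array
        Transmural pressure in Pa.
    radius : float or array
        Sac radius in m.
    thickness : float or array
        Wall thickness in m; must be > 0.
    modulus : float or array
        Young's modulus in Pa; must be > 0.
    poisson : float
        Poisson's ratio, in [0, 0.5).

    Returns
    -------
    float or ndarray
        Dimensionless equivalent strain P*R*(1-nu) / (2*t*E).
    """
    pressure = np.asarray(pressure, dtype=float)
    radius = np.asarray(radius, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    modulus = np.asarray(modulus, dtype=float)
    if np.any(thickness <= 0.0) or np.any(modulus <= 0.0):
        raise ValueError("wall thickness and Young's modulus must be > 0 "
                         "(a non-positive value signals a degenerate wall)")
    if np.any(pressure <= 0.0) or np.any(radius <= 0.0):
        raise ValueError("pressure and radius must be > 0")
    if not (0.0 <= poisson < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5), got {poisson}")
    strain = pressure * radius * (1.0 - poisson) / (2.0 * thickness * modulus)
    return strain if strain.ndim else float(strain)


@dataclass(frozen=True)
class SurrogateParams:
    """Physical constants of the membrane surrogate.

    Defaults follow the cerebral-artery assumptions of the underlying risk
    analysis: nominal wall thickness 0.2 mm, Young's modulus 2.6 MPa
    (median of measured aneurysm moduli), Poisson's ratio 0.49 (nearly
    incompressible), wall density 1000 kg/m^3 (documentation only — the
    quasi-static membrane balance does not use it), and a failure strain of
    0.3 at which the wall is assumed to rupture.  The default pressure is
    13332 Pa (100 mmHg systolic) and the default sac radius 8.12 mm puts the
    nominal-condition strain at the unruptured-group scale (~0.053).
    """

    systolic_pressure: float = 13332.0    # Pa
    sac_radius: float = 8.12e-3           # m
    nominal_thickness: float = 2.0e-4     # m
    nominal_modulus: float = 2.6e6        # Pa
    poisson_ratio: float = 0.49
    wall_density: float = 1000.0          # kg/m^3, informational
    failure_strain: float = 0.3

    def __post_init__(self) -> None:
        for name in ("systolic_pressure", "sac_radius", "nominal_thickness",
                     "nominal_modulus", "wall_density", "failure_strain"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")

    def baseline_strain(self) -> float:
        """Strain at the nominal (100%, 100%) condition."""
        return membrane_strain(self.systolic_pressure, self.sac_radius,
                               self.nominal_thickness, self.nominal_modulus,
                               self.poisson_ratio)

    def strain_at(self, thickness_fraction: float, modulus_fraction: float) -> float:
        """Strain with thickness and modulus reduced to the given fractions."""
        return membrane_strain(self.systolic_pressure, self.sac_radius,
                               self.nominal_thickness * thickness_fraction,
                               self.nominal_modulus * modulus_fraction,
                               self.poisson_ratio)
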