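"""Containers for the (wall-thickness, Young's-modulus) condition sweep.

Rupture risk is probed by re-running the wall-mechanics analysis of each
aneurysm while the wall thickness and the Young's modulus of the thin-walled
area (TWA) are reduced in four steps — 100%, 75%, 50% and 25% of their
nominal values — giving a 4x4 grid of 16 conditions per aneurysm.  The
scalar recorded per condition is the highest equivalent strain in the TWA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Reduction steps applied to wall thickness and Young's modulus, as
#: fractions of the nominal value, in sweep order (100% first).
FRACTIONS: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)


@dataclass(frozen=True)
class ConditionGrid:
    """The 4x4 design of (thickness fraction, modulus fraction) conditions."""

    thickness_fractions: tuple[float, ...] = FRACTIONS
    modulus_fractions: tuple[float, ...] = FRACTIONS

    def __post_init__(self) -> None:
        for name, fr in (("thickness_fractions", self.thickness_fractions),
                         ("modulus_fractions", self.modulus_fractions)):
            fr = tuple(float(f) for f in fr)
            object.__setattr__(self, name, fr)
            if len(fr) != 4:
                raise ValueError(f"{name} must have exactly 4 levels, got {len(fr)}")
            if any(not (0.0 < f <= 1.0) for f in fr):
                raise ValueError(f"{name} must lie in (0, 1]: {fr}")
            if any(a <= b for a, b in zip(fr, fr[1:])):
                raise ValueError(f"{name} must be strictly decreasing: {fr}")

    def conditions(self) -> Iterator[tuple[float, float]]:
        """All 16 (tau, eta) pairs, thickness-major (the tabular order)."""
        for tau in self.thickness_fractions:
            for eta in self.modulus_fractions:
                yield tau, eta

    def index(self, tau: float, eta: float) -> tuple[int, int]:
        try:
            return (self.thickness_fractions.index(tau),
                    self.modulus_fractions.index(eta))
        except ValueError:
            raise KeyError(f"({tau}, {eta}) is not a sweep condition") from None


@dataclass(frozen=True)
class StrainGrid:
    """Per-aneurysm 4x4 matrix of highest TWA equivalent strain.

    ``values[i, j]`` is the strain at thickness fraction
    ``conditions.thickness_fractions[i]`` and modulus fraction
    ``conditions.modulus_fractions[j]``.  All 16 entries must be finite and
    strictly positive (an equivalent strain of a pressurised wall).
    """

    values: np.ndarray
    conditions: ConditionGrid = field(default_factory=ConditionGrid)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (4, 4):
            raise ValueError(f"strain grid must be 4x4, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("strain grid contains non-finite entries")
        if not np.all(v > 0.0):
            raise ValueError("strain grid entries must be strictly positive")

    def __getitem__(self, key: tuple[float, float]) -> float:
        i, j = self.conditions.index(*key)
        return float(self.values[i, j])

    def items(self) -> Iterator[tuple[tuple[float, float], float]]:
        for tau, eta in self.conditions.conditions():
            yield (tau, eta), self[tau, eta]
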