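"""Readers, writers and run configuration.

File conventions: sweep grids and NA tables travel as plain CSV with
fraction coordinates ({1.0, 0.75, 0.5, 0.25}); critical-curve polylines are
written in percent (the plotting convention); reports are JSON.  Cohort
files carry the generator seed in a ``# seed = N`` header comment so a run
is reproducible from its own output.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AneurysmRecord, CohortSpec
from .grids import FRACTIONS, StrainGrid
from .surface import CriticalCurve

__all__ = [
    "CohortFormatError",
    "PipelineConfig",
    "config_hash",
    "load_config",
    "read_cohort_csv",
    "read_na_csv",
    "write_cohort_csv",
    "write_curves_csv",
    "write_na_csv",
]

COHORT_COLUMNS = ("aneurysm_id", "ruptured", "thickness_fraction",
                  "modulus_fraction", "equivalent_strain")


class CohortFormatError(ValueError):
    """A cohort CSV violates the long-format contract."""


def write_cohort_csv(records: list[AneurysmRecord], path, seed: int | None = None
                     ) -> None:
    """Write a cohort in long format, one 16-row block per aneurysm."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed = {int(seed)}\n")
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            for (tau, eta), strain in rec.strain_grid.items():
                writer.writerow([rec.id, int(rec.ruptured), tau, eta,
                                 repr(float(strain))])


def read_cohort_csv(path) -> list[AneurysmRecord]:
    """Read a long-format cohort CSV back into validated records.

    Every aneurysm must contribute exactly the 16 sweep conditions with
    strictly positive strains and a consistent 0/1 rupture label; errors
    name the offending row (1-based, counting header and comment lines).
    """
    path = Path(path)
    grids: dict[str, dict[tuple[float, float], float]] = {}
    labels: dict[str, bool] = {}
    order: list[str] = []
    allowed = set(FRACTIONS)
    with path.open(newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            row = next(csv.reader([line]))
            if not header_seen:
                if tuple(h.strip() for h in row) != COHORT_COLUMNS:
                    raise CohortFormatError(
                        f"row {lineno}: expected header {','.join(COHORT_COLUMNS)}")
                header_seen = True
                continue
            if len(row) != 5:
                raise CohortFormatError(f"row {lineno}: expected 5 fields, got {len(row)}")
            aid, label_s, tau_s, eta_s, strain_s = (f.strip() for f in row)
            if label_s not in ("0", "1"):
                raise CohortFormatError(
                    f"row {lineno}: rupture label must be 0 or 1, got {label_s!r}")
            try:
                tau, eta = float(tau_s), float(eta_s)
                strain = float(strain_s)
            except ValueError as exc:
                raise CohortFormatError(f"row {lineno}: {exc}") from None
            if tau not in allowed or eta not in allowed:
                raise CohortFormatError(
                    f"row {lineno}: ({tau}, {eta}) is not a sweep condition")
            if not (np.isfinite(strain) and strain > 0.0):
                raise CohortFormatError(
                    f"row {lineno}: equivalent strain must be finite and > 0, "
                    f"got {strain_s}")
            ruptured = label_s == "1"
            if aid in labels and labels[aid] != ruptured:
                raise CohortFormatError(
                    f"row {lineno}: inconsistent rupture label for {aid!r}")
            if aid not in grids:
                grids[aid] = {}
                labels[aid] = ruptured
                order.append(aid)
            if (tau, eta) in grids[aid]:
                raise CohortFormatError(
                    f"row {lineno}: duplicate condition ({tau}, {eta}) for {aid!r}")
            grids[aid][(tau, eta)] = strain
    if not header_seen:
        raise CohortFormatError("empty file: no header row")
    records = []
    for aid in order:
        cells = grids[aid]
        missing = [ce for ce in
                   ((t, e) for t in FRACTIONS for e in FRACTIONS)
                   if ce not in cells]
        if missing:
            raise CohortFormatError(
                f"aneurysm {aid!r}: missing condition(s) "
                + ", ".join(f"({t}, {e})" for t, e in missing))
        values = np.array([[cells[(t, e)] for e in FRACTIONS]
                           for t in FRACTIONS])
        grid = StrainGrid(values)
        records.append(AneurysmRecord(id=aid, ruptured=labels[aid],
                                      baseline_strain=grid[1.0, 1.0],
                                      strain_grid=grid))
    return records


def write_na_csv(na_table: pd.DataFrame, path) -> None:
    """Write a per-aneurysm NA table (aneurysm_id, ruptured, na)."""
    na_table.to_csv(path, index=False,
                    columns=["aneurysm_id", "ruptured", "na"])


def read_na_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"aneurysm_id", "ruptured", "na"} - set(df.columns)
    if missing:
        raise CohortFormatError(f"NA table missing columns: {sorted(missing)}")
    if not df["na"].between(0.0, 1.0).all():
        raise CohortFormatError("NA values must lie in [0, 1]")
    return df


def write_curves_csv(curves: dict[str, CriticalCurve], path) -> None:
    """Write critical-curve polylines; coordinates in percent of nominal."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["aneurysm_id", "vertex_index",
                         "thickness_pct", "modulus_pct"])
        for aid, curve in curves.items():
            for k, (tau, eta) in enumerate(curve.vertices()):
                writer.writerow([aid, k, repr(100.0 * tau), repr(100.0 * eta)])


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full risk-analysis run."""

    n_unruptured: int = 27
    n_ruptured: int = 24
    unruptured_baseline_mean: float = 0.053
    unruptured_baseline_sd: float = 0.026
    ruptured_baseline_mean: float = 0.094
    ruptured_baseline_sd: float = 0.048
    condition_noise_cv: float = 0.10
    amplification: str = "empirical"
    t_test: str = "student"
    failure_strain: float = 0.3
    contour_resolution: int = 256
    quadrature_resolution: int = 512
    reference_na: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.failure_strain <= 0.0:
            raise ValueError("failure_strain must be > 0")
        if self.contour_resolution < 32 or self.quadrature_resolution < 32:
            raise ValueError("resolutions must be >= 32")
        if self.amplification not in ("empirical", "membrane"):
            raise ValueError("amplification must be 'empirical' or 'membrane'")
        if self.t_test not in ("student", "welch"):
            raise ValueError("t_test must be 'student' or 'welch'")
        if self.reference_na is not None and not (0.0 < self.reference_na < 1.0):
            raise ValueError("reference_na must lie strictly in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        fields = set(cls.__dataclass_fields__)
        unknown = set(mapping) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_unruptured=self.n_unruptured,
            n_ruptured=self.n_ruptured,
            unruptured_baseline_mean=self.unruptured_baseline_mean,
            unruptured_baseline_sd=self.unruptured_baseline_sd,
            ruptured_baseline_mean=self.ruptured_baseline_mean,
            ruptured_baseline_sd=self.ruptured_baseline_sd,
            condition_noise_cv=self.condition_noise_cv,
            unruptured_amplification=self.amplification,
            ruptured_amplification=self.amplification,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of a config, embedded in reports."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Parse a plain-text ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; values are coerced to int,
    float, or the strings/None they spell.
    """
    mapping: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in stripped.split("=", 1))
        mapping[key] = _coerce(value)
    return PipelineConfig.from_mapping(mapping)


def _coerce(value: str):
    if value.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
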