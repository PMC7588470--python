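"""End-to-end risk analysis: cohort -> NA table -> ROC/Youden report."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import AneurysmRecord, generate_cohort
from .io import PipelineConfig, config_hash
from .stats import (RocResult, YoudenResult, condition_summary, roc_and_auc,
                    youden_cutoff)
from .surface import extract_critical_curve, fit_surface, normalized_area

__all__ = ["build_report", "classify_na", "cohort_critical_curves",
           "cohort_na_table"]


def cohort_na_table(records: Sequence[AneurysmRecord],
                    failure_strain: float = 0.3,
                    resolution: int = 512) -> pd.DataFrame:
    """Per-aneurysm normalized area: columns aneurysm_id, ruptured, na."""
    rows = [{"aneurysm_id": rec.id,
             "ruptured": int(rec.ruptured),
             "na": normalized_area(fit_surface(rec.strain_grid),
                                   level=failure_strain,
                                   resolution=resolution)}
            for rec in records]
    return pd.DataFrame(rows, columns=["aneurysm_id", "ruptured", "na"])


def cohort_critical_curves(records: Sequence[AneurysmRecord],
                           failure_strain: float = 0.3,
                           resolution: int = 256) -> dict:
    """Critical curve per aneurysm, keyed by id."""
    return {rec.id: extract_critical_curve(fit_surface(rec.strain_grid),
                                           level=failure_strain,
                                           resolution=resolution)
            for rec in records}


def classify_na(na_table: pd.DataFrame) -> tuple[RocResult, YoudenResult]:
    """ROC/AUC and Youden operating point of an NA table."""
    roc = roc_and_auc(na_table["na"].to_numpy(),
                      na_table["ruptured"].to_numpy().astype(bool))
    return roc, youden_cutoff(roc)


def build_report(config: PipelineConfig) -> dict:
    """Run the full pipeline and assemble a self-contained JSON-able report.

    Re-running with the echoed config reproduces the report bit for bit.
    """
    records = generate_cohort(config.cohort_spec())
    na_table = cohort_na_table(records, failure_strain=config.failure_strain,
                               resolution=config.quadrature_resolution)
    summary = condition_summary(records,
                                equal_var=(config.t_test == "student"))
    roc, youden = classify_na(na_table)
    return {
        "software": {"name": "strainrisk", "version": __version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "na_table": na_table.to_dict(orient="records"),
        "condition_summary": summary.to_dict(orient="records"),
        "roc": {
            "points": [[float(x), float(y)] for x, y in roc.points],
            "thresholds": [float(t) for t in roc.thresholds],
            "auc": roc.auc,
        },
        "youden": {
            "cutoff": youden.cutoff,
            "youden_j": youden.youden_j,
            "sensitivity_pct": youden.sensitivity,
            "specificity_pct": youden.specificity,
            "confusion": {"tp": youden.tp, "fp": youden.fp,
                          "tn": youden.tn, "fn": youden.fn},
        },
    }
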