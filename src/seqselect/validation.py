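"""Reliability, bias and economic-value summaries for genomic predictions.

Simulation-style validation scores predictions against true breeding
values; real-data-style validation scores them against later deregressed
evaluations, divides by the mean reliability of those evaluations to
strip their error variance, and adds the observed-minus-expected parent
average reliability to account for prior selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ReliabilityReport:
    """Per-trait validation summary (reliability in %, slope unitless)."""

    trait: str
    reliability: float
    slope: float
    n_validation: int
    method: str  # 'tbv' or 'deregressed'

    def __post_init__(self) -> None:
        if not 0.0 <= self.reliability <= 100.0:
            raise ValueError("reliability must be in [0, 100]")


def reliability_vs_tbv(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """100 x squared correlation of predictions with true breeding values."""
    gebv = np.asarray(gebv, dtype=np.float64).ravel()
    tbv = np.asarray(tbv, dtype=np.float64).ravel()
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation animals")
    if gebv.std() == 0 or tbv.std() == 0:
        raise ValueError("zero variance in predictions or TBV")
    r = np.corrcoef(gebv, tbv)[0, 1]
    return float(100.0 * r**2)


def validation_reliability_deregressed(
    pred: np.ndarray,
    dereg: np.ndarray,
    rel_dereg: np.ndarray,
    pa_obs_rel: float = 0.0,
    pa_exp_rel: float = 0.0,
) -> float:
    """Real-data-style reliability (%).

    100 cor(pred, dereg)^2 / mean(rel_dereg) + (pa_obs_rel - pa_exp_rel),
    capped at 100 with a warning.  ``rel_dereg`` are the reliabilities of
    the deregressed evaluations, in (0, 1].
    """
    rel = np.asarray(rel_dereg, dtype=np.float64)
    if ((rel <= 0) | (rel > 1)).any():
        raise ValueError("deregressed reliabilities must be in (0, 1]")
    mean_rel = rel.mean()
    if mean_rel == 0:
        raise ValueError("mean deregressed reliability is zero")
    base = reliability_vs_tbv(pred, dereg) / mean_rel
    out = base + (pa_obs_rel - pa_exp_rel)
    if out > 100.0:
        logger.warning("reliability %.1f capped at 100", out)
        out = 100.0
    return float(out)


def regression_slope(dereg: np.ndarray, pred: np.ndarray) -> float:
    """Least-squares slope of validation data on predictions.

    A slope near the expectation of 1.0 indicates unbiased predictions.
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    dereg = np.asarray(dereg, dtype=np.float64).ravel()
    if len(pred) < 3:
        raise ValueError("need at least 3 animals")
    xc = pred - pred.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("zero predictor variance")
    return float(xc @ (dereg - dereg.mean()) / sxx)


def expected_pa_reliability(rel_sire: np.ndarray, rel_dam: np.ndarray) -> float:
    """Selection-index expectation for parent-average reliability (%).

    mean of (rel_sire + rel_dam)/4 — the standard convention when the
    true expectation is not supplied; inputs in percent.
    """
    return float(np.mean((np.asarray(rel_sire) + np.asarray(rel_dam)) / 4.0))


def accuracy_ratio(rel_new: float, rel_old: float) -> float:
    """sqrt(rel_new / rel_old): the accuracy gain implied by a
    reliability gain (both in the same units)."""
    if rel_new < 0 or rel_old < 0:
        raise ValueError("reliabilities must be non-negative")
    if rel_old == 0:
        raise ValueError("old reliability must be positive")
    return float(np.sqrt(rel_new / rel_old))


def annual_value(
    progress_per_cow: float, ratio: float, replacements: float
) -> float:
    """Annual value of extra accuracy: progress x (ratio - 1) x replacements.

    E.g. $50 annual progress per cow, accuracy ratio 1.02 and 3.3 million
    replacement cows gives about $3.3 million per year.
    """
    if progress_per_cow < 0 or ratio < 0 or replacements < 0:
        raise ValueError("inputs must be non-negative")
    return float(progress_per_cow * (ratio - 1.0) * replacements)


def reliability_table(reports) -> pd.DataFrame:
    """Tidy frame (trait, scenario, reliability, slope, n) from reports.

    ``reports`` maps scenario name -> list of ReliabilityReport.
    """
    rows = []
    for scenario, reps in reports.items():
        for r in reps:
            rows.append(
                (r.trait, scenario, r.reliability, r.slope, r.n_validation, r.method)
            )
    return pd.DataFrame(
        rows,
        columns=["trait", "scenario", "reliability", "slope", "n_validation", "method"],
    )
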