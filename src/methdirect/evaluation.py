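"""Scoring predicted against true per-CpG methylation rates.

The evaluation universe is restricted to "mappable" CpGs (coverage
strictly greater than a threshold, default 5 reads).  A mappable CpG
without any mapped read receives a maximally wrong prediction (0 when the
truth is above 0.5, 1 when below) before RMSE and Spearman correlation
are computed, penalising tools that fail to cover coverable regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st


@dataclass(frozen=True)
class EvalResult:
    rmse: float
    spearman: float
    n_missed: int      # mappable CpGs without any mapped read
    n_mappable: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "spearman": self.spearman,
                "n_missed": self.n_missed, "n_mappable": self.n_mappable}


def mappable_cpgs(coverages, threshold: int = 5) -> np.ndarray:
    """Boolean mask of CpGs with coverage strictly greater than ``threshold``."""
    return np.asarray(coverages) > threshold


def apply_missing_penalty(truth, prediction, covered_flag) -> np.ndarray:
    """Complete predictions at uncovered CpGs with the maximally wrong rate.

    Uncovered with truth > 0.5 -> 0; truth < 0.5 -> 1; truth exactly 0.5
    -> 0 (fixed choice; measure-zero under continuous truth).  Covered
    entries pass through unchanged.
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.array(prediction, dtype=float, copy=True)
    covered = np.asarray(covered_flag, dtype=bool)
    missing = ~covered
    pred[missing & (truth >= 0.5)] = 0.0
    pred[missing & (truth < 0.5)] = 1.0
    return pred


def rmse(truth, prediction) -> float:
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if truth.size == 0:
        raise ValueError("empty CpG set")
    return float(np.sqrt(np.mean((truth - pred) ** 2)))


def spearman(truth, prediction) -> float:
    """Rank correlation with average ranks; NaN for a constant vector."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(prediction, dtype=float)
    if truth.size < 2 or np.all(truth == truth[0]) or np.all(pred == pred[0]):
        return float("nan")
    return float(_st.spearmanr(truth, pred).statistic)


def evaluate(true_rates, predicted_rates, coverage, threshold: int = 5,
             mappable_mask=None) -> EvalResult:
    """Full scoring pipeline over one tool's output.

    ``predicted_rates`` may hold NaN at uncovered CpGs.  ``mappable_mask``
    overrides the own-coverage mappability rule (e.g. when another tool's
    coverage defines the universe); by default CpGs this run covered with
    more than ``threshold`` reads are evaluated.
    """
    truth = np.asarray(true_rates, dtype=float)
    pred = np.asarray(predicted_rates, dtype=float)
    coverage = np.asarray(coverage)
    if mappable_mask is None:
        mappable = mappable_cpgs(coverage, threshold)
    else:
        mappable = np.asarray(mappable_mask, dtype=bool)
    t = truth[mappable]
    p = pred[mappable]
    covered = coverage[mappable] > 0
    p = apply_missing_penalty(t, np.where(covered, p, 0.0), covered)
    return EvalResult(
        rmse=rmse(t, p),
        spearman=spearman(t, p),
        n_missed=int(np.sum(~covered)),
        n_mappable=int(mappable.sum()),
    )
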