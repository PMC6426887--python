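"""Benchmarking segmenters against expert dotting.

Predicted centroids are matched one-to-one to ground-truth dots within a
tolerance radius (default 8 px) by an exact maximum-cardinality assignment;
recall and precision follow.  Density agreement between manual and
automated estimates is summarized by Pearson R^2 and the fraction of images
inside +/-250 and +/-500 cells/mm^2 corridors, and ungradable-image
detection by a 2x2 expert-vs-automatic cross-tabulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io import CentroidSet

__all__ = [
    "MatchReport",
    "AgreementReport",
    "match_centroids",
    "compute_recall_precision",
    "density_agreement",
    "ungradable_crosstab",
]

_BIG = 1e9  # penalty for out-of-tolerance pairs; >> any feasible total distance


@dataclass(frozen=True)
class MatchReport:
    image_id: str
    n_truth: int
    n_pred: int
    n_matched: int
    recall: float  # NaN when undefined (n_truth == 0)
    precision: float  # NaN when undefined (n_pred == 0)
    tolerance_px: float = 8.0


@dataclass(frozen=True)
class AgreementReport:
    n_images: int
    r_squared: float  # NaN when fewer than 2 pairs or zero variance
    pct_within_250: float
    pct_within_500: float


def match_centroids(
    pred: CentroidSet, truth: CentroidSet, tolerance_px: float = 8.0
) -> MatchReport:
    """One-to-one matching maximizing the number of pairs within tolerance.

    Solved exactly as an assignment problem: infeasible pairs carry a large
    penalty, so the optimum first maximizes the count of within-tolerance
    pairs and then minimizes their total distance.
    """
    np_, nt = len(pred), len(truth)
    if np_ and nt:
        d = cdist(pred.points, truth.points)
        cost = np.where(d <= tolerance_px, d, _BIG)
        rows, cols = linear_sum_assignment(cost)
        n_matched = int((cost[rows, cols] < _BIG).sum())
    else:
        n_matched = 0
    recall = n_matched / nt if nt else math.nan
    precision = n_matched / np_ if np_ else math.nan
    return MatchReport(
        image_id=truth.image_id or pred.image_id,
        n_truth=nt,
        n_pred=np_,
        n_matched=n_matched,
        recall=recall,
        precision=precision,
        tolerance_px=tolerance_px,
    )


def compute_recall_precision(report: MatchReport) -> tuple:
    """(recall, precision) per the centroid-count definitions; NaN where the
    denominator is zero."""
    return report.recall, report.precision


def density_agreement(pairs, corridors=(250.0, 500.0)) -> AgreementReport:
    """Agreement between (manual, automated) densities in cells/mm^2."""
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    n = len(arr)
    if n >= 2 and arr[:, 0].std() > 0 and arr[:, 1].std() > 0:
        r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        r2 = r * r
    else:
        r2 = math.nan
    diff = np.abs(arr[:, 0] - arr[:, 1]) if n else np.empty(0)
    pct = [100.0 * float((diff <= c).mean()) if n else math.nan for c in corridors]
    return AgreementReport(n_images=n, r_squared=r2, pct_within_250=pct[0], pct_within_500=pct[1])


def ungradable_crosstab(results) -> np.ndarray:
    """2x2 counts; rows = expert (gradable, ungradable), cols = automatic."""
    table = np.zeros((2, 2), dtype=int)
    for expert, auto in results:
        table[int(bool(expert)), int(bool(auto))] += 1
    return table
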