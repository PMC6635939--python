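"""Distance-based barcoding gap analysis and group identification.

Two leave-one-out classifiers are provided: minimum distance (MD) assigns a
query to the group of its nearest reference, and best close match (BCM)
additionally rejects queries whose nearest reference lies beyond a
within-group distance threshold (default: the 95th percentile of within-group
distances). Success rates are replicated by bootstrap resampling of the
query set; ambiguous and unidentified queries count as failures for the
headline rate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .distances import (
    DistanceMatrix,
    WithinBetweenSummary,
    distance_matrix,
    within_between_summary,
)
from .errors import EstimationError, InputError
from .io import Alignment, PopulationMap

log = logging.getLogger("phylopop.barcode")


class Outcome(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    AMBIGUOUS = "ambiguous"
    NO_IDENTIFICATION = "no-identification"


@dataclass(frozen=True)
class GapSummary:
    """Within/between distance distributions and the gap indicator."""

    summary: WithinBetweenSummary
    gap_positive: bool
    max_within: float
    min_between: float
    bins: tuple[float, ...]
    within_hist: tuple[int, ...]
    between_hist: tuple[int, ...]

    def to_dict(self) -> dict:
        d = self.summary.to_dict()
        d.update(
            {
                "gap_positive": self.gap_positive,
                "max_within": self.max_within,
                "min_between": self.min_between,
                "bins": list(self.bins),
                "within_hist": list(self.within_hist),
                "between_hist": list(self.between_hist),
            }
        )
        return d


def barcoding_gap(
    dm: DistanceMatrix,
    pm: PopulationMap,
    level: str = "population",
    n_bins: int = 30,
) -> GapSummary:
    """Within/between distance distributions; gap positive iff
    min(between) > max(within)."""
    summ = within_between_summary(dm, pm, level=level)
    if not summ.between:
        raise EstimationError("no between-group pairs")
    max_w = max(summ.within)
    min_b = min(summ.between)
    hi = max(max(summ.within), max(summ.between))
    bins = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    wh, _ = np.histogram(summ.within, bins=bins)
    bh, _ = np.histogram(summ.between, bins=bins)
    return GapSummary(
        summary=summ,
        gap_positive=bool(min_b > max_w),
        max_within=float(max_w),
        min_between=float(min_b),
        bins=tuple(float(b) for b in bins),
        within_hist=tuple(int(v) for v in wh),
        between_hist=tuple(int(v) for v in bh),
    )


def _classify_row(
    row: np.ndarray,
    self_idx: int,
    labels: list[str],
    threshold: float | None,
) -> Outcome:
    d = row.copy()
    d[self_idx] = np.inf
    d = np.where(np.isnan(d), np.inf, d)
    dmin = d.min()
    if not math.isfinite(dmin):
        raise EstimationError("query has no usable reference distances")
    if threshold is not None and dmin > threshold:
        return Outcome.NO_IDENTIFICATION
    nearest = {labels[i] for i in np.flatnonzero(d <= dmin + 1e-12)}
    if len(nearest) > 1:
        return Outcome.AMBIGUOUS
    return (
        Outcome.CORRECT
        if nearest.pop() == labels[self_idx]
        else Outcome.INCORRECT
    )


def classify_md(
    query_id: str, dm: DistanceMatrix, pm: PopulationMap, level: str = "population"
) -> Outcome:
    """Minimum-distance leave-one-out classification of one query."""
    if dm.n < 2:
        raise InputError("empty reference set")
    labels = pm.labels_for(dm.ids, level=level)
    idx = dm.index_of(query_id)
    return _classify_row(dm.matrix[idx], idx, labels, threshold=None)


def default_bcm_threshold(
    dm: DistanceMatrix, pm: PopulationMap, level: str = "population"
) -> float:
    """95th percentile of all within-group pairwise distances."""
    summ = within_between_summary(dm, pm, level=level)
    return float(np.percentile(summ.within, 95.0))


def classify_bcm(
    query_id: str,
    dm: DistanceMatrix,
    pm: PopulationMap,
    level: str = "population",
    threshold: float | None = None,
) -> Outcome:
    """Best-close-match classification: MD plus a distance-threshold gate."""
    if dm.n < 2:
        raise InputError("empty reference set")
    if threshold is None:
        threshold = default_bcm_threshold(dm, pm, level)
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    labels = pm.labels_for(dm.ids, level=level)
    idx = dm.index_of(query_id)
    return _classify_row(dm.matrix[idx], idx, labels, threshold=threshold)


@dataclass(frozen=True)
class IdentificationReport:
    """Leave-one-out identification outcomes and bootstrap success rates."""

    method: str
    level: str
    outcomes: dict[str, str]  # query id -> outcome value
    rates: tuple[float, ...]  # per-replication success rates
    mean_rate: float
    ci_low: float
    ci_high: float
    n_replications: int
    bcm_threshold: float | None

    @property
    def outcome_counts(self) -> dict[str, int]:
        counts = {o.value: 0 for o in Outcome}
        for v in self.outcomes.values():
            counts[v] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "level": self.level,
            "outcome_counts": self.outcome_counts,
            "mean_success_rate": self.mean_rate,
            "ci95": [self.ci_low, self.ci_high],
            "ci_method": "normal approximation over replication rates",
            "n_replications": self.n_replications,
            "bcm_threshold": self.bcm_threshold,
        }


def loo_success(
    aln: Alignment,
    pm: PopulationMap,
    method: str = "md",
    level: str = "population",
    n_reps: int = 500,
    seed: int | None = None,
    metric: str = "k2p",
    threshold: float | None = None,
) -> IdentificationReport:
    """Leave-one-out identification with bootstrap-replicated success rates.

    Each replication draws N query ids with replacement; the per-query
    outcome is the deterministic leave-one-out classification. The 95% CI is
    mean +/- 1.96 * SD of the replication rates.
    """
    method = method.lower()
    if method not in ("md", "bcm"):
        raise InputError(f"unknown method: {method!r}")
    pm.validate_against(aln)
    labels = pm.labels_for(aln.ids, level=level)
    if len(set(labels)) < 2:
        raise EstimationError("need >= 2 groups at the chosen level")
    dm = distance_matrix(aln, metric=metric)
    thr = None
    if method == "bcm":
        thr = (
            default_bcm_threshold(dm, pm, level)
            if threshold is None
            else threshold
        )
    outcomes: dict[str, str] = {}
    correct = np.zeros(aln.n, dtype=bool)
    for i, sid in enumerate(aln.ids):
        out = _classify_row(dm.matrix[i], i, labels, threshold=thr)
        outcomes[sid] = out.value
        correct[i] = out is Outcome.CORRECT
    rng = np.random.default_rng(seed)
    rates = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.integers(0, aln.n, size=aln.n)
        rates[r] = correct[draw].mean()
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if n_reps > 1 else 0.0
    lo = max(0.0, mean - 1.96 * sd)
    hi = min(1.0, mean + 1.96 * sd)
    return IdentificationReport(
        method=method,
        level=level,
        outcomes=outcomes,
        rates=tuple(float(x) for x in rates),
        mean_rate=mean,
        ci_low=lo,
        ci_high=hi,
        n_replications=n_reps,
        bcm_threshold=thr,
    )
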