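"""Threshold tuning and operating-point statistics for scored cohorts.

Positive call convention: a case is flagged when ``score >= threshold``.
Candidate thresholds are midpoints between adjacent sorted unique scores
plus the two infinities, which makes the Youden search exhaustive and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoredCohort",
    "roc_auc",
    "roc_curve_points",
    "select_threshold",
    "operating_metrics",
    "bootstrap_ci",
    "OperatingMetrics",
]


@dataclass
class ScoredCohort:
    case_ids: list[str]
    scores: np.ndarray
    is_emergency: np.ndarray
    categories: list[str] | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.is_emergency = np.asarray(self.is_emergency, dtype=bool)
        n = len(self.case_ids)
        if self.scores.shape != (n,) or self.is_emergency.shape != (n,):
            raise ValueError("case_ids, scores, and labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.case_ids)

    def subset(self, idx) -> "ScoredCohort":
        idx = np.asarray(idx)
        return ScoredCohort(
            [self.case_ids[i] for i in idx],
            self.scores[idx],
            self.is_emergency[idx],
            [self.categories[i] for i in idx] if self.categories else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "case_id": self.case_ids,
                "score": self.scores,
                "is_emergency": self.is_emergency,
            }
        )
        if self.categories:
            df["category"] = self.categories
        return df


def _check_two_classes(cohort: ScoredCohort) -> None:
    if cohort.is_emergency.all() or not cohort.is_emergency.any():
        raise ValueError("cohort must contain both emergency and non-emergency cases")


def roc_curve_points(cohort: ScoredCohort) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) over all candidate thresholds."""
    _check_two_classes(cohort)
    rows = []
    for thr in _candidate_thresholds(cohort.scores):
        m = operating_metrics(cohort, thr)
        rows.append(
            {"threshold": thr, "sensitivity": m.sensitivity, "specificity": m.specificity}
        )
    return pd.DataFrame(rows)


def roc_auc(cohort: ScoredCohort) -> float:
    """Trapezoidal ROC area; equals Mann-Whitney concordance with ties
    counted one half."""
    _check_two_classes(cohort)
    pos = cohort.scores[cohort.is_emergency]
    neg = cohort.scores[~cohort.is_emergency]
    # rank-based concordance (exactly the trapezoidal ROC area)
    combined = np.concatenate([pos, neg])
    order = combined.argsort(kind="mergesort")
    ranks = np.empty_like(combined)
    ranks[order] = np.arange(1, combined.size + 1, dtype=np.float64)
    # midrank ties
    uniq, inv, counts = np.unique(combined, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        sums = np.zeros(uniq.size)
        np.add.at(sums, inv, ranks)
        ranks = (sums / counts)[inv]
    r_pos = ranks[: pos.size].sum()
    n1, n0 = pos.size, neg.size
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


@dataclass
class OperatingMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    false_negatives: list[str] = field(default_factory=list)
    false_positives: list[str] = field(default_factory=list)

    @property
    def false_negative_rate(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def false_positive_rate(self) -> float:
        return 1.0 - self.specificity


def operating_metrics(cohort: ScoredCohort, threshold: float) -> OperatingMetrics:
    """Confusion-matrix ratios plus explicit miss/false-alarm case lists."""
    called = cohort.scores >= threshold
    pos = cohort.is_emergency
    tp = int((called & pos).sum())
    tn = int((~called & ~pos).sum())
    fn_idx = np.flatnonzero(~called & pos)
    fp_idx = np.flatnonzero(called & ~pos)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return OperatingMetrics(
        threshold=float(threshold),
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
        accuracy=(tp + tn) / len(cohort),
        false_negatives=[cohort.case_ids[i] for i in fn_idx],
        false_positives=[cohort.case_ids[i] for i in fp_idx],
    )


def select_threshold(
    tuning: ScoredCohort, policy: str = "youden", sensitivity_level: float | None = None
) -> float:
    """Threshold from the tuning cohort.

    ``youden``: maximises sensitivity + specificity - 1, ties resolved
    toward the lowest threshold (higher sensitivity).
    ``sensitivity_level``: the largest candidate threshold whose tuning
    sensitivity is at least the requested level.
    """
    _check_two_classes(tuning)
    cands = _candidate_thresholds(tuning.scores)
    if policy == "youden":
        best_thr, best_j = None, -np.inf
        for thr in cands:
            m = operating_metrics(tuning, thr)
            j = m.sensitivity + m.specificity - 1.0
            if j > best_j:
                best_j, best_thr = j, thr
        return float(best_thr)
    if policy == "sensitivity_level":
        if sensitivity_level is None:
            raise ValueError("sensitivity_level policy requires a target level")
        ok = [
            thr
            for thr in cands
            if operating_metrics(tuning, thr).sensitivity >= sensitivity_level
        ]
        if not ok:
            raise ValueError(
                f"no threshold attains tuning sensitivity {sensitivity_level}"
            )
        return float(max(ok))
    raise ValueError(f"unknown policy {policy!r}")


def bootstrap_ci(
    cohort: ScoredCohort,
    statistic,
    iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    max_retries: int = 1000,
) -> tuple[float, float, float]:
    """Seeded percentile bootstrap over case resampling.

    ``statistic`` maps a :class:`ScoredCohort` to a float; resamples on
    which it raises ``ValueError`` (e.g. a single-class draw) are redrawn
    up to ``max_retries`` times.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    point = float(statistic(cohort))
    vals = np.empty(iterations)
    for it in range(iterations):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                vals[it] = float(statistic(cohort.subset(idx)))
                break
            except ValueError:
                if attempt == max_retries:
                    raise ValueError(
                        "bootstrap exceeded the retry cap on degenerate resamples"
                    )
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, float(lo), float(hi)
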