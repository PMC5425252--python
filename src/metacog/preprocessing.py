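"""Trial/subject exclusion rules and equal-count confidence binning.

The analysis keeps only trials suitable for signal-detection estimates:
the first block is dropped wholesale (staircase burn-in), as are trials
with anticipatory (< 100 ms), late (> 1500 ms) or missing responses.
Low- and high-variance trials are pooled.  Poorly performing subjects are
flagged with the lower Tukey boxplot fence on accuracy.  Continuous
confidence ratings are discretised per subject into six equal-count
(quantile) bins for the type-II ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "exclude_trials",
    "detect_outlier_subjects",
    "bin_confidence",
    "bin_cohort_confidence",
]

_REQUIRED = ("block", "rt_ms", "response", "confidence")


@dataclass
class ExclusionReport:
    """Accounting of trial-level exclusions; arithmetic always balances."""

    n_trials_in: int
    n_removed_block1: int
    n_removed_fast: int
    n_removed_late_or_missing: int
    n_trials_out: int
    excluded_subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = self.n_removed_block1 + self.n_removed_fast + self.n_removed_late_or_missing
        assert self.n_trials_out == self.n_trials_in - removed

    def to_dict(self) -> dict:
        return asdict(self)


def exclude_trials(
    trials: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = (100.0, 1500.0),
    drop_first_block: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply trial-level exclusions, returning the kept rows and a report.

    Removal categories are counted disjointly in this order: block-1
    trials; anticipatory trials (rt < lower bound); late (rt > upper
    bound), missing-response or missing-confidence trials.  A 144-trial
    session with no response-time violations keeps 108 trials.
    """
    missing_cols = [c for c in _REQUIRED if c not in trials.columns]
    if missing_cols:
        raise KeyError(f"trial table lacks required columns: {missing_cols}")
    lo, hi = rt_bounds_ms

    n_in = len(trials)
    block1 = (trials["block"] == 1) if drop_first_block else pd.Series(False, index=trials.index)
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    fast = ~block1 & (rt < lo)
    bad = (
        rt.isna()
        | (rt > hi)
        | (trials["response"].isna())
        | (trials["response"] == "missing")
        | (trials["confidence"].isna())
    )
    late_or_missing = ~block1 & ~fast & bad

    keep = ~(block1 | fast | late_or_missing)
    out = trials.loc[keep].copy()
    report = ExclusionReport(
        n_trials_in=n_in,
        n_removed_block1=int(block1.sum()),
        n_removed_fast=int(fast.sum()),
        n_removed_late_or_missing=int(late_or_missing.sum()),
        n_trials_out=len(out),
    )
    return out, report


def detect_outlier_subjects(accuracy_by_subject) -> list:
    """Subjects below the lower Tukey fence (Q1 - 1.5 IQR) on accuracy.

    Only the lower fence is applied: the exclusion targets subjects who
    perform worse than the rest, never better.  Quartiles use linear
    interpolation between order statistics.
    """
    items = dict(accuracy_by_subject)
    if len(items) < 4:
        raise ValueError("need at least 4 subjects to compute boxplot fences")
    acc = np.asarray(list(items.values()), dtype=float)
    q1, q3 = np.quantile(acc, [0.25, 0.75])
    fence = q1 - 1.5 * (q3 - q1)
    return [sid for sid, a in items.items() if a < fence]


def bin_confidence(confidence, n_bins: int = 6) -> np.ndarray:
    """Equal-count (quantile) binning of one subject's confidence ratings.

    Bin k spans the ((k-1)/n, k/n] empirical quantile interval; a rating
    lying exactly on a boundary takes the lower bin, so ties never split
    across bins and the assignment is monotone in the rating.  With all
    ratings distinct and divisible counts the bins are exactly equal.
    """
    conf = np.asarray(confidence, dtype=float)
    if conf.ndim != 1:
        raise ValueError("confidence must be one-dimensional")
    if np.isnan(conf).any():
        raise ValueError("confidence contains missing values; filter trials first")
    if conf.size < n_bins:
        raise ValueError(f"need at least {n_bins} ratings, got {conf.size}")
    edges = np.quantile(conf, np.arange(1, n_bins) / n_bins)
    # strict '>' puts boundary ties in the lower bin
    return 1 + (conf[:, None] > edges[None, :]).sum(axis=1)


def bin_cohort_confidence(trials: pd.DataFrame, n_bins: int = 6) -> pd.DataFrame:
    """Fill ``confidence_bin`` per subject on an already-filtered table."""
    out = trials.copy()
    bins = np.empty(len(out), dtype=int)
    for _, idx in out.groupby("subject_id", sort=False).indices.items():
        bins[idx] = bin_confidence(out["confidence"].to_numpy()[idx], n_bins=n_bins)
    out["confidence_bin"] = pd.array(bins, dtype="Int64")
    return out
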