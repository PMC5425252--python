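"""Per-subject signal-detection metrics: d', criterion c, and AUROC2.

Type-I metrics summarise the left/right discrimination itself.  Treating
left-stimulus trials as the signal class,

    H  = P(respond left | stimulus left)      (hit rate)
    FA = P(respond left | stimulus right)     (false-alarm rate)
    d' = (z(H) - z(FA)) / sqrt(2)             (2AFC-corrected sensitivity)
    c  = -(z(H) + z(FA)) / 2                  (response bias)

with z the inverse standard-normal CDF.  Type-II sensitivity (AUROC2) is
the area under the ROC curve built from the confidence-rating
distributions conditioned on correct versus incorrect choices: cumulative
hit/false-alarm pairs are accumulated from the highest confidence bin
downward and the area is taken by the trapezoid rule.  This equals the
tie-corrected rank probability P(conf_correct > conf_incorrect) +
P(tie)/2, i.e. 0.5 means confidence carries no information about
accuracy and 1 means perfect metacognitive insight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Type2ROC",
    "SDTType1",
    "UndefinedMetricError",
    "type2_roc",
    "type1_sdt",
    "summarise_subject",
    "summarise_cohort",
    "SUBJECT_COLUMNS",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "n_trials",
    "accuracy",
    "mean_orientation_deg",
    "median_rt_ms",
    "median_confidence",
    "median_confidence_correct",
    "median_confidence_error",
    "dprime",
    "criterion",
    "auroc2",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for this subject (e.g. no error trials)."""


@dataclass(frozen=True)
class Type2ROC:
    h: np.ndarray  # cumulative P(conf >= bin k | correct), (0,...,1)
    f: np.ndarray  # cumulative P(conf >= bin k | incorrect)
    auroc2: float
    n_correct: int
    n_incorrect: int


@dataclass(frozen=True)
class SDTType1:
    H: float
    FA: float
    dprime: float
    c: float
    n_signal: int
    n_noise: int


def type2_roc(confidence_bin, correct, n_bins: int = 6, subject: str | None = None) -> Type2ROC:
    """Type-II ROC and its area from binned confidence and correctness.

    Cumulative rate pairs (f_k, h_k) are formed from the highest bin
    downward, with (0, 0) and (1, 1) endpoints, and the area is the
    trapezoidal integral of h over f.  Requires at least one correct and
    one incorrect trial; otherwise the type-II ROC is undefined.
    """
    bins = np.asarray(confidence_bin, dtype=int)
    corr = np.asarray(correct, dtype=bool)
    if bins.shape != corr.shape:
        raise ValueError("confidence_bin and correct must have equal length")
    if bins.min(initial=1) < 1 or bins.max(initial=n_bins) > n_bins:
        raise ValueError(f"confidence bins must lie in 1..{n_bins}")
    n_c = int(corr.sum())
    n_i = int((~corr).sum())
    if n_c == 0 or n_i == 0:
        who = f" for subject {subject}" if subject else ""
        raise UndefinedMetricError(
            f"type-II ROC undefined{who}: needs both correct and incorrect trials "
            f"(got {n_c} correct, {n_i} incorrect)"
        )
    counts_c = np.bincount(bins[corr], minlength=n_bins + 1)[1:]
    counts_i = np.bincount(bins[~corr], minlength=n_bins + 1)[1:]
    # cumulative from the most-confident bin down, endpoints prepended
    h = np.concatenate(([0.0], np.cumsum(counts_c[::-1]) / n_c))
    f = np.concatenate(([0.0], np.cumsum(counts_i[::-1]) / n_i))
    auroc2 = float(np.trapezoid(h, f))
    return Type2ROC(h=h, f=f, auroc2=auroc2, n_correct=n_c, n_incorrect=n_i)


def _corrected_rate(k: int, n: int) -> float:
    # half-count (log-linear) correction applied only to empty/full cells
    if k == 0:
        return 0.5 / n
    if k == n:
        return 1.0 - 0.5 / n
    return k / n


def type1_sdt(
    stimulus_direction,
    response,
    signal: str = "left",
    printed_criterion_sign: bool = False,
) -> SDTType1:
    """Type-I sensitivity d' and bias c from stimulus/response labels.

    ``signal`` names the stimulus class whose responses count as hits
    (left by default; swapping it flips the sign of d' and c).  Hit and
    false-alarm rates of exactly 0 or 1 receive a half-count correction
    before the inverse-normal transform so d' stays finite.

    ``printed_criterion_sign`` switches c to -(z(H) - z(FA))/2, a variant
    that makes c proportional to d'; the default -(z(H) + z(FA))/2 is the
    standard criterion.
    """
    stim = np.asarray(stimulus_direction)
    resp = np.asarray(response)
    noise_labels = set(np.unique(stim)) - {signal}
    if signal not in stim or not noise_labels:
        raise ValueError("both stimulus classes must be present")
    is_signal = stim == signal
    n_signal = int(is_signal.sum())
    n_noise = int((~is_signal).sum())
    H = _corrected_rate(int((resp[is_signal] == signal).sum()), n_signal)
    FA = _corrected_rate(int((resp[~is_signal] == signal).sum()), n_noise)
    zH, zFA = norm.ppf(H), norm.ppf(FA)
    dprime = (zH - zFA) / np.sqrt(2.0)
    c = -0.5 * ((zH - zFA) if printed_criterion_sign else (zH + zFA))
    return SDTType1(H=H, FA=FA, dprime=float(dprime), c=float(c), n_signal=n_signal, n_noise=n_noise)


def summarise_subject(trials: pd.DataFrame, n_bins: int = 6) -> dict:
    """One subject's summary row from filtered, confidence-binned trials.

    ``auroc2`` is NaN (not an error) when the subject has no error or no
    correct trials after filtering; such subjects are dropped from AUROC2
    group analyses downstream rather than imputed.
    """
    correct = trials["correct"].astype(float).to_numpy()
    conf = trials["confidence"].to_numpy(dtype=float)
    is_corr = correct > 0.5
    sdt = type1_sdt(trials["stimulus_direction"].to_numpy(), trials["response"].to_numpy())
    try:
        auroc2 = type2_roc(
            trials["confidence_bin"].to_numpy(dtype=int),
            is_corr,
            n_bins=n_bins,
            subject=str(trials["subject_id"].iloc[0]),
        ).auroc2
    except UndefinedMetricError:
        auroc2 = np.nan
    return {
        "subject_id": trials["subject_id"].iloc[0],
        "group": trials["group"].iloc[0],
        "n_trials": len(trials),
        "accuracy": float(correct.mean()),
        "mean_orientation_deg": float(trials["mean_orientation_deg"].mean()),
        "median_rt_ms": float(trials["rt_ms"].median()),
        "median_confidence": float(np.median(conf)),
        "median_confidence_correct": float(np.median(conf[is_corr])) if is_corr.any() else np.nan,
        "median_confidence_error": float(np.median(conf[~is_corr])) if (~is_corr).any() else np.nan,
        "dprime": sdt.dprime,
        "criterion": sdt.c,
        "auroc2": auroc2,
    }


def summarise_cohort(trials: pd.DataFrame, n_bins: int = 6) -> pd.DataFrame:
    """Subject summary table (one row per subject) for the whole cohort."""
    rows = [
        summarise_subject(g, n_bins=n_bins)
        for _, g in trials.groupby("subject_id", sort=False)
    ]
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
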