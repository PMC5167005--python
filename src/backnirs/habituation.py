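"""Habituation / sensitization screen.

For every subject, channel, condition and chromophore, the per-trial
response amplitudes (middle-2.5 s medians, in chronological order) are
regressed on trial index 1..15 by ordinary least squares.  A significantly
positive slope (p < .05, two-sided t test, uncorrected) is read as
sensitization - a growing response over the session - and a significantly
negative one as habituation.  The screen is exploratory: no
multiple-comparison correction is applied and no group-level inference is
drawn, only per-subject counts of trending channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import TrialTensor
from .stats import trial_response_scalars


@dataclass
class TrendResult:
    subject: str
    channel: int
    condition: str
    chromophore: str
    slope: float          # umol/L per trial
    intercept: float
    p_value: float
    classification: str   # sensitization | habituation | none


def fit_trial_trend(trial_scalars: np.ndarray, subject: str = "subject",
                    channel: int = 0, condition: str = "", chromophore: str = "",
                    alpha: float = 0.05) -> TrendResult:
    """OLS of trial amplitude on chronological trial index."""
    y = np.asarray(trial_scalars, dtype=float)
    if y.size < 5:
        raise ValueError(f"need >= 5 trials, have {y.size}")
    x = np.arange(1, y.size + 1, dtype=float)
    if np.ptp(y) == 0.0:  # constant input: slope 0, nothing to test
        return TrendResult(subject, channel, condition, chromophore,
                           0.0, float(y[0]), 1.0, "none")
    fit = scipy.stats.linregress(x, y)
    p = float(fit.pvalue)
    if p < alpha and fit.slope > 0:
        cls = "sensitization"
    elif p < alpha and fit.slope < 0:
        cls = "habituation"
    else:
        cls = "none"
    return TrendResult(subject, channel, condition, chromophore,
                       float(fit.slope), float(fit.intercept), p, cls)


def fit_tensor_trends(tensor: TrialTensor, subject: str | None = None,
                      alpha: float = 0.05) -> list[TrendResult]:
    """Trend fits for every long-channel cell of a preprocessed tensor."""
    subject = subject or tensor.subject or "subject"
    out = []
    for key in sorted(tensor.data):
        ch, cond, chrom = key
        if ch in (2, 10):
            continue
        scalars = trial_response_scalars(tensor, key)
        out.append(fit_trial_trend(scalars, subject, ch, cond, chrom, alpha))
    return out


def trends_to_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": r.subject, "channel": r.channel, "condition": r.condition,
          "chromophore": r.chromophore, "slope": r.slope, "p": r.p_value,
          "classification": r.classification}
         for r in results])


def summarize_trends(results: list[TrendResult]) -> pd.DataFrame:
    """Per condition: how many subjects show at least one significant
    positive (sensitization) or negative (habituation) channel, and the
    per-subject channel counts behind those numbers."""
    if not results:
        return pd.DataFrame(columns=["condition", "chromophore",
                                     "n_subjects_sensitization",
                                     "n_subjects_habituation",
                                     "max_channels_per_subject"])
    df = trends_to_frame(results)
    rows = []
    for (cond, chrom), sub in df.groupby(["condition", "chromophore"]):
        per_subj = sub.groupby("subject")["classification"].agg(
            pos=lambda s: (s == "sensitization").sum(),
            neg=lambda s: (s == "habituation").sum())
        rows.append({
            "condition": cond, "chromophore": chrom,
            "n_subjects_sensitization": int((per_subj["pos"] > 0).sum()),
            "n_subjects_habituation": int((per_subj["neg"] > 0).sum()),
            "max_channels_per_subject": int((per_subj["pos"] + per_subj["neg"]).max()),
        })
    return pd.DataFrame(rows)
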