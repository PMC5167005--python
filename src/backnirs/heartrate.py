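"""Heart-rate windowing and condition comparisons.

A 1 Hz heart-rate series is cut into per-event windows: the 5 s stimulus,
the 15 s interstimulus interval (ISI) before the stimulus (pre-ISI) and the
15 s ISI after it (post-ISI); stimulus and post-ISI partition each event's
20 s without gap or overlap.  Per subject and condition the per-event mean
(HRmean) and maximum (HRmax) are aggregated across the 15 events.  At group
level, a paired Wilcoxon signed-rank test per condition compares HRmax in
the post-ISI against HRmax during the stimulus (the three p-values form one
FDR family), and a Friedman test across conditions on the post-minus-
stimulus differences asks whether the transient is condition-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import StimulusProtocol

logger = logging.getLogger(__name__)

WINDOW_KINDS = ("stimulus", "pre_isi", "post_isi")


@dataclass
class HeartRateSeries:
    bpm: np.ndarray
    sampling_rate_hz: float = 1.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.bpm.ndim != 1:
            raise ValueError("heart-rate series must be 1-D")
        if np.any(~np.isfinite(self.bpm)):
            raise ValueError("non-finite heart-rate samples")
        if np.any((self.bpm <= 25) | (self.bpm >= 250)):
            raise ValueError("heart-rate values outside the plausible 25-250 bpm range")


@dataclass
class HrWindowSummary:
    """Per-subject, per-condition aggregate over one window kind."""
    subject: str
    condition: str
    window_kind: str
    hr_mean: float           # mean over events of per-event window means
    hr_max: float            # aggregate of per-event window maxima
    per_event_mean: np.ndarray = field(repr=False, default=None)
    per_event_max: np.ndarray = field(repr=False, default=None)


def _window_slice(hr: HeartRateSeries, start_s: float, length_s: float,
                  what: str) -> np.ndarray:
    fs = hr.sampling_rate_hz
    i0 = int(round((start_s - hr.t0_s) * fs))
    i1 = i0 + int(round(length_s * fs))
    if i0 < 0 or i1 > len(hr.bpm):
        raise ValueError(f"{what} window [{start_s}, {start_s + length_s}) s "
                         "lies outside the heart-rate recording")
    return hr.bpm[i0:i1]


def extract_hr_windows(hr: HeartRateSeries, protocol: "StimulusProtocol",
                       subject: str = "subject",
                       max_aggregate: str = "mean_of_max") -> list[HrWindowSummary]:
    """Per-condition HRmean/HRmax summaries over stimulus, pre- and post-ISI.

    ``max_aggregate`` selects how per-event maxima are combined: the mean of
    the per-event maxima (default, the 'average maximal heart rate') or the
    overall maximum (``"max_of_max"``).
    """
    if max_aggregate not in ("mean_of_max", "max_of_max"):
        raise ValueError(f"unknown max_aggregate {max_aggregate!r}")
    isi = protocol.isi_s
    out = []
    for cond in protocol.conditions:
        windows: dict[str, list[np.ndarray]] = {k: [] for k in WINDOW_KINDS}
        for k, ev in enumerate(protocol.events_of(cond)):
            windows["stimulus"].append(
                _window_slice(hr, ev.onset_s, ev.duration_s, f"{cond} event {k} stimulus"))
            windows["pre_isi"].append(
                _window_slice(hr, ev.onset_s - isi, isi, f"{cond} event {k} pre-ISI"))
            windows["post_isi"].append(
                _window_slice(hr, ev.onset_s + ev.duration_s, isi,
                              f"{cond} event {k} post-ISI"))
        for kind, segs in windows.items():
            ev_means = np.array([s.mean() for s in segs])
            ev_maxes = np.array([s.max() for s in segs])
            hr_max = (ev_maxes.mean() if max_aggregate == "mean_of_max"
                      else ev_maxes.max())
            out.append(HrWindowSummary(subject, cond, kind,
                                       float(ev_means.mean()), float(hr_max),
                                       ev_means, ev_maxes))
    return out


def summaries_to_frame(summaries: list[HrWindowSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": s.subject, "condition": s.condition,
          "window_kind": s.window_kind, "hr_mean": s.hr_mean, "hr_max": s.hr_max}
         for s in summaries])


@dataclass
class HrReport:
    """Group-level heart-rate statistics."""
    wilcoxon: pd.DataFrame   # per condition: post-ISI vs stimulus HRmax
    friedman_chi2: float
    friedman_p: float
    descriptives: pd.DataFrame
    n_subjects: int


def compare_hr(summaries: list[HrWindowSummary],
               q_threshold: float = 0.05) -> HrReport:
    """Paired post-ISI-vs-stimulus Wilcoxon per condition (one FDR family of
    three) and a Friedman test across conditions on the differences."""
    from .stats import bh_fdr, friedman_test, wilcoxon_signed_rank

    df = summaries_to_frame(summaries)
    conditions = list(dict.fromkeys(df["condition"]))
    wide = df.pivot_table(index="subject", columns=["condition", "window_kind"],
                          values="hr_max")
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        logger.warning("dropping subjects with incomplete conditions: %s",
                       sorted(dropped))
    if len(complete) < 5:
        raise ValueError(f"need >= 5 complete subjects, have {len(complete)}")

    rows = []
    diffs = {}
    for cond in conditions:
        d = (complete[(cond, "post_isi")] - complete[(cond, "stimulus")]).to_numpy()
        diffs[cond] = d
        res = wilcoxon_signed_rank(d)
        rows.append({"condition": cond, "mean_diff_bpm": float(d.mean()),
                     "p": res.p, "z": res.z, "n": len(d)})
    wil = pd.DataFrame(rows)
    q, sig = bh_fdr(wil["p"].to_numpy(), q_threshold)
    wil["q"] = q
    wil["significant"] = sig

    chi2, p_f = friedman_test(np.column_stack([diffs[c] for c in conditions]))

    desc = (df.groupby(["condition", "window_kind"])
            .agg(hr_max_mean=("hr_max", "mean"), hr_max_sd=("hr_max", "std"),
                 hr_mean_mean=("hr_mean", "mean"), hr_mean_sd=("hr_mean", "std"),
                 n=("hr_max", "size"))
            .reset_index())
    desc["hr_max_sem"] = desc["hr_max_sd"] / np.sqrt(desc["n"])
    desc["hr_mean_sem"] = desc["hr_mean_sd"] / np.sqrt(desc["n"])
    return HrReport(wil, float(chi2), float(p_f), desc, len(complete))
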