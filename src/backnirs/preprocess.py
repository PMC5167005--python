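"""Signal-processing chain for event-related CW-fNIRS recordings.

Order of operations: optical densities are converted to O2Hb/HHb
concentration changes (Beer-Lambert inversion with an age-dependent DPF),
band-passed with a Savitzky-Golay difference filter (4 s smoothing minus
80 s trend, both third degree), segmented around each stimulus (3.9 s
pre-ISI + 5 s stimulus + 3.9 s post-ISI), per-segment linearly detrended,
baselined to a zero pre-ISI median, and finally corrected for superficial
hemodynamics by short-separation regression (SSR): each long-channel
segment minus the least-squares-scaled segment of its ROI's ~11 mm short
channel, per chromophore.

Window lengths in samples are round(seconds * fs) forced odd for the SG
filters (4 s -> 31, 80 s -> 625 at 7.81 Hz); segments are 30 + 39 + 30 = 99
samples with onsets mapped to the nearest sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .mbll import DpfSpec, compute_dpf, mbll_invert
from .probe import ProbeLayout
from .timeseries import ChannelTimeSeries, intensity_to_od

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig", "Segment", "TrialTensor", "compute_dpf", "DpfSpec",
    "mbll_invert", "intensity_to_od", "sg_bandpass", "segment",
    "detrend_and_baseline", "short_separation_regress", "apply_ssr",
    "preprocess_recording",
]


@dataclass
class PreprocessConfig:
    smooth_window_s: float = 4.0
    trend_window_s: float = 80.0
    sg_order: int = 3
    pre_s: float = 3.9
    post_s: float = 3.9
    ssr_scope: str = "recording"    # "recording" | "segment"
    detrend_scope: str = "pre_isi"  # "pre_isi" | "segment"


@dataclass(frozen=True)
class Segment:
    """One stimulus-locked slice of one channel-chromophore trace."""
    channel: int
    condition: str
    trial: int  # 1-based chronological index
    chromophore: str
    values: np.ndarray  # pre + stim + post samples


@dataclass
class TrialTensor:
    """(channel, condition, chromophore) -> trials x samples segment stack."""

    data: dict[tuple[int, str, str], np.ndarray]
    sampling_rate_hz: float
    pre_samples: int
    stim_samples: int
    post_samples: int
    subject: str | None = None
    ssr_applied: bool = False
    detrended: bool = False
    baselined: bool = False

    @property
    def segment_length(self) -> int:
        return self.pre_samples + self.stim_samples + self.post_samples

    @property
    def onset_index(self) -> int:
        return self.pre_samples

    def channels(self) -> list[int]:
        return sorted({k[0] for k in self.data})

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(k[1] for k in self.data))

    def n_trials(self, key) -> int:
        return self.data[key].shape[0]

    def copy(self, **flag_updates) -> "TrialTensor":
        out = replace(self, data={k: v.copy() for k, v in self.data.items()})
        for k, v in flag_updates.items():
            setattr(out, k, v)
        return out


def _odd_window(seconds: float, fs: float) -> int:
    w = int(round(seconds * fs))
    return w + 1 if w % 2 == 0 else w


def sg_bandpass(series: ChannelTimeSeries, smooth_window_s: float = 4.0,
                trend_window_s: float = 80.0, order: int = 3) -> ChannelTimeSeries:
    """Savitzky-Golay band-pass: SG(x, 4 s) - SG(x, 80 s), third degree.

    The short window removes high-frequency noise, the long window estimates
    the slow physiological trend which is subtracted.  Edges are handled by
    evaluating the terminal in-window polynomial fit (no reflection).
    """
    w_smooth = _odd_window(smooth_window_s, series.sampling_rate_hz)
    w_trend = _odd_window(trend_window_s, series.sampling_rate_hz)
    for w in (w_smooth, w_trend):
        if w < order + 2:
            raise ValueError(f"window of {w} samples shorter than order+2={order + 2}")
    if series.n_samples <= w_trend:
        raise ValueError(
            f"series of {series.n_samples} samples not longer than the "
            f"{w_trend}-sample trend window")
    smooth = savgol_filter(series.values, w_smooth, order, axis=1, mode="interp")
    trend = savgol_filter(series.values, w_trend, order, axis=1, mode="interp")
    return series.copy_with(smooth - trend)


def segment(series: ChannelTimeSeries, protocol, pre_s: float = 3.9,
            post_s: float = 3.9) -> TrialTensor:
    """Cut a chromophore series into stimulus-locked trial stacks."""
    if series.kind != "chromophore":
        raise ValueError("segmentation expects a chromophore series")
    fs = series.sampling_rate_hz
    pre = int(round(pre_s * fs))
    post = int(round(post_s * fs))
    durations = {e.duration_s for e in protocol.events}
    if len(durations) != 1:
        raise ValueError("all events must share one stimulus duration")
    stim = int(round(durations.pop() * fs))
    length = pre + stim + post

    data: dict[tuple[int, str, str], np.ndarray] = {}
    by_cond: dict[str, list[np.ndarray]] = {}
    for ev in protocol.events:
        onset_idx = int(round((ev.onset_s - series.t0_s) * fs))
        lo, hi = onset_idx - pre, onset_idx - pre + length
        if lo < 0 or hi > series.n_samples:
            raise ValueError(
                f"event {ev.condition}@{ev.onset_s}s needs samples [{lo}, {hi}) "
                f"outside the recording of {series.n_samples} samples")
        by_cond.setdefault(ev.condition, []).append(series.values[:, lo:hi])

    for cond, slices in by_cond.items():
        stack = np.stack(slices, axis=1)  # rows x trials x samples
        for r, (ch_id, chrom) in enumerate(series.labels):
            data[(ch_id, cond, chrom)] = stack[r]
    return TrialTensor(data, fs, pre, stim, post)


def detrend_and_baseline(tensor: TrialTensor,
                         detrend_scope: str = "pre_isi") -> TrialTensor:
    """Subtract a per-segment OLS drift line, then the pre-ISI median.

    The line is fitted on the response-free pre-ISI samples and
    extrapolated across the segment (default), so a drift a + b*t is
    removed exactly while the evoked response is left intact; with
    ``detrend_scope="segment"`` the line is fitted over the whole segment
    instead (which also absorbs part of a ramping response).  Afterwards
    every segment's pre-ISI median is exactly zero (up to floating point),
    removing the trial-to-trial variance of starting values.
    """
    if tensor.baselined:
        raise ValueError("tensor is already baselined")
    if detrend_scope not in ("pre_isi", "segment"):
        raise ValueError(f"unknown detrend_scope {detrend_scope!r}")
    length = tensor.segment_length
    pre = tensor.pre_samples
    x = np.arange(length, dtype=float)
    design = np.column_stack([np.ones(length), x])
    fit_rows = slice(0, pre) if detrend_scope == "pre_isi" else slice(0, length)
    pinv_fit = np.linalg.pinv(design[fit_rows])  # 2 x n_fit
    out = {}
    for key, arr in tensor.data.items():
        beta = arr[:, fit_rows] @ pinv_fit.T     # trials x 2
        detrended = arr - beta @ design.T
        base = np.median(detrended[:, :pre], axis=1, keepdims=True)
        out[key] = detrended - base
    result = replace(tensor, data=out)
    result.detrended = True
    result.baselined = True
    return result


def short_separation_regress(long_segment: np.ndarray,
                             short_segment: np.ndarray) -> tuple[np.ndarray, float]:
    """Remove the least-squares-scaled short-channel signal from a long one.

    alpha = <long, short> / <short, short>; the corrected signal
    long - alpha * short is orthogonal to the short-channel signal.  A
    flat short channel yields alpha = 0 (no correction) with a warning.
    """
    long_segment = np.asarray(long_segment, dtype=float)
    short_segment = np.asarray(short_segment, dtype=float)
    if long_segment.shape != short_segment.shape:
        raise ValueError("long and short segments must have equal length")
    denom = float(np.dot(short_segment, short_segment))
    if denom == 0.0:
        logger.warning("short-channel segment has zero power; SSR skipped")
        return long_segment.copy(), 0.0
    alpha = float(np.dot(long_segment, short_segment)) / denom
    return long_segment - alpha * short_segment, alpha


def _ssr_alphas(long_arr: np.ndarray, short_arr: np.ndarray) -> np.ndarray:
    """Per-trial least-squares scaling factors (vectorized over trials)."""
    denom = np.einsum("ij,ij->i", short_arr, short_arr)
    num = np.einsum("ij,ij->i", long_arr, short_arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        alphas = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return alphas


def apply_ssr(tensor: TrialTensor, layout: ProbeLayout,
              return_alphas: bool = False):
    """Correct every long-channel segment with its ROI's short channel.

    alpha is estimated per (segment, chromophore); short channels are kept
    untouched so their provenance remains inspectable.
    """
    out = {}
    alphas: dict[tuple[int, str, str], np.ndarray] = {}
    short_ids = set(layout.short_channel_ids)
    for (ch_id, cond, chrom), arr in tensor.data.items():
        if ch_id in short_ids:
            out[(ch_id, cond, chrom)] = arr.copy()
            continue
        short_id = layout.ssr_map[ch_id]
        short_key = (short_id, cond, chrom)
        if short_key not in tensor.data:
            raise KeyError(f"missing short-channel segments for {short_key}")
        short_arr = tensor.data[short_key]
        a = _ssr_alphas(arr, short_arr)
        if np.any(np.einsum("ij,ij->i", short_arr, short_arr) == 0):
            logger.warning("zero-power short-channel segment for channel %d "
                           "(%s, %s); affected trials left uncorrected",
                           ch_id, cond, chrom)
        out[(ch_id, cond, chrom)] = arr - a[:, None] * short_arr
        alphas[(ch_id, cond, chrom)] = a
    result = replace(tensor, data=out)
    result.ssr_applied = True
    return (result, alphas) if return_alphas else result


def _ssr_recording(chromo: ChannelTimeSeries, layout: ProbeLayout) -> ChannelTimeSeries:
    """Whole-recording SSR alternative: one alpha per channel-chromophore."""
    values = chromo.values.copy()
    short_ids = set(layout.short_channel_ids)
    for r, (ch_id, chrom) in enumerate(chromo.labels):
        if ch_id in short_ids:
            continue
        short = chromo.row(layout.ssr_map[ch_id], chrom)
        values[r], _ = short_separation_regress(values[r], short)
    return chromo.copy_with(values)


def preprocess_recording(od: ChannelTimeSeries, layout: ProbeLayout,
                         age_years: float,
                         protocol,
                         config: PreprocessConfig | None = None,
                         subject: str | None = None) -> TrialTensor:
    """Run the full chain: MBLL inversion, SG band-pass, segmentation,
    detrend + baseline, SSR.  Accepts raw intensity or OD input."""
    config = config or PreprocessConfig()
    if od.kind == "intensity":
        od = intensity_to_od(od, protocol.baseline_s)
    dpf = DpfSpec(age_years)
    chromo = mbll_invert(od, layout, dpf)
    chromo = sg_bandpass(chromo, config.smooth_window_s, config.trend_window_s,
                         config.sg_order)
    if config.ssr_scope == "recording":
        chromo = _ssr_recording(chromo, layout)
    tensor = segment(chromo, protocol, config.pre_s, config.post_s)
    tensor.subject = subject
    tensor = detrend_and_baseline(tensor, config.detrend_scope)
    if config.ssr_scope == "segment":
        tensor = apply_ssr(tensor, layout)
    elif config.ssr_scope == "recording":
        tensor.ssr_applied = True
    else:
        raise ValueError(f"unknown ssr_scope {config.ssr_scope!r}")
    tensor.subject = subject
    return tensor
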