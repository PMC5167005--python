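"""Median-based block averaging and nonparametric channel-wise statistics.

The per-trial summary is the median of the middle 2.5 s of the 5 s
stimulus window; the per-subject block average is the per-sample median
across the 15 trials, and the grand average the per-sample median across
subjects (with a bootstrap standard error of the median, SEMed).

Inference is fully nonparametric: a single-subject Wilcoxon signed-rank
test of the 15 trial medians against zero classifies each
subject-channel-condition cell as a 'responder'; at group level a Friedman
test across the three conditions, per-condition Wilcoxon tests against
zero, and post hoc paired Wilcoxon tests between conditions are run either
over all subjects ('All') or over responder cells only ('Responders'),
each corrected across the 16 long channels per test family with the
Benjamini-Hochberg false-discovery-rate step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocess import TrialTensor
from .probe import LONG_CHANNELS, SMA_CHANNELS

logger = logging.getLogger(__name__)

CONDITION_PAIRS = (("PAPain", "PA30"), ("PAPain", "Brush"), ("PA30", "Brush"))


def _roi_of(channel: int) -> str:
    return "SMA" if channel in SMA_CHANNELS else "S1"


# ---------------------------------------------------------------------------
# block and grand averages

def response_window_indices(segment_length: int, fs: float,
                            stim_onset_index: int) -> range:
    """Sample indices of the middle 2.5 s of the 5 s stimulus window,
    [onset + 1.25 s, onset + 3.75 s], rounded to the nearest sample."""
    start = stim_onset_index + int(round(1.25 * fs))
    stop = stim_onset_index + int(round(3.75 * fs))
    if start < 0 or stop >= segment_length:
        raise ValueError("response window falls outside the segment")
    return range(start, stop + 1)


def trial_response_scalars(tensor: TrialTensor, key) -> np.ndarray:
    """Per-trial medians over the middle-2.5 s response window."""
    win = response_window_indices(tensor.segment_length, tensor.sampling_rate_hz,
                                  tensor.onset_index)
    arr = tensor.data[key]
    return np.median(arr[:, win.start:win.stop], axis=1)


@dataclass
class BlockAverage:
    subject: str
    channel: int
    condition: str
    chromophore: str
    trace: np.ndarray
    response_scalar: float  # median of trace over the middle 2.5 s, umol/L


def block_average(tensor: TrialTensor, subject: str | None = None) -> list[BlockAverage]:
    """Per-sample median across trials, per channel/condition/chromophore."""
    subject = subject or tensor.subject or "subject"
    win = response_window_indices(tensor.segment_length, tensor.sampling_rate_hz,
                                  tensor.onset_index)
    out = []
    for (ch, cond, chrom), arr in sorted(tensor.data.items()):
        if arr.shape[0] < 3:
            raise ValueError(
                f"need >= 3 trials for a block average, have {arr.shape[0]} "
                f"for channel {ch} / {cond} / {chrom}")
        trace = np.median(arr, axis=0)
        scalar = float(np.median(trace[win.start:win.stop]))
        out.append(BlockAverage(subject, ch, cond, chrom, trace, scalar))
    return out


@dataclass
class GrandAverage:
    channel: int
    condition: str
    chromophore: str
    trace: np.ndarray    # per-sample median across subjects
    semed: np.ndarray    # per-sample standard error of the median
    n_subjects: int
    response_scalar: float


def grand_average(blocks: list[BlockAverage], semed_method: str = "bootstrap",
                  n_boot: int = 1000, seed: int = 0) -> list[GrandAverage]:
    """Across-subject median of block-average traces with SEMed.

    SEMed is estimated by a seeded bootstrap over subjects (default) or by
    the Gaussian large-sample approximation 1.2533 * SD / sqrt(n).
    """
    rng = np.random.default_rng(seed)
    grouped: dict[tuple[int, str, str], list[BlockAverage]] = {}
    for b in blocks:
        grouped.setdefault((b.channel, b.condition, b.chromophore), []).append(b)
    out = []
    for (ch, cond, chrom), group in sorted(grouped.items()):
        traces = np.stack([b.trace for b in group])
        n = traces.shape[0]
        med = np.median(traces, axis=0)
        if semed_method == "bootstrap":
            idx = rng.integers(0, n, size=(n_boot, n))
            boot = np.median(traces[idx], axis=1)
            semed = boot.std(axis=0, ddof=1)
        elif semed_method == "gaussian":
            semed = 1.2533 * traces.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            raise ValueError(f"unknown semed_method {semed_method!r}")
        scalar = float(np.median([b.response_scalar for b in group]))
        out.append(GrandAverage(ch, cond, chrom, med, semed, n, scalar))
    return out


# ---------------------------------------------------------------------------
# elementary tests

@dataclass(frozen=True)
class WilcoxonResult:
    p: float
    statistic: float  # sum of positive ranks, W+
    z: float          # signed normal deviate (tie-corrected)
    n: int            # sample size after zero removal


def wilcoxon_signed_rank(values: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test against a zero median.

    Zeros are dropped (Wilcoxon's convention).  The exact null distribution
    is used for n <= 25 without ties; otherwise the normal approximation
    with tie correction.  All-zero input yields p = 1 with a warning.
    """
    d = np.asarray(values, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        logger.warning("all values zero in Wilcoxon signed-rank test; p = 1")
        return WilcoxonResult(1.0, 0.0, 0.0, 0)

    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(var) if var > 0 else 0.0

    has_ties = np.any(tie_counts > 1)
    if n < 5:
        logger.warning("Wilcoxon signed-rank with n=%d (< 5) has little power", n)
    if n <= 25 and not has_ties:
        res = scipy.stats.wilcoxon(d, zero_method="wilcox",
                                   alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = float(min(1.0, 2 * scipy.stats.norm.sf(abs(z)))) if var > 0 else 1.0
    return WilcoxonResult(p, w_plus, float(z), n)


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across k related samples (columns).

    Rows with missing values are dropped (count logged).  Uses mid-ranks
    with tie correction; p from the chi-square approximation, df = k - 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need an n x k matrix with k >= 3 conditions")
    complete = ~np.any(np.isnan(m), axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("Friedman test: dropped %d incomplete rows", dropped)
    m = m[complete]
    if m.shape[0] < 5:
        raise ValueError(f"need >= 5 complete rows, have {m.shape[0]}")
    if np.all(m == m[:, [0]]):  # every row constant: no ranking information
        return 0.0, 1.0
    chi2, p = scipy.stats.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
    return float(chi2), float(p)


def bh_fdr(p_values: np.ndarray, q_threshold: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: q-values and the q <= threshold mask.

    NaN entries (missing cells) are excluded from the family and returned
    as NaN / not significant.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum():
        reject, q_ok, _, _ = multipletests(p[ok], alpha=q_threshold,
                                           method="fdr_bh")
        q[ok] = q_ok
        mask[ok] = q_ok <= q_threshold
    return q, mask


# ---------------------------------------------------------------------------
# responder classification

@dataclass
class ResponderTable:
    """(subject, channel, condition, chromophore) -> (p, is_responder)."""
    entries: dict[tuple[str, int, str, str], tuple[float, bool]]
    alpha_single: float = 0.05

    def is_responder(self, subject: str, channel: int, condition: str,
                     chromophore: str) -> bool:
        entry = self.entries.get((subject, channel, condition, chromophore))
        return bool(entry and entry[1])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject": s, "channel": ch, "condition": c, "chromophore": m,
                 "p": p, "is_responder": r}
                for (s, ch, c, m), (p, r) in sorted(self.entries.items())]
        return pd.DataFrame(rows)


def classify_responders(tensor: TrialTensor, alpha_single: float = 0.05,
                        subject: str | None = None,
                        table: ResponderTable | None = None) -> ResponderTable:
    """Single-subject Wilcoxon of the 15 per-trial response medians vs zero.

    A cell is a responder iff its two-sided uncorrected p < alpha_single.
    Short channels are excluded (they never enter group statistics).
    Pass an existing ``table`` to accumulate several subjects.
    """
    subject = subject or tensor.subject or "subject"
    if table is None:
        table = ResponderTable({}, alpha_single)
    short = {2, 10}
    for key in sorted(tensor.data):
        ch, cond, chrom = key
        if ch in short:
            continue
        scalars = trial_response_scalars(tensor, key)
        res = wilcoxon_signed_rank(scalars)
        table.entries[(subject, ch, cond, chrom)] = (res.p, res.p < alpha_single)
    return table


# ---------------------------------------------------------------------------
# group analysis

@dataclass
class GroupStatsReport:
    track: str
    chromophores: tuple[str, ...]
    friedman: pd.DataFrame
    vs_zero: pd.DataFrame
    posthoc: pd.DataFrame
    q_threshold: float = 0.05


def _scalar_table(blocks: list[BlockAverage]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": b.subject, "channel": b.channel, "condition": b.condition,
          "chromophore": b.chromophore, "scalar": b.response_scalar}
         for b in blocks])


def run_group_analysis(blocks: list[BlockAverage],
                       responders: ResponderTable | None = None,
                       track: str = "All",
                       q_threshold: float = 0.05,
                       min_subjects: int = 5,
                       channels=LONG_CHANNELS,
                       pairs=CONDITION_PAIRS) -> GroupStatsReport:
    """Friedman, condition-vs-zero and post hoc Wilcoxon tests per channel.

    Under ``track="Responders"`` a subject contributes to a
    channel-condition cell only if flagged responder there; cells with
    fewer than ``min_subjects`` contributors are reported as missing and
    excluded from their FDR family.  Each family (one test type, condition
    or pair, and chromophore) is corrected across channels.
    """
    if track not in ("All", "Responders"):
        raise ValueError(f"unknown track {track!r}")
    if track == "Responders" and responders is None:
        raise ValueError("Responders track needs a ResponderTable")
    df = _scalar_table(blocks)
    df = df[df["channel"].isin(channels)].copy()
    if track == "Responders":
        keep = df.apply(lambda r: responders.is_responder(
            r["subject"], r["channel"], r["condition"], r["chromophore"]), axis=1)
        df = df[keep]
    chromophores = tuple(dict.fromkeys(df["chromophore"]))
    conditions = list(dict.fromkeys(b.condition for b in blocks))

    fr_rows, vz_rows, ph_rows = [], [], []
    for chrom in chromophores:
        sub = df[df["chromophore"] == chrom]
        wide = sub.pivot_table(index="subject", columns=["channel", "condition"],
                               values="scalar")
        for ch in channels:
            # Friedman across the three conditions (complete rows only)
            cols = [(ch, c) for c in conditions if (ch, c) in wide.columns]
            chi2 = p_fr = np.nan
            n_fr = 0
            if len(cols) == len(conditions):
                m = wide[cols].to_numpy()
                n_fr = int((~np.any(np.isnan(m), axis=1)).sum())
                if n_fr >= min_subjects:
                    chi2, p_fr = friedman_test(m)
            fr_rows.append({"channel": ch, "roi": _roi_of(ch), "chromophore": chrom,
                            "track": track, "chi2": chi2, "p": p_fr, "n": n_fr})
            # condition vs zero
            for cond in conditions:
                vals = (wide[(ch, cond)].dropna().to_numpy()
                        if (ch, cond) in wide.columns else np.array([]))
                if len(vals) >= min_subjects:
                    res = wilcoxon_signed_rank(vals)
                    vz_rows.append({"channel": ch, "roi": _roi_of(ch),
                                    "chromophore": chrom, "track": track,
                                    "condition": cond, "median": float(np.median(vals)),
                                    "p": res.p, "z": res.z, "n": res.n})
                else:
                    vz_rows.append({"channel": ch, "roi": _roi_of(ch),
                                    "chromophore": chrom, "track": track,
                                    "condition": cond, "median": np.nan,
                                    "p": np.nan, "z": np.nan, "n": len(vals)})
            # post hoc paired comparisons
            for a, b in pairs:
                pair_name = f"{a} vs {b}"
                if (ch, a) in wide.columns and (ch, b) in wide.columns:
                    paired = wide[[(ch, a), (ch, b)]].dropna()
                else:
                    paired = pd.DataFrame()
                if len(paired) >= min_subjects:
                    diff = paired[(ch, a)].to_numpy() - paired[(ch, b)].to_numpy()
                    res = wilcoxon_signed_rank(diff)
                    ph_rows.append({"channel": ch, "roi": _roi_of(ch),
                                    "chromophore": chrom, "track": track,
                                    "pair": pair_name, "p": res.p, "z": res.z,
                                    "n": res.n})
                else:
                    ph_rows.append({"channel": ch, "roi": _roi_of(ch),
                                    "chromophore": chrom, "track": track,
                                    "pair": pair_name, "p": np.nan, "z": np.nan,
                                    "n": len(paired)})

    friedman = pd.DataFrame(fr_rows)
    vs_zero = pd.DataFrame(vz_rows)
    posthoc = pd.DataFrame(ph_rows)

    # FDR within family: test type x (condition | pair) x chromophore
    for frame, extra in ((friedman, None), (vs_zero, "condition"), (posthoc, "pair")):
        frame["q"] = np.nan
        frame["significant"] = False
        group_cols = ["chromophore"] + ([extra] if extra else [])
        for _, idx in frame.groupby(group_cols).groups.items():
            q, mask = bh_fdr(frame.loc[idx, "p"].to_numpy(), q_threshold)
            frame.loc[idx, "q"] = q
            frame.loc[idx, "significant"] = mask
    return GroupStatsReport(track, chromophores, friedman, vs_zero, posthoc,
                            q_threshold)
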