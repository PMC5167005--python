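"""Uniformly sampled multichannel time series containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sampling rate of the continuous-wave imager, Hz.
DEFAULT_FS_HZ = 7.81


@dataclass
class ChannelTimeSeries:
    """Channels-by-samples matrix with per-row labels.

    ``kind`` distinguishes raw light intensity, optical density (one row per
    channel and wavelength) and chromophore concentration changes (one row
    per channel and chromophore, in umol/L).  ``labels`` is a list of
    ``(channel_id, band)`` tuples where band is a wavelength in nm (as int)
    or a chromophore name (``"O2Hb"`` / ``"HHb"``).
    """

    values: np.ndarray
    labels: list[tuple[int, object]]
    sampling_rate_hz: float = DEFAULT_FS_HZ
    t0_s: float = 0.0
    kind: str = "optical_density"  # intensity | optical_density | chromophore

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D channels x samples array")
        if self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.labels)} labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def row_index(self, channel_id: int, band) -> int:
        try:
            return self.labels.index((channel_id, band))
        except ValueError:
            raise KeyError(f"no row for channel {channel_id}, band {band!r}") from None

    def row(self, channel_id: int, band) -> np.ndarray:
        return self.values[self.row_index(channel_id, band)]

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "ChannelTimeSeries":
        return ChannelTimeSeries(
            values=values,
            labels=list(self.labels),
            sampling_rate_hz=self.sampling_rate_hz,
            t0_s=self.t0_s,
            kind=kind or self.kind,
        )


def intensity_to_od(series: ChannelTimeSeries, baseline_s: float) -> ChannelTimeSeries:
    """Convert raw intensity to optical density, -log10(I / I_ref).

    The reference intensity is the per-row mean over the initial rest
    baseline of length ``baseline_s``.
    """
    if series.kind != "intensity":
        raise ValueError(f"expected an intensity series, got {series.kind!r}")
    n_ref = int(round(baseline_s * series.sampling_rate_hz))
    if not 0 < n_ref <= series.n_samples:
        raise ValueError("baseline window outside the recording")
    i_ref = series.values[:, :n_ref].mean(axis=1, keepdims=True)
    if np.any(i_ref <= 0):
        raise ValueError("non-positive reference intensity")
    od = -np.log10(series.values / i_ref)
    return series.copy_with(od, kind="optical_density")
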