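"""Synthetic recordings with the statistical structure the analysis assumes.

The generator emulates a 20-min event-related session: 5 min rest baseline
followed by 45 stimuli (15 per condition: nonpainful posterior-anterior
pressure PA30, individually painful pressure PAPain, and tactile brushing)
of 5 s each with a 15 s interstimulus interval, in pseudo-random order with
no more than two identical stimuli in a row.

Per subject the forward model is, in chromophore space (umol/L):

* a cerebral evoked response on long channels of the responsive ROIs:
  amplitude x canonical double-gamma shape (peak ~6 s, small undershoot),
  additive over events; HHb mirrors O2Hb at a negative fraction;
* a superficial (scalp) component shared - perfectly correlated - by every
  channel of an ROI including its short channel, strongest for painful
  pressure, so that short-separation regression can in principle remove it
  exactly;

projected to optical density at 760/850 nm through the forward
Beer-Lambert relation, after which systemic oscillations (cardiac,
respiratory, Mayer waves), slow drift and white noise are added in OD
space.  A 1 Hz heart-rate series carries a condition-independent
stimulus-locked transient peaking a few seconds after stimulus offset.

Everything is reproducible from the integer seed carried by the parameter
object.  ``PopulationParams``/``draw_subject_params`` add a between-subject
layer (global responsiveness scaling, per-condition and per-channel
amplitude heterogeneity) used by the study generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .heartrate import HeartRateSeries
from .mbll import CHROMOPHORES, DpfSpec, forward_mbll
from .probe import CONDITIONS, ProbeLayout
from .timeseries import DEFAULT_FS_HZ, ChannelTimeSeries

NYQUIST_HZ = DEFAULT_FS_HZ / 2.0


# ---------------------------------------------------------------------------
# stimulus protocol

@dataclass(frozen=True)
class StimulusEvent:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class StimulusProtocol:
    baseline_s: float
    isi_s: float
    events: list[StimulusEvent]
    sampling_rate_hz: float = DEFAULT_FS_HZ

    @property
    def duration_s(self) -> float:
        if not self.events:
            return self.baseline_s
        last = self.events[-1]
        return last.onset_s + last.duration_s + self.isi_s

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(e.condition for e in self.events))

    def events_of(self, condition: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.condition == condition]

    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


def _max_run_length(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def generate_protocol(n_per_condition: int = 15, stim_s: float = 5.0,
                      isi_s: float = 15.0, baseline_s: float = 300.0,
                      seed: int | None = 0, conditions=CONDITIONS,
                      sampling_rate_hz: float = DEFAULT_FS_HZ,
                      max_attempts: int = 10_000) -> StimulusProtocol:
    """Pseudo-randomized event sequence with no more than two identical
    stimuli in a row and exactly ``n_per_condition`` events per condition."""
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if stim_s < 0 or isi_s < 0 or baseline_s < 0:
        raise ValueError("durations must be non-negative")
    rng = np.random.default_rng(seed)
    labels = [c for c in conditions for _ in range(n_per_condition)]
    for _ in range(max_attempts):
        order = list(rng.permutation(len(labels)))
        seq = [labels[i] for i in order]
        if len(conditions) == 1 or _max_run_length(seq) <= 2:
            events = [
                StimulusEvent(c, baseline_s + i * (stim_s + isi_s), stim_s)
                for i, c in enumerate(seq)
            ]
            return StimulusProtocol(baseline_s, isi_s, events, sampling_rate_hz)
    raise RuntimeError(
        f"could not satisfy the run-length constraint in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class Oscillator:
    """A physiological oscillation added in OD space on every channel."""
    frequency_hz: float
    amplitude_od: float
    phase_jitter: float = 0.05  # rad / sqrt(s) random phase diffusion


def default_hrf_amplitudes() -> dict:
    """Evoked-response amplitudes, (condition, roi, chromophore) -> umol/L.

    Both pressure conditions activate SMA and S1 with the painful pressure
    slightly stronger; brushing evokes no cerebral response.  HHb responses
    are negative at 25% of the O2Hb magnitude.
    """
    o2hb = {"PAPain": 0.46, "PA30": 0.36, "Brush": 0.0}
    amps = {}
    for cond, a in o2hb.items():
        for roi in ("SMA", "S1"):
            amps[(cond, roi, "O2Hb")] = a
            amps[(cond, roi, "HHb")] = -0.25 * a
    return amps


def default_scalp_amplitudes() -> dict:
    """Superficial O2Hb amplitudes per condition (umol/L), pain-dominated."""
    return {"PAPain": 0.30, "PA30": 0.15, "Brush": 0.0}


def default_oscillators() -> list[Oscillator]:
    """OD-space systemic oscillations.

    Low-frequency (respiratory, Mayer-wave) power in scalp-probe optical
    recordings is predominantly superficial and therefore lives mostly in
    the shared scalp background (``scalp_background_um``); the OD-space
    amplitudes here are the smaller non-superficial residuals.
    """
    return [
        Oscillator(1.1, 0.0030, 0.05),   # cardiac
        Oscillator(0.25, 0.0010, 0.05),  # respiratory
        Oscillator(0.10, 0.0005, 0.05),  # Mayer wave
    ]


@dataclass
class SimulationParams:
    """Free parameters of one subject's synthetic recording."""

    hrf_amplitude: dict = field(default_factory=default_hrf_amplitudes)
    scalp_amplitude: dict = field(default_factory=default_scalp_amplitudes)
    scalp_hhb_fraction: float = 0.10
    scalp_peak_s: float = 4.0  # scalp blood-flow transient is faster than the HRF
    #: RMS (umol/L) of the ongoing non-task superficial O2Hb fluctuations
    #: (skin blood flow), band-limited and shared within each ROI; this is
    #: the dominant short-channel signal, as in real scalp recordings.
    scalp_background_um: float = 0.5
    scalp_background_band_hz: tuple[float, float] = (0.04, 0.20)
    hrf_peak_s: float = 6.0
    hrf_undershoot_ratio: float = 1.0 / 12.0
    oscillators: list[Oscillator] = field(default_factory=default_oscillators)
    drift_slope_od_per_s: float = 2e-5
    drift_walk_od: float = 1e-5
    #: white-noise SD in OD units at the 30 mm reference separation; the
    #: detected intensity falls roughly exponentially with source-detector
    #: distance, so shot/detector noise in OD grows with separation (one
    #: decade per ``noise_decade_mm``) and short channels are the quietest.
    noise_sd_od: float = 0.002
    noise_decade_mm: float = 20.0
    short_channel_noise_od: float = 0.0  # SSR degradation knob, extra private noise
    #: additive per-channel amplitude heterogeneity,
    #: (condition, chromophore) -> {channel_id: umol/L}
    channel_amplitude_offsets: dict = field(default_factory=dict)
    subject_age_years: float = 33.5
    hr_baseline_bpm: float = 62.0
    hr_transient_bpm: float = 4.0
    hr_transient_peak_s: float = 7.0
    hr_noise_bpm: float = 1.0
    #: uniform +/- jitter (s) on the transient's event lock, emulating
    #: manually clocked stimulus rounds
    hr_clock_jitter_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for osc in self.oscillators:
            if osc.frequency_hz >= NYQUIST_HZ:
                raise ValueError(
                    f"oscillator at {osc.frequency_hz} Hz is at or above the "
                    f"Nyquist frequency {NYQUIST_HZ:.2f} Hz")
        for v in self.hrf_amplitude.values():
            if not math.isfinite(v):
                raise ValueError("non-finite evoked amplitude")

    def amplitude(self, condition: str, channel_id: int, roi: str,
                  chromophore: str) -> float:
        base = self.hrf_amplitude.get((condition, roi, chromophore), 0.0)
        offsets = self.channel_amplitude_offsets.get((condition, chromophore), {})
        return base + offsets.get(channel_id, 0.0)


def null_params(seed: int = 0, **overrides) -> SimulationParams:
    """Parameters with every evoked effect switched off (noise only)."""
    zero_hrf = {k: 0.0 for k in default_hrf_amplitudes()}
    zero_scalp = {c: 0.0 for c in CONDITIONS}
    return SimulationParams(hrf_amplitude=zero_hrf, scalp_amplitude=zero_scalp,
                            hr_transient_bpm=0.0, seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Noise-free constituents of a simulated recording."""
    cerebral: ChannelTimeSeries
    superficial: ChannelTimeSeries
    protocol: StimulusProtocol
    params: SimulationParams


# ---------------------------------------------------------------------------
# canonical response shape

def double_gamma_hrf(t_s: np.ndarray, peak_s: float = 6.0,
                     undershoot_ratio: float = 1.0 / 6.0,
                     undershoot_peak_s: float = 16.0) -> np.ndarray:
    """Canonical double-gamma response, peak normalized to 1."""
    t = np.asarray(t_s, dtype=float)
    shape1 = peak_s  # gamma shape with unit rate peaks at (shape-1)
    shape2 = undershoot_peak_s

    def g(tt, shape):
        out = np.zeros_like(tt)
        pos = tt > 0
        out[pos] = tt[pos] ** (shape - 1) * np.exp(-tt[pos]) / math.gamma(shape)
        return out

    h = g(t, shape1 + 1) - undershoot_ratio * g(t, shape2 + 1)
    peak = h.max()
    return h / peak if peak > 0 else h


def _condition_regressors(protocol: StimulusProtocol, n: int, fs: float,
                          kernel: np.ndarray) -> dict[str, np.ndarray]:
    """Per-condition sum of event-locked copies of a response kernel."""
    out = {}
    for cond in protocol.conditions:
        train = np.zeros(n)
        for ev in protocol.events_of(cond):
            if ev.duration_s < 0:
                raise ValueError(f"negative duration for event at {ev.onset_s}s")
            idx = int(round(ev.onset_s * fs))
            if 0 <= idx < n:
                train[idx] = 1.0
        out[cond] = np.convolve(train, kernel)[:n]
    return out


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band_hz: tuple[float, float], rms: float) -> np.ndarray:
    """Gaussian noise restricted to a frequency band, scaled to a target RMS."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < band_hz[0]) | (freqs > band_hz[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


# ---------------------------------------------------------------------------
# recording simulation

def simulate_recording(layout: ProbeLayout, protocol: StimulusProtocol,
                       params: SimulationParams) -> tuple[ChannelTimeSeries, GroundTruth]:
    """Forward-simulate one subject's two-wavelength OD recording."""
    params.validate()
    fs = protocol.sampling_rate_hz
    n = protocol.n_samples()
    rng = np.random.default_rng(params.seed)

    t_h = np.arange(0.0, 32.0, 1.0 / fs)
    regressors = _condition_regressors(
        protocol, n, fs,
        double_gamma_hrf(t_h, params.hrf_peak_s, params.hrf_undershoot_ratio))
    scalp_regressors = _condition_regressors(
        protocol, n, fs,
        double_gamma_hrf(t_h, params.scalp_peak_s, undershoot_ratio=0.0))

    chrom_labels = [(ch.id, c) for ch in layout.channels for c in CHROMOPHORES]
    cerebral = np.zeros((len(chrom_labels), n))
    superficial = np.zeros_like(cerebral)

    # superficial O2Hb per ROI: task-locked scalp transient plus ongoing
    # band-limited skin-blood-flow fluctuations, shared (perfectly
    # correlated) by every channel of the ROI including its short channel
    scalp_wave = {}
    for roi in ("SMA", "S1"):
        w = np.zeros(n)
        for cond, reg in scalp_regressors.items():
            w += params.scalp_amplitude.get(cond, 0.0) * reg
        if params.scalp_background_um > 0:
            w = w + _band_limited_noise(rng, n, fs, params.scalp_background_band_hz,
                                        params.scalp_background_um)
        scalp_wave[roi] = w

    for i, (ch_id, chrom) in enumerate(chrom_labels):
        ch = layout.channel(ch_id)
        if not ch.is_short:
            for cond, reg in regressors.items():
                a = params.amplitude(cond, ch_id, ch.roi, chrom)
                if a != 0.0:
                    cerebral[i] += a * reg
        frac = 1.0 if chrom == "O2Hb" else params.scalp_hhb_fraction
        superficial[i] = frac * scalp_wave[ch.roi]

    cerebral_ts = ChannelTimeSeries(cerebral, chrom_labels, fs, 0.0, "chromophore")
    superficial_ts = ChannelTimeSeries(superficial, chrom_labels, fs, 0.0, "chromophore")
    total_ts = ChannelTimeSeries(cerebral + superficial, chrom_labels, fs, 0.0,
                                 "chromophore")

    dpf = DpfSpec(params.subject_age_years)
    od = forward_mbll(total_ts, layout, dpf)

    # systemic oscillations: one phase-diffusing waveform per oscillator.
    # They are blood-volume oscillations, so their OD expression scales
    # with the optical pathlength: amplitude_od applies at the 30 mm
    # reference separation and each row is scaled by its separation.
    t = np.arange(n) / fs
    systemic = np.zeros(n)
    for osc in params.oscillators:
        phase0 = rng.uniform(0, 2 * np.pi)
        jitter = np.cumsum(rng.normal(0.0, osc.phase_jitter / math.sqrt(fs), n))
        systemic += osc.amplitude_od * np.sin(2 * np.pi * osc.frequency_hz * t
                                              + phase0 + jitter)
    sep_scale = np.array([layout.channel(ch_id).separation_mm / 30.0
                          for ch_id, _ in od.labels])[:, None]
    values = od.values + sep_scale * systemic
    n_rows = values.shape[0]
    slopes = rng.normal(0.0, params.drift_slope_od_per_s, size=(n_rows, 1))
    values = values + slopes * t
    if params.drift_walk_od > 0:
        values = values + np.cumsum(
            rng.normal(0.0, params.drift_walk_od, size=(n_rows, n)), axis=1)
    if params.noise_sd_od > 0:
        sep = np.array([layout.channel(ch_id).separation_mm
                        for ch_id, _ in od.labels])[:, None]
        sd = params.noise_sd_od * 10.0 ** ((sep - 30.0) / params.noise_decade_mm)
        values = values + sd * rng.standard_normal((n_rows, n))
    if params.short_channel_noise_od > 0:
        short_rows = [i for i, (ch_id, _) in enumerate(od.labels)
                      if layout.channel(ch_id).is_short]
        values[short_rows] += rng.normal(0.0, params.short_channel_noise_od,
                                         size=(len(short_rows), n))

    od_out = ChannelTimeSeries(values, od.labels, fs, 0.0, "optical_density")
    return od_out, GroundTruth(cerebral_ts, superficial_ts, protocol, params)


def simulate_heart_rate(protocol: StimulusProtocol,
                        params: SimulationParams) -> HeartRateSeries:
    """1 Hz heart-rate series with a condition-independent stimulus-locked
    transient peaking in the post-ISI window."""
    rng = np.random.default_rng(params.seed + 105_943)
    n = int(round(protocol.duration_s))
    t = np.arange(n, dtype=float)
    bpm = np.full(n, params.hr_baseline_bpm)
    if params.hr_transient_bpm != 0.0:
        # gamma-shaped bump peaking hr_transient_peak_s after stimulus onset
        tt = np.arange(0.0, 20.0, 1.0)
        peak = params.hr_transient_peak_s
        bump = (tt / peak) ** 3 * np.exp(3 * (1 - tt / peak))
        train = np.zeros(n)
        for ev in protocol.events:
            onset = ev.onset_s
            if params.hr_clock_jitter_s > 0:
                onset += rng.uniform(-params.hr_clock_jitter_s,
                                     params.hr_clock_jitter_s)
            idx = int(round(onset))
            if 0 <= idx < n:
                train[idx] = 1.0
        bpm = bpm + params.hr_transient_bpm * np.convolve(train, bump)[:n]
    bpm = bpm + np.cumsum(rng.normal(0.0, 0.05, n))  # slow wander
    bpm = bpm + rng.normal(0.0, params.hr_noise_bpm, n)
    return HeartRateSeries(bpm=np.clip(bpm, 30.0, 240.0), t0_s=0.0)


# ---------------------------------------------------------------------------
# between-subject population layer

@dataclass
class PopulationParams:
    """Hyperparameters of the between-subject amplitude heterogeneity.

    Per subject i, condition c and long channel k the O2Hb/HHb amplitude is

        A_{i,c,k} = base_c(roi_k) * s_i + u_{i,c} + w_{i,c,k}

    with a global responsiveness scale s_i ~ LogNormal(0, subject_sigma),
    a condition-level subject deviation u with SD condition_frac * |base|
    (shared across channels - a systemic, ROI-wide effect), and a
    channel-level deviation w with SD channel_frac * |base| + floor (large,
    reflecting the strong channel heterogeneity of scalp-probe recordings,
    where a sizeable minority of channels shows no or an inverted evoked
    response).  Conditions without a cerebral response (base = 0) stay
    exactly null.  Scalp amplitudes scale with s_i.
    """

    template: SimulationParams = field(default_factory=SimulationParams)
    subject_sigma: float = 0.25
    condition_frac: float = 0.10
    channel_frac: float = 0.60
    channel_floor: dict = field(default_factory=lambda: {"O2Hb": 0.35, "HHb": 0.25})
    #: idiosyncratic per-channel effects for conditions without a cerebral
    #: response (residual scalp coupling, arousal); keeps such conditions
    #: honestly variable instead of exactly zero in every subject
    null_channel_floor: dict = field(default_factory=lambda: {"O2Hb": 0.06, "HHb": 0.05})
    age_range_years: tuple[float, float] = (22.0, 61.0)
    hr_baseline_sd_bpm: float = 6.0


def null_population(**overrides) -> PopulationParams:
    """Population in which every evoked effect is zero (global null)."""
    return PopulationParams(template=null_params(),
                            subject_sigma=0.0, condition_frac=0.0,
                            channel_frac=0.0, channel_floor={"O2Hb": 0.0, "HHb": 0.0},
                            null_channel_floor={"O2Hb": 0.0, "HHb": 0.0},
                            **overrides)


def draw_subject_params(population: PopulationParams, seed: int) -> SimulationParams:
    """Draw one subject's SimulationParams from the population model."""
    rng = np.random.default_rng(seed)
    tpl = population.template
    s_i = float(np.exp(rng.normal(0.0, population.subject_sigma)))

    hrf = {k: v * s_i for k, v in tpl.hrf_amplitude.items()}
    offsets: dict = {}
    long_ids = [c for c in range(1, 19) if c not in (2, 10)]
    for cond in CONDITIONS:
        for chrom in CHROMOPHORES:
            bases = [abs(tpl.hrf_amplitude.get((cond, roi, chrom), 0.0))
                     for roi in ("SMA", "S1")]
            base_mag = max(bases)
            if base_mag > 0.0:
                u = rng.normal(0.0, population.condition_frac * base_mag)
                w_sd = (population.channel_frac * base_mag
                        + population.channel_floor.get(chrom, 0.0))
            else:
                u = 0.0
                w_sd = population.null_channel_floor.get(chrom, 0.0)
                if w_sd == 0.0:
                    continue
            w = rng.normal(0.0, w_sd, size=len(long_ids))
            offsets[(cond, chrom)] = {k: u + w[j] for j, k in enumerate(long_ids)}

    scalp = {c: v * s_i for c, v in tpl.scalp_amplitude.items()}
    age = float(rng.uniform(*population.age_range_years))
    hr_base = float(rng.normal(tpl.hr_baseline_bpm, population.hr_baseline_sd_bpm))
    return replace(
        tpl, hrf_amplitude=hrf, scalp_amplitude=scalp,
        channel_amplitude_offsets=offsets, subject_age_years=age,
        hr_baseline_bpm=hr_base,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_study(layout: ProbeLayout, n_subjects: int,
                   population: PopulationParams | None = None,
                   seed: int = 0, n_per_condition: int = 15,
                   baseline_s: float = 300.0):
    """Yield (subject_id, protocol, od, heart_rate, ground_truth) tuples."""
    if population is None:
        population = PopulationParams()
    root = np.random.default_rng(seed)
    for i in range(n_subjects):
        sub_seed = int(root.integers(0, 2**31 - 1))
        protocol = generate_protocol(n_per_condition=n_per_condition,
                                     baseline_s=baseline_s, seed=sub_seed)
        params = draw_subject_params(population, sub_seed + 1)
        od, truth = simulate_recording(layout, protocol, params)
        hr = simulate_heart_rate(protocol, params)
        yield f"subject{i + 1:02d}", protocol, od, hr, truth
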