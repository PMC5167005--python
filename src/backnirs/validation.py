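"""Simulation-based validation experiments for the full pipeline.

Because the study's subject recordings are not deposited, the pipeline is
validated against its own forward model: null calibration (false-positive
rates of the responder test and of the FDR-corrected group families under a
noise-only simulation), parameter recovery (the injected O2Hb amplitude
ordering PAPain > PA30 > Brush and the amplitude magnitudes recovered from
grand-average response scalars), and reproduction of the study's
qualitative statistical structure on population-level cohorts.  These
functions are used by the test suite and the acceptance script; every
experiment is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import preprocess_recording
from .probe import CONDITIONS, build_default_probe
from .simulate import (PopulationParams, SimulationParams, draw_subject_params,
                       generate_protocol, null_params, simulate_recording)
from .stats import ResponderTable, block_average, classify_responders, run_group_analysis


def _pooled_scalars(layout, protocol, params, subject="s"):
    """Per-condition mean over long channels of O2Hb block-average scalars."""
    od, _ = simulate_recording(layout, protocol, params)
    tensor = preprocess_recording(od, layout, params.subject_age_years,
                                  protocol, subject=subject)
    out = {c: [] for c in protocol.conditions}
    blocks = block_average(tensor, subject=subject)
    for b in blocks:
        if b.chromophore == "O2Hb" and b.channel not in (2, 10):
            out[b.condition].append(b.response_scalar)
    return {c: float(np.mean(v)) for c, v in out.items()}, tensor, blocks


def noiseless_reference(seed: int = 0, n_protocols: int = 3) -> dict[str, float]:
    """Deterministic pipeline output for the default amplitudes with every
    noise source off; the oracle against which noisy recovery is judged."""
    layout = build_default_probe()
    acc: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for i in range(n_protocols):
        protocol = generate_protocol(seed=seed + i)
        params = SimulationParams(
            seed=seed + i, noise_sd_od=0.0, drift_slope_od_per_s=0.0,
            drift_walk_od=0.0, oscillators=[],
            scalp_amplitude={c: 0.0 for c in CONDITIONS},
            scalp_background_um=0.0)
        scalars, _, _ = _pooled_scalars(layout, protocol, params)
        for c in CONDITIONS:
            acc[c].append(scalars[c])
    return {c: float(np.mean(v)) for c, v in acc.items()}


@dataclass
class RecoveryResult:
    n_runs: int
    n_subjects: int
    ordering_hits: int
    grand_scalars: list[dict]      # per run: condition -> grand median scalar
    reference: dict[str, float]    # noiseless-pipeline oracle

    @property
    def ordering_rate(self) -> float:
        return self.ordering_hits / self.n_runs

    def recovery_ratio(self, condition: str) -> float:
        vals = [g[condition] for g in self.grand_scalars]
        return float(np.mean(vals) / self.reference[condition])


def amplitude_recovery(n_runs: int = 100, n_subjects: int = 30,
                       seed: int = 0) -> RecoveryResult:
    """Recover the injected amplitude ordering and magnitude from
    grand-average response scalars of identically parameterized cohorts."""
    layout = build_default_probe()
    reference = noiseless_reference(seed)
    hits = 0
    grands = []
    root = np.random.default_rng(seed)
    for _ in range(n_runs):
        per_subject = {c: [] for c in CONDITIONS}
        for _ in range(n_subjects):
            s = int(root.integers(0, 2**31 - 1))
            protocol = generate_protocol(seed=s)
            scalars, _, _ = _pooled_scalars(layout, protocol,
                                            SimulationParams(seed=s + 1))
            for c in CONDITIONS:
                per_subject[c].append(scalars[c])
        grand = {c: float(np.median(v)) for c, v in per_subject.items()}
        grands.append(grand)
        hits += grand["PAPain"] > grand["PA30"] > grand["Brush"]
    return RecoveryResult(n_runs, n_subjects, hits, grands, reference)


def null_responder_rate(n_subjects: int = 11, seed: int = 0,
                        alpha: float = 0.05) -> tuple[float, int]:
    """Fraction of (subject, channel, condition) cells the single-subject
    Wilcoxon test rejects on noise-only recordings; nominally ~alpha."""
    layout = build_default_probe()
    root = np.random.default_rng(seed)
    flags = []
    for i in range(n_subjects):
        s = int(root.integers(0, 2**31 - 1))
        protocol = generate_protocol(seed=s)
        params = null_params(seed=s + 1)
        od, _ = simulate_recording(layout, protocol, params)
        tensor = preprocess_recording(od, layout, params.subject_age_years,
                                      protocol, subject=f"s{i}")
        table = classify_responders(tensor, alpha, subject=f"s{i}")
        for (_, _, _, chrom), (_, flag) in table.entries.items():
            if chrom == "O2Hb":
                flags.append(flag)
    return float(np.mean(flags)), len(flags)


def fdr_null_discovery(n_runs: int = 200, n_subjects: int = 8,
                       n_per_condition: int = 6, baseline_s: float = 100.0,
                       seed: int = 0) -> dict[str, float]:
    """Mean discovery proportion per FDR family on all-null cohorts.

    Under the global null the Benjamini-Hochberg procedure keeps the
    expected discovery proportion of every family at or below q = 0.05.
    """
    layout = build_default_probe()
    root = np.random.default_rng(seed)
    props: dict[str, list[float]] = {}
    for _ in range(n_runs):
        blocks = []
        for i in range(n_subjects):
            s = int(root.integers(0, 2**31 - 1))
            protocol = generate_protocol(n_per_condition=n_per_condition,
                                         baseline_s=baseline_s, seed=s)
            params = null_params(seed=s + 1)
            od, _ = simulate_recording(layout, protocol, params)
            tensor = preprocess_recording(od, layout, params.subject_age_years,
                                          protocol, subject=f"s{i}")
            blocks += block_average(tensor, subject=f"s{i}")
        rep = run_group_analysis([b for b in blocks if b.chromophore == "O2Hb"],
                                 None, "All")
        props.setdefault("friedman", []).append(rep.friedman["significant"].mean())
        for cond, sub in rep.vs_zero.groupby("condition"):
            props.setdefault(f"vs_zero:{cond}", []).append(sub["significant"].mean())
        for pair, sub in rep.posthoc.groupby("pair"):
            props.setdefault(f"posthoc:{pair}", []).append(sub["significant"].mean())
    return {fam: float(np.mean(v)) for fam, v in props.items()}


@dataclass
class PatternResult:
    n_runs: int
    hits: int
    details: list[dict] = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.hits / self.n_runs


def pattern_reproduction(n_runs: int = 12, n_subjects: int = 20,
                         seed: int = 0) -> PatternResult:
    """Reproduce the study's qualitative O2Hb structure on population
    cohorts: both pressure conditions FDR-significant against zero across
    the probe while brushing stays clean, and the post hoc contrasts
    separate pressure from brushing but not painful from nonpainful
    pressure.  A family expected to be null is allowed the single stray
    discovery the FDR criterion itself tolerates.
    """
    layout = build_default_probe()
    root = np.random.default_rng(seed)
    pop = PopulationParams()
    hits = 0
    details = []
    for _ in range(n_runs):
        blocks = []
        table = ResponderTable({})
        for i in range(n_subjects):
            s = int(root.integers(0, 2**31 - 1))
            protocol = generate_protocol(seed=s)
            params = draw_subject_params(pop, s + 1)
            od, _ = simulate_recording(layout, protocol, params)
            tensor = preprocess_recording(od, layout, params.subject_age_years,
                                          protocol, subject=f"s{i}")
            blocks += block_average(tensor, subject=f"s{i}")
            classify_responders(tensor, subject=f"s{i}", table=table)
        rep = run_group_analysis([b for b in blocks if b.chromophore == "O2Hb"],
                                 table, "All")
        vz = rep.vs_zero
        ph = rep.posthoc

        def n_sig(frame, col, val):
            return int(frame[(frame[col] == val) & frame["significant"]].shape[0])

        d = {"pain_vs_zero": n_sig(vz, "condition", "PAPain"),
             "pa30_vs_zero": n_sig(vz, "condition", "PA30"),
             "brush_vs_zero": n_sig(vz, "condition", "Brush"),
             "pain_vs_brush": n_sig(ph, "pair", "PAPain vs Brush"),
             "pa30_vs_brush": n_sig(ph, "pair", "PA30 vs Brush"),
             "pain_vs_pa30": n_sig(ph, "pair", "PAPain vs PA30")}
        d["match"] = (d["pain_vs_zero"] >= 3 and d["pa30_vs_zero"] >= 3
                      and d["brush_vs_zero"] <= 1
                      and d["pain_vs_brush"] + d["pa30_vs_brush"] >= 2
                      and d["pain_vs_pa30"] <= 1)
        details.append(d)
        hits += d["match"]
    return PatternResult(n_runs, hits, details)
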