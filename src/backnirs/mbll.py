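"""Modified Beer-Lambert law (MBLL), forward and inverse.

The MBLL relates optical-density changes at two wavelengths to hemoglobin
concentration changes through a per-channel 2x2 linear system

    dOD(lambda) = [e_O2Hb(lambda) dC_O2Hb + e_HHb(lambda) dC_HHb] * d * DPF(lambda)

with molar extinction coefficients e (base-10, cm^-1/M, shipped as package
data), the source-detector distance d in cm, and the dimensionless
differential pathlength factor DPF accounting for the longer scattered
photon path.  The DPF is evaluated from a published closed-form general
equation in subject age and wavelength (coefficients shipped as package
data); one DPF per wavelength is shared across channels.

Concentrations are expressed in umol/L throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .probe import ProbeLayout, WAVELENGTHS_NM
from .timeseries import ChannelTimeSeries

CHROMOPHORES = ("O2Hb", "HHb")


def _read_table(name: str) -> list[dict]:
    ref = resources.files("backnirs.data").joinpath(name)
    with ref.open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def load_extinction_table() -> dict[int, dict[str, float]]:
    """Molar extinction coefficients, {wavelength_nm: {chromophore: cm^-1/M}}."""
    table = {}
    for row in _read_table("extinction_coefficients.tsv"):
        table[int(row["wavelength_nm"])] = {
            "O2Hb": float(row["o2hb"]),
            "HHb": float(row["hhb"]),
        }
    return table


def _load_dpf_coefficients() -> dict[str, float]:
    return {r["coefficient"]: float(r["value"]) for r in _read_table("dpf_coefficients.tsv")}


_DPF_COEF = _load_dpf_coefficients()


def compute_dpf(age_years: float, wavelength_nm: float) -> float:
    """Age- and wavelength-dependent differential pathlength factor.

    Evaluates the published general DPF equation for the adult head
    (cubic polynomial in wavelength plus a power law in age); strictly
    increasing in age at fixed wavelength.
    """
    if not 0 <= age_years <= 100:
        raise ValueError(f"age {age_years} outside [0, 100] years")
    if not 690 <= wavelength_nm <= 950:
        raise ValueError(f"wavelength {wavelength_nm} nm outside the 690-950 nm validity range")
    c = _DPF_COEF
    lam = float(wavelength_nm)
    return (c["alpha"] + c["beta"] * float(age_years) ** c["gamma"]
            + c["delta"] * lam**3 + c["epsilon"] * lam**2 + c["zeta"] * lam)


@dataclass
class DpfSpec:
    """Subject age and the DPF it implies at each measurement wavelength."""

    age_years: float
    dpf_by_wavelength: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dpf_by_wavelength:
            self.dpf_by_wavelength = {
                wl: compute_dpf(self.age_years, wl) for wl in WAVELENGTHS_NM
            }
        for wl, dpf in self.dpf_by_wavelength.items():
            if dpf <= 0:
                raise ValueError(f"non-positive DPF {dpf} at {wl} nm")


def _design_matrix(wavelengths, dpf: DpfSpec, separation_mm: float,
                   extinction_table) -> np.ndarray:
    """2x2 map from (dO2Hb, dHHb) in umol/L to dOD at the two wavelengths."""
    d_cm = separation_mm / 10.0
    rows = []
    for wl in wavelengths:
        if wl not in extinction_table:
            raise KeyError(f"no extinction coefficients for {wl} nm")
        eps = extinction_table[wl]
        dpf_wl = dpf.dpf_by_wavelength[wl]
        rows.append([eps[c] * 1e-6 * d_cm * dpf_wl for c in CHROMOPHORES])
    return np.array(rows)


def forward_mbll(chromophores: ChannelTimeSeries, layout: ProbeLayout,
                 dpf: DpfSpec, extinction_table=None) -> ChannelTimeSeries:
    """Project chromophore concentration changes to optical densities."""
    if chromophores.kind != "chromophore":
        raise ValueError("input must be a chromophore series")
    if extinction_table is None:
        extinction_table = load_extinction_table()
    wavelengths = sorted(extinction_table)
    labels = []
    out = np.empty((len(layout.channels) * len(wavelengths), chromophores.n_samples))
    i = 0
    for ch in layout.channels:
        conc = np.vstack([chromophores.row(ch.id, c) for c in CHROMOPHORES])
        a = _design_matrix(wavelengths, dpf, ch.separation_mm, extinction_table)
        od = a @ conc
        for j, wl in enumerate(wavelengths):
            out[i] = od[j]
            labels.append((ch.id, wl))
            i += 1
    return ChannelTimeSeries(out, labels, chromophores.sampling_rate_hz,
                             chromophores.t0_s, kind="optical_density")


def mbll_invert(od: ChannelTimeSeries, layout: ProbeLayout, dpf: DpfSpec,
                extinction_table=None) -> ChannelTimeSeries:
    """Solve the per-channel 2x2 MBLL system for (dO2Hb, dHHb) in umol/L."""
    if od.kind != "optical_density":
        raise ValueError("input must be an optical-density series")
    if extinction_table is None:
        extinction_table = load_extinction_table()
    wavelengths = sorted(extinction_table)
    if len(wavelengths) != 2:
        raise ValueError("exactly two wavelengths are required")
    labels = []
    out = np.empty((len(layout.channels) * 2, od.n_samples))
    i = 0
    for ch in layout.channels:
        rhs = np.vstack([od.row(ch.id, wl) for wl in wavelengths])
        a = _design_matrix(wavelengths, dpf, ch.separation_mm, extinction_table)
        if abs(np.linalg.det(a)) < 1e-15:
            raise np.linalg.LinAlgError(
                f"singular extinction matrix for channel {ch.id}; "
                "wavelengths are spectrally collinear")
        conc = np.linalg.solve(a, rhs)
        for j, chrom in enumerate(CHROMOPHORES):
            out[i] = conc[j]
            labels.append((ch.id, chrom))
            i += 1
    return ChannelTimeSeries(out, labels, od.sampling_rate_hz, od.t0_s,
                             kind="chromophore")
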