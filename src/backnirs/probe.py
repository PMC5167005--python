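"""Probe geometry and channel bookkeeping.

The montage covers two regions of interest (ROIs) on the sensorimotor
cortex: the bilateral supplementary motor area (SMA, channels 1-6) and the
bilateral primary somatosensory cortex around the midline (S1, channels
7-18).  Two short-separation channels (2 in the SMA, 10 in S1; ~11 mm
source-detector distance) sample mainly extracerebral tissue and serve as
regressors for the short-separation regression (SSR): channel 2 corrects
channels 1 and 3-6, channel 10 corrects channels 7-9 and 11-18.

Per-channel long separations are nominal values within the 25-45 mm design
range; no downstream computation depends on their exact magnitudes beyond
the per-channel pathlength term of the Beer-Lambert conversion, so they are
plain configuration and can be edited in a serialized layout file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

WAVELENGTHS_NM = (760, 850)
CONDITIONS = ("PA30", "PAPain", "Brush")

SMA_CHANNELS = tuple(range(1, 7))
S1_CHANNELS = tuple(range(7, 19))
SHORT_CHANNELS = (2, 10)
#: Long channels entering group statistics (short channels are excluded).
LONG_CHANNELS = tuple(c for c in range(1, 19) if c not in SHORT_CHANNELS)


@dataclass(frozen=True)
class Optode:
    id: int
    kind: str  # "source" | "detector"
    position_1020: str | None = None


@dataclass(frozen=True)
class Channel:
    id: int
    source_id: int
    detector_id: int
    separation_mm: float
    roi: str  # "SMA" | "S1"
    is_short: bool = False


@dataclass
class ProbeLayout:
    """Optodes, channels and the long-to-short SSR correction map."""

    optodes: list[Optode]
    channels: list[Channel]
    ssr_map: dict[int, int]

    def channel(self, channel_id: int) -> Channel:
        for ch in self.channels:
            if ch.id == channel_id:
                return ch
        raise KeyError(f"no channel with id {channel_id}")

    @property
    def long_channel_ids(self) -> list[int]:
        return [c.id for c in self.channels if not c.is_short]

    @property
    def short_channel_ids(self) -> list[int]:
        return [c.id for c in self.channels if c.is_short]

    def roi_of(self, channel_id: int) -> str:
        return self.channel(channel_id).roi

    def to_yaml(self, path) -> None:
        doc = {
            "optodes": [asdict(o) for o in self.optodes],
            "channels": [asdict(c) for c in self.channels],
            "ssr_map": dict(self.ssr_map),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProbeLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        layout = cls(
            optodes=[Optode(**o) for o in doc["optodes"]],
            channels=[Channel(**c) for c in doc["channels"]],
            ssr_map={int(k): int(v) for k, v in doc["ssr_map"].items()},
        )
        violations = validate_probe(layout)
        if violations:
            raise ValueError("invalid probe layout: " + "; ".join(violations))
        return layout


# (channel id, source, detector, separation mm, roi, short?)
_DEFAULT_CHANNELS = [
    (1, 1, 1, 30.0, "SMA", False),
    (2, 1, 2, 11.0, "SMA", True),
    (3, 1, 3, 35.0, "SMA", False),
    (4, 2, 1, 38.0, "SMA", False),
    (5, 2, 3, 30.0, "SMA", False),
    (6, 3, 1, 42.0, "SMA", False),
    (7, 4, 4, 30.0, "S1", False),
    (8, 4, 5, 35.0, "S1", False),
    (9, 5, 4, 32.0, "S1", False),
    (10, 4, 6, 11.0, "S1", True),
    (11, 5, 5, 28.0, "S1", False),
    (12, 5, 6, 40.0, "S1", False),
    (13, 6, 5, 33.0, "S1", False),
    (14, 6, 6, 30.0, "S1", False),
    (15, 6, 7, 36.0, "S1", False),
    (16, 7, 6, 29.0, "S1", False),
    (17, 7, 7, 31.0, "S1", False),
    (18, 8, 8, 44.0, "S1", False),
]

_SOURCE_POSITIONS = {1: "FC1", 2: "FCz", 3: "FC2", 4: "C1", 5: "Cz",
                     6: "C2", 7: "CP1", 8: "CP2"}
_DETECTOR_POSITIONS = {1: "FC3h", 2: "FC1h", 3: "FC4h", 4: "C3h", 5: "CCP1",
                       6: "CCP2", 7: "CPz", 8: "CPP2"}


def build_default_probe() -> ProbeLayout:
    """Return the study montage: 8 sources, 8 detectors, 18 channels."""
    optodes = [Optode(i, "source", _SOURCE_POSITIONS[i]) for i in range(1, 9)]
    optodes += [Optode(i, "detector", _DETECTOR_POSITIONS[i]) for i in range(1, 9)]
    channels = [Channel(*row) for row in _DEFAULT_CHANNELS]
    ssr_map = {c: 2 for c in (1, 3, 4, 5, 6)}
    ssr_map.update({c: 10 for c in (7, 8, 9, 11, 12, 13, 14, 15, 16, 17, 18)})
    return ProbeLayout(optodes=optodes, channels=channels, ssr_map=ssr_map)


def validate_probe(layout: ProbeLayout) -> list[str]:
    """Check all layout invariants; violations are returned, not raised."""
    v: list[str] = []
    if len(layout.channels) != 18:
        v.append(f"channel count != 18 (got {len(layout.channels)})")
    ids = [c.id for c in layout.channels]
    if len(set(ids)) != len(ids):
        v.append("duplicate channel ids")
    for kind in ("source", "detector"):
        oids = [o.id for o in layout.optodes if o.kind == kind]
        if len(set(oids)) != len(oids):
            v.append(f"duplicate {kind} ids")
    by_id = {c.id: c for c in layout.channels}
    for ch in layout.channels:
        expected_short = ch.id in SHORT_CHANNELS
        if ch.is_short != expected_short:
            v.append(f"channel {ch.id}: is_short={ch.is_short}, expected {expected_short}")
        if ch.is_short:
            if not 10.0 <= ch.separation_mm <= 12.0:
                v.append(f"channel {ch.id}: short separation {ch.separation_mm} mm not ~11 mm")
        else:
            if not 25.0 <= ch.separation_mm <= 45.0:
                v.append(f"channel {ch.id}: separation {ch.separation_mm} mm outside 25-45 mm")
        if ch.roi not in ("SMA", "S1"):
            v.append(f"channel {ch.id}: unknown roi {ch.roi!r}")
    short_ids = {c.id for c in layout.channels if c.is_short}
    for long_id, short_id in layout.ssr_map.items():
        if long_id in short_ids:
            v.append(f"ssr_map: short channel {long_id} used as SSR target")
        if short_id not in short_ids:
            v.append(f"ssr_map: channel {long_id} corrected by non-short channel {short_id}")
        if long_id in by_id and short_id in by_id and not by_id[long_id].is_short:
            if by_id[long_id].roi != by_id[short_id].roi:
                v.append(f"ssr_map: channel {long_id} mapped across ROIs")
    long_ids = {c.id for c in layout.channels if not c.is_short}
    missing = long_ids - set(layout.ssr_map)
    if missing:
        v.append(f"ssr_map: long channels without short-channel mapping: {sorted(missing)}")
    return v
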