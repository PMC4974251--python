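"""Electrode montages: channel labels, roles and approximate scalp layout.

Coordinates are a flat schematic projection of the 10-10 system (x: left
negative to right positive, y: front positive to back negative), in
arbitrary head units.  They only parameterize the generator's spatial
falloff, so schematic accuracy is sufficient; no volume conduction is
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

SCALP = "scalp"
MASTOID = "mastoid"

# Required for the analysis chain: vertex/parietal measurement sites, the
# central motor pair, and the reference pair.
REQUIRED_CHANNELS = ("Cz", "Pz", "C3", "C4", "M1", "M2")

_ROWS = [
    ("Fp", 0.9), ("AF", 0.7), ("F", 0.5), ("FC", 0.25), ("C", 0.0),
    ("CP", -0.25), ("P", -0.5), ("PO", -0.7), ("O", -0.9),
]


def _ten_ten_coords() -> dict[str, tuple[float, float]]:
    coords: dict[str, tuple[float, float]] = {}
    for prefix, y in _ROWS:
        coords[prefix.replace("Fp", "Fp") + "z"] = (0.0, y)
        for i, x in zip((1, 3, 5, 7), (0.2, 0.4, 0.6, 0.8)):
            coords[f"{prefix}{i}"] = (-x, y)
            coords[f"{prefix}{i + 1}"] = (x, y)
    # conventional synonyms / extras
    coords["Fpz"] = (0.0, 0.9)
    coords["Oz"] = (0.0, -0.9)
    coords["Iz"] = (0.0, -1.0)
    coords["F9"] = (-0.9, 0.5)
    coords["F10"] = (0.9, 0.5)
    coords["M1"] = (-0.85, -0.75)
    coords["M2"] = (0.85, -0.75)
    return coords


_COORDS = _ten_ten_coords()


@dataclass
class Montage:
    """Ordered channel labels with roles (scalp or mastoid) and layout."""

    channels: list[str]
    roles: dict[str, str]
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for ch in self.channels:
            self.roles.setdefault(ch, SCALP)
            if ch not in self.coords and ch in _COORDS:
                self.coords[ch] = _COORDS[ch]

    @property
    def mastoids(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == MASTOID]

    @property
    def scalp(self) -> list[str]:
        return [c for c in self.channels if self.roles[c] == SCALP]

    def require(self, *labels: str) -> None:
        missing = [l for l in labels if l not in self.channels]
        if missing:
            raise ValueError(f"montage is missing required channel(s): {missing}")

    def index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in montage") from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": self.channels,
            "roles": self.roles,
            "coords": {k: list(v) for k, v in self.coords.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(
            channels=list(payload["channels"]),
            roles=dict(payload["roles"]),
            coords={k: tuple(v) for k, v in payload.get("coords", {}).items()},
        )


def default_montage() -> Montage:
    """64 scalp channels (10-10 layout) plus two mastoids."""
    scalp = [
        "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
        "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
        "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
        "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
        "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
        "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
        "F9", "F10", "AF5", "AF6", "C7", "C8", "P9", "P10", "Iz",
    ]
    # fill a few non-tabled labels with interpolated positions
    extra = {"AF5": (-0.5, 0.7), "AF6": (0.5, 0.7), "C7": (-0.85, 0.0),
             "C8": (0.85, 0.0), "P9": (-0.9, -0.5), "P10": (0.9, -0.5)}
    channels = scalp + ["M1", "M2"]
    roles = {c: SCALP for c in scalp}
    roles.update({"M1": MASTOID, "M2": MASTOID})
    m = Montage(channels=channels, roles=roles, coords=dict(extra))
    assert len(m.scalp) == 64
    return m


def compact_montage() -> Montage:
    """Eight channels: the six the analysis needs plus Fz and Oz.

    Used for desk-scale simulation runs; the signal content at the
    measurement sites is identical to the full montage.
    """
    scalp = ["Fz", "Cz", "Pz", "Oz", "C3", "C4"]
    roles = {c: SCALP for c in scalp}
    roles.update({"M1": MASTOID, "M2": MASTOID})
    return Montage(channels=scalp + ["M1", "M2"], roles=roles)
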