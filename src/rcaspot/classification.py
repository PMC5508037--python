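"""Cross-channel artifact exclusion and allele-class assignment.

A genuine rolling-circle product carries one detection-probe fluorophore, so
it appears in exactly one non-nuclear channel; autofluorescent debris shows
up at the same position in several wavelengths. Spots coincident across
different non-nuclear channels are therefore flagged "unspecific" in every
channel involved and excluded from quantification — including coincidences
between the wild-type and mutant channels, which are never arbitrated by
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial import cKDTree
from skimage.draw import disk

from .detection import Spot
from .imaging import CHANNEL_CLASSES

ALLELE_CLASSES = ("wildtype", "mutant", "control", "unspecific")

#: default overview colors (RGB, 0-255): wild-type green, mutant red,
#: control cyan — mutant is drawn last so it reads on top.
DEFAULT_COLORS = {
    "wildtype": (0, 200, 0),
    "mutant": (230, 0, 0),
    "control": (0, 180, 180),
}
DRAW_ORDER = ("control", "wildtype", "mutant")


@dataclass
class ChannelMap:
    """Mapping channel name → target class, e.g. {"Cy3": "wildtype"}.

    ``probes`` optionally records which detection oligo sits behind each
    channel (assay metadata; not used computationally).
    """

    classes: dict[str, str]
    probes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, cls in self.classes.items():
            if cls not in CHANNEL_CLASSES:
                raise ValueError(f"channel {ch!r}: unknown class {cls!r}")

    def require_quantifiable(self) -> None:
        vals = set(self.classes.values())
        if "wildtype" not in vals or "mutant" not in vals:
            raise ValueError(
                "mutation quantification needs >=1 wildtype and >=1 mutant channel"
            )

    def class_of(self, channel: str) -> str:
        if channel not in self.classes:
            raise KeyError(f"channel {channel!r} not in channel map")
        return self.classes[channel]

    def non_nuclear(self) -> list[str]:
        return [c for c, k in self.classes.items() if k != "nuclear"]

    @classmethod
    def from_yaml(cls, path) -> "ChannelMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc, dict) and "classes" in doc:
            return cls(classes=dict(doc["classes"]), probes=dict(doc.get("probes", {})))
        return cls(classes=dict(doc))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"classes": self.classes, "probes": self.probes}, fh)


def flag_multichannel(
    spots_by_channel: dict[str, list[Spot]],
    radius: float = 2.0,
    nuclear_channels: tuple[str, ...] | list[str] = (),
) -> dict[str, list[Spot]]:
    """Flag spots visible at the same position in >= 2 non-nuclear channels.

    A spot is flagged unspecific iff its center lies within ``radius`` px
    (Euclidean) of a spot in a *different* non-nuclear channel; flags are set
    symmetrically in all channels involved. Nuclear-channel spot lists pass
    through untouched and never participate in matching. Flagged spots are
    retained (for tables and audit), not deleted.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    nuclear = set(nuclear_channels)
    match_channels = [c for c in spots_by_channel if c not in nuclear]
    coords = {
        c: np.array([[s.y, s.x] for s in spots_by_channel[c]], dtype=float).reshape(-1, 2)
        for c in match_channels
    }
    trees = {c: cKDTree(coords[c]) if len(coords[c]) else None for c in match_channels}
    for c in match_channels:
        if not len(coords[c]):
            continue
        flagged = np.zeros(len(coords[c]), dtype=bool)
        for other in match_channels:
            if other == c or trees[other] is None:
                continue
            hits = trees[other].query_ball_point(coords[c], r=radius)
            flagged |= np.array([len(h) > 0 for h in hits])
        for spot, f in zip(spots_by_channel[c], flagged):
            if f:
                spot.unspecific = True
    return spots_by_channel


def assign_allele(
    spots_by_channel: dict[str, list[Spot]], channel_map: ChannelMap
) -> dict[str, list[Spot]]:
    """Give every spot its allele class from the channel map.

    Unflagged spots inherit their channel's class; flagged spots become
    "unspecific" regardless of channel.
    """
    for channel, spots in spots_by_channel.items():
        cls = channel_map.class_of(channel)
        for s in spots:
            s.allele = "unspecific" if s.unspecific else cls
    return spots_by_channel


def render_overview(
    spots: list[Spot],
    canvas_shape: tuple[int, int],
    dilation_radius: int = 50,
    colors: dict[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Color-coded whole-tissue overview: each kept spot as a filled disk.

    Spots are enlarged far beyond their physical size so single transcripts
    read at tissue scale. Draw order is fixed (control, wild-type, mutant) so
    mutant disks sit on top where classes overlap; flagged spots are skipped.
    Returns an RGB uint8 image.
    """
    if dilation_radius < 1:
        raise ValueError("dilation_radius must be >= 1")
    colors = dict(DEFAULT_COLORS if colors is None else colors)
    canvas = np.zeros((*canvas_shape, 3), dtype=np.uint8)
    by_class: dict[str, list[Spot]] = {k: [] for k in DRAW_ORDER}
    for s in spots:
        if s.unspecific or s.allele in (None, "unspecific"):
            continue
        if s.allele in by_class:
            by_class[s.allele].append(s)
    for cls in DRAW_ORDER:
        if cls not in colors:
            continue
        col = np.array(colors[cls], dtype=np.uint8)
        for s in by_class[cls]:
            rr, cc = disk((s.y, s.x), dilation_radius, shape=canvas_shape)
            canvas[rr, cc] = col
    return canvas
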