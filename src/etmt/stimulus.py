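"""Trail-making stimulus layouts.

Four stimuli are used, mirroring a screen-based TMT battery:

* ``tmt_a_simple``  — numbers 1..8, visited in ascending order;
* ``tmt_a_complex`` — numbers 1..25, ascending;
* ``tmt_b_simple``  — numbers 1..4 and letters A..D, visited 1,A,2,B,3,C,4,D;
* ``tmt_b_complex`` — numbers 1..12 and letters A..L, alternating likewise.

Each target is an AOI (area of interest): a disc the participant is expected
to fixate.  Layouts are generated by seeded rejection sampling so that AOIs
never overlap; the study's original on-screen coordinates are not published,
so generated layouts are statistically, not literally, equivalent.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STIMULUS_IDS = ("tmt_a_simple", "tmt_a_complex", "tmt_b_simple", "tmt_b_complex")

DEFAULT_RADIUS_PX = 40.0
DEFAULT_WIDTH = 1280
DEFAULT_HEIGHT = 1024
# minimum center separation as a multiple of the radius; bounded retries give
# a deterministic failure mode on impossible canvases
MIN_SEPARATION_FACTOR = 2.5
MAX_PLACEMENT_RETRIES = 10_000


class LayoutError(ValueError):
    """Unknown stimulus or impossible AOI placement."""


@dataclass(frozen=True)
class AOI:
    """A circular target: label ("1".."25" or "A".."L"), center, radius in px."""

    label: str
    cx: float
    cy: float
    radius: float

    def contains(self, x: float, y: float) -> bool:
        # boundary counts as inside
        return math.hypot(x - self.cx, y - self.cy) <= self.radius


@dataclass
class StimulusLayout:
    stimulus_id: str
    width: int
    height: int
    aois: list[AOI] = field(default_factory=list)
    expected_sequence: list[str] = field(default_factory=list)

    def aoi(self, label: str) -> AOI:
        for a in self.aois:
            if a.label == label:
                return a
        raise KeyError(label)

    def validate(self) -> None:
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            raise LayoutError("duplicate AOI labels")
        if sorted(self.expected_sequence) != sorted(labels):
            raise LayoutError("expected_sequence must name every AOI exactly once")
        for i, a in enumerate(self.aois):
            for b in self.aois[i + 1:]:
                if math.hypot(a.cx - b.cx, a.cy - b.cy) < a.radius + b.radius:
                    raise LayoutError(f"AOIs {a.label} and {b.label} overlap")


def expected_sequence(stimulus_id: str) -> list[str]:
    """The correct visiting order for a stimulus.

    TMT-A is ascending numbers; TMT-B alternates number and letter, both
    subsequences ascending (1, A, 2, B, ...).
    """
    if stimulus_id == "tmt_a_simple":
        return [str(i) for i in range(1, 9)]
    if stimulus_id == "tmt_a_complex":
        return [str(i) for i in range(1, 26)]
    if stimulus_id == "tmt_b_simple":
        n = 4
    elif stimulus_id == "tmt_b_complex":
        n = 12
    else:
        raise LayoutError(f"unknown stimulus_id {stimulus_id!r}")
    seq = []
    for i in range(n):
        seq.append(str(i + 1))
        seq.append(string.ascii_uppercase[i])
    return seq


def make_layout(stimulus_id: str, width: int = DEFAULT_WIDTH,
                height: int = DEFAULT_HEIGHT, seed: int = 0,
                radius: float = DEFAULT_RADIUS_PX) -> StimulusLayout:
    """Generate a random non-overlapping layout for one of the four stimuli.

    Positions are drawn uniformly with rejection sampling: a candidate center
    must be at least ``MIN_SEPARATION_FACTOR * radius`` from every accepted
    center and fully on the canvas.  Same seed, same layout.
    """
    seq = expected_sequence(stimulus_id)  # validates stimulus_id
    labels = sorted(seq, key=lambda t: (t.isalpha(), int(t) if t.isdigit() else ord(t)))
    rng = np.random.default_rng(seed)
    min_sep = MIN_SEPARATION_FACTOR * radius
    centers: list[tuple[float, float]] = []
    for _ in labels:
        for attempt in range(MAX_PLACEMENT_RETRIES):
            x = rng.uniform(radius, width - radius)
            y = rng.uniform(radius, height - radius)
            if all(math.hypot(x - cx, y - cy) >= min_sep for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise LayoutError(
                f"could not place {len(labels)} AOIs of radius {radius} on "
                f"{width}x{height} canvas after {MAX_PLACEMENT_RETRIES} retries")
    layout = StimulusLayout(
        stimulus_id=stimulus_id, width=width, height=height,
        aois=[AOI(lbl, cx, cy, radius) for lbl, (cx, cy) in zip(labels, centers)],
        expected_sequence=seq)
    layout.validate()
    return layout


def make_all_layouts(width: int = DEFAULT_WIDTH, height: int = DEFAULT_HEIGHT,
                     seed: int = 0, radius: float = DEFAULT_RADIUS_PX
                     ) -> dict[str, StimulusLayout]:
    """One layout per stimulus, with per-stimulus derived seeds."""
    return {sid: make_layout(sid, width, height, seed + k, radius)
            for k, sid in enumerate(STIMULUS_IDS)}


def aoi_hit(layout: StimulusLayout, x: float, y: float) -> str | None:
    """Label of the AOI disc containing (x, y), or None.

    Non-overlap is a layout invariant, so at most one AOI can contain the
    point; a point exactly on a boundary circle counts as inside.
    """
    for a in layout.aois:
        if a.contains(x, y):
            return a.label
    return None


# ---------------------------------------------------------------------------
# JSON persistence

def save_layout(layout: StimulusLayout, path: str | Path) -> None:
    doc = {
        "stimulus_id": layout.stimulus_id,
        "width": layout.width,
        "height": layout.height,
        "aois": [{"label": a.label, "cx": a.cx, "cy": a.cy, "radius": a.radius}
                 for a in layout.aois],
        "expected_sequence": layout.expected_sequence,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_layout(path: str | Path) -> StimulusLayout:
    with open(path) as fh:
        doc = json.load(fh)
    layout = StimulusLayout(
        stimulus_id=doc["stimulus_id"], width=doc["width"], height=doc["height"],
        aois=[AOI(d["label"], d["cx"], d["cy"], d["radius"]) for d in doc["aois"]],
        expected_sequence=list(doc["expected_sequence"]))
    layout.validate()
    return layout


def save_layouts(layouts: dict[str, StimulusLayout], path: str | Path) -> None:
    doc = {sid: {"stimulus_id": l.stimulus_id, "width": l.width, "height": l.height,
                 "aois": [{"label": a.label, "cx": a.cx, "cy": a.cy, "radius": a.radius}
                          for a in l.aois],
                 "expected_sequence": l.expected_sequence}
           for sid, l in layouts.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_layouts(path: str | Path) -> dict[str, StimulusLayout]:
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for sid, d in doc.items():
        layout = StimulusLayout(
            stimulus_id=d["stimulus_id"], width=d["width"], height=d["height"],
            aois=[AOI(a["label"], a["cx"], a["cy"], a["radius"]) for a in d["aois"]],
            expected_sequence=list(d["expected_sequence"]))
        layout.validate()
        out[sid] = layout
    return out
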