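"""Mamdani fuzzy-inference scoring.

Two configured systems turn high-level gaze features into interpretable
screening scores on [0, 1]:

* visual search speed — inputs: normalized scanpath score (FH1) and total
  completion time (FH2).  A participant with few path deviations who finishes
  quickly searches efficiently and scores high.
* focused attention — inputs: normalized error count (FH3) and
  inattentional-blindness count (FH4).  Few errors and no replayed visit runs
  mean the participant stayed on task and scores high.

Each input and the output carry three trapezoidal sets (Low/Medium/High) and
the rule base is the full 3x3 grid (9 rules).  Inference uses the standard
Mamdani operators: AND = min, implication = min, aggregation = max,
defuzzification = centroid on a uniform grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

DEFAULT_RESOLUTION = 1e-3
# Input Low/Medium/High trapezoids on [0,1].  Adjacent sets cross at full
# membership (each falling edge lies under the neighbour's plateau), so the
# strongest firing rule is never attenuated mid-transition — that keeps the
# centroid-defuzzified score monotone in each input, which the default set
# partition (adjacent sets crossing at 0.5) cannot guarantee when neighbouring
# rules share a consequent.
DEFAULT_INPUT_SETS = {
    "low": (0.0, 0.0, 0.2, 0.4),
    "medium": (0.0, 0.2, 0.6, 0.8),
    "high": (0.4, 0.6, 1.0, 1.0),
}
# Output bands: standard overlapping partition with full coverage
DEFAULT_OUTPUT_SETS = {
    "low": (0.0, 0.0, 0.2, 0.4),
    "medium": (0.2, 0.4, 0.6, 0.8),
    "high": (0.6, 0.8, 1.0, 1.0),
}
DEFAULT_SETS = DEFAULT_OUTPUT_SETS  # historical alias
# antecedent bands of the *badness* inputs -> output band of the *goodness*
# score; symmetric in the two inputs
DEFAULT_RULES = {
    ("low", "low"): "high",
    ("low", "medium"): "high",
    ("medium", "low"): "high",
    ("medium", "medium"): "medium",
    ("low", "high"): "medium",
    ("high", "low"): "medium",
    ("medium", "high"): "low",
    ("high", "medium"): "low",
    ("high", "high"): "low",
}

# FH2 reference ceiling: slightly above the longest whole-battery completion
# time seen in practice (~168 s), so normalized times stay on [0, 1]
DEFAULT_MAX_TIME_MS = 180_000.0
DEFAULT_IB_CAP = 3.0

VSS_DEFICITS = ("processing_speed", "visual_attention")
FA_DEFICITS = ("motor_impairment", "attentional_disengagement", "memory",
               "neuropsychological_impairment", "executive_functioning")


class FuzzyConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoidal membership function with breakpoints a <= b <= c <= d.

    Membership rises linearly on [a, b], is 1 on [b, c], falls on [c, d];
    a == b or c == d makes the corresponding edge a vertical step.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise FuzzyConfigError(
                f"trapezoid breakpoints must be ordered, got {(self.a, self.b, self.c, self.d)}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        if self.b > self.a:
            rise = (x - self.a) / (self.b - self.a)
            out = np.where((x >= self.a) & (x < self.b), rise, out)
        if self.d > self.c:
            fall = (self.d - x) / (self.d - self.c)
            out = np.where((x > self.c) & (x <= self.d), fall, out)
        return out if out.ndim else float(out)


def trapezoid_membership(mf: TrapezoidMF, x: float) -> float:
    """Membership degree of ``x`` in ``mf`` (convenience wrapper)."""
    return float(mf(x))


@dataclass
class FuzzyVariable:
    name: str
    universe: tuple[float, float]
    sets: dict[str, TrapezoidMF]

    def validate(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise FuzzyConfigError(f"{self.name}: empty universe")
        grid = np.linspace(lo, hi, 201)
        cover = np.zeros_like(grid)
        for mf in self.sets.values():
            cover = np.maximum(cover, mf(grid))
        if np.any(cover <= 0):
            raise FuzzyConfigError(f"{self.name}: sets do not cover the universe")


@dataclass
class MamdaniFIS:
    """A two-input, one-output Mamdani system with a full rule grid."""

    inputs: list[FuzzyVariable]
    output: FuzzyVariable
    rules: dict[tuple[str, str], str]

    def validate(self) -> None:
        if len(self.inputs) != 2:
            raise FuzzyConfigError("exactly two inputs expected")
        for v in self.inputs + [self.output]:
            v.validate()
        combos = {(s1, s2) for s1 in self.inputs[0].sets for s2 in self.inputs[1].sets}
        if set(self.rules) != combos:
            raise FuzzyConfigError("rule base must cover every antecedent combination once")
        for cons in self.rules.values():
            if cons not in self.output.sets:
                raise FuzzyConfigError(f"unknown consequent set {cons!r}")


def mamdani_evaluate(fis: MamdaniFIS, x1: float, x2: float,
                     resolution: float = DEFAULT_RESOLUTION) -> tuple[float, bool]:
    """Crisp score for inputs (x1, x2); returns ``(score, degenerate)``.

    Inputs are clipped to their universes.  AND = min over the two antecedent
    memberships, implication clips the consequent set, aggregation is the
    pointwise max, and the score is the centroid of the aggregate on a uniform
    grid of the given step.  If the aggregate is identically zero (possible
    only under a misconfigured universe) the universe midpoint is returned
    with ``degenerate=True``.
    """
    if not fis.rules:
        raise FuzzyConfigError("empty rule base")
    if resolution <= 0:
        raise FuzzyConfigError("resolution must be positive")
    v1, v2 = fis.inputs
    x1 = float(np.clip(x1, *v1.universe))
    x2 = float(np.clip(x2, *v2.universe))
    lo, hi = fis.output.universe
    grid = np.arange(lo, hi + resolution / 2, resolution)
    aggregate = np.zeros_like(grid)
    for (s1, s2), cons in fis.rules.items():
        strength = min(float(v1.sets[s1](x1)), float(v2.sets[s2](x2)))
        if strength > 0:
            aggregate = np.maximum(aggregate, np.minimum(strength, fis.output.sets[cons](grid)))
    total = float(np.trapezoid(aggregate, grid))
    if total <= 0:
        return (lo + hi) / 2.0, True
    centroid = float(np.trapezoid(aggregate * grid, grid) / total)
    return centroid, False


def _standard_variable(name: str, sets: Mapping[str, tuple] | None = None) -> FuzzyVariable:
    sets = sets or DEFAULT_INPUT_SETS
    return FuzzyVariable(name=name, universe=(0.0, 1.0),
                         sets={k: TrapezoidMF(*v) for k, v in sets.items()})


@dataclass
class NormalizationContext:
    """Reference scales that put the high-level features on [0, 1].

    ``expected_len`` is the length of the expected visiting sequence (per
    session: the sum over the four stimuli), used for both the scanpath score
    and the error count; ``max_time_ms`` caps completion time; ``ib_cap``
    saturates the inattentional-blindness count.
    """

    expected_len: float
    max_time_ms: float = DEFAULT_MAX_TIME_MS
    ib_cap: float = DEFAULT_IB_CAP

    def __post_init__(self) -> None:
        if self.expected_len <= 0 or self.max_time_ms <= 0 or self.ib_cap <= 0:
            raise FuzzyConfigError("normalization scales must be positive")

    def fh1(self, value: float) -> float:
        return min(value / self.expected_len, 1.0)

    def fh2(self, value: float) -> float:
        return min(value / self.max_time_ms, 1.0)

    def fh3(self, value: float) -> float:
        return min(value / self.expected_len, 1.0)

    def fh4(self, value: float) -> float:
        return min(value, self.ib_cap) / self.ib_cap


def build_vss_fis(norm: NormalizationContext,
                  rules: Mapping[tuple[str, str], str] | None = None) -> MamdaniFIS:
    """Visual-search-speed system over normalized (FH1, FH2)."""
    if norm is None:
        raise FuzzyConfigError("normalization context required")
    fis = MamdaniFIS(
        inputs=[_standard_variable("FH1_norm"), _standard_variable("FH2_norm")],
        output=_standard_variable("visual_search_speed", DEFAULT_OUTPUT_SETS),
        rules=dict(rules or DEFAULT_RULES))
    fis.validate()
    return fis


def build_fa_fis(norm: NormalizationContext,
                 rules: Mapping[tuple[str, str], str] | None = None) -> MamdaniFIS:
    """Focused-attention system over normalized (FH3, FH4)."""
    if norm is None:
        raise FuzzyConfigError("normalization context required")
    fis = MamdaniFIS(
        inputs=[_standard_variable("FH3_norm"), _standard_variable("FH4_norm")],
        output=_standard_variable("focused_attention", DEFAULT_OUTPUT_SETS),
        rules=dict(rules or DEFAULT_RULES))
    fis.validate()
    return fis


def score_band(score: float) -> str:
    """Low/medium/high banding at thirds of [0, 1]."""
    if score < 1.0 / 3.0:
        return "low"
    if score < 2.0 / 3.0:
        return "medium"
    return "high"


def deficit_flags(vss: float, fa: float) -> dict[str, str]:
    """Deficit indications graded low/medium/high from the two scores.

    A high score means the ability is intact, so the deficit grade is the
    mirror of the score band: high score -> "low" deficit.  Low visual search
    speed flags processing-speed and visual-attention deficits; low focused
    attention flags the five attention-linked deficits.
    """
    if not (0.0 <= vss <= 1.0 and 0.0 <= fa <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    mirror = {"low": "high", "medium": "medium", "high": "low"}
    flags = {name: mirror[score_band(vss)] for name in VSS_DEFICITS}
    flags.update({name: mirror[score_band(fa)] for name in FA_DEFICITS})
    return flags


# ---------------------------------------------------------------------------
# Config persistence (bit-exact reload)

def save_fis(fis: MamdaniFIS, path: str | Path) -> None:
    doc = {
        "inputs": [{"name": v.name, "universe": list(v.universe),
                    "sets": {k: [mf.a, mf.b, mf.c, mf.d] for k, mf in v.sets.items()}}
                   for v in fis.inputs],
        "output": {"name": fis.output.name, "universe": list(fis.output.universe),
                   "sets": {k: [mf.a, mf.b, mf.c, mf.d]
                            for k, mf in fis.output.sets.items()}},
        "rules": [{"if": list(k), "then": v} for k, v in sorted(fis.rules.items())],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_fis(path: str | Path) -> MamdaniFIS:
    with open(path) as fh:
        doc = json.load(fh)

    def var(d: dict) -> FuzzyVariable:
        return FuzzyVariable(name=d["name"], universe=tuple(d["universe"]),
                             sets={k: TrapezoidMF(*v) for k, v in d["sets"].items()})

    fis = MamdaniFIS(inputs=[var(d) for d in doc["inputs"]],
                     output=var(doc["output"]),
                     rules={tuple(r["if"]): r["then"] for r in doc["rules"]})
    fis.validate()
    return fis
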