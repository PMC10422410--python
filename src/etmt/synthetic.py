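"""Synthetic trail-making sessions with controllable impairment.

The simulator emulates a 60 Hz screen-based eye tracker watching a
participant work through the four trail stimuli.  An ideal observer dwells
on each target in the expected order with brief transits in between; the
impairment knobs inject the behavioral signatures that the downstream
features are designed to pick up:

* ``stray_prob``  — per-transition chance of a stray fixation (a wrong
  target or an off-target location), driving the error count FH3 and the
  scanpath score FH1;
* ``revisit_prob`` — per-transition chance of replaying the previous two
  visited targets, the inattentional-blindness event behind FH4;
* ``slow_factor`` — multiplicative time dilation, driving completion time FH2;
* ``noise_px``    — Gaussian gaze jitter around the fixated point.

Dwell times are truncated-normal (> 50 ms) so every simulated fixation
survives the default detector thresholds.  Everything is reproducible from
the seed.  Deliberately not modeled: saccade main-sequence dynamics, blinks,
pupil responses, drift — the generator exercises the pipeline's feature
definitions, it is not an oculomotor model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .gaze_io import GazeSample, TrialRecord
from .stimulus import STIMULUS_IDS, StimulusLayout, aoi_hit

DEFAULT_RATE_HZ = 60.0
MIN_DWELL_MS = 50.0
# fraction of stray events aimed at a wrong target (vs. empty background),
# so both error branches of FH3 are exercised
WRONG_AOI_FRACTION = 0.6


@dataclass(frozen=True)
class ImpairmentProfile:
    """Behavioral parameters of one simulated impairment level."""

    dwell_mean_ms: float = 250.0
    dwell_sd_ms: float = 50.0
    transit_ms: float = 150.0
    stray_prob: float = 0.02
    revisit_prob: float = 0.01
    slow_factor: float = 1.0
    noise_px: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.stray_prob <= 1 and 0 <= self.revisit_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.dwell_mean_ms <= 0 or self.slow_factor < 1:
            raise ValueError("dwell_mean_ms must be > 0 and slow_factor >= 1")


# The three canonical impairment levels: separation mirrors the qualitative
# contrast between an efficient searcher (few deviations, fast) and an
# impaired one (stray visits, replayed runs, slow completion).
DEFAULT_PROFILES: dict[str, ImpairmentProfile] = {
    "low": ImpairmentProfile(),
    "medium": ImpairmentProfile(stray_prob=0.15, revisit_prob=0.15, slow_factor=1.5),
    "high": ImpairmentProfile(stray_prob=0.35, revisit_prob=0.35, slow_factor=2.5),
}


@dataclass
class CohortSpec:
    n_per_group: int = 10
    profiles: dict[str, ImpairmentProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _truncated_dwell(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d > MIN_DWELL_MS:
            return d
    return max(mean, MIN_DWELL_MS + 1.0)


def _background_point(rng: np.random.Generator, layout: StimulusLayout
                      ) -> tuple[float, float]:
    """A point outside every AOI disc (rejection sampling)."""
    for _ in range(1000):
        x = rng.uniform(0, layout.width)
        y = rng.uniform(0, layout.height)
        if aoi_hit(layout, x, y) is None:
            return x, y
    return 0.0, 0.0


def simulate_trial(profile: ImpairmentProfile, layout: StimulusLayout,
                   rate_hz: float = DEFAULT_RATE_HZ, seed: int = 0,
                   participant_id: str = "sim") -> TrialRecord:
    """One simulated trial: gaze samples only (fixations are for the
    detector to find).

    The walk visits the expected sequence in order.  Before each target
    beyond the first, a stray fixation is inserted with probability
    ``stray_prob``; after each target beyond the second, the previous two
    targets are replayed with probability ``revisit_prob``.
    """
    rng = np.random.default_rng(seed)
    aoi_of = {a.label: a for a in layout.aois}
    seq = layout.expected_sequence

    # fixation plan: (x, y, dwell_ms) triples
    plan: list[tuple[float, float, float]] = []

    def dwell() -> float:
        return _truncated_dwell(rng, profile.dwell_mean_ms, profile.dwell_sd_ms) \
            * profile.slow_factor

    def add_target(label: str) -> None:
        a = aoi_of[label]
        plan.append((a.cx, a.cy, dwell()))

    visited: list[str] = []
    for k, label in enumerate(seq):
        if k > 0 and rng.random() < profile.stray_prob:
            if rng.random() < WRONG_AOI_FRACTION:
                others = [t for t in seq if t != label and t not in visited[-1:]]
                add_target(others[rng.integers(len(others))])
            else:
                x, y = _background_point(rng, layout)
                plan.append((x, y, dwell()))
        add_target(label)
        visited.append(label)
        if k >= 1 and rng.random() < profile.revisit_prob:
            for back in visited[-2:]:
                add_target(back)

    # render the plan into 60 Hz samples with jitter; transits emit samples
    # interpolated between the two fixation points
    dt = 1000.0 / rate_hz
    transit = profile.transit_ms * profile.slow_factor
    samples: list[GazeSample] = []
    t = 0.0
    prev_xy: tuple[float, float] | None = None
    for (x, y, dur) in plan:
        if prev_xy is not None:
            t_end = t + transit
            n_steps = max(int(transit // dt), 0)
            for s in range(n_steps):
                frac = (s + 1) / (n_steps + 1)
                sx = prev_xy[0] + frac * (x - prev_xy[0])
                sy = prev_xy[1] + frac * (y - prev_xy[1])
                samples.append(GazeSample(round(t + s * dt, 3), layout.stimulus_id,
                                          sx, sy, None, True))
            t = t_end
        n_samp = max(int(dur // dt), 2)
        for s in range(n_samp):
            jx = rng.normal(0, profile.noise_px) if profile.noise_px > 0 else 0.0
            jy = rng.normal(0, profile.noise_px) if profile.noise_px > 0 else 0.0
            samples.append(GazeSample(round(t + s * dt, 3), layout.stimulus_id,
                                      x + jx, y + jy, None, True))
        t += n_samp * dt
        prev_xy = (x, y)

    return TrialRecord(participant_id=participant_id,
                       stimulus_id=layout.stimulus_id,
                       samples=samples,
                       trial_start=samples[0].timestamp,
                       trial_end=samples[-1].timestamp)


def simulate_cohort(spec: CohortSpec, layouts: Mapping[str, StimulusLayout]
                    ) -> tuple[dict[str, list[TrialRecord]], dict[str, str]]:
    """A full cohort: ``n_per_group`` participants per impairment group, each
    with one trial per stimulus.  Returns (trials per participant, ground-truth
    group per participant)."""
    seed_seq = np.random.SeedSequence(spec.seed)
    trials: dict[str, list[TrialRecord]] = {}
    truth: dict[str, str] = {}
    counter = 0
    for group in spec.profiles:                     # insertion order: low, medium, high
        profile = spec.profiles[group]
        for i in range(spec.n_per_group):
            pid = f"{group}_{i:03d}"
            truth[pid] = group
            recs = []
            for sid in STIMULUS_IDS:
                if sid not in layouts:
                    continue
                child = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                counter += 1
                recs.append(simulate_trial(profile, layouts[sid],
                                           seed=child, participant_id=pid))
            trials[pid] = recs
    return trials, truth


# ---------------------------------------------------------------------------
# Spec persistence

def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    doc = {"n_per_group": spec.n_per_group, "seed": spec.seed,
           "profiles": {k: asdict(v) for k, v in spec.profiles.items()}}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_cohort_spec(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        doc = json.load(fh)
    return CohortSpec(
        n_per_group=doc.get("n_per_group", 10),
        profiles={k: ImpairmentProfile(**v)
                  for k, v in doc.get("profiles", {}).items()} or dict(DEFAULT_PROFILES),
        seed=doc.get("seed", 0))
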