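"""The 13 trail-making gaze features.

Three tiers:

* low level, from raw fixations — FL1 fixation count, FL2 total fixation time
  (ms), FL3 fixation time as % of trial, FL4 mean fixation duration (ms);
* middle level, per AOI — FM1 dwell time (ms), FM2 dwell %, FM3 glances,
  FM4 revisits, FM5 first-fixation duration (ms);
* high level, from the scanpath — FH1 scanpath score (token Levenshtein
  distance from the expected visiting order), FH2 total completion time (ms),
  FH3 error count (out-of-AOI fixations plus wrong-order visits), FH4
  inattentional-blindness count (replayed visit runs).

The scanpath string is the sequence of AOI labels hit by successive fixation
centroids.  Consecutive duplicates are collapsed by default: a multi-fixation
dwell on one target is a single visit (dwell itself is captured by FM1/FM3),
and the collapsed form is what makes a clean trail score 0 edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .gaze_io import Fixation, TrialRecord, detect_fixations
from .stimulus import StimulusLayout, aoi_hit

FEATURE_NAMES = ("FL1", "FL2", "FL3", "FL4",
                 "FM1", "FM2", "FM3", "FM4", "FM5",
                 "FH1", "FH2", "FH3", "FH4")


@dataclass(frozen=True)
class LowLevelFeatures:
    FL1: int      # fixation count
    FL2: float    # total fixation time, ms
    FL3: float    # fixation time % of trial
    FL4: float    # mean fixation duration, ms


@dataclass(frozen=True)
class AoiFeatures:
    label: str
    FM1: float    # dwell time, ms
    FM2: float    # dwell % of trial
    FM3: int      # glances (fixations in the AOI)
    FM4: int      # revisits (distinct visit runs - 1)
    FM5: float    # first fixation duration, ms


@dataclass(frozen=True)
class HighLevelFeatures:
    FH1: int      # scanpath score (edits)
    FH2: float    # total time, ms
    FH3: int      # error count
    FH4: int      # inattentional-blindness count


@dataclass
class FeatureVector:
    """The 13 aggregated features of one participant, in ANFIS input order."""

    participant_id: str
    values: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_array(self) -> list[float]:
        return [float(self.values[name]) for name in FEATURE_NAMES]


def low_level(fixations: Sequence[Fixation], trial_duration: float) -> LowLevelFeatures:
    """FL1..FL4 from a fixation list; all four are zero when there are no
    fixations."""
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    n = len(fixations)
    total = float(sum(f.duration for f in fixations))
    return LowLevelFeatures(
        FL1=n,
        FL2=total,
        FL3=100.0 * total / trial_duration,
        FL4=total / n if n else 0.0,
    )


def aoi_level(fixations: Sequence[Fixation], layout: StimulusLayout,
              trial_duration: float) -> list[AoiFeatures]:
    """FM1..FM5 for every AOI of the layout, zeros for AOIs never hit.

    A *visit run* is a maximal streak of consecutive fixations whose centroids
    fall in the same AOI; FM4 counts returns, i.e. runs beyond the first.
    """
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    hits = [aoi_hit(layout, f.cx, f.cy) for f in fixations]
    per: dict[str, dict] = {a.label: {"dwell": 0.0, "glances": 0, "runs": 0, "first": 0.0}
                            for a in layout.aois}
    prev: str | None = None
    for f, label in zip(fixations, hits):
        if label is None:
            prev = None
            continue
        d = per[label]
        if d["glances"] == 0:
            d["first"] = f.duration
        d["dwell"] += f.duration
        d["glances"] += 1
        if label != prev:
            d["runs"] += 1
        prev = label
    return [AoiFeatures(label=lbl,
                        FM1=d["dwell"],
                        FM2=100.0 * d["dwell"] / trial_duration,
                        FM3=d["glances"],
                        FM4=max(0, d["runs"] - 1),
                        FM5=d["first"])
            for lbl, d in per.items()]


def scanpath_string(fixations: Sequence[Fixation], layout: StimulusLayout,
                    collapse: bool = True) -> list[str]:
    """Ordered AOI labels hit by fixation centroids.

    Out-of-AOI fixations contribute nothing.  With ``collapse`` (default),
    consecutive duplicates merge into a single token; the raw per-fixation
    string is available with ``collapse=False``.
    """
    tokens: list[str] = []
    for f in fixations:
        label = aoi_hit(layout, f.cx, f.cy)
        if label is None:
            continue
        if collapse and tokens and tokens[-1] == label:
            continue
        tokens.append(label)
    return tokens


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Token-level Levenshtein distance with unit insert/delete/substitute
    costs.  Tokens are atomic, so multi-character labels like "12" cost one
    edit."""
    if len(a) < len(b):          # keep the DP row short
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, tb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1,                      # delete
                         cur[j - 1] + 1,                   # insert
                         prev[j - 1] + (ta != tb))         # substitute
        prev = cur
    return prev[-1]


def scanpath_score(observed: Sequence[str], layout: StimulusLayout) -> int:
    """FH1: edit distance between the observed (collapsed) scanpath and the
    layout's expected visiting sequence."""
    return levenshtein(list(observed), layout.expected_sequence)


def total_time(trial: TrialRecord) -> float:
    """FH2 for one trial: trial_end - trial_start in ms."""
    if not trial.samples and not trial.fixations:
        raise ValueError("empty trial has no duration")
    return trial.trial_end - trial.trial_start


def error_rate(fixations: Sequence[Fixation], layout: StimulusLayout) -> int:
    """FH3: out-of-AOI fixations plus wrong-order visits.

    Wrong-order visits are the collapsed-scanpath tokens that do not belong
    to a longest in-order traversal of the expected sequence (sequence length
    minus the longest common subsequence with the expected order).  A stray
    revisit of an already-passed target therefore counts one error — the
    leading "6" of the worked trail — while a target that was simply never
    fixated adds nothing here (omissions surface in the scanpath score, FH1).
    """
    out_of_aoi = sum(1 for f in fixations if aoi_hit(layout, f.cx, f.cy) is None)
    tokens = scanpath_string(fixations, layout, collapse=True)
    return out_of_aoi + wrong_token_count(tokens, layout.expected_sequence)


def wrong_token_count(tokens: Sequence[str], expected: Sequence[str]) -> int:
    """Count of out-of-order visits (the in-AOI half of FH3):
    ``len(tokens) - LCS(tokens, expected)``."""
    n, m = len(tokens), len(expected)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if tokens[i - 1] == expected[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return n - prev[m]


def inattentional_blindness(scanpath: Sequence[str], min_pattern_len: int = 2) -> int:
    """FH4: count of replayed visit runs.

    Left-to-right scan: at index i, find the longest contiguous run of length
    >= ``min_pattern_len`` starting at i that also occurs earlier in the
    sequence (ending at or before i); if found, count one event and skip past
    the run, else advance one token.  Replaying a previously visited stretch
    of targets — continuing the search without registering that those targets
    were already found — is the behavioral signature scored here.  Single-token
    returns are below the default minimum length and are scored by FM4
    (revisits) instead.
    """
    if min_pattern_len < 1:
        raise ValueError("min_pattern_len must be >= 1")
    seq = list(scanpath)
    n = len(seq)
    count = 0
    i = 0
    while i < n:
        best = 0
        max_len = min(n - i, i)   # run must fit and fully precede i
        for length in range(min_pattern_len, max_len + 1):
            run = seq[i:i + length]
            if any(seq[j:j + length] == run for j in range(0, i - length + 1)):
                best = length
        if best:
            count += 1
            i += best
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# Per-trial bundle and per-participant aggregation

@dataclass
class TrialFeatures:
    stimulus_id: str
    low: LowLevelFeatures
    aoi: list[AoiFeatures]
    high: HighLevelFeatures
    scanpath: list[str]


def extract_trial_features(trial: TrialRecord, layout: StimulusLayout,
                           dispersion_px: float = 50.0,
                           min_duration_ms: float = 100.0) -> TrialFeatures:
    """All three tiers for one trial; fixations are detected from samples
    unless the trial already carries them."""
    fixations = trial.fixations or detect_fixations(
        trial.samples, dispersion_px, min_duration_ms)
    duration = max(trial.duration, 1e-9)
    path = scanpath_string(fixations, layout)
    high = HighLevelFeatures(
        FH1=scanpath_score(path, layout),
        FH2=trial.duration,
        FH3=error_rate(fixations, layout),
        FH4=inattentional_blindness(path),
    )
    return TrialFeatures(
        stimulus_id=trial.stimulus_id,
        low=low_level(fixations, duration),
        aoi=aoi_level(fixations, layout, duration),
        high=high,
        scanpath=path,
    )


def assemble_features(trials: Sequence[TrialRecord],
                      layouts: Mapping[str, StimulusLayout],
                      participant_id: str | None = None,
                      dispersion_px: float = 50.0,
                      min_duration_ms: float = 100.0) -> FeatureVector:
    """Aggregate per-trial features into one 13-entry participant vector.

    Counts and times (FL1, FL2, FH1..FH4; FM1, FM3, FM4 summed over AOIs)
    are summed across trials; percentages and per-event durations (FL3, FL4;
    FM2, FM5 averaged over AOIs) are averaged across trials.  A participant
    missing one of the four trials is aggregated over the trials present and
    flagged in provenance.
    """
    if not trials:
        raise ValueError("no trials to aggregate")
    pid = participant_id or trials[0].participant_id
    per_trial = []
    for trial in trials:
        layout = layouts[trial.stimulus_id]
        per_trial.append(extract_trial_features(
            trial, layout, dispersion_px, min_duration_ms))

    def mean(xs: list[float]) -> float:
        return float(sum(xs) / len(xs)) if xs else 0.0

    values = {
        "FL1": float(sum(t.low.FL1 for t in per_trial)),
        "FL2": float(sum(t.low.FL2 for t in per_trial)),
        "FL3": mean([t.low.FL3 for t in per_trial]),
        "FL4": mean([t.low.FL4 for t in per_trial]),
        "FM1": float(sum(sum(a.FM1 for a in t.aoi) for t in per_trial)),
        "FM2": mean([mean([a.FM2 for a in t.aoi]) for t in per_trial]),
        "FM3": float(sum(sum(a.FM3 for a in t.aoi) for t in per_trial)),
        "FM4": float(sum(sum(a.FM4 for a in t.aoi) for t in per_trial)),
        "FM5": mean([mean([a.FM5 for a in t.aoi]) for t in per_trial]),
        "FH1": float(sum(t.high.FH1 for t in per_trial)),
        "FH2": float(sum(t.high.FH2 for t in per_trial)),
        "FH3": float(sum(t.high.FH3 for t in per_trial)),
        "FH4": float(sum(t.high.FH4 for t in per_trial)),
    }
    covered = sorted(t.stimulus_id for t in per_trial)
    expected = sorted(layouts.keys())
    provenance = {
        "trials": covered,
        "complete": covered == expected,
        "aggregation": "counts+times summed; percentages+durations averaged",
    }
    return FeatureVector(participant_id=pid, values=values, provenance=provenance)
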