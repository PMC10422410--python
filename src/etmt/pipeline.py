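"""End-to-end orchestration: gaze → fixations → features → scores → report.

``run_session`` scores one participant's recorded session; ``fit_cohort``
builds the cognitive-impairment model from a cohort of sessions (features →
k-means labels → ANFIS hybrid training) and reports every participant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import anfis as anfis_mod
from . import features as feat_mod
from . import fuzzy as fuzzy_mod
from .anfis import AnfisModel, ErrorStats, LabeledDataset
from .features import FEATURE_NAMES, FeatureVector
from .gaze_io import TrialRecord
from .stimulus import StimulusLayout


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class SessionConfig:
    dispersion_px: float = 50.0
    min_duration_ms: float = 100.0
    max_time_ms: float = fuzzy_mod.DEFAULT_MAX_TIME_MS
    ib_cap: float = fuzzy_mod.DEFAULT_IB_CAP
    epochs: int = anfis_mod.DEFAULT_EPOCHS
    train_frac: float = anfis_mod.DEFAULT_TRAIN_FRAC
    seed: int = 0

    def hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


@dataclass
class EtmtReport:
    """The full per-participant assessment."""

    participant_id: str
    features: dict[str, float]
    vss_score: float
    fa_score: float
    ci_score: float | None
    bands: dict[str, str]
    deficits: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "features": self.features,
            "scores": {"visual_search_speed": self.vss_score,
                       "focused_attention": self.fa_score,
                       "cognitive_impairment": self.ci_score},
            "bands": self.bands,
            "deficits": self.deficits,
            "provenance": self.provenance,
        }


def _norm_context(layouts: Mapping[str, StimulusLayout],
                  config: SessionConfig) -> fuzzy_mod.NormalizationContext:
    expected_len = sum(len(l.expected_sequence) for l in layouts.values())
    return fuzzy_mod.NormalizationContext(
        expected_len=expected_len, max_time_ms=config.max_time_ms,
        ib_cap=config.ib_cap)


def fuzzy_scores(vector: FeatureVector, layouts: Mapping[str, StimulusLayout],
                 config: SessionConfig | None = None) -> tuple[float, float]:
    """(visual-search-speed, focused-attention) from a feature vector."""
    config = config or SessionConfig()
    norm = _norm_context(layouts, config)
    vss_fis = fuzzy_mod.build_vss_fis(norm)
    fa_fis = fuzzy_mod.build_fa_fis(norm)
    v = vector.values
    vss, _ = fuzzy_mod.mamdani_evaluate(vss_fis, norm.fh1(v["FH1"]), norm.fh2(v["FH2"]))
    fa, _ = fuzzy_mod.mamdani_evaluate(fa_fis, norm.fh3(v["FH3"]), norm.fh4(v["FH4"]))
    return vss, fa


def run_session(trials: Sequence[TrialRecord],
                layouts: Mapping[str, StimulusLayout],
                model: AnfisModel | None = None,
                config: SessionConfig | None = None) -> EtmtReport:
    """Score one participant's session; the impairment score needs a trained
    model and is None without one."""
    config = config or SessionConfig()
    if not trials:
        raise PipelineError("session: no trials supplied")
    try:
        vector = feat_mod.assemble_features(
            trials, layouts, dispersion_px=config.dispersion_px,
            min_duration_ms=config.min_duration_ms)
    except Exception as exc:
        raise PipelineError(f"feature extraction: {exc}") from exc
    vss, fa = fuzzy_scores(vector, layouts, config)
    ci_score: float | None = None
    bands = {"visual_search_speed": fuzzy_mod.score_band(vss),
             "focused_attention": fuzzy_mod.score_band(fa)}
    if model is not None:
        try:
            ci_score, ci_band = anfis_mod.score_participant(model, vector)
        except Exception as exc:
            raise PipelineError(f"impairment scoring: {exc}") from exc
        bands["cognitive_impairment"] = ci_band
    return EtmtReport(
        participant_id=vector.participant_id,
        features={k: vector.values[k] for k in FEATURE_NAMES},
        vss_score=vss, fa_score=fa, ci_score=ci_score,
        bands=bands,
        deficits=fuzzy_mod.deficit_flags(vss, fa),
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    **vector.provenance})


def fit_cohort(sessions: Mapping[str, Sequence[TrialRecord]],
               layouts: Mapping[str, StimulusLayout],
               config: SessionConfig | None = None
               ) -> tuple[AnfisModel, dict[str, ErrorStats], list[EtmtReport],
                          LabeledDataset]:
    """Train the impairment model on a cohort and report every participant.

    Stages: assemble features per participant → k-means labels → ANFIS init →
    hybrid training → per-participant reports.
    """
    config = config or SessionConfig()
    if len(sessions) < 8:
        raise PipelineError(f"cohort: need >= 8 participants, got {len(sessions)}")
    vectors = []
    for pid in sessions:                      # insertion order = deterministic
        vectors.append(feat_mod.assemble_features(
            list(sessions[pid]), layouts, participant_id=pid,
            dispersion_px=config.dispersion_px,
            min_duration_ms=config.min_duration_ms))
    dataset = anfis_mod.kmeans_label(vectors, k=3, seed=config.seed)
    model = anfis_mod.anfis_init(dataset)
    model, stats = anfis_mod.anfis_train(
        model, dataset, epochs=config.epochs,
        train_frac=config.train_frac, seed=config.seed)
    reports = [run_session(list(sessions[pid]), layouts, model, config)
               for pid in sessions]
    return model, stats, reports, dataset
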