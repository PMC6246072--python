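"""Eight-condition experiment matrix on synthetic scenes.

Builds the full factorial of masker kind (stationary SSN / speech-like
modulated) x layout (separated / collocated) x hearing aids (aided /
unaided), renders each condition through synthetic BRIRs, runs the binaural
intelligibility model, and derives the spatial release from masking (SRM)
and the hearing-aid disadvantage per condition — the synthetic analogue of
the study's SRT/SRM/HA-disadvantage summaries.  Optionally, simulated
listeners produce staircase SRTs whose true thresholds track the model's
binaural ratios.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .bte import BteTransform, apply_bte_transform
from .framing import FrameGrid
from .gammatone import design_gammatone_bank
from .model import ModelConfig, ModelOutput, predict_condition
from .noise import generate_speechlike, generate_ssn, speech_shaped_reference
from .rooms import Brir, SceneConfig, simulate_brir
from .scene import SceneRendering, condition_brirs, render_scene
from .signal import MonoSignal
from .staircase import PsychometricListener, run_track

SEPARATED_AZIMUTHS = (90.0, -90.0, 180.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the experiment matrix."""

    masker: str  # "stationary" | "modulated"
    layout: str  # "separated" | "collocated"
    aided: bool
    seed: int = 0

    def __post_init__(self) -> None:
        if self.masker not in ("stationary", "modulated"):
            raise ValueError(f"unknown masker kind {self.masker!r}")
        if self.layout not in ("separated", "collocated"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def name(self) -> str:
        return (
            f"{self.masker}_{self.layout}_{'aided' if self.aided else 'unaided'}"
        )


def full_matrix(seed: int = 0) -> list[ConditionSpec]:
    """The eight-condition factorial."""
    return [
        ConditionSpec(masker, layout, aided, seed)
        for masker in ("stationary", "modulated")
        for layout in ("separated", "collocated")
        for aided in (False, True)
    ]


@dataclass(frozen=True)
class MatrixConfig:
    """Scene/model/stimulus parameters shared across the matrix."""

    rate: float = 44_100.0
    masker_duration: float = 120.0
    target_duration: float = 10.0
    fmin: float = 80.0
    fmax: float = 10_000.0
    ceiling_db: float = 20.0
    weighting: str = "sii"
    scene: SceneConfig = field(default_factory=SceneConfig)
    bte: BteTransform = field(default_factory=BteTransform)
    seed: int = 0

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            ceiling_db=self.ceiling_db,
            grid=FrameGrid(),
            bank=design_gammatone_bank(self.fmin, min(self.fmax, self.rate / 2 * 0.95)),
            weighting=self.weighting,
            masker_duration=self.masker_duration,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_brir_set(cfg: MatrixConfig, aided: bool) -> dict[float, Brir]:
    """Simulate, optionally BTE-transform, and condition the four BRIRs."""
    scene = replace(cfg.scene, rate=cfg.rate, seed=cfg.seed, aided=aided)
    brirs = [simulate_brir(scene, az) for az in scene.azimuths]
    if aided:
        brirs = [apply_bte_transform(b, cfg.bte) for b in brirs]
    reference = speech_shaped_reference(10.0, cfg.rate, cfg.seed)
    brirs = condition_brirs(brirs, reference)
    return {b.azimuth: b for b in brirs}


def build_stimuli(cfg: MatrixConfig) -> dict[str, list[MonoSignal] | MonoSignal]:
    """Target and the two masker triplets, generated once and reused."""
    reference = speech_shaped_reference(10.0, cfg.rate, cfg.seed)
    target = generate_ssn(reference, cfg.target_duration, cfg.seed + 1)
    ssn = [
        generate_ssn(reference, cfg.masker_duration, cfg.seed + 10 + i)
        for i in range(3)
    ]
    modulated = [
        generate_speechlike(
            cfg.masker_duration, cfg.rate, cfg.seed + 20 + i, reference=reference
        )
        for i in range(3)
    ]
    return {"target": target, "stationary": ssn, "modulated": modulated}


def render_condition(
    spec: ConditionSpec,
    cfg: MatrixConfig,
    brirs: dict[float, Brir],
    stimuli: dict,
) -> SceneRendering:
    scene = replace(cfg.scene, rate=cfg.rate, seed=cfg.seed, aided=spec.aided)
    maskers = stimuli[spec.masker]
    if spec.layout == "separated":
        masker_brirs = [brirs[az] for az in SEPARATED_AZIMUTHS]
    else:
        masker_brirs = [brirs[0.0]] * len(maskers)
    return render_scene(brirs[0.0], masker_brirs, stimuli["target"], maskers, scene)


def run_matrix(
    cfg: MatrixConfig = MatrixConfig(),
    conditions: list[ConditionSpec] | None = None,
    n_listeners: int = 0,
    listener_offset_db: float = -5.0,
    listener_slope: float = 0.15,
) -> dict:
    """Run the matrix and derive SRM and HA-disadvantage summaries.

    Returns a dict with ``conditions`` (per-condition model results),
    ``srm`` and ``ha_disadvantage`` DataFrames, and the config hash.  With
    ``n_listeners > 0``, staircase SRTs are simulated per condition with
    each listener's true SRT set to ``listener_offset_db`` minus the
    condition's binaural ratio.
    """
    if conditions is None:
        conditions = full_matrix(cfg.seed)
    model_cfg = cfg.model_config()
    stimuli = build_stimuli(cfg)
    brir_sets = {
        aided: build_brir_set(cfg, aided)
        for aided in sorted({c.aided for c in conditions})
    }

    rows = []
    outputs: dict[str, ModelOutput] = {}
    for spec in conditions:
        rendering = render_condition(spec, cfg, brir_sets[spec.aided], stimuli)
        out = predict_condition(
            rendering.target_ears, rendering.interferer_ears, model_cfg
        )
        outputs[spec.name] = out
        rows.append(
            {
                "condition": spec.name,
                "masker": spec.masker,
                "layout": spec.layout,
                "aided": spec.aided,
                "binaural_ratio_db": out.binaural_ratio_db,
                "better_ear_db": out.better_ear_component_db,
                "binaural_unmasking_db": out.binaural_unmasking_component_db,
            }
        )
    table = pd.DataFrame(rows)

    srm_rows, ha_rows = [], []
    for masker in table["masker"].unique():
        for aided in table.loc[table["masker"] == masker, "aided"].unique():
            sub = table[(table["masker"] == masker) & (table["aided"] == aided)]
            if {"separated", "collocated"} <= set(sub["layout"]):
                sep = sub.loc[sub["layout"] == "separated"].iloc[0]
                col = sub.loc[sub["layout"] == "collocated"].iloc[0]
                srm_rows.append(
                    {
                        "masker": masker,
                        "aided": aided,
                        "predicted_srm_db": sep["binaural_ratio_db"]
                        - col["binaural_ratio_db"],
                        "srm_better_ear_db": sep["better_ear_db"]
                        - col["better_ear_db"],
                        "srm_binaural_unmasking_db": sep["binaural_unmasking_db"]
                        - col["binaural_unmasking_db"],
                    }
                )
        for layout in table.loc[table["masker"] == masker, "layout"].unique():
            sub = table[(table["masker"] == masker) & (table["layout"] == layout)]
            if {True, False} <= set(sub["aided"]):
                aided_row = sub.loc[sub["aided"]].iloc[0]
                unaided_row = sub.loc[~sub["aided"]].iloc[0]
                ha_rows.append(
                    {
                        "masker": masker,
                        "layout": layout,
                        "predicted_ha_disadvantage_db": unaided_row[
                            "binaural_ratio_db"
                        ]
                        - aided_row["binaural_ratio_db"],
                    }
                )

    result = {
        "conditions": table,
        "srm": pd.DataFrame(srm_rows),
        "ha_disadvantage": pd.DataFrame(ha_rows),
        "outputs": outputs,
        "config_hash": cfg.hash(),
    }

    if n_listeners > 0:
        srt_rows = []
        for listener_idx in range(n_listeners):
            for spec in conditions:
                ratio = outputs[spec.name].binaural_ratio_db
                listener = PsychometricListener(
                    true_srt=listener_offset_db - ratio, slope=listener_slope
                )
                track = run_track(
                    listener,
                    start_level=listener.true_srt + 10.0,
                    seed=np.random.default_rng(
                        [cfg.seed, listener_idx, hash(spec.name) % (2**31)]
                    ),
                )
                srt_rows.append(
                    {
                        "listener": listener_idx,
                        "condition": spec.name,
                        "srt_db": track.estimate,
                        "se_db": track.standard_error,
                        "n_trials": track.n_trials,
                    }
                )
        result["srts"] = pd.DataFrame(srt_rows)
    return result
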