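"""End-to-end orchestration: filter -> segment -> label -> extract 22
features -> select -> cross-validated detection -> report.

`run_pipeline` executes the whole detection chain on either a real
EDF + annotation pair or a synthetic recording, writing every intermediate
artifact (segments.csv, features.csv, selection.json, report.json) when an
output directory is given.  Reports are plain JSON with sorted keys and no
timestamps, so identical configuration + seed reproduces byte-identical
files.

All randomness is funneled through per-stage generators derived from the
single run seed (generation = seed, balancing = seed + 1, model/CV = seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features_chaotic, features_spectral, features_time
from .detection_eval import EvalReport, crossvalidate
from .feature_selection import FeatureMatrix, SelectionResult, select_features
from .features_chaotic import CHAOTIC_FEATURE_NAMES, EmbeddingSpec
from .features_spectral import SPECTRAL_FEATURE_NAMES, SpectralConfig
from .features_time import TIME_FEATURE_NAMES
from .signal_io import (
    AnnotationSet,
    EEGRecording,
    FilterSpec,
    bandpass,
    label_segments,
    read_annotations,
    read_edf,
    segment,
)
from .synth_eeg import SynthSpec, generate_recording

log = logging.getLogger("kcomplex")

ALL_FEATURE_NAMES = TIME_FEATURE_NAMES + SPECTRAL_FEATURE_NAMES + CHAOTIC_FEATURE_NAMES


@dataclass
class RunConfig:
    """Full configuration of one detection run; echoed into every artifact."""

    # input: either file paths or a synthetic spec
    edf_path: str | None = None
    annot_path: str | None = None
    channel: str | None = "Cz-A1"
    synth: SynthSpec | None = None

    # pre-processing
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_s: float = 0.5
    step_s: float = 0.1
    min_overlap: float = 0.5

    # features
    use_time: bool = True
    use_spectral: bool = True
    use_chaotic: bool = True
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    chaos_m: int = 3
    chaos_tau: int | None = None
    chaos_q: float = 2.0

    # class balancing: negatives-per-positive kept before selection/CV
    balance_ratio: float | None = 3.0

    # selection + detection
    selection: str | None = "sfs-consistency"
    selection_params: dict = field(default_factory=dict)
    model: str = "dt"
    folds: int = 5
    beta: float = 1.0
    seed: int = 42

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, (tuple, list)):
                return [enc(x) for x in v]
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def feature_names(config: RunConfig) -> list[str]:
    names: list[str] = []
    if config.use_time:
        names += TIME_FEATURE_NAMES
    if config.use_spectral:
        names += SPECTRAL_FEATURE_NAMES
    if config.use_chaotic:
        names += CHAOTIC_FEATURE_NAMES
    return names


def extract_features(windows: np.ndarray, fs: float, config: RunConfig) -> np.ndarray:
    """The 22-feature matrix (or the configured subset of domains)."""
    blocks = []
    if config.use_time:
        blocks.append(features_time.time_feature_matrix(windows))
    if config.use_spectral:
        blocks.append(
            features_spectral.spectral_feature_matrix(windows, fs, config.spectral)
        )
    if config.use_chaotic:
        spec = EmbeddingSpec(m=config.chaos_m, tau=config.chaos_tau)
        blocks.append(
            features_chaotic.chaotic_feature_matrix(windows, spec, config.chaos_q)
        )
    if not blocks:
        raise ValueError("at least one feature domain must be enabled")
    return np.hstack(blocks)


def load_input(config: RunConfig) -> tuple[EEGRecording, AnnotationSet]:
    if config.synth is not None:
        return generate_recording(config.synth)
    if config.edf_path is None or config.annot_path is None:
        raise ValueError("config needs either a synth spec or edf_path + annot_path")
    rec = read_edf(config.edf_path, config.channel)
    ann = read_annotations(config.annot_path)
    return rec, ann


def undersample(
    fm: FeatureMatrix, ratio: float, seed: int
) -> FeatureMatrix:
    """Seeded random undersampling of negatives to ``ratio`` per positive."""
    pos = np.where(fm.y == 1)[0]
    neg = np.where(fm.y == 0)[0]
    keep_neg = int(round(ratio * pos.size))
    if pos.size == 0 or neg.size <= keep_neg:
        return fm
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg, size=keep_neg, replace=False)
    idx = np.sort(np.concatenate([pos, chosen]))
    return FeatureMatrix(fm.X[idx], fm.y[idx], fm.names)


def make_selector(config: RunConfig):
    """A ``FeatureMatrix -> SelectionResult`` callable for in-fold use."""
    if config.selection is None or config.selection == "none":
        return None
    method = config.selection
    params = dict(config.selection_params)
    if method in ("relieff", "sfs-consistency", "sfs-error"):
        params.setdefault("seed", config.seed)

    def selector(fm: FeatureMatrix) -> SelectionResult:
        return select_features(fm, method, **params)

    return selector


def build_feature_matrix(config: RunConfig) -> tuple[FeatureMatrix, dict]:
    """Stages 1-4: load, filter, segment, label, extract, balance."""
    rec, ann = load_input(config)
    filtered = bandpass(rec, config.filter)
    segs = label_segments(
        segment(filtered, config.window_s, config.step_s), ann, config.min_overlap
    )
    windows = segs.values_matrix()
    X = extract_features(windows, filtered.fs, config)
    names = feature_names(config)
    fm = FeatureMatrix(X, segs.labels, names)
    info = {
        "n_samples": int(rec.samples.size),
        "n_segments": len(segs),
        "n_positive": int(np.sum(fm.y == 1)),
        "n_negative": int(np.sum(fm.y == 0)),
        "n_events": len(ann),
    }
    if config.balance_ratio is not None:
        fm = undersample(fm, config.balance_ratio, config.seed + 1)
        info["n_after_balancing"] = fm.n
        info["n_negative_after_balancing"] = int(np.sum(fm.y == 0))
    info["_segments"] = segs
    return fm, info


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full detection chain and return (and optionally write)
    the report."""
    fm, info = build_feature_matrix(config)
    segs = info.pop("_segments")
    selector = make_selector(config)
    report: EvalReport = crossvalidate(
        fm,
        model=config.model,
        k=config.folds,
        seed=config.seed,
        selector=selector,
        beta=config.beta,
    )
    out = {
        "config": config.to_dict(),
        "data": info,
        "evaluation": report.as_dict(),
    }
    if report.selection is not None:
        out["selection"] = {
            "method": report.selection.method,
            "params": report.selection.params,
            "selected": report.selection.selected,
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        segs.to_frame().to_csv(out_dir / "segments.csv", index=False)
        import pandas as pd

        feats = pd.DataFrame(fm.X, columns=fm.names)
        feats["label"] = fm.y
        feats.to_csv(out_dir / "features.csv", index=False)
        if "selection" in out:
            (out_dir / "selection.json").write_text(
                json.dumps(out["selection"], indent=2, sort_keys=True) + "\n"
            )
        (out_dir / "report.json").write_text(
            json.dumps(out, indent=2, sort_keys=True, default=str) + "\n"
        )
    return out


def compare_methods(
    config: RunConfig,
    methods: list[str | None] = (None, "relieff", "cfs", "sfs-consistency", "interact"),
    models: list[str] = ("lda", "lsvm", "dt"),
    out_dir: str | Path | None = None,
):
    """Grid of metric bundles: (selection method + no-selection) x models.

    Features are extracted once; each cell re-runs selection + CV.  Cell
    failures are recorded, not fatal.
    """
    if not methods or not models:
        raise ValueError("need at least one method and one model")
    fm, info = build_feature_matrix(config)
    info.pop("_segments")
    rows = []
    for method in methods:
        for model in models:
            cell_cfg = dataclasses.replace(
                config, selection=method, model=model
            )
            try:
                rep = crossvalidate(
                    fm,
                    model=model,
                    k=config.folds,
                    seed=config.seed,
                    selector=make_selector(cell_cfg),
                    beta=config.beta,
                )
                rows.append(
                    {
                        "selection": method or "none",
                        "model": model,
                        **{k: rep.mean[k] for k in rep.mean},
                        **{f"{k}_sd": rep.sd[k] for k in rep.sd},
                        "n_selected": len(rep.selected) if rep.selected else fm.n_features,
                        "error": "",
                    }
                )
            except Exception as exc:  # partial table allowed
                log.warning("cell (%s, %s) failed: %s", method, model, exc)
                rows.append({"selection": method or "none", "model": model,
                             "error": str(exc)})
    import pandas as pd

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.csv", index=False)
        (out_dir / "comparison.json").write_text(
            json.dumps({"config": config.to_dict(), "cells": rows},
                       indent=2, sort_keys=True, default=str) + "\n"
        )
    return table
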