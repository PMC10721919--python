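"""Whole-surface papillae mapping ("tongue prints") and the one-command
study runner.

``map_papillae`` sweeps a surface, extracts features for every candidate
segment, and classifies each with a trained type model; segments predicted
"none" are excluded from the map.  ``run_study`` reproduces the full
synthetic analogue of the analysis: cohort generation, segment extraction,
feature assembly, correlation pruning, all four classification tasks under
both split schemes, permutation importance, and a papillae map for one
held-out surface.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ml
from .meshes import TriangleMesh
from .ml import (FeatureTable, assemble_features, evaluate_task,
                 importance_for_task, prune_correlated)
from .segmentation import (DEFAULT_CUT_RADIUS_UM, DEFAULT_DELTA_UM,
                           annotated_segments, sweep_surface)
from .synthesis import (CohortConfig, EffectConfig, generate_cohort,
                        generate_surface, rng_stream)
from .topology import TopoConfig

log = logging.getLogger("tonguetopo")


class SchemaError(ValueError):
    """Feature schema mismatch between a trained model and new features."""


@dataclass
class TypeModel:
    """A trained papilla-type classifier plus everything needed to apply it
    to new segments: the fitted pipeline, its feature schema, and the
    feature-extraction configuration used at training time."""

    pipeline: object
    feature_columns: list
    topo_config: TopoConfig
    classes: list


def train_type_classifier(table: FeatureTable, model: str = "svm",
                          topo_config: TopoConfig | None = None) -> TypeModel:
    """Fit the type model on the full feature table (the map consumer's
    training set)."""
    cols = table.feature_columns
    X = table.df[cols].to_numpy(dtype=np.float64)
    y = table.df["type"].to_numpy()
    pipe = ml.make_model(model).fit(X, y)
    return TypeModel(pipe, cols, topo_config or TopoConfig(),
                     sorted(pd.unique(y)))


@dataclass
class PapillaeMap:
    """Detections of typed papillae over one surface."""

    surface_id: str
    detections: list            # (m_point (3,), predicted type, confidence)
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tally: dict = {}
        for _, ptype, _ in self.detections:
            tally[ptype] = tally.get(ptype, 0) + 1
        self.counts = tally

    def to_json(self, path) -> None:
        payload = {
            "surface_id": self.surface_id,
            "counts": self.counts,
            "detections": [
                {"m_um": [float(v) for v in m], "type": t, "confidence": float(c)}
                for m, t, c in self.detections],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        rows = [{"x_um": m[0], "y_um": m[1], "z_um": m[2],
                 "type": t, "confidence": c} for m, t, c in self.detections]
        pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "type",
                                    "confidence"]).to_csv(path, index=False)


def _confidence(pipeline, X: np.ndarray) -> np.ndarray:
    """Classifier decision margin mapped to [0, 1]."""
    clf = pipeline
    if hasattr(clf, "predict_proba"):
        try:
            return clf.predict_proba(X).max(axis=1)
        except AttributeError:
            pass
    df = clf.decision_function(X)
    if df.ndim == 1:
        df = np.column_stack([-df, df])
    margin = np.sort(df, axis=1)[:, -1] - np.sort(df, axis=1)[:, -2]
    return 1.0 - np.exp(-np.maximum(margin, 0.0))


def map_papillae(surface: TriangleMesh, model: TypeModel,
                 r: float = DEFAULT_CUT_RADIUS_UM,
                 delta: float = DEFAULT_DELTA_UM,
                 seed: int = 0, surface_id: str = "surface",
                 max_iterations: int | None = None) -> PapillaeMap:
    """Sweep a surface and classify every candidate segment; detections
    keep only segments predicted fungiform or filiform."""
    segments = sweep_surface(surface, r=r, delta=delta, seed=seed,
                             max_iterations=max_iterations)
    if not segments:
        return PapillaeMap(surface_id, [])
    table = assemble_features(segments, model.topo_config,
                              seed=int(rng_stream(seed, "map-features")
                                       .integers(2 ** 31)))
    missing = [c for c in model.feature_columns if c not in table.df.columns]
    if missing:
        raise SchemaError(f"features missing at mapping time: {missing}")
    X = table.df[model.feature_columns].to_numpy(dtype=np.float64)
    pred = model.pipeline.predict(X)
    conf = _confidence(model.pipeline, X)
    detections = []
    kept_rows = table.df.index.to_numpy()
    for row, p, c in zip(kept_rows, pred, conf):
        if p == "none":
            continue
        detections.append((segments[row].m_point.copy(), str(p), float(c)))
    return PapillaeMap(surface_id, detections)


# ---------------------------------------------------------------------------
# One-command study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration for a full synthetic study run."""

    n_participants: int = 6
    segments_per_participant: int = 60
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise_sd: float = 5.0
    mesh_pitch: float = 15.0
    n_subsample: int = 1000
    h1_subsample: int = 150
    n_splits: int = ml.N_RANDOM_SPLITS
    n_permutations: int = ml.N_PERMUTATIONS
    correlation_threshold: float = ml.CORRELATION_THRESHOLD
    models: tuple = ("svm", "lr")
    run_map: bool = True
    map_width_um: float = 4000.0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        eff = EffectConfig(**raw.pop("effects", {}))
        return cls(effects=eff, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(self.models)
        Path(path).write_text(yaml.safe_dump(d))


def cohort_feature_table(cfg: StudyConfig, seed: int) -> FeatureTable:
    """Generate the cohort and assemble the labelled feature table."""
    from .synthesis import default_segment_counts

    counts = default_segment_counts(cfg.segments_per_participant)
    cohort_cfg = CohortConfig(
        n_participants=cfg.n_participants,
        segments_per_participant=counts,
        effects=cfg.effects, noise_sd=cfg.noise_sd, mesh_pitch=cfg.mesh_pitch)
    surfaces, meta = generate_cohort(cohort_cfg, seed=seed)
    segments = []
    for i, surf in enumerate(surfaces):
        segments.extend(annotated_segments(
            surf, n_none=counts.get("none", 0),
            seed=int(rng_stream(seed, "study-segments", f"s{i}").integers(2 ** 31))))
    table = assemble_features(
        segments,
        TopoConfig(n_subsample=cfg.n_subsample, h1_subsample=cfg.h1_subsample),
        seed=seed)
    return table


def run_study(cfg: StudyConfig | None = None, seed: int = 0,
              outdir=None) -> dict:
    """End-to-end synthetic study.  Returns (and optionally writes) a
    report bundle: per-task/family/model/scheme balanced accuracies, the
    pruning log, permutation importances, and one papillae map."""
    cfg = cfg or StudyConfig()
    t0 = time.time()
    stage = "cohort+features"
    try:
        table = cohort_feature_table(cfg, seed)
        pruned, removals = prune_correlated(table, cfg.correlation_threshold)

        stage = "classification"
        results = []
        for task in ("type", "gender", "age", "participant"):
            for family in ("baseline", "curvature", "topological", "all"):
                for model in cfg.models:
                    schemes = ("random",) if task == "participant" \
                        else ("random", "logo")
                    for scheme in schemes:
                        try:
                            rep = evaluate_task(pruned, task, family, model,
                                                scheme, seed,
                                                n_splits=cfg.n_splits)
                        except ValueError as exc:
                            # e.g. LOGO on a 2-participant cohort where every
                            # fold trains on a single gender/age group
                            log.warning("%s/%s/%s/%s skipped: %s", task,
                                        family, model, scheme, exc)
                            continue
                        results.append(rep.summary())

        stage = "importance"
        imp = importance_for_task(pruned, "type", "all", "svm", seed,
                                  n_permutations=cfg.n_permutations,
                                  n_splits=cfg.n_splits)

        stage = "map"
        map_report = None
        if cfg.run_map:
            model = train_type_classifier(
                pruned, "svm",
                TopoConfig(n_subsample=cfg.n_subsample,
                           h1_subsample=cfg.h1_subsample))
            demo = generate_surface(
                cfg.map_width_um, cfg.map_width_um,
                noise_sd=cfg.noise_sd, mesh_pitch=cfg.mesh_pitch,
                seed=int(rng_stream(seed, "study-map-surface").integers(2 ** 31)))
            pmap = map_papillae(demo.mesh, model, seed=seed, surface_id="demo")
            map_report = {"counts": pmap.counts,
                          "n_planted": {t: sum(p.type == t for p in demo.papillae)
                                        for t in ("fungiform", "filiform")}}
    except Exception as exc:
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "seed": seed,
        "config": {**asdict(cfg), "models": list(cfg.models)},
        "n_segments": int(len(table.df)),
        "pruned_features": [r[0] for r in removals],
        "kept_features": pruned.feature_columns,
        "classification": results,
        "importance": {
            "ranking": imp.ranking(),
            "family_importance": imp.family_importance,
        },
        "map": map_report,
        "runtime_s": round(time.time() - t0, 1),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv")
        (outdir / "summary.json").write_text(json.dumps(bundle, indent=2))
    return bundle
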