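"""End-to-end orchestration: simulate -> track -> features -> classify.

A single TOML file configures every stage; the global seed is propagated
deterministically (via ``numpy.random.SeedSequence`` spawning) so a rerun
with the same configuration produces byte-identical artifacts.  The report
includes per-video feature vectors, a per-feature one-way ANOVA across the
labelled groups (no multiple-testing correction is applied across the ten
tests), and — when evolution runs — the classifier's accuracy, its exported
expression and the features it actually uses.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as cio
from .cgp import Classifier, EvolutionParams, evolve
from .contacts import ContactParams, analyse_contacts
from .features import extract_features
from .simulate import FEATURE_NAMES, FeatureTableConfig, SceneConfig, generate_scene
from .tracking import DetectionParams, TrackingParams, run_tracking

__all__ = [
    "AnovaResult",
    "RunConfig",
    "PipelineError",
    "one_way_anova",
    "anova_table",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("cellmot")


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects ANOVA for one feature."""

    feature: str
    group_names: list[str]
    f_statistic: float
    p_value: float
    group_means: list[float]
    group_sizes: list[int]


def one_way_anova(groups: dict[str, list[float]], feature: str = "") -> AnovaResult:
    """One-way ANOVA: F = between-group MS / within-group MS, df (k-1, N-k).

    Requires at least two groups of at least two values each and non-zero
    pooled within-group variance (a degenerate input raises rather than
    returning an infinite statistic).
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in data):
        raise ValueError("every group needs at least two values")
    if all(np.var(g) == 0 for g in data):
        raise ValueError("zero within-group variance: F statistic undefined")
    f, p = stats.f_oneway(*data)
    return AnovaResult(
        feature=feature,
        group_names=names,
        f_statistic=float(f),
        p_value=float(p),
        group_means=[float(g.mean()) for g in data],
        group_sizes=[len(g) for g in data],
    )


def anova_table(features_df: pd.DataFrame, label_column: str = "label") -> pd.DataFrame:
    """Per-feature one-way ANOVA across labelled groups of a features table.

    Features that are undefined (NaN) in some videos use the defined subset;
    features with a degenerate remaining sample are reported with NaN F/p.
    """
    rows = []
    for feat in FEATURE_NAMES:
        groups = {}
        for name, grp in features_df.groupby(label_column):
            vals = grp[feat].dropna().tolist()
            if len(vals) >= 2:
                groups[name] = vals
        try:
            res = one_way_anova(groups, feature=feat)
            rows.append((feat, res.f_statistic, res.p_value))
        except ValueError:
            rows.append((feat, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["feature", "F", "p"])


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    n_videos_per_class: int = 2
    scene: SceneConfig = field(default_factory=SceneConfig)
    class_overrides: dict[str, dict] = field(default_factory=lambda: {
        "control": {"speed_mean": 3.5, "turn_concentration": 0.6},
        "treated": {"speed_mean": 2.0, "turn_concentration": 0.35},
    })
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    contacts: ContactParams = field(default_factory=ContactParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    run_evolution: bool = True
    test_fraction: float = 0.25
    per_track_mean: bool = False


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a TOML file with per-stage sections
    ([scene], [detection], [tracking], [contacts], [evolution],
    [classes.<name>] overrides, and top-level seed / n_videos_per_class)."""
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    cfg = RunConfig(out_dir=Path(out_dir or doc.get("out_dir", "cellmot_run")))
    cfg.seed = int(doc.get("seed", 0))
    cfg.n_videos_per_class = int(doc.get("n_videos_per_class", cfg.n_videos_per_class))
    cfg.run_evolution = bool(doc.get("run_evolution", True))
    cfg.test_fraction = float(doc.get("test_fraction", cfg.test_fraction))
    cfg.per_track_mean = bool(doc.get("per_track_mean", False))
    if "scene" in doc:
        cfg.scene = SceneConfig(**doc["scene"])
    if "classes" in doc:
        cfg.class_overrides = {k: dict(v) for k, v in doc["classes"].items()}
    if "detection" in doc:
        cfg.detection = DetectionParams(**doc["detection"])
    if "tracking" in doc:
        cfg.tracking = TrackingParams(**doc["tracking"])
    if "contacts" in doc:
        cfg.contacts = ContactParams(**doc["contacts"])
    if "evolution" in doc:
        cfg.evolution = EvolutionParams(**doc["evolution"])
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> track -> features (-> ANOVA -> evolve) end to end.

    Writes frames, track/contact CSVs, ``features.csv``, ``anova.csv``,
    ``classifier.json`` and ``report.txt`` under ``config.out_dir`` and
    returns a summary dict.  Deterministic given ``config.seed``; stage
    failures raise :class:`PipelineError` naming the failing stage and
    leave earlier artifacts in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    class_names = sorted(config.class_overrides)
    video_specs = [(cname, i) for cname in class_names
                   for i in range(config.n_videos_per_class)]
    video_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in seed_seq.spawn(len(video_specs) + 1)]
    evo_seed = video_seeds[-1]

    feature_rows = []
    summary: dict = {"videos": []}

    @_stage("simulate+track+features")
    def process_video(cname: str, idx: int, seed: int):
        scene_cfg = replace(config.scene, seed=seed, **config.class_overrides[cname])
        vid = f"{cname}_{idx}"
        scene = generate_scene(scene_cfg)
        cio.write_frames(scene.frames, out / f"{vid}.tif")
        cio.write_tracks(scene.true_tracks, out / f"{vid}_truth.csv")
        cio.write_contacts(scene.true_contacts, out / f"{vid}_truth_contacts.csv")
        tracks = run_tracking(scene.frames, config.detection, config.tracking)
        cio.write_tracks(tracks, out / f"{vid}_tracks.csv")
        analysis = analyse_contacts(tracks, config.contacts)
        fv = extract_features(tracks, analysis, per_track_mean=config.per_track_mean)
        log.info("video %s: seed=%d frames=%s tracks=%d digest=%s",
                 vid, seed, scene.frames.shape, len(tracks),
                 _digest(out / f"{vid}_tracks.csv"))
        return vid, fv

    for (cname, idx), seed in zip(video_specs, video_seeds):
        vid, fv = process_video(cname, idx, seed)
        feature_rows.append((vid, fv, cname))
        summary["videos"].append({"video_id": vid, "label": cname,
                                  **fv.to_dict()})

    features_path = out / "features.csv"
    cio.write_features(feature_rows, features_path)
    df = cio.read_features(features_path)

    @_stage("anova")
    def do_anova():
        tab = anova_table(df)
        tab.to_csv(out / "anova.csv", index=False, float_format="%.6g")
        return tab

    anova = do_anova()
    summary["anova"] = anova
    report_lines = ["per-video features:", df.to_string(index=False), "",
                    "one-way ANOVA across labelled groups "
                    "(no multiple-testing correction):",
                    anova.to_string(index=False), ""]

    classifier: Classifier | None = None
    if config.run_evolution:
        @_stage("evolve")
        def do_evolve():
            X = df[FEATURE_NAMES].fillna(0.0).to_numpy(float)
            y = df["label"].to_numpy()
            rng = np.random.default_rng(evo_seed)
            n = len(y)
            n_test = max(0, int(round(config.test_fraction * n)))
            # stratified split: hold out a proportional slice of each class
            test_idx: list[int] = []
            for cname in class_names:
                rows_c = [i for i in range(n) if y[i] == cname]
                k = max(1, int(round(config.test_fraction * len(rows_c)))) if n_test else 0
                test_idx.extend(rng.permutation(rows_c)[:k].tolist())
            train_idx = [i for i in range(n) if i not in set(test_idx)]
            params = replace(config.evolution, seed=evo_seed)
            clf, trace = evolve(X[train_idx], y[train_idx], params,
                                feature_names=FEATURE_NAMES)
            train_acc = clf.accuracy(X[train_idx], y[train_idx])
            test_acc = clf.accuracy(X[test_idx], y[test_idx]) if test_idx else float("nan")
            (out / "classifier.json").write_text(clf.to_json())
            expr, used = clf.expression()
            log.info("evolve: seed=%d generations=%d train=%.3f test=%.3f",
                     evo_seed, len(trace) - 1, train_acc, test_acc)
            return clf, trace, train_acc, test_acc, expr, used

        classifier, trace, train_acc, test_acc, expr, used = do_evolve()
        summary.update(train_accuracy=train_acc, test_accuracy=test_acc,
                       expression=expr,
                       used_features=[FEATURE_NAMES[i] for i in sorted(used)],
                       generations=len(trace) - 1)
        report_lines += [
            f"CGP classifier (training accuracy {train_acc:.3f}, "
            f"test accuracy {test_acc:.3f}, {len(trace) - 1} generations):",
            f"  expression: {expr}",
            f"  used features: {', '.join(FEATURE_NAMES[i] for i in sorted(used))}",
        ]

    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    summary["features_csv"] = features_path
    summary["classifier"] = classifier
    return summary
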