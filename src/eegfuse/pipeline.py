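"""Configuration-driven end-to-end pipeline.

Stages: synthesize or load recordings -> deterministic preprocessing ->
microstate feature extraction (GFP peaks pooled over all subjects into
one polarity-invariant clustering) -> EMD feature tensors -> feature
fusion -> repeated subject-wise CV per feature mode -> Shapley
explanation of the fused model.  Every stage logs one structured line
and persists its artifacts, and the whole run is reproducible from
(config, master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emd as emd_mod
from . import explain as explain_mod
from . import fusion, microstate, preprocess, synthetic
from ._seeds import derive_seed
from .modeling import CVConfig, CVResult, run_cv
from .types import FeatureMatrix, Recording

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    output_dir: str = "eegfuse_out"
    seed: int = 0
    # input: either a data directory with a manifest, or a synthetic spec
    input_dir: str | None = None
    synthetic: dict = field(default_factory=dict)  # see synthetic.default_group_specs
    modes: tuple[str, ...] = ("microstate", "emd", "fused")
    # preprocessing
    band_low: float = 0.1
    band_high: float = 40.0
    notch: float | None = 50.0
    target_rate: float = 250.0
    # microstate stage
    n_peak_maps: int = 1000
    k_microstates: int = 4
    n_restarts: int = 50
    # EMD stage
    m_imfs: int = 9
    # modeling
    cv_k: int = 10
    n_repeats: int = 10
    budget: int = 20
    positive_class: object | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.modes = tuple(cfg.modes)
        return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage=%s elapsed=%.1fs", name, time.time() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def simulate_cohort(cfg: PipelineConfig, out_dir: Path):
    spec = dict(cfg.synthetic)
    kind = spec.pop("kind", "default")
    if kind == "null":
        group_specs = synthetic.null_group_specs(**spec)
    elif kind == "three_class":
        group_specs = synthetic.three_group_specs(**spec)
    else:
        group_specs = synthetic.default_group_specs(**spec)
    cohort = synthetic.generate_cohort(
        group_specs, seed=derive_seed(cfg.seed, "cohort")
    )
    synthetic.write_cohort(cohort, out_dir / "data")
    return [rec for rec, _ in cohort]


@_stage("load")
def load_cohort(cfg: PipelineConfig) -> list[Recording]:
    data_dir = Path(cfg.input_dir)
    manifest = pd.read_csv(data_dir / "manifest.tsv", sep="\t")
    recordings = []
    for _, row in manifest.iterrows():
        rec = preprocess.read_recording(data_dir / row["file"])
        rec.subject_id = str(row["subject_id"])
        rec.group_label = row["group_label"]
        recordings.append(rec)
    return recordings


@_stage("preprocess")
def preprocess_cohort(cfg: PipelineConfig, recordings: list[Recording]):
    out = []
    for rec in recordings:
        rec = preprocess.filter_resample(
            rec, cfg.band_low, cfg.band_high, cfg.notch, cfg.target_rate
        )
        rec = preprocess.rereference_select(rec)
        out.append(rec)
    logger.info(
        "preprocessed %d recordings: %d channels @ %g Hz",
        len(out), out[0].n_channels, out[0].sampling_rate,
    )
    return out


@_stage("microstates")
def extract_microstate_features(cfg: PipelineConfig, recordings):
    pooled = []
    for i, rec in enumerate(recordings):
        g = microstate.gfp(rec)
        peaks = microstate.find_gfp_peaks(g)
        maps = microstate.sample_peak_maps(
            rec, peaks, n_maps=cfg.n_peak_maps,
            seed=derive_seed(cfg.seed, f"peaks:{rec.subject_id}"),
        )
        pooled.append(maps)
    ts = microstate.cluster_microstates(
        np.vstack(pooled),
        k=cfg.k_microstates,
        n_restarts=cfg.n_restarts,
        seed=derive_seed(cfg.seed, "cluster"),
        channel_names=recordings[0].channel_names,
    )
    ts = microstate.assign_canonical_labels(ts)
    features = {}
    for rec in recordings:
        seg = microstate.backfit(rec, ts)
        features[rec.subject_id] = microstate.compute_parameters(
            seg, n_classes=cfg.k_microstates, subject_id=rec.subject_id
        )
    return ts, features


@_stage("emd")
def extract_emd_features(cfg: PipelineConfig, recordings):
    return {
        rec.subject_id: emd_mod.emd_feature_tensor(rec, m_imfs=cfg.m_imfs)
        for rec in recordings
    }


def write_emd_long_table(tensors: dict, path: Path) -> None:
    """Long-format persistence: subject, channel, imf_index, statistic, value."""
    rows = []
    for sid, t in tensors.items():
        for i, ch in enumerate(t.channel_names):
            for j, imf in enumerate(t.imf_index):
                for k, st in enumerate(t.statistic_names):
                    rows.append((sid, ch, imf, st, t.values[i, j, k]))
    pd.DataFrame(
        rows, columns=["subject_id", "channel", "imf_index", "statistic", "value"]
    ).to_csv(path, index=False)


@_stage("classify")
def classify_mode(cfg: PipelineConfig, fm: FeatureMatrix,
                  collect_explanations: bool) -> CVResult:
    cv_cfg = CVConfig(
        k=cfg.cv_k,
        n_repeats=cfg.n_repeats,
        seed=derive_seed(cfg.seed, f"cv:{fm.mode}"),
        budget=cfg.budget,
        positive_class=cfg.positive_class,
        collect_explanations=collect_explanations,
    )
    return run_cv(fm, cv_cfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the summary report."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.input_dir:
        recordings = load_cohort(cfg)
    else:
        recordings = simulate_cohort(cfg, out_dir)
    recordings = preprocess_cohort(cfg, recordings)

    ts, ms_features = extract_microstate_features(cfg, recordings)
    (out_dir / "templates.json").write_text(
        json.dumps(
            {
                "labels": ts.labels,
                "channel_names": ts.channel_names,
                "maps": ts.maps.tolist(),
                "gev": ts.gev,
            }
        )
    )
    tensors = extract_emd_features(cfg, recordings)
    write_emd_long_table(tensors, out_dir / "emd_tensor.csv")

    subjects = [
        (rec.subject_id, rec.group_label, ms_features[rec.subject_id],
         tensors[rec.subject_id])
        for rec in recordings
    ]

    report: dict = {"config": {**dataclasses.asdict(cfg)}, "modes": {}}
    for mode in cfg.modes:
        fm = fusion.build_feature_matrix(subjects, mode)
        fusion.write_feature_matrix(fm, out_dir / f"features_{mode}.csv")
        cv = classify_mode(cfg, fm, collect_explanations=(mode == "fused"))
        report["modes"][mode] = {
            m: cv.summary[m] for m in ("AUC", "ACC", "SPE", "SEN")
        }
        report["modes"][mode]["n_features"] = fm.X.shape[1]
        (out_dir / f"confusion_{mode}.json").write_text(
            json.dumps(
                {"classes": [str(c) for c in cv.classes],
                 "matrix": cv.confusion.tolist()}
            )
        )
        pd.DataFrame(
            [
                {"repeat": r["repeat"], "fold": r["fold"],
                 **r["metrics"], "lambda": r["lambda"], "C": r["C"],
                 "n_selected": len(r["selected"])}
                for r in cv.fold_records
            ]
        ).to_csv(out_dir / f"cv_folds_{mode}.csv", index=False)
        cv.selected_counts.rename("times_selected").to_csv(
            out_dir / f"selected_features_{mode}.csv"
        )
        if cv.explanation is not None and mode == "fused":
            rows = []
            for j, c in enumerate(cv.explanation.class_labels):
                gi = explain_mod.global_importance(cv.explanation, j)
                gi.insert(0, "class", str(c))
                rows.append(gi)
            pd.concat(rows).to_csv(out_dir / "shap_importance.csv", index=False)
            report["modality_contribution"] = {
                str(c): v
                for c, v in explain_mod.report_modality_contribution(
                    cv.explanation
                ).items()
            }
        report.setdefault("_cv_results", {})[mode] = cv

    persisted = {k: v for k, v in report.items() if k != "_cv_results"}
    (out_dir / "summary.json").write_text(json.dumps(persisted, indent=2))
    logger.info("pipeline complete; report at %s", out_dir / "summary.json")
    return report
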