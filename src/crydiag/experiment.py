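"""End-to-end experiment orchestration.

One experiment = acquire expiratory segments (synthetic corpus or a
directory of WAV + label files) -> extract the configured feature set
(HR, GFCC, or their fusion) -> z-normalise with train-fitted statistics
-> 55/15/30 stratified split -> grid-search hyperparameters on the
validation partition -> train the winning configuration -> evaluate on
the held-out test partition. A suite runs the three feature sets side
by side for classifier comparison.

One global seed fans out to named sub-seeds (corpus, split, MLP
initialisation) so stages can be varied independently while the whole
run stays reproducible; identical configs produce byte-identical metric
tables.

WAV-directory layout: ``<data_dir>/<class_label>/<recording>.wav`` with
a sibling ``<recording>.lab`` label file; the subject id is the
recording stem up to the last ``_``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import GridSpec, TrainedModel, grid_search, train_mlp, train_svm
from .evaluation import EvalReport, evaluate, plot_confusion_heatmap, plot_roc
from .features import FeatureTable, SplitSpec, fit_normalizer, fuse_tables, split_dataset
from .gfcc import GfccExtractor
from .hr import HarmonicRatioExtractor
from .io import extract_segments, parse_label_file, read_wav
from .synthetic import default_corpus_spec, generate_corpus

logger = logging.getLogger("crydiag")

FEATURE_SETS = ("hr", "gfcc", "fused")
CLASSIFIERS = ("svm", "mlp")
POSITIVE_CLASS = "septic"

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_suite",
    "load_config_file",
    "subseeds",
    "load_segments",
    "extract_feature_table",
]


@dataclass(frozen=True)
class ExperimentConfig:
    feature_set: str = "fused"
    classifier: str = "both"  # svm | mlp | both
    data_dir: str | None = None  # None -> synthetic corpus
    n_per_class: int = 200
    sample_rate: int = 44100
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    split: SplitSpec | None = None  # None -> default fractions with the split sub-seed
    out_dir: str | None = None
    write_plots: bool = False

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.classifier not in CLASSIFIERS + ("both",):
            raise ValueError("classifier must be svm, mlp or both")


@dataclass
class ExperimentResult:
    feature_set: str
    reports: dict  # classifier kind -> EvalReport
    best_configs: dict  # classifier kind -> dict
    grid_tables: dict  # classifier kind -> DataFrame
    models: dict  # classifier kind -> TrainedModel
    n_rows: int = 0
    n_features: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for kind, rep in self.reports.items():
            rows.append({
                "feature_set": self.feature_set,
                "classifier": kind.upper(),
                "accuracy_pct": round(rep.accuracy, 4),
                "precision": round(rep.precision, 4),
                "recall": round(rep.recall, 4),
                "f1": round(rep.f1, 4),
                "auc": round(rep.auc, 4) if rep.auc is not None else np.nan,
            })
        return pd.DataFrame(rows)


def subseeds(seed: int, n: int = 4) -> list[int]:
    """Fan a global seed out into named 31-bit sub-seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def load_segments(config: ExperimentConfig):
    """Synthetic corpus, or WAV + label files from a class-per-folder tree."""
    corpus_seed = subseeds(config.seed)[0]
    if config.data_dir is None:
        spec = default_corpus_spec(seed=corpus_seed, n_per_class=config.n_per_class)
        spec = dataclass_replace(spec, sample_rate=config.sample_rate)
        segments, manifest = generate_corpus(spec)
        return segments, manifest
    segments = []
    root = Path(config.data_dir)
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for wav_path in sorted(class_dir.glob("*.wav")):
            lab_path = wav_path.with_suffix(".lab")
            if not lab_path.exists():
                raise FileNotFoundError(f"missing label file for {wav_path}")
            waveform = read_wav(wav_path)
            subject = wav_path.stem.rsplit("_", 1)[0]
            segments.extend(
                extract_segments(
                    waveform, parse_label_file(lab_path), keep_tag="EXP",
                    class_label=class_dir.name, subject_id=subject,
                )
            )
    if not segments:
        raise ValueError(f"no EXP segments found under {root}")
    manifest = pd.DataFrame(
        [{"recording_id": s.recording_id, "subject_id": s.subject_id,
          "class_label": s.class_label} for s in segments]
    )
    return segments, manifest


def extract_feature_table(segments, feature_set: str) -> FeatureTable:
    labels = np.array([s.class_label for s in segments])
    subjects = np.array([s.subject_id for s in segments])

    def table(extractor, modality):
        mat = extractor.fit(segments).transform(segments)
        names = tuple(extractor.get_feature_names_out())
        return FeatureTable(mat, labels, subjects, names, (modality,) * mat.shape[1])

    if feature_set == "hr":
        return table(HarmonicRatioExtractor(), "hr")
    if feature_set == "gfcc":
        return table(GfccExtractor(), "gfcc")
    return fuse_tables(table(GfccExtractor(), "gfcc"), table(HarmonicRatioExtractor(), "hr"))


def _stage(name, t0, n):
    logger.info("stage=%s elapsed_s=%.2f rows=%d", name, time.perf_counter() - t0, n)


def run_experiment(config: ExperimentConfig, feature_table: FeatureTable | None = None) -> ExperimentResult:
    """Run one feature-set experiment end to end.

    ``feature_table`` short-circuits acquisition + extraction when the
    caller already has features (the suite reuses one extraction pass).
    """
    _, split_seed, mlp_seed, _ = subseeds(config.seed)

    t0 = time.perf_counter()
    if feature_table is None:
        segments, _ = load_segments(config)
        _stage("acquire", t0, len(segments))
        t0 = time.perf_counter()
        feature_table = extract_feature_table(segments, config.feature_set)
    _stage("features", t0, feature_table.n_rows)

    split = config.split or SplitSpec(seed=split_seed)
    idx_train, idx_val, idx_test = split_dataset(feature_table, split)
    train, val, test = (feature_table.rows(i) for i in (idx_train, idx_val, idx_test))

    normalizer = fit_normalizer(train.matrix)
    X_train = normalizer.transform(train.matrix)
    X_val = normalizer.transform(val.matrix)
    X_test = normalizer.transform(test.matrix)

    kinds = CLASSIFIERS if config.classifier == "both" else (config.classifier,)
    reports, best_configs, grid_tables, models = {}, {}, {}, {}
    for kind in kinds:
        t0 = time.perf_counter()
        best, table = grid_search(
            config.grid, kind, X_train, train.labels, X_val, val.labels, seed=mlp_seed
        )
        if kind == "svm":
            model = train_svm(X_train, train.labels, **best)
        else:
            model = train_mlp(X_train, train.labels, X_val, val.labels,
                              seed=mlp_seed, **best)
        model.normalizer = normalizer
        model.grid_table = table
        y_pred = model.predict(X_test)
        scores = model.score_for(X_test, POSITIVE_CLASS)
        reports[kind] = evaluate(test.labels, y_pred, scores, POSITIVE_CLASS)
        best_configs[kind] = best
        grid_tables[kind] = table
        models[kind] = model
        _stage(f"train+eval[{kind}]", t0, test.n_rows)

    result = ExperimentResult(
        feature_set=config.feature_set, reports=reports, best_configs=best_configs,
        grid_tables=grid_tables, models=models,
        n_rows=feature_table.n_rows, n_features=feature_table.n_features,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, idx_train, idx_val, idx_test)
    return result


def _write_outputs(config, result, idx_train, idx_val, idx_test):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary_frame().to_csv(out / f"metrics_{config.feature_set}.tsv",
                                  sep="\t", index=False, float_format="%.6f")
    for kind, table in result.grid_tables.items():
        table.to_csv(out / f"grid_{config.feature_set}_{kind}.tsv",
                     sep="\t", index=False, float_format="%.6f")
    for kind, rep in result.reports.items():
        np.savetxt(out / f"roc_{config.feature_set}_{kind}.tsv", rep.roc_points,
                   delimiter="\t", header="fpr\ttpr", comments="", fmt="%.6f")
        if config.write_plots:
            plot_confusion_heatmap(rep, out / f"confusion_{config.feature_set}_{kind}.png")
    if config.write_plots:
        plot_roc({k.upper(): r for k, r in result.reports.items()},
                 out / f"roc_{config.feature_set}.png")
    split_manifest = {
        "train": [int(i) for i in idx_train],
        "val": [int(i) for i in idx_val],
        "test": [int(i) for i in idx_test],
    }
    manifest = {
        "config": _config_dict(config),
        "best_configs": result.best_configs,
        "split": split_manifest,
    }
    (out / f"manifest_{config.feature_set}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["grid"] = asdict(config.grid)
    d["split"] = asdict(config.split) if config.split else None
    return d


def run_suite(configs) -> tuple[pd.DataFrame, dict]:
    """Run several experiments and consolidate one comparison table.

    Configs that share data source, seed and corpus size reuse a single
    fused extraction pass, so suite rows match individually-run
    experiments exactly (each feature set is a column projection of the
    fused table).
    """
    configs = list(configs)
    if not configs:
        raise ValueError("need at least one experiment config")
    results = {}
    cache: dict[tuple, FeatureTable] = {}
    for config in configs:
        key = (config.data_dir, config.seed, config.n_per_class, config.sample_rate)
        if key not in cache:
            segments, _ = load_segments(config)
            cache[key] = extract_feature_table(segments, "fused")
        fused = cache[key]
        table = fused if config.feature_set == "fused" else fused.select_modality(config.feature_set)
        results[config.feature_set] = run_experiment(config, feature_table=table)
    summary = pd.concat([r.summary_frame() for r in results.values()], ignore_index=True)
    return summary, results


def dataclass_replace(obj, **changes):
    from dataclasses import replace
    return replace(obj, **changes)


def load_config_file(path) -> dict:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return values
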