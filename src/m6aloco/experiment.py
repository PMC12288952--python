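"""End-to-end experiment orchestration: balance -> split -> encode -> train
-> evaluate -> report, for any combination of balanced replicates, split
modes (RS / LOCO) and model variants.

All randomness flows from one global seed: stage seeds are derived by
hashing ``(global_seed, stage-tags...)`` with SHA-256 and reducing modulo
2^31, so a single integer reproduces every artifact of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .encoding import FeatureBundle, encode_dataset
from .evaluation import (
    MetricsReport,
    aggregate,
    evaluate_predictions,
    reports_to_csv,
    roc_points,
)
from .io import Dataset, read_tabular
from .models import ModelSpec, NeuralModel, TrainConfig, build_model, predict, train
from .splitting import SplitPlan, balance_negatives, loco_split, random_split
from .synthetic import SynthConfig, generate, make_confounded_pair

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, *tags) -> int:
    """Stable per-stage seed: SHA-256 of the tag tuple, reduced mod 2^31."""
    h = hashlib.sha256(f"{global_seed}:{':'.join(map(str, tags))}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """One experiment: a data source, split mode(s), and model variant(s)."""

    dataset_path: str | None = None
    synth: SynthConfig | None = None
    confounded: bool = False
    n_subsets: int = 1
    modes: tuple[str, ...] = ("RS",)
    variants: tuple[str, ...] = ("HM",)
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    training: dict = field(default_factory=dict)  # TrainConfig overrides
    fast_profile: bool = True
    cv_folds: int = 5
    cv_reports: bool = True
    test_fraction: float = 0.2
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        for m in self.modes:
            if m not in ("RS", "LOCO"):
                raise ValueError(f"unknown split mode {m!r}")
        if not self.variants:
            raise ValueError("at least one model variant required")
        if self.dataset_path is None and self.synth is None:
            raise ValueError("either dataset_path or a synth config is required")


def _load_dataset(cfg: ExperimentConfig) -> Dataset:
    if cfg.dataset_path is not None:
        return read_tabular(cfg.dataset_path)
    synth = cfg.synth
    if synth.seed != cfg.seed:
        synth = SynthConfig(**{**synth.to_dict(), "seed": derive_seed(cfg.seed, "synth")})
    return make_confounded_pair(synth) if cfg.confounded else generate(synth)


def _model_spec(cfg: ExperimentConfig, variant: str, L: int) -> ModelSpec:
    if cfg.fast_profile:
        return ModelSpec.fast(variant, L=L, **cfg.model)
    return ModelSpec(variant=variant, L=L, **cfg.model)


def train_and_evaluate(
    bundle: FeatureBundle,
    train_ids,
    test_ids,
    spec: ModelSpec,
    tcfg: TrainConfig,
    scope: str,
) -> tuple[MetricsReport, NeuralModel, np.ndarray]:
    """Train a fresh model on ``train_ids`` and score ``test_ids``."""
    tr = bundle.subset_ids(train_ids)
    te = bundle.subset_ids(test_ids)
    model = build_model(spec, seed=tcfg.seed)
    train(model, tr, tcfg)
    probs = predict(model, te)
    report = evaluate_predictions(te.labels, probs, scope=scope)
    return report, model, probs


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the experiment and write its artifact tree under
    ``cfg.out_dir`` (when given).  Returns an in-memory result bundle:
    ``{(replicate, mode, variant): {"folds": [...], "test": ..., "aggregate": ...}}``
    plus the long-format summary DataFrame under key ``"summary"``.
    """
    t0 = time.time()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    ds = _load_dataset(cfg)
    logger.info("dataset: %d records, L=%d", len(ds), ds.L)
    replicates = balance_negatives(ds, cfg.n_subsets, seed=derive_seed(cfg.seed, "balance"))
    results: dict = {}
    rows = []
    for bd in replicates:
        rep_ds = bd.as_dataset()
        # frequency-normalized k-mers condition the hybrid paths' inputs
        bundle = encode_dataset(rep_ds, scheme="both", k=5, normalized_kmer=True)
        for mode in cfg.modes:
            split_seed = derive_seed(cfg.seed, "split", bd.replicate, mode)
            if mode == "RS":
                plan = random_split(
                    bd, cfg.test_fraction, max(cfg.cv_folds, 2), seed=split_seed
                )
            else:
                plan = loco_split(bd, cv_folds=cfg.cv_folds, seed=split_seed)
            for variant in cfg.variants:
                key = (bd.replicate, mode, variant)
                spec = _model_spec(cfg, variant, ds.L)
                tseed = derive_seed(cfg.seed, "train", bd.replicate, mode, variant)
                tcfg = TrainConfig(**{"seed": tseed, **cfg.training})
                vdir = out / f"replicate{bd.replicate}" / mode / variant if out else None
                if vdir:
                    vdir.mkdir(parents=True, exist_ok=True)
                    plan.to_json(vdir / "split_plan.json")
                fold_reports: list[MetricsReport] = []
                if mode == "RS":
                    if cfg.cv_reports:
                        for f in plan.folds:
                            rep, _, _ = train_and_evaluate(
                                bundle, f.train, f.validation, spec, tcfg, scope=f.label
                            )
                            fold_reports.append(rep)
                    pool = tuple(plan.folds[0].train) + tuple(plan.folds[0].validation)
                    test_rep, model, probs = train_and_evaluate(
                        bundle, pool, plan.folds[0].test, spec, tcfg, scope="independent-test"
                    )
                    test_ids = plan.folds[0].test
                else:
                    for f in plan.folds:
                        rep, model, probs = train_and_evaluate(
                            bundle, f.train, f.test, spec, tcfg, scope=f.label
                        )
                        fold_reports.append(rep)
                    test_rep = aggregate(fold_reports, by="chromosome")
                    test_ids = plan.folds[-1].test
                agg = (
                    aggregate(fold_reports, by="cv_fold" if mode == "RS" else "chromosome")
                    if fold_reports
                    else test_rep
                )
                results[key] = {"folds": fold_reports, "test": test_rep, "aggregate": agg}
                if vdir:
                    if fold_reports:
                        reports_to_csv(fold_reports, vdir / "fold_reports.csv")
                    reports_to_csv([test_rep], vdir / "test_report.csv")
                    model.save(vdir / "model")
                    te = bundle.subset_ids(test_ids)
                    try:
                        fpr, tpr, _ = roc_points(te.labels, probs)
                        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                            vdir / "roc_test.csv", index=False
                        )
                    except ValueError:
                        logger.warning("ROC undefined for %s (single class)", key)
                for scope_name, rep in [("test", test_rep)] + [
                    (r.scope, r) for r in fold_reports
                ]:
                    row = {
                        "replicate": bd.replicate,
                        "mode": mode,
                        "variant": variant,
                        "scope": scope_name,
                        **{m: rep.metric(m) for m in ("accuracy", "sensitivity", "specificity", "mcc", "auc_roc")},
                        "n": rep.n,
                    }
                    rows.append(row)
    summary = pd.DataFrame(rows)
    results["summary"] = summary
    if out:
        summary.to_csv(out / "summary.csv", index=False)
        manifest = {
            "config": _config_dict(cfg),
            "seed": cfg.seed,
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "wall_time_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    if cfg.synth is not None:
        d["synth"] = cfg.synth.to_dict()
    return d


def compare_runs(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Merge the summaries of >= 2 completed runs into one long table
    (run x variant x mode x metric) mirroring a model-comparison report."""
    if len(run_dirs) < 2:
        raise ValueError(f"need >= 2 run directories to compare, got {len(run_dirs)}")
    frames = []
    for d in run_dirs:
        d = Path(d)
        f = d / "summary.csv"
        if not f.exists():
            raise FileNotFoundError(f"run {d} is missing its aggregate summary ({f})")
        df = pd.read_csv(f)
        df.insert(0, "run", d.name)
        frames.append(df)
    cols = [set(f.columns) for f in frames]
    common = set.intersection(*cols)
    if any(c - common for c in cols):
        raise ValueError(
            "incompatible metric sets across runs: " + str([sorted(c - common) for c in cols])
        )
    merged = pd.concat(frames, ignore_index=True)
    long = merged[merged["scope"] == "test"].melt(
        id_vars=["run", "replicate", "mode", "variant", "scope", "n"],
        value_vars=["accuracy", "sensitivity", "specificity", "mcc", "auc_roc"],
        var_name="metric",
        value_name="value",
    )
    return long
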