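"""Configuration-driven orchestration: simulate -> preprocess -> train ->
diagnose -> evaluate, with a single root seed and a config-hashed report.

Models only ever receive training rows at fit time; validation labels are
read exclusively by the scoring step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import synth
from .diagnostics import PLSDAPipeline, permutation_test, vip_table
from .evaluate import confusion, f1_macro
from .forest import BorutaConfig, BorutaRFClassifier
from .io import SpectraSet, write_feature_matrix, write_spectra
from .latent_svm import PLSDASVMClassifier
from .preprocess import PreprocessSpec, preprocess

logger = logging.getLogger(__name__)

_BENCHMARKS = {
    "four_class": synth.four_class_design,
    "mixture": synth.mixture_design,
    "cross_field": synth.cross_field_design,
}


@dataclass
class RunConfig:
    out_dir: str = "cellfp_run"
    benchmark: str = "four_class"        # simulated input design
    n_per_class: int = 30
    models: Sequence[str] = ("plsda_svm", "boruta_rfc")
    split_fraction: float = 0.70
    seed: int = 0
    cv_folds: int = 5
    n_components: int | None = None      # default: one less than the class count
    boruta_max_iter: int = 50
    run_permutation_test: bool = False
    n_permutations: int = 99
    run_vip: bool = True
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.benchmark not in _BENCHMARKS:
            raise ValueError(f"unknown benchmark {self.benchmark!r}")
        for m in self.models:
            if m not in ("plsda_svm", "boruta_rfc"):
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = raw.pop("preprocess", None)
        cfg = cls(**raw)
        if pp:
            cfg.preprocess = PreprocessSpec(**pp)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def split_train_validation(sample_ids: Sequence[str], labels: Sequence[str],
                           fraction: float = 0.70, seed: int = 0
                           ) -> tuple[list[str], list[str]]:
    """Stratified random train/validation split of sample ids."""
    labels = list(labels)
    counts = {c: labels.count(c) for c in set(labels)}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"class(es) {small} have fewer than 2 members")
    train, valid = train_test_split(list(sample_ids), train_size=fraction,
                                    stratify=labels, random_state=seed)
    return list(train), list(valid)


def run_pipeline(config: RunConfig, spectra_set: SpectraSet | None = None,
                 write_artifacts: bool = True) -> dict:
    """Execute the full workflow and return (and optionally write) the report."""
    t0 = time.time()
    out = Path(config.out_dir)
    report: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "stages": {}, "models": {}}

    def stage(name):
        report["stages"][name] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.1fs", name, time.time() - t0)

    try:
        if spectra_set is None:
            design = _BENCHMARKS[config.benchmark](config.seed,
                                                   n_per_class=config.n_per_class)
            spectra_set, truth = synth.simulate_dataset(design)
            if write_artifacts:
                out.mkdir(parents=True, exist_ok=True)
                write_spectra(spectra_set, out / "spectra.csv", out / "meta.csv")
                truth.to_csv(out / "truth.csv", index=False)
        stage("simulate")

        pure_ids = [sid for sid in spectra_set.sample_ids
                    if spectra_set.meta[sid].mixture_fraction is None]
        pure = spectra_set.subset(pure_ids)
        norm = preprocess(spectra_set, config.preprocess)
        matrix = norm.normalized
        if write_artifacts:
            out.mkdir(parents=True, exist_ok=True)
            write_feature_matrix(matrix, out / "features.csv")
        stage("preprocess")

        labels = {sid: spectra_set.meta[sid].label_str for sid in spectra_set.sample_ids}
        train_ids, valid_ids = split_train_validation(
            pure.sample_ids, [labels[s] for s in pure.sample_ids],
            config.split_fraction, config.seed)
        X_train = matrix.rows(train_ids).values
        y_train = [labels[s] for s in train_ids]
        X_valid = matrix.rows(valid_ids).values
        y_valid = [labels[s] for s in valid_ids]
        n_classes = len(set(y_train))
        A = config.n_components or max(2, n_classes - 1)
        stage("split")

        for name in config.models:
            if name == "plsda_svm":
                model = PLSDASVMClassifier(n_components=A, cv_folds=config.cv_folds,
                                           seed=config.seed)
            else:
                model = BorutaRFClassifier(
                    boruta=BorutaConfig(max_iter=config.boruta_max_iter),
                    cv_folds=config.cv_folds, seed=config.seed)
            model.fit(X_train, y_train)
            pred = model.predict(X_valid)
            entry = {
                "held_out_f1": f1_macro(y_valid, pred),
                "confusion": confusion(y_valid, pred).to_dict(),
                "n_train": len(train_ids), "n_valid": len(valid_ids),
            }
            if name == "boruta_rfc":
                entry["n_confirmed_features"] = int(model.selection_.confirmed.size)
            report["models"][name] = entry
        stage("train_evaluate")

        if config.run_vip and "plsda_svm" in config.models:
            pipe = PLSDAPipeline(A).fit(X_train, y_train)
            table = vip_table(pipe.model, matrix.bucket_centers)
            if write_artifacts:
                table.to_csv(out / "vip.csv", index=False)
            report["models"].setdefault("plsda_svm", {})["top_vip_ppm"] = [
                round(float(v), 3) for v in
                table.sort_values("rank")["feature"].head(10)]
        if config.run_permutation_test:
            res = permutation_test(lambda: PLSDAPipeline(A), X_train,
                                   np.asarray(y_train), config.n_permutations,
                                   config.cv_folds, seed=config.seed)
            report["permutation_test"] = {"observed_cv_f1": res.observed,
                                          "p_value": res.p_value,
                                          "n_permutations": res.n_permutations}
        stage("diagnose")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        done = set(report["stages"])
        order = ["simulate", "preprocess", "split", "train_evaluate", "diagnose"]
        current = next((s for s in order if s not in done), "unknown")
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 3)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
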