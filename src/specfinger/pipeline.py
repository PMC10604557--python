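"""End-to-end orchestration: simulate -> preprocess/train -> validate ->
deconvolve -> compare, as one reproducible run writing a CSV report bundle.

A single master seed fans out to stage seeds by fixed offsets (simulation =
seed, split = seed + 1000), so two runs with the same config are
bit-identical.  Every numeric in the human-readable summary is read back
from a CSV cell of the bundle; the formatter recomputes nothing.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SpecfingerError
from .io import write_dataset
from .synth import SimulationConfig, default_class_profiles, simulate_cohort
from .preprocess import PreprocessConfig
from .chemometrics import (
    DiscriminantModel,
    ModelConfig,
    external_validate,
    loocv,
    roc,
    split_dataset,
)
from .deconv import FitConfig, deconvolve_group
from .stats import compare_band_tables

log = logging.getLogger("specfinger")


@dataclass
class RunConfig:
    classes: tuple[str, ...] = ("FM", "LC")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    alpha: float = 0.05
    outdir: str = "specfinger_run"
    seed: int = 0

    def resolved(self) -> "RunConfig":
        """Fan the master seed out to the stage seeds."""
        sim = SimulationConfig(**{**asdict(self.simulation), "seed": self.seed})
        model = ModelConfig(**{**asdict(self.model), "split_seed": self.seed + 1000})
        return RunConfig(self.classes, sim, self.preprocess, model, self.fit,
                         self.alpha, self.outdir, self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in [("simulation", SimulationConfig), ("preprocess", PreprocessConfig),
                         ("model", ModelConfig), ("fit", FitConfig)]:
            if key in raw:
                section = dict(raw.pop(key))
                for tup_key in ("region", "fwhm_bounds"):
                    if tup_key in section:
                        section[tup_key] = tuple(section[tup_key])
                kwargs[key] = sub(**section)
        if "classes" in raw:
            raw["classes"] = tuple(raw["classes"])
        return cls(**{**raw, **kwargs})


def _write_roc(curve, path: Path) -> None:
    pd.DataFrame({"threshold": curve.thresholds, "tpr": curve.tpr,
                  "fpr": curve.fpr}).to_csv(path, index=False)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the bundle's file paths.

    Any stage failure aborts with the stage name; files written by earlier
    stages are preserved.
    """
    cfg = config.resolved()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}
    stage = "configure"
    t0 = time.time()
    timings: dict[str, float] = {}

    def done(name: str) -> None:
        timings[name] = round(time.time() - t0 - sum(timings.values()), 3)

    try:
        stage = "simulate"
        profiles = default_class_profiles()
        cohort = simulate_cohort([profiles[c] for c in cfg.classes], cfg.simulation)
        bundle["cohort"] = out / "cohort.csv"
        write_dataset(cohort, bundle["cohort"])
        bundle["truth"] = out / "truth.csv"
        cohort.truth.to_csv(bundle["truth"], index=False)
        done(stage)

        stage = "train"
        train, val = split_dataset(cohort, cfg.model)
        model = DiscriminantModel.fit(train, cfg.preprocess, cfg.model)
        cv = loocv(train, cfg.preprocess, cfg.model)
        ev = external_validate(model, val)
        cv_roc = roc(cv.y_hat, train.labels, cfg.model.positive_class, direction="less")
        ev_roc = roc(ev.y_hat, val.labels, cfg.model.positive_class, direction="less")
        pd.DataFrame({"sample_id": cv.sample_ids, "label": train.labels,
                      "y": cv.y, "y_hat": cv.y_hat,
                      "predicted": cv.predicted_labels}).to_csv(out / "cv_predictions.csv", index=False)
        pd.DataFrame({"sample_id": ev.sample_ids, "label": val.labels,
                      "y": ev.y, "y_hat": ev.y_hat,
                      "predicted": ev.predicted_labels}).to_csv(out / "ev_predictions.csv", index=False)
        bundle["cv_predictions"] = out / "cv_predictions.csv"
        bundle["ev_predictions"] = out / "ev_predictions.csv"
        metrics = pd.DataFrame([
            {"metric": "SECV", "value": cv.secv},
            {"metric": "SEP", "value": ev.sep},
            {"metric": "Rcv", "value": cv.rcv},
            {"metric": "R2", "value": ev.r2},
            {"metric": "Sensitivity_pct", "value": ev.sensitivity},
            {"metric": "Specificity_pct", "value": ev.specificity},
            {"metric": "Accuracy_pct", "value": ev.accuracy},
            {"metric": "CV_misclassifications", "value": cv.misclassifications},
            {"metric": "AUC_cv", "value": cv_roc.auc},
            {"metric": "AUC_ev", "value": ev_roc.auc},
            {"metric": "explained_X_variance_LV1_pct",
             "value": float(model.pls.explained_x_variance[0])},
        ])
        bundle["metrics"] = out / "metrics.csv"
        metrics.to_csv(bundle["metrics"], index=False)
        _write_roc(cv_roc, out / "roc_cv.csv")
        _write_roc(ev_roc, out / "roc_ev.csv")
        bundle["roc_cv"] = out / "roc_cv.csv"
        bundle["roc_ev"] = out / "roc_ev.csv"
        pd.DataFrame({"wavenumber": model.pipeline.wavenumbers,
                      "b": model.pls.b}).to_csv(out / "regression_vector.csv", index=False)
        bundle["regression_vector"] = out / "regression_vector.csv"
        pd.DataFrame({"sample_id": train.sample_ids, "label": train.labels,
                      **{f"LV{k+1}": model.pls.scores[:, k]
                         for k in range(model.pls.scores.shape[1])}}
                     ).to_csv(out / "scores.csv", index=False)
        bundle["scores"] = out / "scores.csv"
        done(stage)

        stage = "deconvolve"
        groups = {}
        for c in cfg.classes:
            groups[c] = deconvolve_group(cohort, c, cfg.preprocess, cfg.fit)
            groups[c].per_sample_table().to_csv(out / f"deconv_{c}.csv", index=False)
            groups[c].summary().to_csv(out / f"summary_{c}.csv", index=False)
            bundle[f"deconv_{c}"] = out / f"deconv_{c}.csv"
            bundle[f"summary_{c}"] = out / f"summary_{c}.csv"
        done(stage)

        stage = "compare"
        if len(cfg.classes) >= 2:
            a, b = cfg.classes[:2]
            comparison = compare_band_tables(groups[a], groups[b], cfg.alpha)
            bundle["comparison"] = out / "comparison.csv"
            comparison.to_csv(bundle["comparison"], index=False)
        done(stage)

        stage = "manifest"
        n_train = {c: sum(lab == c for lab in train.labels) for c in cfg.classes}
        n_val = {c: sum(lab == c for lab in val.labels) for c in cfg.classes}
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "n_train": n_train,
            "n_validation": n_val,
        }
        bundle["manifest"] = out / "manifest.yaml"
        with open(bundle["manifest"], "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            for name, sec in timings.items():
                fh.write(f"{name}: {sec}s\n")
        bundle["log"] = out / "run.log"
    except SpecfingerError as exc:
        raise SpecfingerError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def report_summary(outdir) -> str:
    """One-page text summary of a finished bundle.

    Reads the bundle CSVs only; recomputes nothing.  Raises with the missing
    file's name if the bundle is incomplete.
    """
    out = Path(outdir)
    for required in ["metrics.csv", "manifest.yaml"]:
        if not (out / required).exists():
            raise SpecfingerError(f"bundle file missing: {required}")
    metrics = pd.read_csv(out / "metrics.csv").set_index("metric")["value"]
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)

    def fmt(key: str, pct: bool = False) -> str:
        if key not in metrics.index or pd.isna(metrics[key]):
            return "absent"
        return f"{metrics[key]:.1f}" if pct else f"{metrics[key]:.4g}"

    lines = [
        "specfinger run summary",
        "======================",
        f"version {manifest['version']}   master seed {manifest['seed']}",
        f"training {manifest['n_train']}   validation {manifest['n_validation']}",
        "",
        "figures of merit (calibration / prediction)",
        f"  SECV / SEP        : {fmt('SECV')} / {fmt('SEP')}",
        f"  Rcv / R2          : {fmt('Rcv')} / {fmt('R2')}",
        f"  Sensitivity (%)   : {fmt('Sensitivity_pct', True)}",
        f"  Specificity (%)   : {fmt('Specificity_pct', True)}",
        f"  Accuracy (%)      : {fmt('Accuracy_pct', True)}",
        f"  AUC (ICV / EV)    : {fmt('AUC_cv')} / {fmt('AUC_ev')}",
    ]
    for csv in sorted(out.glob("summary_*.csv")):
        df = pd.read_csv(csv)
        cls = csv.stem.split("_", 1)[1]
        lines.append("")
        lines.append(f"deconvolved bands, class {cls} (center / %area, n)")
        for _, row in df.iterrows():
            lines.append(
                f"  {row['center_mean']:7.1f} cm-1  {row['pct_area_mean']:5.1f} %"
                f"  (n={int(row['n'])})"
            )
    return "\n".join(lines) + "\n"
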