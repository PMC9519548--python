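"""End-to-end orchestration: preprocess -> split -> decompose -> classify -> report.

A single :class:`PipelineConfig` (loadable from YAML) drives the run:

1. obtain the cube — from a CSV archive or the synthetic generator;
2. excise Rayleigh/Raman scatter and fill the gaps by interpolation;
3. stratified Kennard-Stone split into train/validation/test (distances on
   the scatter-corrected, pre-MSC unfolded vectors, so the assignment of a
   training sample can never depend on test data);
4. MSC against the training-mean reference (config switch for a global mean);
5. PARAFAC or Tucker3 fit on the training cube only; validation/test samples
   scored by least-squares projection;
6. QDA on the training scores; predictions for all three stages;
7. figures-of-merit tables, predictions TSV, split TSV and the serialized
   model written under the output directory.

Test-set metrics are computed once, after everything else; model selection
(:func:`select_factors`) only ever sees training and validation samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EEMCube, SampleTable, WavelengthAxes
from .eem_io import load_cube
from .preprocess import ScatterParams, excise_scatter, fill_masked, msc_correct
from .split import ROLES, SplitAssignment, stratified_split
from .decompose import (
    explained_variance, export_loadings_tsv, parafac_fit, project_scores, save_model, tucker3_fit,
)
from .classify import qda_fit, qda_score
from .metrics import ConfusionCounts, FiguresOfMerit, cc_table, confusion, figures_of_merit, merit_table
from .synthetic import CohortSpec, generate_cohort

DEFAULT_FRACTIONS = (162 / 230, 34 / 230, 34 / 230)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``archive``/``synthetic`` given."""

    archive: str | None = None
    synthetic: CohortSpec | None = None
    scatter: ScatterParams = field(default_factory=ScatterParams)
    msc_reference: str = "train"            # "train" or "all"
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    counts: dict[str, tuple[int, int, int]] | None = None  # explicit per-class quotas
    model: str = "parafac"                  # "parafac" or "tucker3"
    factors: int = 6
    ranks: tuple[int, int, int] | None = None  # Tucker3; defaults to (factors,)*3
    tol: float = 1e-8
    max_iter: int = 2000
    beta: float = 2.0
    positive_class: str = "AD"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.archive is None) == (self.synthetic is None):
            raise ValueError("exactly one of archive / synthetic must be given")
        if self.model not in ("parafac", "tucker3"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.msc_reference not in ("train", "all"):
            raise ValueError("msc_reference must be 'train' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "scatter" in raw and isinstance(raw["scatter"], dict):
            raw["scatter"] = ScatterParams(**raw["scatter"])
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            if "axes" in syn and isinstance(syn["axes"], dict):
                syn["axes"] = WavelengthAxes(
                    np.asarray(syn["axes"]["excitation_nm"], dtype=float),
                    np.asarray(syn["axes"]["emission_nm"], dtype=float),
                )
            syn.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = CohortSpec(**syn)
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        if "ranks" in raw and raw["ranks"] is not None:
            raw["ranks"] = tuple(raw["ranks"])
        return cls(**raw)


@dataclass
class RunReport:
    """Everything a finished run produced, plus paths of written artifacts."""

    config: PipelineConfig
    split: SplitAssignment
    explained_variance_pct: float
    converged: bool
    n_iter: int
    cc: pd.DataFrame                    # stage x class CC% table
    merits: dict[str, FiguresOfMerit]   # per stage (validation, test)
    predictions: pd.DataFrame
    artifacts: dict[str, str] = field(default_factory=dict)


def _obtain(config: PipelineConfig) -> tuple[EEMCube, SampleTable]:
    if config.archive is not None:
        return load_cube(config.archive)
    cube, table, _ = generate_cohort(config.synthetic)
    return cube, table


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; see the module docstring for the stages."""
    cube, table = _obtain(config)

    excised = excise_scatter(cube, config.scatter)
    filled = fill_masked(excised)

    split = stratified_split(filled, table, config.fractions, counts=config.counts)
    train_idx = split.indices("train")

    ref_samples = None if config.msc_reference == "all" else train_idx
    corrected, msc = msc_correct(filled, reference_samples=ref_samples)

    train_cube = corrected.take(train_idx)
    if config.model == "parafac":
        model = parafac_fit(train_cube, config.factors, tol=config.tol, max_iter=config.max_iter)
    else:
        ranks = config.ranks or (config.factors,) * 3
        ranks = tuple(min(r, d) for r, d in zip(ranks, train_cube.shape))
        model = tucker3_fit(train_cube, ranks, tol=config.tol, max_iter=config.max_iter)
    ev = explained_variance(model)

    train_labels = [table.label[i] for i in train_idx]
    qda = qda_fit(model.A, train_labels, classes=("AD", "HC"))

    # score every stage; test is touched only here, after all fitting
    pred_frames = []
    stage_counts: dict[str, ConfusionCounts] = {}
    merits: dict[str, FiguresOfMerit] = {}
    for role in ROLES:
        idx = split.indices(role)
        if idx.size == 0:
            continue
        scores = model.A if role == "train" else project_scores(model, corrected.take(idx))
        sc = qda_score(qda, scores)
        labels = [table.label[i] for i in idx]
        stage_counts[role] = confusion(labels, sc.predicted, config.positive_class)
        merits[role] = figures_of_merit(stage_counts[role], beta=config.beta)
        qa, qh = sc.Q[:, sc.classes.index("AD")], sc.Q[:, sc.classes.index("HC")]
        pred_frames.append(pd.DataFrame({
            "sample_id": [table.sample_id[i] for i in idx],
            "label": labels, "predicted": sc.predicted,
            "Q_AD": qa, "Q_HC": qh, "role": role,
        }))
    predictions = pd.concat(pred_frames, ignore_index=True)
    cc = cc_table(stage_counts, config.positive_class)

    report = RunReport(
        config=config, split=split, explained_variance_pct=ev,
        converged=model.converged, n_iter=model.n_iter,
        cc=cc, merits=merits, predictions=predictions,
    )
    if config.out_dir is not None:
        _write_artifacts(report, model, cube.axes, Path(config.out_dir))
    return report


def _write_artifacts(report: RunReport, model, axes, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.split.save_tsv(out / "split.tsv")
    report.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    report.cc.to_csv(out / "cc_table.tsv", sep="\t")
    if "test" in report.merits:
        merit_table({report.config.model: report.merits["test"]}).to_csv(out / "merit_table.tsv", sep="\t")
    save_model(model, out / "model.h5")
    export_loadings_tsv(model, axes, out)
    log = {
        "model": report.config.model,
        "explained_variance_pct": report.explained_variance_pct,
        "converged": report.converged,
        "n_iter": report.n_iter,
        "per_class_quotas": {
            cls: {r: int(sum(1 for l, ro in zip(report.split.label, report.split.role)
                             if l == cls and ro == r)) for r in ROLES}
            for cls in sorted(set(report.split.label))
        },
        "seed": report.config.seed,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    report.artifacts = {p.stem: str(p) for p in out.iterdir()}


def metrics_from_predictions(predictions: pd.DataFrame, role: str = "test",
                             positive_class: str = "AD", beta: float = 2.0) -> FiguresOfMerit:
    """Recompute figures of merit from a predictions table (self-consistency check)."""
    sub = predictions[predictions["role"] == role]
    counts = confusion(sub["label"], sub["predicted"], positive_class)
    return figures_of_merit(counts, beta=beta)


def select_factors(config: PipelineConfig, candidate_F) -> pd.DataFrame:
    """Validation metrics per candidate factor count; the test set is never touched.

    Returns one row per candidate, sorted by candidate, with the validation
    per-class CC%, accuracy, MCC and the training explained variance.
    """
    candidates = sorted(set(int(f) for f in candidate_F))
    if not candidates:
        raise ValueError("need at least one candidate")
    cube, table = _obtain(config)
    excised = excise_scatter(cube, config.scatter)
    filled = fill_masked(excised)
    split = stratified_split(filled, table, config.fractions, counts=config.counts)
    train_idx, val_idx = split.indices("train"), split.indices("validation")
    ref_samples = None if config.msc_reference == "all" else train_idx
    corrected, _ = msc_correct(filled, reference_samples=ref_samples)
    train_cube, val_cube = corrected.take(train_idx), corrected.take(val_idx)
    train_labels = [table.label[i] for i in train_idx]
    val_labels = [table.label[i] for i in val_idx]

    rows = []
    for F in candidates:
        if config.model == "parafac":
            model = parafac_fit(train_cube, F, tol=config.tol, max_iter=config.max_iter)
        else:
            ranks = tuple(min(F, d) for d in train_cube.shape)
            model = tucker3_fit(train_cube, ranks, tol=config.tol, max_iter=config.max_iter)
        qda = qda_fit(model.A, train_labels, classes=("AD", "HC"))
        pred = qda_score(qda, project_scores(model, val_cube)).predicted
        fom = figures_of_merit(confusion(val_labels, pred, config.positive_class), beta=config.beta)
        rows.append({
            "F": F,
            "explained_variance_pct": explained_variance(model),
            "val_cc_AD": fom.cc_positive, "val_cc_HC": fom.cc_negative,
            "val_accuracy": fom.accuracy, "val_mcc": fom.mcc,
        })
    return pd.DataFrame(rows)
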