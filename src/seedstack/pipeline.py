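"""End-to-end orchestration: data → preprocessing → CARS → fusion → KOA
tuning → stacking → evaluation reports.

The stages mirror the six-stage classification workflow: (1) obtain or
simulate the multimodal dataset, (2) preprocess (SG smoothing of
spectra, max–min scaling of both modalities, scaler fitted on the
training split only), (3) CARS feature selection per modality on the
training split, (4) early fusion of the selected blocks (spectral block
first), (5) KOA-tuned base learners and the stacked ensemble with
combinatorial meta-learner selection, (6) evaluation reports in the
per-model metrics-table layout.

Every stage that *fits* anything is recorded in a :class:`DataFlowAudit`
with the original row indices it saw, so a run can prove that no
test-set row reached a preprocessing fit, CARS, the tuning fitness, or
meta-learner selection. Savitzky–Golay smoothing is per-row (no
cross-sample statistics) and is applied to all rows.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone

from . import evaluation, stacking, synthetic
from .cars import PLSConfig, run_cars
from .koa import KOAConfig
from .preprocessing import SGParams, apply_min_max, fit_min_max, savitzky_golay_smooth
from .stacking import StackingSpec, split_train_test
from .tuning import FAMILIES, TuningConfig, build_model, tune_model

__all__ = [
    "FusedDataset",
    "RunConfig",
    "DataFlowAudit",
    "StageError",
    "early_fuse",
    "run_pipeline",
    "run_ablation",
    "PipelineResult",
]


# --------------------------------------------------------------------------- #
# fusion
# --------------------------------------------------------------------------- #

@dataclass
class FusedDataset:
    matrix: np.ndarray
    provenance: list[tuple[str, str]]  # (modality, original feature id) per column
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.provenance):
            raise ValueError("provenance must cover every column exactly once")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def early_fuse(
    blocks: list[tuple[np.ndarray, list[tuple[str, str]]]],
    labels: np.ndarray | None = None,
) -> FusedDataset:
    """Column-wise concatenation of feature blocks, provenance retained."""
    if not blocks:
        raise ValueError("early_fuse needs at least one block")
    counts = {len(np.asarray(m)) for m, _ in blocks}
    if len(counts) != 1:
        raise ValueError(f"blocks have mismatched row counts: {sorted(counts)}")
    mats, prov = [], []
    for m, p in blocks:
        m = np.asarray(m, float)
        if m.shape[1] != len(p):
            raise ValueError("each block needs one provenance entry per column")
        mats.append(m)
        prov.extend(tuple(x) for x in p)
    return FusedDataset(np.hstack(mats), prov, labels)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``spectra_csv``/``image_csv`` load an existing dataset; otherwise a
    synthetic one is generated from ``synthetic_params`` (keyword
    arguments of :func:`seedstack.synthetic.default_spec`). ``modality``
    restricts the fused dataset for ablation runs.
    """

    spectra_csv: str | None = None
    image_csv: str | None = None
    synthetic_params: dict = field(default_factory=dict)
    sg_window: int = 15
    sg_polyorder: int = 3
    cars_runs: int = 20
    cars_components: int = 10
    cars_cv_folds: int = 5
    cars_mc_ratio: float = 0.8
    koa_population: int = 10
    koa_iterations: int = 20
    tuning_fitness: str = "holdout"
    families: tuple[str, ...] = FAMILIES
    stacking_folds: int = 5
    meta_feature_mode: str = "labels"
    test_fraction: float = 0.2
    modality: str = "fused"  # "fused" | "spectra" | "image"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("fused", "spectra", "image"):
            raise ValueError("modality must be 'fused', 'spectra' or 'image'")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for replay."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class DataFlowAudit:
    """Records, per fitting stage, the original row indices it consumed."""

    def __init__(self) -> None:
        self.stages: dict[str, set[int]] = {}

    def record(self, stage: str, indices: np.ndarray) -> None:
        self.stages.setdefault(stage, set()).update(int(i) for i in np.asarray(indices))

    def touched(self, stage: str) -> set[int]:
        return self.stages.get(stage, set())

    def fit_stage_names(self) -> list[str]:
        return [s for s in self.stages if not s.startswith("evaluate")]


# --------------------------------------------------------------------------- #
# result container
# --------------------------------------------------------------------------- #

@dataclass
class PipelineResult:
    config: RunConfig
    split: stacking.SplitResult
    cars_results: dict
    fused_train: FusedDataset
    fused_test: FusedDataset
    tuned: dict
    base_report: pd.DataFrame           # Table-2 layout: KOA-tuned model test metrics
    stack_report: pd.DataFrame          # Table-3 layout: candidate stacks, test metrics
    selection_report: pd.DataFrame      # training-split CV ranking of meta-learners
    chosen_meta: str
    stack_model: stacking.StackedModel
    stack_eval: evaluation.EvaluationReport
    audit: DataFlowAudit
    predictions: pd.DataFrame
    runtime_s: float


# --------------------------------------------------------------------------- #
# the run
# --------------------------------------------------------------------------- #

def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> PipelineResult:
    t0 = time.time()
    seeds = _child_seeds(config.seed, 8)
    s_data, s_split, s_cars_sp, s_cars_im, s_tune, s_stack, s_meta, _ = seeds
    audit = DataFlowAudit()

    # ---- stage 1: data -------------------------------------------------- #
    @_stage("data")
    def _load():
        if config.spectra_csv and config.image_csv:
            return (
                synthetic.read_spectra_csv(config.spectra_csv),
                synthetic.read_image_csv(config.image_csv),
            )
        spec = synthetic.default_spec(seed=s_data, **config.synthetic_params)
        return synthetic.generate_multimodal(spec)

    spectra, images = _load()
    if not np.array_equal(spectra.labels, images.labels):
        raise StageError("data", ValueError("spectra and image tables have mismatched labels"))
    labels = spectra.labels

    # ---- stage 2: split + preprocessing --------------------------------- #
    @_stage("preprocess")
    def _preprocess():
        smoothed = savitzky_golay_smooth(
            spectra, SGParams(config.sg_window, config.sg_polyorder)
        )
        split = split_train_test(
            np.arange(len(labels)).reshape(-1, 1), labels,
            test_fraction=config.test_fraction, seed=s_split,
        )
        tr = split.train_indices
        stats_sp = fit_min_max(smoothed.intensities[tr], smoothed.grid.column_names())
        stats_im = fit_min_max(images.values[tr], list(images.feature_names))
        audit.record("preprocessing_fit", tr)
        Xsp = apply_min_max(smoothed.intensities, stats_sp)
        Xim = apply_min_max(images.values, stats_im)
        return split, Xsp, Xim, stats_sp, stats_im

    split, Xsp, Xim, stats_sp, stats_im = _preprocess()
    tr, te = split.train_indices, split.test_indices
    y_train, y_test = labels[tr], labels[te]

    # ---- stage 3: CARS per modality on the training split ---------------- #
    @_stage("cars")
    def _cars():
        pls = PLSConfig(
            n_components=config.cars_components,
            cv_folds=config.cars_cv_folds,
            mc_sample_ratio=config.cars_mc_ratio,
        )
        out = {}
        if config.modality in ("fused", "spectra"):
            audit.record("cars_spectra", tr)
            out["spectra"] = run_cars(
                Xsp[tr], y_train, N=config.cars_runs, config=pls,
                seed=s_cars_sp, feature_names=spectra.grid.column_names(),
            )
        if config.modality in ("fused", "image"):
            audit.record("cars_image", tr)
            out["image"] = run_cars(
                Xim[tr], y_train, N=config.cars_runs, config=pls,
                seed=s_cars_im, feature_names=list(images.feature_names),
            )
        return out

    cars_results = _cars()

    # ---- stage 4: early fusion of the selected blocks -------------------- #
    @_stage("fuse")
    def _fuse():
        blocks_all = []
        if "spectra" in cars_results:
            ids = cars_results["spectra"].selected_features
            names = cars_results["spectra"].selected_names
            blocks_all.append((Xsp[:, ids], [("spectra", n) for n in names]))
        if "image" in cars_results:
            ids = cars_results["image"].selected_features
            names = cars_results["image"].selected_names
            blocks_all.append((Xim[:, ids], [("image", n) for n in names]))
        fused_all = early_fuse(blocks_all, labels)
        return (
            FusedDataset(fused_all.matrix[tr], fused_all.provenance, y_train),
            FusedDataset(fused_all.matrix[te], fused_all.provenance, y_test),
        )

    fused_train, fused_test = _fuse()

    # ---- stage 5: KOA tuning of the base-learner families ---------------- #
    @_stage("tune")
    def _tune():
        tuned = {}
        tuning = TuningConfig(
            fitness=config.tuning_fitness,
            koa=KOAConfig(
                population_size=config.koa_population,
                max_iterations=config.koa_iterations,
            ),
        )
        for j, family in enumerate(config.families):
            audit.record("koa_fitness", tr)
            tuned[family] = tune_model(
                family, fused_train.matrix, y_train, config=tuning,
                seed=(s_tune + j) % 2**31,
            )
        return tuned

    tuned = _tune()

    # ---- stage 6a: test-set evaluation of each tuned base learner -------- #
    classes = np.unique(labels)
    base_rows = []
    for family, tm in tuned.items():
        y_pred = tm.model.predict(fused_test.matrix)
        rep = evaluation.evaluate_predictions(y_test, y_pred, classes)
        base_rows.append(rep.summary_row(f"KOA-{family}"))
    base_report = pd.DataFrame(base_rows)

    # ---- stage 6b: stacking with combinatorial meta-learner selection ---- #
    @_stage("stack")
    def _stack():
        base_learners = [
            (family, build_model(family, tm.best_params, seed=(s_tune + j) % 2**31))
            for j, (family, tm) in enumerate(tuned.items())
        ]
        spec = StackingSpec(
            base_learners=base_learners,
            meta_learner=base_learners[0],  # placeholder until selection
            k=config.stacking_folds,
            meta_feature_mode=config.meta_feature_mode,
            seed=s_stack,
        )
        audit.record("meta_selection", tr)
        # one OOF matrix serves meta-learner selection, the final stack and
        # the candidate comparison; one set of refit base learners serves all
        meta = stacking.out_of_fold_predictions(
            base_learners, fused_train.matrix, y_train,
            k=spec.k, mode=spec.meta_feature_mode, seed=spec.seed,
        )
        selection_report, chosen = stacking.select_meta_learner(
            base_learners, spec, fused_train.matrix, y_train, seed=s_meta, meta=meta
        )
        Z = stacking.encode_meta_features(meta)
        refit = [
            (name, stacking._fit_quiet(clone(est), fused_train.matrix, y_train))
            for name, est in base_learners
        ]
        rows, models = [], {}
        for name, est in base_learners:
            meta_model = stacking._fit_quiet(clone(est), Z, y_train)
            sm = stacking.StackedModel(
                StackingSpec(base_learners, (name, est), spec.k,
                             spec.meta_feature_mode, spec.seed),
                refit, meta_model, meta.classes, meta,
                {n: len(y_train) for n, _ in base_learners},
            )
            models[name] = sm
            y_pred = stacking.predict(sm, fused_test.matrix)
            scores = stacking.predict_scores(sm, fused_test.matrix)
            rep = evaluation.evaluate_predictions(y_test, y_pred, classes, scores)
            rows.append(rep.summary_row(f"{name}-stacking"))
        stack_report = pd.DataFrame(rows)
        chosen_name = chosen[0]
        final = models[chosen_name]
        y_pred = stacking.predict(final, fused_test.matrix)
        scores = stacking.predict_scores(final, fused_test.matrix)
        final_eval = evaluation.evaluate_predictions(y_test, y_pred, classes, scores)
        return selection_report, chosen_name, final, final_eval, stack_report, y_pred

    selection_report, chosen_meta, stack_model, stack_eval, stack_report, y_pred = _stack()
    audit.record("evaluate_test", te)

    predictions = pd.DataFrame(
        {"index": te, "true": y_test, "predicted": y_pred}
    ).sort_values("index").reset_index(drop=True)

    result = PipelineResult(
        config=config,
        split=split,
        cars_results=cars_results,
        fused_train=fused_train,
        fused_test=fused_test,
        tuned=tuned,
        base_report=base_report,
        stack_report=stack_report,
        selection_report=selection_report,
        chosen_meta=chosen_meta,
        stack_model=stack_model,
        stack_eval=stack_eval,
        audit=audit,
        predictions=predictions,
        runtime_s=time.time() - t0,
    )
    if config.out_dir:
        _write_artifacts(result, Path(config.out_dir))
    return result


def run_ablation(config: RunConfig, modalities=("spectra", "image", "fused")) -> dict[str, PipelineResult]:
    """Re-run the pipeline per modality with otherwise identical settings."""
    out = {}
    for modality in modalities:
        cfg_dict = asdict(config)
        cfg_dict["modality"] = modality
        if cfg_dict["out_dir"]:
            cfg_dict["out_dir"] = str(Path(cfg_dict["out_dir"]) / modality)
        cfg_dict["families"] = tuple(cfg_dict["families"])
        out[modality] = run_pipeline(RunConfig(**cfg_dict))
    return out


# --------------------------------------------------------------------------- #
# artifacts
# --------------------------------------------------------------------------- #

def _write_artifacts(result: PipelineResult, out: Path) -> None:
    import joblib

    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config.config_hash(), "seed": result.config.seed}
    (out / "run_meta.json").write_text(json.dumps({
        **stamp,
        "chosen_meta_learner": result.chosen_meta,
        "modality": result.config.modality,
        "n_train": len(result.split.train_indices),
        "n_test": len(result.split.test_indices),
        "n_fused_features": result.fused_train.n_features,
        "runtime_s": round(result.runtime_s, 2),
        "best_params": {f: tm.best_params for f, tm in result.tuned.items()},
    }, indent=1, default=str))
    for modality, res in result.cars_results.items():
        res.write_report(out / f"cars_{modality}.csv", out / f"cars_{modality}_selected.json")
    for family, tm in result.tuned.items():
        pd.DataFrame({"iteration": np.arange(1, len(tm.history) + 1),
                      "best_fitness": tm.history}).to_csv(
            out / f"tuning_{family}.csv", index=False)
    result.base_report.to_csv(out / "base_models_report.csv", index=False)
    result.stack_report.to_csv(out / "stacking_report.csv", index=False)
    result.selection_report.to_csv(out / "meta_selection_report.csv", index=False)
    result.stack_eval.cm.to_frame().to_csv(out / "confusion_matrix.csv")
    if result.stack_eval.per_class_auc is not None:
        result.stack_eval.per_class_auc.to_csv(out / "per_class_auc.csv")
    result.predictions.to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(result.fused_train.provenance, columns=["modality", "feature"]).to_csv(
        out / "fused_provenance.csv", index=False)
    joblib.dump(result.stack_model, out / "stacked_model.joblib")
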