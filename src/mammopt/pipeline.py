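"""End-to-end orchestration: data -> tuned segmenter -> tuned classifier.

The run proceeds in the narrative order of the method: acquire data (the
synthetic phantom generator by default), search segmenter hyperparameters
by minimising S1 on a validation split, train the final segmenter, segment
every sample, search classifier hyperparameters by minimising S2 over the
segmented inputs, train the final classifier, and evaluate on a held-out
test split. Data are split 70/15/15 (train/val/test): the optimizer fitness
only ever sees the validation split and the report only the test split.

Hyperparameter-search objective evaluations run with a reduced surrogate
budget (capped epochs/steps) because the full printed training ranges are
not desk-feasible at ~500 evaluations; the final models train with the
full configured budget. Every random draw descends from the single run
seed via numpy SeedSequence spawning, so a repeat with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import cls_net, metrics, mml_eoo, seg_net
from .datasets import PhantomConfig, PhantomSample, generate_phantoms

__all__ = [
    "RunConfig",
    "SurrogateBudget",
    "StageError",
    "run_two_stage",
    "evaluate_report",
    "load_config",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class SurrogateBudget:
    """Training caps applied during hyperparameter search (not final fits)."""

    search_max_epochs: int = 2
    search_max_steps: int = 8
    final_max_epochs: int | None = None
    final_max_steps: int | None = None


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a two-stage run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seg_model: seg_net.SegModelConfig = field(default_factory=seg_net.SegModelConfig)
    seg_ranges: dict = field(default_factory=lambda: {
        "hidden_neurons": (5, 255), "epochs": (5, 50), "steps_per_epoch": (300, 1000)})
    cls_ranges: dict = field(default_factory=lambda: {
        "hidden_neurons": (5, 255), "epochs": (5, 50),
        "batch_size": cls_net.CLS_BATCH_CHOICES})
    pop_size: int = 10
    max_iter: int = 50
    surrogate: SurrogateBudget = field(default_factory=SurrogateBudget)
    seed: int = 0
    outdir: str = "runs/latest"
    allow_budget_override: bool = False

    def __post_init__(self):
        for name, (lo, hi) in seg_net.SEG_TUNING_RANGES.items():
            rlo, rhi = self.seg_ranges[name]
            if not (lo <= rlo <= rhi <= hi):
                raise ValueError(
                    f"seg search range {name}={self.seg_ranges[name]} outside [{lo}, {hi}]")
        for name, (lo, hi) in (("hidden_neurons", (5, 255)), ("epochs", (5, 50))):
            rlo, rhi = self.cls_ranges[name]
            if not (lo <= rlo <= rhi <= hi):
                raise ValueError(
                    f"cls search range {name}={self.cls_ranges[name]} outside [{lo}, {hi}]")
        bad = [b for b in self.cls_ranges["batch_size"]
               if b not in cls_net.CLS_BATCH_CHOICES]
        if bad:
            raise ValueError(
                f"batch sizes {bad} not in the choice list {cls_net.CLS_BATCH_CHOICES}")
        if not self.allow_budget_override and (self.pop_size > 10 or self.max_iter > 50):
            raise ValueError(
                "population is capped at 10 and iterations at 50; "
                "set allow_budget_override to exceed them")


def seg_search_space(ranges: dict) -> mml_eoo.SearchSpace:
    return mml_eoo.SearchSpace(
        dims=(mml_eoo.IntDim(*ranges["hidden_neurons"]),
              mml_eoo.IntDim(*ranges["epochs"]),
              mml_eoo.IntDim(*ranges["steps_per_epoch"])),
        names=("hidden_neurons", "epochs", "steps_per_epoch"),
    )


def cls_search_space(ranges: dict) -> mml_eoo.SearchSpace:
    return mml_eoo.SearchSpace(
        dims=(mml_eoo.IntDim(*ranges["hidden_neurons"]),
              mml_eoo.IntDim(*ranges["epochs"]),
              mml_eoo.ChoiceDim(tuple(ranges["batch_size"]))),
        names=("hidden_neurons", "epochs", "batch_size"),
    )


def _split(n: int, rng: np.random.Generator):
    order = rng.permutation(n)
    n_test = max(1, int(round(0.15 * n)))
    n_val = max(1, int(round(0.15 * n)))
    test = order[:n_test]
    val = order[n_test:n_test + n_val]
    train = order[n_test + n_val:]
    return train, val, test


def _metric_block(pred_labels, true_labels) -> dict:
    """Classification metrics in both formula modes, malignant vs rest,
    plus multiclass accuracy."""
    c = metrics.confusion_counts(pred_labels, true_labels, positive_label="malignant")
    block = {
        "confusion_malignant_vs_rest": dataclasses.asdict(c),
        "multiclass_accuracy": float(np.mean(
            [p == t for p, t in zip(pred_labels, true_labels)])),
    }
    for mode in ("standard", "as_printed"):
        rep = metrics.classification_metrics(c, mode=mode).as_dict()
        block[mode] = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                       for k, v in rep.items()}
    return block


def evaluate_report(pred_labels, true_labels, pred_masks=None, true_masks=None) -> dict:
    """Metric fragment: pooled classification metrics plus per-image overlap."""
    if len(pred_labels) != len(true_labels):
        raise ValueError("prediction/truth label lists misaligned")
    frag = {"classification": _metric_block(list(pred_labels), list(true_labels))}
    if pred_masks is not None:
        if true_masks is None or len(pred_masks) != len(true_masks):
            raise ValueError("prediction/truth mask lists misaligned")
        dices = [metrics.dice(p, t) for p, t in zip(pred_masks, true_masks)]
        jacs = [metrics.jaccard(p, t) for p, t in zip(pred_masks, true_masks)]
        frag["segmentation"] = {
            "dice_per_image": dices,
            "jaccard_per_image": jacs,
            "dice_mean": float(np.mean(dices)),
            "jaccard_mean": float(np.mean(jacs)),
        }
    return frag


def _save_checkpoint(model, meta: dict, prefix: str) -> None:
    np.savez(prefix + ".npz", **model.state_dict())
    with open(prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def run_two_stage(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and persists) the run report."""
    os.makedirs(cfg.outdir, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    (s_data, s_split, s_seg_opt, s_seg_train, s_cls_opt,
     s_cls_train) = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(6)]

    report: dict = {"seed": cfg.seed, "stages": []}

    def stage(name):
        report["stages"].append(name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    with open(os.path.join(cfg.outdir, "report_partial.json"), "w") as fh:
                        json.dump(report, fh, indent=2, default=str)
                    raise StageError(name, exc)
                return False

        return _Ctx()

    # ---- data ------------------------------------------------------------
    with stage("data"):
        phantom_cfg = dataclasses.replace(cfg.phantom, seed=s_data)
        samples = generate_phantoms(phantom_cfg)
        rng = np.random.default_rng(s_split)
        tr_idx, va_idx, te_idx = _split(len(samples), rng)
        report["split_sizes"] = {"train": len(tr_idx), "val": len(va_idx),
                                 "test": len(te_idx)}

    imgs = [s.image for s in samples]
    msks = [s.mask for s in samples]
    seg_pairs = lambda idx: [(imgs[i], msks[i]) for i in idx]

    # ---- segmenter hyperparameter search ----------------------------------
    with stage("optimize-seg"):
        space = seg_search_space(cfg.seg_ranges)

        def s1_of(params: dict) -> float:
            hp = seg_net.SegHyperparams(**params)
            d, a = seg_net.fit_and_score_seg(
                hp, seg_pairs(tr_idx), seg_pairs(va_idx), cfg.seg_model,
                seed=s_seg_train,
                max_epochs=cfg.surrogate.search_max_epochs,
                max_steps_per_epoch=cfg.surrogate.search_max_steps,
            )
            return seg_net.s1_from_scores(d, a)

        seg_opt = mml_eoo.optimize(
            s1_of, space, pop_size=cfg.pop_size, max_iter=cfg.max_iter,
            seed=s_seg_opt, seed_midpoint=True,
            log_path=os.path.join(cfg.outdir, "optimizer_seg.jsonl"),
        )
        baseline_s1 = s1_of(space.decode(space.midpoint()))
        report["seg_search"] = {
            "best_params": seg_opt.best_params,
            "best_fitness": seg_opt.best_fitness,
            "history": seg_opt.history,
            "evaluations": seg_opt.evaluations,
            "objective_calls": seg_opt.objective_calls,
            "baseline_midrange_s1": baseline_s1,
        }

    # ---- final segmenter ---------------------------------------------------
    with stage("train-seg"):
        best_seg_hp = seg_net.SegHyperparams(**seg_opt.best_params)
        seg_model = seg_net.build_aca_atrunet(best_seg_hp, cfg.seg_model,
                                              seed=s_seg_train)
        _, seg_log = seg_net.train_segmenter(
            seg_model, [imgs[i] for i in tr_idx], [msks[i] for i in tr_idx],
            best_seg_hp, seed=s_seg_train,
            max_epochs=cfg.surrogate.final_max_epochs,
            max_steps_per_epoch=cfg.surrogate.final_max_steps,
        )
        _save_checkpoint(seg_model, {"hp": dataclasses.asdict(best_seg_hp),
                                     "cfg": dataclasses.asdict(cfg.seg_model),
                                     "seed": s_seg_train},
                         os.path.join(cfg.outdir, "segmenter"))
        report["seg_training_loss"] = seg_log["loss"]

    # ---- segment everything -----------------------------------------------
    with stage("segment"):
        seg_out = seg_net.segment_batch(seg_model, imgs)
        pred_masks = [o.binary_mask for o in seg_out]

    cls_samples = [(imgs[i], pred_masks[i], samples[i].label)
                   for i in range(len(samples))]

    # ---- classifier hyperparameter search -----------------------------------
    with stage("optimize-cls"):
        cspace = cls_search_space(cfg.cls_ranges)

        def s2_of(params: dict) -> float:
            hp = cls_net.ClsHyperparams(**params)
            arcy, xy = cls_net.fit_and_score_cls(
                hp, [cls_samples[i] for i in tr_idx],
                [cls_samples[i] for i in va_idx], seed=s_cls_train,
                max_epochs=cfg.surrogate.search_max_epochs,
            )
            return cls_net.s2_from_scores(arcy, xy)

        cls_opt = mml_eoo.optimize(
            s2_of, cspace, pop_size=cfg.pop_size, max_iter=cfg.max_iter,
            seed=s_cls_opt, seed_midpoint=True,
            log_path=os.path.join(cfg.outdir, "optimizer_cls.jsonl"),
        )
        report["cls_search"] = {
            "best_params": cls_opt.best_params,
            "best_fitness": cls_opt.best_fitness,
            "history": cls_opt.history,
            "evaluations": cls_opt.evaluations,
            "objective_calls": cls_opt.objective_calls,
        }

    # ---- final classifier ----------------------------------------------------
    with stage("train-cls"):
        best_cls_hp = cls_net.ClsHyperparams(**cls_opt.best_params)
        cls_model = cls_net.build_aca_amdn(best_cls_hp, seed=s_cls_train)
        _, cls_log = cls_net.train_classifier(
            cls_model, [cls_samples[i] for i in tr_idx], best_cls_hp,
            seed=s_cls_train, max_epochs=cfg.surrogate.final_max_epochs,
        )
        _save_checkpoint(cls_model, {"hp": dataclasses.asdict(best_cls_hp),
                                     "seed": s_cls_train},
                         os.path.join(cfg.outdir, "classifier"))
        report["cls_training"] = cls_log

    # ---- evaluation ------------------------------------------------------------
    with stage("evaluate"):
        test_preds = cls_net.predict_batch(cls_model,
                                           [cls_samples[i] for i in te_idx])
        pred_labels = [o.predicted_label for o in test_preds]
        true_labels = [samples[i].label for i in te_idx]
        frag = evaluate_report(
            pred_labels, true_labels,
            pred_masks=[pred_masks[i] for i in te_idx],
            true_masks=[msks[i] for i in te_idx],
        )
        report["test"] = frag
        _persist_predictions(cfg.outdir, te_idx, test_preds, true_labels,
                             [pred_masks[i] for i in te_idx],
                             [msks[i] for i in te_idx])

    report["best_seg_hyperparams"] = seg_opt.best_params
    report["best_cls_hyperparams"] = cls_opt.best_params
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _persist_predictions(outdir, te_idx, test_preds, true_labels,
                         pred_masks, true_masks) -> None:
    import pandas as pd

    rows = []
    for i, o, t in zip(te_idx, test_preds, true_labels):
        p = o.probabilities
        rows.append({"sample_id": int(i), "p_normal": p[0], "p_benign": p[1],
                     "p_malignant": p[2], "predicted": o.predicted_label,
                     "true": t})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "test_predictions.csv"),
                              index=False)
    rows = []
    for i, pm, tm in zip(te_idx, pred_masks, true_masks):
        rows.append({"sample_id": int(i),
                     "dice": metrics.dice(pm, tm),
                     "jaccard": metrics.jaccard(pm, tm)})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "test_seg_metrics.csv"),
                              index=False)


def load_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    if "phantom" in raw and isinstance(raw["phantom"], dict):
        raw["phantom"] = PhantomConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                          for k, v in raw["phantom"].items()})
    if "seg_model" in raw and isinstance(raw["seg_model"], dict):
        sm = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in raw["seg_model"].items()}
        raw["seg_model"] = seg_net.SegModelConfig(**sm)
    if "surrogate" in raw and isinstance(raw["surrogate"], dict):
        raw["surrogate"] = SurrogateBudget(**raw["surrogate"])
    for key in ("seg_ranges", "cls_ranges"):
        if key in raw:
            raw[key] = {k: tuple(v) if isinstance(v, list) else v
                        for k, v in raw[key].items()}
    return RunConfig(**raw)
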