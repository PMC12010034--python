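"""Model/Results facade over the cascade pipeline.

``CascadeModel`` is constructed from a cohort (in memory or on disk) plus a
:class:`~hncascade.config.CascadeConfig`; ``fit`` trains the coarse+fine
pair on one fold and returns a :class:`CascadeResults` carrying the trained
networks, the per-epoch history, and evaluation helpers, in the spirit of
statsmodels' ``Model.fit() -> Results``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import run_cascade
from .config import CascadeConfig
from .metrics import CohortScore, EvalPair, score_cohort
from .postprocessing import postprocess
from .training import (LossSchedule, PreparedCase, TrainResult, make_folds,
                       prepare_case, train)
from .unet3d import save_checkpoint
from .volume_io import CaseRecord, LabelVolume, load_cohort


class CascadeModel:
    """Coarse-to-fine cascade segmenter bound to a cohort and a config."""

    def __init__(self, cases: Sequence[CaseRecord], config: CascadeConfig):
        if not cases:
            raise ValueError("empty cohort")
        self.cases = list(cases)
        self.config = config
        self._prepared: dict[str, PreparedCase] = {}

    @classmethod
    def from_cohort_dir(cls, root: str | Path, config: CascadeConfig,
                        require_mid_mask: bool = True) -> "CascadeModel":
        return cls(load_cohort(root, require_mid_mask=require_mid_mask), config)

    # ---- data ------------------------------------------------------------
    def prepared(self, case_ids: Optional[Sequence[str]] = None) -> list[PreparedCase]:
        """Normalized/resampled cases with dilated priors (cached)."""
        ids = list(case_ids) if case_ids is not None else [c.case_id for c in self.cases]
        by_id = {c.case_id: c for c in self.cases}
        out = []
        for cid in ids:
            if cid not in self._prepared:
                self._prepared[cid] = prepare_case(
                    by_id[cid], self.config.grid, self.config.normalization,
                    self.config.dilation)
            out.append(self._prepared[cid])
        return out

    def folds(self) -> list[dict[str, list[str]]]:
        return make_folds([c.case_id for c in self.cases], k=self.config.train.folds,
                          split=self.config.train.split, seed=self.config.train.seed)

    # ---- fitting ---------------------------------------------------------
    def fit(self, fold: int = 0, mode: str = "end_to_end",
            verbose: bool = False) -> "CascadeResults":
        split = self.folds()[fold]
        train_set = self.prepared(split["train"])
        val_set = self.prepared(split["val"])
        result = train(train_set, val_set, self.config.recipe, self.config.network,
                       self.config.crop, self.config.train,
                       sched=LossSchedule(total_epochs=self.config.train.epochs),
                       mode=mode, verbose=verbose)
        return CascadeResults(self, result, fold=fold, split=split)


@dataclass
class CascadeResults:
    model: CascadeModel
    fit_result: TrainResult
    fold: int
    split: dict[str, list[str]]

    @property
    def history(self) -> pd.DataFrame:
        return self.fit_result.history

    @property
    def config(self) -> CascadeConfig:
        return self.model.config

    def with_cases(self, cases: Sequence[CaseRecord]) -> "CascadeResults":
        """Bind the fitted networks to a different cohort (e.g. an external
        held-out set); predict()/evaluate() then default to all its cases."""
        model = CascadeModel(cases, self.config)
        split = {"train": [], "val": [], "test": [c.case_id for c in cases]}
        return CascadeResults(model, self.fit_result, fold=self.fold, split=split)

    def predict(self, case_ids: Optional[Sequence[str]] = None,
                apply_postprocess: bool = True) -> dict[str, LabelVolume]:
        """Segment cases (default: the fold's test split) on the fixed grid."""
        ids = list(case_ids) if case_ids is not None else self.split["test"]
        out = {}
        for pc in self.model.prepared(ids):
            pred = run_cascade(pc.case, self.fit_result.coarse_net,
                               self.fit_result.fine_net, self.config.recipe,
                               self.config.crop, dilated_prior=pc.prior,
                               coarse_feed=self.config.train.coarse_feed)
            if apply_postprocess:
                pred = postprocess(pred, self.config.postprocess)
            out[pc.case.case_id] = pred
        return out

    def evaluate(self, case_ids: Optional[Sequence[str]] = None,
                 metrics: Sequence[str] = ("dscagg", "surface", "hd95"),
                 apply_postprocess: bool = True
                 ) -> tuple[dict[str, CohortScore], pd.DataFrame]:
        ids = list(case_ids) if case_ids is not None else self.split["test"]
        preds = self.predict(ids, apply_postprocess=apply_postprocess)
        pairs = []
        for pc in self.model.prepared(ids):
            if pc.case.mid_mask is None:
                raise ValueError(f"case {pc.case.case_id} has no ground truth")
            pairs.append(EvalPair(truth=pc.case.mid_mask, pred=preds[pc.case.case_id]))
        return score_cohort(pairs, metrics, self.config.surface)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config.hash(), "fold": self.fold,
                "mode": self.fit_result.mode}
        save_checkpoint(out_dir / "coarse.npz", self.fit_result.coarse_net, meta)
        save_checkpoint(out_dir / "fine.npz", self.fit_result.fine_net, meta)
        self.history.to_csv(out_dir / "history.csv", index=False)
        self.config.to_yaml(out_dir / "config.yaml")
        return out_dir

    def summary(self) -> str:
        """Plain-text fit summary in the style of statsmodels results."""
        cfg = self.config
        h = self.history
        joint = h[h["phase"] != "coarse"] if "phase" in h else h
        lines = [
            "Coarse-to-fine cascade segmentation results",
            "=" * 55,
            f"recipe:            {cfg.recipe.value}",
            f"mode:              {self.fit_result.mode}",
            f"fold:              {self.fold} "
            f"(train {len(self.split['train'])} / val {len(self.split['val'])}"
            f" / test {len(self.split['test'])})",
            f"grid / crop:       {cfg.grid.target_shape} / {cfg.crop.crop_shape}",
            f"network widths:    {cfg.network.stage_widths}",
            f"parameters:        coarse {self.fit_result.coarse_net.param_count():,}"
            f", fine {self.fit_result.fine_net.param_count():,}",
            f"epochs:            {cfg.train.epochs}",
            f"final train loss:  {h['total'].iloc[-1]:.4f}",
            f"best val DSCagg:   {self.fit_result.best_val:.4f}"
            f" (epoch {self.fit_result.best_epoch})",
            "=" * 55,
        ]
        return "\n".join(lines)


def run_experiment(cases: Sequence[CaseRecord], config: CascadeConfig,
                   recipes: Sequence[str], folds: Sequence[int] = (0,),
                   mode: str = "end_to_end", out_dir: Optional[str | Path] = None,
                   verbose: bool = False) -> pd.DataFrame:
    """Train/predict/postprocess/evaluate each recipe on each fold.

    Returns a long-format table (recipe x fold x class x metric) shaped like
    the comparative-results tables of the input-ablation study; when
    ``out_dir`` is given, writes scores.csv, per-recipe checkpoints and the
    resolved config for provenance.
    """
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for recipe in recipes:
        cfg = config.with_recipe(recipe)
        model = CascadeModel(cases, cfg)
        for fold in folds:
            res = model.fit(fold=fold, mode=mode, verbose=verbose)
            scores, _ = res.evaluate()
            for metric, cs in scores.items():
                for cname, v in cs.per_class.items():
                    rows.append({"recipe": cfg.recipe.value, "fold": fold,
                                 "metric": metric, "class": cname, "value": v})
                rows.append({"recipe": cfg.recipe.value, "fold": fold,
                             "metric": metric, "class": "mean", "value": cs.mean})
            if out_dir is not None:
                res.save(out_dir / f"{cfg.recipe.value}_fold{fold}")
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "scores.csv", index=False)
        config.to_yaml(out_dir / "config.yaml")
    return table
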