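"""Metrics and experiment harnesses.

Metrics: accuracy, F1 (``TP / (TP + 0.5 (FP + FN))``), Matthews
correlation coefficient (zero by convention when a denominator factor
vanishes) and AUC as the Mann-Whitney rank statistic (the probability a
positive outranks a negative, ties counted half).

Harnesses mirror the three experiment designs: intra-species (repeated
72/8/20 holdout on one table), cross-species (train on the source's
training split, evaluate on the target's test split) and the transfer
curve, which fits each configuration at cumulative target-chunk sizes
0..max_total and evaluates everything on the fixed target test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models as M
from .datasets import DatasetSplit, SplitSpec, sample_chunks, stratified_split
from .records import FeatureTable

INTRA, CROSS, TRANSFER = "intra", "cross", "transfer"

CURVE_CONFIGS = (
    "ann_transfer",
    "ann_mix_no_transfer",
    "ann_target_only",
    "ann_baseline_full",
    "xgb_transfer",
    "xgb_baseline_full",
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ExperimentResult:
    experiment_kind: str
    source_species: str
    target_species: str
    config_name: str
    chunk_size: int
    repeat_index: int
    metrics: Dict[str, float]


def confusion(labels: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
        threshold=threshold,
    )


def metrics_from_confusion(c: ConfusionCounts) -> Dict[str, float]:
    acc = (c.TP + c.TN) / c.total
    f1_den = c.TP + 0.5 * (c.FP + c.FN)
    f1 = c.TP / f1_den if f1_den > 0 else 0.0
    factors = [(c.TP + c.FP), (c.TP + c.FN), (c.TN + c.FP), (c.TN + c.FN)]
    if min(factors) == 0:
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(
            float(factors[0]) * factors[1] * factors[2] * factors[3]
        )
    return {"ACC": float(acc), "F1": float(f1), "MCC": float(mcc)}


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    from scipy.stats import rankdata

    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class labels")
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_metrics(labels: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> Dict[str, float]:
    """ACC / AUC / F1 / MCC of probability scores against binary labels."""
    s = np.asarray(scores, dtype=float)
    if len(s) != len(labels) or len(s) == 0:
        raise ValueError("labels and scores must be equal-length, non-empty")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be probabilities in [0,1]")
    out = metrics_from_confusion(confusion(labels, s, threshold))
    out["AUC"] = auc_score(labels, s)
    return out


# --------------------------------------------------------------------------
# shared fitting helpers
# --------------------------------------------------------------------------

def _model_seed(base_seed: int, repeat: int, salt: int = 0) -> int:
    return int((base_seed * 1_000_003 + repeat * 9176 + salt) % (2 ** 31))


def _fit(
    family: str,
    train: FeatureTable,
    validation: Optional[FeatureTable],
    seed: int,
    ann_cfg: Optional[M.AnnConfig],
    xgb_params: Optional[dict],
) -> M.TransferModel:
    if family == M.ANN:
        from dataclasses import replace
        cfg = replace(ann_cfg or M.AnnConfig(), rng_seed=seed)
        return M.train_ann(train, cfg, validation)
    params = dict(xgb_params or {})
    params["seed"] = seed
    return M.train_xgb(train, params, validation)


def _partitions(table: FeatureTable, split: DatasetSplit
                ) -> Tuple[FeatureTable, FeatureTable, FeatureTable]:
    return (table.subset(split.train_ids),
            table.subset(split.validation_ids),
            table.subset(split.test_ids))


# --------------------------------------------------------------------------
# experiment harnesses
# --------------------------------------------------------------------------

def run_intra(
    species_table: FeatureTable,
    spec: SplitSpec,
    family: str,
    ann_cfg: Optional[M.AnnConfig] = None,
    xgb_params: Optional[dict] = None,
    threshold: float = 0.5,
) -> List[ExperimentResult]:
    """Repeated stratified holdout on one species dataset."""
    sp = species_table.df["species"].iloc[0]
    results = []
    for split in stratified_split(species_table, spec):
        train, val, test = _partitions(species_table, split)
        mdl = _fit(family, train, val,
                   _model_seed(spec.rng_seed, split.repeat_index), ann_cfg,
                   xgb_params)
        m = compute_metrics(test.y, mdl.predict(test), threshold)
        results.append(ExperimentResult(
            INTRA, sp, sp, family, 0, split.repeat_index, m))
    return results


def run_cross(
    source_table: FeatureTable,
    target_table: FeatureTable,
    spec: SplitSpec,
    family: str,
    ann_cfg: Optional[M.AnnConfig] = None,
    xgb_params: Optional[dict] = None,
    threshold: float = 0.5,
) -> List[ExperimentResult]:
    """Train on the source training split, test on the target test split.

    With ``source_table is target_table`` this reproduces
    :func:`run_intra` exactly (same splits, same model seeds).
    """
    source_table.require_same_schema(target_table)
    src = source_table.df["species"].iloc[0]
    tgt = target_table.df["species"].iloc[0]
    src_splits = stratified_split(source_table, spec)
    tgt_splits = (src_splits if target_table is source_table
                  else stratified_split(target_table, spec))
    results = []
    for s_split, t_split in zip(src_splits, tgt_splits):
        train, val, _ = _partitions(source_table, s_split)
        test = target_table.subset(t_split.test_ids)
        mdl = _fit(family, train, val,
                   _model_seed(spec.rng_seed, s_split.repeat_index), ann_cfg,
                   xgb_params)
        m = compute_metrics(test.y, mdl.predict(test), threshold)
        results.append(ExperimentResult(
            CROSS, src, tgt, family, 0, s_split.repeat_index, m))
    return results


def run_transfer_curve(
    source_table: FeatureTable,
    target_table: FeatureTable,
    spec: SplitSpec,
    configs: Sequence[str] = CURVE_CONFIGS,
    chunk_size: int = 100,
    max_total: int = 500,
    repeats: Sequence[int] = (0,),
    ann_cfg: Optional[M.AnnConfig] = None,
    transfer_cfg: Optional[M.AnnConfig] = None,
    xgb_params: Optional[dict] = None,
    n_new_trees: int = M.DEFAULT_NEW_TREES,
    threshold: float = 0.5,
) -> List[ExperimentResult]:
    """The chunked transfer-curve experiment.

    For each requested configuration and cumulative chunk size the model
    is fitted per its recipe and evaluated on the fixed target test set.
    At size 0 the transfer configurations coincide with the cross-species
    result; the full-data baselines are fitted once per repeat and
    reported constant across sizes.
    """
    unknown = set(configs) - set(CURVE_CONFIGS)
    if unknown:
        raise ValueError(f"unknown curve configs: {sorted(unknown)}")
    source_table.require_same_schema(target_table)
    src = source_table.df["species"].iloc[0]
    tgt = target_table.df["species"].iloc[0]
    src_splits = stratified_split(source_table, spec)
    tgt_splits = (src_splits if target_table is source_table
                  else stratified_split(target_table, spec))

    if transfer_cfg is None:
        base = ann_cfg or M.AnnConfig()
        # default freeze: all dense layers except the last two; generous
        # epoch budget with early stopping on the target validation split
        from dataclasses import replace
        frozen = frozenset(range(max(0, base.n_layers - 2)))
        transfer_cfg = replace(base, frozen_layers=frozen, epochs=80,
                               early_stopping_patience=8)

    results: List[ExperimentResult] = []
    sizes = list(range(0, max_total + 1, chunk_size))
    for r in repeats:
        s_split, t_split = src_splits[r], tgt_splits[r]
        src_train, src_val, _ = _partitions(source_table, s_split)
        tgt_train, tgt_val, tgt_test = _partitions(target_table, t_split)
        seed = _model_seed(spec.rng_seed, r)
        rng = np.random.default_rng([spec.rng_seed, r, 7])
        chunks = sample_chunks(tgt_train, rng, chunk_size, max_total)
        # test-set isolation: no chunk id may be a target test id
        for ch in chunks:
            leak = set(ch) & set(t_split.test_ids)
            assert not leak, f"test ids leaked into chunks: {sorted(leak)[:5]}"

        def emit(config: str, size: int, mdl: M.TransferModel) -> None:
            m = compute_metrics(tgt_test.y, mdl.predict(tgt_test), threshold)
            results.append(ExperimentResult(
                TRANSFER, src, tgt, config, size, r, m))

        ann_source = xgb_source = None
        if "ann_transfer" in configs or "ann_mix_no_transfer" in configs:
            ann_source = _fit(M.ANN, src_train, src_val, seed, ann_cfg, None)
        if "xgb_transfer" in configs:
            xgb_source = _fit(M.XGB, src_train, src_val, seed, None,
                              xgb_params)
        if "ann_baseline_full" in configs:
            mdl = _fit(M.ANN, tgt_train, tgt_val, seed, ann_cfg, None)
            for size in sizes:
                emit("ann_baseline_full", size, mdl)
        if "xgb_baseline_full" in configs:
            mdl = _fit(M.XGB, tgt_train, tgt_val, seed, None, xgb_params)
            for size in sizes:
                emit("xgb_baseline_full", size, mdl)

        for size in sizes:
            chunk = (tgt_train.subset(chunks[size // chunk_size - 1])
                     if size else None)
            if "ann_transfer" in configs:
                mdl = (ann_source if size == 0
                       else M.transfer_ann(ann_source, chunk, transfer_cfg,
                                           validation=tgt_val))
                emit("ann_transfer", size, mdl)
            if "xgb_transfer" in configs:
                mdl = (xgb_source if size == 0
                       else M.transfer_xgb(xgb_source, chunk, n_new_trees))
                emit("xgb_transfer", size, mdl)
            if "ann_mix_no_transfer" in configs:
                mix = (src_train if size == 0 else FeatureTable(
                    pd.concat([src_train.df, chunk.df], ignore_index=True),
                    src_train.schema_version))
                mdl = _fit(M.ANN, mix, src_val, seed, ann_cfg, None)
                emit("ann_mix_no_transfer", size, mdl)
            if "ann_target_only" in configs and size >= chunk_size:
                mdl = _fit(M.ANN, chunk, tgt_val, seed, ann_cfg, None)
                emit("ann_target_only", size, mdl)
    return results


# --------------------------------------------------------------------------
# result shaping
# --------------------------------------------------------------------------

def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Tidy one-row-per-result table."""
    rows = []
    for r in results:
        row = {
            "experiment_kind": r.experiment_kind,
            "source_species": r.source_species,
            "target_species": r.target_species,
            "config_name": r.config_name,
            "chunk_size": r.chunk_size,
            "repeat_index": r.repeat_index,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_metric(results: Sequence[ExperimentResult], metric: str = "ACC",
                **filters) -> float:
    """Mean of one metric over repeats, after filtering result fields."""
    df = results_to_frame(results)
    for k, v in filters.items():
        df = df[df[k] == v]
    if df.empty:
        raise ValueError(f"no results match {filters}")
    return float(df[metric].mean())


def heatmap_matrix(results: Sequence[ExperimentResult], metric: str = "ACC"
                   ) -> pd.DataFrame:
    """Species x species mean-metric matrix (sources as rows)."""
    df = results_to_frame(results)
    return df.pivot_table(index="source_species", columns="target_species",
                          values=metric, aggfunc="mean")
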