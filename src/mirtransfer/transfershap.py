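"""TransferSHAP: per-feature importance of the transfer step.

The method computes a Shapley-value matrix (observations x features,
positive values pushing toward the positive class) for the source-phase
and the transferred model on the *same* evaluation observations, takes
the elementwise absolute difference, and sums columns.  A feature that is
important in both models but unchanged by fine-tuning therefore scores
zero: the importance measures what the transfer step changed, not what
the model uses.  Importance vectors of different <source,target> model
pairs are compared by Spearman correlation of their MinMax-normalised
vectors and grouped by average-linkage hierarchical clustering on the
distance 1 - rho.

Shapley back-ends:

* ``exact_small`` — full coalition enumeration (<= 12 features) against a
  background sample; satisfies local accuracy exactly.
* ``sampling`` — unbiased permutation-sampling estimator with a recorded
  draw count and seed.
* ``tree_exact`` — xgboost's path-dependent TreeSHAP for the tree family
  (contributions live in margin/log-odds space; consistent within the
  family, which is all the differencing needs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from . import models as M
from .records import FeatureTable

EXACT_SMALL = "exact_small"
SAMPLING = "sampling"
TREE_EXACT = "tree_exact"

MAX_EXACT_FEATURES = 12


@dataclass
class ShapleyMatrix:
    """Per-observation, per-feature contributions of one model phase."""

    values: np.ndarray  # (n_obs, n_features)
    observation_ids: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    base_values: np.ndarray  # (n_obs,) expected output under the background
    model_ref: str = ""
    method: str = EXACT_SMALL
    meta: dict = field(default_factory=dict)


@dataclass
class TransferSHAPResult:
    """Column-summed |target phi - source phi| per feature."""

    importance: Dict[str, float]
    normalized_importance: Dict[str, float]
    pair: Tuple[str, str]
    family: str

    @property
    def label(self) -> str:
        return f"{self.pair[0]}→{self.pair[1]}"

    def top_features(self, k: int) -> List[str]:
        return [f for f, _ in sorted(self.importance.items(),
                                     key=lambda kv: -kv[1])[:k]]


def _predict_fn(model: M.TransferModel, which: str):
    if which == "source":
        return model.predict_source
    if which == "target":
        return model.predict
    raise ValueError(f"which must be 'source' or 'target', not {which!r}")


def _as_background(background, eval_table: FeatureTable) -> np.ndarray:
    if background is None:
        return eval_table.X
    if isinstance(background, FeatureTable):
        return background.X
    return np.asarray(background, dtype=float)


def _exact_shapley(predict, X: np.ndarray, bg: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Full coalition enumeration with a background distribution.

    v(S) for observation x is the background-mean model output with the
    features in S fixed to x; phi is the Shapley combination over all
    2^m coalitions.
    """
    n, m = X.shape
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{m} features exceed the exact enumeration cap "
            f"({MAX_EXACT_FEATURES}); use method='sampling'"
        )
    n_bg = len(bg)
    # v[mask] -> (n,) mean prediction per observation
    v = np.empty((1 << m, n))
    for mask in range(1 << m):
        members = [k for k in range(m) if mask >> k & 1]
        Xrep = np.repeat(bg[None, :, :], n, axis=0)  # (n, n_bg, m)
        if members:
            Xrep[:, :, members] = X[:, None, members]
        preds = predict(Xrep.reshape(n * n_bg, m)).reshape(n, n_bg)
        v[mask] = preds.mean(axis=1)
    fact = [math.factorial(k) for k in range(m + 1)]
    phi = np.zeros((n, m))
    for mask in range(1 << m):
        s = bin(mask).count("1")
        w = fact[s] * fact[m - s - 1] / fact[m]
        for k in range(m):
            if mask >> k & 1:
                continue
            phi[:, k] += w * (v[mask | (1 << k)] - v[mask])
    return phi, v[0]


def _sampling_shapley(predict, X: np.ndarray, bg: np.ndarray,
                      n_permutations: int, rng: np.random.Generator
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Unbiased permutation estimator of Shapley values.

    For each permutation a background row is drawn per observation and
    features are switched on in permutation order; marginal prediction
    differences average to phi.
    """
    n, m = X.shape
    phi = np.zeros((n, m))
    base = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(m)
        z = bg[rng.integers(0, len(bg), n)]
        cur = z.copy()
        prev = predict(cur)
        base += prev
        for k in order:
            cur[:, k] = X[:, k]
            nxt = predict(cur)
            phi[:, k] += nxt - prev
            prev = nxt
    return phi / n_permutations, base / n_permutations


def shapley_matrix(
    model: M.TransferModel,
    which: str,
    eval_table: FeatureTable,
    method: str = "auto",
    background=None,
    n_permutations: int = 64,
    rng_seed: int = 0,
) -> ShapleyMatrix:
    """Shapley-value matrix of one model phase on an evaluation table.

    ``background`` (a FeatureTable or array) supplies the reference
    distribution for the enumeration/sampling back-ends; it defaults to
    the evaluation table itself (shared-background mode).  TreeSHAP is
    path-dependent and ignores the background.
    """
    X = eval_table.X
    m = X.shape[1]
    if method == "auto":
        method = (TREE_EXACT if model.family == M.XGB
                  else (EXACT_SMALL if m <= MAX_EXACT_FEATURES else SAMPLING))
    predict = _predict_fn(model, which)
    meta: dict = {}
    if method == TREE_EXACT:
        if model.family != M.XGB:
            raise ValueError("tree_exact applies to the xgb family only")
        import xgboost as xgb

        state = (model.source_state if which == "source"
                 else (model.transfer_state or model.source_state))
        contribs = state["booster"].predict(
            xgb.DMatrix(X), pred_contribs=True
        )
        phi, base = contribs[:, :-1].astype(float), contribs[:, -1].astype(float)
        meta["space"] = "margin"
    elif method == EXACT_SMALL:
        bg = _as_background(background, eval_table)
        phi, base = _exact_shapley(predict, X, bg)
        meta["space"] = "probability"
    elif method == SAMPLING:
        bg = _as_background(background, eval_table)
        rng = np.random.default_rng(rng_seed)
        phi, base = _sampling_shapley(predict, X, bg, n_permutations, rng)
        meta.update(space="probability", n_permutations=n_permutations,
                    rng_seed=rng_seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ShapleyMatrix(
        values=phi,
        observation_ids=tuple(eval_table.ids),
        feature_names=tuple(eval_table.feature_names),
        base_values=np.asarray(base, dtype=float),
        model_ref=f"{model.family}:{which}",
        method=method,
        meta=meta,
    )


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        warnings.warn("constant importance vector; normalising to zeros")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def transfershap(source_phi: ShapleyMatrix, target_phi: ShapleyMatrix,
                 pair: Tuple[str, str] = ("source", "target"),
                 family: str = "") -> TransferSHAPResult:
    """Aggregate two aligned Shapley matrices into transfer importances."""
    if source_phi.observation_ids != target_phi.observation_ids:
        a = set(source_phi.observation_ids)
        b = set(target_phi.observation_ids)
        raise ValueError(
            "observation ids differ between matrices; "
            f"mismatches: {sorted(a ^ b)[:10]}"
        )
    if source_phi.feature_names != target_phi.feature_names:
        a = set(source_phi.feature_names)
        b = set(target_phi.feature_names)
        raise ValueError(
            f"feature names differ between matrices; mismatches: "
            f"{sorted(a ^ b)[:10]}"
        )
    imp = np.abs(target_phi.values - source_phi.values).sum(axis=0)
    norm = _minmax(imp)
    names = source_phi.feature_names
    return TransferSHAPResult(
        importance={f: float(v) for f, v in zip(names, imp)},
        normalized_importance={f: float(v) for f, v in zip(names, norm)},
        pair=pair,
        family=family,
    )


def compare_pairs(results: Sequence[TransferSHAPResult]
                  ) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Spearman correlation matrix across pairs + average-linkage tree.

    Returns (correlation DataFrame labelled "source->target", the scipy
    linkage matrix on distance 1 - rho, and the dendrogram leaf order).
    """
    if len(results) < 2:
        raise ValueError("need at least two TransferSHAP results")
    feats = list(results[0].normalized_importance)
    for r in results[1:]:
        if list(r.normalized_importance) != feats:
            raise ValueError("results do not share a common feature set")
    vecs = np.array([[r.normalized_importance[f] for f in feats]
                     for r in results])
    labels = [r.label for r in results]
    k = len(results)
    rho = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(vecs[i]) == 0 or np.ptp(vecs[j]) == 0:
                warnings.warn(f"constant vector in pair {labels[i]}/"
                              f"{labels[j]}; correlation undefined")
                r_ij = np.nan
            else:
                r_ij = spearmanr(vecs[i], vecs[j]).statistic
            rho[i, j] = rho[j, i] = r_ij
    corr = pd.DataFrame(rho, index=labels, columns=labels)
    dist = 1.0 - np.nan_to_num(rho, nan=-1.0)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in sch.leaves_list(Z)]
    return corr, Z, order


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram into k clusters."""
    return sch.fcluster(Z, t=k, criterion="maxclust")


# --------------------------------------------------------------------------
# planted-structure recovery experiment
# --------------------------------------------------------------------------

def adjusted_rand(a: Sequence[int], b: Sequence[int]) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(a), list(b)))


def ari_permutation_pvalue(observed_labels: Sequence[int],
                           reference: Sequence[int],
                           rng: np.random.Generator,
                           n_permutations: int = 999) -> Tuple[float, float]:
    """Permutation p-value for ARI(observed, reference) under relabelling."""
    obs = adjusted_rand(observed_labels, reference)
    ref = np.asarray(list(reference))
    count = 0
    for _ in range(n_permutations):
        if adjusted_rand(observed_labels, rng.permutation(ref)) >= obs - 1e-12:
            count += 1
    return obs, (count + 1) / (n_permutations + 1)


def recovery_experiment(
    rule,
    specs,
    family: str,
    n_per_species: int = 3000,
    chunk_total: int = 500,
    n_eval: Optional[int] = None,
    n_background: int = 40,
    n_permutations: int = 20,
    split_seed: int = 0,
    ann_cfg: Optional[M.AnnConfig] = None,
    transfer_cfg: Optional[M.AnnConfig] = None,
    xgb_params: Optional[dict] = None,
    n_new_trees: int = 5 * M.DEFAULT_NEW_TREES,
) -> dict:
    """Train all ordered <source,target> pairs on synthetic species and
    test whether TransferSHAP recovers the planted structure.

    Reports per-pair top-|S| recall of each pair's shifted feature union,
    the pairwise correlation/cluster structure, and the adjusted Rand
    index of the k-species dendrogram cut against the same-target
    partition.
    """
    from dataclasses import replace

    from .datasets import SplitSpec, sample_chunks, stratified_split
    from .simdata import simulate_feature_tables

    if len(specs) < 3:
        raise ValueError("recovery experiment needs >= 3 species")
    if n_eval is None:
        # TreeSHAP is cheap; the ANN sampling estimator is not
        n_eval = 250 if family == M.XGB else 80
    tables = simulate_feature_tables(rule, specs, n_per_species)
    names = [s.name for s in specs]
    split_spec = SplitSpec(n_repeats=1, rng_seed=split_seed)
    splits = {sp: stratified_split(tables[sp], split_spec)[0]
              for sp in names}
    parts = {
        sp: (
            tables[sp].subset(splits[sp].train_ids),
            tables[sp].subset(splits[sp].validation_ids),
            tables[sp].subset(splits[sp].test_ids),
        )
        for sp in names
    }

    if family == M.ANN and transfer_cfg is None:
        base = ann_cfg or M.AnnConfig()
        transfer_cfg = replace(
            base, frozen_layers=frozenset(range(max(0, base.n_layers - 2))),
            epochs=80, early_stopping_patience=8)

    results: List[TransferSHAPResult] = []
    recalls: Dict[str, float] = {}
    for src_index, src in enumerate(names):
        src_train, src_val, _ = parts[src]
        seed = int((split_seed * 7919 + src_index * 131) % (2 ** 31))
        if family == M.ANN:
            cfg = replace(ann_cfg or M.AnnConfig(), rng_seed=seed)
            source_model = M.train_ann(src_train, cfg, src_val)
        else:
            params = dict(xgb_params or {})
            params["seed"] = seed
            source_model = M.train_xgb(src_train, params, src_val)
        for tgt in names:
            if tgt == src:
                continue
            tgt_train, tgt_val, tgt_test = parts[tgt]
            # each <source,target> run draws its own chunk of the target's
            # training split, mirroring independently run pair experiments
            rng = np.random.default_rng(
                [split_seed, src_index, names.index(tgt), 5])
            chunk_ids = sample_chunks(tgt_train, rng, chunk_size=chunk_total,
                                      max_total=chunk_total)[-1]
            chunk = tgt_train.subset(chunk_ids)
            if family == M.ANN:
                model = M.transfer_ann(source_model, chunk, transfer_cfg,
                                       validation=tgt_val)
            else:
                model = M.transfer_xgb(source_model, chunk, n_new_trees)
            eval_tab = FeatureTable(
                tgt_test.df.iloc[:n_eval].copy(), tgt_test.schema_version)
            bg = src_train.X[:n_background]
            bg_t = np.concatenate([bg, chunk.X])[:n_background]
            kw = dict(n_permutations=n_permutations, rng_seed=seed % 4096)
            method = TREE_EXACT if family == M.XGB else SAMPLING
            phi_s = shapley_matrix(model, "source", eval_tab, method,
                                   background=bg, **kw)
            phi_t = shapley_matrix(model, "target", eval_tab, method,
                                   background=bg_t, **kw)
            res = transfershap(phi_s, phi_t, pair=(src, tgt), family=family)
            results.append(res)
            relevant = rule.shifted_features(src) | rule.shifted_features(tgt)
            top = set(res.top_features(len(relevant))) if relevant else set()
            recalls[res.label] = (len(top & relevant) / len(relevant)
                                  if relevant else float("nan"))

    corr, Z, order = compare_pairs(results)
    clusters = cut_clusters(Z, len(names))
    same_target = [names.index(r.pair[1]) for r in results]
    ari = adjusted_rand(clusters, same_target)
    return {
        "results": results,
        "correlation": corr,
        "linkage": Z,
        "leaf_order": order,
        "clusters": clusters,
        "same_target_partition": same_target,
        "adjusted_rand": ari,
        "top_recall": recalls,
        "mean_top_recall": float(np.mean(list(recalls.values()))),
    }
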