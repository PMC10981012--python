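"""Dataset mechanics: merging, stratified splitting, transfer chunks.

The split is an 80/20 train/test partition with 10% of the training set
held out for validation (so 72/8/20 of the whole), stratified at the
miRNA level: each miRNA's interactions are allocated across the three
partitions so that per-miRNA proportions track the global fractions as
closely as integer allocation allows, and miRNAs with a single
interaction go entirely to the test set, forcing the model to predict for
unseen miRNAs.  The procedure is repeated ``n_repeats`` times with
different random memberships.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import FeatureTable, SchemaError

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    validation_fraction_of_train: float = 0.1
    n_repeats: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0,1)")
        if not (0.0 <= self.validation_fraction_of_train < 1.0):
            raise ValueError("validation_fraction_of_train must be in [0,1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def fractions(self) -> Tuple[float, float, float]:
        """(train, validation, test) shares of the whole dataset."""
        tr = self.train_fraction * (1.0 - self.validation_fraction_of_train)
        va = self.train_fraction * self.validation_fraction_of_train
        return (tr, va, 1.0 - self.train_fraction)


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: frozenset
    validation_ids: frozenset
    test_ids: frozenset
    repeat_index: int

    def __post_init__(self) -> None:
        if (self.train_ids & self.validation_ids
                or self.train_ids & self.test_ids
                or self.validation_ids & self.test_ids):
            raise ValueError("split partitions overlap")

    @property
    def all_ids(self) -> frozenset:
        return self.train_ids | self.validation_ids | self.test_ids


def merge_species(tables: Sequence[FeatureTable], species: str
                  ) -> FeatureTable:
    """Concatenate per-experiment datasets into one species dataset.

    Provenance (`source`) is preserved; duplicate interaction ids across
    inputs are deduplicated keeping the first occurrence.
    """
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    for t in tables[1:]:
        first.require_same_schema(t)
    df = pd.concat([t.df for t in tables], ignore_index=True)
    before = len(df)
    df = df.drop_duplicates(subset="interaction_id", keep="first")
    dropped = before - len(df)
    if dropped:
        logger.info("merge_species(%s): dropped %d duplicate ids",
                    species, dropped)
    df = df.copy()
    df["species"] = species
    return FeatureTable(df.reset_index(drop=True), first.schema_version)


def _allocate_group(deficits: np.ndarray, g: int, fracs: np.ndarray
                    ) -> np.ndarray:
    """Round a group's fractional shares to integers.

    Each partition receives floor or ceil of its share ``g * frac`` (so
    per-group deviation stays below one row); the running global deficits
    decide which partitions round up, keeping totals on target as well.
    """
    shares = g * fracs
    base = np.floor(shares).astype(int)
    room = (np.ceil(shares) - base).astype(int)
    alloc = base.copy()
    priority = deficits - base  # deficit left if we only assign the floor
    for _ in range(g - base.sum()):
        k = int(np.argmax(np.where(room > 0, priority, -np.inf)))
        alloc[k] += 1
        room[k] -= 1
        priority[k] -= 1.0
    return alloc


def stratified_split(table: FeatureTable, spec: SplitSpec
                     ) -> List[DatasetSplit]:
    """miRNA-stratified repeated 72/8/20 splits.

    A cumulative largest-remainder allocator walks the miRNA groups in
    name order, so per-group allocations stay within one row of the ideal
    fractional share while global partition sizes also land within one
    row of the 72/8/20 targets.  Singleton miRNAs are forced to test.
    """
    if len(table) < 5:
        raise ValueError(
            f"table has {len(table)} rows; need >= 5 to honor the fractions"
        )
    fracs = np.array(spec.fractions)
    ids = table.ids
    groups = table.groups
    group_names = sorted(set(groups))
    by_group: Dict[str, np.ndarray] = {
        g: ids[groups == g] for g in group_names
    }

    splits: List[DatasetSplit] = []
    for r in range(spec.n_repeats):
        rng = np.random.default_rng([spec.rng_seed, r])
        parts: Dict[str, list] = {p: [] for p in PARTITIONS}
        target = np.zeros(3)
        assigned = np.zeros(3, dtype=int)
        for g in group_names:
            rows = by_group[g]
            n = len(rows)
            target += n * fracs
            if n == 1:  # unseen-miRNA rule
                parts["test"].extend(rows)
                assigned[2] += 1
                continue
            alloc = _allocate_group(target - assigned, n, fracs)
            perm = rng.permutation(rows)
            parts["train"].extend(perm[:alloc[0]])
            parts["validation"].extend(perm[alloc[0]:alloc[0] + alloc[1]])
            parts["test"].extend(perm[alloc[0] + alloc[1]:])
            assigned += alloc
        splits.append(DatasetSplit(
            train_ids=frozenset(parts["train"]),
            validation_ids=frozenset(parts["validation"]),
            test_ids=frozenset(parts["test"]),
            repeat_index=r,
        ))
    return splits


def sample_chunks(
    train_table: FeatureTable,
    rng: np.random.Generator,
    chunk_size: int = 100,
    max_total: int = 500,
) -> List[np.ndarray]:
    """Nested, label-balanced cumulative chunks from a training table.

    Returns id arrays of sizes ``chunk_size, 2*chunk_size, ...,
    max_total``; each is a prefix of the next, each balanced 50/50 when
    the table allows it.  Sampling is without replacement.
    """
    if len(train_table) < max_total:
        new_total = (len(train_table) // chunk_size) * chunk_size
        warnings.warn(
            f"training table has {len(train_table)} rows < {max_total}; "
            f"truncating chunk curve at {new_total}"
        )
        max_total = new_total
    half = chunk_size // 2
    n_chunks = max_total // chunk_size
    ids = train_table.ids
    y = train_table.y
    pos = rng.permutation(ids[y == 1])
    neg = rng.permutation(ids[y == 0])
    need = n_chunks * half
    if len(pos) < need or len(neg) < need:
        warnings.warn("cannot keep chunks exactly 1:1; topping up from the "
                      "majority class")
    seq: List = []
    pi = ni = 0
    pool = rng.permutation(
        np.concatenate([pos[need:], neg[need:]])
    ) if (len(pos) > need or len(neg) > need) else np.array([], dtype=ids.dtype)
    fi = 0
    for _ in range(n_chunks):
        take_p = min(half, len(pos) - pi)
        take_n = min(half, len(neg) - ni)
        seq.extend(pos[pi:pi + take_p])
        seq.extend(neg[ni:ni + take_n])
        pi += take_p
        ni += take_n
        short = chunk_size - take_p - take_n
        seq.extend(pool[fi:fi + short])
        fi += short
    return [np.array(seq[: (k + 1) * chunk_size])
            for k in range(n_chunks)]


# ---------------------------------------------------------------- manifests

def split_manifest(splits: Sequence[DatasetSplit]) -> dict:
    return {
        str(s.repeat_index): {
            "train": sorted(s.train_ids),
            "validation": sorted(s.validation_ids),
            "test": sorted(s.test_ids),
        }
        for s in splits
    }


def write_split_manifest(splits: Sequence[DatasetSplit], path) -> None:
    with open(path, "w") as fh:
        json.dump(split_manifest(splits), fh, indent=1)


def read_split_manifest(path) -> List[DatasetSplit]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        DatasetSplit(
            train_ids=frozenset(v["train"]),
            validation_ids=frozenset(v["validation"]),
            test_ids=frozenset(v["test"]),
            repeat_index=int(k),
        )
        for k, v in sorted(data.items(), key=lambda kv: int(kv[0]))
    ]
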