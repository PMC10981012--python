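"""Core containers: interaction records and tabular feature data.

The package moves data around in a "standard format" table: a handful of
metadata columns (interaction id, provenance, species, miRNA group, label)
followed by named numeric/Boolean feature columns.  :class:`FeatureTable`
is a thin wrapper over a :class:`pandas.DataFrame` that enforces that
layout and provides the views (feature matrix, labels, groups) the models
and split machinery need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: metadata columns, in canonical order, preceding the feature columns
META_COLUMNS = ("interaction_id", "source", "species", "mirna_id", "label")


@dataclass
class InteractionRecord:
    """One miRNA-target-site pair with its sequences and label.

    Coordinates follow the package convention: miRNA positions are 1-based
    from the 5' end; ``site_offset`` is the 0-based offset of the site
    within its 3'UTR (``None`` when no UTR context exists).
    """

    interaction_id: str
    mirna_id: str
    mirna_seq: str
    site_seq: str
    label: int
    species: str = "unknown"
    source: str = "sim"
    utr_id: Optional[str] = None
    utr_length: Optional[int] = None
    site_offset: Optional[int] = None
    seed_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if self.site_offset is not None and self.utr_length is not None:
            if self.site_offset + len(self.site_seq) > self.utr_length:
                raise ValueError(
                    f"record {self.interaction_id}: site exceeds UTR "
                    f"(offset {self.site_offset} + site {len(self.site_seq)} "
                    f"> UTR {self.utr_length})"
                )


class SchemaError(ValueError):
    """Raised when two tables that must share a feature schema do not."""


@dataclass
class FeatureTable:
    """Observations x features with metadata; the package's workhorse table."""

    df: pd.DataFrame
    schema_version: str = "v1"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
        # canonical column order: metadata first, features after
        feats = [c for c in self.df.columns if c not in META_COLUMNS]
        self.df = self.df[list(META_COLUMNS) + feats].reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def ids(self) -> np.ndarray:
        return self.df["interaction_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        """miRNA group id per row (the stratification unit for splits)."""
        return self.df["mirna_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    # -------------------------------------------------------------- utilities
    def subset(self, ids: Iterable[str]) -> "FeatureTable":
        wanted = set(ids)
        mask = self.df["interaction_id"].isin(wanted)
        return FeatureTable(self.df[mask].copy(), self.schema_version)

    def is_balanced(self) -> bool:
        counts = self.df["label"].value_counts()
        return len(counts) == 2 and counts.iloc[0] == counts.iloc[1]

    def same_schema(self, other: "FeatureTable") -> bool:
        return (
            self.schema_version == other.schema_version
            and self.feature_names == other.feature_names
        )

    def require_same_schema(self, other: "FeatureTable") -> None:
        if not self.same_schema(other):
            raise SchemaError(
                "feature schema mismatch: "
                f"{self.schema_version}/{len(self.feature_names)} cols vs "
                f"{other.schema_version}/{len(other.feature_names)} cols"
            )

    # ---------------------------------------------------------------- i/o
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, schema_version: str = "v1") -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t"), schema_version)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: Sequence[int],
        feature_names: Sequence[str],
        ids: Optional[Sequence[str]] = None,
        mirna_ids: Optional[Sequence[str]] = None,
        species: str = "unknown",
        source: str = "sim",
        schema_version: str = "v1",
    ) -> "FeatureTable":
        n = len(X)
        if ids is None:
            ids = [f"{species}-{i}" for i in range(n)]
        if mirna_ids is None:
            mirna_ids = [f"{species}-mir-{i}" for i in range(n)]
        df = pd.DataFrame(X, columns=list(feature_names))
        df.insert(0, "interaction_id", list(ids))
        df.insert(1, "source", source)
        df.insert(2, "species", species)
        df.insert(3, "mirna_id", list(mirna_ids))
        df.insert(4, "label", list(y))
        return cls(df, schema_version)
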