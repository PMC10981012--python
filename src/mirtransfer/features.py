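"""Interaction feature extraction.

Each (miRNA, site) pair is described by a fixed-order vector of ~45
numeric and Boolean features spanning four families: seed-match
indicators, duplex pairing composition by miRNA region (seed 1-8, central
9-12, 3'-compensatory 13-end), sequence composition of site and miRNA,
and site location within the 3'UTR.  The order and names are pinned by a
versioned JSON manifest shipped with the package; extraction is a pure
function of its inputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import duplexseed as dx
from .records import FeatureTable, InteractionRecord, META_COLUMNS

SCHEMA_VERSION = "v1"

_NTS = "ACGU"
_DINTS = ["".join(p) for p in itertools.product(_NTS, repeat=2)]

#: (name, type, description), in canonical vector order
FEATURE_DEFS: List[Tuple[str, str, str]] = (
    [
        ("seed_canonical_2_7", "bool", "exact WC consecutive pairing of miRNA 2-7"),
        ("seed_canonical_3_8", "bool", "exact WC consecutive pairing of miRNA 3-8"),
        ("seed_noncanonical_2_7", "bool",
         "window 2-7 pairs with GU allowed and at most one defect"),
        ("seed_noncanonical_3_8", "bool",
         "window 3-8 pairs with GU allowed and at most one defect"),
    ]
    + [
        (f"{kind}_count_r{lo}_{hi}", "int",
         f"{desc} in miRNA region {lo}-{hi}")
        for (lo, hi) in ((1, 8), (9, 12), (13, 0))
        for kind, desc in (
            ("wc", "Watson-Crick pairs"),
            ("gu", "GU wobble pairs"),
            ("unpaired", "unpaired miRNA positions"),
        )
    ]
    + [
        ("duplex_score", "int", "total duplex DP score"),
        ("paired_total", "int", "number of paired miRNA positions"),
    ]
    + [(f"site_freq_{n}", "float", f"site {n} mononucleotide frequency")
       for n in _NTS]
    + [(f"site_difreq_{d}", "float", f"site {d} dinucleotide frequency")
       for d in _DINTS]
    + [
        ("site_au_content", "float", "site A+U fraction"),
        ("site_gc_content", "float", "site G+C fraction"),
        ("site_length", "int", "site length in nt"),
        ("site_rel_position", "float",
         "site offset / (UTR length - site length); 0 without context"),
    ]
    + [(f"mirna_freq_{n}", "float", f"miRNA {n} mononucleotide frequency")
       for n in _NTS]
    + [
        ("mirna_gc_content", "float", "miRNA G+C fraction"),
        ("mirna_length", "int", "miRNA length in nt"),
    ]
)

FEATURE_NAMES: List[str] = [name for name, _, _ in FEATURE_DEFS]

# region bounds; hi == 0 means "to the miRNA 3' end"
_REGIONS = ((1, 8), (9, 12), (13, 0))


@dataclass(frozen=True)
class FeatureVector:
    values: Dict[str, float]
    schema_version: str = SCHEMA_VERSION

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def load_manifest() -> List[Dict[str, str]]:
    """The versioned feature-schema manifest shipped with the package."""
    text = resources.files("mirtransfer").joinpath(
        f"feature_schema_{SCHEMA_VERSION}.json"
    ).read_text()
    return json.loads(text)["features"]


def _composition(seq: str) -> Dict[str, float]:
    n = len(seq)
    out = {f"freq_{b}": seq.count(b) / n for b in _NTS}
    return out


def extract_features(
    mirna: str,
    site: str,
    utr_context: Optional[Tuple[int, int]] = None,
    duplex: Optional[dx.DuplexStructure] = None,
) -> FeatureVector:
    """Feature vector for one miRNA-site pair.

    ``utr_context`` is ``(utr_length, site_offset)``; when given, the
    site must fit inside the UTR.  A precomputed duplex may be supplied
    to avoid rescoring.
    """
    mirna = dx.clean_rna(mirna, "miRNA")
    site = dx.clean_rna(site, "site")
    if utr_context is not None:
        utr_len, offset = utr_context
        if offset + len(site) > utr_len:
            raise ValueError(
                f"site (offset {offset}, len {len(site)}) exceeds UTR "
                f"length {utr_len}"
            )
    if duplex is None:
        duplex = dx.predict_duplex(mirna, site)

    v: Dict[str, float] = {}
    w27 = dx.window_status(duplex, 2, 7)
    w38 = dx.window_status(duplex, 3, 8)
    v["seed_canonical_2_7"] = float(w27 == dx.CANONICAL)
    v["seed_canonical_3_8"] = float(w38 == dx.CANONICAL)
    v["seed_noncanonical_2_7"] = float(w27 == dx.NON_CANONICAL)
    v["seed_noncanonical_3_8"] = float(w38 == dx.NON_CANONICAL)

    n = len(mirna)
    by_pos = {i: t for (i, _), t in zip(duplex.pairs, duplex.pair_types)}
    for lo, hi in _REGIONS:
        hi_eff = n if hi == 0 else min(hi, n)
        span = range(lo, hi_eff + 1) if lo <= hi_eff else range(0)
        wc = sum(1 for i in span if by_pos.get(i) == "WC")
        gu = sum(1 for i in span if by_pos.get(i) == "GU")
        tag = f"r{lo}_{hi}"
        v[f"wc_count_{tag}"] = float(wc)
        v[f"gu_count_{tag}"] = float(gu)
        v[f"unpaired_count_{tag}"] = float(max(0, len(span) - wc - gu))

    v["duplex_score"] = float(duplex.score)
    v["paired_total"] = float(duplex.n_paired)

    for b, f in _composition(site).items():
        v[f"site_{b}"] = f
    nd = max(1, len(site) - 1)
    di_counts = {d: 0 for d in _DINTS}
    for k in range(len(site) - 1):
        di_counts[site[k:k + 2]] += 1
    for d in _DINTS:
        v[f"site_difreq_{d}"] = di_counts[d] / nd
    v["site_au_content"] = v["site_freq_A"] + v["site_freq_U"]
    v["site_gc_content"] = v["site_freq_G"] + v["site_freq_C"]
    v["site_length"] = float(len(site))
    if utr_context is not None and utr_context[0] > len(site):
        v["site_rel_position"] = utr_context[1] / (utr_context[0] - len(site))
    else:
        v["site_rel_position"] = 0.0

    for b, f in _composition(mirna).items():
        v[f"mirna_{b}"] = f
    v["mirna_gc_content"] = v["mirna_freq_G"] + v["mirna_freq_C"]
    v["mirna_length"] = float(n)

    assert list(v) == FEATURE_NAMES, "feature order drifted from schema"
    return FeatureVector(values=v)


def extract_table(records: Sequence[InteractionRecord]) -> FeatureTable:
    """Row-aligned feature table for a list of interaction records."""
    rows = []
    for rec in records:
        ctx = None
        if rec.utr_length is not None and rec.site_offset is not None:
            ctx = (rec.utr_length, rec.site_offset)
        fv = extract_features(rec.mirna_seq, rec.site_seq, ctx)
        row = {
            "interaction_id": rec.interaction_id,
            "source": rec.source,
            "species": rec.species,
            "mirna_id": rec.mirna_id,
            "label": rec.label,
        }
        row.update(fv.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + FEATURE_NAMES)
    return FeatureTable(df, SCHEMA_VERSION)
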