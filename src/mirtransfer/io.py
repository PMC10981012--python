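"""FASTA / TSV / JSON I/O for catalogs, tables and experiment configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import FeatureTable, InteractionRecord
from .simdata import GroundTruthRule, SpeciesSpec


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    """Name -> sequence; miRBase-style headers keep only the first token."""
    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_interactions_tsv(records: Sequence[InteractionRecord], path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False)


def read_interactions_tsv(path) -> List[InteractionRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    fields = {f.name for f in dataclasses.fields(InteractionRecord)}
    out = []
    for _, row in df.iterrows():
        kw = {k: (None if pd.isna(v) else v)
              for k, v in row.items() if k in fields}
        for intish in ("utr_length", "site_offset", "label"):
            if kw.get(intish) is not None:
                kw[intish] = int(kw[intish])
        out.append(InteractionRecord(**kw))
    return out


def write_species_sidecar(spec: SpeciesSpec, rule: GroundTruthRule | None,
                          path) -> None:
    """JSON sidecar recording the generator settings (incl. the planted S)."""
    payload = {"species_spec": dataclasses.asdict(spec)}
    if rule is not None:
        payload["ground_truth_rule"] = {
            "base_weights": rule.base_weights,
            "species_deltas": rule.species_deltas,
            "mean_shifts": rule.mean_shifts,
            "intercept": rule.intercept,
            "shifted_features": sorted(rule.shifted_features()),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_species_specs(path) -> List[SpeciesSpec]:
    data = json.loads(Path(path).read_text())
    specs = data["species"] if isinstance(data, dict) else data
    return [SpeciesSpec(**{**s, "utr_length_range":
                           tuple(s.get("utr_length_range", (80, 300)))})
            for s in specs]
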