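"""Readers and writers for SV count tables, metadata, sequences and config.

Count tables travel as tab-separated text (samples as rows by default; a
flag accepts the common SVs-as-rows orientation and transposes on read) or
as BIOM 1.0 JSON, where rows are observations (SVs) and columns are samples
per the format convention. Sequences use FASTA via Biopython; configuration
is YAML.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CountTable,
    MCReference,
    SVSequenceSet,
    ValidationError,
    validate_metadata,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
    "read_mc_references",
    "load_config",
]

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org"


def _read_tsv_counts(path: Path, orientation: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if orientation == "svs":
        df = df.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'samples' or 'svs'")
    return df


def read_count_table(path, format: str = "tsv", orientation: str = "samples") -> CountTable:
    """Read a count table from TSV or BIOM 1.0 JSON.

    Parameters
    ----------
    format : {"tsv", "biom"}
    orientation : {"samples", "svs"}
        TSV only: whether rows of the file are samples or SVs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_tsv_counts(path, orientation)
    elif format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != _BIOM_FORMAT:
            raise ValidationError(f"unsupported BIOM format: {doc.get('format')!r}")
        sv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if doc["matrix_type"] == "sparse":
            for r, c, v in doc["data"]:
                mat[r, c] = v
        elif doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"])
        else:
            raise ValidationError(f"unknown matrix_type {doc['matrix_type']!r}")
        # BIOM rows are observations (SVs); transpose to samples-as-rows
        df = pd.DataFrame(mat.T, index=sample_ids, columns=sv_ids)
    else:
        raise ValueError("format must be 'tsv' or 'biom'")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0) or not np.all(arr % 1 == 0):
        raise ValidationError(f"{path}: counts must be non-negative integers")
    return CountTable(df)


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    """Write a count table as TSV (samples as rows) or BIOM 1.0 JSON."""
    path = Path(path)
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        mat = table.counts.T  # BIOM: rows = observations
        data = [
            [int(r), int(c), int(mat[r, c])]
            for r, c in zip(*np.nonzero(mat))
        ]
        doc = {
            "id": None,
            "format": _BIOM_FORMAT,
            "format_url": _BIOM_URL,
            "type": "OTU table",
            "generated_by": "spikeline",
            "date": datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S"),
            "rows": [{"id": sv, "metadata": None} for sv in table.sv_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(table.sv_ids), len(table.sample_ids)],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError("format must be 'tsv' or 'biom'")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample metadata TSV."""
    meta = pd.read_csv(Path(path), sep="\t", comment="#")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(Path(path), sep="\t", index=False)


def read_fasta(path) -> SVSequenceSet:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return SVSequenceSet(records)


def write_fasta(sequences: SVSequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sv_id, description="")
        for sv_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mc_references(path, spec: Iterable[dict]) -> list[MCReference]:
    """Build MC references from a FASTA file plus per-taxon dose metadata.

    ``spec`` entries need keys ``name`` (FASTA record id), ``gram``,
    ``copies_per_dose`` and ``cells_per_dose``.
    """
    seqs = read_fasta(path)
    refs = []
    for entry in spec:
        name = entry["name"]
        if name not in seqs:
            raise ValidationError(f"reference {name!r} not in {path}")
        refs.append(
            MCReference(
                name=name,
                gram=entry["gram"],
                sequence=seqs[name],
                copies_per_dose=float(entry["copies_per_dose"]),
                cells_per_dose=float(entry["cells_per_dose"]),
            )
        )
    return refs


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg
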