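"""Plain-text readers and writers (TSV tables, FASTA, YAML configs).

All tabular I/O is tab-separated with a header row; sequences are FASTA
(via Biopython); coordinates in sequence outputs are 0-based, half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition", "replicate", "pool", "signal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: signal table needs columns {sorted(required)}")
    return df


def read_fractions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"pool", "condition", "fraction"} <= set(df.columns):
        raise ValueError(f"{path}: fractions table needs pool/condition/fraction columns")
    return df


def read_counts(path) -> pd.DataFrame:
    """Count matrix: gene_id column plus one integer column per timepoint (minutes)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: counts table needs a gene_id column")
    df = df.set_index("gene_id")
    df.columns = [int(c) for c in df.columns]
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_counts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    write_table(out, path, index=True)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_sets(path) -> dict:
    """Gene sets as a two-column TSV (set_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"set_name", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: gene set table needs set_name/gene_id columns")
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("set_name")}


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
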