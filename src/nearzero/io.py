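"""Readers and writers for the pipeline's plain-text formats.

Expression matrix: TSV, first column gene id, remaining columns sample
ids.  Metadata: TSV with sample_id, growth_rate, mode, replicate,
time_d.  Biomass series: TSV with time_h, cx_total_g_per_l,
viability_fraction.  Gene sets: GMT.  Promoters: FASTA with gene ids as
headers.  Kinetic parameters: YAML.
"""

from __future__ import annotations

from dataclasses import asdict

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import BiomassTimeSeries, RetentostatParams

__all__ = [
    "read_matrix", "write_matrix",
    "read_metadata", "write_metadata",
    "read_series", "write_series",
    "read_params", "write_params",
    "read_fasta", "write_fasta",
    "read_gene_list", "write_gene_list",
]


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_series(path) -> BiomassTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return BiomassTimeSeries(
        t=df["time_h"].to_numpy(),
        Cx_total=df["cx_total_g_per_l"].to_numpy(),
        viability=df["viability_fraction"].to_numpy(),
    )


def write_series(series: BiomassTimeSeries, path) -> None:
    pd.DataFrame(
        {
            "time_h": series.t,
            "cx_total_g_per_l": series.Cx_total,
            "viability_fraction": series.viability,
        }
    ).to_csv(path, sep="\t", index=False)


def read_params(path) -> RetentostatParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RetentostatParams(**data)


def write_params(params: RetentostatParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=str(g), description="") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
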