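"""File I/O: genomes, strain metadata, GFF3 feature tables."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


@dataclass
class StrainRecord:
    """One genome: contigs plus strain-level metadata."""

    strain_id: str
    contigs: dict[str, str]
    species: str | None = None
    host: str | None = None
    region: str | None = None

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def read_genome_fasta(path: str | Path, strain_id: str | None = None) -> StrainRecord:
    path = Path(path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return StrainRecord(strain_id=strain_id or path.stem, contigs=contigs)


def read_genomes(paths: Iterable[str | Path]) -> list[StrainRecord]:
    return [read_genome_fasta(p) for p in paths]


def write_genome_fasta(strain: StrainRecord, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=cid, description=strain.strain_id)
            for cid, seq in sorted(strain.contigs.items())]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Strain metadata table: strain_id, species, host, region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise ValueError("metadata must have a strain_id column")
    return df


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write features (columns seqid, source, type, start0, end, strand,
    attributes-dict or str) as GFF3 with 1-based inclusive coordinates."""
    rows = []
    for _, f in features.iterrows():
        attrs = f["attributes"]
        if isinstance(attrs, Mapping):
            attrs = ";".join(f"{k}={v}" for k, v in attrs.items())
        rows.append({
            "seqid": f["seqid"],
            "source": f.get("source", "rhskit"),
            "type": f.get("type", "gene"),
            "start": int(f["start0"]) + 1,  # 0-based half-open -> 1-based incl.
            "end": int(f["end"]),
            "score": ".",
            "strand": f["strand"],
            "phase": ".",
            "attributes": attrs,
        })
    out = pd.DataFrame(rows, columns=GFF3_COLUMNS)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file back to a features table with 0-based half-open
    ``start0``/``end`` columns mirroring :func:`write_gff3` input."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS)
    df["start0"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df
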