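"""File-format plumbing: FASTA via Biopython, tables via pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .residues import AlignmentMatrix


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) as an id → sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_alignment_fasta(path, focal_species: str, reference_species: str) -> AlignmentMatrix:
    """Aligned FASTA (record ids = species ids) into an AlignmentMatrix."""
    rows = read_fasta(path)
    return AlignmentMatrix(sorted(rows), rows, focal_species, reference_species)


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes-as-rows counts table with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_labels_tsv(path) -> pd.DataFrame:
    """Sample annotation: sample_id, species_id, group (focal/other)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"labels file needs columns {sorted(required)}")
    return df.set_index("sample_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
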