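"""Readers and writers for the pipeline's plain-text formats.

Everything is UTF-8 TSV with a header row (bit-exact diffable), FASTA via
Biopython.  The presence matrix is written with a leading ``sample`` column
and 0/1 cells; distance matrices as square tables of fractions with a leading
``seq_id`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cooccurrence import AnchorSet, validate_presence_matrix
from .distances import DistanceMatrix

__all__ = [
    "read_presence_matrix", "write_presence_matrix",
    "read_anchor_table", "write_anchor_table",
    "read_orf_lengths", "write_orf_lengths",
    "read_abundance_table", "write_abundance_table",
    "read_distance_matrix", "write_distance_matrix",
    "read_groups", "write_groups",
    "write_fasta", "read_fasta",
]


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample', got {df.columns[0]!r}")
    df = df.set_index("sample")
    return validate_presence_matrix(df)


def write_presence_matrix(matrix: pd.DataFrame, path) -> None:
    out = validate_presence_matrix(matrix).astype(int)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_anchor_table(path) -> dict[str, AnchorSet]:
    """Anchors TSV (virus_id, transcript_id) -> one AnchorSet per virus."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("virus_id", "transcript_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        virus: AnchorSet(virus, frozenset(sub["transcript_id"]))
        for virus, sub in df.groupby("virus_id", sort=True)
    }


def write_anchor_table(anchors: dict[str, AnchorSet], path) -> None:
    rows = [(a.virus_id, t) for a in anchors.values()
            for t in sorted(a.anchor_transcripts)]
    pd.DataFrame(rows, columns=["virus_id", "transcript_id"]).to_csv(
        path, sep="\t", index=False)


def read_orf_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in ("transcript_id", "max_orf_len"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["transcript_id"], df["max_orf_len"].astype(int)))


def write_orf_lengths(lengths: dict[str, int], path) -> None:
    pd.DataFrame(sorted(lengths.items()),
                 columns=["transcript_id", "max_orf_len"]).to_csv(
        path, sep="\t", index=False)


def read_abundance_table(path) -> pd.DataFrame:
    from .abundance import validate_abundance_table
    return validate_abundance_table(pd.read_csv(path, sep="\t", dtype={"sample": str}))


def write_abundance_table(table: pd.DataFrame, path) -> None:
    from .abundance import validate_abundance_table
    validate_abundance_table(table).to_csv(path, sep="\t", index=False)


def read_distance_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("seq_id")
    df.columns.name = None
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: distance matrix rows and columns disagree")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T):
        raise ValueError(f"{path}: distance matrix is not symmetric")
    return df


def write_distance_matrix(D: DistanceMatrix | pd.DataFrame, path,
                          lower_triangle: bool = False) -> None:
    frame = D.to_frame() if isinstance(D, DistanceMatrix) else D.copy()
    frame.index.name = "seq_id"
    if lower_triangle:
        frame = frame.where(np.tril(np.ones(frame.shape, dtype=bool)))
    frame.to_csv(path, sep="\t")


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("seq_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["seq_id"], df["group"]))


def write_groups(groups: dict[str, str], path) -> None:
    pd.DataFrame(groups.items(), columns=["seq_id", "group"]).to_csv(
        path, sep="\t", index=False)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    SeqIO.write([SeqRecord(Seq(s), id=i, description="") for i, s in records],
                str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
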