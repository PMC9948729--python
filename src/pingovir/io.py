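"""Sequence, table and metadata I/O.

Sequences travel as :class:`ContigRecord` (plain id + uppercase DNA),
matrices as labelled :class:`pandas.DataFrame` TSVs with the row labels
in the first column, and sample metadata as a TSV with one row per
sequencing library.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigRecord",
    "SampleMetadata",
    "read_sequences",
    "write_sequences",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "get_logger",
]

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide sequence with its id; alphabet {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SampleMetadata:
    """Per-library metadata linking paired starter and cheese samples.

    ``pair_id`` ties one producer's starter library to the cheese made
    from that same starter.
    """

    table: pd.DataFrame  # columns: sample_id, producer_id, stage, pair_id

    def __post_init__(self) -> None:
        required = ["sample_id", "producer_id", "stage", "pair_id"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample_id in metadata: {dupes}")
        bad = set(self.table["stage"]) - {"starter", "cheese"}
        if bad:
            raise ValueError(f"unknown stage values: {sorted(bad)}")

    def samples(self, stage: str | None = None) -> list[str]:
        t = self.table
        if stage is not None:
            t = t[t["stage"] == stage]
        return list(t["sample_id"])

    def producer_pairs(self) -> pd.DataFrame:
        """One row per producer with its starter and cheese sample ids.

        Raises if any cheese sample's pair_id does not resolve to exactly
        one starter sample.
        """
        starters = self.table[self.table["stage"] == "starter"]
        cheeses = self.table[self.table["stage"] == "cheese"]
        rows = []
        for _, c in cheeses.iterrows():
            match = starters[starters["pair_id"] == c["pair_id"]]
            if len(match) != 1:
                raise ValueError(
                    f"cheese sample {c['sample_id']} pair_id {c['pair_id']!r} "
                    f"matches {len(match)} starter samples (expected 1)"
                )
            s = match.iloc[0]
            rows.append(
                {
                    "producer_id": c["producer_id"],
                    "starter": s["sample_id"],
                    "cheese": c["sample_id"],
                }
            )
        return pd.DataFrame(rows, columns=["producer_id", "starter", "cheese"])


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(
            f"record {rec_id}: unsupported characters {sorted(bad)} "
            "(alphabet is A/C/G/T/N; U is converted to T)"
        )
    return seq


def read_sequences(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into records, preserving order.

    Sequences are uppercased, U is converted to T, and any ambiguity
    code other than N is rejected.  Duplicate headers and empty
    sequences are errors.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence for record {rec.id}")
        records.append(ContigRecord(rec.id, _clean_seq(str(rec.seq), rec.id)))
    return records


def write_sequences(records: Iterable[ContigRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path, *, allow_na: bool = False) -> None:
    """Write a labelled numeric matrix as TSV, row labels in column one.

    Values round-trip through :func:`read_matrix` to 12 significant
    digits.  Non-finite entries are errors unless ``allow_na`` is set.
    """
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("matrix row and column labels must be unique")
    values = matrix.to_numpy(dtype=float)
    if not allow_na and not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries (pass allow_na=True to permit)")
    matrix.to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def get_logger(name: str = "pingovir", level: str = "info") -> logging.Logger:
    """Stage logger writing to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))
    return logger
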