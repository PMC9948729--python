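"""Viral contig triage.

A curated assembly is reduced to a viral catalog in three steps:
length/redundancy filtering, computation of intrinsic evidence (ORFs
and terminal repeats), and the four-criterion inclusion rule — a contig
enters the catalog if at least one of these holds:

* an external viral-sequence detector flagged it;
* it aligns to a viral reference at E < 1e-10 over >90% of its length
  with >50% identity;
* at least three of its ORFs hit viral orthologous groups (E <= 1e-5);
* it is circular (exact terminal direct repeat of >= 20 nt).

An rRNA signal is recorded as metadata but never used for exclusion.
Temperate (lysogeny-capable) phages are flagged by integrase or
site-specific recombinase annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .io import ContigRecord
from .votu import dedupe_contigs  # noqa: F401  (triage surface includes dedupe)

__all__ = [
    "EvidenceRecord",
    "TriageDecision",
    "find_orfs",
    "detect_terminal_repeat",
    "classify_viral",
    "flag_temperate",
    "triage_catalog",
    "read_evidence",
    "write_evidence",
    "write_triage_table",
    "dedupe_contigs",
]

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class EvidenceRecord:
    """Externally computed per-contig evidence consumed by triage."""

    contig_id: str
    pvog_orf_hits: int = 0
    ref_evalue: float | None = None
    ref_qcov: float | None = None     # fraction of the contig aligned
    ref_identity: float | None = None  # percent identity of the best hit
    detector_flag: bool = False
    rrna_flag: bool = False
    annotations: list[str] = field(default_factory=list)

    @property
    def has_ref_hit(self) -> bool:
        return self.ref_evalue is not None


@dataclass
class TriageDecision:
    contig_id: str
    included: bool
    criteria: list[str]  # subset of {orf_hits, ref_alignment, detector, circular}
    circular: bool
    tr_len: int
    temperate: bool


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_orfs(seq: str, min_len_nt: int = 150) -> list[tuple[int, int, str, int]]:
    """Six-frame maximal ORF scan.

    Returns (start, end, strand, frame) tuples with 0-based half-open
    coordinates on the forward strand; an ORF runs from a start codon
    (ATG/GTG/TTG) to the first in-frame stop, stop included, and only
    the longest ORF per stop (the earliest start) is reported.
    """
    if min_len_nt < 6:
        raise ValueError("min_len_nt must be >= 6 (one start and one stop codon)")
    n = len(seq)
    orfs: list[tuple[int, int, str, int]] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None and pos + 3 - start >= min_len_nt:
                        lo, hi = start, pos + 3
                        if strand == "-":
                            lo, hi = n - hi, n - lo
                        orfs.append((lo, hi, strand, frame))
                    start = None
                elif start is None and codon in START_CODONS:
                    start = pos
    orfs.sort()
    return orfs


def detect_terminal_repeat(seq: str, tr_min_len: int = 20) -> tuple[bool, int]:
    """Exact terminal direct repeat detection.

    Circular iff a prefix of length >= tr_min_len equals a suffix of the
    same length; returns the longest such length (capped at half the
    sequence) or 0.  Linear time via the KMP border chain.
    """
    n = len(seq)
    if n < 2 * tr_min_len:
        raise ValueError(f"sequence shorter than 2*tr_min_len ({n} < {2 * tr_min_len})")
    # failure function: fail[i] = longest proper border of seq[:i+1]
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    border = fail[n - 1]
    while border > n // 2:
        border = fail[border - 1]
    if border >= tr_min_len:
        return True, border
    return False, 0


def flag_temperate(annotations: list[str]) -> bool:
    """True iff any annotation names an integrase or a site-specific
    recombinase (case-insensitive substring match)."""
    for token in annotations:
        low = token.lower()
        if "integrase" in low or "site-specific recombinase" in low:
            return True
    return False


def classify_viral(
    contig: ContigRecord, evidence: EvidenceRecord, config: PipelineConfig
) -> TriageDecision:
    """Apply the four-criterion inclusion rule to one contig."""
    if evidence.contig_id != contig.id:
        raise ValueError(f"evidence row {evidence.contig_id} does not match contig {contig.id}")
    criteria: list[str] = []
    if evidence.detector_flag:
        criteria.append("detector")
    if (
        evidence.has_ref_hit
        and evidence.ref_evalue < config.ref_evalue_max
        and evidence.ref_qcov > config.ref_qcov_min
        and evidence.ref_identity > 100.0 * config.ref_identity_min
    ):
        criteria.append("ref_alignment")
    if evidence.pvog_orf_hits >= config.pvog_min_orfs:
        criteria.append("orf_hits")
    circular, tr_len = (
        detect_terminal_repeat(contig.seq, config.tr_min_len)
        if contig.length >= 2 * config.tr_min_len
        else (False, 0)
    )
    if circular:
        criteria.append("circular")
    return TriageDecision(
        contig_id=contig.id,
        included=bool(criteria),
        criteria=criteria,
        circular=circular,
        tr_len=tr_len,
        temperate=flag_temperate(evidence.annotations),
    )


def triage_catalog(
    contigs: list[ContigRecord],
    evidence: dict[str, EvidenceRecord],
    config: PipelineConfig,
) -> list[TriageDecision]:
    """Triage every contig; a missing evidence row is an error."""
    decisions = []
    for contig in contigs:
        if contig.id not in evidence:
            raise ValueError(f"no evidence row for contig {contig.id}")
        decisions.append(classify_viral(contig, evidence[contig.id], config))
    return decisions


# ---------------------------------------------------------------------------
# tables

def write_evidence(records: list[EvidenceRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "contig_id": r.contig_id,
                "pvog_orf_hits": r.pvog_orf_hits,
                "ref_evalue": "" if r.ref_evalue is None else repr(r.ref_evalue),
                "ref_qcov": "" if r.ref_qcov is None else r.ref_qcov,
                "ref_identity": "" if r.ref_identity is None else r.ref_identity,
                "detector_flag": int(r.detector_flag),
                "rrna_flag": int(r.rrna_flag),
                "annotations": ";".join(r.annotations),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> dict[str, EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, EvidenceRecord] = {}
    for _, row in df.iterrows():
        rec = EvidenceRecord(
            contig_id=str(row["contig_id"]),
            pvog_orf_hits=int(row["pvog_orf_hits"]),
            ref_evalue=None if row["ref_evalue"] == "" else float(row["ref_evalue"]),
            ref_qcov=None if row["ref_qcov"] == "" else float(row["ref_qcov"]),
            ref_identity=None if row["ref_identity"] == "" else float(row["ref_identity"]),
            detector_flag=bool(int(row["detector_flag"])),
            rrna_flag=bool(int(row["rrna_flag"])),
            annotations=[a for a in str(row["annotations"]).split(";") if a],
        )
        if rec.contig_id in out:
            raise ValueError(f"duplicate evidence row for {rec.contig_id}")
        out[rec.contig_id] = rec
    return out


def write_triage_table(decisions: list[TriageDecision], path: str | Path) -> None:
    pd.DataFrame(
        {
            "contig_id": [d.contig_id for d in decisions],
            "included": [int(d.included) for d in decisions],
            "criteria": [",".join(d.criteria) for d in decisions],
            "circular": [int(d.circular) for d in decisions],
            "tr_len": [d.tr_len for d in decisions],
            "temperate": [int(d.temperate) for d in decisions],
        }
    ).to_csv(path, sep="\t", index=False)
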