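"""Abundance quantification: breadth masking and normalization.

Read counts recruited to a contig are only trusted when the mapping
covers most of the contig: a count is zeroed when fewer than 75% of the
contig's positions reach 1x depth (``breadth_min`` / ``depth_min``).
This guards against spurious recruitment of conserved fragments, which
inflates presence calls far more than it inflates depth.

Masked counts are then normalized by DESeq2-style median-of-ratios
size factors, so that samples of different sequencing depth are
comparable without rarefaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "coverage_breadth",
    "breadth_table",
    "apply_breadth_mask",
    "median_of_ratios_normalize",
    "read_depth_profiles",
    "write_depth_profiles",
]


@dataclass
class DepthProfile:
    """Per-base depth for one (contig, sample), run-length encoded as
    non-overlapping 0-based half-open intervals."""

    contig_id: str
    sample_id: str
    contig_length: int
    intervals: list[tuple[int, int, float]]  # (start, end, depth)

    def validate(self) -> "DepthProfile":
        prev_end = 0
        for start, end, depth in sorted(self.intervals):
            if start < 0 or end > self.contig_length or start >= end:
                raise ValueError(
                    f"{self.contig_id}/{self.sample_id}: interval [{start},{end}) "
                    f"out of bounds for length {self.contig_length}"
                )
            if depth < 0:
                raise ValueError(f"{self.contig_id}/{self.sample_id}: negative depth")
            if start < prev_end:
                raise ValueError(
                    f"{self.contig_id}/{self.sample_id}: overlapping intervals at {start}"
                )
            prev_end = end
        return self


def coverage_breadth(profile: DepthProfile, depth_min: float = 1.0) -> float:
    """Fraction of contig positions with depth >= depth_min, exactly."""
    profile.validate()
    covered = sum(end - start for start, end, depth in profile.intervals if depth >= depth_min)
    return covered / profile.contig_length


def breadth_table(
    profiles: list[DepthProfile], depth_min: float = 1.0
) -> pd.DataFrame:
    """Long-format breadth per (contig, sample)."""
    rows = [
        {
            "contig_id": p.contig_id,
            "sample_id": p.sample_id,
            "breadth": coverage_breadth(p, depth_min),
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["contig_id", "sample_id", "breadth"])


def apply_breadth_mask(
    counts: pd.DataFrame,
    breadths: pd.DataFrame,
    breadth_min: float = 0.75,
    inverted_rule: bool = False,
) -> pd.DataFrame:
    """Zero counts whose mapping breadth falls below ``breadth_min``.

    ``breadths`` is the long-format table from :func:`breadth_table`.
    Every nonzero count must have a breadth entry.  With
    ``inverted_rule`` the alternative reading of the filter is applied:
    a count is zeroed only when breadth < 1 - breadth_min (i.e. less
    than 25% covered by default).
    """
    threshold = (1.0 - breadth_min) if inverted_rule else breadth_min
    lookup = {
        (r.contig_id, r.sample_id): r.breadth for r in breadths.itertuples(index=False)
    }
    masked = counts.copy().astype(float)
    for contig in counts.index:
        for sample in counts.columns:
            count = counts.at[contig, sample]
            if count == 0:
                continue
            key = (contig, sample)
            if key not in lookup:
                raise ValueError(f"no breadth for nonzero count at {key}")
            if lookup[key] < threshold:
                masked.at[contig, sample] = 0.0
    return masked


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization.

    For features with counts positive in every sample, compute the
    per-feature geometric mean g_i across samples; the size factor of
    sample j is the median over those features of c_ij / g_i, and the
    normalized value is c_ij / s_j.  When no feature is positive
    everywhere, geometric means fall back to positive entries only (and
    a warning is raised).  Returns (normalized matrix, size factors).
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    col_zero = (values.sum(axis=0) == 0)
    if col_zero.any():
        bad = list(counts.columns[col_zero])
        raise ValueError(f"samples with all-zero counts: {bad}")
    all_pos = (values > 0).all(axis=1)
    if all_pos.any():
        sub = values[all_pos]
        log_gmean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_gmean[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no feature is positive in every sample; using positive-entry "
            "geometric means for size factors",
            stacklevel=2,
        )
        logs = np.full(values.shape, np.nan)
        np.log(values, out=logs, where=values > 0)
        log_gmean = np.nanmean(logs, axis=1)
        ratios = logs - log_gmean[:, None]
        size_factors = np.exp(np.nanmedian(ratios, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    normalized = counts.astype(float).div(sf, axis=1)
    return normalized, sf


# ---------------------------------------------------------------------------
# depth profile TSV (contig, sample, start, end, depth)

def write_depth_profiles(profiles: list[DepthProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        if not p.intervals:
            continue
        for start, end, depth in p.intervals:
            rows.append((p.contig_id, p.sample_id, p.contig_length, start, end, depth))
    pd.DataFrame(
        rows, columns=["contig_id", "sample_id", "contig_length", "start", "end", "depth"]
    ).to_csv(path, sep="\t", index=False)


def read_depth_profiles(path: str | Path) -> list[DepthProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (contig, sample), group in df.groupby(["contig_id", "sample_id"], sort=False):
        lengths = group["contig_length"].unique()
        if len(lengths) != 1:
            raise ValueError(f"inconsistent contig_length for {contig}/{sample}")
        profiles.append(
            DepthProfile(
                contig_id=str(contig),
                sample_id=str(sample),
                contig_length=int(lengths[0]),
                intervals=[
                    (int(r.start), int(r.end), float(r.depth))
                    for r in group.itertuples(index=False)
                ],
            ).validate()
        )
    return profiles
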