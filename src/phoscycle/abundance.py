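"""Normalize gene counts and express them relative to community size.

Raw per-gene hit counts are corrected for gene copy number and reference
length:

    normalized = raw_count * cn_factor(gene) * len_factor(gene)

Community size per sample is proxied by the mean of five conserved
single-copy genes (recA, atpD, tufA, gyrB, hsp70), each length-normalized
to the shortest of them (recA) so longer housekeeping genes do not inflate
the estimate:

    community_size = mean_m [ raw_count(m) * length(recA) / length(m) ]

Relative abundance of a gene is then 100 * normalized / community_size,
interpretable as the percentage of community members encoding the gene.
A per-100k-reads rate is also available for metatranscriptome-style
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .genes import MARKER_GENES
from .reference_db import NormalizationFactors

logger = logging.getLogger(__name__)

#: Default mean reference lengths (aa) for the five single-copy markers.
DEFAULT_MARKER_LENGTHS_AA: dict[str, float] = {
    "recA": 350.0,
    "atpD": 460.0,
    "tufA": 395.0,
    "gyrB": 640.0,
    "hsp70": 640.0,
}


@dataclass(frozen=True)
class MarkerSet:
    """The five single-copy community-size markers and their reference lengths.

    The base marker (recA, the shortest) defines the length normalization:
    factor(m) = length(recA) / length(m) <= 1.
    """

    lengths_aa: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS_AA)
    )
    base_marker: str = "recA"

    def __post_init__(self) -> None:
        missing = set(MARKER_GENES) - set(self.lengths_aa)
        if missing:
            raise ValueError(f"marker lengths missing for: {sorted(missing)}")
        if any(l <= 0 for l in self.lengths_aa.values()):
            raise ValueError("marker lengths must be positive")
        base_len = self.lengths_aa[self.base_marker]
        if base_len > min(self.lengths_aa[m] for m in MARKER_GENES):
            raise ValueError(
                f"base marker {self.base_marker} must be the shortest marker"
            )

    @property
    def markers(self) -> tuple[str, ...]:
        return MARKER_GENES

    def length_factor(self, marker: str) -> float:
        return self.lengths_aa[self.base_marker] / self.lengths_aa[marker]

    @classmethod
    def from_tsv(cls, path: str | Path, base_marker: str = "recA") -> "MarkerSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            lengths_aa=dict(zip(df["marker"], df["length_aa"].astype(float))),
            base_marker=base_marker,
        )


def normalized_gene_count(
    raw_count: float, gene: str, factors: NormalizationFactors
) -> float:
    """raw_count x copy-number factor x length factor."""
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count * factors.cn_factor(gene) * factors.len_factor(gene)


def marker_community_size(
    marker_counts: Mapping[str, float],
    markers: MarkerSet | None = None,
    *,
    on_missing: str = "error",
) -> float:
    """Mean length-normalized count of the five single-copy markers.

    ``on_missing`` governs absent markers: "error" raises; "mean" averages
    over the available markers with a warning.
    """
    markers = markers or MarkerSet()
    present = [m for m in markers.markers if m in marker_counts]
    absent = [m for m in markers.markers if m not in marker_counts]
    if absent:
        if on_missing == "error":
            raise ValueError(f"missing marker counts for: {absent}")
        if on_missing != "mean":
            raise ValueError("on_missing must be 'error' or 'mean'")
        logger.warning("community size averaged over %d/%d markers (missing %s)",
                       len(present), len(markers.markers), absent)
    if not present:
        raise ValueError("no marker counts available")
    normalized = [marker_counts[m] * markers.length_factor(m) for m in present]
    return sum(normalized) / len(normalized)


def rate_per_100k(raw_count: float, total_reads: int) -> float:
    """Hits per 100,000 reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return raw_count * 100_000 / total_reads


def relative_abundance_table(
    counts: pd.DataFrame,
    factors: NormalizationFactors,
    markers: MarkerSet | None = None,
    metadata: pd.DataFrame | None = None,
    *,
    on_missing_marker: str = "error",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample per-gene normalized counts and relative abundances.

    ``counts`` is a long table (sample_id, gene, raw_count[, total_reads])
    containing both phosphonate genes and the five markers.  Returns the
    abundance table (phosphonate genes only) and the list of samples
    excluded for having zero community size.  Relative abundances above
    100 % are permitted but logged.
    """
    markers = markers or MarkerSet()
    required = {"sample_id", "gene", "raw_count"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")

    rows = []
    excluded: list[str] = []
    for sample_id, grp in counts.groupby("sample_id", sort=True):
        per_gene = dict(zip(grp["gene"], grp["raw_count"].astype(float)))
        marker_counts = {m: per_gene[m] for m in markers.markers if m in per_gene}
        community = marker_community_size(
            marker_counts, markers, on_missing=on_missing_marker
        )
        if community <= 0:
            excluded.append(str(sample_id))
            continue
        total_reads = (
            int(grp["total_reads"].iloc[0]) if "total_reads" in grp.columns else None
        )
        for gene, raw in per_gene.items():
            if gene in markers.markers:
                continue
            norm = normalized_gene_count(raw, gene, factors)
            rel = 100.0 * norm / community
            if rel > 100.0:
                logger.warning(
                    "sample %s gene %s: relative abundance %.1f%% exceeds 100%%",
                    sample_id, gene, rel,
                )
            row = {
                "sample_id": sample_id,
                "gene": gene,
                "raw_count": raw,
                "normalized_count": norm,
                "community_size": community,
                "relative_abundance_pct": rel,
            }
            if total_reads:
                row["rate_per_100k"] = rate_per_100k(raw, total_reads)
            rows.append(row)
    if excluded:
        logger.warning("excluded %d samples with zero community size: %s",
                       len(excluded), excluded)
    table = pd.DataFrame(rows)
    if metadata is not None and not table.empty:
        table = table.merge(metadata, on="sample_id", how="left")
    return table, excluded


SAMPLE_METADATA_COLUMNS = (
    "sample_id",
    "dataset",
    "depth_zone",
    "region",
    "season",
    "phosphate_umol_L",
    "read_length_bp",
    "total_reads",
)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV; missing phosphate stays NaN (distinct from 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id"} - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    if "phosphate_umol_L" in df.columns:
        df["phosphate_umol_L"] = pd.to_numeric(df["phosphate_umol_L"], errors="coerce")
    return df
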