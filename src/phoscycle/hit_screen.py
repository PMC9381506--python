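"""Parse tabular translated-search hits and apply per-gene screening filters.

Translated searches (DIAMOND/BLASTX-style, best hit per read) of each gene
family's nr database against a metagenome produce 12-column tabular output
("m8" / outfmt 6).  A hit counts toward a gene iff its percent identity
meets that family's homology cut-off (50-65 % depending on family) over a
minimum alignment length chosen by read length: 32 aa for 100 bp reads,
40 aa for 125 bp reads.  Every unique passing read is counted; forward and
reverse mates are distinct reads and both count, and a read may count
toward several families since each family is screened independently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genes import (
    DEFAULT_MIN_IDENTITY_PCT,
    MARKER_GENES,
    MIN_ALN_LENGTH_BY_READ_LENGTH,
)

#: Marker genes are screened with the same machinery; 50 % identity default.
DEFAULT_MARKER_IDENTITY_PCT = 50.0

logger = logging.getLogger(__name__)

#: Standard 12 columns of BLAST/DIAMOND tabular output (outfmt 6).
M8_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

_M8_DTYPES = {
    "qseqid": str,
    "sseqid": str,
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


class MalformedHitError(ValueError):
    """A tabular hit row that cannot be parsed (strict mode)."""


@dataclass(frozen=True)
class ScreenConfig:
    """Per-gene identity thresholds plus the minimum alignment length.

    All thresholds are inclusive (>=).  ``min_aln_length_aa`` defaults by
    read length: 100 bp reads -> 32 aa, 125 bp -> 40 aa.
    """

    min_identity_pct: Mapping[str, float] = field(
        default_factory=lambda: {
            **DEFAULT_MIN_IDENTITY_PCT,
            **{m: DEFAULT_MARKER_IDENTITY_PCT for m in MARKER_GENES},
        }
    )
    min_aln_length_aa: int = 32

    @classmethod
    def for_read_length(cls, read_length_bp: int, **kwargs) -> "ScreenConfig":
        try:
            min_len = MIN_ALN_LENGTH_BY_READ_LENGTH[int(read_length_bp)]
        except KeyError:
            raise ValueError(
                f"no default alignment-length cut-off for {read_length_bp} bp reads; "
                f"known read lengths: {sorted(MIN_ALN_LENGTH_BY_READ_LENGTH)} "
                "(pass min_aln_length_aa explicitly)"
            ) from None
        return cls(min_aln_length_aa=min_len, **kwargs)

    def identity_threshold(self, gene: str) -> float:
        try:
            return float(self.min_identity_pct[gene])
        except KeyError:
            raise KeyError(
                f"no identity threshold configured for gene {gene!r}; "
                f"configured genes: {sorted(self.min_identity_pct)}"
            ) from None


def parse_tabular_hits(path_or_buffer, *, strict: bool = True) -> pd.DataFrame:
    """Parse a 12-column tabular hit file into a DataFrame with M8 columns.

    Comment lines starting with '#' are skipped.  In strict mode a malformed
    row raises :class:`MalformedHitError` with its line number; in lenient
    mode malformed rows are dropped and counted in the log.
    """
    if isinstance(path_or_buffer, (str, Path)):
        opener = gzip.open if str(path_or_buffer).endswith(".gz") else open
        with opener(path_or_buffer, "rt") as fh:
            lines = fh.readlines()
    else:
        lines = path_or_buffer.readlines()

    rows = []
    n_bad = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(M8_COLUMNS):
            if strict:
                raise MalformedHitError(
                    f"line {lineno}: expected {len(M8_COLUMNS)} tab-separated fields, "
                    f"got {len(fields)}"
                )
            n_bad += 1
            continue
        try:
            rows.append(
                tuple(_M8_DTYPES[c](v) for c, v in zip(M8_COLUMNS, fields))
            )
        except ValueError as exc:
            if strict:
                raise MalformedHitError(f"line {lineno}: {exc}") from None
            n_bad += 1
    if n_bad:
        logger.warning("skipped %d malformed rows (lenient mode)", n_bad)
    df = pd.DataFrame(rows, columns=list(M8_COLUMNS))
    if df.empty:
        df = df.astype({c: ("object" if t is str else t) for c, t in _M8_DTYPES.items()})
    bad_id = df[(df["pident"] < 0) | (df["pident"] > 100)]
    if len(bad_id):
        raise MalformedHitError(
            f"{len(bad_id)} rows with percent identity outside [0, 100]"
        )
    return df


def best_hit_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per query: max bitscore, ties by min evalue, then input order.

    Idempotent on already-reduced input.
    """
    if hits.empty:
        return hits.copy()
    df = hits.reset_index(drop=True)
    order = np.lexsort(
        (df.index.to_numpy(), df["evalue"].to_numpy(), -df["bitscore"].to_numpy())
    )
    best = df.iloc[order].drop_duplicates("qseqid", keep="first")
    return best.sort_index().reset_index(drop=True)


def filter_hits(hits: pd.DataFrame, gene: str, config: ScreenConfig) -> pd.DataFrame:
    """Rows passing the per-gene identity and alignment-length cut-offs, in order."""
    min_id = config.identity_threshold(gene)
    keep = (hits["pident"] >= min_id) & (hits["length"] >= config.min_aln_length_aa)
    return hits[keep].reset_index(drop=True)


def count_hits(hits: pd.DataFrame) -> int:
    """Number of distinct passing queries (forward/reverse mates count separately,
    being distinct query ids)."""
    return int(hits["qseqid"].nunique())


MANIFEST_COLUMNS = ("sample_id", "gene", "path", "read_length", "total_reads")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "gene": str, "path": str}
    )
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def screen_manifest(
    manifest: pd.DataFrame,
    *,
    config: ScreenConfig | None = None,
    base_dir: str | Path | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Screen every (sample, gene) hit file listed in a manifest.

    The alignment-length cut-off is chosen per sample from its read length
    unless a fixed ``config`` is supplied.  Returns a long count table with
    columns sample_id, gene, raw_count, total_reads.
    """
    rows = []
    for _, entry in manifest.iterrows():
        path = Path(entry["path"])
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        if not path.exists():
            raise FileNotFoundError(
                f"hit file for sample {entry['sample_id']!r} gene {entry['gene']!r} "
                f"not found: {path}"
            )
        cfg = config or ScreenConfig.for_read_length(int(entry["read_length"]))
        hits = parse_tabular_hits(path, strict=strict)
        hits = best_hit_per_query(hits)
        passing = filter_hits(hits, entry["gene"], cfg)
        n = count_hits(passing)
        logger.info(
            "sample %s gene %s: %d/%d hits pass",
            entry["sample_id"], entry["gene"], n, len(hits),
        )
        rows.append(
            {
                "sample_id": entry["sample_id"],
                "gene": entry["gene"],
                "raw_count": n,
                "total_reads": int(entry["total_reads"]),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "raw_count", "total_reads"])
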