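"""Orchestrate curate -> dereplicate -> factors -> screen -> abundance -> stats.

A single YAML config names every input; validation is strict (unknown keys
are rejected with a nearest-key suggestion, all failures reported at once).
Each run writes its outputs plus a machine-readable JSON run manifest with
input paths, package version, seeds, and SHA-256 checksums of every output,
so a rerun with identical config and inputs is byte-identical for all
deterministic stages.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .abundance import MarkerSet, read_sample_metadata, relative_abundance_table
from .community_stats import (
    anosim,
    bray_curtis_matrix,
    cooccurrence_long,
    cooccurrence_matrix,
    shannon_evenness,
)
from .genes import PHOSPHONATE_GENES
from .hit_screen import ScreenConfig, read_manifest, screen_manifest
from .reference_db import (
    NormalizationFactors,
    apply_residue_rules,
    compute_normalization_factors,
    dereplicate,
    load_alignment,
    load_database,
    load_residue_rules,
    presence_matrix,
    write_clusters,
    write_database,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    db_dir: Path
    manifest: Path
    samples: Path
    out_dir: Path
    rules: Path | None = None
    marker_lengths: Path | None = None
    derep_threshold: float = 0.99
    min_identity: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    anosim_group: str | None = None
    permutations: int = 999
    allow_missing_stages: bool = False


_REQUIRED_KEYS = ("db_dir", "manifest", "samples", "out_dir")
_OPTIONAL_KEYS = (
    "rules",
    "marker_lengths",
    "derep_threshold",
    "min_identity",
    "seed",
    "anosim_group",
    "permutations",
    "allow_missing_stages",
)
_ALL_KEYS = _REQUIRED_KEYS + _OPTIONAL_KEYS


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, reporting all problems at once."""
    path = Path(path)
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    problems: list[str] = []
    for key in raw:
        if key not in _ALL_KEYS:
            suggestion = difflib.get_close_matches(key, _ALL_KEYS, n=1)
            hint = f" (did you mean {suggestion[0]!r}?)" if suggestion else ""
            problems.append(f"unknown key {key!r}{hint}")
    for key in _REQUIRED_KEYS:
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    if problems:
        raise ConfigError(problems)

    base = path.parent

    def resolve(p: str | None) -> Path | None:
        if p is None:
            return None
        q = Path(p)
        return q if q.is_absolute() else base / q

    cfg = RunConfig(
        db_dir=resolve(raw["db_dir"]),
        manifest=resolve(raw["manifest"]),
        samples=resolve(raw["samples"]),
        out_dir=resolve(raw["out_dir"]),
        rules=resolve(raw.get("rules")),
        marker_lengths=resolve(raw.get("marker_lengths")),
        derep_threshold=float(raw.get("derep_threshold", 0.99)),
        min_identity={k: float(v) for k, v in (raw.get("min_identity") or {}).items()},
        seed=raw.get("seed"),
        anosim_group=raw.get("anosim_group"),
        permutations=int(raw.get("permutations", 999)),
        allow_missing_stages=bool(raw.get("allow_missing_stages", False)),
    )
    for name in ("db_dir", "manifest", "samples", "rules", "marker_lengths"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name} path does not exist: {p}")
    if cfg.anosim_group is not None and cfg.seed is None:
        problems.append("seed is required when anosim_group is set")
    if problems:
        raise ConfigError(problems)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # stage 1: load databases (one {gene}.fasta + {gene}.tsv pair per family)
    db_dir = Path(config.db_dir)
    redundant = {}
    for gene in PHOSPHONATE_GENES:
        fasta = db_dir / f"{gene}.fasta"
        meta = db_dir / f"{gene}.tsv"
        if not fasta.exists():
            if config.allow_missing_stages:
                logger.warning("stage load: no database for %s, skipping", gene)
                continue
            raise FileNotFoundError(f"stage load: missing database FASTA for {gene}: {fasta}")
        redundant[gene] = load_database(fasta, meta)
    if not redundant:
        raise ValueError("stage load: no gene databases found")

    # stage 2 (optional): residue curation on supplied alignments
    if config.rules is not None:
        rules = load_residue_rules(config.rules)
        by_gene: dict[str, list] = {}
        for r in rules:
            by_gene.setdefault(r.gene, []).append(r)
        for gene, gene_rules in by_gene.items():
            aln_path = db_dir / f"{gene}.afa"
            if not aln_path.exists():
                continue
            aln = load_alignment(aln_path, db_dir / f"{gene}.tsv")
            result = apply_residue_rules(aln, gene_rules)
            keep = set(result.kept)
            db = redundant[gene]
            db.records = [r for r in db.records if r.seq_id in keep]
            logger.info("stage curate %s: removed %d sequences", gene, len(result.removed))

    # stage 3: dereplicate and compute factors
    nr = {}
    for gene, db in sorted(redundant.items()):
        nr_db, clusters = dereplicate(db, threshold=config.derep_threshold)
        nr[gene] = nr_db
        cpath = out / f"clusters_{gene}.tsv"
        write_clusters(clusters, cpath)
        outputs.append(cpath)
        write_database(nr_db, out / f"nr_{gene}.fasta", out / f"nr_{gene}.tsv")
        outputs += [out / f"nr_{gene}.fasta", out / f"nr_{gene}.tsv"]
    factors = compute_normalization_factors(nr)
    fpath = out / "factors.tsv"
    factors.to_tsv(fpath)
    outputs.append(fpath)

    # stage 4: screen hit tables
    manifest = read_manifest(config.manifest)
    screen_cfg = None
    if config.min_identity:
        base = ScreenConfig()
        merged = {**dict(base.min_identity_pct), **config.min_identity}
        screen_cfg = ScreenConfig(min_identity_pct=merged)
    counts = screen_manifest(manifest, config=screen_cfg, base_dir=Path(config.manifest).parent)
    cpath = out / "counts.tsv"
    counts.to_csv(cpath, sep="\t", index=False)
    outputs.append(cpath)

    # stage 5: abundance
    markers = (
        MarkerSet.from_tsv(config.marker_lengths) if config.marker_lengths else MarkerSet()
    )
    metadata = read_sample_metadata(config.samples)
    table, excluded = relative_abundance_table(counts, factors, markers, metadata)
    apath = out / "abundance.tsv"
    table.to_csv(apath, sep="\t", index=False, float_format="%.6g")
    outputs.append(apath)

    # stage 6: statistics
    pres = presence_matrix(redundant.values())
    co = cooccurrence_matrix(pres)
    copath = out / "cooccurrence.tsv"
    cooccurrence_long(co).to_csv(copath, sep="\t", index=False, float_format="%.6g")
    outputs.append(copath)

    div_rows = []
    for gene, db in sorted(redundant.items()):
        classes = [r.tax_class or "unclassified" for r in db.records]
        d = shannon_evenness(classes)
        div_rows.append(
            {"gene": gene, "H": d.H, "S": d.S, "J": d.J if d.J is not None else ""}
        )
    dpath = out / "diversity.tsv"
    pd.DataFrame(div_rows).to_csv(dpath, sep="\t", index=False, float_format="%.6g")
    outputs.append(dpath)

    wide = table.pivot(index="sample_id", columns="gene", values="relative_abundance_pct")
    wide = wide.fillna(0.0)
    anosim_report = None
    if len(wide) >= 2 and (wide.sum(axis=1) > 0).all():
        dist = bray_curtis_matrix(wide)
        mpath = out / "distance.tsv"
        dist.to_csv(mpath, sep="\t", float_format="%.6g")
        outputs.append(mpath)
        if config.anosim_group:
            groups = metadata.set_index("sample_id").loc[wide.index, config.anosim_group]
            res = anosim(
                dist, groups.to_numpy(), n_permutations=config.permutations,
                seed=int(config.seed),
            )
            anosim_report = {
                "R": res.R, "p": res.p,
                "n_permutations": res.n_permutations, "group": config.anosim_group,
            }

    run_manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "excluded_samples": excluded,
        "anosim": anosim_report,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    return run_manifest
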