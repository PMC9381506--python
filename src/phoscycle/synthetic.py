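"""Synthetic reference databases, communities, and hit tables with known truth.

The generator emulates the three pipeline inputs so every stage is testable
without any external download:

* reference databases — per gene family, sequences evolve by substitution
  from a random ancestor: cluster founders diverge far below the
  dereplication threshold from each other, members sit just above it
  relative to their founder, conserved residues are planted to satisfy the
  shipped rule files with a configurable fraction of violators, and locus
  tables place a configurable fraction of synteny-rescued candidates away
  from any companion gene;
* communities — genomes receive a taxonomic class (Dirichlet-weighted),
  log-normal relative abundances, per-gene carriage by Bernoulli draws with
  optional conditional co-occurrence overrides, and integer copy numbers;
* hit tables — per sample, gene, and genome the number of passing reads is
  Poisson with rate proportional to abundance x copies x gene length (the
  minimal model under which the copy-number and length corrections are the
  exact inverse transforms); identities of true hits are uniform above the
  gene's threshold, and decoys are planted strictly below the identity or
  alignment-length cut-off so filter correctness is exactly testable.

One global seed drives a hierarchical seed tree (per gene, per sample), so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import MarkerSet
from .genes import (
    AMINO_ACIDS,
    DEFAULT_MIN_IDENTITY_PCT,
    MARKER_GENES,
    MIN_ALN_LENGTH_BY_READ_LENGTH,
    PHOSPHONATE_GENES,
    PRODUCTION_GENES,
)
from .reference_db import (
    ClusterSet,
    GeneDatabase,
    MultipleAlignment,
    NormalizationFactors,
    ProteinRecord,
    ResidueRule,
)

#: Mean reference protein lengths (aa) per family, typical of the enzymes.
DEFAULT_GENE_LENGTHS_AA: dict[str, float] = {
    "pepM": 295.0,
    "aepY": 380.0,
    "phpC": 390.0,
    "mpnS": 450.0,
    "hepD": 450.0,
    "palA": 280.0,
    "phnA": 410.0,
    "phnW": 370.0,
    "phnX": 270.0,
    "phnY": 500.0,
    "phnZ": 190.0,
    "phnI": 350.0,
    "phnJ": 280.0,
    "phnM": 380.0,
    "recA": 350.0,
    "atpD": 460.0,
    "tufA": 395.0,
    "gyrB": 640.0,
    "hsp70": 640.0,
}

#: Carrier probabilities echoing the survey's prevalence ordering: production
#: entry genes and 2-AEP hydrolysis are common, C-P lyase genes are rare.
DEFAULT_CARRIER_PROB: dict[str, float] = {
    "pepM": 0.15,
    "aepY": 0.14,
    "phpC": 0.06,
    "mpnS": 0.02,
    "hepD": 0.01,
    "palA": 0.02,
    "phnA": 0.08,
    "phnW": 0.25,
    "phnX": 0.08,
    "phnY": 0.06,
    "phnZ": 0.15,
    "phnI": 0.04,
    "phnJ": 0.04,
    "phnM": 0.05,
}

DEFAULT_CLASS_POOL: tuple[str, ...] = (
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Bacilli",
    "Actinomycetia",
    "Cyanobacteriia",
    "Flavobacteriia",
    "Planctomycetia",
    "Nitrososphaeria",
    "Deltaproteobacteria",
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-like defaults."""

    seed: int = 0
    # community
    n_genomes: int = 200
    class_pool: tuple[str, ...] = DEFAULT_CLASS_POOL
    class_concentration: float = 2.0
    carrier_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_PROB)
    )
    #: conditional co-occurrence overrides {(src, co): P(co | src)}; the
    #: biosynthesis entry pair is tightly linked in genomes.
    cooccurrence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("pepM", "aepY"): 0.86}
    )
    copy_number: Mapping[str, int] = field(default_factory=dict)
    gene_length_aa: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS_AA)
    )
    gene_length_sd: float = 0.0
    abundance_sigma: float = 1.0
    # sequencing / hit model
    n_samples: int = 4
    total_reads: int = 1_000_000
    read_length_bp: int = 100
    decoy_rate: float = 0.2
    l_norm: float = 100_000.0
    # sample design (length n_samples each, or broadcast)
    sample_depth_zones: tuple[str, ...] = ()
    sample_seasons: tuple[str, ...] = ()
    sample_regions: tuple[str, ...] = ()
    depth_effect: Mapping[str, float] = field(default_factory=dict)
    season_effect: Mapping[str, float] = field(default_factory=dict)
    # reference-database generation
    db_n_clusters: int = 6
    db_members_per_cluster: int = 3
    db_member_identity: float = 0.995
    db_founder_divergence: float = 0.3
    db_violator_fraction: float = 0.0
    db_n_rules: int = 3
    synteny_isolated_fraction: float = 0.3

    def __post_init__(self) -> None:
        for g, p in self.carrier_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"carrier_prob[{g}] outside [0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if not 0 < self.db_member_identity <= 1:
            raise ValueError("db_member_identity must be in (0, 1]")
        if self.read_length_bp not in MIN_ALN_LENGTH_BY_READ_LENGTH:
            raise ValueError(
                f"read_length_bp must be one of {sorted(MIN_ALN_LENGTH_BY_READ_LENGTH)}"
            )
        for g, c in self.copy_number.items():
            if c < 1:
                raise ValueError(f"copy_number[{g}] must be >= 1")
            if c > 1 and self.db_n_clusters % c:
                raise ValueError(
                    f"copy_number[{g}]={c} must divide db_n_clusters={self.db_n_clusters}"
                )

    def copies(self, gene: str) -> int:
        return int(self.copy_number.get(gene, 1))

    def length(self, gene: str) -> float:
        return float(self.gene_length_aa[gene])

    def _sample_field(self, values: tuple[str, ...], default: str) -> list[str]:
        if not values:
            return [default] * self.n_samples
        if len(values) == self.n_samples:
            return list(values)
        raise ValueError("per-sample fields must match n_samples")

    def depth_zones(self) -> list[str]:
        return self._sample_field(self.sample_depth_zones, "SUR")

    def seasons(self) -> list[str]:
        return self._sample_field(self.sample_seasons, "summer")

    def regions(self) -> list[str]:
        return self._sample_field(self.sample_regions, "global")


def structured_config(seed: int = 0, **overrides) -> SimConfig:
    """A sample design with depth and season structure for the statistics
    layer: surface-summer, surface-winter, and mesopelagic sample groups,
    with phosphonate genes enriched at depth and production genes enriched
    in winter (magnitudes in line with 2-3 fold field gradients)."""
    n = 12
    zones = tuple(["SUR"] * 8 + ["MES"] * 4)
    seasons = tuple(["summer"] * 4 + ["winter"] * 4 + ["summer"] * 4)
    depth_effect = {g: 3.0 for g in PRODUCTION_GENES}
    depth_effect.update({g: 2.0 for g in PHOSPHONATE_GENES if g not in depth_effect})
    season_effect = {g: 2.0 for g in PRODUCTION_GENES}
    base = dict(
        seed=seed,
        n_samples=n,
        sample_depth_zones=zones,
        sample_seasons=seasons,
        depth_effect=depth_effect,
        season_effect=season_effect,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# community


@dataclass
class SyntheticCommunity:
    """Realized community: genome table and per-genome gene copy counts."""

    genomes: pd.DataFrame  # genome_id, tax_class, abundance (sums to 1)
    carriage: pd.DataFrame  # genome_id x gene -> integer copies

    def presence(self) -> pd.DataFrame:
        return self.carriage > 0


@dataclass
class TruthTable:
    """Analytic ground truth of the realized community.

    carrier_fraction f_g = sum of abundances of genomes carrying g;
    copy_weighted_fraction w_g additionally weights by copy count (the
    quantity raw hit counts are proportional to).
    """

    table: pd.DataFrame  # index gene; columns carrier_fraction, copy_weighted_fraction

    def carrier_fraction(self, gene: str) -> float:
        return float(self.table.loc[gene, "carrier_fraction"])

    def copy_weighted_fraction(self, gene: str) -> float:
        return float(self.table.loc[gene, "copy_weighted_fraction"])


def simulate_community(config: SimConfig) -> tuple[SyntheticCommunity, TruthTable]:
    """Draw a community with known class composition, abundances, and carriage."""
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    n = config.n_genomes
    genome_ids = [f"G{i:05d}" for i in range(n)]
    class_weights = rng.dirichlet([config.class_concentration] * len(config.class_pool))
    classes = rng.choice(config.class_pool, size=n, p=class_weights)
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    abundance /= abundance.sum()

    carriage = pd.DataFrame(0, index=genome_ids, columns=list(PHOSPHONATE_GENES))
    for gene in PHOSPHONATE_GENES:
        p = config.carrier_prob.get(gene, 0.0)
        carriers = rng.random(n) < p
        carriage[gene] = np.where(carriers, config.copies(gene), 0)
    # conditional overrides: redraw co-gene carriage among source carriers
    for (src, co), p_cond in config.cooccurrence.items():
        src_carriers = carriage[src] > 0
        redraw = rng.random(int(src_carriers.sum())) < p_cond
        values = np.where(redraw, config.copies(co), 0)
        carriage.loc[src_carriers, co] = values
    carriage.index.name = "genome_id"

    genomes = pd.DataFrame(
        {"genome_id": genome_ids, "tax_class": classes, "abundance": abundance}
    )
    community = SyntheticCommunity(genomes=genomes, carriage=carriage)
    return community, compute_truth(community)


def compute_truth(community: SyntheticCommunity) -> TruthTable:
    """Recompute the truth table from the realized community (definitional)."""
    ab = community.genomes.set_index("genome_id")["abundance"]
    rows = {}
    for gene in community.carriage.columns:
        copies = community.carriage[gene]
        rows[gene] = {
            "carrier_fraction": float(ab[copies > 0].sum()),
            "copy_weighted_fraction": float((ab * copies).sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return TruthTable(table=table)


# ---------------------------------------------------------------------------
# analytic factors and expected abundances


def analytic_factors(config: SimConfig) -> NormalizationFactors:
    """Normalization factors implied by the generating model: database mean
    lengths equal the true gene lengths and cn_factor = 1/copies."""
    rows = {}
    lengths = [config.length(g) for g in PHOSPHONATE_GENES]
    study_mean = float(np.mean(lengths))
    for gene in PHOSPHONATE_GENES:
        rows[gene] = {
            "cn_factor": 1.0 / config.copies(gene),
            "len_factor": study_mean / config.length(gene),
            "mean_length_aa": config.length(gene),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return NormalizationFactors(table=table, study_mean_length_aa=study_mean)


def analytic_markers(config: SimConfig) -> MarkerSet:
    return MarkerSet(
        lengths_aa={m: config.length(m) for m in MARKER_GENES}, base_marker="recA"
    )


def expected_relative_abundance(
    truth: TruthTable,
    factors: NormalizationFactors,
    markers: MarkerSet | None = None,
) -> pd.Series:
    """Expected pipeline relative abundance (%) per gene.

    For a single-copy gene with study mean length equal to the recA baseline
    this is exactly 100 * carrier_fraction; copy number cancels against the
    copy-number factor, and the residual length scale is the ratio of the
    phosphonate study mean length to the recA reference length (the paper's
    normalization references phosphonate counts to the study mean but the
    community size to recA).
    """
    markers = markers or MarkerSet()
    scale = factors.study_mean_length_aa / markers.lengths_aa[markers.base_marker]
    out = {}
    for gene in truth.table.index:
        w = truth.copy_weighted_fraction(gene)
        out[gene] = 100.0 * w * factors.cn_factor(gene) * scale
    return pd.Series(out, name="expected_relative_abundance_pct")


# ---------------------------------------------------------------------------
# hit tables


@dataclass
class SimulatedHits:
    """Per-sample per-gene m8 hit tables with manifest and sample metadata."""

    hits: dict[str, dict[str, pd.DataFrame]]  # sample -> gene -> m8 rows
    manifest: pd.DataFrame
    samples: pd.DataFrame
    true_counts: pd.DataFrame  # sample_id, gene, true_count (planted passing hits)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "m8").mkdir(parents=True, exist_ok=True)
        for sample, per_gene in self.hits.items():
            for gene, df in per_gene.items():
                path = out / "m8" / f"{sample}_{gene}.m8"
                _write_m8(df, path)
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.true_counts.to_csv(out / "true_counts.tsv", sep="\t", index=False)


def _write_m8(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.qseqid}\t{row.sseqid}\t{row.pident:.1f}\t{row.length}\t"
                f"{row.mismatch}\t{row.gapopen}\t{row.qstart}\t{row.qend}\t"
                f"{row.sstart}\t{row.send}\t{row.evalue:.2e}\t{row.bitscore:.1f}\n"
            )


def _gene_rows(
    rng: np.random.Generator,
    sample: str,
    gene: str,
    lam: float,
    min_identity: float,
    min_len: int,
    decoy_rate: float,
) -> tuple[pd.DataFrame, int]:
    """True hits above both cut-offs plus decoys strictly below one of them."""
    n_true = int(rng.poisson(lam))
    n_id_decoy = int(rng.poisson(decoy_rate * lam / 2))
    n_len_decoy = int(rng.poisson(decoy_rate * lam / 2))

    rows = []
    read_no = 0

    def add(n: int, ident_lo: float, ident_hi: float, lengths: np.ndarray) -> None:
        nonlocal read_no
        idents = rng.uniform(ident_lo, ident_hi, size=n)
        for ident, aln_len in zip(idents, lengths):
            mate = 1 + (read_no % 2)
            qid = f"{sample}:{gene}:r{read_no:06d}/{mate}"
            read_no += 1
            aln_len = int(aln_len)
            mism = int(round(aln_len * (1 - ident / 100)))
            bitscore = max(25.0, ident * aln_len / 50.0)
            evalue = 10.0 ** (-rng.uniform(5, 40))
            rows.append(
                (qid, f"{gene}|ref", round(float(ident), 1), aln_len, mism, 0,
                 1, aln_len * 3, 1, aln_len, evalue, bitscore)
            )

    true_lengths = rng.integers(min_len, min_len + 2, size=n_true)
    add(n_true, min_identity, 100.0, true_lengths)
    # identity decoys: valid length, identity strictly below the cut-off
    decoy_id_lengths = rng.integers(min_len, min_len + 2, size=n_id_decoy)
    add(n_id_decoy, 20.0, max(20.0, min_identity - 0.6), decoy_id_lengths)
    # length decoys: passing identity, alignment too short
    decoy_len_lengths = rng.integers(max(10, min_len - 8), min_len, size=n_len_decoy)
    add(n_len_decoy, min_identity, 100.0, decoy_len_lengths)

    from .hit_screen import M8_COLUMNS  # local import to avoid cycle at import time

    df = pd.DataFrame(rows, columns=list(M8_COLUMNS))
    # clamp: rounding to one decimal must not promote a decoy across the cut-off
    return df, n_true


def simulate_hit_tables(
    community: SyntheticCommunity,
    config: SimConfig,
) -> SimulatedHits:
    """Generate per-sample m8 tables from the community under the Poisson model."""
    root = np.random.SeedSequence(config.seed).spawn(2)[1]
    ab = community.genomes.set_index("genome_id")["abundance"]
    min_len = MIN_ALN_LENGTH_BY_READ_LENGTH[config.read_length_bp]
    zones, seasons, regions = config.depth_zones(), config.seasons(), config.regions()

    genes = list(PHOSPHONATE_GENES) + list(MARKER_GENES)
    thresholds = {
        **DEFAULT_MIN_IDENTITY_PCT,
        **{m: 50.0 for m in MARKER_GENES},
    }
    # copy-weighted carriage sums per gene (markers: every genome, one copy)
    w = {g: float((ab * community.carriage[g]).sum()) for g in PHOSPHONATE_GENES}
    w.update({m: 1.0 for m in MARKER_GENES})

    sample_seeds = root.spawn(config.n_samples)
    hits: dict[str, dict[str, pd.DataFrame]] = {}
    manifest_rows, sample_rows, true_rows = [], [], []
    for s in range(config.n_samples):
        sample = f"S{s:03d}"
        gene_seeds = sample_seeds[s].spawn(len(genes) + 1)
        meta_rng = np.random.default_rng(gene_seeds[-1])
        phosphate = float(np.round(meta_rng.lognormal(mean=-2.0, sigma=1.0), 3))
        per_gene: dict[str, pd.DataFrame] = {}
        for gi, gene in enumerate(genes):
            rng = np.random.default_rng(gene_seeds[gi])
            lam = config.total_reads * w[gene] * config.length(gene) / config.l_norm
            if gene in config.depth_effect and zones[s] == "MES":
                lam *= config.depth_effect[gene]
            if gene in config.season_effect and seasons[s] == "winter":
                lam *= config.season_effect[gene]
            df, n_true = _gene_rows(
                rng, sample, gene, lam, thresholds[gene], min_len, config.decoy_rate
            )
            per_gene[gene] = df
            manifest_rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "path": f"m8/{sample}_{gene}.m8",
                    "read_length": config.read_length_bp,
                    "total_reads": config.total_reads,
                }
            )
            true_rows.append({"sample_id": sample, "gene": gene, "true_count": n_true})
        hits[sample] = per_gene
        sample_rows.append(
            {
                "sample_id": sample,
                "dataset": "synthetic",
                "depth_zone": zones[s],
                "region": regions[s],
                "season": seasons[s],
                "phosphate_umol_L": phosphate,
                "read_length_bp": config.read_length_bp,
                "total_reads": config.total_reads,
            }
        )
    return SimulatedHits(
        hits=hits,
        manifest=pd.DataFrame(manifest_rows),
        samples=pd.DataFrame(sample_rows),
        true_counts=pd.DataFrame(true_rows),
    )


# ---------------------------------------------------------------------------
# reference databases


@dataclass
class SimulatedGeneDatabase:
    """One gene family's planted database with full generation truth."""

    gene: str
    redundant: GeneDatabase
    nr_expected: GeneDatabase  # cluster founders
    clusters_expected: ClusterSet
    alignment: MultipleAlignment
    rules: list[ResidueRule]
    violators: list[str]  # seq_ids planted to fail a residue rule
    loci: pd.DataFrame | None = None
    isolated: list[str] = field(default_factory=list)  # planted synteny failures


def _mutate(
    rng: np.random.Generator, seq: list[str], positions: np.ndarray, n_mut: int
) -> tuple[list[str], list[int]]:
    """Substitute ``n_mut`` distinct positions (chosen from ``positions``) with
    a different residue; returns the sequence and the mutated positions."""
    out = list(seq)
    chosen = rng.choice(positions, size=min(n_mut, len(positions)), replace=False)
    for pos in chosen:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return out, [int(p) for p in chosen]


def simulate_reference_databases(
    config: SimConfig, genes: Sequence[str] | None = None
) -> dict[str, SimulatedGeneDatabase]:
    """Generate per-gene redundant databases with planted clustering, residue
    rules (and violators), copy numbers, and synteny locus tables."""
    genes = list(genes) if genes is not None else list(PHOSPHONATE_GENES)
    root = np.random.SeedSequence(config.seed).spawn(3)[2]
    gene_seeds = root.spawn(len(genes))
    out: dict[str, SimulatedGeneDatabase] = {}
    for gene, seed in zip(genes, gene_seeds):
        rng = np.random.default_rng(seed)
        out[gene] = _simulate_one_gene(rng, gene, config)
    return out


def _simulate_one_gene(
    rng: np.random.Generator, gene: str, config: SimConfig
) -> SimulatedGeneDatabase:
    L = int(config.length(gene))
    K = config.db_n_clusters
    M = config.db_members_per_cluster
    c = config.copies(gene)
    if (K * M) % c:
        raise ValueError(f"{gene}: cluster grid {K}x{M} not divisible by copies {c}")

    ancestor = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=L)]
    rule_positions = rng.choice(L, size=config.db_n_rules, replace=False)
    rule_positions.sort()
    free_positions = np.setdiff1d(np.arange(L), rule_positions)

    anchor_id = f"{gene}|c00|s00"
    rules = [
        ResidueRule(
            gene=gene,
            ref_seq_id=anchor_id,
            ref_position=int(pos) + 1,
            allowed=frozenset({ancestor[pos]}),
            role=("catalytic", "substrate", "cofactor")[i % 3],
        )
        for i, pos in enumerate(rule_positions)
    ]

    n_founder_mut = int(round(config.db_founder_divergence * L))
    n_member_mut = max(1, int(round((1 - config.db_member_identity) * L)))

    founders = [
        _mutate(rng, ancestor, free_positions, n_founder_mut)[0] if k else list(ancestor)
        for k in range(K)
    ]

    # genome assignment: sequence (k, j) belongs to genome (j*K + k) // c, so a
    # genome's copies land in distinct clusters (K % c == 0 enforced upstream)
    def genome_of(k: int, j: int) -> str:
        return f"{gene}_genome{(j * K + k) // c:04d}"

    seq_ids, sequences, genome_ids = [], [], []
    mutated_at: list[list[int]] = []
    cluster_of: list[int] = []
    cluster_members: list[list[str]] = [[] for _ in range(K)]
    for k in range(K):
        for j in range(M):
            sid = f"{gene}|c{k:02d}|s{j:02d}"
            if j == 0:
                seq, muts = founders[k], []
            else:
                seq, muts = _mutate(rng, founders[k], free_positions, n_member_mut)
            seq_ids.append(sid)
            sequences.append(seq)
            mutated_at.append(muts)
            cluster_of.append(k)
            genome_ids.append(genome_of(k, j))
            cluster_members[k].append(sid)

    # plant residue-rule violators among non-founder members; the rule-position
    # mutation replaces one ordinary mutation so planted cluster identities hold
    n_viol = int(round(config.db_violator_fraction * len(seq_ids)))
    candidates = [i for i, m in enumerate(mutated_at) if m]
    violator_idx = sorted(
        rng.choice(candidates, size=min(n_viol, len(candidates)), replace=False)
    )
    violators = []
    for i in violator_idx:
        seq = list(sequences[i])
        revert = mutated_at[i][0]
        seq[revert] = founders[cluster_of[i]][revert]
        pos = int(rule_positions[rng.integers(len(rule_positions))])
        alternatives = [a for a in AMINO_ACIDS if a != ancestor[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
        sequences[i] = seq
        violators.append(seq_ids[i])

    class_pool = config.class_pool
    records = []
    genome_class = {}
    for sid, seq, gid in zip(seq_ids, sequences, genome_ids):
        if gid not in genome_class:
            genome_class[gid] = class_pool[rng.integers(len(class_pool))]
        records.append(
            ProteinRecord(
                seq_id=sid,
                gene=gene,
                genome_id=gid,
                taxonomy=("Bacteria", "", genome_class[gid], "", "", "", ""),
                marine=bool(rng.random() < 0.5),
                sequence="".join(seq),
            )
        )
    redundant = GeneDatabase(gene=gene, records=records, redundant=True)
    alignment = MultipleAlignment(records=list(records))

    founder_ids = {f"{gene}|c{k:02d}|s00" for k in range(K)}
    nr_records = [r for r in redundant.records if r.seq_id in founder_ids]
    member_genomes = {
        f"{gene}|c{k:02d}|s00": frozenset(
            genome_of(k, j) for j in range(M)
        )
        for k in range(K)
    }
    nr_expected = GeneDatabase(
        gene=gene, records=nr_records, redundant=False, member_genomes=member_genomes
    )
    clusters_expected = ClusterSet(
        clusters=[(f"{gene}|c{k:02d}|s00", cluster_members[k]) for k in range(K)],
        threshold=0.99,
    )

    loci, isolated = None, []
    if gene in ("phpC", "phnY"):
        loci, isolated = _simulate_loci(rng, gene, seq_ids, genome_ids, config)

    return SimulatedGeneDatabase(
        gene=gene,
        redundant=redundant,
        nr_expected=nr_expected,
        clusters_expected=clusters_expected,
        alignment=alignment,
        rules=rules,
        violators=violators,
        loci=loci,
        isolated=isolated,
    )


def _simulate_loci(
    rng: np.random.Generator,
    gene: str,
    seq_ids: list[str],
    genome_ids: list[str],
    config: SimConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Locus tables for synteny verification: most candidates get a companion
    phosphonate gene within two locus ranks; a planted fraction sit isolated."""
    rows = []
    isolated = []
    for sid, gid in zip(seq_ids, genome_ids):
        contig = f"{gid}_ctg1"
        base = int(rng.integers(5, 50))
        rows.append(
            {"genome_id": gid, "contig_id": contig, "locus_index": base,
             "gene_label": gene, "seq_id": sid}
        )
        if rng.random() < config.synteny_isolated_fraction:
            isolated.append(sid)
            # companion exists, but on a different contig
            rows.append(
                {"genome_id": gid, "contig_id": f"{gid}_ctg2", "locus_index": 3,
                 "gene_label": "phnW", "seq_id": f"{sid}|companion"}
            )
        else:
            rows.append(
                {"genome_id": gid, "contig_id": contig, "locus_index": base + 2,
                 "gene_label": "phnW", "seq_id": f"{sid}|companion"}
            )
    return pd.DataFrame(rows), isolated


# ---------------------------------------------------------------------------
# regression fixture


def simulate_regression_dataset(
    seed: int,
    n: int = 50,
    slope: float = -0.8,
    intercept: float = 1.0,
    noise_sd: float = 0.3,
    pseudocount: float = 0.01,
    zero_pi_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Samples following ln(abundance) = intercept + slope*ln(Pi + pseudocount)
    + Gaussian noise; a fraction of phosphate values sit at 0 (below the
    detection limit)."""
    rng = np.random.default_rng(seed)
    pi = np.exp(rng.uniform(np.log(0.02), np.log(2.0), size=n))
    pi[rng.random(n) < zero_pi_fraction] = 0.0
    log_ab = intercept + slope * np.log(pi + pseudocount) + rng.normal(0, noise_sd, n)
    return np.exp(log_ab), pi
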