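"""Build, verify, dereplicate, and summarize gene-family reference databases.

A reference database for one enzyme family is a set of protein sequences
with per-sequence metadata (source genome, ranked taxonomy, marine flag).
Curation proceeds in three steps:

1. residue verification — sequences lacking the conserved catalytic,
   substrate-binding, or cofactor-binding residues of the family (supplied
   as data, anchored to a named reference sequence in the alignment) are
   removed;
2. synteny rescue — families that annotation alone cannot distinguish from
   related protein superfamilies (phpC, phnY) additionally require another
   phosphonate-cycling gene in the genomic neighbourhood;
3. dereplication — a greedy longest-first clustering at 99 % identity
   yields the non-redundant (nr) database used for screening, while the
   redundant database is kept for genome co-occurrence analysis.

The nr databases also provide the two per-gene normalization factors used
downstream: a copy-number factor (genomes/sequences) and a length factor
(study-wide mean length / family mean length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import AMINO_ACIDS, TAXONOMY_RANKS

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

METADATA_COLUMNS = (
    ["seq_id", "gene", "genome_id"] + list(TAXONOMY_RANKS) + ["marine", "length_aa"]
)


def _ungapped(sequence: str) -> str:
    return "".join(c for c in sequence if c not in GAP_CHARS)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its source-genome metadata.

    ``marine`` is True/False when habitat metadata is available and None
    otherwise (habitat is known for only a minority of public genomes, so
    "unknown" must stay distinct from "non-marine").
    """

    seq_id: str
    gene: str
    genome_id: str
    taxonomy: tuple[str, ...] = ("",) * len(TAXONOMY_RANKS)
    marine: bool | None = None
    sequence: str = ""

    @property
    def length_aa(self) -> int:
        return len(_ungapped(self.sequence))

    @property
    def tax_class(self) -> str:
        return self.taxonomy[2] if len(self.taxonomy) > 2 else ""


@dataclass
class GeneDatabase:
    """A named gene family's sequence records, redundant or dereplicated.

    For an nr database produced by :func:`dereplicate`, ``member_genomes``
    maps each representative to the full set of genome ids of its cluster's
    members, for cluster-level reporting.  ``n_genomes`` always counts the
    distinct genomes among the records themselves (representatives, for an
    nr database), keeping n_genomes <= n_sequences and hence copy-number
    factors in (0, 1].
    """

    gene: str
    records: list[ProteinRecord]
    redundant: bool = True
    member_genomes: dict[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_id in {self.gene} database: {dupes}")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def genome_ids(self) -> set[str]:
        return {r.genome_id for r in self.records}

    @property
    def member_union_genomes(self) -> set[str]:
        """Distinct genomes across all cluster members (nr databases only)."""
        if self.member_genomes is None:
            return self.genome_ids
        out: set[str] = set()
        for members in self.member_genomes.values():
            out |= members
        return out

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def mean_length_aa(self) -> float:
        if not self.records:
            raise ValueError(f"empty database for {self.gene}")
        return sum(r.length_aa for r in self.records) / len(self.records)


@dataclass
class MultipleAlignment:
    """Gapped protein records of identical aligned length."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def get(self, seq_id: str) -> ProteinRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"sequence {seq_id!r} not in alignment")


@dataclass(frozen=True)
class ResidueRule:
    """A conserved-residue requirement anchored to a reference sequence.

    ``ref_position`` is 1-based on the *ungapped* anchor; ``allowed`` is the
    set of residues compatible with function at that position.
    """

    gene: str
    ref_seq_id: str
    ref_position: int
    allowed: frozenset[str]
    role: str = ""

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("empty allowed residue set")
        bad = set(self.allowed) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"allowed set contains non-amino-acid symbols: {bad}")
        if self.ref_position < 1:
            raise ValueError("ref_position is 1-based and must be >= 1")


@dataclass
class ClusterSet:
    """Clusters as (representative, members) with representative ∈ members."""

    clusters: list[tuple[str, list[str]]]
    threshold: float

    def __post_init__(self) -> None:
        for rep, members in self.clusters:
            if rep not in members:
                raise ValueError(f"representative {rep!r} not among its members")
        all_members = [m for _, members in self.clusters for m in members]
        if len(all_members) != len(set(all_members)):
            raise ValueError("a seq_id appears in more than one cluster")

    def assignment(self) -> dict[str, str]:
        """Map every member seq_id to its representative."""
        return {m: rep for rep, members in self.clusters for m in members}


@dataclass
class NormalizationFactors:
    """Per-gene copy-number and length normalization factors.

    cn_factor = n_genomes / n_sequences of the nr database (1 for strictly
    single-copy families, < 1 when genomes carry multiple copies).
    len_factor = study_mean_length_aa / mean_length_aa(gene), correcting the
    hit-count bias toward longer genes; the study mean is taken over the
    union of all sequences in all phosphonate nr databases.
    """

    table: pd.DataFrame  # index: gene; columns: cn_factor, len_factor, mean_length_aa
    study_mean_length_aa: float

    def cn_factor(self, gene: str) -> float:
        return self._get(gene, "cn_factor")

    def len_factor(self, gene: str) -> float:
        return self._get(gene, "len_factor")

    def _get(self, gene: str, col: str) -> float:
        if gene not in self.table.index:
            raise KeyError(
                f"no normalization factors for gene {gene!r}; "
                f"available: {sorted(self.table.index)}"
            )
        return float(self.table.loc[gene, col])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out["study_mean_length_aa"] = self.study_mean_length_aa
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizationFactors":
        df = pd.read_csv(path, sep="\t")
        study = float(df["study_mean_length_aa"].iloc[0])
        table = df.set_index("gene")[["cn_factor", "len_factor", "mean_length_aa"]]
        return cls(table=table, study_mean_length_aa=study)


# ---------------------------------------------------------------------------
# loading


def _parse_marine(value: object) -> bool | None:
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "1", "marine"}:
        return True
    if s in {"false", "f", "no", "0", "non-marine"}:
        return False
    return None


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sequence metadata TSV (seq_id, gene, genome_id, ranked taxonomy,
    marine, length_aa)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"seq_id", "gene", "genome_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    if df["seq_id"].duplicated().any():
        dupes = df.loc[df["seq_id"].duplicated(), "seq_id"].tolist()
        raise ValueError(f"duplicate seq_id in metadata {path}: {dupes[:5]}")
    return df


def load_database(
    fasta_path: str | Path,
    metadata_path: str | Path,
    *,
    max_missing_frac: float = 0.0,
) -> GeneDatabase:
    """Load a gene-family database from FASTA + metadata TSV.

    Records whose FASTA id is absent from the metadata are dropped with a
    warning; if their fraction exceeds ``max_missing_frac`` the mismatch is
    treated as a corrupt input and raised.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    meta = read_metadata(metadata_path).set_index("seq_id")

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate seq_id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        warnings.warn(f"empty FASTA {fasta_path}")

    missing = [sid for sid in seqs if sid not in meta.index]
    if seqs and len(missing) / len(seqs) > max_missing_frac:
        raise ValueError(
            f"{len(missing)}/{len(seqs)} FASTA ids missing from metadata "
            f"{metadata_path} (tolerance {max_missing_frac:.0%}); first: {missing[:5]}"
        )
    if missing:
        logger.warning("dropping %d records without metadata: %s", len(missing), missing)

    records = []
    genes = set()
    for sid, seq in seqs.items():
        if sid in missing:
            continue
        row = meta.loc[sid]
        taxonomy = tuple(str(row.get(rank, "")) for rank in TAXONOMY_RANKS)
        records.append(
            ProteinRecord(
                seq_id=sid,
                gene=str(row["gene"]),
                genome_id=str(row["genome_id"]),
                taxonomy=taxonomy,
                marine=_parse_marine(row.get("marine", "")),
                sequence=seq,
            )
        )
        genes.add(str(row["gene"]))
    gene = genes.pop() if len(genes) == 1 else (sorted(genes)[0] if genes else "")
    if len(genes) >= 1:
        logger.warning("database %s mixes genes: %s", fasta_path, sorted(genes | {gene}))
    return GeneDatabase(gene=gene, records=records, redundant=True)


def write_database(db: GeneDatabase, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a database back to FASTA + metadata TSV."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in db.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    rows = []
    for r in db.records:
        row = {"seq_id": r.seq_id, "gene": r.gene, "genome_id": r.genome_id}
        row.update(dict(zip(TAXONOMY_RANKS, r.taxonomy)))
        row["marine"] = "" if r.marine is None else str(r.marine).lower()
        row["length_aa"] = r.length_aa
        rows.append(row)
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def load_alignment(path: str | Path, metadata_path: str | Path | None = None) -> MultipleAlignment:
    """Load an aligned FASTA ('-' gaps); metadata is optional."""
    meta = read_metadata(metadata_path).set_index("seq_id") if metadata_path else None
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = genome = ""
        taxonomy = ("",) * len(TAXONOMY_RANKS)
        marine = None
        if meta is not None and rec.id in meta.index:
            row = meta.loc[rec.id]
            gene, genome = str(row["gene"]), str(row["genome_id"])
            taxonomy = tuple(str(row.get(rank, "")) for rank in TAXONOMY_RANKS)
            marine = _parse_marine(row.get("marine", ""))
        records.append(
            ProteinRecord(
                seq_id=rec.id,
                gene=gene,
                genome_id=genome,
                taxonomy=taxonomy,
                marine=marine,
                sequence=str(rec.seq).upper(),
            )
        )
    return MultipleAlignment(records=records)


def load_residue_rules(path: str | Path) -> list[ResidueRule]:
    """Read a rule TSV: gene, ref_seq_id, ref_position, allowed, role.

    ``allowed`` is a string of one-letter residue codes, e.g. ``DE``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules = []
    for _, row in df.iterrows():
        rules.append(
            ResidueRule(
                gene=row["gene"],
                ref_seq_id=row["ref_seq_id"],
                ref_position=int(row["ref_position"]),
                allowed=frozenset(row["allowed"].strip().upper()),
                role=row.get("role", ""),
            )
        )
    return rules


def write_residue_rules(rules: Sequence[ResidueRule], path: str | Path) -> None:
    rows = [
        {
            "gene": r.gene,
            "ref_seq_id": r.ref_seq_id,
            "ref_position": r.ref_position,
            "allowed": "".join(sorted(r.allowed)),
            "role": r.role,
        }
        for r in rules
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# residue verification


def map_reference_positions(
    alignment: MultipleAlignment, ref_seq_id: str, positions: Sequence[int]
) -> list[int]:
    """Map 1-based ungapped anchor positions to 1-based alignment columns.

    Column c is returned for position p iff the p-th non-gap character of
    the anchor sequence sits in column c.
    """
    anchor = alignment.get(ref_seq_id).sequence
    col_of: list[int] = []  # col_of[p-1] = 1-based column of p-th residue
    for col, char in enumerate(anchor, start=1):
        if char not in GAP_CHARS:
            col_of.append(col)
    out = []
    for p in positions:
        if not 1 <= p <= len(col_of):
            raise ValueError(
                f"position {p} exceeds ungapped length {len(col_of)} of anchor {ref_seq_id!r}"
            )
        out.append(col_of[p - 1])
    return out


@dataclass
class CurationResult:
    kept: list[str]
    removed: list[str]
    report: pd.DataFrame  # index seq_id, one bool column per rule


def apply_residue_rules(
    alignment: MultipleAlignment,
    rules: Sequence[ResidueRule],
    *,
    allow_empty_rules: bool = False,
) -> CurationResult:
    """Keep sequences carrying every required conserved residue.

    A rule passes for a sequence iff the character at the mapped alignment
    column is in the rule's allowed set; a gap at that column fails the rule
    (the residue is absent).  A sequence is kept iff it passes all rules.
    Anchor sequences always pass their own rules.
    """
    if not alignment.records:
        raise ValueError("empty alignment")
    if not rules:
        if allow_empty_rules:
            kept = [r.seq_id for r in alignment.records]
            return CurationResult(kept=kept, removed=[], report=pd.DataFrame(index=kept))
        raise ValueError("refusing to verify with an empty rule list "
                         "(pass allow_empty_rules=True to pass everything through)")

    columns = {
        rule: map_reference_positions(alignment, rule.ref_seq_id, [rule.ref_position])[0]
        for rule in rules
    }
    rule_names = [
        f"{r.gene}:{r.ref_seq_id}:{r.ref_position}:{''.join(sorted(r.allowed))}"
        for r in rules
    ]
    report_rows = {}
    kept, removed = [], []
    for rec in alignment.records:
        passes = []
        for rule, name in zip(rules, rule_names):
            if rec.seq_id == rule.ref_seq_id:
                passes.append(True)
                continue
            char = rec.sequence[columns[rule] - 1]
            passes.append(char in rule.allowed)
        report_rows[rec.seq_id] = passes
        (kept if all(passes) else removed).append(rec.seq_id)
    report = pd.DataFrame.from_dict(report_rows, orient="index", columns=rule_names)
    logger.info("residue verification: kept %d, removed %d", len(kept), len(removed))
    return CurationResult(kept=kept, removed=removed, report=report)


# ---------------------------------------------------------------------------
# synteny verification

LOCUS_COLUMNS = ("genome_id", "contig_id", "locus_index", "gene_label", "seq_id")


def read_locus_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus_index": int})
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    for _, grp in df.groupby(["genome_id", "contig_id"]):
        idx = grp["locus_index"].to_numpy()
        if not (idx[1:] > idx[:-1]).all():
            grp = grp.sort_values("locus_index")
            if grp["locus_index"].duplicated().any():
                raise ValueError("locus_index not strictly increasing within a contig")
    return df


@dataclass
class SyntenyResult:
    kept: list[str]
    removed: list[str]
    unverifiable: list[str]  # candidates absent from the locus table


def verify_by_neighborhood(
    loci: pd.DataFrame,
    candidates: Iterable[str],
    companion_genes: set[str],
    window: int = 10,
) -> SyntenyResult:
    """Keep candidate sequences with a companion phosphonate gene nearby.

    A candidate is kept iff a locus labelled with a companion gene lies on
    the same contig within ``window`` locus ranks.  Candidates absent from
    the locus table cannot be verified and are excluded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_seq = loci.set_index("seq_id")
    kept, removed, unverifiable = [], [], []
    for cand in candidates:
        if cand not in by_seq.index:
            unverifiable.append(cand)
            continue
        row = by_seq.loc[cand]
        contig = loci[
            (loci["genome_id"] == row["genome_id"])
            & (loci["contig_id"] == row["contig_id"])
        ]
        near = contig[
            contig["gene_label"].isin(companion_genes)
            & ((contig["locus_index"] - int(row["locus_index"])).abs() <= window)
        ]
        (kept if len(near) else removed).append(cand)
    if unverifiable:
        logger.warning("synteny: %d candidates absent from locus table", len(unverifiable))
    return SyntenyResult(kept=kept, removed=removed, unverifiable=unverifiable)


# ---------------------------------------------------------------------------
# dereplication

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the shorter sequence length.

    The match count is the maximum number of identical aligned residue pairs
    over all global alignments (a longest-common-subsequence recurrence),
    which makes the identity deterministic — no dependence on which of
    several co-optimal alignment tracebacks a particular aligner reports.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    row = np.zeros(len(b) + 1, dtype=np.int32)
    for ch in a.encode():
        # row[j] = max(prev[j], prev[j-1] + match_j, row[j-1]); the running
        # max over j is a prefix maximum since LCS rows are nondecreasing
        extended = np.where(arr_b == ch, prev[:-1] + 1, 0)
        row[1:] = np.maximum.accumulate(np.maximum(prev[1:], extended))
        prev, row = row, prev
    matches = int(prev[-1])
    return matches / min(len(a), len(b))


def dereplicate(
    db: GeneDatabase, threshold: float = 0.99
) -> tuple[GeneDatabase, ClusterSet]:
    """Greedy longest-first clustering at a fractional identity threshold.

    Sequences are processed longest-first (ties broken lexicographically by
    seq_id); each joins the first existing cluster (in creation order) whose
    representative it matches at >= threshold identity, else founds a new
    cluster.  The nr database consists of the representatives, retaining
    each cluster's full member genome set for genome accounting.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not db.records:
        warnings.warn(f"dereplicating empty database {db.gene}")
        return (
            GeneDatabase(gene=db.gene, records=[], redundant=False, member_genomes={}),
            ClusterSet(clusters=[], threshold=threshold),
        )

    order = sorted(db.records, key=lambda r: (-r.length_aa, r.seq_id))
    reps: list[ProteinRecord] = []
    members: list[list[ProteinRecord]] = []
    for rec in order:
        seq = _ungapped(rec.sequence)
        for i, rep in enumerate(reps):
            if pairwise_identity(_ungapped(rep.sequence), seq) >= threshold:
                members[i].append(rec)
                break
        else:
            reps.append(rec)
            members.append([rec])

    clusters = ClusterSet(
        clusters=[
            (rep.seq_id, [m.seq_id for m in mem]) for rep, mem in zip(reps, members)
        ],
        threshold=threshold,
    )
    member_genomes = {
        rep.seq_id: frozenset(m.genome_id for m in mem)
        for rep, mem in zip(reps, members)
    }
    nr = GeneDatabase(
        gene=db.gene, records=list(reps), redundant=False, member_genomes=member_genomes
    )
    logger.info("dereplicated %s: %d -> %d at %.0f%%",
                db.gene, db.n_sequences, nr.n_sequences, threshold * 100)
    return nr, clusters


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    rows = [
        {"representative": rep, "member": m}
        for rep, mem in clusters.clusters
        for m in mem
    ]
    pd.DataFrame(rows, columns=["representative", "member"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# normalization factors & presence matrix


def compute_normalization_factors(
    nr_dbs: Mapping[str, GeneDatabase]
) -> NormalizationFactors:
    """Copy-number and length factors for each nr database.

    The study-wide mean length is over the union of all sequences in all
    supplied phosphonate databases (markers excluded by construction: pass
    only the phosphonate families here).
    """
    for gene, db in nr_dbs.items():
        if not db.records:
            raise ValueError(f"empty database for gene {gene}")
    lengths = [r.length_aa for db in nr_dbs.values() for r in db.records]
    study_mean = sum(lengths) / len(lengths)
    rows = {}
    for gene, db in nr_dbs.items():
        mean_len = db.mean_length_aa
        rows[gene] = {
            "cn_factor": db.n_genomes / db.n_sequences,
            "len_factor": study_mean / mean_len,
            "mean_length_aa": mean_len,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return NormalizationFactors(table=table, study_mean_length_aa=study_mean)


def presence_matrix(redundant_dbs: Iterable[GeneDatabase]) -> pd.DataFrame:
    """Genome x gene boolean matrix: True iff the genome contributes at least
    one sequence to that gene's redundant database."""
    dbs = list(redundant_dbs)
    genes = [db.gene for db in dbs]
    genomes = sorted({r.genome_id for db in dbs for r in db.records})
    mat = pd.DataFrame(False, index=genomes, columns=genes)
    for db in dbs:
        for rec in db.records:
            mat.loc[rec.genome_id, db.gene] = True
    mat.index.name = "genome_id"
    return mat
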