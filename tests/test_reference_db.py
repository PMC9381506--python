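"""Reference-database curation: loading, residue rules, synteny, dereplication,
normalization factors, and the presence matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment, make_db, make_record, make_rule
from phoscycle.genes import AMINO_ACIDS
from phoscycle.reference_db import (
    GeneDatabase,
    apply_residue_rules,
    compute_normalization_factors,
    dereplicate,
    load_database,
    map_reference_positions,
    pairwise_identity,
    presence_matrix,
    read_locus_table,
    verify_by_neighborhood,
)


# ---------------------------------------------------------------------------
# loading


def _write_db(tmp_path, records, meta_rows=None):
    fasta = tmp_path / "db.fasta"
    fasta.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in records))
    meta = tmp_path / "db.tsv"
    if meta_rows is None:
        meta_rows = [
            {"seq_id": sid, "gene": "pepM", "genome_id": f"G{i}"}
            for i, (sid, _) in enumerate(records)
        ]
    pd.DataFrame(meta_rows).to_csv(meta, sep="\t", index=False)
    return fasta, meta


def test_load_database_counts_sequences_and_genomes(tmp_path):
    fasta, meta = _write_db(tmp_path, [("a", "MKV"), ("b", "MKL"), ("c", "MKI")])
    db = load_database(fasta, meta)
    assert db.n_sequences == 3
    assert db.n_genomes == 3
    assert db.records[0].length_aa == 3


def test_load_database_shared_genome_counted_once(tmp_path):
    rows = [
        {"seq_id": "a", "gene": "pepM", "genome_id": "G1"},
        {"seq_id": "b", "gene": "pepM", "genome_id": "G1"},
    ]
    fasta, meta = _write_db(tmp_path, [("a", "MKV"), ("b", "MKL")], rows)
    db = load_database(fasta, meta)
    assert (db.n_sequences, db.n_genomes) == (2, 1)


def test_load_database_duplicate_fasta_id_is_error(tmp_path):
    fasta, meta = _write_db(tmp_path, [("a", "MKV"), ("a", "MKL")])
    with pytest.raises(ValueError, match="duplicate"):
        load_database(fasta, meta)


def test_load_database_metadata_mismatch_beyond_tolerance(tmp_path):
    rows = [{"seq_id": "a", "gene": "pepM", "genome_id": "G1"}]
    fasta, meta = _write_db(tmp_path, [("a", "MKV"), ("b", "MKL")], rows)
    with pytest.raises(ValueError, match="missing from metadata"):
        load_database(fasta, meta)
    db = load_database(fasta, meta, max_missing_frac=0.5)
    assert db.n_sequences == 1


def test_load_database_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_database(tmp_path / "absent.fasta", tmp_path / "absent.tsv")


# ---------------------------------------------------------------------------
# reference position mapping


@pytest.mark.parametrize(
    "anchor,positions,expected",
    [
        ("AC-DE", [3], [4]),  # gap before the mapped residue
        ("ACDE", [1, 2, 3, 4], [1, 2, 3, 4]),  # identity without gaps
        ("-A-C", [1, 2], [2, 4]),  # leading gap
        ("A--CD", [2, 3], [4, 5]),
    ],
)
def test_map_reference_positions(anchor, positions, expected):
    aln = make_alignment({"ref": anchor, "other": "X" * len(anchor)})
    assert map_reference_positions(aln, "ref", positions) == expected


def test_map_reference_positions_errors():
    aln = make_alignment({"ref": "AC-DE"})
    with pytest.raises(ValueError, match="exceeds ungapped length"):
        map_reference_positions(aln, "ref", [5])
    with pytest.raises(KeyError):
        map_reference_positions(aln, "missing", [1])


# ---------------------------------------------------------------------------
# residue rules


def test_apply_residue_rules_match_mismatch_gap():
    aln = make_alignment(
        {"ref": "ACWDE", "good": "GGGDG", "bad": "GGGNG", "gapped": "GGG-G"}
    )
    rule = make_rule("ref", 4, "DE")
    result = apply_residue_rules(aln, [rule])
    assert set(result.kept) == {"ref", "good"}
    assert set(result.removed) == {"bad", "gapped"}
    assert not result.report.loc["bad"].all()


def test_apply_residue_rules_anchor_always_passes_own_rule():
    # the anchor's own residue is not in `allowed` (rule transplanted from
    # elsewhere), yet the anchor is retained by definition
    aln = make_alignment({"ref": "AAAA", "other": "AADA"})
    result = apply_residue_rules(aln, [make_rule("ref", 3, "D")])
    assert "ref" in result.kept
    assert "other" in result.kept


def test_apply_residue_rules_requires_rules():
    aln = make_alignment({"a": "ACDE"})
    with pytest.raises(ValueError, match="empty rule"):
        apply_residue_rules(aln, [])
    result = apply_residue_rules(aln, [], allow_empty_rules=True)
    assert result.kept == ["a"]


@settings(deadline=None)
@given(st.data())
def test_apply_residue_rules_partitions_input(data):
    n_cols = data.draw(st.integers(4, 8))
    n_seqs = data.draw(st.integers(2, 6))
    alphabet = "ACDG-"
    rows = {"ref": "".join(data.draw(st.sampled_from("ACDG")) for _ in range(n_cols))}
    for i in range(n_seqs - 1):
        rows[f"s{i}"] = "".join(
            data.draw(st.sampled_from(alphabet)) for _ in range(n_cols)
        )
    aln = make_alignment(rows)
    rules = [
        make_rule("ref", data.draw(st.integers(1, n_cols)), data.draw(st.sampled_from("ACDG")))
        for _ in range(data.draw(st.integers(1, 3)))
    ]
    result = apply_residue_rules(aln, rules)
    assert sorted(result.kept + result.removed) == sorted(rows)
    assert not set(result.kept) & set(result.removed)


# ---------------------------------------------------------------------------
# synteny


def _loci(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "contig_id", "locus_index", "gene_label", "seq_id"]
    )


def test_verify_by_neighborhood_within_window():
    loci = _loci([
        ("G1", "c1", 10, "phpC", "cand"),
        ("G1", "c1", 12, "phnW", "comp"),
    ])
    res = verify_by_neighborhood(loci, ["cand"], {"phnW"}, window=5)
    assert res.kept == ["cand"]


def test_verify_by_neighborhood_outside_window_and_contig():
    loci = _loci([
        ("G1", "c1", 10, "phpC", "far"),
        ("G1", "c1", 30, "phnW", "comp1"),
        ("G1", "c2", 11, "phpC", "other_contig"),
        ("G1", "c3", 12, "phnW", "comp2"),
    ])
    res = verify_by_neighborhood(loci, ["far", "other_contig"], {"phnW"}, window=5)
    assert res.kept == []
    assert set(res.removed) == {"far", "other_contig"}


def test_verify_by_neighborhood_unverifiable_candidate():
    loci = _loci([("G1", "c1", 10, "phpC", "cand")])
    res = verify_by_neighborhood(loci, ["ghost"], {"phnW"}, window=5)
    assert res.unverifiable == ["ghost"]
    assert res.kept == []


def test_read_locus_table_roundtrip(tmp_path):
    loci = _loci([("G1", "c1", 1, "phpC", "a"), ("G1", "c1", 3, "phnW", "b")])
    path = tmp_path / "loci.tsv"
    loci.to_csv(path, sep="\t", index=False)
    assert len(read_locus_table(path)) == 2


# ---------------------------------------------------------------------------
# dereplication


def _lcs_oracle(a: str, b: str) -> float:
    """Independent quadratic LCS identity (pure python)."""
    la, lb = len(a), len(b)
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            dp[i][j] = (
                dp[i - 1][j - 1] + 1
                if a[i - 1] == b[j - 1]
                else max(dp[i - 1][j], dp[i][j - 1])
            )
    return dp[la][lb] / min(la, lb)


def _greedy_oracle(records, threshold):
    """Brute-force greedy clustering with exhaustively computed identities."""
    order = sorted(records, key=lambda r: (-len(r.sequence), r.seq_id))
    clusters: list[tuple[str, str, list[str]]] = []  # (rep_id, rep_seq, members)
    for rec in order:
        for rep_id, rep_seq, members in clusters:
            if _lcs_oracle(rep_seq, rec.sequence) >= threshold:
                members.append(rec.seq_id)
                break
        else:
            clusters.append((rec.seq_id, rec.sequence, [rec.seq_id]))
    return {rep: sorted(m) for rep, _, m in clusters}


@pytest.mark.parametrize(
    "a,b,expected",
    [("ACDE", "ACDE", 1.0), ("ACDE", "ACDF", 0.75), ("AAAA", "AA", 1.0)],
)
def test_pairwise_identity_simple_cases(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_matches_independent_dp():
    rng = np.random.default_rng(11)
    for _ in range(25):
        a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 40)))
        b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 40)))
        assert pairwise_identity(a, b) == pytest.approx(_lcs_oracle(a, b))


def test_dereplicate_identical_sequences_merge():
    db = make_db([("a", "M" * 100, "G1"), ("b", "M" * 100, "G2")])
    nr, clusters = dereplicate(db, threshold=0.99)
    assert nr.n_sequences == 1
    assert clusters.clusters[0][1] == ["a", "b"]
    assert nr.member_union_genomes == {"G1", "G2"}


def test_dereplicate_below_threshold_stays_split():
    base = list("ACDEFGHIKL" * 10)
    other = list(base)
    other[0], other[50] = "W", "W"  # 98 % identity
    db = make_db([("a", "".join(base), "G1"), ("b", "".join(other), "G2")])
    nr, _ = dereplicate(db, threshold=0.99)
    assert nr.n_sequences == 2


def test_dereplicate_empty_database_warns():
    db = GeneDatabase(gene="pepM", records=[])
    with pytest.warns(UserWarning):
        nr, clusters = dereplicate(db)
    assert nr.n_sequences == 0 and clusters.clusters == []


def test_dereplicate_threshold_bounds():
    db = make_db([("a", "ACDE", "G1")])
    with pytest.raises(ValueError):
        dereplicate(db, threshold=0.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("threshold", [0.6, 0.9, 1.0])
def test_dereplicate_matches_bruteforce_oracle(seed, threshold):
    """Greedy clustering equals the brute-force oracle on random instances."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list(AMINO_ACIDS), size=40)
    records = []
    for i in range(30):
        seq = base.copy()
        n_mut = rng.integers(0, 18)
        pos = rng.choice(40, size=n_mut, replace=False)
        for p in pos:
            seq[p] = AMINO_ACIDS[rng.integers(20)]
        records.append(make_record(f"s{i:02d}", "".join(seq), genome_id=f"G{i}"))
    db = GeneDatabase(gene="pepM", records=records)
    nr, clusters = dereplicate(db, threshold=threshold)
    expected = _greedy_oracle(records, threshold)
    got = {rep: sorted(m) for rep, m in clusters.clusters}
    assert got == expected
    assert {r.seq_id for r in nr.records} == set(expected)


def test_dereplicate_threshold_one_merges_only_exact_duplicates():
    db = make_db(
        [("a", "ACDEACDE", "G1"), ("b", "ACDEACDE", "G2"), ("c", "ACDEACDW", "G3")]
    )
    nr, _ = dereplicate(db, threshold=1.0)
    assert nr.n_sequences == 2


# ---------------------------------------------------------------------------
# normalization factors


def test_cn_factor_single_copy_and_two_copy():
    single = make_db([(f"s{i}", "M" * 10, f"G{i}") for i in range(6)])
    double = make_db([(f"s{i}", "M" * 10, f"G{i % 5}") for i in range(10)], gene="phnM")
    factors = compute_normalization_factors({"pepM": single, "phnM": double})
    assert factors.cn_factor("pepM") == 1.0
    assert factors.cn_factor("phnM") == 0.5


def test_len_factors_direct_arithmetic():
    db300 = make_db([(f"a{i}", "M" * 300, f"G{i}") for i in range(10)])
    db600 = make_db([(f"b{i}", "M" * 600, f"H{i}") for i in range(10)], gene="phnJ")
    factors = compute_normalization_factors({"pepM": db300, "phnJ": db600})
    assert factors.study_mean_length_aa == pytest.approx(450.0)
    assert factors.len_factor("pepM") == pytest.approx(1.5)
    assert factors.len_factor("phnJ") == pytest.approx(0.75)


def test_empty_database_raises_with_gene_name():
    with pytest.raises(ValueError, match="phnZ"):
        compute_normalization_factors(
            {"phnZ": GeneDatabase(gene="phnZ", records=[])}
        )


def test_len_factor_weighted_average_is_identity():
    """Size-weighted mean of mean_length*len_factor recovers the study mean."""
    rng = np.random.default_rng(5)
    dbs = {}
    for g, n, L in [("pepM", 4, 200), ("phnZ", 7, 350), ("phnJ", 3, 500)]:
        dbs[g] = make_db(
            [(f"{g}{i}", "M" * int(L + rng.integers(-20, 20)), f"G{g}{i}") for i in range(n)],
            gene=g,
        )
    f = compute_normalization_factors(dbs)
    num = sum(
        db.n_sequences * db.mean_length_aa * f.len_factor(g) for g, db in dbs.items()
    )
    den = sum(db.n_sequences for db in dbs.values())
    assert num / den == pytest.approx(f.study_mean_length_aa)


@pytest.mark.parametrize("k", [2, 3])
def test_cn_factor_duplication_property(k):
    """Duplicating sequences alone divides cn_factor by k; duplicating genomes
    alongside leaves it invariant."""
    base = [(f"s{i}", "M" * 50, f"G{i}") for i in range(5)]
    f0 = compute_normalization_factors({"pepM": make_db(base)}).cn_factor("pepM")
    seq_dup = make_db(
        [(f"s{i}_{t}", "M" * 50, f"G{i}") for i in range(5) for t in range(k)]
    )
    both_dup = make_db(
        [(f"s{i}_{t}", "M" * 50, f"G{i}_{t}") for i in range(5) for t in range(k)]
    )
    assert compute_normalization_factors({"pepM": seq_dup}).cn_factor("pepM") == pytest.approx(f0 / k)
    assert compute_normalization_factors({"pepM": both_dup}).cn_factor("pepM") == pytest.approx(f0)


def test_factors_tsv_roundtrip(tmp_path):
    db = make_db([("a", "M" * 100, "G1"), ("b", "M" * 200, "G2")])
    f = compute_normalization_factors({"pepM": db})
    path = tmp_path / "factors.tsv"
    f.to_tsv(path)
    from phoscycle.reference_db import NormalizationFactors

    g = NormalizationFactors.from_tsv(path)
    assert g.cn_factor("pepM") == pytest.approx(f.cn_factor("pepM"))
    assert g.study_mean_length_aa == pytest.approx(f.study_mean_length_aa)


# ---------------------------------------------------------------------------
# presence matrix


def test_presence_matrix_direct_construction():
    pepm = make_db([("p1", "MK", "G1")], gene="pepM")
    aepy = make_db([("a1", "MK", "G1"), ("a2", "MK", "G2")], gene="aepY")
    mat = presence_matrix([pepm, aepy])
    assert mat.loc["G1"].tolist() == [True, True]
    assert mat.loc["G2"].tolist() == [False, True]


def test_presence_matrix_empty_input():
    assert presence_matrix([]).empty


def test_presence_matrix_column_sums_equal_genome_counts():
    rng = np.random.default_rng(2)
    dbs = []
    for g in ["pepM", "aepY", "phnZ"]:
        n = int(rng.integers(3, 7))
        genomes = rng.choice([f"G{i}" for i in range(6)], size=n, replace=False)
        dbs.append(make_db([(f"{g}{i}", "MK", gid) for i, gid in enumerate(genomes)], gene=g))
    mat = presence_matrix(dbs)
    for db in dbs:
        assert mat[db.gene].sum() == db.n_genomes
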