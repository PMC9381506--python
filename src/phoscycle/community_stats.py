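"""Statistical layer: co-occurrence, diversity, ANOVA/Tukey, regression,
Bray-Curtis, and ANOSIM.

Co-occurrence works on the genome x gene presence matrix of the redundant
databases: cell(src, co) is the fraction of genomes carrying the source
gene that also carry the co-occurring gene (asymmetric because the source
genome sets differ).  Database taxonomic diversity is summarized by the
Shannon index over class labels with Pielou evenness J = H / ln(S).

Sample-level comparisons use one-way ANOVA with Tukey HSD post-hoc tests,
ordinary least squares of log relative abundance on log phosphate (with a
0.01 umol/L pseudocount so below-detection samples stay in the model), and
Bray-Curtis dissimilarities with a rank-based ANOSIM permutation test for
group separation.  Natural logarithms are used throughout; the log base
does not affect any p-value, only the regression slope scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# co-occurrence


@dataclass
class CooccurrenceMatrix:
    """fractions[src, co] = P(genome has co | genome has src); n_source per gene."""

    fractions: pd.DataFrame  # index = source gene, columns = co gene
    n_source: pd.Series  # per source gene, number of genomes carrying it
    undefined: list[str]  # genes with zero source genomes


def cooccurrence_matrix(presence: pd.DataFrame) -> CooccurrenceMatrix:
    """Asymmetric genome co-occurrence fractions from a boolean presence matrix."""
    if presence.empty:
        raise ValueError("empty presence matrix")
    P = presence.astype(bool)
    genes = list(P.columns)
    n_source = P.sum(axis=0)
    # |genomes with src AND co| for all pairs in one matrix product
    both = P.T.astype(int) @ P.astype(int)
    frac = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    undefined = [g for g in genes if n_source[g] == 0]
    for src in genes:
        if n_source[src] > 0:
            frac.loc[src] = both.loc[src] / n_source[src]
    if undefined:
        logger.warning("co-occurrence undefined for source genes: %s", undefined)
    frac.index.name = "source_gene"
    return CooccurrenceMatrix(
        fractions=frac, n_source=n_source.astype(int), undefined=undefined
    )


def cooccurrence_long(co: CooccurrenceMatrix) -> pd.DataFrame:
    """Long-format co-occurrence table: source_gene, co_gene, fraction, n_source."""
    long = co.fractions.stack(future_stack=True).reset_index()
    long.columns = ["source_gene", "co_gene", "fraction"]
    long["n_source"] = long["source_gene"].map(co.n_source)
    return long


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversitySummary:
    """Shannon index H (natural log), class count S, Pielou evenness J = H/ln S
    (undefined when S = 1), and the class frequency spectrum."""

    H: float
    S: int
    J: float | None
    class_fractions: dict[str, float]


def shannon_evenness(labels: Sequence[str] | Mapping[str, int]) -> DiversitySummary:
    """Shannon index and Pielou evenness of a label tally.

    Accepts either a sequence of labels (one per sequence) or a mapping
    label -> multiplicity.
    """
    if isinstance(labels, Mapping):
        counts = {k: int(v) for k, v in labels.items() if v > 0}
    else:
        counts = dict(pd.Series(list(labels)).value_counts())
    if not counts:
        raise ValueError("need at least one label")
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    H = -sum(p * math.log(p) for p in fractions.values() if p > 0)
    S = len(counts)
    J = H / math.log(S) if S > 1 else None
    return DiversitySummary(H=H, S=S, J=J, class_fractions=fractions)


# ---------------------------------------------------------------------------
# ANOVA & Tukey HSD


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: list[float]


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way between/within variance decomposition."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate: zero total variance")
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = len(pooled)
    return AnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=n - k,
        p=float(p),
        group_means=[float(a.mean()) for a in arrays],
    )


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD comparisons (Tukey-Kramer for unbalanced groups)."""

    table: pd.DataFrame  # columns: group_i, group_j, mean_diff, q, p_adj
    ms_within: float
    df_within: int

    def p_adj(self, i: int, j: int) -> float:
        t = self.table
        row = t[((t.group_i == i) & (t.group_j == j)) | ((t.group_i == j) & (t.group_j == i))]
        if row.empty:
            raise KeyError(f"no comparison for pair ({i}, {j})")
        return float(row["p_adj"].iloc[0])


def tukey_hsd(groups: Sequence[Sequence[float]]) -> TukeyResult:
    """All-pairs Tukey HSD.

    q_ij = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)); adjusted
    p from the studentized-range distribution with k groups and the within
    degrees of freedom.
    """
    anova = one_way_anova(groups)  # validates input
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    ns = [len(a) for a in arrays]
    means = [a.mean() for a in arrays]
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_within = anova.df_within
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("degenerate: zero within-group variance")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = math.sqrt(ms_within / 2 * (1 / ns[i] + 1 / ns[j]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
            rows.append(
                {"group_i": i, "group_j": j, "mean_diff": diff, "q": q,
                 "p_adj": min(1.0, p_adj)}
            )
    return TukeyResult(
        table=pd.DataFrame(rows), ms_within=float(ms_within), df_within=df_within
    )


# ---------------------------------------------------------------------------
# log-log phosphate regression


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    r_squared: float
    n: int
    pseudocount: float
    n_excluded_missing: int
    n_excluded_zero: int


def loglog_pi_regression(
    abundance: Sequence[float],
    phosphate_umol_L: Sequence[float],
    pseudocount: float = 0.01,
) -> RegressionResult:
    """OLS of ln(relative abundance) on ln(phosphate + pseudocount).

    The pseudocount (default 0.01 umol/L) keeps samples with phosphate
    below the detection limit in the model.  Samples with missing phosphate
    or zero abundance are excluded and counted.
    """
    a = np.asarray(abundance, dtype=float)
    pi = np.asarray(phosphate_umol_L, dtype=float)
    if a.shape != pi.shape:
        raise ValueError("abundance and phosphate must have equal length")
    missing = np.isnan(pi)
    if missing.all():
        raise ValueError("all phosphate values missing")
    zero = (a <= 0) & ~missing
    keep = ~missing & ~zero
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 usable samples, have {n}")
    if zero.any():
        logger.info("regression: excluded %d zero-abundance samples", int(zero.sum()))
    x = np.log(pi[keep] + pseudocount)
    y = np.log(a[keep])
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_p=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        n=n,
        pseudocount=pseudocount,
        n_excluded_missing=int(missing.sum()),
        n_excluded_zero=int(zero.sum()),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis & ANOSIM


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix from a samples x genes table.

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i), in [0, 1].
    """
    X = abundance.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = abundance.index[(X.sum(axis=1) == 0)].tolist()
    if zero_rows:
        raise ValueError(f"all-zero samples have undefined dissimilarity: {zero_rows}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=abundance.index, columns=abundance.index)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray) -> float:
    n_pairs = len(ranks)
    r_within = ranks[same_group].mean()
    r_between = ranks[~same_group].mean()
    return (r_between - r_within) / (n_pairs / 2)


def anosim(
    dist: pd.DataFrame | np.ndarray,
    group_labels: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
) -> AnosimResult:
    """Rank-based permutation test of group separation in a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/4), with
    ranks (mid-ranks for ties) over all M = n(n-1)/2 pairwise distances.
    p uses the add-one estimator (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    With ``exhaustive=True`` all n! label permutations are enumerated (small
    n only) and p is the exact fraction with R_perm >= R_obs (the identity
    permutation included).
    """
    if seed is None and not exhaustive:
        raise ValueError("anosim requires an explicit seed for reproducibility")
    D = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(group_labels)
    if len(labels) != n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with a single member: {small}")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(D[iu, ju])  # mid-ranks for ties
    observed = _anosim_r(ranks, labels[iu] == labels[ju])

    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration is limited to n <= 9 samples")
        perms = np.array(list(itertools.permutations(range(n))))
        n_permutations = len(perms)
        permuted_labels = labels[perms]
        same = permuted_labels[:, iu] == permuted_labels[:, ju]
        n_pairs = len(ranks)
        r_within = (ranks * same).sum(axis=1) / same.sum(axis=1)
        r_between = (ranks * ~same).sum(axis=1) / (~same).sum(axis=1)
        r_perm = (r_between - r_within) / (n_pairs / 2)
        p = int((r_perm >= observed - 1e-12).sum()) / n_permutations
        return AnosimResult(
            R=float(observed), p=float(p), n_permutations=n_permutations,
            seed=seed if seed is not None else 0,
        )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    permuted_labels = labels[perms]  # (n_perm, n)
    same = permuted_labels[:, iu] == permuted_labels[:, ju]  # (n_perm, n_pairs)
    n_pairs = len(ranks)
    r_within = (ranks * same).sum(axis=1) / same.sum(axis=1)
    r_between = (ranks * ~same).sum(axis=1) / (~same).sum(axis=1)
    r_perm = (r_between - r_within) / (n_pairs / 2)
    p = (1 + int((r_perm >= observed - 1e-12).sum())) / (1 + n_permutations)
    return AnosimResult(
        R=float(observed), p=float(p), n_permutations=n_permutations, seed=seed
    )
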