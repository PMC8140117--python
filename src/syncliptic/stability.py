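"""Downstream statistics for the RNA-stability time course and RNA-seq sets.

Covers expression filtering, a two-group negative-binomial differential test
with BH-FDR, correlation-based hierarchical clustering of 4-time-point decay
profiles (distance (1 - R)/2, average linkage, tree cut at k = 3),
set-enrichment (one-sided hypergeometric) and association (Pearson
chi-square with minimum-expected-count exclusion) tests, binding-location
majority classes, transcript-feature length comparisons, and QC PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _nb
from .io import CountMatrix, GenomeAnnotation
from .manorm import tmm_factors


# ---------------------------------------------------------------------------
# expression filters


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million, using the matrix's library sizes."""
    if (counts.lib_size <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.counts / counts.lib_size * 1e6


def filter_expressed(counts: CountMatrix, rule: str = "armor", **params) -> pd.Index:
    """Genes passing one of the expression filters used across the analyses.

    rules:
      - ``armor``: cpm >= min_count / median(lib size) * 1e6 in at least
        ``min_samples`` samples, and total count >= ``min_total``
        (defaults 10 / 4 / 15).
      - ``count_fraction``: raw count > ``threshold`` in at least a
        ``fraction`` of the samples (defaults 10, 2/3).
      - ``cpm_all``: cpm >= ``threshold`` in every sample (default 1).
    """
    X = counts.counts
    if rule == "armor":
        min_count = params.get("min_count", 10)
        min_samples = params.get("min_samples", 4)
        min_total = params.get("min_total", 15)
        threshold = min_count / np.median(counts.lib_size) * 1e6
        ok = (cpm(counts) >= threshold).sum(axis=1) >= min_samples
        ok &= X.sum(axis=1) >= min_total
    elif rule == "count_fraction":
        threshold = params.get("threshold", 10)
        fraction = params.get("fraction", 2 / 3)
        ok = (X > threshold).sum(axis=1) >= fraction * X.shape[1] - 1e-9
    elif rule == "cpm_all":
        threshold = params.get("threshold", 1)
        ok = (cpm(counts) >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return X.index[ok]


# ---------------------------------------------------------------------------
# two-group NB differential test


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_de_two_group(counts: CountMatrix, groups: Sequence[str]) -> pd.DataFrame:
    """Two-group differential expression with a common NB dispersion.

    Effective library sizes come from TMM; a single dispersion is estimated
    by Cox-Reid adjusted profile likelihood with the two group means
    profiled out per gene, and each gene is tested with a likelihood-ratio
    test of a shared rate against group-specific rates (chi-square, 1 df).
    logFC is log2(mean of group 2 / mean of group 1) in the order the group
    labels first appear.
    """
    groups = np.asarray(groups)
    if groups.size != counts.counts.shape[1]:
        raise ValueError("one group label per sample required")
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    cols = [np.flatnonzero(groups == lv) for lv in levels]
    if any(c.size < 2 for c in cols):
        raise ValueError("each group needs at least two replicates")

    eff = tmm_factors(counts).effective_lib_size.to_numpy()
    offsets = np.log(eff)[None, :]
    X = counts.counts.to_numpy(dtype=float)

    phi, _ = _nb.estimate_dispersion_apl(X, offsets, group_cols=cols)

    ll_null, _ = _nb.loglik_shared(X, np.broadcast_to(offsets, X.shape), phi)
    ll_alt = np.zeros(X.shape[0])
    mus = []
    for c in cols:
        ll, mu = _nb.loglik_shared(X[:, c], np.broadcast_to(offsets[:, c], X[:, c].shape), phi)
        ll_alt += ll
        mus.append(mu)
    stat = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(X.sum(axis=1) == 0, 1.0, p)
    # half-count pseudo-rate keeps logFC finite for groups with all-zero counts
    delta = 0.5 / np.exp(np.mean(np.log(eff)))
    logfc = np.log2(mus[1] + delta) - np.log2(mus[0] + delta)
    return pd.DataFrame(
        {
            "gene_id": counts.counts.index,
            "logFC": logfc,
            "lrt_stat": stat,
            "p": p,
            "q": bh_fdr(p),
            "dispersion": phi,
        }
    ).set_index("gene_id")


def split_by_direction(de: pd.DataFrame, fdr: float = 0.05) -> tuple[pd.Index, pd.Index]:
    """Significant genes split into increased (logFC > 0) and decreased sets."""
    sig = de[de["q"] < fdr]
    return sig.index[sig["logFC"] > 0], sig.index[sig["logFC"] < 0]


# ---------------------------------------------------------------------------
# profile clustering


def correlation_distance(profiles: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distance (1 - Pearson R)/2 between per-gene logFC profiles.

    Returns (distance matrix, mask of degenerate zero-variance profiles).
    Pairs involving a degenerate profile get the uninformative distance 0.5;
    the diagonal is 0.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    sd = X.std(axis=1)
    degenerate = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1))
    denom[degenerate] = 1.0
    U = Xc / denom[:, None]
    R = np.clip(U @ U.T, -1.0, 1.0)
    D = 0.5 * (1.0 - R)
    D[degenerate, :] = 0.5
    D[:, degenerate] = 0.5
    np.fill_diagonal(D, 0.0)
    return D, degenerate


def average_linkage(D: np.ndarray) -> list[tuple[int, int, float, int]]:
    """UPGMA merge sequence of a distance matrix.

    Returns scipy-style rows (cluster_a, cluster_b, distance, size) where
    original points are 0..n-1 and the i-th merge creates cluster n+i.
    Ties are broken by the smallest member index of the candidate pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    dist = {}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[(i, j) if i < j else (j, i)]
                key = (d, min(members[i] + members[j]), min(members[i][0], members[j][0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, a, b = best
        d_ab = dist[(a, b)]
        na, nb = len(members[a]), len(members[b])
        members[next_id] = sorted(members[a] + members[b])
        active.discard(a)
        active.discard(b)
        for k in sorted(active):
            d_ka = dist[(min(a, k), max(a, k))]
            d_kb = dist[(min(b, k), max(b, k))]
            dist[(min(k, next_id), max(k, next_id))] = (na * d_ka + nb * d_kb) / (
                na + nb
            )
        merges.append((a, b, float(d_ab), na + nb))
        active.add(next_id)
        next_id += 1
    return merges


def average_linkage_cut(D: np.ndarray, k: int = 3) -> np.ndarray:
    """Cut the UPGMA tree into k clusters; labels 1..k by smallest member index."""
    n = np.asarray(D).shape[0]
    if k > n or k < 1:
        raise ValueError("k must lie in [1, number of points]")
    merges = average_linkage(D)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    for step, (a, b, _, _) in enumerate(merges[: n - k]):
        members[n + step] = sorted(members[a] + members[b])
        active.discard(a)
        active.discard(b)
        active.add(n + step)
    labels = np.zeros(n, dtype=int)
    for rank, cid in enumerate(sorted(active, key=lambda c: members[c][0]), start=1):
        labels[members[cid]] = rank
    return labels


# ---------------------------------------------------------------------------
# enrichment / association tests


def fisher_one_sided(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k): enrichment of a set of size K
    among n drawn genes from a background of N."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError("inconsistent contingency quantities")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class ChiSquareResult:
    statistic: float | None
    p: float | None
    df: int
    expected: np.ndarray
    excluded: bool


def chi_square_association(
    table: np.ndarray | pd.DataFrame, min_expected: float = 5.0
) -> ChiSquareResult:
    """Pearson chi-square test without continuity correction.

    Tables with any expected cell below ``min_expected`` are excluded from
    testing (statistic and p set to None) rather than reported.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / obs.sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if (expected < min_expected).any():
        return ChiSquareResult(None, None, df, expected, excluded=True)
    x2 = ((obs - expected) ** 2 / expected).sum()
    return ChiSquareResult(
        float(x2), float(stats.chi2.sf(x2, df)), df, expected, excluded=False
    )


# ---------------------------------------------------------------------------
# binding-location classes and feature lengths


def binding_location_class(peak_classes: Sequence[str]) -> str:
    """Majority binding location of one gene's peaks.

    Strict majority of exon / 3'UTR / intron peaks wins; an exact tie
    between exon and any other class is "exon_plus_other"; 5'UTR (and any
    remaining) peaks count within "other".
    """
    if len(peak_classes) == 0:
        raise ValueError("gene has no peaks")
    tally = {"exon": 0, "three_prime_utr": 0, "intron": 0, "other": 0}
    for c in peak_classes:
        tally[c if c in tally else "other"] += 1
    top = max(tally.values())
    winners = [c for c, v in tally.items() if v == top]
    if winners == ["exon"]:
        return "exon"
    if "exon" in winners:
        return "exon_plus_other"
    if winners == ["three_prime_utr"]:
        return "three_prime_utr"
    if winners == ["intron"]:
        return "intron"
    return "exon_plus_other"


def feature_lengths(gene_id: str, annotation: GenomeAnnotation) -> dict[str, int]:
    """Spliced lengths (transcript, CDS, 3'UTR, 5'UTR) of the gene's longest transcript.

    The transcript with maximal total exonic length is used (ties broken by
    transcript id); features a transcript lacks contribute length 0.  The
    lengths satisfy 5'UTR + CDS + 3'UTR = transcript length for coding
    transcripts.
    """
    gene = annotation.genes.get(gene_id)
    if gene is None:
        raise KeyError(f"unknown gene {gene_id!r}")
    tx = sorted(
        gene.transcripts.values(), key=lambda t: (-t.exonic_length, t.transcript_id)
    )[0]
    return {
        "transcript": tx.exonic_length,
        "cds": tx.cds_length,
        "three_prime_utr": sum(e - s for s, e in tx.three_prime_utr),
        "five_prime_utr": sum(e - s for s, e in tx.five_prime_utr),
    }


@dataclass
class LengthTestReport:
    t_stat: float
    t_p: float
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None


def length_tests(
    group_a: np.ndarray,
    group_b: np.ndarray,
    clusters: Mapping[str, np.ndarray] | None = None,
    alternative: str = "greater",
) -> LengthTestReport:
    """One-sided pooled t-test between two length sets, plus ANOVA + Tukey HSD
    across clusters when given.

    ``alternative="greater"`` tests mean(group_a) > mean(group_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    report = LengthTestReport(float(t_stat), float(t_p))
    if clusters is not None:
        names = sorted(clusters)
        samples = [np.asarray(clusters[c], dtype=float) for c in names]
        if any(s.size < 2 for s in samples):
            raise ValueError("each cluster needs at least two observations")
        f, p = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "diff": samples[i].mean() - samples[j].mean(),
                        "p": hsd.pvalue[i, j],
                    }
                )
        report.anova_f = float(f)
        report.anova_p = float(p)
        report.tukey = pd.DataFrame(rows)
    return report


# ---------------------------------------------------------------------------
# QC PCA


def pca_qc(
    log_cpm: pd.DataFrame, top_n: int | None = 1000
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples on the top-variance genes.

    Genes (rows) are ranked by variance across samples (ties broken by gene
    id), the top ``top_n`` retained (all genes when fewer, or top_n=None),
    and components of the gene-centred matrix computed by SVD.  Returns
    (per-sample component scores, explained-variance fractions).
    """
    if log_cpm.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    var = log_cpm.var(axis=1)
    order = sorted(log_cpm.index, key=lambda g: (-var[g], str(g)))
    if top_n is not None:
        order = order[: min(top_n, len(order))]
    X = log_cpm.loc[order].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: no variance to decompose")
    # samples as observations
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    scores = U * S
    frac = S**2 / np.sum(S**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=log_cpm.columns, columns=cols), frac
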