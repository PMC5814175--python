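"""Per-cohort gene-set deregulation statistic with a permutation null.

The statistic compares the median log2 expression of a gene set (e.g. the
GO "cell cycle" members) against the median of all other genes in one
cohort.  Per-gene medians across samples are computed first; the
set-vs-other medians are then taken over genes (the per-gene-median
aggregation; pooling all gene×sample values before the median is available
via ``aggregation="pooled"``).  Because the data are already log2, the
difference of medians is a log2 fold change.

Significance comes two ways: a two-sided Wilcoxon rank-sum test between the
set-member and non-member per-gene medians, and an empirical permutation
null built by re-drawing equally sized random gene sets.  The empirical p
uses the add-one estimator (1 + #{null >= observed}) / (M + 1), so it is
never zero and ties count against significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import DataValidationError, ExpressionDataset, GeneSet

__all__ = [
    "DeregulationResult",
    "PermutationNull",
    "QuantileReference",
    "gene_medians",
    "set_fold_change",
    "ranksum_test",
    "permutation_null",
    "pancancer_rank",
    "quantile_reference",
    "matched_paired_test",
    "cohort_deregulation",
]


@dataclass
class DeregulationResult:
    cohort: str
    n_set: int
    n_other: int
    median_set: float
    median_other: float
    log2_fc: float
    ranksum_p: float
    perm_p: float | None = None
    n_perm: int | None = None
    rank: int | None = None


@dataclass
class PermutationNull:
    observed: float
    null_values: np.ndarray
    p_emp: float
    seed: int


@dataclass
class QuantileReference:
    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise DataValidationError("quantiles must be non-decreasing")


def gene_medians(dataset: ExpressionDataset, cohort: str) -> dict[str, float]:
    """Per-gene median log2 expression within one cohort.

    Missing (NA) entries are excluded; genes with no non-missing
    observation in the cohort are dropped from the result.
    """
    cols = dataset.cohort_columns(cohort)  # raises on unknown cohort
    if cols.shape[1] < 2:
        raise DataValidationError(f"cohort {cohort!r} has fewer than 2 samples")
    med = np.nanmedian(cols, axis=1)
    out: dict[str, float] = {}
    for g, m in zip(dataset.gene_ids, med):
        if np.isfinite(m):
            out[g] = float(m)
    return out


def set_fold_change(
    medians: dict[str, float], gene_set: GeneSet
) -> tuple[float, float, float]:
    """Median-of-set minus median-of-rest on log2 medians.

    Returns (median_set, median_other, log2_fc).  Data are log2, so the
    difference of medians is the log2 fold change of the set against the
    background.
    """
    set_vals = [v for g, v in medians.items() if g in gene_set.members]
    other_vals = [v for g, v in medians.items() if g not in gene_set.members]
    if not set_vals:
        raise DataValidationError(
            f"gene set {gene_set.name!r} shares no genes with the measured matrix"
        )
    if not other_vals:
        raise DataValidationError("no background genes outside the set")
    median_set = float(np.median(set_vals))
    median_other = float(np.median(other_vals))
    return median_set, median_other, median_set - median_other


def ranksum_test(set_values, other_values) -> float:
    """Two-sided Wilcoxon rank-sum p between two groups of values.

    Exact enumeration for small untied samples (both n < 20), otherwise the
    normal approximation with midrank tie handling and continuity
    correction.  Returns 1.0 with no error when every value is tied.
    """
    x = np.asarray(set_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size < 20 and y.size < 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def permutation_null(
    medians: dict[str, float] | np.ndarray,
    set_size: int,
    observed: float,
    M: int = 10_000,
    seed: int = 0,
) -> PermutationNull:
    """Empirical null for the set statistic from random gene relabelings.

    Each of the M iterations draws ``set_size`` genes uniformly without
    replacement from the measured genes and recomputes the median-set minus
    median-rest difference.  p_emp = (1 + #{null >= observed}) / (M + 1).
    """
    values = (
        np.fromiter(medians.values(), dtype=float)
        if isinstance(medians, dict)
        else np.asarray(medians, dtype=float)
    )
    n = values.size
    if set_size >= n:
        raise DataValidationError("set_size must be < number of genes")
    if M < 1:
        raise DataValidationError("M must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(M)
    for i in range(M):
        perm = rng.permutation(n)
        in_set = perm[:set_size]
        out_set = perm[set_size:]
        null[i] = np.median(values[in_set]) - np.median(values[out_set])
    p_emp = (1.0 + np.count_nonzero(null >= observed)) / (M + 1.0)
    return PermutationNull(observed=float(observed), null_values=null, p_emp=float(p_emp), seed=seed)


def exhaustive_permutation_p(values: np.ndarray, set_size: int, observed: float) -> float:
    """Exact permutation p over all C(n, set_size) gene labelings.

    Only feasible for small n; used as the oracle the Monte-Carlo p
    converges to.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    idx = range(n)
    count = 0
    total = 0
    for combo in itertools.combinations(idx, set_size):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        fc = np.median(values[mask]) - np.median(values[~mask])
        if fc >= observed:
            count += 1
        total += 1
    return count / total


def pancancer_rank(results: list[DeregulationResult]) -> list[DeregulationResult]:
    """Rank cohorts by log2 fold change (rank 1 = largest).

    Ties broken by smaller rank-sum p, then lexicographic cohort label.
    Returns the results sorted in rank order with ``rank`` filled in.
    """
    labels = [r.cohort for r in results]
    if len(set(labels)) != len(labels):
        raise DataValidationError("duplicate cohort labels in ranking input")
    if not results:
        raise DataValidationError("need at least one result to rank")
    ordered = sorted(results, key=lambda r: (-r.log2_fc, r.ranksum_p, r.cohort))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def quantile_reference(medians) -> QuantileReference:
    """25/50/75% quantiles of per-gene medians (type-7 linear interpolation)."""
    values = (
        np.fromiter(medians.values(), dtype=float)
        if isinstance(medians, dict)
        else np.asarray(medians, dtype=float)
    )
    if values.size < 4:
        raise DataValidationError("need at least 4 values for quantile reference")
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return QuantileReference(float(q25), float(q50), float(q75))


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Works with midranks, so it remains exact under tied absolute
    differences (which scipy's exact path refuses).
    """
    n = ranks.size
    total = ranks.sum()
    mu = total / 2.0
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2.0**n


def matched_paired_test(tumor, normal) -> tuple[float, int]:
    """Two-sided Wilcoxon signed-rank test on matched tumor/normal values.

    Zero differences are dropped; ties in |difference| get midranks.  Exact
    enumeration of sign assignments for n <= 12 non-zero pairs, normal
    approximation with tie correction above.  Returns (p, direction) where
    direction is the sign of the median paired difference.
    """
    t = np.asarray(tumor, dtype=float)
    c = np.asarray(normal, dtype=float)
    if t.shape != c.shape:
        raise DataValidationError("tumor and normal vectors must pair one-to-one")
    if t.size < 6:
        raise DataValidationError("need at least 6 pairs")
    d = t - c
    direction = int(np.sign(np.median(d)))
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if d.size <= 12:
        p = _signed_rank_exact_p(ranks, w_pos)
    else:
        n = d.size
        mu = n * (n + 1) / 4.0
        # tie-corrected variance of W+
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return min(1.0, float(p)), direction


def cohort_deregulation(
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    cohort: str,
    n_perm: int = 10_000,
    seed: int = 0,
    aggregation: str = "per_gene_median",
) -> tuple[DeregulationResult, PermutationNull]:
    """Full set statistic for one cohort: medians, fold change, both p-values.

    ``aggregation="per_gene_median"`` (default) takes per-gene medians over
    samples first; ``"pooled"`` pools all gene×sample values of each group
    before the median (the alternative reading of the set statistic).
    """
    if aggregation not in ("per_gene_median", "pooled"):
        raise DataValidationError(f"unknown aggregation {aggregation!r}")
    med = gene_medians(dataset, cohort)
    if aggregation == "per_gene_median":
        median_set, median_other, fc = set_fold_change(med, gene_set)
        set_vals = np.array([v for g, v in med.items() if g in gene_set.members])
        other_vals = np.array([v for g, v in med.items() if g not in gene_set.members])
    else:
        cols = dataset.cohort_columns(cohort)
        in_set = np.array([g in gene_set.members for g in dataset.gene_ids])
        set_vals = cols[in_set].ravel()
        set_vals = set_vals[np.isfinite(set_vals)]
        other_vals = cols[~in_set].ravel()
        other_vals = other_vals[np.isfinite(other_vals)]
        if set_vals.size == 0 or other_vals.size == 0:
            raise DataValidationError("empty set or background after pooling")
        median_set = float(np.median(set_vals))
        median_other = float(np.median(other_vals))
        fc = median_set - median_other
    p = ranksum_test(set_vals, other_vals)
    n_set = int(sum(1 for g in med if g in gene_set.members))
    null = permutation_null(med, n_set, fc, M=n_perm, seed=seed)
    result = DeregulationResult(
        cohort=cohort,
        n_set=n_set,
        n_other=len(med) - n_set,
        median_set=median_set,
        median_other=median_other,
        log2_fc=fc,
        ranksum_p=p,
        perm_p=null.p_emp,
        n_perm=n_perm,
    )
    return result, null
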