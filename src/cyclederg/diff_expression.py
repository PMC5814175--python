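"""Treated-vs-control differential expression and over-representation.

Gene-wise testing is a moderated pooled-variance t-test on log2 values
with the fold change taken as the difference of arm means (log2 data, so a
difference is a log2 fold change).  The per-gene pooled variance s_g^2 is
shrunk toward the genome-wide median variance s_0^2 with a fixed prior
weight d0:

    s_mod^2 = (d0 * s_0^2 + d * s_g^2) / (d0 + d),    d = n1 + n2 - 2,

and the statistic fc / sqrt(s_mod^2 (1/n1 + 1/n2)) is referred to a t
distribution with d0 + d degrees of freedom.  This is a gene-wise
simplification of empirical-Bayes moderated statistics: with triplicate
arms a raw per-gene variance has only 4 df and is far too noisy to rank
genes reliably; borrowing strength across genes stabilises it.  The full
empirical-Bayes machinery (estimating d0 and s_0 from the variance
distribution) is deliberately not reproduced, so exact DE lists from
moderated pipelines will differ; the shrinkage target is the median pooled
variance and d0 defaults to 4 (equal weight to the data at triplicates).

Significance calls use Benjamini-Hochberg FDR < 0.05 combined with
|log2FC| > 1; a gene is "up" when log2_fc > 1 and "down" when
log2_fc < -1 at adjusted p < 0.05, otherwise "ns".

Over-representation of a DE gene list in flat gene sets uses the
upper-tail hypergeometric test with Bonferroni correction over the number
of sets actually tested (non-empty overlap with the universe).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import DataValidationError, GeneSet

__all__ = [
    "DEResult",
    "EnrichmentResult",
    "gene_tests",
    "bh_adjust",
    "overlap_sets",
    "hypergeom_enrichment",
]

P_THRESHOLD = 0.05  # BH-adjusted significance cut
FC_THRESHOLD = 1.0  # |log2 fold change| cut


@dataclass
class DEResult:
    gene: str
    log2_fc: float
    t_stat: float
    p: float
    adj_p: float
    status: str  # up | down | ns


@dataclass
class EnrichmentResult:
    term: str
    k: int  # DE genes in term
    K: int  # universe genes in term
    n: int  # DE genes
    N: int  # universe size
    p_hyper: float
    p_bonf: float


def gene_tests(
    treated: np.ndarray,
    control: np.ndarray,
    gene_ids: list[str] | None = None,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    prior_df: float = 4.0,
) -> list[DEResult]:
    """Per-gene moderated pooled-variance t-tests between replicate arms.

    ``treated`` and ``control`` are genes × replicates arrays with >= 2
    replicates each; values are log2.  Each gene's pooled variance is
    shrunk toward the genome-wide median with weight ``prior_df`` (see
    module docstring).  Genes with zero moderated variance and equal means
    are untestable and get p = 1.  All genes are returned.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.ndim != 2 or control.ndim != 2:
        raise DataValidationError("arms must be genes x replicates matrices")
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise DataValidationError("each arm needs at least 2 replicates")
    if treated.shape[0] != control.shape[0]:
        raise DataValidationError("arms must cover the same genes")
    n_genes = treated.shape[0]
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise DataValidationError("gene_ids length must match matrix rows")

    nt, nc = treated.shape[1], control.shape[1]
    mt = treated.mean(axis=1)
    mc = control.mean(axis=1)
    vt = treated.var(axis=1, ddof=1)
    vc = control.var(axis=1, ddof=1)
    log2_fc = mt - mc

    d = nt + nc - 2
    pooled = ((nt - 1) * vt + (nc - 1) * vc) / d
    s0 = float(np.median(pooled))
    v_mod = (prior_df * s0 + d * pooled) / (prior_df + d)
    # keep degenerate all-constant fixtures finite without inventing variance
    v_mod = np.maximum(v_mod, 1e-12)
    df = prior_df + d

    se2 = v_mod * (1.0 / nt + 1.0 / nc)
    t = log2_fc / np.sqrt(se2)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    # untestable: no variance anywhere and no mean difference
    degenerate = (pooled == 0) & (s0 == 0) & (log2_fc == 0)
    pvals = np.where(degenerate | ~np.isfinite(pvals), 1.0, pvals)
    t = np.where(np.isfinite(t), t, 0.0)

    adj = bh_adjust(pvals)
    results = []
    for g, fc, ts, p, ap in zip(gene_ids, log2_fc, t, pvals, adj):
        if ap < p_threshold and fc > fc_threshold:
            status = "up"
        elif ap < p_threshold and fc < -fc_threshold:
            status = "down"
        else:
            status = "ns"
        results.append(DEResult(g, float(fc), float(ts), float(p), float(ap), status))
    return results


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_sets(de_lists: dict[str, set[str]] | list) -> dict[tuple[str, ...], set[str]]:
    """Exact Venn-partition of >= 2 significant-gene lists.

    Returns a mapping from each non-empty combination of list names (the
    lists a gene belongs to) to the genes falling exactly in that region.
    Region sets are pairwise disjoint and their union is the union of the
    inputs.
    """
    if not isinstance(de_lists, dict):
        de_lists = {f"list{i + 1}": set(lst) for i, lst in enumerate(de_lists)}
    names = list(de_lists)
    if len(names) < 2:
        raise DataValidationError("need at least 2 lists for overlaps")
    sets = {k: set(v) for k, v in de_lists.items()}
    regions: dict[tuple[str, ...], set[str]] = {}
    for membership in product((False, True), repeat=len(names)):
        if not any(membership):
            continue
        inside = [nm for nm, m in zip(names, membership) if m]
        outside = [nm for nm, m in zip(names, membership) if not m]
        region = set.intersection(*(sets[nm] for nm in inside))
        for nm in outside:
            region -= sets[nm]
        regions[tuple(inside)] = region
    return regions


def hypergeom_enrichment(
    de_genes: set[str],
    universe: set[str],
    terms: list[GeneSet],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per gene set.

    Terms are intersected with the universe first; terms with no universe
    overlap are excluded from testing and from the Bonferroni multiplier.
    Results are sorted by raw p.
    """
    if not universe:
        raise DataValidationError("universe must be non-empty")
    de = set(de_genes)
    if not de <= universe:
        raise DataValidationError("DE genes must be a subset of the universe")
    N = len(universe)
    n = len(de)
    tested = []
    for term in terms:
        members = term.members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & de)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((term.name, k, K, p))
    m = len(tested)
    results = [
        EnrichmentResult(
            term=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_hyper=p,
            p_bonf=min(1.0, p * m),
        )
        for name, k, K, p in tested
    ]
    results.sort(key=lambda r: (r.p_hyper, r.term))
    return results
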