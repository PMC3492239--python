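"""Positional enrichment of differentially methylated genes along
chromosomes.

For every run of >= 2 consecutive analyzed genes (up to ``max_run``) on a
chromosome, the number of changed genes in the run is compared against the
genome-wide changed fraction with a hypergeometric upper-tail test; the
candidates are Benjamini-Hochberg adjusted and a greedy, most-significant-
first selection returns non-overlapping regions below alpha.

The tail probability P[X >= k] for X ~ Hypergeometric(N, K, n) is computed
in log space (gammaln + logsumexp) so extreme enrichments do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_tail",
    "scan_regions",
    "adjust_and_select",
    "RegionResult",
]


@dataclass(frozen=True)
class RegionResult:
    """One run of consecutive genes with its enrichment statistics."""

    chrom: str
    start: int                 # genomic position of the first gene (1-based)
    end: int                   # genomic position of the last gene
    k: int                     # changed genes in the region
    n: int                     # analyzed genes in the region
    K: int                     # changed genes genome-wide
    N: int                     # analyzed genes genome-wide
    p_raw: float
    p_adj: float = float("nan")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@lru_cache(maxsize=4096)
def _tail_vector(n: int, K: int, N: int) -> np.ndarray:
    """log P[X >= k] for k = 0..n, X ~ Hypergeometric(N, K, n)."""
    kmax = min(n, K)
    k = np.arange(kmax + 1)
    logpmf = (
        _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)
    )
    # suffix logsumexp: tail(k) = logsum(pmf[k:])
    tail = np.empty(n + 2)
    tail[kmax + 1:] = -np.inf
    running = -np.inf
    for i in range(kmax, -1, -1):
        running = np.logaddexp(running, logpmf[i])
        tail[i] = running
    return np.minimum(tail[: n + 1], 0.0)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), log-space computation.

    N = population size, K = successes in the population, n = draws,
    k = observed successes.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(
            f"impossible counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K) and n <= N)"
        )
    if k == 0:
        return 1.0
    return float(np.exp(_tail_vector(n, K, N)[k]))


def _check_sorted(genes: pd.DataFrame) -> None:
    for chrom, sub in genes.groupby("chrom", sort=False):
        if not sub.pos.is_monotonic_increasing:
            raise ValueError(f"gene positions on {chrom} are not sorted")


def scan_regions(
    genes: pd.DataFrame, changed: set, max_run: int = 100
) -> pd.DataFrame:
    """Enumerate candidate regions of consecutive analyzed genes.

    ``genes`` has columns gene, chrom, pos and must be position-sorted
    within each chromosome; ``changed`` is the set of differentially
    methylated gene names.  Every run of length 2..max_run of consecutive
    genes on one chromosome becomes a candidate with its hypergeometric
    upper-tail p-value.

    Returns a DataFrame of candidates (chrom, start, end, k, n, K, N,
    p_raw plus the gene-index span used for overlap resolution).
    """
    if max_run < 2:
        raise ValueError("max_run must be >= 2")
    _check_sorted(genes)
    N = len(genes)
    K = int(genes.gene.isin(changed).sum())
    rows = []
    for chrom, sub in genes.groupby("chrom", sort=False):
        flags = sub.gene.isin(changed).to_numpy().astype(int)
        pos = sub.pos.to_numpy()
        m = len(sub)
        csum = np.concatenate([[0], np.cumsum(flags)])
        for n_run in range(2, min(max_run, m) + 1):
            tail = _tail_vector(n_run, K, N)
            ks = csum[n_run:] - csum[:-n_run]       # changed per window
            ps = np.exp(tail[ks])
            for i0, (kk, pp) in enumerate(zip(ks, ps)):
                rows.append((
                    chrom, int(pos[i0]), int(pos[i0 + n_run - 1]),
                    int(kk), n_run, K, N, float(pp), i0, i0 + n_run - 1,
                ))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "k", "n", "K", "N", "p_raw",
                 "idx_start", "idx_end"],
    )


def adjust_and_select(
    candidates: pd.DataFrame, alpha: float = 0.05, method: str = "bh"
) -> list[RegionResult]:
    """Multiple-testing adjustment and greedy non-overlapping selection.

    All candidates are adjusted together (Benjamini-Hochberg by default,
    ``method='bonferroni'`` available).  Candidates are then taken in
    ascending adjusted-p order, discarding any that overlaps (same
    chromosome, intersecting gene-index span) an already selected region;
    regions with adjusted p < alpha are returned.
    """
    if candidates.empty:
        return []
    mt = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    p_adj = multipletests(candidates.p_raw.to_numpy(), method=mt)[1]
    cand = candidates.assign(p_adj=p_adj)
    cand = cand.sort_values(
        ["p_adj", "p_raw", "chrom", "start", "end"], kind="mergesort"
    )
    selected: list[RegionResult] = []
    spans: dict[str, list[tuple[int, int]]] = {}
    for row in cand.itertuples():
        if row.p_adj >= alpha:
            break
        taken = spans.setdefault(row.chrom, [])
        if any(row.idx_start <= e and s <= row.idx_end for s, e in taken):
            continue
        taken.append((row.idx_start, row.idx_end))
        selected.append(RegionResult(
            chrom=row.chrom, start=row.start, end=row.end,
            k=row.k, n=row.n, K=row.K, N=row.N,
            p_raw=row.p_raw, p_adj=float(row.p_adj),
        ))
    return selected


def regions_to_frame(regions: list[RegionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in regions])


def regions_to_bed9(regions: list[RegionResult]) -> pd.DataFrame:
    """BED9 export for genome-browser display (score = -10*log10 p_adj)."""
    rows = []
    for r in regions:
        score = int(min(1000, round(-10 * np.log10(max(r.p_adj, 1e-100)))))
        rows.append((
            r.chrom, r.start - 1, r.end, f"{r.k}/{r.n}", score, ".",
            r.start - 1, r.end, "178,34,34",
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb",
    ])
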