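"""Correlation statistics for co-variation screening.

Two families of statistics are implemented:

* Kendall tau-b rank correlation with an *exact* one-sided null p-value,
  used to screen candidate partner genes against a seed set at a hard
  threshold pair (tau > r_min AND p <= p_max).  The exact null is the
  permutation distribution of the number of discordant pairs, computed by
  the classical inversion-count recurrence (the number of permutations of n
  items with exactly k inversions), valid for tie-free data.  Tied data
  fall back to the tie-corrected normal approximation.

* Pearson product-moment correlation matrices over all samples, with a
  t-based two-sided significance classification and per-gene counts of
  significant partners.  A ``df = n - 1`` compatibility convention is
  offered alongside the standard ``n - 2`` because published worked
  examples sometimes quote n - 1 degrees of freedom for n samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .iofmt import ExpressionMatrix, GeneSet, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationEdge",
    "CovariationNetwork",
    "CorrelationMatrix",
    "kendall_tau",
    "kendall_pvalue",
    "kendall_test",
    "build_covariation_network",
    "pearson_matrix",
    "classify_significance",
]

#: Largest n for which the exact inversion-count null is used.
EXACT_N_MAX = 60


# ---------------------------------------------------------------------------
# exact Kendall null
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _inversion_counts(n: int) -> tuple[int, ...]:
    """Number of permutations of ``n`` items with exactly k inversions.

    Returns the full table for k = 0 .. n(n-1)/2 as exact integers, via the
    prefix-sum form of the recurrence
    ``c(n, k) = sum_{j=0}^{min(k, n-1)} c(n-1, k-j)``.
    """
    counts = [1]
    for m in range(2, n + 1):
        kmax = m * (m - 1) // 2
        new = [0] * (kmax + 1)
        running = 0
        for k in range(kmax + 1):
            running += counts[k] if k < len(counts) else 0
            if k - m >= 0 and k - m < len(counts):
                running -= counts[k - m]
            new[k] = running
        counts = new
    return tuple(counts)


@lru_cache(maxsize=None)
def _discordant_cdf(n: int) -> tuple[int, ...]:
    """Cumulative inversion counts: #permutations with <= k discordant pairs."""
    counts = _inversion_counts(n)
    out, running = [], 0
    for c in counts:
        running += c
        out.append(running)
    return tuple(out)


def kendall_pvalue(tau: float, n: int) -> float:
    """One-sided upper-tail null probability P(T >= tau) for Kendall's tau.

    For ``n <= 60`` and tie-free data the p-value is exact: the number of
    permutations of n items whose discordant-pair count D satisfies
    ``tau(D) >= tau``, divided by n!.  For larger n a normal approximation
    with variance n(n-1)(2n+5)/18 and a one-unit continuity correction on
    the S = C - D scale is used.
    """
    if abs(tau) > 1 + 1e-12:
        raise ValueError(f"|tau| = {abs(tau)} exceeds 1")
    if n < 3:
        raise ValueError("kendall_pvalue requires n >= 3")
    tau = min(max(tau, -1.0), 1.0)
    m = n * (n - 1) // 2
    if n <= EXACT_N_MAX:
        # tau = 1 - 2 D / m  =>  T >= tau  <=>  D <= (1 - tau) m / 2
        k = math.floor((1.0 - tau) * m / 2.0 + 1e-9)
        k = min(max(k, 0), m)
        cdf = _discordant_cdf(n)
        return cdf[k] / math.factorial(n)
    s = tau * m
    var = n * (n - 1) * (2 * n + 5) / 18.0
    z = (s - 1.0) / math.sqrt(var)  # continuity correction on the S scale
    return float(stats.norm.sf(z))


def _tie_corrected_pvalue(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """One-sided upper-tail p under the tie-corrected normal null for tau-b."""
    n = len(x)

    def tie_terms(v: np.ndarray):
        _, c = np.unique(v, return_counts=True)
        t = c[c > 1]
        v1 = float(np.sum(t * (t - 1) * (2 * t + 5)))
        v2 = float(np.sum(t * (t - 1) * (t - 2)))
        v3 = float(np.sum(t * (t - 1)))
        return v1, v2, v3

    x1, x2, x3 = tie_terms(x)
    y1, y2, y3 = tie_terms(y)
    n0 = n * (n - 1)
    var_s = (
        (n0 * (2 * n + 5) - x1 - y1) / 18.0
        + x2 * y2 / (9.0 * n0 * (n - 2))
        + x3 * y3 / (2.0 * n0)
    )
    denom = math.sqrt((n0 / 2.0 - x3 / 2.0) * (n0 / 2.0 - y3 / 2.0))
    s = tau * denom  # invert tau-b back to the S statistic
    z = (s - 1.0) / math.sqrt(var_s) if var_s > 0 else -math.inf
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Kendall tau-b of two equal-length series (None if either is constant).

    Returns the tie-corrected tau-b; for tie-free data this equals
    (C - D) / (n(n-1)/2).  A zero-variance series makes the coefficient
    undefined: the flagged null result ``None`` is returned rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("kendall_tau requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def kendall_test(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float]:
    """(tau-b, one-sided upper-tail p); exact when tie-free and n <= 60."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tau = kendall_tau(x, y)
    if tau is None:
        return None, 1.0
    tie_free = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    if tie_free and len(x) <= EXACT_N_MAX:
        return tau, kendall_pvalue(tau, len(x))
    return tau, _tie_corrected_pvalue(x, y, tau)


# ---------------------------------------------------------------------------
# co-variation network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationEdge:
    gene1: str
    gene2: str
    tau: float
    p_value: float
    n: int


@dataclass
class CovariationNetwork:
    """Seed-to-gene Kendall edges passing (tau > r_min, p <= p_max)."""

    edges: list[CorrelationEdge]
    r_min: float
    p_max: float
    n_zero_variance: int = 0

    def __len__(self) -> int:
        return len(self.edges)

    def partners_of(self, gene: str) -> list[str]:
        out = []
        for e in self.edges:
            if e.gene1 == gene:
                out.append(e.gene2)
            elif e.gene2 == gene:
                out.append(e.gene1)
        return sorted(set(out))

    def supported_genes(self, seeds: Iterable[str], r_min: float | None = None,
                        p_max: float | None = None) -> set[str]:
        """Non-seed genes with a qualifying edge to at least one seed."""
        seeds = {normalize_symbol(s) for s in seeds}
        r = self.r_min if r_min is None else r_min
        p = self.p_max if p_max is None else p_max
        out: set[str] = set()
        for e in self.edges:
            if e.tau > r and e.p_value <= p:
                if e.gene1 in seeds and e.gene2 not in seeds:
                    out.add(e.gene2)
                elif e.gene2 in seeds and e.gene1 not in seeds:
                    out.add(e.gene1)
        return out


def _pairwise_tau_vs_seeds(values: np.ndarray, seed_rows: np.ndarray):
    """Vectorized tau-b of every gene row against every seed row.

    Uses the sign-matrix identity S = sum_{i<j} sgn(x_i-x_j) sgn(y_i-y_j)
    over the n(n-1)/2 sample pairs.  Returns (tau, S) arrays of shape
    (n_seeds, n_genes).  Assumes columns are samples.
    """
    n = values.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    gsign = np.sign(values[:, iu] - values[:, ju])  # genes x pairs
    ssign = np.sign(seed_rows[:, iu] - seed_rows[:, ju])  # seeds x pairs
    s = ssign @ gsign.T  # seeds x genes
    m = n * (n - 1) / 2.0
    gn = m - np.sum(gsign == 0, axis=1)  # tie-corrected pair counts per gene
    sn = m - np.sum(ssign == 0, axis=1)
    denom = np.sqrt(np.outer(sn, gn))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom > 0, s / denom, 0.0)
    return tau, s


def build_covariation_network(
    matrix: ExpressionMatrix,
    seeds: GeneSet | None = None,
    r_min: float = 0.6,
    p_max: float = 1e-3,
    log2: bool = False,
) -> CovariationNetwork:
    """Kendall co-variation edges between each seed and every candidate gene.

    An edge (seed, gene) is kept when tau-b > ``r_min`` and the one-sided
    upper-tail null p <= ``p_max``.  Zero-variance genes are excluded with a
    logged count.  ``seeds=None`` screens every gene against every other
    (quadratic; intended for small matrices).  Kendall is invariant to the
    optional log2 transform; the switch exists for interface symmetry with
    the Pearson path.
    """
    n_samples = len(matrix.sample_ids)
    if n_samples < 6:
        raise ValueError("co-variation screening requires >= 6 samples")
    values = matrix.values.values.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    genes = np.array(matrix.gene_ids)

    variable = np.ptp(values, axis=1) > 0
    n_zero = int((~variable).sum())
    if n_zero:
        logger.info("excluded %d zero-variance gene(s) from co-variation screen", n_zero)

    if seeds is None:
        seed_names = [g for g, v in zip(genes, variable) if v]
    else:
        seed_names = list(seeds.genes)
        absent = [s for s in seed_names if s not in matrix.values.index]
        if absent:
            raise KeyError(f"seed gene(s) not in expression matrix: {absent}")
    gene_index = {g: i for i, g in enumerate(genes)}
    seed_rows = values[[gene_index[s] for s in seed_names]]
    seed_variable = np.ptp(seed_rows, axis=1) > 0

    cand_mask = variable.copy()
    cand_genes = genes[cand_mask]
    cand_values = values[cand_mask]

    tau_mat, s_mat = _pairwise_tau_vs_seeds(cand_values, seed_rows)

    # tie detection per series: exact path only for tie-free pairs
    def tie_free(v: np.ndarray) -> np.ndarray:
        return np.array([len(np.unique(row)) == len(row) for row in v])

    cand_tf = tie_free(cand_values)
    seed_tf = tie_free(seed_rows)

    edges: list[CorrelationEdge] = []
    seen: set[tuple[str, str]] = set()
    m = n_samples * (n_samples - 1) // 2
    for si, seed in enumerate(seed_names):
        if not seed_variable[si]:
            continue
        taus = tau_mat[si]
        # qualifying tau screen first; p-values only for survivors
        for gi in np.nonzero(taus > r_min)[0]:
            gene = cand_genes[gi]
            if gene == seed:
                continue
            key = (seed, gene) if seed <= gene else (gene, seed)
            if key in seen:
                continue
            tau = float(taus[gi])
            if cand_tf[gi] and seed_tf[si] and n_samples <= EXACT_N_MAX:
                d = (m - int(round(s_mat[si, gi]))) // 2
                p = _discordant_cdf(n_samples)[d] / math.factorial(n_samples)
            else:
                p = _tie_corrected_pvalue(seed_rows[si], cand_values[gi], tau)
            if p <= p_max:
                seen.add(key)
                edges.append(CorrelationEdge(key[0], key[1], tau, float(p), n_samples))
    edges.sort(key=lambda e: (e.gene1, e.gene2))
    return CovariationNetwork(edges=edges, r_min=r_min, p_max=p_max, n_zero_variance=n_zero)


# ---------------------------------------------------------------------------
# Pearson matrices and significance classification
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over samples for a gene set."""

    genes: list[str]
    r: np.ndarray
    n: int
    df_convention: str = "n_minus_2"

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape does not match gene list")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.max(np.abs(r)) > 1 + 1e-10:
            raise ValueError("correlation magnitudes exceed 1")
        self.r = r

    @property
    def df(self) -> int:
        if self.df_convention == "n_minus_2":
            return self.n - 2
        if self.df_convention == "n_minus_1":
            return self.n - 1
        raise ValueError(f"unknown df convention {self.df_convention!r}")


def pearson_matrix(matrix: ExpressionMatrix, genes: GeneSet, log2: bool = False,
                   df_convention: str = "n_minus_2") -> CorrelationMatrix:
    """Pairwise Pearson r of the given genes' FPKM profiles across samples."""
    sub = matrix.subset(genes.genes)
    values = sub.values.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    constant = [g for g, row in zip(sub.index, values) if np.ptp(row) == 0]
    if constant:
        raise ValueError(f"constant gene(s) cannot be correlated: {constant}")
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes=list(sub.index), r=r, n=values.shape[1],
                             df_convention=df_convention)


def critical_r(alpha: float, df: int) -> float:
    """|r| above which the two-sided t test on r is significant at alpha."""
    t = stats.t.isf(alpha / 2.0, df)
    return t / math.sqrt(t * t + df)


def classify_significance(
    cm: CorrelationMatrix,
    alpha: float = 0.05,
    df_convention: str | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Two-sided significance mask plus per-gene significant-partner counts.

    An off-diagonal entry is significant iff the two-sided p of
    ``t = r sqrt(df) / sqrt(1 - r^2)`` is <= alpha, with df = n - 2 by
    default or n - 1 in compatibility mode.  The diagonal is never flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    conv = df_convention or cm.df_convention
    df = cm.n - 2 if conv == "n_minus_2" else cm.n - 1
    rc = critical_r(alpha, df)
    mask = np.abs(cm.r) >= rc
    np.fill_diagonal(mask, False)
    counts = {g: int(mask[i].sum()) for i, g in enumerate(cm.genes)}
    if df_convention and df_convention != cm.df_convention:
        base_df = cm.n - 2 if cm.df_convention == "n_minus_2" else cm.n - 1
        base_mask = np.abs(cm.r) >= critical_r(alpha, base_df)
        np.fill_diagonal(base_mask, False)
        if not np.array_equal(mask, base_mask):
            logger.info("df convention %s changes the significance classification", df_convention)
    return mask, counts
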