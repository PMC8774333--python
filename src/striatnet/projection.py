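"""Correlation-input PCA, clustering, and group-separation tests.

PCA is always computed from the genes' Pearson correlation matrix
(standardized variables), never the covariance matrix, so FPKM scale is
irrelevant and eigenvalues sum to the number of genes.  Sample scores are
the standardized expression projected on the eigenvectors; the sign of each
axis is fixed so its largest-magnitude gene loading is positive.

The half-plane test asks whether one sample group concentrates on one side
of a chosen axis.  Two one-sided constructions are offered:

* ``binomial_per_sample`` — each of the g group samples falls in either
  half independently with probability 1/2 under H0;
  p = P(Binomial(g, 1/2) >= m) for the majority count m.
* ``hypergeometric_split`` — conditions on the observed half sizes among
  all samples; p is the upper hypergeometric tail of m.

Both are exact; which one a published bound corresponds to is often
ambiguous, so the variant is always explicit in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .covariation import CorrelationMatrix
from .iofmt import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PCAProjection",
    "HalfPlaneResult",
    "ClusterAssignment",
    "pca_correlation",
    "ahc_cluster",
    "assign_gene_clusters",
    "half_plane_test",
]


@dataclass
class PCAProjection:
    """Eigendecomposition of a gene-set correlation matrix plus projections."""

    genes: list[str]
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    sample_scores: pd.DataFrame  # samples x axes
    gene_loadings: pd.DataFrame  # genes x axes (eigenvector * sqrt(eigenvalue))
    sample_groups: dict[str, str]
    sign_convention: str = "largest-loading-positive"

    @property
    def axes(self) -> list[str]:
        return list(self.sample_scores.columns)


def pca_correlation(matrix: ExpressionMatrix, genes: GeneSet,
                    log2: bool = False) -> PCAProjection:
    """PCA of the gene set's Pearson correlation matrix across samples."""
    sub = matrix.subset(genes.genes)
    values = sub.values.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    if len(sub) < 2:
        raise ValueError("PCA needs at least 2 genes")
    sds = values.std(axis=1, ddof=1)
    constant = [g for g, s in zip(sub.index, sds) if s == 0]
    if constant:
        raise ValueError(f"constant gene(s) cannot enter correlation PCA: {constant}")
    z = (values - values.mean(axis=1, keepdims=True)) / sds[:, None]
    r = np.corrcoef(values)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|loading| entry of each axis is positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    axes = [f"PC{j + 1}" for j in range(len(evals))]
    scores = pd.DataFrame(z.T @ evecs, index=sub.columns, columns=axes)
    loadings = pd.DataFrame(evecs * np.sqrt(evals), index=sub.index, columns=axes)
    return PCAProjection(
        genes=list(sub.index),
        eigenvalues=evals,
        variance_fraction=evals / evals.sum(),
        sample_scores=scores,
        gene_loadings=loadings,
        sample_groups=dict(matrix.sample_groups),
    )


def ahc_cluster(cm: CorrelationMatrix, k: int | None = None,
                cut_height: float | None = None) -> dict[str, int]:
    """Average-linkage agglomeration on dissimilarity 1 - r.

    Returns gene -> cluster label (1-based).  Exactly one of ``k`` or
    ``cut_height`` must be given.
    """
    if (k is None) == (cut_height is None):
        raise ValueError("give exactly one of k or cut_height")
    n = len(cm.genes)
    if k is not None and k > n:
        raise ValueError(f"k = {k} exceeds the {n} items")
    d = 1.0 - cm.r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    if k is not None:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    return {g: int(lab) for g, lab in zip(cm.genes, labels)}


@dataclass(frozen=True)
class ClusterAssignment:
    gene: str
    label: str  # single group or joint "A/B" when ambiguous
    best_group: str
    runner_up: str
    margin: float
    correlations: dict[str, float] = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return "/" in self.label


#: correlation-margin below which a gene's top two group indicators are
#: considered indistinguishable; ~1.5x the sampling sd of a correlation
#: difference at 18 samples
DEFAULT_MARGIN = 0.35


def assign_gene_clusters(
    matrix: ExpressionMatrix,
    genes: GeneSet,
    margin: float = DEFAULT_MARGIN,
    log2: bool = True,
) -> dict[str, ClusterAssignment]:
    """Assign each gene to the group whose indicator profile it tracks.

    The indicator of a group is 1 on its samples and 0 elsewhere; a gene is
    assigned to the group with maximal Pearson correlation.  When the
    margin to the runner-up falls below ``margin`` the gene receives the
    joint label of its top two groups (alphabetical), mirroring clusters
    shared between two experimental groups.  The correlation is computed on
    log2(FPKM + 1) by default: indicator tracking is a location effect, and
    the log scale keeps a single extreme sample from dominating it.
    """
    groups = matrix.groups
    if len(groups) < 2:
        raise ValueError("cluster assignment needs >= 2 groups")
    sub = matrix.subset(genes.genes)
    values = sub.values.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    indicators = np.array(
        [[1.0 if matrix.sample_groups[s] == g else 0.0 for s in sub.columns] for g in groups]
    )
    out: dict[str, ClusterAssignment] = {}
    for gene, row in zip(sub.index, values):
        if np.ptp(row) == 0:
            logger.info("constant gene %s left unassigned", gene)
            continue
        rs = {g: float(np.corrcoef(row, ind)[0, 1]) for g, ind in zip(groups, indicators)}
        ranked = sorted(rs, key=lambda g: (-rs[g], g))
        best, runner = ranked[0], ranked[1]
        gap = rs[best] - rs[runner]
        label = best if gap >= margin else "/".join(sorted([best, runner]))
        out[gene] = ClusterAssignment(
            gene=gene, label=label, best_group=best, runner_up=runner,
            margin=gap, correlations=rs,
        )
    return out


@dataclass(frozen=True)
class HalfPlaneResult:
    axis: str
    group: str
    in_majority_half: int
    group_size: int
    variant: str
    p_value: float
    zero_scores_flagged: int = 0

    @property
    def counts(self) -> tuple[int, int]:
        return (self.in_majority_half, self.group_size - self.in_majority_half)


def half_plane_test(
    proj: PCAProjection,
    group: str,
    axis: str = "PC1",
    variant: str = "binomial_per_sample",
) -> HalfPlaneResult:
    """One-sided test of a group concentrating on one side of a PCA axis.

    Halves are the sign of the sample score on the axis; a score of exactly
    zero is assigned to the positive half and flagged.  ``m`` is the number
    of the group's samples in its majority half.
    """
    if axis not in proj.sample_scores.columns:
        raise KeyError(f"axis {axis!r} not in projection")
    scores = proj.sample_scores[axis]
    group_samples = [s for s in scores.index if proj.sample_groups.get(s) == group]
    if not group_samples:
        raise ValueError(f"group {group!r} has no samples in the projection")
    positive = scores >= 0
    n_zero = int((scores == 0).sum())
    if n_zero:
        logger.warning("%d sample score(s) exactly 0 on %s assigned to the positive half",
                       n_zero, axis)
    g = len(group_samples)
    m_pos = int(positive.loc[group_samples].sum())
    m = max(m_pos, g - m_pos)
    majority_positive = m_pos >= g - m_pos
    if variant == "binomial_per_sample":
        p = float(stats.binom.sf(m - 1, g, 0.5))
    elif variant == "hypergeometric_split":
        half_size = int(positive.sum()) if majority_positive else int((~positive).sum())
        p = float(stats.hypergeom.sf(m - 1, len(scores), half_size, g))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return HalfPlaneResult(
        axis=axis, group=group, in_majority_half=m, group_size=g,
        variant=variant, p_value=min(p, 1.0), zero_scores_flagged=n_zero,
    )
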