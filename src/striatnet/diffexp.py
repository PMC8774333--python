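"""Differential-expression records, a stand-in caller, and DEG summaries.

The caller here is a deliberately simple two-group test — Welch's t on
log2(FPKM + pseudocount) with Benjamini-Hochberg adjustment — intended for
synthetic-data testing and as a transparent stand-in where externally
produced DEG tables are unavailable.  It is NOT a reimplementation of any
count-model DE tool; real analyses should ingest their tool's tables via
``iofmt.read_deg_table``.

Summaries reproduce the two dataset-level views used downstream: the
up/down direction split of a comparison and the per-gene-family breakdown
(fixed-length symbol prefix by default, with an explicit family-map
override for curated family abbreviations).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iofmt import ExpressionMatrix, normalize_symbol

__all__ = [
    "DEGRecord",
    "FamilySummaryRow",
    "DirectionSplit",
    "call_degs",
    "bh_adjust",
    "split_by_direction",
    "family_summary",
]

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result for an ordered group pair.

    ``log2fc`` is group2 relative to group1; ``direction`` derives from its
    sign.  ``q_value >= p_value`` is deliberately not asserted (BH can
    reorder); a table-wide minimum attainable q, where one exists, is a
    property of the input data and travels with the table, not the record.
    """

    gene: str
    comparison: tuple[str, str]
    log2fc: float
    p_value: float
    q_value: float
    significant: bool = False
    log2fc_capped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")

    @property
    def direction(self) -> str | None:
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return None


@dataclass(frozen=True)
class FamilySummaryRow:
    family_prefix: str
    n_degs: int
    min_q: float
    max_q: float
    stddev_q: float

    def __post_init__(self) -> None:
        if self.min_q > self.max_q:
            raise ValueError("min_q exceeds max_q")
        if self.n_degs < 1:
            raise ValueError("family with no DEGs")


class DirectionSplit(NamedTuple):
    n_up: int
    n_down: int
    n_unclassified: int


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (order-preserving mapping)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def call_degs(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    alpha_fdr: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEGRecord]:
    """Welch-t stand-in DE caller on log2(FPKM + pseudocount).

    Per gene: log2fc = log2((mean2 + c)/(mean1 + c)) on the FPKM scale
    (group2 relative to group1), p from a two-sided Welch t-test on the
    log-transformed values, q by BH over all tested genes.  Genes all-zero
    in both groups are skipped; a gene with identical values in both groups
    has t = 0 and p = 1.
    """
    s1 = matrix.samples_of(group1)
    s2 = matrix.samples_of(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"groups {group1!r}/{group2!r} need >= 2 samples each")
    v1 = matrix.values[s1].values.astype(float)
    v2 = matrix.values[s2].values.astype(float)
    tested = ~((v1 == 0).all(axis=1) & (v2 == 0).all(axis=1))
    genes = np.array(matrix.gene_ids)[tested]
    v1, v2 = v1[tested], v2[tested]

    l1 = np.log2(v1 + pseudocount)
    l2 = np.log2(v2 + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(l2, l1, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> no evidence (p = 1);
    # unequal means -> separation is perfect (p = 0)
    nan = ~np.isfinite(p)
    if nan.any():
        mean_diff = l2.mean(axis=1) - l1.mean(axis=1)
        p[nan & (np.abs(mean_diff) < 1e-12)] = 1.0
        p[nan & (np.abs(mean_diff) >= 1e-12)] = 0.0
    q = np.array(bh_adjust(p))
    log2fc = np.log2(v2.mean(axis=1) + pseudocount) - np.log2(v1.mean(axis=1) + pseudocount)

    return [
        DEGRecord(
            gene=str(g),
            comparison=(group1, group2),
            log2fc=float(f),
            p_value=float(pv),
            q_value=float(qv),
            significant=bool(qv < alpha_fdr),
        )
        for g, f, pv, qv in zip(genes, log2fc, p, q)
    ]


def split_by_direction(degs: Sequence[DEGRecord]) -> DirectionSplit:
    """Counts of up/down records by log2fc sign (zeros reported separately)."""
    comparisons = {r.comparison for r in degs}
    if len(comparisons) > 1:
        raise ValueError(f"records mix comparisons: {sorted(comparisons)}")
    up = sum(1 for r in degs if r.log2fc > 0)
    down = sum(1 for r in degs if r.log2fc < 0)
    return DirectionSplit(up, down, len(degs) - up - down)


def family_summary(
    degs: Sequence[DEGRecord],
    prefix_len: int = 3,
    min_count: int = 5,
    family_map: Mapping[str, str] | None = None,
) -> list[FamilySummaryRow]:
    """Per-family DEG counts with min/max/stddev of q.

    Families are fixed-length case-normalized symbol prefixes by default;
    an explicit gene -> family map overrides the prefix rule for curated
    abbreviations.  Families with fewer than ``min_count`` DEGs are
    dropped; output is sorted by count descending, ties by prefix.
    """
    if prefix_len < 1:
        raise ValueError("prefix_len must be >= 1")
    fam_q: dict[str, list[float]] = defaultdict(list)
    norm_map = (
        {normalize_symbol(k): v for k, v in family_map.items()} if family_map else {}
    )
    for r in degs:
        gene = normalize_symbol(r.gene)
        fam = norm_map.get(gene, gene[:prefix_len])
        fam_q[fam].append(r.q_value)
    rows = []
    for fam, qs in fam_q.items():
        if len(qs) < min_count:
            continue
        arr = np.asarray(qs, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append(
            FamilySummaryRow(
                family_prefix=fam,
                n_degs=len(qs),
                min_q=float(arr.min()),
                max_q=float(arr.max()),
                stddev_q=sd,
            )
        )
    rows.sort(key=lambda r: (-r.n_degs, r.family_prefix))
    return rows
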