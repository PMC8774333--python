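"""Readers and writers for the pipeline's external file formats.

All tabular formats are UTF-8, tab-delimited TSV (LF or CRLF).  Gene symbols
are matched case-insensitively and rendered in canonical mouse capitalization
(first letter upper, rest lower), so that alias/case mismatches can never
silently corrupt joins between the expression matrix, DEG tables, evidence
edge lists and seed sets.

Formats
-------
expression matrix   column 1 header ``gene``; remaining headers = sample names
sample sheet        columns ``sample``, ``group``
evidence edge list  columns ``gene1``, ``gene2``, ``combined_score``
                    (scores either in (0, 1] or STRING's 0-1000 integers)
DEG table           ``cuffdiff`` (gene_exp.diff layout) or ``simple``
                    (gene, log2fc, p, q) dialect
gene list           one symbol per line, ``#`` comments
annotation map      columns ``term_id``, ``term_name``, ``genes`` (comma-sep)
alias table         two columns: alias, canonical symbol
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "EvidenceNetwork",
    "GeneSet",
    "AnnotationMap",
    "normalize_symbol",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_deg_table",
    "write_deg_table",
    "read_gene_list",
    "write_gene_list",
    "read_annotation",
    "write_annotation",
    "read_alias_table",
    "DEFAULT_ALIASES",
]

#: log2 fold changes reported as infinite (zero expression in one group) are
#: capped at this magnitude so downstream sorting always has finite keys.
DEFAULT_LOG2FC_CAP = 20.0

#: Default alias map shipped with the package (striatal-literature aliases).
DEFAULT_ALIASES: dict[str, str] = {"Darpp-32": "Ppp1r1b"}


def normalize_symbol(symbol: str) -> str:
    """Canonical mouse capitalization: first letter upper, rest lower."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


def _apply_aliases(symbol: str, aliases: Mapping[str, str] | None) -> str:
    s = normalize_symbol(symbol)
    if aliases:
        norm_aliases = {normalize_symbol(k): normalize_symbol(v) for k, v in aliases.items()}
        s = norm_aliases.get(s, s)
    return s


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a group label per sample.

    ``values`` is a pandas DataFrame indexed by normalized gene symbol with
    sample names as columns; all entries are non-negative, linear-scale FPKM.
    Rows that are zero in every sample are retained but flagged in
    ``all_zero_genes``.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbol(s) after normalization: {dup}")
        if (v.values < 0).any():
            bad = v.index[(v.values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative FPKM values for gene(s): {bad}")
        missing = [s for s in v.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"sample(s) missing from sample sheet: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.sample_groups[s], None)
        return list(seen)

    @property
    def all_zero_genes(self) -> list[str]:
        mask = (self.values.values == 0).all(axis=1)
        return [g for g, m in zip(self.values.index, mask) if m]

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups[s] == group]

    def require_min_group_size(self, n: int = 2) -> None:
        for g in self.groups:
            if len(self.samples_of(g)) < n:
                raise ValueError(f"group {g!r} has fewer than {n} samples")

    def subset(self, genes: Sequence[str]) -> pd.DataFrame:
        """Rows for ``genes`` (normalized); raises naming any absent gene."""
        norm = [normalize_symbol(g) for g in genes]
        absent = [g for g in norm if g not in self.values.index]
        if absent:
            raise KeyError(f"gene(s) not in expression matrix: {absent}")
        return self.values.loc[norm]


@dataclass
class EvidenceNetwork:
    """Undirected gene-gene interaction edges with confidence scores in (0, 1].

    Backed by a dict keyed on the unordered (sorted) gene pair.  Symmetric
    duplicates keep the maximum score; self-loops are rejected at insertion.
    """

    _edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-loop edge on {a!r}")
        if not 0 < score <= 1:
            raise ValueError(f"edge score {score} outside (0, 1]")
        k = self._key(a, b)
        self._edges[k] = max(score, self._edges.get(k, 0.0))

    def has_edge(self, a: str, b: str) -> bool:
        return self._key(a, b) in self._edges

    def score(self, a: str, b: str) -> float:
        return self._edges[self._key(a, b)]

    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, s) for (a, b), s in sorted(self._edges.items())]

    def neighbors(self, gene: str) -> list[tuple[str, float]]:
        out = []
        for (a, b), s in self._edges.items():
            if a == gene:
                out.append((b, s))
            elif b == gene:
                out.append((a, s))
        return sorted(out)

    def nodes(self) -> list[str]:
        ns: set[str] = set()
        for a, b in self._edges:
            ns.add(a)
            ns.add(b)
        return sorted(ns)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def density(self) -> float:
        n = len(self.nodes())
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), s in self._edges.items():
            g.add_edge(a, b, score=s)
        return g


@dataclass
class GeneSet:
    """Named ordered list of gene symbols, unique after case normalization."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        norm, seen = [], set()
        for g in self.genes:
            s = normalize_symbol(g)
            if s in seen:
                raise ValueError(f"duplicate gene {s!r} in gene set {self.name!r}")
            seen.add(s)
            norm.append(s)
        self.genes = norm

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes


@dataclass
class AnnotationMap:
    """term_id -> (term name, gene list); empty terms are invalid."""

    terms: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"annotation term {tid!r} has no genes")
            self.terms[tid] = (self.terms[tid][0], [normalize_symbol(g) for g in genes])

    def __len__(self) -> int:
        return len(self.terms)

    def items(self):
        return self.terms.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    sample_sheet: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an FPKM matrix TSV plus its sample sheet.

    The first column must be headed ``gene``; every remaining column is a
    numeric FPKM column named for its sample.  Duplicate symbols after case
    normalization, samples absent from the sheet and negative values are all
    hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0].strip().lower() != "gene":
        raise ValueError(f"first column header must be 'gene', got {df.columns[0]!r}")
    df = df.rename(columns={df.columns[0]: "gene"})
    df["gene"] = [_apply_aliases(g, aliases) for g in df["gene"]]
    dupes = df["gene"][df["gene"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate gene symbol(s) after normalization: {sorted(set(dupes))}")
    values = df.set_index("gene").astype(float)

    sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(sheet.columns):
        raise ValueError("sample sheet must have columns 'sample' and 'group'")
    groups = dict(zip(sheet["sample"], sheet["group"]))
    em = ExpressionMatrix(values=values, sample_groups=groups)
    if em.all_zero_genes:
        logger.info("%d gene(s) have all-zero FPKM rows (retained, flagged)", len(em.all_zero_genes))
    return em


def write_expression_matrix(em: ExpressionMatrix, path: str | Path, sample_sheet: str | Path) -> None:
    out = em.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")
    sheet = pd.DataFrame(
        {"sample": em.sample_ids, "group": [em.sample_groups[s] for s in em.sample_ids]}
    )
    sheet.to_csv(sample_sheet, sep="\t", index=False, lineterminator="\n")


def read_edge_list(
    path: str | Path,
    score_min: float = 0.0,
    aliases: Mapping[str, str] | None = None,
) -> EvidenceNetwork:
    """Read a STRING-style edge TSV keeping edges with score >= ``score_min``.

    Scores above 1 anywhere in the file trigger the STRING 0-1000 integer
    convention (all scores divided by 1000).  Symmetric duplicates keep the
    maximum score; self-loop rows are dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    need = {"gene1", "gene2", "combined_score"}
    if not need.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(need)}")
    scores = df["combined_score"].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    net = EvidenceNetwork()
    n_loops = 0
    for g1, g2, s in zip(df["gene1"], df["gene2"], scores):
        a, b = _apply_aliases(g1, aliases), _apply_aliases(g2, aliases)
        if a == b:
            n_loops += 1
            continue
        if s >= score_min:
            net.add_edge(a, b, float(s))
    if n_loops:
        logger.warning("dropped %d self-loop row(s) from %s", n_loops, path)
    return net


def write_edge_list(net: EvidenceNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.edges(), columns=["gene1", "gene2", "combined_score"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


_CUFFDIFF_COLS = [
    "gene", "sample_1", "sample_2", "value_1", "value_2",
    "log2(fold_change)", "p_value", "q_value", "significant",
]


def read_deg_table(
    path: str | Path,
    dialect: str = "simple",
    log2fc_cap: float = DEFAULT_LOG2FC_CAP,
    aliases: Mapping[str, str] | None = None,
):
    """Read a DEG table in ``cuffdiff`` (gene_exp.diff) or ``simple`` dialect.

    Infinite log2 fold changes (zero expression in one group) are mapped to
    +/-``log2fc_cap`` and flagged on the record.  Rows whose numeric fields
    cannot be parsed as finite (after capping) are skipped.  The table's
    minimum attainable q is an input property and is never recomputed here.
    """
    from .diffexp import DEGRecord  # local import avoids a module cycle

    df = pd.read_csv(path, sep="\t")
    if dialect == "cuffdiff":
        missing = [c for c in _CUFFDIFF_COLS[:8] if c not in df.columns]
        if missing:
            raise ValueError(f"cuffdiff dialect missing column(s): {missing}")
        comparison = None
        rows = df[["gene", "sample_1", "sample_2", "log2(fold_change)", "p_value", "q_value"]]
        records = []
        for gene, s1, s2, lfc, p, q in rows.itertuples(index=False):
            rec = _make_record(gene, (str(s1), str(s2)), lfc, p, q, log2fc_cap, aliases)
            if rec is not None:
                records.append(rec)
        return records
    elif dialect == "simple":
        need = {"gene", "log2fc", "p", "q"}
        if not need.issubset(df.columns):
            raise ValueError(f"simple dialect must have columns {sorted(need)}")
        g1 = str(df["group1"].iloc[0]) if "group1" in df.columns and len(df) else "group1"
        g2 = str(df["group2"].iloc[0]) if "group2" in df.columns and len(df) else "group2"
        records = []
        for _, row in df.iterrows():
            rec = _make_record(row["gene"], (g1, g2), row["log2fc"], row["p"], row["q"], log2fc_cap, aliases)
            if rec is not None:
                records.append(rec)
        return records
    raise ValueError(f"unknown DEG table dialect {dialect!r}")


def _make_record(gene, comparison, lfc, p, q, cap, aliases):
    from .diffexp import DEGRecord

    try:
        lfc, p, q = float(lfc), float(p), float(q)
    except (TypeError, ValueError):
        return None
    capped = False
    if np.isinf(lfc):
        lfc, capped = np.sign(lfc) * cap, True
    if not (np.isfinite(lfc) and np.isfinite(p) and np.isfinite(q)):
        return None
    if not (0 <= p <= 1 and 0 <= q <= 1):
        return None
    return DEGRecord(
        gene=_apply_aliases(str(gene), aliases),
        comparison=comparison,
        log2fc=lfc,
        p_value=p,
        q_value=q,
        log2fc_capped=capped,
    )


def write_deg_table(records, path: str | Path) -> None:
    """Write DEG records in the ``simple`` dialect (plus group columns)."""
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "group1": [r.comparison[0] for r in records],
            "group2": [r.comparison[1] for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_list(path: str | Path, name: str | None = None,
                   aliases: Mapping[str, str] | None = None) -> GeneSet:
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(_apply_aliases(line, aliases))
    return GeneSet(name=name or Path(path).stem, genes=genes)


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.genes) + "\n", encoding="utf-8")


def read_annotation(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"term_id", "term_name", "genes"}
    if not need.issubset(df.columns):
        raise ValueError(f"annotation map must have columns {sorted(need)}")
    terms = {}
    for tid, tname, genes in df[["term_id", "term_name", "genes"]].itertuples(index=False):
        gene_list = [g for g in str(genes).split(",") if g.strip()]
        terms[tid] = (tname, gene_list)
    return AnnotationMap(terms=terms)


def write_annotation(am: AnnotationMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "term_id": list(am.terms),
            "term_name": [am.terms[t][0] for t in am.terms],
            "genes": [",".join(am.terms[t][1]) for t in am.terms],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias, canonical); returns a normalized mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"], dtype=str)
    return {normalize_symbol(a): normalize_symbol(c) for a, c in df.itertuples(index=False)}
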