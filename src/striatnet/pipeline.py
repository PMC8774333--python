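"""End-to-end orchestration: DEGs -> clusters -> co-variation -> expansion.

A single JSON-configurable run executes, in order: (1) DEG ingestion or
stand-in calling with FDR filtering; (2) direction split and family summary
per comparison; (3) seed-set cluster assignment by group; (4) per-cluster
min/max expansion requiring both interaction evidence (connectivity) and
co-variation support; (5) PPI and term enrichment of each expanded network;
(6) gene-set PCA projections with half-plane group-separation tests;
(7) a single JSON + TSV report.  Every threshold and skip decision is
logged at INFO so a run reads as an audit trail.

Identical config + seed produces a byte-identical report bundle.  Removing
the evidence network disables expansion and enrichment but leaves every
statistic of the earlier stages unchanged; an empty seed set completes
stages 1-2 and skips the rest with an explicit notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import diffexp, iofmt, netexpand, projection
from .covariation import build_covariation_network
from .iofmt import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "verify_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    matrix: str
    samples: str
    out_dir: str
    seeds: str | None = None
    evidence: str | None = None
    annotation: str | None = None
    deg_tables: dict[str, str] = field(default_factory=dict)  # "G1_vs_G2" -> path
    comparisons: list[list[str]] | None = None
    alpha_fdr: float = 0.05
    r_min: float = 0.6
    p_max: float = 1e-3
    alpha_cor: float = 0.05
    df_convention: str = "n_minus_2"
    test_variant: str = "binomial_per_sample"
    cluster_margin: float = projection.DEFAULT_MARGIN
    family_inclusion: bool = True
    family_prefix_len: int = 3
    max_path_len: int = 3
    evidence_score_min: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1 or not 0 < self.alpha_cor < 1:
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _round(x: float, nd: int = 10) -> float:
    return float(round(float(x), nd))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": {}}

    # -- stage 1: expression + DEGs ------------------------------------
    stage = "deg_ingestion"
    try:
        matrix = iofmt.read_expression_matrix(config.matrix, config.samples)
        matrix.require_min_group_size(2)
        groups = matrix.groups
        if config.comparisons:
            comparisons = [tuple(c) for c in config.comparisons]
        else:
            comparisons = [
                (groups[i], groups[j])
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            ]
        degs_by_comp: dict[str, list[diffexp.DEGRecord]] = {}
        for g1, g2 in comparisons:
            key = f"{g1}_vs_{g2}"
            if key in config.deg_tables:
                recs = iofmt.read_deg_table(config.deg_tables[key], dialect="simple")
                recs = [
                    diffexp.DEGRecord(
                        gene=r.gene, comparison=(g1, g2), log2fc=r.log2fc,
                        p_value=r.p_value, q_value=r.q_value,
                        significant=r.q_value < config.alpha_fdr,
                        log2fc_capped=r.log2fc_capped,
                    )
                    for r in recs
                ]
            else:
                recs = diffexp.call_degs(matrix, g1, g2, alpha_fdr=config.alpha_fdr)
            degs_by_comp[key] = recs
            sig = [r for r in recs if r.significant]
            logger.info("comparison %s: %d genes tested, %d significant at FDR < %g",
                        key, len(recs), len(sig), config.alpha_fdr)
            iofmt.write_deg_table(sig, out / f"degs_{key}.tsv")
        report["stages"]["degs"] = {
            k: {"n_tested": len(v), "n_significant": sum(r.significant for r in v)}
            for k, v in degs_by_comp.items()
        }
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(e)) from e

    # -- stage 2: summaries --------------------------------------------
    stage = "deg_summaries"
    try:
        summaries = {}
        for key, recs in degs_by_comp.items():
            sig = [r for r in recs if r.significant]
            split = diffexp.split_by_direction(sig)
            fams = diffexp.family_summary(sig, prefix_len=config.family_prefix_len)
            summaries[key] = {
                "n_up": split.n_up,
                "n_down": split.n_down,
                "n_unclassified": split.n_unclassified,
                "families": [
                    {"family": f.family_prefix, "n": f.n_degs,
                     "min_q": _round(f.min_q), "max_q": _round(f.max_q),
                     "stddev_q": _round(f.stddev_q)}
                    for f in fams
                ],
            }
        report["stages"]["summaries"] = summaries
    except Exception as e:
        raise StageError(stage, str(e)) from e

    seeds = None
    if config.seeds:
        seeds = iofmt.read_gene_list(config.seeds, name="seeds")
    if seeds is None or len(seeds) == 0:
        logger.info("no seed genes given: skipping cluster assignment, expansion, "
                    "enrichment and projection stages")
        report["stages"]["skipped"] = ["clusters", "expansion", "enrichment", "projection"]
        return _write_report(report, out)

    # -- stage 3: seed cluster assignment ------------------------------
    stage = "cluster_assignment"
    try:
        assignments = projection.assign_gene_clusters(
            matrix, seeds, margin=config.cluster_margin
        )
        clusters: dict[str, list[str]] = {}
        for g in seeds.genes:
            if g in assignments:
                clusters.setdefault(assignments[g].label, []).append(g)
        report["stages"]["clusters"] = {
            lab: sorted(genes) for lab, genes in sorted(clusters.items())
        }
        logger.info("seed set split into %d cluster(s): %s",
                    len(clusters), {k: len(v) for k, v in sorted(clusters.items())})
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- stage 4: co-variation + expansion -----------------------------
    evidence = None
    expansions: dict[str, netexpand.ExpandedNeighborhood] = {}
    if config.evidence:
        stage = "expansion"
        try:
            evidence = iofmt.read_edge_list(config.evidence, score_min=config.evidence_score_min)
            cov = build_covariation_network(
                matrix, seeds, r_min=config.r_min, p_max=config.p_max
            )
            logger.info("co-variation screen at tau > %g, p <= %g: %d edge(s)",
                        config.r_min, config.p_max, len(cov))
            params = netexpand.ExpansionParams(
                r_min=config.r_min, p_max=config.p_max,
                family_inclusion=config.family_inclusion,
                family_prefix_len=config.family_prefix_len,
                max_path_len=config.max_path_len,
            )
            exp_report = {}
            for lab, genes in sorted(clusters.items()):
                cluster_seeds = GeneSet(name=f"cluster_{lab}", genes=genes)
                try:
                    nb = netexpand.expand_neighborhood_minmax(
                        cluster_seeds, evidence, cov, params
                    )
                except ValueError as err:
                    logger.warning("cluster %s not expandable: %s", lab, err)
                    continue
                expansions[lab] = nb
                exp_report[lab] = {
                    "nodes": nb.nodes,
                    "edges": [list(e) for e in nb.edges],
                    "seeds_covered": nb.seeds_covered,
                    "uncovered_seeds": nb.uncovered_seeds,
                    "total_nodes": nb.total_nodes,
                }
                _write_neighborhood_tsv(nb, out / f"neighborhood_{lab.replace('/', '-')}.tsv")
            report["stages"]["expansion"] = exp_report
        except StageError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e
    else:
        logger.info("no evidence network given: expansion and enrichment disabled")

    # -- stage 5: enrichment -------------------------------------------
    if evidence is not None and expansions:
        stage = "enrichment"
        try:
            annotation = iofmt.read_annotation(config.annotation) if config.annotation else None
            background = GeneSet(name="background", genes=matrix.gene_ids)
            enr = {}
            for lab, nb in sorted(expansions.items()):
                gs = GeneSet(name=f"network_{lab}", genes=sorted(nb.node_set()))
                row: dict = {}
                if len(gs) >= 2:
                    ppi = netexpand.ppi_enrichment(gs, evidence)
                    row["ppi"] = {
                        "observed_edges": ppi.observed_edges,
                        "expected_edges": _round(ppi.expected_edges),
                        "p_value": _round(ppi.p_value, 15),
                    }
                if annotation is not None:
                    rows = netexpand.term_enrichment(
                        GeneSet(name=gs.name,
                                genes=[g for g in gs.genes if g in set(background.genes)]),
                        annotation, background,
                    )
                    row["terms"] = [
                        {"term_id": r.term_id, "k": r.k, "K": r.K,
                         "p": _round(r.p_value, 15), "q": _round(r.q_value, 15)}
                        for r in rows[:20]
                    ]
                enr[lab] = row
            report["stages"]["enrichment"] = enr
        except Exception as e:
            raise StageError(stage, str(e)) from e

    # -- stage 6: projections + half-plane tests -----------------------
    stage = "projection"
    try:
        proj_sets: dict[str, list[str]] = {"seed_set": list(seeds.genes)}
        for lab, nb in sorted(expansions.items()):
            proj_sets[f"network_{lab}"] = sorted(nb.node_set())
        proj_report = {}
        gene_pool = set(matrix.gene_ids)
        for name, genes in proj_sets.items():
            present = [g for g in genes if g in gene_pool]
            if len(present) < 2:
                continue
            try:
                proj = projection.pca_correlation(matrix, GeneSet(name=name, genes=present))
            except ValueError as err:
                logger.warning("projection %s skipped: %s", name, err)
                continue
            tests = {}
            for g in matrix.groups:
                res = projection.half_plane_test(proj, g, axis="PC1",
                                                 variant=config.test_variant)
                tests[g] = {"m": res.in_majority_half, "g": res.group_size,
                            "p_value": _round(res.p_value, 15)}
            proj_report[name] = {
                "pc1_variance_fraction": _round(float(proj.variance_fraction[0])),
                "half_plane": tests,
            }
        report["stages"]["projection"] = proj_report
    except Exception as e:
        raise StageError(stage, str(e)) from e

    return _write_report(report, out)


def _write_neighborhood_tsv(nb: netexpand.ExpandedNeighborhood, path: Path) -> None:
    lines = ["gene1\tgene2"]
    lines += [f"{a}\t{b}" for a, b in nb.edges]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_report(report: dict, out: Path) -> dict:
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    # flat TSV of the DEG summaries for spreadsheet users
    lines = ["comparison\tn_up\tn_down\tn_unclassified"]
    for key, s in sorted(report["stages"].get("summaries", {}).items()):
        lines.append(f"{key}\t{s['n_up']}\t{s['n_down']}\t{s['n_unclassified']}")
    (out / "report.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report


def verify_report(report: dict, evidence: iofmt.EvidenceNetwork,
                  cov_supported: set[str]) -> bool:
    """Independent checker: every expansion node satisfies the two criteria.

    Every reported node is a seed, covariation-supported (criterion b), a
    family mate, or a tagged connector; every edge exists in the evidence
    network (criterion a).
    """
    exp = report.get("stages", {}).get("expansion", {})
    for lab, nb in exp.items():
        for a, b in (tuple(e) for e in nb["edges"]):
            if not evidence.has_edge(a, b):
                return False
        for node, tag in nb["nodes"].items():
            if tag == "covariation-supported" and node not in cov_supported:
                return False
            if tag not in {"seed", "covariation-supported", "family-included", "connector"}:
                return False
    return True
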