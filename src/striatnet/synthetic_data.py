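"""Synthetic FPKM datasets with planted group effects and co-expressed modules.

The generator emulates the statistical structure of a 3-group x 6-sample
bulk RNA-Seq FPKM design so that every downstream stage (DEG calling,
co-variation screening, seed expansion, projection) can be exercised and
power-tested against a known ground truth without any external download.

Model
-----
log2-FPKM of gene g in sample s:

    x_gs = mu_g + s_g * a_g * f_{m(g),s} + s_g * delta_{g,G(s)} * 1[s active] + eps_gs

with one independent standard-normal latent factor f per module per sample,
idiosyncratic noise eps ~ Normal(0, sigma_g^2), and FPKM = 2^x (hence always
positive).  ``s_g`` is -1 for a module's antiphase members and +1 otherwise,
so a module can carry two mutually anticorrelated sub-blocks.  Background
genes have a = 0 and delta = 0.  Expected pairwise Pearson correlation of
two same-phase members of a module without group shifts is a^2/(a^2+sigma^2).

A matched interaction-evidence network plants within-module edges with
probability ``p_in`` and background edges with probability ``p_out``.

The default study fixture reproduces, at a configurable scale, the shape of
the study this package targets: 3 groups (Control, A20, AD) x 6 samples, a
12-gene seed TF set split 6/3/3 across a control-up cluster, a subset-active
AD-up cluster and a joint A20/AD-up cluster, an asymmetric pair of up/down
DEG modules at the 170:839 ratio, an 8-gene antiphase "circadian" structure
and two very-high-expression marker genes (~1000 and ~800 FPKM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iofmt import (
    EvidenceNetwork,
    ExpressionMatrix,
    GeneSet,
    normalize_symbol,
    write_edge_list,
    write_expression_matrix,
    write_gene_list,
)

__all__ = [
    "ModuleSpec",
    "SyntheticTruth",
    "StudyFixture",
    "generate_dataset",
    "generate_evidence_network",
    "default_study_fixture",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS: dict[str, int] = {"Control": 6, "A20": 6, "AD": 6}

#: conventional log2-scale dispersion for FPKM-level noise
DEFAULT_NOISE_SD = 0.7


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``members`` is either a count (genes are auto-named from the module
    name) or an explicit symbol list.  ``antiphase_members`` marks a subset
    (count from the tail, or explicit list) whose factor loading and group
    shifts are sign-flipped, producing two anticorrelated sub-blocks.
    ``active_samples`` restricts the group shift to a subset of one group's
    samples (subset-active module).
    """

    name: str
    members: int | list[str]
    factor_loading: float = 0.0
    group_shift: dict[str, float] = field(default_factory=dict)
    active_samples: list[str] | None = None
    baseline_mean: float = 5.0
    noise_sd: float = DEFAULT_NOISE_SD
    antiphase_members: int | list[str] = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError(f"module {self.name!r}: noise_sd must be > 0")
        if self.factor_loading < 0:
            raise ValueError(f"module {self.name!r}: factor_loading must be >= 0")

    def gene_names(self) -> list[str]:
        if isinstance(self.members, int):
            base = normalize_symbol(self.name.replace("_", ""))
            return [f"{base}{i + 1:04d}" for i in range(self.members)]
        return [normalize_symbol(g) for g in self.members]

    def antiphase_names(self) -> set[str]:
        genes = self.gene_names()
        if isinstance(self.antiphase_members, int):
            if self.antiphase_members == 0:
                return set()
            return set(genes[-self.antiphase_members:])
        return {normalize_symbol(g) for g in self.antiphase_members}


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    modules: dict[str, list[str]]
    specs: list[ModuleSpec]
    design: dict[str, list[str]]
    all_genes: list[str]
    intended_degs: dict[str, dict[str, str]]
    seed_genes: list[str] = field(default_factory=list)
    antiphase: dict[str, list[str]] = field(default_factory=dict)
    n_planted_evidence_edges: int | None = None

    @property
    def gene_module(self) -> dict[str, str]:
        return {g: m for m, genes in self.modules.items() for g in genes}

    def intended_split(self, group1: str, group2: str) -> tuple[int, int]:
        """Intended (up, down) DEG counts for group2 relative to group1."""
        d = self.intended_degs.get(f"{group1}_vs_{group2}")
        flipped = False
        if d is None:
            d = self.intended_degs.get(f"{group2}_vs_{group1}", {})
            flipped = True
        up = sum(1 for v in d.values() if v == "up")
        down = len(d) - up
        return (down, up) if flipped else (up, down)

    def to_json(self) -> str:
        payload = {
            "modules": self.modules,
            "design": self.design,
            "intended_degs": self.intended_degs,
            "seed_genes": self.seed_genes,
            "antiphase": self.antiphase,
            "n_genes": len(self.all_genes),
            "n_planted_evidence_edges": self.n_planted_evidence_edges,
            "module_params": [
                {
                    "name": s.name,
                    "factor_loading": s.factor_loading,
                    "group_shift": s.group_shift,
                    "active_samples": s.active_samples,
                    "baseline_mean": s.baseline_mean,
                    "noise_sd": s.noise_sd,
                }
                for s in self.specs
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _sample_names(groups: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    samples, labels = [], {}
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        for i in range(n):
            s = f"{g}_{i + 1}"
            samples.append(s)
            labels[s] = g
    return samples, labels


def generate_dataset(
    specs: list[ModuleSpec],
    n_background_genes: int,
    groups: dict[str, int] | None = None,
    seed: int = 0,
    background_mean: float = 4.0,
    background_mean_sd: float = 2.0,
    background_noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one FPKM matrix plus its ground truth, bit-identically per seed.

    Background gene baselines are drawn Normal(background_mean,
    background_mean_sd) in log2 space, giving a realistic spread of
    expression levels; background genes carry no factor and no shift.
    """
    groups = dict(groups or DEFAULT_GROUPS)
    samples, labels = _sample_names(groups)
    n_samples = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples)}

    seen: dict[str, str] = {}
    for spec in specs:
        for g in spec.gene_names():
            if g in seen:
                raise ValueError(
                    f"gene {g!r} appears in modules {seen[g]!r} and {spec.name!r}"
                )
            seen[g] = spec.name
        if spec.active_samples:
            act_groups = {labels.get(s) for s in spec.active_samples}
            if None in act_groups or len(act_groups) != 1:
                raise ValueError(
                    f"module {spec.name!r}: active_samples must lie in one group"
                )

    rng = np.random.default_rng(seed)
    blocks, gene_names = [], []
    modules: dict[str, list[str]] = {}
    antiphase: dict[str, list[str]] = {}
    for spec in specs:
        genes = spec.gene_names()
        anti = spec.antiphase_names()
        modules[spec.name] = genes
        if anti:
            antiphase[spec.name] = sorted(anti)
        sign = np.array([-1.0 if g in anti else 1.0 for g in genes])
        f = rng.standard_normal(n_samples)  # one factor per module per sample
        shift = np.zeros(n_samples)
        for grp, delta in spec.group_shift.items():
            if grp not in groups:
                raise ValueError(f"module {spec.name!r}: unknown group {grp!r}")
            for s in samples:
                if labels[s] == grp:
                    shift[sample_pos[s]] = delta
        if spec.active_samples is not None:
            active = np.zeros(n_samples)
            for s in spec.active_samples:
                active[sample_pos[s]] = 1.0
            shift = shift * active
        eps = rng.normal(0.0, spec.noise_sd, size=(len(genes), n_samples))
        x = (
            spec.baseline_mean
            + np.outer(sign, spec.factor_loading * f)
            + np.outer(sign, shift)
            + eps
        )
        blocks.append(x)
        gene_names.extend(genes)

    if n_background_genes:
        bg_names = [f"Bkg{i + 1:05d}" for i in range(n_background_genes)]
        mu = rng.normal(background_mean, background_mean_sd, size=n_background_genes)
        eps = rng.normal(0.0, background_noise_sd, size=(n_background_genes, n_samples))
        blocks.append(mu[:, None] + eps)
        gene_names.extend(bg_names)

    log2fpkm = np.vstack(blocks) if blocks else np.empty((0, n_samples))
    values = pd.DataFrame(np.exp2(log2fpkm), index=gene_names, columns=samples)
    values.index.name = "gene"
    matrix = ExpressionMatrix(values=values, sample_groups=labels)

    intended = _intended_degs(specs, groups, labels)
    truth = SyntheticTruth(
        modules=modules,
        specs=list(specs),
        design={g: [s for s in samples if labels[s] == g] for g in groups},
        all_genes=list(gene_names),
        intended_degs=intended,
        antiphase=antiphase,
    )
    return matrix, truth


def _intended_degs(specs, groups, labels) -> dict[str, dict[str, str]]:
    """Per-comparison intended DEG directions from effective group shifts.

    The effective shift of a gene in a group is delta scaled by the active
    fraction of that group's samples (1 for fully active modules), with the
    antiphase sign applied; direction is the sign of (group2 - group1).
    """
    group_list = list(groups)
    out: dict[str, dict[str, str]] = {}
    for i, g1 in enumerate(group_list):
        for g2 in group_list[i + 1:]:
            key = f"{g1}_vs_{g2}"
            d: dict[str, str] = {}
            for spec in specs:
                eff = {}
                for grp in (g1, g2):
                    delta = spec.group_shift.get(grp, 0.0)
                    if delta and spec.active_samples is not None:
                        grp_samples = [s for s, lab in labels.items() if lab == grp]
                        frac = sum(1 for s in spec.active_samples if labels[s] == grp)
                        delta *= frac / len(grp_samples)
                    eff[grp] = delta
                diff = eff[g2] - eff[g1]
                if diff == 0:
                    continue
                anti = spec.antiphase_names()
                for gene in spec.gene_names():
                    signed = -diff if gene in anti else diff
                    d[gene] = "up" if signed > 0 else "down"
            if d:
                out[key] = d
    return out


def generate_evidence_network(
    truth: SyntheticTruth,
    p_in: float,
    p_out: float,
    seed: int = 0,
    score_low: float = 0.4,
    score_high: float = 1.0,
) -> EvidenceNetwork:
    """Planted-partition evidence network over the dataset's genes.

    Within-module pairs become edges with probability ``p_in``, all other
    pairs with ``p_out``; scores are Uniform(score_low, score_high).
    Deterministic given the seed.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    genes = truth.all_genes
    module_of = truth.gene_module
    ids = {name: i for i, name in enumerate(truth.modules)}
    mod_ids = np.array(
        [ids.get(module_of.get(g), -1) for g in genes], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    net = EvidenceNetwork()
    n = len(genes)
    n_within = 0
    for i in range(n - 1):
        draws = rng.random(n - 1 - i)
        same = (mod_ids[i + 1:] == mod_ids[i]) & (mod_ids[i] >= 0)
        p = np.where(same, p_in, p_out)
        hits = np.nonzero(draws < p)[0]
        if hits.size == 0:
            continue
        scores = rng.uniform(score_low, score_high, size=hits.size)
        for j, sc in zip(hits, scores):
            net.add_edge(genes[i], genes[i + 1 + j], float(sc))
            if same[j]:
                n_within += 1
    truth.n_planted_evidence_edges = n_within
    return net


# ---------------------------------------------------------------------------
# the default study-shaped fixture
# ---------------------------------------------------------------------------


@dataclass
class StudyFixture:
    matrix: ExpressionMatrix
    truth: SyntheticTruth
    evidence: EvidenceNetwork
    seeds: GeneSet
    paths: dict[str, Path] = field(default_factory=dict)


#: seed TF clusters of the default fixture (6 control / 3 AD / 3 joint)
CONTROL_TFS = [f"Ctf{i}" for i in range(1, 7)]
AD_TFS = [f"Dtf{i}" for i in range(1, 4)]
JOINT_TFS = [f"Jtf{i}" for i in range(1, 4)]
CIRCADIAN_GENES = [f"Cir{i}" for i in range(1, 9)]
MARKER_GENES = ["Marka1", "Markb1"]

#: TF-cluster group shift, log2 units.  Chosen once so that indicator-profile
#: cluster assignment separates the three clusters reliably at n = 6/group
#: (see docs/methods.md); the up/down DEG modules use the 2-log2 shift of the
#: emulated direction-split design.
TF_DELTA = 4.0
DEG_DELTA = 2.0


def default_study_fixture(
    scale: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
    p_in: float = 0.9,
    p_out: float = 5e-4,
) -> StudyFixture:
    """Generate the full study-shaped bundle at the given gene-count scale.

    Writes matrix.tsv / samples.tsv / evidence.tsv / seeds.txt / truth.json
    when ``out_dir`` is given.  All randomness derives from ``seed`` via
    fixed offsets, so the whole bundle is reproducible from one integer.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    n_up = round(170 * scale)
    n_down = round(839 * scale)
    n_background = round(20000 * scale)
    ad_active = ["AD_3", "AD_4", "AD_5", "AD_6"]

    specs = [
        ModuleSpec("tf_control", CONTROL_TFS, factor_loading=2.0,
                   group_shift={"Control": TF_DELTA}),
        ModuleSpec("tf_ad", AD_TFS, factor_loading=1.0,
                   group_shift={"AD": TF_DELTA}, active_samples=ad_active),
        ModuleSpec("tf_joint", JOINT_TFS, factor_loading=0.5,
                   group_shift={"A20": TF_DELTA, "AD": TF_DELTA}),
        # direction-split shape: independent DEGs, no shared factor
        ModuleSpec("a20_up", n_up, factor_loading=0.0,
                   group_shift={"A20": DEG_DELTA}),
        ModuleSpec("a20_down", n_down, factor_loading=0.0,
                   group_shift={"A20": -DEG_DELTA}),
        # antiphase circadian-like pair structure: first four genes control-
        # leaning, last four aggressive-leaning, anticorrelated blocks
        ModuleSpec("circadian", CIRCADIAN_GENES, factor_loading=1.5,
                   group_shift={"Control": 2.5, "A20": -2.5},
                   antiphase_members=4),
        ModuleSpec("marker_a", [MARKER_GENES[0]], baseline_mean=float(np.log2(1000.0))),
        ModuleSpec("marker_b", [MARKER_GENES[1]], baseline_mean=float(np.log2(800.0))),
    ]
    matrix, truth = generate_dataset(
        specs, n_background_genes=n_background, groups=DEFAULT_GROUPS, seed=seed
    )
    truth.seed_genes = CONTROL_TFS + AD_TFS + JOINT_TFS

    evidence = generate_evidence_network(
        truth, p_in=p_in, p_out=p_out, seed=(seed + 1) % 2**31
    )
    # planted high-confidence hub: the first circadian gene is linked to the
    # other seven at the maximum score, emulating a curated local interactome
    hub = CIRCADIAN_GENES[0]
    for g in CIRCADIAN_GENES[1:]:
        evidence.add_edge(hub, g, 1.0)

    seeds = GeneSet(name="seed_tfs", genes=list(truth.seed_genes))
    fixture = StudyFixture(matrix=matrix, truth=truth, evidence=evidence, seeds=seeds)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out / "matrix.tsv",
            "samples": out / "samples.tsv",
            "evidence": out / "evidence.tsv",
            "seeds": out / "seeds.txt",
            "truth": out / "truth.json",
        }
        write_expression_matrix(matrix, paths["matrix"], paths["samples"])
        write_edge_list(evidence, paths["evidence"])
        write_gene_list(seeds, paths["seeds"])
        paths["truth"].write_text(truth.to_json(), encoding="utf-8")
        fixture.paths = paths
    return fixture
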