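"""Correlation-input PCA, AHC, cluster assignment and half-plane tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from striatnet import projection as pj
from striatnet.covariation import CorrelationMatrix
from striatnet.iofmt import ExpressionMatrix, GeneSet


def _em(rows: dict, groups=None):
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    groups = groups or {c: "G" for c in df.columns}
    return ExpressionMatrix(values=df, sample_groups=groups)


class TestPCACorrelation:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        em = _em({"Aa": [1, 2, 3, 4, 5], "Bb": [2, 4, 6, 8, 10]})
        proj = pj.pca_correlation(em, GeneSet(name="g", genes=["Aa", "Bb"]))
        assert proj.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_pair_splits_variance(self):
        # orthogonal, zero-correlation profiles
        em = _em({"Aa": [1, 2, 1, 2], "Bb": [1, 1, 2, 2]})
        proj = pj.pca_correlation(em, GeneSet(name="g", genes=["Aa", "Bb"]))
        assert proj.eigenvalues == pytest.approx([1.0, 1.0], abs=1e-12)
        assert proj.variance_fraction == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_equicorrelation_closed_form(self):
        """All off-diagonals 0.5 -> eigenvalues (2, 0.5, 0.5)."""
        rng = np.random.default_rng(3)
        f = rng.normal(size=4000)
        rows = {}
        for i in range(3):
            # pairwise r -> 0.5; offset keeps FPKM non-negative
            rows[f"Gg{i}"] = 50.0 + f + rng.normal(size=4000)
        em = _em(rows)
        proj = pj.pca_correlation(em, GeneSet(name="g", genes=list(rows)))
        assert proj.eigenvalues == pytest.approx([2.0, 0.5, 0.5], abs=0.06)

    def test_eigenvalues_sum_to_gene_count_and_fractions_to_one(self, study_fixture):
        genes = GeneSet(name="g", genes=study_fixture.seeds.genes)
        proj = pj.pca_correlation(study_fixture.matrix, genes)
        assert proj.eigenvalues.sum() == pytest.approx(len(genes), rel=1e-10)
        assert proj.variance_fraction.sum() == pytest.approx(1.0, rel=1e-12)

    def test_scores_invariant_to_gene_order_and_affine_rescaling(self):
        rng = np.random.default_rng(8)
        rows = {f"Gg{i}": rng.normal(5, 2, 10) for i in range(4)}
        em = _em(rows)
        base = pj.pca_correlation(em, GeneSet(name="g", genes=list(rows)))
        # per-gene positive affine rescaling + reversed gene order
        rows2 = {g: 3.0 * v + 7.0 for g, v in reversed(list(rows.items()))}
        em2 = _em(rows2)
        other = pj.pca_correlation(em2, GeneSet(name="g", genes=list(rows2)))
        assert np.allclose(
            base.sample_scores.values, other.sample_scores.values, atol=1e-8
        )

    def test_constant_gene_is_error(self):
        em = _em({"Aa": [1, 2, 3, 4], "Flat1": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="Flat1"):
            pj.pca_correlation(em, GeneSet(name="g", genes=["Aa", "Flat1"]))


class TestAHCCluster:
    @staticmethod
    def _two_block_matrix():
        genes = ["Aa", "Ab", "Ac", "Ba", "Bb", "Bc"]
        r = np.zeros((6, 6))
        for i, j in itertools.product(range(6), repeat=2):
            same = (i < 3) == (j < 3)
            r[i, j] = 1.0 if i == j else (0.9 if same else 0.0)
        return CorrelationMatrix(genes=genes, r=r, n=18)

    def test_two_blocks_recovered(self):
        cm = self._two_block_matrix()
        labels = pj.ahc_cluster(cm, k=2)
        assert labels["Aa"] == labels["Ab"] == labels["Ac"]
        assert labels["Ba"] == labels["Bb"] == labels["Bc"]
        assert labels["Aa"] != labels["Ba"]

    def test_k_equals_n_gives_singletons(self):
        cm = self._two_block_matrix()
        labels = pj.ahc_cluster(cm, k=6)
        assert len(set(labels.values())) == 6

    def test_identical_rows_merge_first(self):
        genes = ["Aa", "Ab", "Cc"]
        r = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]])
        cm = CorrelationMatrix(genes=genes, r=r, n=18)
        labels = pj.ahc_cluster(cm, k=2)
        assert labels["Aa"] == labels["Ab"] != labels["Cc"]

    def test_k_larger_than_items_is_error(self):
        with pytest.raises(ValueError):
            pj.ahc_cluster(self._two_block_matrix(), k=7)


class TestAssignGeneClusters:
    def test_planted_single_group_gene(self, study_fixture):
        a = pj.assign_gene_clusters(study_fixture.matrix, study_fixture.seeds)
        assert a["Ctf1"].label == "Control"

    def test_joint_elevation_gets_joint_label(self):
        groups = {f"s{i}": ["Control", "A20", "AD"][i // 4] for i in range(12)}
        rng = np.random.default_rng(0)
        rows = {"Jj1": np.concatenate([np.full(4, 4.0), np.full(8, 64.0)])
                + rng.normal(0, 0.3, 12)}
        rows["Var1"] = rng.lognormal(2, 1, 12)
        em = _em(rows, groups=groups)
        a = pj.assign_gene_clusters(em, GeneSet(name="g", genes=["Jj1"]))
        assert a["Jj1"].label == "A20/AD"
        assert a["Jj1"].ambiguous

    def test_seed_set_cluster_split_recovered(self, study_fixture):
        a = pj.assign_gene_clusters(study_fixture.matrix, study_fixture.seeds)
        truth = {
            **{g: "Control" for g in study_fixture.truth.modules["tf_control"]},
            **{g: "AD" for g in study_fixture.truth.modules["tf_ad"]},
            **{g: "A20/AD" for g in study_fixture.truth.modules["tf_joint"]},
        }
        correct = sum(a[g].label == lab for g, lab in truth.items())
        assert correct >= 10  # at least ~90% of the 12 seeds


def _score_projection(scores: dict, groups: dict):
    """Minimal PCAProjection carrying prescribed PC1 scores."""
    samples = list(scores)
    df = pd.DataFrame({"PC1": [scores[s] for s in samples]}, index=samples)
    return pj.PCAProjection(
        genes=["Aa", "Bb"],
        eigenvalues=np.array([1.5, 0.5]),
        variance_fraction=np.array([0.75, 0.25]),
        sample_scores=df,
        gene_loadings=pd.DataFrame({"PC1": [1.0, 0.5]}, index=["Aa", "Bb"]),
        sample_groups=groups,
    )


class TestHalfPlaneTest:
    def test_binomial_all_in_one_half(self):
        groups = {f"g{i}": "A20" for i in range(6)}
        groups.update({f"o{i}": "Control" for i in range(6)})
        scores = {f"g{i}": -1.0 - i for i in range(6)}
        scores.update({f"o{i}": (-1) ** i * (i + 1.0) for i in range(6)})
        res = pj.half_plane_test(_score_projection(scores, groups), "A20")
        assert res.in_majority_half == 6
        assert res.p_value == pytest.approx(1 / 64)

    def test_hypergeometric_nine_nine_split(self):
        groups = {f"g{i}": "AD" for i in range(6)}
        groups.update({f"o{i}": "Other" for i in range(12)})
        scores = {f"g{i}": 1.0 + i for i in range(6)}
        scores.update({f"o{i}": (3.0 + i if i < 3 else -1.0 - i) for i in range(12)})
        proj = _score_projection(scores, groups)
        res = pj.half_plane_test(proj, "AD", variant="hypergeometric_split")
        # 9 positive of 18; all 6 AD in the positive half
        assert res.p_value == pytest.approx(
            math.comb(9, 6) / math.comb(18, 6), rel=1e-12
        )

    def test_balanced_split_is_never_significant(self):
        groups = {f"g{i}": "A20" for i in range(6)}
        scores = {f"g{i}": (-1.0 if i < 3 else 1.0) for i in range(6)}
        res = pj.half_plane_test(_score_projection(scores, groups), "A20")
        assert res.in_majority_half == 3
        assert res.p_value > 0.5

    def test_zero_score_goes_positive_and_is_flagged(self):
        groups = {"g0": "A20", "g1": "A20", "g2": "A20"}
        scores = {"g0": 0.0, "g1": 1.0, "g2": 2.0}
        res = pj.half_plane_test(_score_projection(scores, groups), "A20")
        assert res.zero_scores_flagged == 1
        assert res.in_majority_half == 3

    @pytest.mark.parametrize("variant", ["binomial_per_sample", "hypergeometric_split"])
    def test_exact_against_enumeration(self, variant):
        """Both constructions agree with brute-force enumeration (n <= 12)."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            g = int(rng.integers(2, min(6, n - 1) + 1))
            scores = {f"s{i}": float(rng.normal()) for i in range(n)}
            groups = {f"s{i}": ("T" if i < g else "O") for i in range(n)}
            proj = _score_projection(scores, groups)
            res = pj.half_plane_test(proj, "T", variant=variant)
            pos = [s for s in scores if scores[s] >= 0]
            m = res.in_majority_half
            if variant == "binomial_per_sample":
                # one-sided: count fair-coin half assignments with >= m in
                # the designated half
                total = 2 ** g
                hits = sum(
                    1 for bits in itertools.product([0, 1], repeat=g)
                    if sum(bits) >= m
                )
                assert res.p_value == pytest.approx(hits / total, rel=1e-12)
            else:
                H = len(pos) if sum(scores[s] >= 0 for s in groups if groups[s] == "T") * 2 >= g else n - len(pos)
                others = n - g
                hits = total = 0
                for chosen in itertools.combinations(range(n), H):
                    total += 1
                    in_half = sum(1 for i in chosen if i < g)
                    hits += in_half >= m
                assert res.p_value == pytest.approx(hits / total, rel=1e-12)
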