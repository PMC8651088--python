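"""Normalization, differential expression, translation efficiency, torso
counts, and hypergeometric enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tuarch import expression
from tuarch.models import CountMatrix, ExtremityPartition
from tuarch.simulate import SimConfig, simulate_counts

from conftest import make_gene, make_track
from test_simulate import _truth_for_counts


def cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(gene_ids=genes, sample_ids=samples, counts=counts)


class TestSizeFactors:
    def test_median_of_ratios_hand_example(self):
        factors = expression.size_factors(cm([[100, 200], [10, 20], [40, 80]]))
        assert factors == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        factors = expression.size_factors(cm([[5, 5], [80, 80], [13, 13]]))
        assert factors == pytest.approx([1.0, 1.0])

    def test_scale_equivariance(self):
        base = np.array([[100, 200], [10, 20], [40, 80]])
        f0 = expression.size_factors(cm(base))
        scaled = base.copy()
        scaled[:, 0] *= 3
        f1 = expression.size_factors(cm(scaled))
        # equivariance holds up to the overall geometric-mean renormalization:
        assert f1[0] / f1[1] == pytest.approx(3 * f0[0] / f0[1], rel=1e-9)

    def test_all_zero_gene_matrix_rejected(self):
        with pytest.raises(ValueError, match="nonzero count in every sample"):
            expression.size_factors(cm([[0, 5], [3, 0]]))

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.integers(1, 2000, size=(50, 4))
            factors = expression.size_factors(cm(counts))
            renorm = expression.size_factors(counts / factors[None, :])
            assert renorm == pytest.approx(np.ones(4), abs=1e-9)


class TestNormalize:
    def test_continues_hand_example(self):
        mat = cm([[100, 200]])
        out = expression.normalize(mat, np.array([0.7071, 1.4142]))
        assert out.to_numpy().flatten() == pytest.approx([141.42, 141.42], abs=0.01)

    def test_unit_factors_are_identity(self):
        mat = cm([[3, 7], [0, 0]])
        out = expression.normalize(mat, np.ones(2))
        assert np.array_equal(out.to_numpy(), mat.counts)
        assert (out.loc["g1"] == 0).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="size factors"):
            expression.normalize(cm([[1, 2]]), np.ones(3))


class TestExpressedGenes:
    DESIGN = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}

    def _norm(self, means):
        data = {s: [means[self.DESIGN[s]]] for s in self.DESIGN}
        return pd.DataFrame(data, index=["g"])

    def test_floor_respected_per_condition(self):
        assert expression.expressed_genes(
            self._norm({"A": 12, "B": 11, "C": 15}), self.DESIGN
        ) == ["g"]
        assert expression.expressed_genes(
            self._norm({"A": 12, "B": 9, "C": 15}), self.DESIGN
        ) == []

    def test_zero_floor_keeps_any_expression(self):
        assert expression.expressed_genes(
            self._norm({"A": 0.1, "B": 0, "C": 0}), self.DESIGN, floor=0
        ) == ["g"]


class TestCallDegs:
    DESIGN = {"CTRL_1": "CTRL", "CTRL_2": "CTRL", "HL_1": "HL", "HL_2": "HL"}

    def _frame(self, ctrl, hl):
        return pd.DataFrame(
            {"CTRL_1": ctrl, "CTRL_2": ctrl, "HL_1": hl, "HL_2": hl},
            index=[f"g{i}" for i in range(len(ctrl))],
        ).astype(float) + np.random.default_rng(0).normal(0, 1e-4, (len(ctrl), 4))

    def test_five_fold_change_is_deg(self):
        (res,) = expression.call_degs(
            self._frame([10], [50]), self.DESIGN, "HL", "CTRL", pseudocount=0
        )
        assert res.log2fc == pytest.approx(math.log2(5), abs=0.01)
        assert res.is_deg and res.direction == "up"

    def test_null_gene_not_called(self):
        (res,) = expression.call_degs(self._frame([20], [20]), self.DESIGN, "HL", "CTRL")
        assert abs(res.log2fc) < 0.01 and not res.is_deg and res.direction == "none"

    def test_fold_change_gate_beats_tiny_p(self):
        def always_significant(a, b):
            return 1e-9

        (res,) = expression.call_degs(
            self._frame([100], [100 * 2**0.9]), self.DESIGN, "HL", "CTRL",
            pseudocount=0, test=always_significant,
        )
        assert res.log2fc == pytest.approx(0.9, abs=0.01)
        assert not res.is_deg

    def test_single_replicate_rejected(self):
        design = {"CTRL_1": "CTRL", "HL_1": "HL"}
        frame = pd.DataFrame({"CTRL_1": [1.0], "HL_1": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            expression.call_degs(frame, design, "HL", "CTRL")

    def test_recovery_on_negative_binomial_data(self):
        """Sensitivity >= 0.9 and FPR <= 0.05 at planted |log2FC| = 2,
        3 replicates, dispersion 0.05."""
        n = 1000
        rng = np.random.default_rng(42)
        lfc = np.zeros(n)
        planted = rng.choice(n, size=100, replace=False)
        lfc[planted] = rng.choice([-2.0, 2.0], size=100)
        truth = _truth_for_counts(n, rng.uniform(200, 2000, n), lfc)
        cfg = SimConfig(
            seed=13, n_genes=n, genome_length=10_000_000, nb_dispersion=0.05,
            conditions=("CTRL", "LT"), n_replicates=3,
        )
        rna, _ = simulate_counts(truth, cfg)
        design = {s: s.split("_")[0] for s in rna.sample_ids}
        norm = expression.normalize(rna, expression.size_factors(rna))
        res = expression.call_degs(norm, design, "LT", "CTRL")
        called = np.array([r.is_deg for r in res])
        is_planted = np.zeros(n, dtype=bool)
        is_planted[planted] = True
        sensitivity = called[is_planted].mean()
        fpr = called[~is_planted].mean()
        assert sensitivity >= 0.9
        assert fpr <= 0.05


class TestTranslationEfficiency:
    DESIGN = {"CTRL_1": "CTRL", "CTRL_2": "CTRL"}

    def _te(self, rna, rpf, pc):
        rna_df = pd.DataFrame({"CTRL_1": [rna], "CTRL_2": [rna]}, index=["g"], dtype=float)
        rpf_df = pd.DataFrame({"CTRL_1": [rpf], "CTRL_2": [rpf]}, index=["g"], dtype=float)
        res = expression.translation_efficiency(
            rna_df, rpf_df, self.DESIGN, pseudocount=pc, floor=0
        )
        return res[0].te if res else None

    def test_definition(self):
        assert self._te(100, 50, pc=0) == pytest.approx(0.5)

    def test_pseudocount_floor(self):
        assert self._te(0.01, 0, pc=1) == pytest.approx(1.0, abs=0.01)

    def test_homogeneity(self):
        assert self._te(200, 50, pc=0) == pytest.approx(self._te(100, 50, pc=0) / 2)

    def test_relative_te_invariant_under_global_rpf_scaling(self):
        """Median-of-ratios factors are invariant to a global library
        rescaling, so scaling every RPF library by the same constant shifts
        all TEs by exactly that constant and leaves relative TE (the quantity
        compared across genes and conditions) unchanged."""
        cfg = SimConfig(seed=14, n_genes=50, genome_length=10_000_000,
                        conditions=("CTRL", "LT"), n_replicates=2)
        rng = np.random.default_rng(3)
        truth = _truth_for_counts(50, rng.uniform(100, 1000, 50), np.zeros(50))
        rna, rpf = simulate_counts(truth, cfg)
        design = {s: s.split("_")[0] for s in rna.sample_ids}
        rna_norm = expression.normalize(rna, expression.size_factors(rna))

        def te_of(rpf_counts):
            mat = CountMatrix(rpf.gene_ids, rpf.sample_ids, rpf_counts)
            norm = expression.normalize(mat, expression.size_factors(mat))
            return [
                t.te for t in expression.translation_efficiency(
                    rna_norm, norm, design, pseudocount=0, floor=0
                )
            ]

        base = np.array(te_of(rpf.counts))
        scaled = np.array(te_of(rpf.counts * 7))
        assert scaled == pytest.approx(base * 7, rel=1e-9)
        assert scaled / scaled[0] == pytest.approx(base / base[0], rel=1e-9)


class TestTorsoCounts:
    def test_uniform_depth_window_arithmetic(self):
        gene = make_gene(cds_start=101, cds_end=400)  # 300-bp CDS
        track = make_track(np.full(600, 2.0))
        part = ExtremityPartition()
        assert expression.torso_counts(track, gene, part) == pytest.approx(2 * 207)

    def test_depth_confined_to_extremities(self):
        gene = make_gene(cds_start=101, cds_end=400)
        depth = np.zeros(600)
        part = ExtremityPartition()
        for pos in part.start_extremity_positions(gene) + part.stop_extremity_positions(gene):
            depth[pos - 1] = 5.0
        assert expression.torso_counts(make_track(depth), gene, part) == 0.0

    def test_short_cds_has_no_torso(self):
        gene = make_gene(cds_start=101, cds_end=190)  # 90 bp
        with pytest.raises(ValueError, match="torso empty"):
            expression.torso_counts(make_track(np.ones(400)), gene, ExtremityPartition())


def exact_hypergeom_upper_tail(N, K, n, k):
    """Independent oracle: exact combinatorial tail sum as a Fraction."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return total


class TestEnrichment:
    def test_worked_example(self):
        background = [f"g{i}" for i in range(100)]
        term_genes = background[:10]
        query = background[:3] + background[95:97]  # 3 of 5 in the term
        df = expression.hypergeom_enrichment(query, {"T": term_genes}, background)
        expected = float(exact_hypergeom_upper_tail(100, 10, 5, 3))
        assert df.loc[0, "p"] == pytest.approx(expected, abs=1e-10)
        assert df.loc[0, "p"] == pytest.approx(0.00664, abs=5e-5)

    def test_matches_exact_oracle_on_random_configurations(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            background = [f"g{i}" for i in range(N)]
            term = set(rng.choice(background, size=K, replace=False))
            query = set(rng.choice(background, size=n, replace=False))
            k = len(term & query)
            df = expression.hypergeom_enrichment(query, {"T": term}, background)
            assert df.loc[0, "k"] == k
            expected = float(exact_hypergeom_upper_tail(N, K, n, k))
            assert df.loc[0, "p"] == pytest.approx(expected, abs=1e-10)

    def test_disjoint_term_has_p_one(self):
        background = [f"g{i}" for i in range(50)]
        df = expression.hypergeom_enrichment(
            background[:5], {"T": background[40:]}, background
        )
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_single_term_bh_identity(self):
        background = [f"g{i}" for i in range(50)]
        df = expression.hypergeom_enrichment(
            background[:5], {"T": background[:8]}, background
        )
        assert df.loc[0, "p_adjusted"] == pytest.approx(df.loc[0, "p"])

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            expression.hypergeom_enrichment(["x"], {"T": ["a"]}, ["a", "b"])
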