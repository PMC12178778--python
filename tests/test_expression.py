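"""Normalization, HVG selection, dot-plot statistics and tau specificity."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from irdselect import expression as E
from irdselect.errors import ConfigurationError, DataIntegrityError, DomainError


def counts_from_dense(dense, types, genes=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{j}" for j in range(dense.shape[1])]
    return E.LabeledCounts(sp.csr_matrix(dense), np.asarray(types, dtype=object), genes)


class TestLabeledCounts:
    def test_label_count_mismatch_rejected(self):
        with pytest.raises(DataIntegrityError):
            counts_from_dense([[1, 2]], ["a", "b"])

    def test_duplicate_gene_symbols_rejected(self):
        with pytest.raises(DataIntegrityError, match="dup"):
            counts_from_dense([[1, 2]], ["a"], genes=["dup", "dup"])


class TestNormalize:
    def test_worked_example_scale_then_log1p(self):
        lc = counts_from_dense([[2, 0, 8]], ["a"])
        out = E.normalize(lc, target_sum=10).toarray().ravel()
        assert out == pytest.approx([np.log(3), 0.0, np.log(9)])

    def test_zero_cell_rejected(self):
        lc = counts_from_dense([[1, 1], [0, 0]], ["a", "b"])
        with pytest.raises(DomainError, match="zero total"):
            E.normalize(lc)

    def test_depth_invariance(self):
        lc1 = counts_from_dense([[2, 0, 8]], ["a"])
        lc2 = counts_from_dense([[4, 0, 16]], ["a"])
        np.testing.assert_allclose(
            E.normalize(lc1).toarray(), E.normalize(lc2).toarray()
        )

    def test_matches_scanpy_normalization(self, labeled_counts, normalized):
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        adata = ad.AnnData(labeled_counts.matrix.astype(float))
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        np.testing.assert_allclose(
            np.asarray(adata.X.todense()), normalized.toarray(), rtol=1e-10, atol=1e-12
        )


class TestSelectHVG:
    def test_constant_gene_excluded(self):
        # gene 0 constant across equal-depth cells -> zero dispersion
        dense = np.array([[5, 1, 9], [5, 9, 1], [5, 5, 5], [5, 2, 8]])
        lc = counts_from_dense(dense, list("abcd"))
        norm = E.normalize(lc, target_sum=15)
        out = E.select_hvg(norm, lc.gene_symbols, E.HVGParams(
            min_mean=1e-3, max_mean=1e6, min_disp=0.5, n_bins=1))
        assert not out.set_index("gene").loc["g0", "highly_variable"]

    def test_gene_above_max_mean_excluded_despite_dispersion(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, size=(50, 10))
        dense[:, 0] = rng.poisson(500, size=50) * 10  # huge mean, huge variance
        dense += 1  # avoid zero cells
        lc = counts_from_dense(dense, ["t"] * 50)
        norm = E.normalize(lc)
        out = E.select_hvg(norm, lc.gene_symbols, E.HVGParams(
            min_mean=0.0125, max_mean=3.0, min_disp=0.5))
        assert not out.set_index("gene").loc["g0", "highly_variable"]

    def test_planted_bimodal_gene_included(self):
        # half the cells silent, half high: large binned dispersion
        rng = np.random.default_rng(1)
        dense = rng.poisson(5.0, size=(100, 30)).astype(float)
        dense[:50, 0] = 0
        dense[50:, 0] = rng.poisson(60, size=50)
        lc = counts_from_dense(dense + (dense.sum(1, keepdims=True) == 0), ["t"] * 100)
        norm = E.normalize(lc, target_sum=dense.sum(1).mean())
        out = E.select_hvg(norm, lc.gene_symbols, E.HVGParams(
            min_mean=0.1, max_mean=1e6, min_disp=0.5, n_bins=5))
        assert out.set_index("gene").loc["g0", "highly_variable"]

    def test_bins_reduced_with_warning_when_few_genes(self):
        lc = counts_from_dense([[1, 2, 3], [3, 2, 1]], ["a", "b"])
        norm = E.normalize(lc)
        with pytest.warns(UserWarning, match="reducing"):
            E.select_hvg(norm, lc.gene_symbols, E.HVGParams(n_bins=20))

    def test_invariant_to_gene_and_cell_permutations(self, rng):
        dense = rng.poisson(2.0, size=(40, 12)) + 1
        lc = counts_from_dense(dense, ["t"] * 40)
        params = E.HVGParams(min_mean=1e-3, max_mean=1e6, min_disp=0.25, n_bins=4)
        base = E.select_hvg(E.normalize(lc), lc.gene_symbols, params)
        gperm = rng.permutation(12)
        cperm = rng.permutation(40)
        lc2 = counts_from_dense(
            dense[np.ix_(cperm, gperm)], ["t"] * 40, genes=[f"g{j}" for j in gperm]
        )
        perm = E.select_hvg(E.normalize(lc2), lc2.gene_symbols, params)
        merged = base.set_index("gene").join(perm.set_index("gene"), rsuffix="_p")
        assert (merged.highly_variable == merged.highly_variable_p).all()
        np.testing.assert_allclose(merged.dispersion_norm, merged.dispersion_norm_p)


def naive_dot_statistics(dense, norm_dense, labels, genes, gene_symbols):
    """Independent double-loop oracle for the dot-plot statistics."""
    rows = []
    for gene in genes:
        for cell_type in sorted(set(labels)):
            n_t = expressed = 0
            total = 0.0
            for i, label in enumerate(labels):
                if label != cell_type:
                    continue
                n_t += 1
                if gene in gene_symbols:
                    j = gene_symbols.index(gene)
                    if dense[i][j] > 0:
                        expressed += 1
                    total += norm_dense[i][j]
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "fraction_expressing": expressed / n_t if n_t else 0.0,
                    "mean_expression": total / n_t if n_t else 0.0,
                }
            )
    return pd.DataFrame(rows)


class TestDotStatistics:
    def test_fraction_by_direct_count(self):
        lc = counts_from_dense([[0], [0], [1], [3]], ["t", "t", "t", "t"])
        # avoid the zero-cell rejection by adding a housekeeping column
        lc = counts_from_dense([[0, 1], [0, 1], [1, 1], [3, 1]], ["t"] * 4)
        norm = E.normalize(lc)
        out = E.dot_statistics(norm, lc, ["g0"])
        assert out.fraction_expressing.iloc[0] == pytest.approx(0.5)

    def test_absent_gene_gets_zero_rows_for_every_type(self):
        lc = counts_from_dense([[1, 2], [2, 1]], ["a", "b"])
        out = E.dot_statistics(E.normalize(lc), lc, ["missing"])
        assert len(out) == 2
        assert (out.fraction_expressing == 0).all()
        assert (out.mean_expression == 0).all()

    def test_matches_naive_oracle_exactly(self, rng):
        dense = rng.poisson(0.8, size=(200, 50))
        dense[:, 0] += 1  # no zero cells
        labels = [f"T{k}" for k in rng.integers(0, 4, size=200)]
        lc = counts_from_dense(dense, labels)
        norm = E.normalize(lc)
        genes = [f"g{j}" for j in range(50)] + ["absent"]
        fast = E.dot_statistics(norm, lc, genes)
        slow = naive_dot_statistics(
            dense.tolist(), norm.toarray().tolist(), labels, genes, lc.gene_symbols
        )
        merged = fast.merge(slow, on=["gene", "cell_type"], suffixes=("", "_naive"))
        assert len(merged) == len(fast)
        np.testing.assert_array_equal(
            merged.fraction_expressing, merged.fraction_expressing_naive
        )
        np.testing.assert_allclose(
            merged.mean_expression, merged.mean_expression_naive, rtol=1e-12
        )

    def test_planted_markers_recovered(self, sim_config, bundle, labeled_counts, normalized):
        markers = bundle["manifest"]["markers"]
        all_markers = [g for gs in markers.values() for g in gs]
        dot = E.dot_statistics(normalized, labeled_counts, all_markers)
        for cell_type, genes in markers.items():
            for g in genes:
                own = dot[(dot.gene == g) & (dot.cell_type == cell_type)]
                other = dot[(dot.gene == g) & (dot.cell_type != cell_type)]
                assert own.fraction_expressing.iloc[0] > 0.9
                assert (other.fraction_expressing < 0.1).all()


class TestSpecificityTau:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([1, 1, 1, 1], 0.0),
            ([0, 0, 1, 0], 1.0),
            ([2, 1, 1, 1], 0.5),
            ([0, 0, 0], 0.0),
        ],
    )
    def test_reference_values(self, vec, expected):
        assert E.specificity_tau(np.array(vec)) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        vec = rng.uniform(0.1, 5.0, size=6)
        assert E.specificity_tau(vec) == pytest.approx(E.specificity_tau(vec * 13.7))

    def test_monotone_under_concentration(self):
        taus = [
            E.specificity_tau(np.array([peak, 1.0, 1.0, 1.0])) for peak in (1, 2, 5, 50)
        ]
        assert taus == sorted(taus)

    def test_requires_two_types(self):
        with pytest.raises(DomainError):
            E.specificity_tau(np.array([1.0]))

    def test_markers_maximize_tau_in_fixture(self, bundle, labeled_counts, normalized):
        markers = [g for gs in bundle["manifest"]["markers"].values() for g in gs]
        ubiquitous = bundle["manifest"]["ubiquitous"][1:]  # even-level set
        dot = E.dot_statistics(normalized, labeled_counts, markers + list(ubiquitous))
        tau = E.specificity_table(dot).set_index("gene")["specificity_tau"]
        assert tau.loc[markers].min() > tau.loc[list(ubiquitous)].max()
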