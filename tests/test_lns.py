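"""Local Network Similarity: closed forms, brute-force oracle equivalence,
randomization-null behaviour and the module-level summaries."""

import numpy as np
import pandas as pd
import pytest

from rhodonet import (
    ModulePartition,
    NetworkParams,
    OrthologMap,
    ValidationError,
    atanh_corr,
    bicor_matrix,
    lns_all,
    lns_null,
    lns_vs_kmeall,
    median_lns_per_module,
    module_preservation,
    restrict_to_common,
    within_species_lns,
)
from rhodonet.lns import AtanhCorrMatrix, _lns_core
from rhodonet.network import CorrMatrix

from conftest import expr_from_array


def lns_reference(WA, WB, k):
    """Explicit-loop LNS of pair k for aligned matrices."""
    n = WA.shape[0]
    a, b = [], []
    for j in range(n):
        if j == k:
            continue
        a.append(WA[k, j])
        b.append(WB[k, j])
    a, b = np.asarray(a), np.asarray(b)
    am, bm = a - a.mean(), b - b.mean()
    return float(am @ bm / np.sqrt((am @ am) * (bm @ bm)))


def _atanh_from_array(W, genes=None):
    genes = genes or [f"g{i}" for i in range(W.shape[0])]
    return AtanhCorrMatrix(pd.DataFrame(W, index=genes, columns=genes))


def _random_aligned(rng, n, n_cond=30):
    WA = atanh_corr(bicor_matrix(expr_from_array(rng.standard_normal((n, n_cond)))))
    WB = atanh_corr(bicor_matrix(expr_from_array(rng.standard_normal((n, n_cond)))))
    WB.data.index = WA.data.index
    WB.data.columns = WA.data.columns
    return WA, WB


class TestAtanh:
    def test_closed_forms_and_clipping(self):
        genes = list("abc")
        R = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -1.0], [0.5, -1.0, 1.0]])
        cor = CorrMatrix(pd.DataFrame(R, index=genes, columns=genes))
        W = atanh_corr(cor).values
        assert W[0, 1] == 0.0
        assert W[0, 2] == pytest.approx(np.log(3) / 2, rel=1e-12)
        assert np.isfinite(W).all()
        assert W[0, 0] > 13  # clipped atanh(1)
        assert W[1, 2] < -13


class TestLnsAll:
    def test_self_similarity_is_exactly_one(self, rng):
        WA, _ = _random_aligned(rng, 20)
        ident = OrthologMap.identity(WA.gene_ids)
        out = lns_all(WA, WA, ident)
        assert (out["lns"].to_numpy() == 1.0).all()

    def test_anti_network_gives_minus_one(self, rng):
        WA, _ = _random_aligned(rng, 15)
        WB = _atanh_from_array(-WA.values, WA.gene_ids)
        out = lns_all(WA, WB, OrthologMap.identity(WA.gene_ids))
        np.testing.assert_allclose(out["lns"], -1.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for n in (5, 12, 25):
            WA, WB = _random_aligned(rng, n)
            out = lns_all(WA, WB, OrthologMap.identity(WA.gene_ids))
            for k in range(n):
                assert out["lns"].iloc[k] == pytest.approx(
                    lns_reference(WA.values, WB.values, k), abs=1e-12
                )

    def test_four_gene_hand_fixture(self):
        WA = np.array(
            [
                [5.0, 0.2, -0.1, 0.4],
                [0.2, 5.0, 0.3, -0.2],
                [-0.1, 0.3, 5.0, 0.1],
                [0.4, -0.2, 0.1, 5.0],
            ]
        )
        WB = np.array(
            [
                [5.0, 0.1, 0.0, 0.5],
                [0.1, 5.0, 0.4, -0.1],
                [0.0, 0.4, 5.0, 0.2],
                [0.5, -0.1, 0.2, 5.0],
            ]
        )
        out = lns_all(_atanh_from_array(WA), _atanh_from_array(WB),
                      OrthologMap.identity([f"g{i}" for i in range(4)]))
        for k in range(4):
            assert out["lns"].iloc[k] == pytest.approx(
                lns_reference(WA, WB, k), abs=1e-12
            )

    def test_dataset_order_symmetry(self, rng):
        WA, WB = _random_aligned(rng, 18)
        ident = OrthologMap.identity(WA.gene_ids)
        fwd = lns_all(WA, WB, ident)["lns"].to_numpy()
        rev = lns_all(WB, WA, ident)["lns"].to_numpy()
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_simultaneous_reordering_invariance(self, rng):
        WA, WB = _random_aligned(rng, 16)
        ident = OrthologMap.identity(WA.gene_ids)
        base = lns_all(WA, WB, ident).set_index("ref_gene")["lns"]
        perm = list(np.random.default_rng(1).permutation(WA.gene_ids))
        WAp = AtanhCorrMatrix(WA.data.loc[perm, perm])
        WBp = AtanhCorrMatrix(WB.data.loc[perm, perm])
        out = lns_all(WAp, WBp, OrthologMap.identity(perm)).set_index(
            "ref_gene")["lns"]
        np.testing.assert_allclose(out.loc[base.index], base, atol=1e-12)

    def test_too_few_genes_error(self, rng):
        WA, WB = _random_aligned(rng, 5)
        tiny = [g for g in WA.gene_ids[:3]]
        WA3 = AtanhCorrMatrix(WA.data.loc[tiny, tiny])
        WB3 = AtanhCorrMatrix(WB.data.loc[tiny, tiny])
        with pytest.raises(ValidationError):
            lns_all(WA3, WB3, OrthologMap.identity(tiny))


class TestLnsNull:
    def test_null_is_centred_for_independent_networks(self, rng):
        WA, WB = _random_aligned(rng, 120)
        table, null = lns_null(WA, WB, OrthologMap.identity(WA.gene_ids),
                               n_perm=40, seed=0)
        se = null.sd / np.sqrt(null.values.size)
        assert abs(null.mean) < 3 * se

    def test_identity_signal_beats_every_null(self, rng):
        WA, _ = _random_aligned(rng, 40)
        table, null = lns_null(WA, WA, OrthologMap.identity(WA.gene_ids),
                               n_perm=25, seed=0)
        n_null = null.values.size
        np.testing.assert_allclose(table["empirical_p"],
                                   1.0 / (1.0 + n_null))
        assert (table["lns"].to_numpy() == 1.0).all()

    def test_seeded_determinism(self, rng):
        WA, WB = _random_aligned(rng, 30)
        ident = OrthologMap.identity(WA.gene_ids)
        t1, n1 = lns_null(WA, WB, ident, n_perm=10, seed=3)
        t2, n2 = lns_null(WA, WB, ident, n_perm=10, seed=3)
        np.testing.assert_array_equal(n1.values, n2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_node_shuffle_null_also_centred(self, rng):
        WA, WB = _random_aligned(rng, 60)
        _, null = lns_null(WA, WB, OrthologMap.identity(WA.gene_ids),
                           n_perm=30, seed=1, shuffle_nodes=True)
        se = null.sd / np.sqrt(null.values.size)
        assert abs(null.mean) < 4 * se


class TestWithinSpecies:
    def test_module_genes_exceed_noise_genes(self, planted_scenario):
        zA = planted_scenario["zA"]
        truth = planted_scenario["truth"].labels_series()
        per_gene, table = within_species_lns(zA, n_rep=8, seed=2)
        module_median = per_gene[truth > 0].median()
        noise_median = per_gene[truth == 0].median()
        assert module_median > 0.5
        assert module_median > noise_median + 0.3
        assert table.shape == (zA.n_genes, 8)

    def test_single_repeat_deterministic(self, planted_scenario):
        zA = planted_scenario["zA"].subset_genes(
            planted_scenario["zA"].gene_ids[:60]
        )
        a, _ = within_species_lns(zA, n_rep=1, seed=9)
        b, _ = within_species_lns(zA, n_rep=1, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_conditions(self, rng):
        with pytest.raises(ValidationError):
            within_species_lns(expr_from_array(rng.standard_normal((30, 6))),
                               n_rep=2)


class TestModuleSummaries:
    def test_median_by_definition(self):
        table = pd.DataFrame(
            {"ref_gene": ["a", "b", "c", "d"],
             "test_gene": ["a", "b", "c", "d"],
             "lns": [0.2, 0.4, 0.9, -0.5]}
        )
        part = ModulePartition(pd.Series({"a": 1, "b": 1, "c": 1, "d": 2}))
        med = median_lns_per_module(table, part)
        assert med[1] == 0.4
        assert med[2] == -0.5  # single-pair module

    def test_preserved_modules_score_higher(self, planted_scenario):
        zA, zB = planted_scenario["zA"], planted_scenario["zB"]
        part = planted_scenario["partition"]
        r, t, p = restrict_to_common(zA, zB, planted_scenario["mapping"], part)
        WA = atanh_corr(bicor_matrix(r))
        WB = atanh_corr(bicor_matrix(t))
        out = lns_all(WA, WB, OrthologMap.identity(r.gene_ids))
        med = median_lns_per_module(out, p)
        truth = planted_scenario["truth"].preserved
        pres = [m for m, f in truth.items() if f]
        non = [m for m, f in truth.items() if not f]
        assert med[pres].min() > med[non].max() + 0.3

    def test_lns_vs_kmeall_tracks_preservation(self, planted_scenario):
        zA, zB = planted_scenario["zA"], planted_scenario["zB"]
        part = planted_scenario["partition"]
        r, t, p = restrict_to_common(zA, zB, planted_scenario["mapping"], part)
        WA = atanh_corr(bicor_matrix(r))
        WB = atanh_corr(bicor_matrix(t))
        out = lns_all(WA, WB, OrthologMap.identity(r.gene_ids))
        med = median_lns_per_module(out, p)
        rep = module_preservation(r, t, p, NetworkParams(), n_perm=60, seed=0)
        corr, pval, paired = lns_vs_kmeall(med, rep.preservation)
        assert corr > 0.5
        assert len(paired) == 5

    def test_identical_vectors_give_r_one(self):
        med = pd.Series({1: 0.1, 2: 0.5, 3: 0.9})
        pres = pd.DataFrame({"cor.kMEall": [0.1, 0.5, 0.9]},
                            index=[1, 2, 3])
        r, p, _ = lns_vs_kmeall(med, pres)
        assert r == pytest.approx(1.0)

    def test_constant_vector_warns_and_returns_nan(self):
        med = pd.Series({1: 0.4, 2: 0.4, 3: 0.4})
        pres = pd.DataFrame({"cor.kMEall": [0.1, 0.5, 0.9]},
                            index=[1, 2, 3])
        with pytest.warns(UserWarning):
            r, p, _ = lns_vs_kmeall(med, pres)
        assert np.isnan(r)
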