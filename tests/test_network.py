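"""Network construction and module detection, checked against brute-force
oracles and planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from rhodonet import (
    ExprMatrix,
    ModulePartition,
    NetworkParams,
    ValidationError,
    bicor_matrix,
    cluster_conditions_bootstrap,
    detect_modules,
    kme,
    module_eigengenes,
    module_stability,
    signed_adjacency,
    tom_similarity,
)
from rhodonet.network import Adjacency, CorrMatrix

from conftest import expr_from_array, small_two_species


def bicor_reference(x, y):
    """Independent literal evaluation of the biweight midcorrelation."""

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        out = np.empty_like(v, dtype=float)
        for i, vi in enumerate(v):
            u = (vi - med) / (9 * mad)
            w = (1 - u**2) ** 2 if abs(u) < 1 else 0.0
            out[i] = (vi - med) * w
        return out

    xt, yt = transform(np.asarray(x, float)), transform(np.asarray(y, float))
    return float(
        np.sum(xt * yt) / (np.sqrt(np.sum(xt**2)) * np.sqrt(np.sum(yt**2)))
    )


def tom_reference(A):
    """Triple-loop topological overlap."""
    A = np.asarray(A, float)
    n = A.shape[0]
    k = np.array([A[i].sum() - A[i, i] for i in range(n)])
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestBicor:
    def test_self_and_anti_correlation(self, rng):
        x = rng.standard_normal(30)
        expr = expr_from_array(np.vstack([x, -x]))
        R = bicor_matrix(expr).values
        assert R[0, 0] == 1.0
        assert R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.standard_normal((12, 200))
        X[0, :4] += 20  # outliers exercise the biweight downweighting
        R = bicor_matrix(expr_from_array(X)).values
        for i in range(12):
            for j in range(i + 1, 12):
                assert R[i, j] == pytest.approx(
                    bicor_reference(X[i], X[j]), abs=1e-12
                )

    def test_outlier_robustness_vs_pearson(self, rng):
        x = rng.standard_normal(60)
        y = x + 0.1 * rng.standard_normal(60)
        y_out = y.copy()
        y_out[0] = 1000.0
        R = bicor_matrix(expr_from_array(np.vstack([x, y_out]))).values
        pearson = np.corrcoef(x, y_out)[0, 1]
        assert R[0, 1] > 0.9 > pearson + 0.3

    def test_mad_zero_pearson_fallback(self, rng):
        X = rng.standard_normal((3, 20))
        X[0] = np.arange(20.0)
        X[1] = np.r_[np.zeros(11), np.ones(9)]  # MAD = 0, not constant
        with pytest.warns(UserWarning, match="Pearson fallback"):
            cor = bicor_matrix(expr_from_array(X))
        assert cor.fallback_genes == ["g0001"]
        assert np.isfinite(cor.values).all()

    def test_pairwise_complete_minimum_enforced(self):
        X = np.full((2, 8), np.nan)
        X[0, :5] = [1, 2, 3, 4, 5]
        X[1, 5:] = [1, 2, 3]
        with pytest.raises(ValidationError, match="complete observations"):
            bicor_matrix(expr_from_array(X))


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r,expected",
        [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**18)],
    )
    def test_transform_values(self, r, expected):
        cor = CorrMatrix(
            pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        )
        A = signed_adjacency(cor, NetworkParams()).values
        assert A[0, 1] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        r1=st.floats(-0.999, 0.999),
        r2=st.floats(-0.999, 0.999),
    )
    def test_strictly_monotone_in_correlation(self, r1, r2):
        from hypothesis import assume

        assume(abs(r1 - r2) > 1e-9)  # below this the powers collide in fp
        cor = CorrMatrix(
            pd.DataFrame(
                [[1, r1, r2], [r1, 1, 0], [r2, 0, 1]],
                index=list("abc"), columns=list("abc"), dtype=float,
            )
        )
        A = signed_adjacency(cor, NetworkParams()).values
        if r1 > r2:
            assert A[0, 1] > A[0, 2]
        elif r2 > r1:
            assert A[0, 2] > A[0, 1]


class TestTom:
    def _adj(self, M):
        labels = [f"n{i}" for i in range(len(M))]
        return Adjacency(pd.DataFrame(np.asarray(M, float), index=labels,
                                      columns=labels))

    def test_clique_saturates_to_one(self):
        T = tom_similarity(self._adj(np.ones((3, 3)))).values
        np.testing.assert_allclose(T, 1.0)

    def test_disconnected_nodes_have_zero_overlap(self):
        T = tom_similarity(self._adj(np.eye(3))).values
        assert T[0, 1] == 0.0 and T[0, 2] == 0.0

    def test_chain_hand_value(self):
        A = [[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]]
        T = tom_similarity(self._adj(A)).values
        assert T[0, 2] == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        A = rng.random((15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(self._adj(A)).values
        np.testing.assert_allclose(T, tom_reference(A), atol=1e-12)
        assert T.min() >= 0 and T.max() <= 1


class TestEigengenes:
    def test_rank_one_module(self, rng):
        profile = rng.standard_normal(20)
        X = np.tile(profile, (5, 1))
        expr = expr_from_array(X)
        part = ModulePartition(pd.Series([1] * 5, index=expr.gene_ids))
        megs = module_eigengenes(expr, part)
        assert megs.prop_var_explained[1] == pytest.approx(1.0)
        me = megs.profiles[1].to_numpy()
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_two_orthogonal_profiles_split_variance(self):
        # two exactly orthogonal standardized profiles, equal gene counts
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        p, q = np.sin(t), np.cos(t)
        X = np.vstack([p, p, q, q])
        expr = expr_from_array(X)
        part = ModulePartition(pd.Series([1] * 4, index=expr.gene_ids))
        megs = module_eigengenes(expr, part)
        assert megs.prop_var_explained[1] == pytest.approx(0.5, abs=1e-9)

    def test_sign_oriented_to_mean_profile(self, planted_scenario):
        megs = module_eigengenes(planted_scenario["zA"],
                                 planted_scenario["partition"])
        zA = planted_scenario["zA"]
        for m in megs.module_labels:
            members = planted_scenario["partition"].members(m)
            mean_profile = zA.data.loc[members].mean(axis=0)
            c = np.corrcoef(megs.profiles[m], mean_profile)[0, 1]
            assert c >= 0

    def test_tiny_module_errors(self):
        expr = expr_from_array(np.random.default_rng(0).standard_normal((3, 8)))
        part = ModulePartition(pd.Series([1, 2, 2], index=expr.gene_ids))
        with pytest.raises(ValidationError):
            module_eigengenes(expr, part)


class TestKme:
    def test_identical_and_orthogonal_genes(self, rng):
        me = rng.standard_normal(24)
        me -= me.mean()
        g2 = rng.standard_normal(24)
        g2 -= g2.mean()
        g2 -= (g2 @ me) / (me @ me) * me  # Gram-Schmidt in centered space
        X = np.vstack([me, me, g2])
        expr = expr_from_array(X)
        part = ModulePartition(pd.Series([1, 1, 0], index=expr.gene_ids))
        megs = module_eigengenes(expr, part)
        K = kme(expr, megs, method="pearson")
        assert K.iloc[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert K.iloc[2, 0] == pytest.approx(0.0, abs=1e-10)

    def test_members_beat_random_modules(self, planted_scenario):
        zA = planted_scenario["zA"]
        part = planted_scenario["partition"]
        megs = module_eigengenes(zA, part)
        K = kme(zA, megs)
        for m in part.module_labels:
            members = part.members(m)
            own = K.loc[members, m].mean()
            others = [K.loc[members, o].mean() for o in part.module_labels
                      if o != m]
            assert own > max(others) + 0.3


class TestDetectModules:
    def test_planted_recovery(self, planted_scenario):
        part, megs, K = detect_modules(planted_scenario["zA"], NetworkParams())
        truth = planted_scenario["truth"].labels_series().loc[part.gene_ids]
        mask = truth > 0
        ari = adjusted_rand_score(truth[mask], part.labels[mask])
        assert ari >= 0.9
        assert len(part.module_labels) == 5

    def test_row_permutation_invariance(self, planted_scenario):
        zA = planted_scenario["zA"]
        part1, _, _ = detect_modules(zA, NetworkParams())
        shuffled = zA.subset_genes(
            list(np.random.default_rng(3).permutation(zA.gene_ids))
        )
        part2, _, _ = detect_modules(shuffled, NetworkParams())
        joined = part1.labels.to_frame("a").join(part2.labels.rename("b"))
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_all_noise_mostly_unassigned(self):
        # stochastic bound: over 10 seeds no more than 20% of pure-noise
        # genes may end up in modules
        fracs = []
        for seed in range(10):
            X = np.random.default_rng(seed).standard_normal((500, 30))
            part, _, _ = detect_modules(expr_from_array(X), NetworkParams())
            fracs.append((part.labels != 0).mean())
        assert max(fracs) <= 0.2

    def test_correlated_modules_are_merged(self, rng):
        e1 = rng.standard_normal(30)
        e2 = 0.98 * e1 + np.sqrt(1 - 0.98**2) * rng.standard_normal(30)
        rows = []
        for e in (e1, e2):
            noise = rng.standard_normal((30, 30))
            rows.append(0.92 * e + np.sqrt(1 - 0.92**2) * noise)
        X = np.vstack(rows + [rng.standard_normal((100, 30))])
        part, _, _ = detect_modules(expr_from_array(X), NetworkParams())
        planted = part.labels.iloc[:60]
        labels = planted[planted != 0].unique()
        assert len(labels) == 1

    def test_min_sizes_respected(self, planted_scenario):
        part, _, _ = detect_modules(planted_scenario["zA"], NetworkParams())
        assert all(s >= 15 for s in part.sizes().values())

    def test_too_small_input_errors(self):
        X = np.random.default_rng(0).standard_normal((20, 10))
        with pytest.raises(ValidationError):
            detect_modules(expr_from_array(X), NetworkParams())


class TestModuleStability:
    def test_planted_modules_are_stable(self):
        spec, exprA, *_ , truth = small_two_species(
            seed=5, preserved=(True, True, True), rho=0.95, n_genes=200,
            module_size=30,
        )
        from rhodonet.preprocess import robust_z

        zA, _ = robust_z(exprA)
        table = module_stability(zA, NetworkParams(seed=2), n_resamples=10)
        assert (table.table["median_overlap"] >= 0.8).all()

    def test_minimum_resamples(self, planted_scenario):
        with pytest.raises(ValidationError):
            module_stability(planted_scenario["zA"], NetworkParams(), 1)


class TestConditionBootstrap:
    def test_planted_condition_groups_supported(self, rng):
        n_genes = 150
        u = rng.standard_normal(n_genes)
        v = rng.standard_normal(n_genes)
        X = np.empty((n_genes, 10))
        for j in range(5):
            X[:, j] = u + 0.4 * rng.standard_normal(n_genes)
        for j in range(5, 10):
            X[:, j] = v + 0.4 * rng.standard_normal(n_genes)
        Z, support = cluster_conditions_bootstrap(expr_from_array(X),
                                                  n_boot=300, seed=0)
        left = frozenset(range(5))
        right = frozenset(range(5, 10))
        assert support[left] >= 0.9
        assert support[right] >= 0.9

    def test_duplicate_conditions_join_at_zero(self, rng):
        X = rng.standard_normal((80, 4))
        X[:, 3] = X[:, 2]
        Z, support = cluster_conditions_bootstrap(expr_from_array(X),
                                                  n_boot=120, seed=1)
        first = Z[0]
        assert {int(first[0]), int(first[1])} == {2, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert support[frozenset({2, 3})] == 1.0

    def test_low_boot_warns(self, rng):
        with pytest.warns(UserWarning, match="n_boot"):
            cluster_conditions_bootstrap(
                expr_from_array(rng.standard_normal((30, 5))), n_boot=50,
                seed=0,
            )
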