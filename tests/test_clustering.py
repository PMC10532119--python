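"""Matrix assembly, complete-linkage clustering, bootstrap Jaccard stability."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from codyn.clustering import (InteractionMatrix, bootstrap_stability, build_matrix,
                              cluster_matrix, linkage_to_newick)
from codyn.errors import AnalysisError, InputError
from codyn.interactions import InteractionRecord
from codyn.simulate import planted_block_matrix


def _rec(s1, s2, index, parameter="auc", outcome="D"):
    return InteractionRecord(parameter=parameter, strain_1=s1, strain_2=s2,
                             species_1="X", species_2="X", index=index, outcome=outcome,
                             p_avg=0.01, p_max=0.5, p_min=0.5,
                             effect_direction="positive", n_co=4, n_m1=3, n_m2=3)


class TestBuildMatrix:
    def test_symmetric_zero_diagonal(self):
        mat = build_matrix([_rec("a", "b", 0.1), _rec("a", "c", -0.2), _rec("b", "c", 0.0)], "auc")
        assert mat.values.shape == (3, 3)
        np.testing.assert_allclose(mat.values, mat.values.T)
        np.testing.assert_allclose(np.diag(mat.values), 0.0)
        assert mat.values[0, 1] == 0.1

    def test_missing_pair_named(self):
        with pytest.raises(InputError, match="b.*c"):
            build_matrix([_rec("a", "b", 0.1), _rec("a", "c", -0.2)], "auc")

    def test_duplicate_pair_rejected(self):
        recs = [_rec("a", "b", 0.1), _rec("a", "b", 0.2), _rec("a", "c", 0.0), _rec("b", "c", 0.0)]
        with pytest.raises(InputError, match="duplicate"):
            build_matrix(recs, "auc")

    def test_full_design_is_15x15(self, neutral_records):
        mat = build_matrix(neutral_records, "auc")
        assert mat.n == 15
        iu = np.triu_indices(15, k=1)
        assert len(mat.values[iu]) == 105


class TestClusterMatrix:
    def test_duplicate_blocks_recovered(self):
        # two exact duplicate row-blocks
        strains = tuple("abcdef")
        base = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        values = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                values[i, j] = values[j, i] = abs(base[i] - base[j])
        mat = InteractionMatrix("auc", strains, ("X",) * 6, values, np.zeros((6, 6), bool))
        assignments, _ = cluster_matrix(mat, 2)
        assert assignments["a"] == assignments["b"] == assignments["c"]
        assert assignments["d"] == assignments["e"] == assignments["f"]
        assert assignments["a"] != assignments["d"]

    def test_invariant_to_strain_input_order(self):
        mat, labels = planted_block_matrix(seed=5, separation=5.0, within_sd=1.0)
        a, _ = cluster_matrix(mat, 5)
        perm = np.random.default_rng(0).permutation(mat.n)
        mat2 = InteractionMatrix(mat.parameter,
                                 tuple(mat.strains[i] for i in perm),
                                 tuple(mat.species[i] for i in perm),
                                 mat.values[np.ix_(perm, perm)],
                                 mat.significant[np.ix_(perm, perm)])
        b, _ = cluster_matrix(mat2, 5)
        pa = [a[s] for s in mat.strains]
        pb = [b[s] for s in mat.strains]
        assert adjusted_rand_score(pa, pb) == 1.0

    def test_planted_species_blocks_ari_one(self):
        mat, labels = planted_block_matrix(seed=1, separation=5.0, within_sd=1.0)
        assignments, _ = cluster_matrix(mat, 5)
        found = [assignments[s] for s in mat.strains]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_k_out_of_range(self):
        mat, _ = planted_block_matrix(seed=1)
        for k in (1, 16):
            with pytest.raises(AnalysisError):
                cluster_matrix(mat, k)


class TestStability:
    def test_deterministic_given_seed(self):
        mat, _ = planted_block_matrix(seed=2)
        s1 = bootstrap_stability(mat, 5, B=50, method="subset", seed=9)
        s2 = bootstrap_stability(mat, 5, B=50, method="subset", seed=9)
        assert s1.jaccard == s2.jaccard and s1.assignments == s2.assignments

    @pytest.mark.parametrize("method,floor", [("subset", 0.7), ("bootstrap", 0.9)])
    def test_separated_blocks_are_stable(self, method, floor):
        # subset draws score lower because a 3-member cluster misses the
        # half-size subsample ~12% of the time and then counts as dissolved
        mat, _ = planted_block_matrix(seed=3, separation=8.0, within_sd=1.0)
        stab = bootstrap_stability(mat, 5, B=100, method=method, seed=1)
        assert min(stab.jaccard.values()) >= floor
        assert not stab.dissolved()

    def test_stability_monotone_in_separation(self):
        """Scaling block separation x10 never lowers any cluster's Jaccard."""
        lo, _ = planted_block_matrix(seed=4, separation=5.0, within_sd=1.0)
        hi_vals = lo.values.copy()
        # rebuild with the same within-block noise but 10x the block offsets
        hi_src, _ = planted_block_matrix(seed=4, separation=50.0, within_sd=1.0)
        s_lo = bootstrap_stability(lo, 5, B=100, method="subset", seed=2)
        s_hi = bootstrap_stability(hi_src, 5, B=100, method="subset", seed=2)
        for c in s_lo.jaccard:
            assert s_hi.jaccard[c] >= s_lo.jaccard[c] - 1e-12

    def test_intermediate_strain_forms_unstable_singleton(self):
        """One intermediate profile clusters alone; because a lone strain
        drops out of resamples (and then counts as dissolved) its mean
        Jaccard is capped near its inclusion probability (~0.64 under
        bootstrap), markedly below the multi-member clusters."""
        rng = np.random.default_rng(6)
        sd = 0.05
        centers = {0: 0.0, 1: 3.0, 2: 6.0, 3: 9.0}
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3, 3, 3]  # 14 strains in 4 blocks
        profiles = np.array([centers[l] for l in labels], dtype=float)
        profiles = np.append(profiles, 1.35)  # the intermediate 15th strain
        n = 15
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = abs(profiles[i] - profiles[j]) + rng.normal(0, sd)
        strains = tuple(f"s{i:02d}" for i in range(n))
        mat = InteractionMatrix("auc", strains, ("X",) * n, values, np.zeros((n, n), bool))
        assignments, _ = cluster_matrix(mat, 5)
        singleton_cluster = assignments["s14"]
        assert sum(1 for v in assignments.values() if v == singleton_cluster) == 1
        stab = bootstrap_stability(mat, 5, B=200, method="bootstrap", seed=3)
        others = [j for c, j in stab.jaccard.items() if c != singleton_cluster]
        assert stab.jaccard[singleton_cluster] < min(others) - 0.1
        assert 0.5 < stab.jaccard[singleton_cluster] < 0.8

    def test_invalid_inputs(self):
        mat, _ = planted_block_matrix(seed=1)
        with pytest.raises(AnalysisError):
            bootstrap_stability(mat, 5, B=0)
        with pytest.raises(AnalysisError):
            bootstrap_stability(mat, 5, B=10, method="jackknife")
        with pytest.raises(AnalysisError):
            cluster_matrix(mat, 1)


def test_newick_export_is_parseable():
    import dendropy

    mat, _ = planted_block_matrix(seed=1)
    _, Z = cluster_matrix(mat, 5)
    nwk = linkage_to_newick(Z, list(mat.strains))
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(tree.leaf_nodes()) == 15
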