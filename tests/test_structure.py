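"""Distances, NJ trees, PCA, F_ST permutation test, isolation-by-distance
and the admixture Gibbs sampler."""

from itertools import combinations

import dendropy
import numpy as np
import pytest

from hairsnag.model import LocusGenotype as LG
from hairsnag.model import MultilocusGenotype, SampleRecord, Source
from hairsnag.simulate import (
    SimulationConfig,
    simulate_allele_frequencies,
    simulate_individuals,
)
from hairsnag.structure import (
    DistanceMatrix,
    admixture_cluster,
    best_label_permutation,
    dissimilarity_vs_distance,
    haversine_m,
    kosman_dissimilarity,
    neighbor_joining,
    pairwise_fst,
    pca_genotypes,
    shared_allele_distance,
    weir_cockerham_theta,
)

from tests.conftest import make_mlg


def _random_genotypes(rng, n, n_loci=10, k=6, missing_rate=0.0):
    out = []
    for _ in range(n):
        pairs = []
        for l in range(n_loci):
            if rng.random() < missing_rate:
                pairs.append(None)
            else:
                a, b = rng.integers(0, k, size=2)
                pairs.append((100 + 40 * l + 2 * int(a), 100 + 40 * l + 2 * int(b)))
        out.append(make_mlg(pairs))
    return out


def _two_pop_genotypes(seed, n_per_pop, fst, n_loci=10):
    cfg = SimulationConfig(
        n_individuals=2 * n_per_pop, n_loci=n_loci, target_fst=fst,
        subpop_weights=None, seed=seed,
    )
    rng = np.random.default_rng(seed)
    loci, sizes, freqs = simulate_allele_frequencies(cfg, rng)
    truth = simulate_individuals(loci, sizes, freqs, cfg, rng)
    g = [t.genotype for t in truth.individuals.values()]
    subpops = np.array([t.subpop for t in truth.individuals.values()])
    return [g[i] for i in np.flatnonzero(subpops == 0)], [
        g[i] for i in np.flatnonzero(subpops == 1)
    ], subpops


class TestSharedAlleleDistance:
    def test_identical_zero(self):
        g = make_mlg([(100, 102), (200, 204)])
        dm = shared_allele_distance([g, g])
        assert dm.values[0, 1] == 0.0

    def test_fully_disjoint_one(self):
        g1 = make_mlg([(100, 102), (200, 204)])
        g2 = make_mlg([(110, 112), (210, 214)])
        assert shared_allele_distance([g1, g2]).values[0, 1] == 1.0

    def test_het_vs_hom_single_locus_half(self):
        g1 = make_mlg([(100, 102)])
        g2 = make_mlg([(100, 100)])
        assert shared_allele_distance([g1, g2]).values[0, 1] == 0.5

    def test_no_shared_loci_flagged_undefined(self):
        g1 = make_mlg([(100, 102), None])
        g2 = make_mlg([None, (200, 204)])
        dm = shared_allele_distance([g1, g2], ["a", "b"])
        assert np.isnan(dm.values[0, 1])
        assert dm.undefined_pairs == [("a", "b")]

    def test_kosman_identity_on_random_pairs(self, rng):
        genotypes = _random_genotypes(rng, 45, missing_rate=0.1)
        d1 = shared_allele_distance(genotypes).values
        d2 = kosman_dissimilarity(genotypes).values
        defined = ~np.isnan(d1)
        assert np.allclose(d1[defined], d2[defined])

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


def _patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return taxa, pdm


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 5.0, 9.0], [5.0, 0, 10.0], [9.0, 10.0, 0]])
        )
        taxa, pdm = _patristic(neighbor_joining(dm))
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(5.0)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(9.0)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(10.0)

    def test_additive_matrix_reproduced_exactly(self):
        # 4-taxon additive tree: ((a:2,b:3):1,(c:4,d:5))
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        labels = ["a", "b", "c", "d"]
        taxa, pdm = _patristic(neighbor_joining(DistanceMatrix(labels, d)))
        for i, j in combinations(range(4), 2):
            assert pdm.distance(taxa[labels[i]], taxa[labels[j]]) == pytest.approx(
                d[i, j], abs=1e-9
            )

    def test_topology_matches_least_squares_oracle(self):
        # brute-force least-squares over the three unrooted 4-taxon topologies
        d = np.array(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], dtype=float
        )
        labels = ["a", "b", "c", "d"]
        newick = neighbor_joining(DistanceMatrix(labels, d))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        splits = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree if not node.is_leaf()
        }
        # the generating topology pairs (a,b) against (c,d)
        assert {"a", "b"} in splits or {"c", "d"} in splits

    def test_identical_individuals_form_zero_cherry(self):
        g = make_mlg([(100, 102), (200, 204)])
        g3 = make_mlg([(110, 112), (210, 214)])
        dm = shared_allele_distance([g, g, g3], ["x1", "x2", "y"])
        taxa, pdm = _patristic(neighbor_joining(dm))
        assert pdm.distance(taxa["x1"], taxa["x2"]) == pytest.approx(0.0)

    def test_undefined_entries_error(self):
        v = np.array([[0, np.nan, 1.0], [np.nan, 0, 1.0], [1.0, 1.0, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], v))


class TestPCA:
    def test_duplicate_individual_identical_coordinates(self, rng):
        genotypes = _random_genotypes(rng, 10)
        genotypes.append(genotypes[0])
        res = pca_genotypes(genotypes)
        assert np.allclose(res.coordinates[0], res.coordinates[-1])

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        genotypes = _random_genotypes(rng, 20)
        res = pca_genotypes(genotypes)
        assert res.explained_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_pc1_separates_divergent_populations(self):
        ga, gb, _ = _two_pop_genotypes(seed=11, n_per_pop=30, fst=0.2)
        res = pca_genotypes(ga + gb)
        signs = np.sign(res.coordinates[:, 0])
        acc = max(
            np.mean(signs[: len(ga)] > 0) * 0.5 + np.mean(signs[len(ga):] < 0) * 0.5,
            np.mean(signs[: len(ga)] < 0) * 0.5 + np.mean(signs[len(ga):] > 0) * 0.5,
        )
        assert acc >= 0.95


class TestPairwiseFst:
    def test_identical_groups_not_significant(self, rng):
        genotypes = _random_genotypes(rng, 40)
        theta, p = pairwise_fst(genotypes[:20], genotypes[20:], 500, seed=4)
        assert theta <= 0.02
        assert p > 0.05

    def test_recovers_balding_nichols_target(self):
        ga, gb, _ = _two_pop_genotypes(seed=5, n_per_pop=50, fst=0.10)
        theta = weir_cockerham_theta(ga, gb)
        assert 0.05 <= theta <= 0.15

    def test_permutation_p_invariant_to_group_order(self, rng):
        # theta is exactly symmetric; the permutation p is the same test on a
        # re-ordered pool, so it agrees up to Monte-Carlo noise
        genotypes = _random_genotypes(rng, 24)
        t1, p1 = pairwise_fst(genotypes[:10], genotypes[10:], 2000, seed=9)
        t2, p2 = pairwise_fst(genotypes[10:], genotypes[:10], 2000, seed=9)
        assert t1 == pytest.approx(t2)
        assert abs(p1 - p2) < 0.06

    def test_type_i_error_calibrated(self):
        """Permutation p on panmictic data rejects at ~alpha."""
        hits = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            genotypes = _random_genotypes(rng, 30, n_loci=6)
            _, p = pairwise_fst(genotypes[:15], genotypes[15:], 199, seed=i)
            hits += p <= 0.05
        assert 0.01 <= hits / reps <= 0.09

    def test_small_group_errors(self, rng):
        genotypes = _random_genotypes(rng, 5)
        with pytest.raises(ValueError):
            pairwise_fst(genotypes[:1], genotypes[1:], 10, seed=0)


def _sample_at(sid, mlg, lat, lon):
    return SampleRecord(
        sid, "Artvin", Source.TREE, 2010, lat, lon,
        consensus=mlg, consensus_status="accepted",
    )


class TestDissimilarityVsDistance:
    def test_resampled_individual_same_location(self, rng):
        g = _random_genotypes(rng, 1)[0]
        others = _random_genotypes(rng, 5)
        samples = [_sample_at("a", g, 41.0, 41.0), _sample_at("b", g, 41.0, 41.0)]
        samples += [
            _sample_at(f"c{i}", o, 41.0 + 0.1 * i, 41.0) for i, o in enumerate(others)
        ]
        res = dissimilarity_vs_distance(samples, n_permutations=99)
        idx = np.argmin(res.distances_m)
        assert res.distances_m[idx] == pytest.approx(0.0)
        assert res.dissimilarities[idx] == pytest.approx(0.0)

    def test_long_distance_resample_shows_zero_dissimilarity(self, rng):
        g = _random_genotypes(rng, 1)[0]
        others = _random_genotypes(rng, 4)
        # same genotype at two sites ~160 km apart
        samples = [_sample_at("a", g, 41.18, 41.82), _sample_at("b", g, 40.26, 40.22)]
        samples += [_sample_at(f"c{i}", o, 41.2, 41.8) for i, o in enumerate(others)]
        res = dissimilarity_vs_distance(samples, n_permutations=99)
        far_zero = [
            (d, g_) for d, g_ in zip(res.distances_m, res.dissimilarities)
            if g_ == 0.0 and d > 100_000
        ]
        assert far_zero and 140_000 < far_zero[0][0] < 180_000

    def test_panmictic_running_average_flat(self):
        """No isolation-by-distance signal in a panmictic population."""
        nonsig = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(2000 + i)
            genotypes = _random_genotypes(rng, 14, n_loci=8)
            samples = [
                _sample_at(
                    f"s{j}", g_, 41.0 + rng.normal(0, 0.5), 41.0 + rng.normal(0, 0.5)
                )
                for j, g_ in enumerate(genotypes)
            ]
            res = dissimilarity_vs_distance(samples, n_permutations=199, seed=i)
            nonsig += res.mantel_p > 0.05
        assert nonsig / reps >= 0.9

    def test_missing_coordinates_skipped_and_counted(self, rng):
        genotypes = _random_genotypes(rng, 5)
        samples = [
            _sample_at(f"s{j}", g_, 41.0 + 0.01 * j, 41.0) for j, g_ in enumerate(genotypes)
        ]
        samples[0].lat = None
        res = dissimilarity_vs_distance(samples, n_permutations=49)
        assert res.n_pairs_skipped >= 1


class TestAdmixture:
    def test_k1_memberships_are_one(self, rng):
        genotypes = _random_genotypes(rng, 12)
        post = admixture_cluster(genotypes, K=1, sweeps=200, burn_in=50, seed=0)
        assert np.allclose(post.q_matrix, 1.0)
        assert np.allclose(post.q_matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_two_populations_recovered(self):
        ga, gb, subpops = _two_pop_genotypes(seed=7, n_per_pop=30, fst=0.15)
        post = admixture_cluster(ga + gb, K=2, sweeps=1500, burn_in=500, seed=3)
        acc = best_label_permutation(
            post.q_matrix, np.array([0] * len(ga) + [1] * len(gb))
        )
        assert acc >= 0.9

    def test_panmictic_prefers_k1(self):
        """lnP model score maximal at K=1 on unstructured data."""
        wins = 0
        reps = 10
        for i in range(reps):
            rng = np.random.default_rng(3000 + i)
            genotypes = _random_genotypes(rng, 30, n_loci=8)
            scores = [
                admixture_cluster(
                    genotypes, K, sweeps=800, burn_in=300, seed=10 * i + K
                ).lnp_estimate
                for K in (1, 2, 3)
            ]
            wins += int(np.argmax(scores) == 0)
        assert wins / reps >= 0.8

    def test_sweeps_must_exceed_burnin(self, rng):
        with pytest.raises(ValueError):
            admixture_cluster(_random_genotypes(rng, 5), K=2, sweeps=10, burn_in=10)


def test_haversine_known_distance():
    # Artvin to Bayburt province centres: ~160 km
    d = haversine_m(41.18, 41.82, 40.26, 40.22)
    assert 150_000 < d < 180_000
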