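import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import adjusted_rand_score

from tumorevo import synthetic
from tumorevo.phylogeny import (
    ClonePrevalenceMatrix,
    DegenerateSampleError,
    DistanceMatrix,
    classify_seeding,
    cluster_variants,
    cp_to_distribution,
    expected_vaf,
    founding_clone,
    jensen_shannon_divergence,
    neighbor_joining,
    pairwise_distances,
    pyclone_input_filter,
    vaf_to_cp,
)

from conftest import make_table
from oracles import best_topology_splits, random_additive_matrix, skbio_tree_splits


def make_cpm(data, samples=None):
    cp = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        cp.columns = samples
    n_mut = pd.Series(1, index=cp.index)
    return ClonePrevalenceMatrix(cp=cp, n_mutations=n_mut)


class TestVafCp:
    @pytest.mark.parametrize(
        "vaf,purity,cn,mult,expected",
        [
            (0.5, 1.0, 2, 1, 1.0),       # clonal heterozygous limit
            (0.25, 0.5, 2, 1, 1.0),      # 0.25 * (1 + 1) / 0.5
            (0.0, 0.7, 3, 1, 0.0),
        ],
    )
    def test_known_values(self, vaf, purity, cn, mult, expected):
        assert vaf_to_cp(vaf, purity, cn, mult) == pytest.approx(expected)

    def test_zero_purity_invalid(self):
        with pytest.raises(ValueError):
            vaf_to_cp(0.2, 0.0, 2)

    def test_round_trip_with_expected_vaf(self, rng):
        for _ in range(50):
            cp = rng.uniform(0, 1)
            purity = rng.uniform(0.1, 1.0)
            cn = rng.integers(1, 5)
            v = float(expected_vaf(cp, purity, cn))
            assert vaf_to_cp(v, purity, cn) == pytest.approx(cp, abs=1e-12)


class TestPycloneInputFilter:
    def _cn(self, samples):
        return pd.DataFrame(
            {
                "sample_id": list(samples),
                "chrom": "chr1",
                "start": 1,
                "end": 10**9,
                "cn_total": 2,
            }
        )

    def test_boundary_pass_and_strict_depth(self):
        rows = [
            # depth 101 > 20 everywhere, maf 0.16 in s1
            {"sample_id": "s1", "variant_id": "keep", "alt_count": 16, "ref_count": 85},
            {"sample_id": "s2", "variant_id": "keep", "alt_count": 5, "ref_count": 96},
            # depth exactly 20 in s2 -> dropped (strict >)
            {"sample_id": "s1", "variant_id": "shallow", "alt_count": 30, "ref_count": 70},
            {"sample_id": "s2", "variant_id": "shallow", "alt_count": 10, "ref_count": 10},
        ]
        table = make_table(rows, sample_ids=["s1", "s2"])
        got = pyclone_input_filter(table, self._cn(["s1", "s2"]))
        assert got == {"keep"}

    def test_matches_brute_force_enumeration(self, rng):
        samples = ["s1", "s2", "s3"]
        rows = []
        for v in range(8):
            for s in samples:
                depth = int(rng.integers(15, 60))
                alt = int(rng.integers(0, depth + 1))
                rows.append({"sample_id": s, "variant_id": f"v{v}",
                             "alt_count": alt, "ref_count": depth - alt})
        table = make_table(rows, sample_ids=samples)
        got = pyclone_input_filter(table, self._cn(samples))
        obs = table.observations
        expect = set()
        for v in obs["variant_id"].unique():
            sub = obs[obs["variant_id"] == v]
            if (
                len(sub) == 3
                and (sub["depth"] > 20).all()
                and (sub["maf"] > 0.15).any()
            ):
                expect.add(v)
        assert got == expect

    def test_missing_cn_record_fails(self):
        rows = [
            {"sample_id": "s1", "variant_id": "v", "alt_count": 30, "ref_count": 70},
            {"sample_id": "s2", "variant_id": "v", "alt_count": 30, "ref_count": 70},
        ]
        table = make_table(rows, sample_ids=["s1", "s2"])
        cn = self._cn(["s1"])  # no segments for s2
        assert pyclone_input_filter(table, cn) == set()


class TestJsd:
    def test_identity_and_disjoint(self):
        assert jensen_shannon_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_value(self):
        got = jensen_shannon_divergence([0.5, 0.5], [1.0, 0.0])
        assert got == pytest.approx(0.311278, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jensen_shannon_divergence([1.0], [0.5, 0.5])

    def test_properties_and_scipy_cross_check(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            a = jensen_shannon_divergence(p, q)
            b = jensen_shannon_divergence(q, p)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0 <= a <= 1
            # scipy returns the square root of the divergence
            assert a == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-10)
        assert jensen_shannon_divergence(p, p) == 0.0


class TestDistributionsAndDistances:
    def test_cp_to_distribution(self):
        np.testing.assert_allclose(cp_to_distribution([0.8, 0.2, 0.0]), [0.8, 0.2, 0.0])
        np.testing.assert_allclose(cp_to_distribution([0.4, 0.4]), [0.5, 0.5])
        with pytest.raises(DegenerateSampleError):
            cp_to_distribution([0.0, 0.0, 0.0])

    def test_pairwise_matches_elementwise_oracle(self):
        cpm = make_cpm(
            {"c1": [0.9, 0.5, 0.1], "c2": [0.1, 0.5, 0.2], "c3": [0.0, 0.0, 0.7]},
            samples=None,
        )
        d = pairwise_distances(cpm)
        vals = d.to_frame()
        cols = cpm.cp.columns
        for i in cols:
            for j in cols:
                expect = (
                    0.0
                    if i == j
                    else jensen_shannon_divergence(
                        cp_to_distribution(cpm.cp[i]), cp_to_distribution(cpm.cp[j])
                    )
                )
                assert vals.loc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_duplicate_columns_distance_zero(self):
        cpm = make_cpm({"c1": [0.6, 0.6, 0.3], "c2": [0.4, 0.4, 0.2]})
        d = pairwise_distances(cpm).to_frame()
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestNeighborJoining:
    ADDITIVE4 = {
        ("A", "B"): 2.0, ("A", "C"): 4.0, ("A", "D"): 6.0,
        ("B", "C"): 4.0, ("B", "D"): 6.0, ("C", "D"): 4.0,
    }

    def _dm(self, dist, leaves):
        n = len(leaves)
        m = np.zeros((n, n))
        for (i, j), v in dist.items():
            a, b = leaves.index(i), leaves.index(j)
            m[a, b] = m[b, a] = v
        return DistanceMatrix(values=m, sample_ids=list(leaves))

    def test_additive_four_leaf_exact(self):
        leaves = ["A", "B", "C", "D"]
        tree = neighbor_joining(self._dm(self.ADDITIVE4, leaves))
        paths = tree.tip_distances()
        for (i, j), v in self.ADDITIVE4.items():
            assert paths.loc[i, j] == pytest.approx(v, abs=1e-9)
        splits, resid = best_topology_splits(leaves, self.ADDITIVE4)
        assert resid < 1e-18
        assert skbio_tree_splits(tree.root) == splits  # (AB)(CD)

    def test_random_additive_five_leaf(self, rng):
        leaves = list("ABCDE")
        for _ in range(5):
            dist, _ = random_additive_matrix(leaves, rng)
            tree = neighbor_joining(self._dm(dist, leaves))
            paths = tree.tip_distances()
            for (i, j), v in dist.items():
                assert paths.loc[i, j] == pytest.approx(v, abs=1e-9)

    def test_three_leaf_closed_form(self):
        dist = {("A", "B"): 2.0, ("A", "C"): 3.0, ("B", "C"): 3.0}
        tree = neighbor_joining(self._dm(dist, ["A", "B", "C"]))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_leaf_order_invariance(self, rng):
        leaves = list("ABCDE")
        dist, _ = random_additive_matrix(leaves, rng)
        t1 = neighbor_joining(self._dm(dist, leaves))
        perm = ["C", "A", "E", "B", "D"]
        t2 = neighbor_joining(self._dm(dist, perm))
        p1, p2 = t1.tip_distances(), t2.tip_distances()
        for i in leaves:
            for j in leaves:
                assert p1.loc[i, j] == pytest.approx(p2.loc[i, j], abs=1e-9)
        assert skbio_tree_splits(t1.root) == skbio_tree_splits(t2.root)

    def test_agrees_with_skbio_nj_on_additive_input(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        leaves = list("ABCDEF")
        dist, _ = random_additive_matrix(leaves, rng)
        mine = neighbor_joining(self._dm(dist, leaves))
        theirs = nj(SkDM(self._dm(dist, leaves).values, ids=leaves))
        assert skbio_tree_splits(mine.root) == skbio_tree_splits(theirs)

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))

    def test_negative_branches_clamped_and_recorded(self):
        # a strongly non-additive matrix forces a negative NJ branch
        m = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], float
        )
        m[0, 1] = m[1, 0] = 5.9
        tree = neighbor_joining(DistanceMatrix(m, list("ABCD")))
        for node in tree.root.traverse(include_self=False):
            assert node.length >= 0


class TestSeedingAndFounder:
    def test_classification_rule(self):
        assert classify_seeding([0.9, 0.03, 0.02]) == "monoclonal"
        assert classify_seeding([0.5, 0.4, 0.1]) == "polyclonal"
        with pytest.raises(DegenerateSampleError):
            classify_seeding([0.0, 0.0])

    def test_round_trip_against_simulated_truth(self):
        for seed in range(5):
            cfg = synthetic.SimulationConfig(
                n_samples_pre=2, n_samples_post=6, n_clones=5,
                mutations_per_clone=5, seed=seed,
            )
            tree = synthetic.simulate_clone_tree(cfg.n_clones, 5, seed)
            cpm, truth = synthetic.simulate_cp_matrix(tree, cfg)
            got = {
                s: classify_seeding(
                    cpm.cp[s].to_numpy(), synthetic.SEEDING_PRESENCE_THRESHOLD
                )
                for s in cpm.sample_ids
            }
            assert got == truth

    def test_founder_max_cp_everywhere(self):
        cpm = make_cpm({"cA": [0.9, 0.8], "cB": [0.5, 0.4]})
        per_sample, cohort = founding_clone(cpm)
        assert set(per_sample.values()) == {"cA"} and cohort == "cA"

    def test_founder_tie_goes_to_lowest_clone_id(self):
        cpm = make_cpm({"cA": [0.5], "cB": [0.5]})
        per_sample, cohort = founding_clone(cpm)
        assert per_sample == {0: "cA"} or list(per_sample.values()) == ["cA"]
        assert cohort == "cA"

    def test_no_clone_above_threshold_flagged(self):
        cpm = make_cpm({"cA": [0.05, 0.9], "cB": [0.04, 0.0]})
        per_sample, cohort = founding_clone(cpm)
        assert list(per_sample.values())[0] is None
        assert cohort == "cA"

    def test_truncal_clone_is_cohort_founder(self):
        cfg = synthetic.SimulationConfig(
            n_samples_pre=2, n_samples_post=5, n_clones=4,
            mutations_per_clone=5, seed=9,
        )
        tree = synthetic.simulate_clone_tree(4, 5, 9)
        cpm, _ = synthetic.simulate_cp_matrix(tree, cfg)
        _, cohort = founding_clone(cpm)
        assert cohort == tree.root


class TestClusterVariants:
    def _simulate(self, n_clones, seed, mpc=100, n_pre=2, n_post=4):
        cfg = synthetic.SimulationConfig(
            n_samples_pre=n_pre, n_samples_post=n_post, n_clones=n_clones,
            mutations_per_clone=mpc, depth_mean=200, seed=seed,
        )
        return synthetic.simulate_cohort(cfg)

    def test_single_clone_selects_k_one(self):
        cohort = self._simulate(n_clones=2, seed=2, mpc=60)
        # keep only truncal variants: a one-clone problem
        truncal = set(cohort.truth.tree.mutations_of["clone_0"])
        model = cluster_variants(
            cohort.variants, truncal, cn=cohort.copy_number,
            k_range=range(1, 4), n_restarts=2, seed=0,
        )
        assert model.K == 1

    def test_separated_clones_recovered(self):
        cohort = self._simulate(n_clones=2, seed=4, mpc=100)
        eligible = pyclone_input_filter(cohort.variants, cohort.copy_number)
        model = cluster_variants(
            cohort.variants, eligible, cn=cohort.copy_number,
            k_range=range(1, 5), n_restarts=3, seed=1,
        )
        truth = cohort.truth.assignment_true
        ari = adjusted_rand_score(
            [truth[v] for v in model.assignment.index], model.assignment.to_list()
        )
        assert ari >= 0.95

    def test_noise_free_counts_recover_cp(self):
        # alt = round(depth * expected VAF): CP estimates within 0.02 of truth
        cohort = self._simulate(n_clones=3, seed=6, mpc=40)
        table = cohort.variants
        obs = table.observations.copy()
        truth = cohort.truth
        clone_of = truth.assignment_true
        purity = truth.purity_true
        ev = [
            float(
                expected_vaf(
                    truth.cp_true.cp.loc[clone_of[v], s], purity[s], 2.0
                )
            )
            for v, s in zip(obs["variant_id"], obs["sample_id"])
        ]
        obs["alt_count"] = np.round(obs["depth"].to_numpy() * np.asarray(ev)).astype(int)
        obs["ref_count"] = obs["depth"].to_numpy() - obs["alt_count"]
        noise_free = table.with_observations(
            obs.drop(columns=["depth", "maf", "pass_any"])
        )
        model = cluster_variants(
            noise_free, set(obs["variant_id"]), cn=cohort.copy_number,
            k_range=range(1, 6), n_restarts=3, seed=2,
        )
        assert model.K == 3
        # match estimated clones to truth by assignment majority
        for clone_hat in model.cp_hat.clone_ids:
            members = model.assignment.index[model.assignment == clone_hat]
            true_clone = pd.Series([clone_of[v] for v in members]).mode()[0]
            diff = (
                model.cp_hat.cp.loc[clone_hat] - truth.cp_true.cp.loc[true_clone]
            ).abs()
            assert diff.max() <= 0.02

    def test_deterministic_given_seed(self):
        cohort = self._simulate(n_clones=3, seed=8, mpc=30)
        eligible = pyclone_input_filter(cohort.variants, cohort.copy_number)
        kw = dict(cn=cohort.copy_number, k_range=range(1, 5), n_restarts=2, seed=3)
        m1 = cluster_variants(cohort.variants, eligible, **kw)
        m2 = cluster_variants(cohort.variants, eligible, **kw)
        assert m1.assignment.equals(m2.assignment)
        assert m1.bic == m2.bic

    def test_empty_filter_rejected(self, toy_table):
        with pytest.raises(ValueError):
            cluster_variants(toy_table, [])
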