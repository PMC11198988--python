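import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmanifold.inference import (
    bh_fdr,
    network_behavior_test,
    paired_contrast,
    seed_contrast,
    spin_null,
    spin_permutations,
)
from connmanifold.io import ValidationError
from connmanifold.spd import CovarianceMatrix
from connmanifold.synth import make_parcellation

from conftest import random_spd


def brute_bh(p, q):
    """Step-up BH: largest k with p_(k) <= k*q/m; reject the k smallest."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestBHFDR:
    @given(st.lists(st.floats(0.0001, 1.0), min_size=1, max_size=200), st.sampled_from([0.01, 0.05, 0.1]))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_step_up(self, p, q):
        p = np.array(p)
        assert np.array_equal(bh_fdr(p, q), brute_bh(p, q))


class TestPairedContrast:
    def test_equal_maps_give_zero_t_nothing_significant(self, rng):
        A = rng.standard_normal((6, 10))
        with pytest.warns(UserWarning, match="zero-variance"):
            cmap = paired_contrast(A, A.copy())
        assert np.all(cmap.t == 0)
        assert not cmap.significant.any()

    def test_planted_shift_has_largest_t(self, rng):
        A = rng.standard_normal((12, 15))
        B = A + 0.05 * rng.standard_normal((12, 15))
        B[:, 4] += 2.0
        cmap = paired_contrast(A, B)
        assert np.argmax(cmap.t) == 4
        assert cmap.significant[4]

    def test_null_calibration_any_discovery_rate(self):
        """Under the global null, the fraction of datasets with any
        BH-flagged region stays at the FDR level (weak FWER control)."""
        hits = 0
        n_sims = 200
        for s in range(n_sims):
            r = np.random.default_rng(s)
            A = r.standard_normal((10, 20))
            B = r.standard_normal((10, 20))
            hits += paired_contrast(A, B, q=0.05).significant.any()
        limit = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_sims)
        assert hits / n_sims <= limit

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            paired_contrast(rng.standard_normal((2, 5)), rng.standard_normal((2, 5)))


class TestSeedContrast:
    def _covs(self, rng, n_sub, R=10):
        ids = [f"r{k}" for k in range(R)]
        return [CovarianceMatrix(random_spd(rng, R), ids) for _ in range(n_sub)]

    def test_identical_epochs_zero_map(self, rng):
        covs = self._covs(rng, 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            cmap, _ = seed_contrast(covs, [CovarianceMatrix(c.values.copy(), c.region_ids) for c in covs], ["r0"])
        assert np.all(cmap.t == 0)

    def test_single_region_seed_is_row_contrast(self, rng):
        a = self._covs(rng, 6)
        b = self._covs(rng, 6)
        cmap, _ = seed_contrast(a, b, ["r3"])
        rows_a = np.array([c.values[3] for c in a])
        rows_b = np.array([c.values[3] for c in b])
        direct = paired_contrast(rows_a, rows_b)
        assert np.allclose(cmap.t, direct.t)

    def test_unknown_seed_region_rejected(self, rng):
        with pytest.raises(ValidationError, match="unknown seed region"):
            seed_contrast(self._covs(rng, 4), self._covs(rng, 4), ["nope"])

    def test_network_summary_identifies_coupled_network(self, rng):
        """A planted connectivity increase between the seed rows and one
        network makes that network carry the largest summary |t|."""
        meta = make_parcellation(34, 7, 17, seed=0)
        ids = meta.region_ids
        labels = meta.network_labels(17)
        target = labels[20]
        a, b = [], []
        for _ in range(10):
            S = random_spd(rng, 34)
            a.append(CovarianceMatrix(S, ids))
            S2 = S.copy()
            cols = np.flatnonzero(labels == target)
            S2[np.ix_([0], cols)] += 1.0
            S2[np.ix_(cols, [0])] += 1.0
            b.append(CovarianceMatrix((S2 + S2.T) / 2, ids))
        _, summary = seed_contrast(a, b, [ids[0]], meta=meta)
        best = summary.networks[int(np.argmax(np.abs(summary.values)))]
        assert best == target


class TestSpinNull:
    @pytest.fixture(scope="class")
    def meta(self):
        return make_parcellation(60, 7, 17, seed=3)

    def test_every_spin_is_a_permutation(self, meta):
        perms = spin_permutations(meta, 20, seed=0)
        for p in perms:
            assert sorted(p) == list(range(60))

    def test_constant_map_null_is_constant(self, meta):
        sn = spin_null(np.full(60, 3.25), meta, n_spins=50, seed=1)
        assert np.all(sn.null == 3.25)

    def test_subcortical_regions_never_rotate(self):
        meta = make_parcellation(40, 7, 17, seed=5)
        hemi = list(meta.hemisphere)
        hemi[0] = hemi[1] = "subcortical"
        from connmanifold.io import ParcellationMeta

        meta2 = ParcellationMeta(meta.region_ids, hemi, meta.network7, meta.network17,
                                 meta.centroids.copy())
        perms = spin_permutations(meta2, 10, seed=2)
        assert np.all(perms[:, 0] == 0) and np.all(perms[:, 1] == 1)

    def test_null_unbiased_over_value_maps(self, meta):
        """Averaged over independent value maps, the spin null of each
        network is centered on the map mean (the exchangeability property;
        for a single fixed map the greedy unique matching carries a small
        geometry-dependent offset)."""
        rng = np.random.default_rng(7)
        biases = []
        for rep in range(20):
            vals = rng.standard_normal(60)
            sn = spin_null(vals, meta, n_spins=100, seed=100 + rep)
            biases.append(sn.null.mean(axis=1) - vals.mean())
        biases = np.array(biases)
        se = biases.std(axis=0, ddof=1) / np.sqrt(len(biases))
        assert np.all(np.abs(biases.mean(axis=0)) < 3 * se + 1e-12)

    def test_spin_p_never_exactly_zero(self, meta, rng):
        vals = rng.standard_normal(60)
        vals[:9] += 50.0  # extreme observed network value
        from connmanifold.inference import _spin_p

        sn = spin_null(vals, meta, n_spins=100, seed=4)
        for k in range(len(sn.networks)):
            obs = sn.null[k].max() + 100.0
            assert _spin_p(obs, sn.null[k]) >= 2.0 / 101.0


class TestNetworkBehaviorTest:
    @pytest.fixture(scope="class")
    def meta(self):
        return make_parcellation(68, 7, 17, seed=42)

    def test_planted_coupling_flagged_with_positive_r(self, meta):
        rng = np.random.default_rng(0)
        labels = meta.network_labels(17)
        target = "Net17_1"
        scores = rng.standard_normal(36)
        maps = 0.5 * rng.standard_normal((36, 68))
        maps[:, labels == target] += 1.0 * scores[:, None]
        tab = network_behavior_test(maps, scores, meta, n_spins=300, seed=1)
        row = tab.set_index("network").loc[target]
        assert row["significant"] == 1
        assert row["r"] > 0

    def test_negative_coupling_gives_negative_r(self, meta):
        rng = np.random.default_rng(1)
        labels = meta.network_labels(17)
        scores = rng.standard_normal(36)
        maps = 0.5 * rng.standard_normal((36, 68))
        maps[:, labels == "Net17_2"] -= 1.0 * scores[:, None]
        tab = network_behavior_test(maps, scores, meta, n_spins=300, seed=2)
        assert tab.set_index("network").loc["Net17_2", "r"] < 0

    def test_too_few_subjects_rejected(self, meta, rng):
        with pytest.raises(ValidationError, match="subjects"):
            network_behavior_test(rng.standard_normal((4, 68)), rng.standard_normal(4), meta)


class TestFullPipelineRecovery:
    """Injected epoch effect uncorrelated with behavior: the eccentricity
    contrast detects the affected network while the brain-behavior test
    stays silent."""

    def test_effect_detected_and_behavior_test_silent(self):
        from connmanifold.manifold import align, build_affinity, build_template, embed
        from connmanifold.spd import CovarianceSet, center_set, shrinkage_covariance
        from connmanifold.synth import SyntheticStudyConfig, make_study

        sens, any_flagged = [], []
        for seed in range(25):
            cfg = SyntheticStudyConfig(
                n_subjects=12, n_regions=42, volumes_per_epoch=120, seed=300 + seed
            )
            study = make_study(cfg)
            covs = [[shrinkage_covariance(ts) for ts in row] for row in study.timeseries]
            cs = center_set(CovarianceSet(matrices=covs))
            template = build_template([cs.centered[i][0] for i in range(12)])
            ecc = np.empty((12, 3, 42))
            for i in range(12):
                for j in range(3):
                    emb = align(embed(build_affinity(cs.centered[i][j]), 3), template)
                    ecc[i, j] = np.linalg.norm(emb.coords, axis=1)
            cmap = paired_contrast(ecc[:, 0], ecc[:, 1], q=0.05)
            sens.append(cmap.significant[study.affected_mask].mean())
            # behavioral aptitude is generated independently of connectivity
            tab = network_behavior_test(
                ecc[:, 1] - ecc[:, 0], study.aptitude, study.parcellation,
                n_spins=200, seed=seed, q=0.05,
            )
            any_flagged.append(tab["significant"].any())
        assert np.mean(sens) >= 0.8
        assert np.mean(any_flagged) <= 0.1
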