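"""ANOSIM, Mantel, group-similarity, and trait-correlation inference tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from bodyrep.cohort import CohortConfig, generate_pattern_set, generate_traits
from bodyrep.conditions import BODY_PARTS
from bodyrep.inference import (
    PartitionModel,
    anosim_r,
    anosim_test,
    enumerate_partitions,
    hypothesized_partition,
    mantel_test,
    subject_anosim_r,
    trait_correlations,
    within_between_similarity,
)
from bodyrep.rsa import DissimilarityMatrix, compute_split_half_rdm

from conftest import random_rdm


class TestEnumeratePartitions:
    def test_canonical_count_is_420(self):
        models = enumerate_partitions()
        assert len(models) == 420
        assert models[0] == hypothesized_partition()

    def test_small_case_count(self):
        models = enumerate_partitions(
            conditions=("a", "b", "c", "d"), sizes=(2, 1, 1), labels=("x", "y", "z")
        )
        assert len(models) == 12  # 4!/2! labeled assignments

    def test_each_condition_assigned_once(self):
        for model in enumerate_partitions()[::37]:
            d = model.as_dict()
            assert sorted(d) == sorted(BODY_PARTS)
            counts = [list(d.values()).count(lab) for lab in model.labels]
            assert counts == [4, 2, 2]

    def test_models_unique(self):
        models = enumerate_partitions()
        assert len({m.assignment for m in models}) == 420

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enumerate_partitions(sizes=(5, 2, 2))


class TestAnosimR:
    def test_toy_two_group_perfect_separation(self):
        """4 samples, within ranks {1,2}, between {3..6}: R = (4.5-1.5)/3 = 1."""
        d = np.array(
            [
                [0.0, 0.1, 0.5, 0.6],
                [0.1, 0.0, 0.7, 0.8],
                [0.5, 0.7, 0.0, 0.2],
                [0.6, 0.8, 0.2, 0.0],
            ]
        )
        # pairs (0,1) and (2,3) within: ranks 1 and 2 of the six dissimilarities
        model = PartitionModel(
            assignment=("g1", "g1", "g2", "g2"),
            conditions=("a", "b", "c", "d"),
            sizes=(2, 2),
            labels=("g1", "g2"),
        )
        D = DissimilarityMatrix(d, conditions=("a", "b", "c", "d"))
        assert anosim_r(D, model) == pytest.approx(1.0)

    def test_constant_dissimilarities_give_zero(self):
        d = np.full((8, 8), 0.7)
        np.fill_diagonal(d, 0.0)
        D = DissimilarityMatrix(d)
        assert anosim_r(D, hypothesized_partition()) == pytest.approx(0.0)

    def test_matches_rank_oracle(self):
        """First-principles oracle: explicit pair loop with average ranks."""
        rng = np.random.default_rng(11)
        model = hypothesized_partition()
        for _ in range(20):
            D = random_rdm(rng)
            pairs = list(itertools.combinations(range(8), 2))
            vals = np.array([D.values[i, j] for i, j in pairs])
            ranks = sps.rankdata(vals)
            within = np.array(
                [model.assignment[i] == model.assignment[j] for i, j in pairs]
            )
            expected = (ranks[~within].mean() - ranks[within].mean()) / (len(pairs) / 2)
            assert anosim_r(D, model) == pytest.approx(expected, rel=1e-12)

    def test_matches_scikit_bio(self):
        """Independent cross-check against scikit-bio's ANOSIM R."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(23)
        model = hypothesized_partition()
        D = random_rdm(rng)
        dm = skbio_distance.DistanceMatrix(D.values, ids=list(D.conditions))
        res = skbio_distance.anosim(
            dm, grouping=list(model.assignment), permutations=0
        )
        assert anosim_r(D, model) == pytest.approx(res["test statistic"], rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        D = random_rdm(rng)
        model = hypothesized_partition()
        transformed = DissimilarityMatrix(np.exp(D.values) - 1.0)
        assert anosim_r(D, model) == pytest.approx(anosim_r(transformed, model))


class TestAnosimTest:
    def test_noiseless_minimum_p(self, clustered_rdm):
        """A strict winner yields p = 2/420 (size-2 label-swap twin included)."""
        res = anosim_test(clustered_rdm)
        assert res.p == pytest.approx(2 / 420)
        assert len(res.null_distribution) == 420

    def test_p_floor(self):
        rng = np.random.default_rng(17)
        res = anosim_test(random_rdm(rng))
        assert res.p >= 1 / 420

    def test_null_pairs_into_210_twins(self, clustered_rdm):
        """Swapping the two size-2 category labels duplicates every R value."""
        res = anosim_test(clustered_rdm)
        vals = np.sort(np.round(res.null_distribution, 12))
        assert np.allclose(vals[0::2], vals[1::2])

    def test_hypothesized_appears_once(self):
        models = enumerate_partitions()
        assert models.count(hypothesized_partition()) == 1


class TestMantel:
    def test_self_correlation(self, clustered_rdm):
        res = mantel_test(clustered_rdm, clustered_rdm)
        assert res.r == pytest.approx(1.0)
        assert res.n_permutations == math.factorial(8)

    def test_affine_invariance(self, clustered_rdm):
        scaled = DissimilarityMatrix(0.5 * clustered_rdm.values + 0.1)
        res = mantel_test(clustered_rdm, scaled)
        assert res.r == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(29)
        d1, d2 = random_rdm(rng), random_rdm(rng)
        assert mantel_test(d1, d2).r == pytest.approx(mantel_test(d2, d1).r)

    def test_monte_carlo_converges_to_complete(self):
        rng = np.random.default_rng(31)
        d1, d2 = random_rdm(rng), random_rdm(rng)
        full = mantel_test(d1, d2, scheme="complete")
        mc = mantel_test(d1, d2, scheme="monte_carlo", n_permutations=4000, seed=1)
        # binomial error on the Monte-Carlo p
        se = np.sqrt(full.p * (1 - full.p) / 4000)
        assert abs(mc.p - full.p) < 4 * se + 1e-3

    def test_r_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(37)
        d1, d2 = random_rdm(rng), random_rdm(rng)
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values),
            skbio_distance.DistanceMatrix(d2.values),
            permutations=0,
        )
        assert mantel_test(d1, d2).r == pytest.approx(r_skbio, rel=1e-9)

    def test_constant_matrix_rejected(self, clustered_rdm):
        flat = np.full((8, 8), 0.5)
        np.fill_diagonal(flat, 0.0)
        with pytest.raises(ValueError):
            mantel_test(clustered_rdm, DissimilarityMatrix(flat))


class TestWithinBetweenSimilarity:
    def make_rdms(self, n_per_group, geometry_shift=0.0, jitter=0.02, seed=0):
        rng = np.random.default_rng(seed)
        base = random_rdm(rng)
        other = random_rdm(rng)
        rdms = []
        for g, shift in (("TD-like", 0.0), ("ASD-like", geometry_shift)):
            target = (1 - shift) * base.values + shift * other.values
            for s in range(n_per_group):
                noise = rng.normal(0, jitter, (8, 8))
                noise = (noise + noise.T) / 2
                np.fill_diagonal(noise, 0)
                rdms.append(
                    DissimilarityMatrix(
                        target + noise, subject=f"{g}-{s}", group=g
                    )
                )
        return rdms

    def test_shared_geometry_gives_null_effects(self):
        res = within_between_similarity(self.make_rdms(8, geometry_shift=0.0))
        assert res.anova["factor_a"].p > 0.01  # correlation type
        within = res.z_table[res.z_table.type == "within"].z.mean()
        between = res.z_table[res.z_table.type == "between"].z.mean()
        assert abs(within - between) < 0.2

    def test_distinct_geometries_raise_within_over_between(self):
        res = within_between_similarity(self.make_rdms(8, geometry_shift=0.9))
        within = res.z_table[res.z_table.type == "within"].z.mean()
        between = res.z_table[res.z_table.type == "between"].z.mean()
        assert within > between
        assert res.anova["factor_a"].p < 0.05

    def test_z_is_atanh_of_r(self):
        res = within_between_similarity(self.make_rdms(3))
        assert np.allclose(res.z_table.z, np.arctanh(res.z_table.r))


class TestTraitCorrelations:
    def make_tables(self, rho_sign=1):
        n = 12
        r_vals = np.linspace(0.1, 0.9, n)
        subject_r = pd.DataFrame(
            {
                "subject": [f"sub-{i:03d}" for i in range(n)],
                "group": ["TD-like"] * n,
                "anosim_r": r_vals,
            }
        )
        traits = pd.DataFrame(
            {
                "subject": subject_r.subject,
                "group": subject_r.group,
                "aq_total": rho_sign * (r_vals**2 * 10 + 5),
            }
        )
        return subject_r, traits

    def test_monotone_extremes(self):
        sr, tr = self.make_tables(1)
        table = trait_correlations(sr, tr, family=16)
        assert table.loc[0, "rho"] == pytest.approx(1.0)
        sr, tr = self.make_tables(-1)
        table = trait_correlations(sr, tr, family=16)
        assert table.loc[0, "rho"] == pytest.approx(-1.0)

    def test_bonferroni_family(self):
        sr, tr = self.make_tables(1)
        tr["aq_total"] += np.random.default_rng(0).normal(0, 3, len(tr))
        table = trait_correlations(sr, tr, family=16)
        raw, corr = table.loc[0, "p_raw"], table.loc[0, "p_bonferroni"]
        assert corr == pytest.approx(min(1.0, raw * 16))

    def test_cohort_integration(self):
        cfg = CohortConfig(n_per_group=3, n_voxels=20, seed=41,
                           category_separation=1.0, run_noise_sd=1.5)
        rdms = [compute_split_half_rdm(generate_pattern_set(cfg, i))
                for i in range(cfg.n_subjects)]
        sr = subject_anosim_r(rdms)
        traits = generate_traits(cfg)
        table = trait_correlations(sr, traits)
        assert len(table) == 8
        assert set(table.columns) >= {"trait", "rho", "p_raw", "p_bonferroni"}


def test_mean_anosim_r_increases_with_separation():
    """Common-random-number sweep: stronger clusters, larger mean subject R."""
    model = hypothesized_partition()
    means = []
    for sep in (0.0, 0.5, 1.0, 2.0):
        rs = []
        for i in range(6):
            cfg = CohortConfig(
                n_per_group=3, n_voxels=25, seed=55,
                category_separation=sep, condition_separation=0.4,
                run_noise_sd=0.8,
            )
            rs.append(anosim_r(compute_split_half_rdm(generate_pattern_set(cfg, i)), model))
        means.append(np.mean(rs))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
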