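"""Caller behavior: polar transform, cluster fitting, scoring semantics,
two-pass joint calling, cluster-file round trips and no-call rescue."""
import numpy as np
import pytest

from exochip.caller import (
    ClassParams,
    ClusterFile,
    ClusterModel,
    apply_cluster_file,
    call_genotype,
    call_variant,
    fit_clusters,
    joint_call,
    rescue_nocalls,
    to_polar,
)
from exochip.errors import (
    InsufficientDataError,
    MissingVariantError,
    UndefinedPointError,
)
from exochip.genotypes import GT_AA, GT_AB, GT_BB, GT_XX, GenotypeMatrix, IntensityMatrix
from exochip.simchip import SimConfig, simulate_dataset


def _model(means, devs=None, r_means=None, weights=None, variant_id="V1", expected=3):
    classes = {}
    order = [GT_AA, GT_AB, GT_BB][: len(means)] if expected == 3 else [GT_AA, GT_BB]
    devs = devs or [0.02] * len(means)
    r_means = r_means or [1.0] * len(means)
    weights = weights or [1.0 / len(means)] * len(means)
    for cls, m, d, r, w in zip(order, means, devs, r_means, weights):
        classes[cls] = ClassParams(m, d, r, w)
    return ClusterModel(variant_id, "active", expected, classes)


class TestPolar:
    @pytest.mark.parametrize(
        "x, y, theta, r",
        [(1.0, 0.0, 0.0, 1.0), (0.0, 1.0, 1.0, 1.0), (1.0, 1.0, 0.5, 2.0)],
    )
    def test_pure_and_balanced_signals(self, x, y, theta, r):
        p = to_polar(x, y)
        assert p.theta == pytest.approx(theta, abs=1e-12)
        assert p.r == pytest.approx(r)

    def test_origin_is_undefined(self):
        with pytest.raises(UndefinedPointError):
            to_polar(0.0, 0.0)


class TestFitClusters:
    def test_recovers_well_separated_centers_within_0_01(self, rng):
        centers = (0.05, 0.50, 0.95)
        n = 1000
        cls = rng.choice(3, size=n, p=(0.5, 0.35, 0.15))
        theta = rng.normal(np.array(centers)[cls], 0.02)
        theta = np.abs(theta)
        theta = np.where(theta > 1, 2 - theta, theta)
        model = fit_clusters(theta, np.ones(n))
        assert sorted(model.classes) == [GT_AA, GT_AB, GT_BB]
        for cls_code, center in zip((GT_AA, GT_AB, GT_BB), centers):
            assert model.classes[cls_code].theta_mean == pytest.approx(center, abs=0.01)

    def test_monomorphic_cluster_labeled_aa(self, rng):
        theta = rng.normal(0.04, 0.02, size=500).clip(0, 1)
        model = fit_clusters(theta, np.ones(500))
        assert list(model.classes) == [GT_AA]

    def test_hemizygous_two_cluster_fit_labels_homozygotes(self, rng):
        cls = rng.choice(2, size=400)
        theta = np.clip(rng.normal(np.where(cls == 0, 0.05, 0.95), 0.02), 0, 1)
        model = fit_clusters(theta, np.ones(400), expected_clusters=2)
        assert sorted(model.classes) == [GT_AA, GT_BB]

    def test_single_rare_het_gets_its_own_cluster(self, rng):
        theta = np.concatenate([rng.normal(0.05, 0.02, 499).clip(0, 1), [0.5]])
        model = fit_clusters(theta, np.ones(500))
        assert sorted(model.classes) == [GT_AA, GT_AB]
        assert model.classes[GT_AB].theta_mean == pytest.approx(0.5, abs=0.02)

    def test_theta_means_strictly_increasing(self, small_clean_calls):
        _, _, cluster_file = small_clean_calls
        for model in cluster_file:
            means = [model.classes[c].theta_mean for c in model.present_classes()]
            assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_clusters(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestCallGenotype:
    def test_point_on_cluster_mean_scores_near_one(self):
        model = _model([0.05, 0.50, 0.95])
        res = call_genotype(model, to_polar(1.0, 1.0))  # theta 0.5
        assert res.genotype == GT_AB
        assert res.score > 0.99

    def test_midpoint_scores_no_higher_than_on_mean(self):
        model = _model([0.05, 0.50, 0.95])
        mid = call_genotype(model, to_polar(*_xy_for_theta(0.275)))
        on_mean = call_genotype(model, to_polar(*_xy_for_theta(0.5)))
        assert mid.score <= on_mean.score
        assert mid.score == pytest.approx(0.0, abs=1e-9)

    def test_zeroed_model_forces_missing_with_zero_score(self):
        model = ClusterModel("V1", "zeroed", 3, {})
        res = call_genotype(model, to_polar(1.0, 1.0))
        assert (res.genotype, res.score) == (GT_XX, 0.0)

    def test_distant_point_decays_to_no_call(self):
        model = _model([0.05], devs=[0.02])
        res = call_genotype(model, to_polar(*_xy_for_theta(0.5)))
        assert res.genotype == GT_XX
        assert res.score < 0.15

    def test_no_call_iff_score_below_threshold(self, small_clean_calls):
        calls, scores, _ = small_clean_calls
        applicable = ~np.isnan(scores)
        missing = calls.genotypes == GT_XX
        assert np.all(missing[applicable] == (scores[applicable] < 0.15))

    def test_raising_threshold_never_decreases_no_calls(self, small_clean_sim):
        _, intensities, truth = small_clean_sim
        sexes = truth.sample_meta["sex"].to_numpy()
        chrom = truth.variant_meta["chrom_class"].to_numpy()
        counts = []
        for thr in (0.05, 0.15, 0.5, 0.9):
            calls, _, _ = joint_call(intensities, sexes, chrom, no_call_threshold=thr)
            counts.append(int(np.sum(calls.genotypes == GT_XX)))
        assert counts == sorted(counts)


def _xy_for_theta(theta, r=1.0):
    t = np.tan(theta * np.pi / 2)
    x = r / (1 + t)
    return x, r - x


class TestJointCall:
    def test_clean_simulation_concordance(self, small_clean_sim, small_clean_calls):
        _, _, truth = small_clean_sim
        calls, _, _ = small_clean_calls
        t, c = truth.genotypes.genotypes, calls.genotypes
        both = (t != GT_XX) & (c != GT_XX)
        assert np.mean(t[both] == c[both]) > 0.999

    def test_females_not_called_for_y_variants(self, small_clean_sim, small_clean_calls):
        _, _, truth = small_clean_sim
        calls, scores, _ = small_clean_calls
        y = (truth.variant_meta["chrom_class"] == "Y").to_numpy()
        female = (truth.sample_meta["sex"] == "F").to_numpy()
        if y.any():
            assert np.all(calls.genotypes[np.ix_(y, female)] == GT_XX)
            assert np.all(np.isnan(scores[np.ix_(y, female)]))

    def test_monomorphic_variants_called_monomorphic(self, small_clean_sim, small_clean_calls):
        _, _, truth = small_clean_sim
        calls, _, _ = small_clean_calls
        mono = (truth.variant_meta["maf"] == 0).to_numpy() & (
            truth.variant_meta["chrom_class"] == "autosome"
        ).to_numpy()
        variant_ok = [
            not np.any(np.isin(calls.genotypes[vi], (GT_AB, GT_BB)))
            for vi in np.nonzero(mono)[0]
        ]
        assert np.mean(variant_ok) >= 0.99

    def test_deterministic_given_inputs(self, small_clean_sim):
        _, intensities, truth = small_clean_sim
        sexes = truth.sample_meta["sex"].to_numpy()
        chrom = truth.variant_meta["chrom_class"].to_numpy()
        c1, s1, _ = joint_call(intensities, sexes, chrom)
        c2, s2, _ = joint_call(intensities, sexes, chrom)
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(s1, s2)


class TestClusterFile:
    def test_round_trip_reproduces_calls_bit_identically(self, tmp_path, small_clean_sim, small_clean_calls):
        _, intensities, truth = small_clean_sim
        calls, scores, cluster_file = small_clean_calls
        path = tmp_path / "clusters.tsv"
        cluster_file.write(path)
        reread = ClusterFile.read(path)
        sexes = truth.sample_meta["sex"].to_numpy()
        chrom = truth.variant_meta["chrom_class"].to_numpy()
        c1, s1 = apply_cluster_file(cluster_file, intensities, sexes, chrom)
        c2, s2 = apply_cluster_file(reread, intensities, sexes, chrom)
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        np.testing.assert_array_equal(s1, s2)

    def test_apply_matches_joint_call_pass_two(self, small_clean_sim, small_clean_calls):
        _, intensities, truth = small_clean_sim
        calls, _, cluster_file = small_clean_calls
        sexes = truth.sample_meta["sex"].to_numpy()
        chrom = truth.variant_meta["chrom_class"].to_numpy()
        reapplied, _ = apply_cluster_file(cluster_file, intensities, sexes, chrom)
        np.testing.assert_array_equal(reapplied.genotypes, calls.genotypes)

    def test_apply_to_second_cohort_concordance_close(self, small_clean_sim, small_clean_calls):
        cfg, _, _ = small_clean_sim
        _, _, cluster_file = small_clean_calls
        cfg2 = SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        ints2, truth2 = simulate_dataset(cfg2)
        calls2, _ = apply_cluster_file(
            cluster_file,
            ints2,
            truth2.sample_meta["sex"].to_numpy(),
            truth2.variant_meta["chrom_class"].to_numpy(),
        )
        t, c = truth2.genotypes.genotypes, calls2.genotypes
        both = (t != GT_XX) & (c != GT_XX)
        assert np.mean(t[both] == c[both]) > 0.998

    def test_all_zeroed_file_yields_all_missing(self, small_clean_sim, small_clean_calls):
        _, intensities, truth = small_clean_sim
        _, _, cluster_file = small_clean_calls
        zeroed = ClusterFile([m.zeroed() for m in cluster_file])
        calls, _ = apply_cluster_file(
            zeroed,
            intensities,
            truth.sample_meta["sex"].to_numpy(),
            truth.variant_meta["chrom_class"].to_numpy(),
        )
        assert np.all(calls.genotypes == GT_XX)

    def test_missing_variant_is_hard_error(self, small_clean_sim):
        _, intensities, _ = small_clean_sim
        with pytest.raises(MissingVariantError):
            apply_cluster_file(ClusterFile(), intensities)


class TestRescue:
    def test_no_op_without_no_calls(self):
        rng = np.random.default_rng(3)
        n = 50
        theta = np.concatenate([np.full(20, 0.05), np.full(20, 0.5), np.full(10, 0.95)])
        theta += rng.normal(0, 0.01, n)
        r = np.ones(n)
        t = np.tan(theta.clip(0, 1) * np.pi / 2)
        x = r / (1 + t)
        ints = IntensityMatrix(["V1"], [f"S{i}" for i in range(n)], x[None, :], (r - x)[None, :])
        genos = np.array([[GT_AA] * 20 + [GT_AB] * 20 + [GT_BB] * 10], dtype=np.int8)
        calls = GenotypeMatrix(["V1"], ints.samples, genos)
        rescued = rescue_nocalls(calls, ints, ClusterFile())
        np.testing.assert_array_equal(rescued.genotypes, calls.genotypes)

    def test_rescue_is_monotone_in_missingness(self, small_clean_sim, small_clean_calls):
        _, intensities, _ = small_clean_sim
        calls, _, cluster_file = small_clean_calls
        rescued = rescue_nocalls(calls, intensities, cluster_file)
        assert rescued.missing_rate() <= calls.missing_rate()
        # previously called genotypes are never changed
        was_called = calls.genotypes != GT_XX
        np.testing.assert_array_equal(
            rescued.genotypes[was_called], calls.genotypes[was_called]
        )

    def test_dropped_rare_het_is_recovered(self):
        # one no-called heterozygote whose intensities sit in the AB quadrant
        rng = np.random.default_rng(4)
        n = 60
        theta = np.concatenate([rng.normal(0.05, 0.01, 40), rng.normal(0.95, 0.01, 19), [0.5]])
        r = np.ones(n)
        t = np.tan(theta.clip(0, 1) * np.pi / 2)
        x = r / (1 + t)
        ints = IntensityMatrix(["V1"], [f"S{i}" for i in range(n)], x[None, :], (r - x)[None, :])
        genos = np.array([[GT_AA] * 40 + [GT_BB] * 19 + [GT_XX]], dtype=np.int8)
        calls = GenotypeMatrix(["V1"], ints.samples, genos)
        rescued = rescue_nocalls(calls, ints, ClusterFile(), z=7)
        assert rescued.genotypes[0, -1] == GT_AB
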