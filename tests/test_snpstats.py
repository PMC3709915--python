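"""SNP/sample statistics: hand-computed vectors, brute-force oracle
equivalence on small fixtures, and the invariants of each statistic."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exochip.genotypes import GT_AA, GT_AB, GT_BB, GT_XX, GenotypeMatrix
from exochip.snpstats import (
    cluster_separation,
    compute_sample_stats,
    compute_snp_stats,
    het_excess_statistic,
    maf_bin_label,
    maf_table,
    mendel_errors,
    replicate_errors,
)


def _stats(genos, theta=None, r=None, sexes=None, chrom="autosome", scores=None):
    genos = np.asarray(genos, dtype=np.int8)
    n = genos.size
    theta = np.asarray(theta if theta is not None else np.zeros(n), dtype=float)
    r = np.asarray(r if r is not None else np.ones(n), dtype=float)
    sexes = np.asarray(sexes if sexes is not None else ["M"] * n)
    return compute_snp_stats("V1", genos, scores, theta, r, sexes, chrom)


class TestHandComputedVectors:
    def test_exact_hwe_genotypes_have_zero_het_excess(self):
        s = _stats([GT_AA] * 81 + [GT_AB] * 18 + [GT_BB] * 1)
        assert s.maf == pytest.approx(0.1)
        assert s.het_excess == pytest.approx(0.0, abs=1e-12)

    def test_het_excess_with_missing_homozygote_class(self):
        s = _stats([GT_AA] * 50 + [GT_AB] * 50)
        assert s.het_excess == pytest.approx((0.5 - 0.375) / 0.375)

    def test_cluster_sep_formula_two_classes(self):
        assert cluster_separation([0.50, 0.95], [0.02, 0.02]) == pytest.approx(
            0.45 / 0.49
        )

    def test_het_excess_guards_at_zero_expectation(self):
        assert het_excess_statistic(0.0, 0.0) == 0.0
        assert het_excess_statistic(0.2, 0.0) == 10.0

    def test_p10gc_lower_order_statistic(self):
        scores = np.array([0.10] * 10 + [0.90] * 90)
        genos = np.full(100, GT_AA, dtype=np.int8)
        s = compute_sample_stats("S1", genos, scores)
        assert s.p10gc == pytest.approx(0.10)

    def test_p10gc_constant_scores(self):
        s = compute_sample_stats("S1", np.full(50, GT_AA, np.int8), np.full(50, 0.38))
        assert s.p10gc == pytest.approx(0.38)

    def test_call_rate_complete_sample(self):
        s = compute_sample_stats("S1", np.full(50, GT_AB, np.int8), np.ones(50))
        assert s.call_rate == 1.0

    def test_female_y_excluded_from_denominators(self):
        genos = np.array([GT_AA, GT_BB, GT_XX, GT_AA], dtype=np.int8)
        sexes = np.array(["M", "M", "M", "F"])
        s = _stats(genos, sexes=sexes, chrom="Y")
        assert s.n_total == 3
        assert s.n_called == 2
        assert s.call_frequency == pytest.approx(2 / 3)
        assert s.het_excess is None  # haploid class: no HWE expectation


class TestBruteForceOracle:
    """Every field equals a from-scratch recomputation by direct counting."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_snp_stats_match_direct_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        genos = rng.choice(
            [GT_AA, GT_AB, GT_BB, GT_XX], size=n, p=[0.5, 0.25, 0.15, 0.1]
        ).astype(np.int8)
        theta = rng.uniform(0, 1, n)
        r = rng.uniform(0.5, 1.5, n)
        s = _stats(genos, theta, r)

        called = [g for g in genos if g != GT_XX]
        nc = len(called)
        assert s.n_total == n and s.n_called == nc
        assert s.call_frequency == pytest.approx(nc / n)
        if nc == 0:
            return
        n_aa = sum(g == GT_AA for g in called)
        n_ab = sum(g == GT_AB for g in called)
        n_bb = sum(g == GT_BB for g in called)
        assert s.aa_freq == pytest.approx(n_aa / nc)
        assert s.ab_freq == pytest.approx(n_ab / nc)
        assert s.bb_freq == pytest.approx(n_bb / nc)
        assert s.aa_freq + s.ab_freq + s.bb_freq == pytest.approx(1.0, abs=1e-9)
        p_b = (2 * n_bb + n_ab) / (2 * nc)
        assert s.maf == pytest.approx(min(p_b, 1 - p_b))
        assert s.minor_allele_count == round(2 * nc * s.maf)
        e = 2 * p_b * (1 - p_b)
        if e > 0:
            assert s.het_excess == pytest.approx((n_ab / nc - e) / e)
        means, devs = [], []
        for cls, prefix in ((GT_AA, "aa"), (GT_AB, "ab"), (GT_BB, "bb")):
            members = [i for i in range(n) if genos[i] == cls]
            if not members:
                assert getattr(s, f"{prefix}_theta_mean") is None
                continue
            mean = sum(theta[i] for i in members) / len(members)
            var = sum((theta[i] - mean) ** 2 for i in members) / len(members)
            assert getattr(s, f"{prefix}_theta_mean") == pytest.approx(mean)
            assert getattr(s, f"{prefix}_theta_dev") == pytest.approx(var**0.5)
            if cls == GT_AB:
                assert s.ab_r_mean == pytest.approx(
                    sum(r[i] for i in members) / len(members)
                )
            means.append(mean)
            devs.append(var**0.5)
        if len(means) >= 2:
            expected = min(
                abs(m2 - m1) / (abs(m2 - m1) + d1 + d2)
                for (m1, d1), (m2, d2) in zip(zip(means, devs), zip(means[1:], devs[1:]))
            )
            assert s.cluster_sep == pytest.approx(expected)
        else:
            assert s.cluster_sep == 1.0

    def test_x_variant_allele_counts_respect_ploidy(self):
        # 2 female AB (2 B), 1 male BB (1 B), 3 male AA, 2 female AA
        genos = np.array([GT_AB, GT_AB, GT_BB, GT_AA, GT_AA, GT_AA, GT_AA, GT_AA], np.int8)
        sexes = np.array(["F", "F", "M", "M", "M", "M", "F", "F"])
        s = _stats(genos, sexes=sexes, chrom="X")
        # alleles: females 2 each (6 F? no: 4 females -> 8) + males 1 each (4) = 12
        assert s.maf == pytest.approx(3 / 12)
        assert s.minor_allele_count == 3


class TestPropertyInvariants:
    @given(
        n_aa=st.integers(0, 50), n_ab=st.integers(0, 50), n_bb=st.integers(0, 50)
    )
    @settings(max_examples=200, deadline=None)
    def test_het_excess_bounded_below_by_minus_one(self, n_aa, n_ab, n_bb):
        n = n_aa + n_ab + n_bb
        if n == 0:
            return
        p = (2 * n_bb + n_ab) / (2 * n)
        he = het_excess_statistic(n_ab / n, p)
        assert he >= -1.0

    @given(
        means=st.lists(st.floats(0, 1), min_size=2, max_size=3, unique=True),
        devs=st.lists(st.floats(0.001, 0.3), min_size=3, max_size=3),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_cluster_sep_is_scale_free(self, means, devs, scale):
        means = sorted(means)
        devs = devs[: len(means)]
        base = cluster_separation(means, devs)
        scaled = cluster_separation(
            [m * scale for m in means], [d * scale for d in devs]
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mean_call_frequency_equals_mean_call_rate_without_sex_rules(self, rng):
        genos = rng.choice([GT_AA, GT_AB, GT_BB, GT_XX], size=(30, 40)).astype(np.int8)
        call_freq = np.mean(genos != GT_XX, axis=1)
        call_rate = np.mean(genos != GT_XX, axis=0)
        assert np.mean(call_freq) == pytest.approx(np.mean(call_rate))


class TestPedigreeCounts:
    def _gm(self, columns):
        arr = np.array(columns, dtype=np.int8).T
        return GenotypeMatrix(
            [f"V{i}" for i in range(arr.shape[0])],
            [f"S{i}" for i in range(arr.shape[1])],
            arr,
        )

    def test_identical_duplicates_have_zero_errors(self):
        gm = self._gm([[GT_AA, GT_AB, GT_BB], [GT_AA, GT_AB, GT_BB]])
        assert np.all(replicate_errors(gm, [("S0", "S1")]) == 0)

    def test_single_discordant_pair_counts_once(self):
        gm = self._gm([[GT_AA, GT_AB], [GT_AB, GT_AB]])
        np.testing.assert_array_equal(replicate_errors(gm, [("S0", "S1")]), [1, 0])

    def test_missing_call_is_not_discordance(self):
        gm = self._gm([[GT_XX], [GT_AA]])
        assert replicate_errors(gm, [("S0", "S1")])[0] == 0

    @pytest.mark.parametrize(
        "father, mother, child, ppc",
        [
            (GT_AA, GT_AA, GT_AB, 1),
            (GT_AA, GT_AA, GT_BB, 1),
            (GT_AA, GT_BB, GT_AA, 1),
            (GT_AA, GT_BB, GT_AB, 0),
            (GT_AB, GT_AB, GT_AA, 0),
            (GT_AB, GT_AB, GT_AB, 0),
            (GT_AB, GT_AB, GT_BB, 0),
            (GT_AA, GT_AB, GT_BB, 1),
        ],
    )
    def test_parent_parent_child_rules(self, father, mother, child, ppc):
        gm = self._gm([[father], [mother], [child]])
        got_ppc, got_pc = mendel_errors(gm, [("S2", "S0", "S1")])
        assert int(got_ppc[0]) == ppc
        assert int(got_pc[0]) == 0

    @pytest.mark.parametrize(
        "parent, child, pc",
        [(GT_AA, GT_BB, 1), (GT_BB, GT_AA, 1), (GT_AA, GT_AB, 0), (GT_AB, GT_BB, 0)],
    )
    def test_single_parent_opposite_homozygote_rule(self, parent, child, pc):
        gm = self._gm([[parent], [child]])
        got_ppc, got_pc = mendel_errors(gm, [("S1", "S0", None)])
        assert int(got_pc[0]) == pc
        assert int(got_ppc[0]) == 0

    def test_missing_parent_call_degrades_to_pairwise_check(self):
        gm = self._gm([[GT_AA], [GT_XX], [GT_BB]])
        got_ppc, got_pc = mendel_errors(gm, [("S2", "S0", "S1")])
        assert (int(got_ppc[0]), int(got_pc[0])) == (0, 1)

    def test_sex_chromosomes_exempt(self):
        gm = self._gm([[GT_AA], [GT_AA], [GT_BB]])
        got_ppc, _ = mendel_errors(gm, [("S2", "S0", "S1")], chrom_classes=np.array(["X"]))
        assert int(got_ppc[0]) == 0


class TestMafTable:
    @pytest.mark.parametrize(
        "maf, label",
        [
            (0.0, "0"),
            (0.0005, "(0, 0.001]"),
            (0.001, "(0, 0.001]"),  # right edge inclusive
            (0.0011, "(0.001, 0.005]"),
            (0.05, "(0.01, 0.05]"),
            (0.5, "(0.2, 0.5]"),
        ],
    )
    def test_bin_edges_left_open_right_closed(self, maf, label):
        assert maf_bin_label(maf) == label

    def test_out_of_range_maf_rejected(self):
        with pytest.raises(ValueError):
            maf_bin_label(0.6)

    def test_percentages_sum_to_100_per_group(self, rng):
        mafs = rng.uniform(0, 0.5, 500)
        mafs[:50] = 0.0
        groups = rng.choice(["A", "B"], size=500)
        table = maf_table(mafs, groups)
        for col in table.columns:
            assert table[col].sum() == pytest.approx(100.0)

    def test_generator_spectrum_round_trip(self, small_clean_sim):
        _, _, truth = small_clean_sim
        auto = truth.variant_meta["chrom_class"] == "autosome"
        mafs = truth.variant_meta.loc[auto, "maf"].to_numpy()
        table = maf_table(mafs)
        n = mafs.size
        from exochip.simchip import DEFAULT_MAF_SPECTRUM

        for (edge, prop), label in zip(
            DEFAULT_MAF_SPECTRUM, table.index
        ):
            se_pct = 100 * np.sqrt(prop * (1 - prop) / n)
            assert abs(table.loc[label, "All"] - 100 * prop) <= max(4 * se_pct, 1.0)
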