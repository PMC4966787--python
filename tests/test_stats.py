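import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from feulgen import (
    compare_groups,
    delta_ct,
    describe_sample,
    dna_area_correlation,
    fold_histogram,
    pool_samples,
    replicate_summary,
)
from feulgen.stats import SampleSummary


# --- independent brute-force oracles (definition-level implementations) ---

def _oracle_moments(x):
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    g1 = m3 / m2**1.5
    skew = g1 * math.sqrt(n * (n - 1)) / (n - 2)  # adjusted Fisher-Pearson
    g2 = m4 / m2**2 - 3.0
    kurt = ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))
    return mean, sd, skew, kurt


class TestDescribeSample:
    def test_against_brute_force_oracle(self, rng):
        pg = rng.gamma(4.0, 1.5, size=257)
        areas = rng.uniform(20, 90, size=257)
        s = describe_sample(pg, areas, "x")
        mean_pg, sd_pg, skew, kurt = _oracle_moments(list(pg))
        mean_a, sd_a, _, _ = _oracle_moments(list(areas))
        assert s.mean_pg == pytest.approx(mean_pg, rel=1e-10)
        assert s.sd_pg == pytest.approx(sd_pg, rel=1e-10)
        assert s.skewness == pytest.approx(skew, rel=1e-10)
        assert s.kurtosis == pytest.approx(kurt, rel=1e-10)
        assert s.mean_area_um2 == pytest.approx(mean_a, rel=1e-10)
        assert s.cv_area_percent == pytest.approx(sd_a / mean_a * 100,
                                                  rel=1e-10)
        assert s.dcv_percent == pytest.approx(sd_pg / mean_pg * 100,
                                              rel=1e-10)
        assert s.se_area_um2 == pytest.approx(sd_a / math.sqrt(257),
                                              rel=1e-10)
        lo, hi = s.ci95_area_um2
        assert lo == pytest.approx(mean_a - 1.96 * s.se_area_um2, rel=1e-10)
        assert hi == pytest.approx(mean_a + 1.96 * s.se_area_um2, rel=1e-10)
        assert lo < s.mean_area_um2 < hi

    def test_symmetric_distribution_has_small_shape_stats(self, rng):
        pg = rng.normal(6.0, 1.0, size=100_000)
        s = describe_sample(pg, np.abs(pg) * 10, "sym")
        assert abs(s.skewness) < 0.05
        assert abs(s.kurtosis) < 0.1

    def test_constant_sample_degenerate(self):
        s = describe_sample(np.full(20, 6.0), np.full(20, 60.0), "const")
        assert s.sd_pg == 0.0
        assert s.dcv_percent == 0.0
        assert s.skewness == 0.0
        assert "degenerate_constant_sample" in s.notes

    def test_n1_leaves_sd_fields_undefined(self):
        s = describe_sample([6.0], [60.0], "single")
        assert np.isnan(s.sd_pg)
        assert "n_lt_2_sd_undefined" in s.notes

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            describe_sample([], [], "empty")


class TestPoolSamples:
    def test_pooling_equals_describe_on_concatenation(self, rng):
        chunks = [rng.normal(6, 1, 83), rng.normal(3, 0.5, 41),
                  rng.normal(9, 2, 120)]
        areas = [c * 10 for c in chunks]
        summaries = [describe_sample(c, a, str(i))
                     for i, (c, a) in enumerate(zip(chunks, areas))]
        pooled = pool_samples(summaries)
        direct = describe_sample(np.concatenate(chunks),
                                 np.concatenate(areas), "all")
        assert pooled.n == direct.n
        assert pooled.mean_pg == pytest.approx(direct.mean_pg, rel=1e-12)
        assert pooled.sd_pg == pytest.approx(direct.sd_pg, rel=1e-12)
        assert pooled.mean_area_um2 == pytest.approx(direct.mean_area_um2,
                                                     rel=1e-12)
        assert pooled.sd_area_um2 == pytest.approx(direct.sd_area_um2,
                                                   rel=1e-12)
        assert pooled.se_area_um2 == pytest.approx(direct.se_area_um2,
                                                   rel=1e-12)

    def test_two_identical_samples_pool_to_themselves(self):
        s = SampleSummary.from_moments("a", 50, 6.0, 1.0, 60.0, 10.0)
        pooled = pool_samples([s, s])
        assert pooled.n == 100
        assert pooled.mean_area_um2 == pytest.approx(60.0)
        # combined SS with equal means and SDs: s^2 * (2(n-1))/(2n-1)
        expected_sd = math.sqrt(10.0**2 * 98 / 99)
        assert pooled.sd_area_um2 == pytest.approx(expected_sd, rel=1e-12)

    def test_single_summary_rejected(self):
        s = SampleSummary.from_moments("a", 50, 6.0, 1.0, 60.0, 10.0)
        with pytest.raises(ValueError):
            pool_samples([s])


class TestCompareGroups:
    def test_frozen_dunn_example(self):
        """Three small groups with cross-group ties, checked against a
        hand-computed rank solution."""
        groups = {"A": [1.1, 2.2, 3.3, 4.4, 5.5],
                  "B": [2.2, 4.4, 6.6, 8.8],
                  "C": [10.0, 11.0, 12.0]}
        res = compare_groups(groups)
        assert res.h_statistic == pytest.approx(7.146127, abs=1e-5)
        assert res.p_value == pytest.approx(0.028070, abs=1e-5)
        expected = {("A", "B"): (-0.93353, 0.350546),
                    ("A", "C"): (-2.667785, 0.007635),
                    ("B", "C"): (-1.730961, 0.083459)}
        assert len(res.pairwise) == 3
        for p in res.pairwise:
            z, pval = expected[(p.group_a, p.group_b)]
            assert p.z == pytest.approx(z, abs=1e-5)
            assert p.p_raw == pytest.approx(pval, abs=1e-5)
            assert p.p_adjusted == p.p_raw  # default: no adjustment

    def test_bonferroni_and_holm_adjustments(self):
        groups = {"A": [1.1, 2.2, 3.3, 4.4, 5.5],
                  "B": [2.2, 4.4, 6.6, 8.8],
                  "C": [10.0, 11.0, 12.0]}
        bon = compare_groups(groups, adjust="bonferroni")
        assert all(p.p_adjusted == pytest.approx(min(1.0, 3 * p.p_raw))
                   for p in bon.pairwise)
        holm = compare_groups(groups, adjust="holm")
        raws = sorted(p.p_raw for p in holm.pairwise)
        adjs = {p.p_raw: p.p_adjusted for p in holm.pairwise}
        assert adjs[raws[0]] == pytest.approx(3 * raws[0])

    def test_pairwise_count_is_k_choose_2(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 12) for i in range(5)}
        res = compare_groups(groups)
        assert len(res.pairwise) == 5 * 4 // 2

    def test_large_shift_detected(self, rng):
        a = rng.normal(6.0, 1.0, 100)
        res = compare_groups({"a": a, "b": a + 3.0})
        assert res.p_value < 0.05
        assert res.significant

    def test_identical_constant_groups_give_h_zero(self):
        res = compare_groups({"a": [5.0] * 8, "b": [5.0] * 8})
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        groups = {"a": rng.normal(6, 1, 40), "b": rng.normal(6.5, 1, 35),
                  "c": rng.normal(5.5, 1, 30)}
        res1 = compare_groups(groups)
        res2 = compare_groups({k: np.exp(v) for k, v in groups.items()})
        assert res1.h_statistic == pytest.approx(res2.h_statistic, rel=1e-12)
        assert res1.p_value == pytest.approx(res2.p_value, rel=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0], "b": []})


class TestCorrelation:
    def test_perfect_proportionality(self):
        pg = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2, p = dna_area_correlation(pg, 10.36 * pg)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_variables_near_zero(self, rng):
        r, _, _ = dna_area_correlation(rng.normal(6, 1, 1000),
                                       rng.normal(60, 10, 1000))
        assert abs(r) < 0.1

    def test_generator_low_area_noise_gives_strong_relation(self):
        rng = np.random.default_rng(77)
        pg = rng.normal(6.0, 1.2, 400)
        area = 10.36 * pg * rng.lognormal(0, 0.05, 400)
        _, r2, p = dna_area_correlation(pg, area)
        assert r2 > 0.9
        assert p < 1e-6

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            dna_area_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


class TestFoldHistogram:
    def test_pure_diploid_population_modes_at_2(self, rng):
        folds = rng.normal(2.0, 0.1, 500)
        h = fold_histogram(folds)
        assert h.unimodal
        assert h.modal_fold == pytest.approx(2.0, abs=0.25)
        assert h.near_gaussian

    def test_2c_4c_mixture_has_two_modes(self, rng):
        folds = np.concatenate([rng.normal(2.0, 0.12, 400),
                                rng.normal(4.0, 0.12, 300)])
        h = fold_histogram(folds)
        assert len(h.modes) == 2
        assert min(abs(m - 2.0) for m in h.modes) < 0.3
        assert min(abs(m - 4.0) for m in h.modes) < 0.3

    def test_heavily_skewed_sample_not_near_gaussian(self, rng):
        folds = rng.lognormal(0.0, 1.2, 2000)  # skewness well above 2
        h = fold_histogram(folds)
        assert abs(h.skewness) > 2.0
        assert not h.near_gaussian

    def test_empty_and_bad_bin_width_raise(self):
        with pytest.raises(ValueError):
            fold_histogram([])
        with pytest.raises(ValueError):
            fold_histogram([2.0], bin_width=0.0)


class TestQpcrHelpers:
    def test_replicate_summary_identity(self):
        assert replicate_summary([4.2, 4.2]) == (4.2, 0.0)

    def test_replicate_summary_needs_two(self):
        with pytest.raises(ValueError):
            replicate_summary([37.0])

    def test_delta_ct_identity_and_arithmetic(self):
        assert delta_ct(5.0, 5.0) == 0.0
        assert delta_ct(35.34, 30.24) == pytest.approx(5.10)
        with pytest.raises(ValueError):
            delta_ct(float("nan"), 1.0)


@given(arrays(np.float64, st.integers(min_value=4, max_value=60),
              elements=st.floats(min_value=0.1, max_value=100.0)))
def test_describe_sample_property(x):
    """SD/SE/CI relations hold on arbitrary positive vectors."""
    s = describe_sample(x, x * 2, "h")
    if np.isnan(s.sd_pg):
        return
    assert s.se_area_um2 == pytest.approx(
        s.sd_area_um2 / math.sqrt(len(x)), rel=1e-9)
    lo, hi = s.ci95_area_um2
    assert lo <= s.mean_area_um2 <= hi
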