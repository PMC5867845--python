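"""Variant-calling filter cascade, frequency arithmetic, detection floor."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthet import (
    AlleleCounts,
    FilterConfig,
    call_position,
    detection_floor,
    frequencies,
    strand_balance_ratio,
    table2,
)

CFG = FilterConfig()


def make_counts(np_=1000, sample="s", **base_counts):
    fwd = {b: 0 for b in "ACGT"}
    rev = {b: 0 for b in "ACGT"}
    for key, n in base_counts.items():
        base, d = key[0], key[2:]
        (fwd if d == "fwd" else rev)[base] = n
    return AlleleCounts(sample, np_, fwd, rev)


def oracle_status(counts: AlleleCounts, cfg: FilterConfig) -> str:
    """Independent re-statement of the cascade, evaluated step by literal step."""
    if counts.np in cfg.excluded_positions:
        return "failed_filter:excluded"
    total = counts.total
    if total == 0:
        return "insufficient_coverage"
    by_freq = sorted("ACGT", key=lambda b: (-counts.count(b) / total, b))
    major, minor = by_freq[0], by_freq[1]
    if total < cfg.min_total_coverage:
        return "failed_filter:min_total_coverage"
    if counts.count(minor) / total < cfg.analytical_threshold:
        return "failed_filter:analytical_threshold"
    if counts.count(minor) < cfg.min_variant_reads:
        return "failed_filter:min_variant_reads"
    nf, nr = counts.fwd[minor], counts.rev[minor]
    mf, mr = counts.fwd[major], counts.rev[major]
    if nf == 0 or nr == 0:
        ratio = math.inf
    elif cfg.balance_mode == "minor_only" or mf == 0 or mr == 0:
        ratio = max(nf, nr) / min(nf, nr)
    else:
        odds = (nf / nr) / (mf / mr)
        ratio = max(odds, 1 / odds)
    if ratio > cfg.max_balance_ratio:
        return "failed_filter:balance_ratio"
    if counts.count(minor) / total < cfg.reporting_threshold:
        return "below_reporting"
    return "reported"


class TestFrequencies:
    def test_monomorphic_pileup(self):
        c = make_counts(T_fwd=50, T_rev=50)
        assert frequencies(c) == {"A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0}

    def test_printed_worked_example_np2746(self):
        # mother buccal at np 2746: minor C 655+1600 of an implied total
        # 11214 (major 8934 at 79.67%) -> minor 20.11%
        total = round(8934 / 0.7967)
        other = total - 8934 - 2255
        c = make_counts(
            2746, T_fwd=2920, T_rev=6014, C_fwd=655, C_rev=1600,
            G_fwd=other - other // 2, G_rev=other // 2,
        )
        f = frequencies(c)
        assert 100 * f["C"] == pytest.approx(20.11, abs=0.005)
        assert 100 * f["T"] == pytest.approx(79.67, abs=0.005)

    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=8, max_size=8)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_fractions_match_bruteforce_and_sum_to_one(self, counts8):
        if sum(counts8) == 0:
            return
        c = AlleleCounts(
            "s", 1, dict(zip("ACGT", counts8[:4])), dict(zip("ACGT", counts8[4:]))
        )
        f = frequencies(c)
        total = sum(counts8)
        for i, b in enumerate("ACGT"):
            assert f[b] == pytest.approx((counts8[i] + counts8[i + 4]) / total)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            frequencies(make_counts())


class TestCallCascade:
    def test_below_reporting_printed_example_np200(self):
        # child buccal at np 200: minor A at 1.13% with 5 fwd : 54 rev
        c = make_counts(200 + 0, G_fwd=1148, G_rev=3998, A_fwd=5, A_rev=54)
        call = call_position(c, CFG)
        assert not call.reported
        # above the analytical threshold but under the 2% reporting threshold
        assert call.minor_freq > 0.01

    def test_min_variant_reads_boundary(self):
        c = make_counts(T_fwd=981, T_rev=980, C_fwd=20, C_rev=19)
        call = call_position(c, CFG)
        assert call.status == "failed_filter:min_variant_reads"
        assert call.minor_freq >= CFG.analytical_threshold
        c2 = make_counts(T_fwd=980, T_rev=980, C_fwd=20, C_rev=20)
        assert call_position(c2, CFG).status == "reported"  # exactly 40 of 2000

    def test_excluded_position_and_zero_coverage(self):
        assert call_position(make_counts(310, T_fwd=5000, C_fwd=500, C_rev=500)).status \
            == "failed_filter:excluded"
        assert call_position(make_counts()).status == "insufficient_coverage"

    def test_one_sided_minor_fails_balance(self):
        c = make_counts(T_fwd=5000, T_rev=5000, C_fwd=300, C_rev=0)
        assert call_position(c, CFG).status == "failed_filter:balance_ratio"

    def test_major_normalized_balance_tracks_amplicon_bias(self):
        # both alleles skewed the same way: passes under the default mode,
        # fails under the raw minor-only reading
        c = make_counts(T_fwd=3088, T_rev=856, C_fwd=552, C_rev=155)
        assert call_position(c, CFG).reported
        raw = FilterConfig(balance_mode="minor_only")
        assert call_position(c, raw).status == "failed_filter:balance_ratio"
        assert strand_balance_ratio(c, "T", "C", "minor_only") > 2.5
        assert strand_balance_ratio(c, "T", "C", "major_normalized") < 1.1

    def test_score_balance_applied_only_with_quality(self):
        fwd = {"A": 0, "C": 250, "G": 0, "T": 4750}
        rev = {"A": 0, "C": 250, "G": 0, "T": 4750}
        plain = AlleleCounts("s", 50, fwd, rev)
        assert call_position(plain, CFG).reported
        qual = AlleleCounts("s", 50, fwd, rev, {"T": 38.0, "C": 20.0, "A": 0, "G": 0})
        assert call_position(qual, CFG).status == "failed_filter:score_balance"

    @pytest.mark.parametrize("coverage", [200, 1000, 2000, 4000])
    @pytest.mark.parametrize("minor_reads", [0, 5, 39, 40, 41, 80, 100])
    @pytest.mark.parametrize("split", [0.0, 0.2, 0.5])
    def test_grid_matches_bruteforce_oracle(self, coverage, minor_reads, split):
        if minor_reads > coverage:
            return
        nf = int(minor_reads * split)
        nr = minor_reads - nf
        maj = coverage - minor_reads
        c = make_counts(T_fwd=maj - maj // 2, T_rev=maj // 2, C_fwd=nf, C_rev=nr)
        assert call_position(c, CFG).status == oracle_status(c, CFG)

    @given(
        st.integers(0, 4000), st.integers(0, 200), st.floats(0, 1),
        st.sampled_from([1, 310, 3107, 8000]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_random_pileups_match_oracle(self, cov, minor, split_f, np_):
        minor = min(minor, cov)
        nf = int(minor * split_f)
        maj = cov - minor
        c = make_counts(np_, G_fwd=maj // 2, G_rev=maj - maj // 2,
                        A_fwd=nf, A_rev=minor - nf)
        assert call_position(c, CFG).status == oracle_status(c, CFG)

    def test_monotone_in_minor_reads(self):
        # increasing minor reads at fixed coverage never flips reported ->
        # unreported
        cov = 4000
        reported = []
        for k in range(0, 400, 7):
            c = make_counts(T_fwd=(cov - k) // 2, T_rev=(cov - k) - (cov - k) // 2,
                            C_fwd=k // 2, C_rev=k - k // 2)
            reported.append(call_position(c, CFG).reported)
        first = next((i for i, r in enumerate(reported) if r), len(reported))
        assert all(reported[first:])

    def test_every_reported_call_satisfies_all_thresholds(self, classified=None):
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(500):
            cov = int(rng.integers(1, 30000))
            k = int(rng.integers(0, cov // 2 + 1))
            nf = int(rng.binomial(k, 0.5))
            c = make_counts(T_fwd=(cov - k) // 2, T_rev=(cov - k) - (cov - k) // 2,
                            C_fwd=nf, C_rev=k - nf)
            call = call_position(c, CFG)
            if call.reported:
                assert call.total_coverage >= 200
                assert call.minor_freq >= 0.02
                assert call.minor_fwd + call.minor_rev >= 40
                assert strand_balance_ratio(c, call.major_allele, call.minor_allele) <= 2.5


class TestTable2Reconstruction:
    def test_heteroplasmy_reported_only_in_carrier_samples(self, cohort):
        from mthet import call_position

        t2 = table2()
        lookup = {(str(r["sample_code"]), int(r["np"])): r for _, r in t2.iterrows()}
        by_key = {(c.sample_id, c.np): c for c in cohort.pileup}
        for (sid, np_), row in lookup.items():
            call = call_position(by_key[(sid, np_)], CFG)
            is_carrier_sample = row["carrier"] in row["slot"]
            assert call.reported == is_carrier_sample, (sid, np_, call.status)


class TestDetectionFloor:
    def test_floor_at_2000_reads(self):
        c = make_counts(T_fwd=1000, T_rev=1000)
        fl = detection_floor(c, CFG)
        assert fl.floor == pytest.approx(0.02)
        assert fl.adequate_for_reporting

    def test_boundary_1999(self):
        c = make_counts(T_fwd=1000, T_rev=999)
        assert not detection_floor(c, CFG).adequate_for_reporting

    def test_analytical_threshold_binds_at_high_coverage(self):
        c = make_counts(T_fwd=2000, T_rev=2000)
        assert detection_floor(c, CFG).floor == pytest.approx(0.01)

    def test_zero_coverage_floor_infinite(self):
        fl = detection_floor(make_counts(), CFG)
        assert math.isinf(fl.floor) and not fl.adequate_for_reporting
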