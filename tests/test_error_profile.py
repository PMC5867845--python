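"""Assumed substitution-error profiling and coverage assessment."""
import numpy as np
import pytest

from mthet import (
    AlleleCounts,
    FilterConfig,
    MtReference,
    SimConfig,
    coverage_assessment,
    error_rates,
    hotspots,
    simulate_cohort,
)


def counts(sample, np_, **kw):
    fwd = {b: 0 for b in "ACGT"}
    rev = {b: 0 for b in "ACGT"}
    for key, n in kw.items():
        base, d = key[0], key[2:]
        (fwd if d == "fwd" else rev)[base] = n
    return AlleleCounts(sample, np_, fwd, rev)


class TestErrorRates:
    def test_clean_pileup_all_rates_zero(self):
        prof = error_rates([counts("s", 100, T_fwd=50, T_rev=50)])
        assert all(prof.rate(100, b) == 0.0 for b in "ACGT")

    def test_direct_ratio(self):
        prof = error_rates([counts("s", 100, T_fwd=500, T_rev=495, C_fwd=3, C_rev=2)])
        assert prof.rate(100, "C") == pytest.approx(0.5)
        assert prof.rate(100, "T") == 0.0  # major call, not assumed error

    def test_fifty_percent_call_included(self):
        # exactly 50% sits inside the assumed-error cut on both alleles
        prof = error_rates([counts("s", 7, T_fwd=250, T_rev=250, C_fwd=250, C_rev=250)])
        assert prof.rate(7, "C") == pytest.approx(50.0)
        assert prof.rate(7, "T") == pytest.approx(50.0)

    def test_heteroplasmy_below_50pct_inflates_rate(self):
        # a true 20% heteroplasmy contributes its full fraction (documented
        # conservatism of the estimator)
        prof = error_rates([counts("s", 9, T_fwd=4000, T_rev=4000, C_fwd=1000, C_rev=1000)])
        assert prof.rate(9, "C") == pytest.approx(20.0)

    def test_per_sample_cut_applied_before_summation(self):
        # base at 60% in one sample (not error) and 10% in another (error):
        # only the second sample's calls enter the numerator
        rows = [
            counts("s1", 5, C_fwd=300, C_rev=300, T_fwd=200, T_rev=200),  # C=60%
            counts("s2", 5, C_fwd=50, C_rev=50, T_fwd=450, T_rev=450),    # C=10%
        ]
        prof = error_rates(rows)
        assert prof.rate(5, "C") == pytest.approx(100 * 100 / 2000)

    def test_zero_coverage_positions_flagged_not_poisoning(self):
        prof = error_rates([counts("s", 50, T_fwd=100, T_rev=100)])
        assert np.isnan(prof.rate(51, "A"))
        assert 51 in prof.undefined_positions()
        avg = prof.average_rates()
        assert all(v == 0.0 for v in avg.values())

    def test_average_equals_coverage_weighted_mean(self):
        rows = [
            counts("s", 1, T_fwd=500, T_rev=500, C_fwd=10, C_rev=10),
            counts("s", 2, T_fwd=2000, T_rev=2000, G_fwd=2, G_rev=2),
        ]
        prof = error_rates(rows)
        num = 20 + 0
        den = 1020 + 4004
        assert prof.average_rates()["C"] == pytest.approx(100 * num / den)

    def test_conservation_sum_of_rates_bounded(self):
        rng = np.random.default_rng(5)
        rows = []
        for np_ in range(1, 200):
            c = rng.integers(0, 500, size=8)
            rows.append(AlleleCounts("s", np_, dict(zip("ACGT", c[:4])),
                                     dict(zip("ACGT", c[4:]))))
        prof = error_rates(rows)
        avg = prof.average_rates()
        assert sum(avg.values()) <= 100.0

    def test_injected_error_recovery_synthetic_cohort(self):
        """Per-position rates recover injected error within binomial error."""
        n_samples, n_pos = 50, 1000
        positions = tuple(range(1, n_pos + 1))
        cfg = SimConfig(
            n_families=13,  # 52 samples, close to the 50-sample design
            sites_per_family=1,
            error_rate_per_base=5e-4,
            coverage_median=5000,
            coverage_sigma=0.3,
            positions=positions,
            seed=42,
        )
        sim = simulate_cohort(cfg)
        prof = error_rates(sim.allele_counts())
        # heteroplasmic sites knowingly inflate their own positions, so the
        # recovery check pools the unseeded positions: every read errs with
        # p = 5e-4, so the summed assumed-error fraction there is 0.05%
        seeded = {t["np"] for t in sim.truth} | set(cfg.excluded_positions)
        unseeded = np.array([p - 1 for p in positions if p not in seeded])
        num = prof.numerators[unseeded].sum()
        den = prof.denominators[unseeded].sum()
        assert 100 * num / den == pytest.approx(0.05, rel=0.05)
        # per-position totals scatter binomially around the injected rate
        with np.errstate(invalid="ignore"):
            per_pos = (
                100 * prof.numerators[unseeded].sum(axis=1)
                / prof.denominators[unseeded]
            )
        assert np.median(per_pos) == pytest.approx(0.05, rel=0.2)
        assert (per_pos < 0.5).mean() > 0.99
        # and the average equals the coverage-weighted mean of per-position
        # rates (conservation)
        avg = prof.average_rates()
        num_all = prof.numerators.sum()
        den_all = prof.denominators.sum()
        assert sum(avg.values()) == pytest.approx(100 * num_all / den_all)


class TestHotspots:
    def test_single_nonzero_rate_is_sole_hotspot(self, reference):
        rows = [
            counts("s", 2487, A_fwd=30, A_rev=30, C_fwd=500, C_rev=440),
            counts("s", 100, T_fwd=1000, T_rev=1000),
        ]
        prof = error_rates(rows)
        report = hotspots(prof, reference)
        a_rows = report.for_base("A")
        assert len(a_rows) == 1 and a_rows[0].np == 2487
        assert a_rows[0].adjacent_sequence == "CTT*CCCC"  # printed context
        assert "polyC" in a_rows[0].motifs

    def test_polyc_seeded_hotspots_dominate_flag_fraction(self, reference):
        # elevate error exclusively at positions flanked by C-runs
        from mthet import motif_flags

        polyc_nps = [p for p in range(1, 16570)
                     if p != 3107
                     and "polyC" in motif_flags(reference.adjacent_sequence(p))][:30]
        rows = []
        for np_ in polyc_nps:
            major = "T" if reference.base(np_) != "T" else "G"
            kw = {f"{major}_fwd": 2000, f"{major}_rev": 2000}
            err = "A" if major != "A" else "C"
            kw[f"{err}_fwd"], kw[f"{err}_rev"] = 40, 40
            rows.append(counts("s", np_, **kw))
        prof = error_rates(rows)
        report = hotspots(prof, reference)
        flagged = sum(1 for r in report.rows if "polyC" in r.motifs)
        assert flagged / len(report.rows) == pytest.approx(1.0)

    def test_rates_above_reporting_threshold_warned(self, reference, caplog):
        import logging

        rows = [counts("s", 3511, A_fwd=60, A_rev=60, C_fwd=470, C_rev=410)]
        prof = error_rates(rows)
        with caplog.at_level(logging.WARNING):
            report = hotspots(prof, reference)
        assert any(np_ == 3511 for np_, _, _ in report.above_reporting_threshold)
        assert "3511" in caplog.text

    def test_placeholder_position_excluded(self, reference):
        rows = [counts("s", 3107, A_fwd=100, A_rev=100, C_fwd=30, C_rev=30)]
        prof = error_rates(rows)
        assert prof.denominators[3106] == 0


class TestCoverageAssessment:
    def test_all_positions_at_floor(self):
        rows = [counts("s", p, T_fwd=1000, T_rev=1000) for p in range(1, 51)]
        cov = coverage_assessment(rows, FilterConfig())
        assert cov.cohort_fraction_adequate == 1.0
        assert cov.mean_coverage == 2000

    def test_half_genome_below_floor(self):
        rows = [counts("s", p, T_fwd=500, T_rev=500) for p in range(1, 51)]
        rows += [counts("s", p, T_fwd=2000, T_rev=2000) for p in range(51, 101)]
        cov = coverage_assessment(rows, FilterConfig())
        row = cov.per_sample.iloc[0]
        assert row["n_positions_below_floor"] == 50
        assert cov.cohort_fraction_adequate == pytest.approx(0.5)

    def test_lognormal_cohort_matches_direct_count(self):
        cfg = SimConfig(n_families=3, positions=tuple(range(1, 301)),
                        coverage_median=3000, coverage_sigma=0.6, seed=9)
        sim = simulate_cohort(cfg)
        rows = list(sim.allele_counts())
        cov = coverage_assessment(rows, FilterConfig())
        n_below = sum(1 for c in rows if c.total < 2000)
        assert cov.cohort_fraction_adequate == pytest.approx(1 - n_below / len(rows))
        assert cov.mean_coverage == pytest.approx(
            sum(c.total for c in rows) / len(rows)
        )
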