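import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from aneucall.cna_calls import call_arm
from aneucall.genome_model import GenomeBuild, LOCUS_1Q23_2, make_bins
from aneucall.synthetic_cohort import (
    CohortConfig,
    DEFAULT_FISH_PROBE,
    Karyotype,
    Segment,
    copies_per_bin,
    render_bin_profile,
    simulate_cohort,
    simulate_duplex_reads,
    simulate_expression,
    simulate_fish_counts,
    simulate_karyotype,
    write_cohort,
)


def pure_karyotype(build, ploidy=2):
    segs = [Segment(c.name, 1, c.length, ploidy) for c in build.chromosomes]
    return Karyotype("s", "PDAC", ploidy, segs)


class TestSimulateKaryotype:
    def test_normal_has_no_events(self, rng):
        cfg = CohortConfig(seed=0)
        for i in range(20):
            kt, events = simulate_karyotype(f"s{i}", "NORMAL", cfg, rng)
            assert events == []
            assert all(s.copies == 2 for s in kt.segments)

    def test_forced_focal_contains_anchor(self, hg19, rng):
        cfg = CohortConfig(
            seed=0,
            arm_gain_probs={"1q": {"PDAC": 1.0}},
            arm_loss_probs={},
            focal_fraction={"1q": 1.0},
            anchors={"1q": (LOCUS_1Q23_2,)},
            wgd_prob={"PDAC": 0.0},
        )
        for i in range(10):
            kt, events = simulate_karyotype(f"s{i}", "PDAC", cfg, rng, hg19)
            (ev,) = events
            assert not ev.full
            assert ev.start <= LOCUS_1Q23_2.start
            assert ev.end >= LOCUS_1Q23_2.end
            for pos in (LOCUS_1Q23_2.start, LOCUS_1Q23_2.end):
                assert kt.copies_at("1", pos) == 3

    def test_binomial_frequency_recovery(self, hg19, rng):
        p = 0.40
        cfg = CohortConfig(seed=0, arm_gain_probs={"1q": {"PDAC": p}},
                           arm_loss_probs={}, wgd_prob={"PDAC": 0.0})
        n = 2000
        hits = 0
        for i in range(n):
            _, events = simulate_karyotype(f"s{i}", "PDAC", cfg, rng, hg19)
            hits += any(e.arm == "1q" and e.direction == "GAIN" for e in events)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se

    def test_unknown_grade(self, rng):
        with pytest.raises(KeyError):
            simulate_karyotype("s", "BOGUS", CohortConfig(seed=0), rng)

    def test_segments_tile_chromosomes(self, hg19, rng):
        cfg = CohortConfig(seed=0)
        kt, _ = simulate_karyotype("s", "PDAC", cfg, rng, hg19)
        by_chrom = {}
        for seg in kt.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom in hg19.chromosomes:
            segs = sorted(by_chrom[chrom.name], key=lambda s: s.start)
            assert segs[0].start == 1
            assert segs[-1].end == chrom.length
            for a, b in zip(segs, segs[1:]):
                assert b.start == a.end + 1


class TestRenderBinProfile:
    def test_diploid_all_neutral(self, hg19, hg19_bins, rng):
        kt = pure_karyotype(hg19, 2)
        lr, calls = render_bin_profile(kt, hg19_bins, 1.0, 0.0, rng)
        assert np.all(calls == "N")
        assert np.allclose(lr, 0.0)

    def test_wgd_blindness_under_median_normalization(self, hg19, hg19_bins,
                                                      rng):
        kt = pure_karyotype(hg19, 4)
        _, calls = render_bin_profile(kt, hg19_bins, 1.0, 0.0, rng,
                                      normalization="median")
        assert np.all(calls == "N")

    def test_single_arm_gain_closed_form(self, hg19, hg19_bins, rng):
        # chr1 q arm at 3 copies: gained bins' centered log-ratio = log2(1.5)
        cen = hg19.chromosome("1").centromere
        segs = []
        for c in hg19.chromosomes:
            if c.name == "1":
                segs.append(Segment("1", 1, cen, 2))
                segs.append(Segment("1", cen + 1, c.length, 3))
            else:
                segs.append(Segment(c.name, 1, c.length, 2))
        kt = Karyotype("s", "PDAC", 2, segs)
        lr, calls = render_bin_profile(kt, hg19_bins, 1.0, 0.0, rng)
        # copies are looked up at bin midpoints, including the centromere bin
        gained = np.array([b.chrom == "1" and b.midpoint > cen
                           for b in hg19_bins])
        assert np.all(calls[gained] == "G")
        assert np.all(calls[~gained] == "N")
        assert np.allclose(lr[gained], math.log2(1.5))

    def test_purity_attenuation_still_called(self, hg19, hg19_bins, rng):
        cen = hg19.chromosome("1").centromere
        segs = [Segment(c.name, 1, c.length, 2) for c in hg19.chromosomes
                if c.name != "1"]
        segs += [Segment("1", 1, cen, 2),
                 Segment("1", cen + 1, hg19.chromosome("1").length, 3)]
        kt = Karyotype("s", "PDAC", 2, segs)
        _, calls = render_bin_profile(kt, hg19_bins, 0.6, 0.0, rng)
        gained = np.array([b.chrom == "1" and b.start > cen for b in hg19_bins])
        assert np.all(calls[gained] == "G")

    def test_purity_range(self, hg19, hg19_bins, rng):
        with pytest.raises(ValueError):
            render_bin_profile(pure_karyotype(hg19), hg19_bins, 0.0, 0.0, rng)

    def test_empty_karyotype(self, hg19_bins, rng):
        with pytest.raises(ValueError):
            render_bin_profile(Karyotype("s", "PDAC", 2, []), hg19_bins,
                               1.0, 0.0, rng)


class TestSimulateFish:
    def test_diploid_perfect_detection(self, hg19, rng):
        counts = simulate_fish_counts(pure_karyotype(hg19), DEFAULT_FISH_PROBE,
                                      50, 1.0, rng)
        assert np.all(counts == 2)

    def test_counts_cannot_exceed_true_copies(self, hg19, rng):
        counts = simulate_fish_counts(pure_karyotype(hg19), DEFAULT_FISH_PROBE,
                                      900, 0.9, rng)
        assert np.mean(counts >= 3) == 0.0

    def test_tetraploid_mean_oracle(self, hg19, rng):
        counts = simulate_fish_counts(pure_karyotype(hg19, 4),
                                      DEFAULT_FISH_PROBE, 10_000, 0.9, rng)
        # mean of Binomial(4, 0.9) = 3.6, sd = sqrt(4*0.9*0.1)
        se = math.sqrt(4 * 0.9 * 0.1 / 10_000)
        assert abs(counts.mean() - 3.6) <= 3 * se

    def test_uncovered_locus(self, rng):
        kt = Karyotype("s", "PDAC", 2, [Segment("2", 1, 1000, 2)])
        with pytest.raises(KeyError):
            simulate_fish_counts(kt, DEFAULT_FISH_PROBE, 10, 1.0, rng)

    def test_p_detect_range(self, hg19, rng):
        with pytest.raises(ValueError):
            simulate_fish_counts(pure_karyotype(hg19), DEFAULT_FISH_PROBE,
                                 10, 0.0, rng)


class TestSimulateExpression:
    def test_zero_effect_is_null(self, rng):
        from aneucall.focal_mapping import dosage_expression_association

        cn = pd.DataFrame(rng.integers(2, 5, size=(100, 50)).astype(float),
                          index=[f"g{i}" for i in range(100)],
                          columns=[f"s{i}" for i in range(50)])
        expr, _ = simulate_expression(cn, 0.0, 1.0, rng,
                                      responsive={g: True for g in cn.index})
        out = dosage_expression_association(cn, expr, alpha=1e-5)
        assert out["significant"].sum() == 0

    def test_single_sample_flagged(self, rng):
        cn = pd.DataFrame([[2.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            simulate_expression(cn, 1.0, 0.1, rng)

    def test_truth_recorded(self, rng):
        cn = pd.DataFrame(rng.integers(2, 5, size=(10, 20)).astype(float),
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(20)])
        _, responsive = simulate_expression(cn, 2.0, 0.1, rng)
        assert set(responsive) == set(cn.index)


class TestSimulateDuplexReads:
    @pytest.fixture
    def amplicon(self, rng):
        from aneucall.duplex_caller import make_synthetic_amplicons

        return make_synthetic_amplicons(rng, genes=["KRAS"])[0]

    def test_uids_distinct_and_14nt(self, amplicon, rng):
        reads, truth = simulate_duplex_reads(amplicon, 30, 3, [], 0.0, rng)
        assert len(set(truth["uids"])) == 30
        assert all(len(u) == 14 for u in truth["uids"])
        assert len(reads) == 30 * 2 * 3

    def test_variant_carrier_count_exact(self, amplicon, rng):
        pos = amplicon.start + 60
        alt = "A" if amplicon.ref_seq[60] != "A" else "C"
        _, truth = simulate_duplex_reads(amplicon, 20, 2, [(pos, alt, 0.25)],
                                         0.0, rng)
        assert len(truth["carriers"]) == 5

    def test_variant_outside_amplicon(self, amplicon, rng):
        with pytest.raises(ValueError):
            simulate_duplex_reads(amplicon, 5, 2,
                                  [(amplicon.end + 10, "A", 0.5)], 0.0, rng)

    def test_error_rate_bounds(self, amplicon, rng):
        with pytest.raises(ValueError):
            simulate_duplex_reads(amplicon, 5, 2, [], 0.1, rng)

    def test_geometric_family_sizes(self, amplicon, rng):
        reads, _ = simulate_duplex_reads(amplicon, 50, 4, [], 0.0, rng,
                                         family_size_dist="geometric")
        # every family has at least one read per strand
        assert len(reads) >= 50 * 2


class TestSimulateCohort:
    def test_empty_cohort_schema_valid(self, tmp_path):
        cfg = CohortConfig(seed=1, n_per_grade={})
        data = simulate_cohort(cfg)
        assert data.matrix.calls.shape[1] == 0
        assert list(data.meta.columns) == ["sample_id", "patient_id", "grade",
                                           "preservation"]
        paths = write_cohort(data, tmp_path / "empty")
        assert (tmp_path / "empty" / "bin_calls.tsv").exists()

    def test_determinism_byte_identical(self, tmp_path):
        cfg = dict(seed=11, n_per_grade={"PDAC": 6, "HG_PANIN": 4})
        d1 = simulate_cohort(CohortConfig(**cfg))
        d2 = simulate_cohort(CohortConfig(**cfg))
        p1 = write_cohort(d1, tmp_path / "a")
        p2 = write_cohort(d2, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_grade_frequency_recovery(self, demo_cohort, demo_arm_calls):
        cfg = demo_cohort.config
        for grade, n in cfg.n_per_grade.items():
            p = cfg.arm_gain_probs["1q"].get(grade, 0.0)
            if n < 30:
                continue
            truth_hits = sum(
                any(e["arm"] == "1q" and e["direction"] == "GAIN"
                    for e in demo_cohort.truth[s]["arm_events"])
                for s in demo_cohort.meta.loc[
                    demo_cohort.meta.grade == grade, "sample_id"]
            )
            se = math.sqrt(p * (1 - p) / n) if 0 < p < 1 else 0
            assert abs(truth_hits / n - p) <= 3 * se + 1e-9, grade

    def test_reads_emitted_and_callable(self, tmp_path):
        from aneucall.duplex_caller import call_sample, lesion_mutation_table

        cfg = CohortConfig(seed=4, n_per_grade={"HG_PANIN": 6},
                           simulate_reads=True, reads_error=0.0)
        data = simulate_cohort(cfg)
        assert set(data.reads) == set(data.matrix.samples)
        paths = write_cohort(data, tmp_path / "c")
        assert (tmp_path / "c" / "amplicons.tsv").exists()
        assert (tmp_path / "c" / "reads").is_dir()
        # duplex caller recovers the planted per-gene mutation truth
        for sid in data.matrix.samples:
            calls, _ = call_sample([(r.r1, r.r2) for r in data.reads[sid]],
                                   data.amplicons, data.cosmic)
            got = {c.gene for c in calls if c.passed}
            want = {g for g, m in data.truth[sid]["mutations"].items() if m}
            assert got == want, sid

    def test_caller_recovers_truth_on_cohort(self, demo_cohort, demo_arm_calls):
        """Arm caller output matches simulated truth for every sample."""
        table = demo_arm_calls
        for s in demo_cohort.matrix.samples:
            true_gain = any(e["arm"] == "1q" and e["direction"] == "GAIN"
                            for e in demo_cohort.truth[s]["arm_events"])
            row = table[(table.sample_id == s) & (table.arm == "1q")].iloc[0]
            assert bool(row["has_gain"]) == true_gain, s


class TestWgdMechanism:
    def test_wgs_blind_fish_sees(self, hg19, hg19_bins, rng):
        """Pure WGD: all-N bin calls, but FISH modal count 4."""
        kt = pure_karyotype(hg19, 4)
        _, calls = render_bin_profile(kt, hg19_bins, 1.0, 0.0, rng)
        assert np.all(calls == "N")
        counts = simulate_fish_counts(kt, DEFAULT_FISH_PROBE, 200, 1.0, rng)
        assert np.all(counts == 4)

    def test_discordance_classified(self, hg19, hg19_bins, rng):
        from aneucall.fish_scoring import (
            FishSample, classify_positive, summarize, wgs_fish_concordance,
        )

        kt = pure_karyotype(hg19, 4)
        _, calls = render_bin_profile(kt, hg19_bins, 0.8, 0.0, rng)
        res = call_arm(calls[[b.chrom == "1" and
                              b.start > hg19.chromosome("1").centromere
                              for b in hg19_bins]])
        counts = simulate_fish_counts(kt, DEFAULT_FISH_PROBE, 100, 0.95, rng)
        summ = summarize(FishSample("s", "1q25", "neoplastic", counts.tolist()))
        positive = classify_positive(summ, "ge3_at_20pct")
        assert positive
        assert wgs_fish_concordance(res["state"], positive,
                                    tumor_fraction=0.8) == \
            "discordant_relative_cn"
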