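import math

import numpy as np
import pysam
import pytest

from dibench.index import annotate_runs
from dibench.reads import (
    arrival_dispersion,
    arrival_dispersion_from_counts,
    coverage_vs_gc,
    hp_quality_by_length,
    profile_reads,
    quality_calibration,
    read_starts_per_bin,
    substitution_spectrum,
)
from dibench.sim import GenomeSpec, ReadSpec, simulate_diploid_genome, simulate_reads


def _write_sam(path, ref_seqs, records):
    """records: (qname, ref, pos, cigar, seq, quals or None, flag)."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in ref_seqs.items()],
    }
    names = list(ref_seqs)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for qname, ref, pos, cigar, seq, quals, flag in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = qname
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = names.index(ref)
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = 60
            if quals is not None:
                a.query_qualities = pysam.qualitystring_to_array("".join(chr(q + 33) for q in quals))
            fh.write(a)


@pytest.fixture()
def mini_bench():
    from dibench.index import DiploidBenchmark

    rng = np.random.default_rng(42)
    s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    s2 = s1  # identical homologs keep the mini tests simple
    return DiploidBenchmark({"m_hap1": s1}, {"m_hap2": s2}, {"m_hap1": "m_hap2"})


class TestProfile:
    def test_perfect_read(self, mini_bench, tmp_path):
        s = mini_bench.seq("m_hap1")[100:1100]
        _write_sam(tmp_path / "a.sam", mini_bench.hap1_seqs | mini_bench.hap2_seqs,
                   [("r1", "m_hap1", 100, "1000=", s, [30] * 1000, 0)])
        p = profile_reads(tmp_path / "a.sam", mini_bench)
        assert p.aligned_bp == 1000 and p.n_mismatches == 0
        assert p.ins_events == p.del_events == 0
        assert p.clipped_bp == 0 and p.total_read_bp == 1000

    def test_cigar_semantics(self, mini_bench, tmp_path):
        ref = mini_bench.seq("m_hap1")
        # 500M 2I 498M with 3 mismatches
        seq = list(ref[0:500] + "GG" + ref[500:998])
        for i in (10, 20, 30):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        seq = "".join(seq)
        _write_sam(tmp_path / "b.sam", mini_bench.hap1_seqs | mini_bench.hap2_seqs,
                   [("r1", "m_hap1", 0, "500M2I498M", seq, [30] * 1000, 0)])
        with pytest.raises(ValueError, match="MD"):
            profile_reads(tmp_path / "b.sam", mini_bench)
        # with =/X ops instead
        cig = []
        last = 0
        for i in (10, 20, 30):
            cig.append(f"{i - last}=1X")
            last = i + 1
        cig = "".join(cig) + f"{500 - last}=2I498="
        _write_sam(tmp_path / "c.sam", mini_bench.hap1_seqs | mini_bench.hap2_seqs,
                   [("r1", "m_hap1", 0, cig, seq, [30] * 1000, 0)])
        p = profile_reads(tmp_path / "c.sam", mini_bench)
        assert p.ins_events == 1 and p.ins_bp == 2
        assert p.n_mismatches == 3

    def test_md_tag_route(self, mini_bench, tmp_path):
        ref = mini_bench.seq("m_hap1")
        seq = list(ref[:100])
        seq[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[50]]
        seq = "".join(seq)
        sam = tmp_path / "d.sam"
        _write_sam(sam, mini_bench.hap1_seqs | mini_bench.hap2_seqs,
                   [("r1", "m_hap1", 0, "100M", seq, [30] * 100, 0)])
        # add MD via pysam calmd-equivalent: write the tag manually
        lines = sam.read_text().splitlines()
        lines[-1] += f"\tMD:Z:50{ref[50]}49"
        sam.write_text("\n".join(lines) + "\n")
        p = profile_reads(sam, mini_bench)
        assert p.n_mismatches == 1

    def test_clipping_and_conservation(self, mini_bench, tmp_path):
        ref = mini_bench.seq("m_hap1")
        seq = "ACGTACGTAC" + ref[200:700] + "GGGGG"
        _write_sam(tmp_path / "e.sam", mini_bench.hap1_seqs | mini_bench.hap2_seqs,
                   [("r1", "m_hap1", 200, "10S500=5S", seq, [20] * len(seq), 0)])
        p = profile_reads(tmp_path / "e.sam", mini_bench)
        assert p.clipped_bp == 15 and p.aligned_bp == 500
        assert p.aligned_bp + p.clipped_bp + p.unaligned_bp == p.total_read_bp

    def test_secondary_and_supplementary_skipped(self, mini_bench, tmp_path):
        ref = mini_bench.seq("m_hap1")
        recs = [
            ("r1", "m_hap1", 0, "100=", ref[:100], [30] * 100, 0),
            ("r1", "m_hap1", 500, "100=", ref[500:600], [30] * 100, 256),
            ("r1", "m_hap1", 800, "100=", ref[800:900], [30] * 100, 2048),
        ]
        _write_sam(tmp_path / "f.sam", mini_bench.hap1_seqs | mini_bench.hap2_seqs, recs)
        p = profile_reads(tmp_path / "f.sam", mini_bench)
        assert p.n_primary == 1 and p.aligned_bp == 100
        assert p.n_secondary == 1 and p.n_supplementary == 1

    def test_het_mask(self, tmp_path):
        from dibench.index import DiploidBenchmark, build_het_catalog
        from dibench.alignio import AlignmentSegment

        rng = np.random.default_rng(7)
        s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
        s2 = s1[:400] + ("G" if s1[400] != "G" else "A") + s1[401:]
        bench = DiploidBenchmark({"h_hap1": s1}, {"h_hap2": s2}, {"h_hap1": "h_hap2"})
        hets = build_het_catalog(
            bench,
            [AlignmentSegment("h_hap1", 0, 1000, 1000, "+", "h_hap2", 0, 1000, [(1000, "M")])],
        )
        # a hap2-derived read mapped onto hap1: mismatch only at the het site
        read = s2[300:600]
        cig = "100=1X199="
        _write_sam(tmp_path / "g.sam", {"h_hap1": s1, "h_hap2": s2},
                   [("r1", "h_hap1", 300, cig, read, [30] * 300, 0)])
        on = profile_reads(tmp_path / "g.sam", bench, het_mask=True, hets=hets)
        off = profile_reads(tmp_path / "g.sam", bench, het_mask=False)
        assert on.n_mismatches == 0 and off.n_mismatches == 1


class TestSpectrum:
    def test_only_transitions(self):
        from dibench.reads import ReadProfile

        p = ReadProfile()
        p.aligned_bp = 10**6
        p.sub_counts[0, 2] = 10  # A>G
        s = substitution_spectrum(p)
        assert s["tv_per_mb"] == 0 and s["ti_per_mb"] == 10

    def test_equal_cells_ratio_half(self):
        from dibench.reads import ReadProfile

        p = ReadProfile()
        p.aligned_bp = 10**6
        for i in range(4):
            for j in range(4):
                if i != j:
                    p.sub_counts[i, j] = 7
        s = substitution_spectrum(p)
        assert s["ti_tv_ratio"] == pytest.approx(0.5)

    def test_simulated_rates_within_3_sigma(self, tmp_path):
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=300_000, seed=31))
        spec = ReadSpec(read_len=5000, depth=8, sub_rate=1e-3, ins_rate=5e-4, del_rate=5e-4, seed=32)
        stats = simulate_reads(g, spec, tmp_path / "r.sam")
        p = profile_reads(tmp_path / "r.sam", g.bench, het_mask=False)
        for rate, got in ((spec.sub_rate, p.n_mismatches), (spec.ins_rate, p.ins_events), (spec.del_rate, p.del_events)):
            mean = rate * p.aligned_bp
            sigma = math.sqrt(mean * (1 - rate))
            assert abs(got - mean) < 3 * sigma + 3

    def test_strand_symmetric_complement_pairs(self, tmp_path):
        # substitutions drawn uniformly: complementary cells agree within 3 sigma
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=300_000, seed=33))
        spec = ReadSpec(read_len=5000, depth=10, sub_rate=2e-3, seed=34)
        simulate_reads(g, spec, tmp_path / "s.sam")
        p = profile_reads(tmp_path / "s.sam", g.bench, het_mask=False)
        idx = {b: i for i, b in enumerate("ACGT")}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for a in "ACGT":
            for b in "ACGT":
                if a == b:
                    continue
                x = p.sub_counts[idx[a], idx[b]]
                y = p.sub_counts[idx[comp[a]], idx[comp[b]]]
                assert abs(x - y) < 3 * math.sqrt(x + y + 1) + 3


class TestHpQuality:
    def _bench_with_run(self, run_len=12):
        from dibench.index import DiploidBenchmark

        rng = np.random.default_rng(3)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=199))
        flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=199))
        # C/G sentinels stop the A-run from extending into the flanks
        seq = flank + "C" + "A" * run_len + "G" + flank2
        return DiploidBenchmark({"p_hap1": seq}, {"p_hap2": seq}, {"p_hap1": "p_hap2"}), 200, run_len

    def test_deletion_in_run_incorrect(self, tmp_path):
        bench, start, rl = self._bench_with_run()
        seq = bench.seq("p_hap1")
        runs = annotate_runs({n: bench.seq(n) for n in bench.names()})
        read = seq[: start + 5] + seq[start + 6 :]  # 1bp deletion inside the run
        cig = f"{start + 5}=1D{len(seq) - start - 6}="
        _write_sam(tmp_path / "h.sam", {n: bench.seq(n) for n in bench.names()},
                   [("r1", "p_hap1", 0, cig, read, [30] * len(read), 0)])
        p = profile_reads(tmp_path / "h.sam", bench, runs=runs, min_run_len=8)
        table = hp_quality_by_length(p)
        assert table[rl]["spanned"] == 1 and table[rl]["incorrect"] == 1

    def test_flank_substitution_incorrect(self, tmp_path):
        bench, start, rl = self._bench_with_run()
        seq = bench.seq("p_hap1")
        runs = annotate_runs({n: bench.seq(n) for n in bench.names()})
        p3 = start - 3  # 3 bp before the run: inside the 5bp flank
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p3]]
        read = seq[:p3] + alt + seq[p3 + 1 :]
        cig = f"{p3}=1X{len(seq) - p3 - 1}="
        _write_sam(tmp_path / "i.sam", {n: bench.seq(n) for n in bench.names()},
                   [("r1", "p_hap1", 0, cig, read, [30] * len(read), 0)])
        p = profile_reads(tmp_path / "i.sam", bench, runs=runs, min_run_len=8)
        assert hp_quality_by_length(p)[rl]["incorrect"] == 1

    def test_substitution_outside_flank_correct(self, tmp_path):
        bench, start, rl = self._bench_with_run()
        seq = bench.seq("p_hap1")
        runs = annotate_runs({n: bench.seq(n) for n in bench.names()})
        p8 = start - 8  # beyond the 5bp flank
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p8]]
        read = seq[:p8] + alt + seq[p8 + 1 :]
        cig = f"{p8}=1X{len(seq) - p8 - 1}="
        _write_sam(tmp_path / "j.sam", {n: bench.seq(n) for n in bench.names()},
                   [("r1", "p_hap1", 0, cig, read, [30] * len(read), 0)])
        p = profile_reads(tmp_path / "j.sam", bench, runs=runs, min_run_len=8)
        assert hp_quality_by_length(p)[rl]["incorrect"] == 0


class TestCalibration:
    def test_formula(self):
        from dibench.reads import ReadProfile

        p = ReadProfile()
        p.q_aligned[40] = 1_000_000
        p.q_mismatch[40] = 100
        row = next(r for r in quality_calibration(p) if r["reported_q"] == 40)
        assert row["observed_q"] == pytest.approx(40.0)

    def test_zero_error_bound(self):
        from dibench.reads import ReadProfile

        p = ReadProfile()
        p.q_aligned[30] = 10_000
        row = quality_calibration(p)[0]
        assert row["is_bound"] and row["observed_q"] == pytest.approx(40.0)

    def test_truthful_simulator_calibrated(self, tmp_path):
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=300_000, seed=41))
        spec = ReadSpec(read_len=5000, depth=12, q_mode="per_base", q_choices=(20, 25, 30), seed=42)
        simulate_reads(g, spec, tmp_path / "q.sam")
        p = profile_reads(tmp_path / "q.sam", g.bench, het_mask=False)
        for row in quality_calibration(p):
            if row["errors"] >= 10 and row["reported_q"] in (20, 25, 30):
                assert abs(row["observed_q"] - row["reported_q"]) < 1.0


class TestDispersion:
    def test_poisson_small_d(self):
        rng = np.random.default_rng(55)
        counts = rng.poisson(30, size=10_000)
        d = arrival_dispersion_from_counts(counts)
        assert d["d_below"] < 0.02 and d["d_above"] < 0.02

    def test_overdispersion_detected(self):
        rng = np.random.default_rng(56)
        counts = rng.poisson(30, size=10_000)
        base = arrival_dispersion_from_counts(counts)
        dup = counts.copy()
        dup[: len(dup) // 2] *= 2
        over = arrival_dispersion_from_counts(dup)
        assert over["d_below"] >= 2 * base["d_below"]
        assert over["d_above"] >= 2 * base["d_above"]

    def test_constant_arrivals_underdispersed(self):
        counts = np.full(1000, 30)
        d = arrival_dispersion_from_counts(counts)
        assert d["d_below"] > 0 or d["d_above"] > 0

    def test_too_few_bins_refused(self):
        with pytest.raises(ValueError, match="100 bins"):
            arrival_dispersion_from_counts(np.ones(50))

    def test_simulated_reads_poissonian(self, tmp_path):
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=400_000, seed=57))
        simulate_reads(g, ReadSpec(read_len=2000, depth=40, seed=58), tmp_path / "p.sam")
        counts = read_starts_per_bin(tmp_path / "p.sam", g.bench, bin_size=1000)
        d = arrival_dispersion_from_counts(counts)
        assert d["d_below"] < 0.05 and d["d_above"] < 0.05


class TestGc:
    def test_uniform_coverage_flat(self, tmp_path):
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=400_000, seed=61))
        simulate_reads(g, ReadSpec(read_len=2000, depth=30, seed=62), tmp_path / "u.sam")
        gc = coverage_vs_gc(tmp_path / "u.sam", g.bench, window=100)
        sel = gc["n_windows"] >= 50
        mid = gc["mean_coverage"][sel]
        assert mid.size > 3
        assert np.nanmax(mid) - np.nanmin(mid) < 0.35 * np.nanmean(mid)

    def test_n_window_excluded(self, tmp_path):
        from dibench.index import DiploidBenchmark

        s = "N" * 100 + "ACGT" * 100
        bench = DiploidBenchmark({"n_hap1": s}, {"n_hap2": s}, {"n_hap1": "n_hap2"})
        _write_sam(tmp_path / "n.sam", {"n_hap1": s, "n_hap2": s},
                   [("r1", "n_hap1", 100, "400=", s[100:500], [30] * 400, 0)])
        gc = coverage_vs_gc(tmp_path / "n.sam", bench, window=100)
        assert gc["n_windows"].sum() == 8  # the all-N window is dropped (2 haplotypes)

    def test_gc_dropout_recovered(self, tmp_path):
        g = simulate_diploid_genome(GenomeSpec(n_chroms=1, chrom_len=400_000, seed=63))
        simulate_reads(
            g, ReadSpec(read_len=1000, depth=30, gc_dropout_mid=0.45, gc_dropout_steep=30.0, seed=64),
            tmp_path / "gcd.sam",
        )
        gc = coverage_vs_gc(tmp_path / "gcd.sam", g.bench, window=200)
        ok = gc["n_windows"] >= 30
        pct = gc["pct_gc"][ok]
        cov = gc["mean_coverage"][ok]
        low = cov[pct <= 47]
        high = cov[pct >= 53]
        assert low.size and high.size
        assert low.mean() > high.mean()  # programmed decline with GC
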