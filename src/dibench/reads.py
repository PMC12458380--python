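"""Read benchmarking: error spectra, context/quality stratification, coverage dispersion.

Input is a BAM/SAM of reads aligned to the diploid benchmark (both haplotypes
present as mapping targets). Only primary alignments contribute; duplicates
and QC-fail records are skipped. CIGARs must use =/X match ops or carry MD
tags so mismatches can be located without re-alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy import stats

from dibench import sequtil
from dibench.index import DiploidBenchmark, RunCatalog, het_snv_lookup

log = logging.getLogger(__name__)

MAX_Q = 94

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class ReadProfile:
    aligned_bp: int = 0
    clipped_bp: int = 0
    unaligned_bp: int = 0
    total_read_bp: int = 0
    n_primary: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    sub_counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))
    ins_events: int = 0
    del_events: int = 0
    ins_bp: int = 0
    del_bp: int = 0
    has_quals: bool = True
    # per reported quality value: aligned bases, mismatches, ins events, del events
    q_aligned: np.ndarray = field(default_factory=lambda: np.zeros(MAX_Q, dtype=np.int64))
    q_mismatch: np.ndarray = field(default_factory=lambda: np.zeros(MAX_Q, dtype=np.int64))
    q_ins: np.ndarray = field(default_factory=lambda: np.zeros(MAX_Q, dtype=np.int64))
    q_del: np.ndarray = field(default_factory=lambda: np.zeros(MAX_Q, dtype=np.int64))
    # (unit_len, run_len) -> [spanned, correct]
    run_table: dict = field(default_factory=dict)

    @property
    def n_mismatches(self) -> int:
        return int(self.sub_counts.sum())

    def rates_per_mb(self) -> dict:
        mb = self.aligned_bp / 1e6
        return {
            "sub_per_mb": self.n_mismatches / mb,
            "ins_per_mb": self.ins_events / mb,
            "del_per_mb": self.del_events / mb,
        }


def _mismatch_positions_from_md(rec) -> list[int]:
    """Mismatched query positions from the MD tag of an M-op alignment."""
    out = []
    for qpos, _rpos, rbase in rec.get_aligned_pairs(with_seq=True, matches_only=True):
        if rbase is not None and rbase.islower():
            out.append(qpos)
    return out


def profile_reads(
    bam,
    bench: DiploidBenchmark,
    runs: RunCatalog | None = None,
    het_mask: bool = True,
    hets=None,
    flank: int = 5,
    min_run_len: int = 4,
) -> ReadProfile:
    """Aggregate error/quality/context counters over primary read alignments.

    With ``het_mask`` (default on), mismatches at het SNV positions where the
    read base equals the *other* haplotype's allele are not counted as errors:
    reads from either haplotype may legitimately map across homologs. ``hets``
    is the het-site catalog (list or lookup dict) required for masking.

    Homopolymer/STR observations: a benchmark run of length >= ``min_run_len``
    is *spanned* when the primary alignment covers it plus ``flank`` bases on
    each side, and *correct* when the read reproduces that whole window with
    no mismatch or indel.
    """
    het_lut = {}
    if het_mask and hets is not None:
        het_lut = hets if isinstance(hets, dict) else het_snv_lookup(hets)
    prof = ReadProfile()
    tbytes = {name: sequtil.seq_bytes(bench.seq(name)) for name in bench.names()}

    run_arrays = {}
    if runs is not None:
        for name in bench.names():
            starts, ends, rs = runs.arrays(name)
            keep = (ends - starts) >= min_run_len
            ulen = np.array([r.unit_len for r in rs], dtype=np.int64)
            run_arrays[name] = (starts[keep], ends[keep], ulen[keep])

    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            rl = rec.query_length or (rec.infer_read_length() or 0)
            if rec.is_unmapped:
                prof.total_read_bp += rl
                prof.unaligned_bp += rl
                continue
            if rec.is_secondary:
                prof.n_secondary += 1
                continue
            if rec.is_supplementary:
                prof.n_supplementary += 1
                continue
            if rec.is_duplicate or rec.is_qcfail:
                continue
            prof.n_primary += 1
            prof.total_read_bp += rl
            _profile_one(rec, prof, tbytes, het_lut, run_arrays, flank)
    return prof


def _profile_one(rec, prof: ReadProfile, tbytes, het_lut, run_arrays, flank: int) -> None:
    tname = rec.reference_name
    tb = tbytes[tname]
    qseq = rec.query_sequence
    qb = sequtil.seq_bytes(qseq) if qseq else None
    quals = rec.query_qualities
    qarr = np.array(quals, dtype=np.int64) if quals is not None else None
    if qarr is None:
        prof.has_quals = False

    cig = rec.cigartuples or []
    has_eqx = any(op in (7, 8) for op, _ in cig)
    md_mismatches: set[int] | None = None
    if not has_eqx and any(op == 0 for op, _ in cig):
        if not rec.has_tag("MD"):
            raise ValueError(
                f"read {rec.query_name}: CIGAR uses M without an MD tag; "
                "run 'samtools calmd' or align with --eqx"
            )
        md_mismatches = set(_mismatch_positions_from_md(rec))

    t = rec.reference_start
    q = 0
    aligned_mask = np.zeros(len(qseq) if qseq else 0, dtype=bool)
    err_tpos: list[int] = []  # doubled coords, as in assembly eval

    for op, n in cig:
        code = "MIDNSHP=X"[op]
        if code in "=MX":
            aligned_mask[q : q + n] = True
            if code == "=":
                mism = np.empty(0, dtype=np.int64)
            elif code == "X":
                mism = np.arange(n, dtype=np.int64)
            else:
                if md_mismatches is not None:
                    mism = np.array([i - q for i in range(q, q + n) if i in md_mismatches], dtype=np.int64)
                else:
                    mism = np.nonzero(tb[t : t + n] != qb[q : q + n])[0]
            for off in map(int, mism):
                rbase = chr(tb[t + off])
                abase = qseq[q + off]
                if rbase == "N" or abase not in _BASE_IDX:
                    continue
                if rbase == abase:
                    continue
                het = het_lut.get((tname, t + off))
                if het is not None and abase == het[1]:
                    continue  # other-haplotype allele, not a sequencing error
                prof.sub_counts[_BASE_IDX[rbase], _BASE_IDX[abase]] += 1
                err_tpos.append(2 * (t + off))
                if qarr is not None:
                    prof.q_mismatch[qarr[q + off]] += 1
            prof.aligned_bp += n
            t += n
            q += n
        elif code == "I":
            prof.ins_events += 1
            prof.ins_bp += n
            err_tpos.append(2 * t - 1)
            if qarr is not None and q > 0:
                prof.q_ins[qarr[q - 1]] += 1
            q += n
        elif code == "D":
            prof.del_events += 1
            prof.del_bp += n
            err_tpos.extend(2 * p for p in range(t, t + n))
            if qarr is not None and q > 0:
                prof.q_del[qarr[q - 1]] += 1
            t += n
        elif code == "N":
            t += n
        elif code == "S":
            prof.clipped_bp += n
            q += n
        elif code == "H":
            prof.clipped_bp += n
            prof.total_read_bp += n  # hard-clipped bases are not in the record

    if qarr is not None and len(aligned_mask):
        prof.q_aligned += np.bincount(qarr[aligned_mask], minlength=MAX_Q)
    prof.unaligned_bp += int(np.count_nonzero(~aligned_mask)) - sum(
        n for op, n in cig if "MIDNSHP=X"[op] == "S"
    )

    if run_arrays and rec.reference_name in run_arrays:
        starts, ends, ulen = run_arrays[tname]
        t0, t1 = rec.reference_start, rec.reference_end
        lo = np.searchsorted(starts, t0 + flank, side="left")
        hi = np.searchsorted(starts, t1, side="left")
        if lo < hi:
            idx = np.arange(lo, hi)
            idx = idx[(ends[idx] + flank) <= t1]
            if len(idx):
                edits = np.array(sorted(err_tpos), dtype=np.int64)
                n_in = np.searchsorted(edits, 2 * (ends[idx] + flank) - 1) - np.searchsorted(
                    edits, 2 * (starts[idx] - flank)
                )
                for i, bad in zip(idx, n_in > 0):
                    key = (int(ulen[i]), int(ends[i] - starts[i]))
                    cell = prof.run_table.setdefault(key, [0, 0])
                    cell[0] += 1
                    cell[1] += int(not bad)


def substitution_spectrum(profile: ReadProfile) -> dict:
    """Per-Mb rate of each of the 12 single-base errors, plus Ti/Tv totals."""
    mb = profile.aligned_bp / 1e6
    cells = {}
    ti = tv = 0
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            if i == j:
                continue
            n = int(profile.sub_counts[i, j])
            cells[f"{a}>{b}"] = {"count": n, "per_mb": n / mb if mb else float("nan")}
            if f"{a}>{b}" in ("A>G", "G>A", "C>T", "T>C"):
                ti += n
            else:
                tv += n
    return {
        "cells": cells,
        "ti_count": ti,
        "tv_count": tv,
        "ti_per_mb": ti / mb if mb else float("nan"),
        "tv_per_mb": tv / mb if mb else float("nan"),
        "ti_tv_ratio": ti / tv if tv else float("inf"),
    }


def hp_quality_by_length(profile: ReadProfile, cap: float = 60.0) -> dict[int, dict]:
    """Phred-scaled homopolymer accuracy per benchmark run length.

    Uses the (unit_len == 1) cells of the profile's run table; the spanning and
    flank rules are applied during profiling.
    """
    out: dict[int, dict] = {}
    for (ulen, rlen), (spanned, correct) in sorted(profile.run_table.items()):
        if ulen != 1:
            continue
        bad = spanned - correct
        if bad == 0:
            out[rlen] = {"spanned": spanned, "incorrect": 0, "qv": cap, "capped": True}
        else:
            out[rlen] = {
                "spanned": spanned,
                "incorrect": bad,
                "qv": -10.0 * math.log10(bad / spanned),
                "capped": False,
            }
    return out


def quality_calibration(profile: ReadProfile) -> list[dict]:
    """Observed vs reported base quality per reported-Q bin.

    Observed Q = -10*log10((mismatches + ins + del events attributed to the
    base) / aligned bases); indels attribute to the base 5' of the event.
    Zero-error bins are lower bounds.
    """
    if not profile.has_quals:
        log.warning("reads carry no base qualities; calibration table omitted")
        return []
    out = []
    for qrep in range(MAX_Q):
        aligned = int(profile.q_aligned[qrep])
        if aligned == 0:
            continue
        errors = int(profile.q_mismatch[qrep] + profile.q_ins[qrep] + profile.q_del[qrep])
        if errors == 0:
            out.append(
                {"reported_q": qrep, "aligned": aligned, "errors": 0,
                 "observed_q": -10.0 * math.log10(1.0 / aligned), "is_bound": True}
            )
        else:
            out.append(
                {"reported_q": qrep, "aligned": aligned, "errors": errors,
                 "observed_q": -10.0 * math.log10(errors / aligned), "is_bound": False}
            )
    return out


def read_starts_per_bin(bam, bench: DiploidBenchmark, bin_size: int = 1000) -> np.ndarray:
    """Primary-alignment start counts per non-overlapping genomic bin."""
    counts = []
    per_seq = {name: np.zeros(max(1, len(bench.seq(name)) // bin_size), dtype=np.int64) for name in bench.names()}
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate or rec.is_qcfail:
                continue
            arr = per_seq.get(rec.reference_name)
            if arr is None:
                continue
            b = rec.reference_start // bin_size
            if b < len(arr):
                arr[b] += 1
    for name in bench.names():
        counts.append(per_seq[name])
    return np.concatenate(counts)


def arrival_dispersion_from_counts(counts: np.ndarray) -> dict:
    """Poisson-scaled arrival CDF and below/above-median KS distances.

    Counts are shifted by their median and scaled by sqrt(mean); the empirical
    CDF is compared to the identically transformed Poisson CDF. ``d_below`` and
    ``d_above`` are sup-norm differences over support values at or below /
    at or above the median.
    """
    counts = np.asarray(counts)
    if len(counts) < 100:
        raise ValueError("fewer than 100 bins: dispersion statistics unstable")
    lam = float(counts.mean())
    if lam < 5:
        log.warning("mean arrivals per bin %.2f < 5; consider a larger bin size", lam)
    med = float(np.median(counts))
    vmax = int(counts.max())
    support = np.arange(vmax + 1)
    ecdf = np.searchsorted(np.sort(counts), support, side="right") / len(counts)
    pcdf = stats.poisson.cdf(support, lam)
    diff = np.abs(ecdf - pcdf)
    below = support <= med
    above = support >= med
    scaled_x = (support - med) / math.sqrt(lam)
    return {
        "lambda": lam,
        "median": med,
        "n_bins": int(len(counts)),
        "d_below": float(diff[below].max()) if below.any() else 0.0,
        "d_above": float(diff[above].max()) if above.any() else 0.0,
        "scaled_x": scaled_x,
        "ecdf": ecdf,
        "poisson_cdf": pcdf,
    }


def arrival_dispersion(bam, bench: DiploidBenchmark, bin_size: int = 1000) -> dict:
    return arrival_dispersion_from_counts(read_starts_per_bin(bam, bench, bin_size))


def coverage_vs_gc(bam, bench: DiploidBenchmark, window: int = 100, max_n_frac: float = 0.10) -> dict:
    """Mean primary-alignment depth per integer %GC of non-overlapping windows."""
    depth = {name: np.zeros(len(bench.seq(name)) + 1, dtype=np.int64) for name in bench.names()}
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate or rec.is_qcfail:
                continue
            d = depth.get(rec.reference_name)
            if d is None:
                continue
            d[rec.reference_start] += 1
            d[rec.reference_end] -= 1
    gc_sum = np.zeros(101, dtype=np.float64)
    gc_n = np.zeros(101, dtype=np.int64)
    for name in bench.names():
        seq = bench.seq(name)
        cov = np.cumsum(depth[name][:-1])
        b = sequtil.encode(seq)
        nwin = len(seq) // window
        if nwin == 0:
            continue
        bw = b[: nwin * window].reshape(nwin, window)
        cw = cov[: nwin * window].reshape(nwin, window).mean(axis=1)
        n_frac = (bw == sequtil.N_CODE).mean(axis=1)
        acgt = (bw != sequtil.N_CODE).sum(axis=1)
        gc = ((bw == 1) | (bw == 2)).sum(axis=1)
        ok = (n_frac <= max_n_frac) & (acgt > 0)
        pct = np.rint(100.0 * gc[ok] / acgt[ok]).astype(int)
        np.add.at(gc_sum, pct, cw[ok])
        np.add.at(gc_n, pct, 1)
    with np.errstate(invalid="ignore"):
        mean_cov = np.where(gc_n > 0, gc_sum / np.maximum(gc_n, 1), np.nan)
    return {"pct_gc": np.arange(101), "mean_coverage": mean_cov, "n_windows": gc_n, "window": window}
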