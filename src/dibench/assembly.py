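"""Assembly evaluation against the diploid benchmark.

Covers alignment-block continuity (NGAx), phase-aware discrepancy cataloging,
alignment-based QV, mononucleotide-run accuracy, uncovered-base accounting and
region stratification. All target coordinates are benchmark coordinates,
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dibench import sequtil
from dibench.alignio import AlignmentSegment
from dibench.index import DiploidBenchmark, HetSite, RunCatalog, het_snv_lookup

#: the four transition substitutions among the 12 ordered base changes
TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}
SUB_TYPES = [f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
PHASE_CONSISTENT = "phase_consistent"


@dataclass(frozen=True)
class Discrepancy:
    target_hap: str
    target_seq: str
    t_pos: int  # insertions anchor to the base left of the inserted sequence
    klass: str
    sub_type: str | None = None  # "A>G" etc., substitutions only
    ti_tv: str | None = None
    length: int = 1
    query: str | None = None
    q_pos: int = -1


@dataclass
class DiscrepancyCatalog:
    records: list[Discrepancy]
    aligned_bp: int
    covered: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def count(self, klass: str) -> int:
        return sum(1 for r in self.records if r.klass == klass)

    @property
    def n_substitutions(self) -> int:
        return self.count(SUBSTITUTION)

    @property
    def n_insertions(self) -> int:
        return self.count(INSERTION)

    @property
    def n_deletions(self) -> int:
        return self.count(DELETION)

    @property
    def n_phase_consistent(self) -> int:
        return self.count(PHASE_CONSISTENT)


@dataclass
class NgaxCurve:
    """Size-ordered aligned block lengths vs cumulative benchmark fraction."""

    lengths: np.ndarray  # descending block target-span lengths
    reference_bp: int

    def points(self) -> list[tuple[float, int]]:
        cum = np.cumsum(self.lengths) / self.reference_bp
        return [(float(c), int(l)) for c, l in zip(cum, self.lengths)]

    def nga(self, x: float = 50.0) -> int | None:
        """NGA50-style statistic: block length at cumulative x% of the benchmark."""
        target = x / 100.0
        cum = 0.0
        for l in self.lengths:
            cum += l / self.reference_bp
            if cum >= target:
                return int(l)
        return None


def split_for_ngax(segments: list[AlignmentSegment], max_indel: int = 10000) -> list[AlignmentSegment]:
    """Break alignments at every single indel of at least ``max_indel`` bp."""
    blocks: list[AlignmentSegment] = []
    for seg in segments:
        cur: list[tuple[int, str]] = []
        cur_t = seg.t_start
        cur_q = 0  # local query offset in target orientation
        t = seg.t_start
        q = 0

        def flush(t_end: int, q_end: int) -> None:
            nonlocal cur, cur_t, cur_q
            if cur and t_end > cur_t:
                if seg.strand == "-":
                    qs, qe = seg.q_end - q_end, seg.q_end - cur_q
                else:
                    qs, qe = seg.q_start + cur_q, seg.q_start + q_end
                blocks.append(
                    AlignmentSegment(
                        query=seg.query,
                        q_start=qs,
                        q_end=qe,
                        q_len=seg.q_len,
                        strand=seg.strand,
                        target_seq=seg.target_seq,
                        t_start=cur_t,
                        t_end=t_end,
                        cigar=list(cur),
                        is_primary=seg.is_primary,
                        target_hap=seg.target_hap,
                    )
                )
            cur = []

        for n, op in seg.cigar:
            if op in "ID" and n >= max_indel:
                flush(t, q)
                if op == "I":
                    q += n
                else:
                    t += n
                cur_t, cur_q = t, q
                continue
            cur.append((n, op))
            if op in "MI=X":
                q += n
            if op in "MDN=X":
                t += n
        flush(t, q)
    return blocks


def ngax(blocks: list[AlignmentSegment], bench: DiploidBenchmark, per_hap: str | None = None) -> NgaxCurve:
    """NGAx curve from split alignment blocks.

    The denominator is the total non-N benchmark length (both haplotypes), or a
    single haplotype's non-N length when ``per_hap`` is ``"hap1"``/``"hap2"``.
    """
    if per_hap is None:
        ref_bp = bench.total_diploid_bp
        use = blocks
    else:
        seqs = bench.hap1_seqs if per_hap == "hap1" else bench.hap2_seqs
        ref_bp = sum(len(s) - s.count("N") for s in seqs.values())
        use = [b for b in blocks if b.target_seq in seqs]
    lengths = np.sort(np.array([b.target_span for b in use], dtype=np.int64))[::-1]
    return NgaxCurve(lengths=lengths, reference_bp=ref_bp)


def _classify_sub(ref: str, alt: str) -> tuple[str, str]:
    st = f"{ref}>{alt}"
    return st, ("Ti" if st in TRANSITIONS else "Tv")


def catalog_discrepancies(
    segments: list[AlignmentSegment],
    bench: DiploidBenchmark,
    hets: list[HetSite] | dict,
    assembly_seqs: dict[str, str],
) -> DiscrepancyCatalog:
    """Catalog every base-level difference between assembly and benchmark.

    A substitution whose assembly allele equals the *other* haplotype's allele
    at a het SNV is classed ``phase_consistent`` (a phasing, not a base-call,
    error). Benchmark N positions never host discrepancies. Target positions
    covered by overlapping segments are counted once, longer segments first.
    """
    het_lut = hets if isinstance(hets, dict) else het_snv_lookup(hets)
    covered: dict[str, np.ndarray] = {}
    tbytes: dict[str, np.ndarray] = {}
    records: list[Discrepancy] = []

    for seg in sorted(segments, key=lambda s: -s.target_span):
        tname = seg.target_seq
        tseq = bench.seq(tname)
        hap = seg.target_hap or bench.hap_of(tname)
        if tname not in covered:
            covered[tname] = np.zeros(len(tseq), dtype=bool)
            tbytes[tname] = sequtil.seq_bytes(tseq)
        cov = covered[tname]
        tb = tbytes[tname]
        prev = cov[seg.t_start : seg.t_end].copy()
        qs = seg.oriented_query(assembly_seqs)
        qb = sequtil.seq_bytes(qs)

        def qorig(qoff: int) -> int:
            return seg.q_end - 1 - qoff if seg.strand == "-" else seg.q_start + qoff

        t = seg.t_start
        q = 0
        for n, op in seg.cigar:
            if op in "M=X":
                chunk_prev = prev[t - seg.t_start : t - seg.t_start + n]
                if op == "X":
                    mism = np.nonzero(~chunk_prev)[0]
                else:
                    mism = np.nonzero((tb[t : t + n] != qb[q : q + n]) & ~chunk_prev)[0]
                for off in map(int, mism):
                    rbase = tseq[t + off]
                    abase = qs[q + off]
                    if rbase == "N" or abase == "N" or rbase == abase:
                        continue
                    het = het_lut.get((tname, t + off))
                    if het is not None and abase == het[1]:
                        records.append(
                            Discrepancy(hap, tname, t + off, PHASE_CONSISTENT, query=seg.query, q_pos=qorig(q + off))
                        )
                    else:
                        st, titv = _classify_sub(rbase, abase)
                        records.append(
                            Discrepancy(
                                hap, tname, t + off, SUBSTITUTION, sub_type=st, ti_tv=titv,
                                query=seg.query, q_pos=qorig(q + off),
                            )
                        )
                cov[t : t + n] = True
                t += n
                q += n
            elif op == "I":
                anchor = t - 1
                already = anchor >= seg.t_start and prev[anchor - seg.t_start]
                if not already:
                    records.append(
                        Discrepancy(hap, tname, anchor, INSERTION, length=n, query=seg.query, q_pos=qorig(q))
                    )
                q += n
            elif op == "D":
                already = prev[t - seg.t_start]
                if not already and tseq[t : t + n].count("N") < n:
                    records.append(
                        Discrepancy(hap, tname, t, DELETION, length=n, query=seg.query, q_pos=qorig(q))
                    )
                t += n
            elif op == "N":
                t += n
            elif op == "S":
                q += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    aligned_bp = 0
    for name, cov in covered.items():
        aligned_bp += int(np.count_nonzero(cov & bench.non_n_mask(name)))
    records.sort(key=lambda r: (r.target_hap, r.target_seq, r.t_pos))
    return DiscrepancyCatalog(records=records, aligned_bp=aligned_bp, covered=covered)


@dataclass
class QvResult:
    qv: float
    capped: bool
    cap: float
    n_discrepancies: int
    aligned_bp: int

    def __str__(self) -> str:
        return f">=Q{self.cap:g}" if self.capped else f"Q{self.qv:.1f}"


def qv(catalog: DiscrepancyCatalog, aligned_bp: int | None = None, per_bp: bool = False, cap: float = 90.0) -> QvResult:
    """Alignment-based quality: -10*log10(#discrepancies / #aligned bases).

    Indels count one discrepancy per event by default (``per_bp`` switches to
    per-base counting); phase-consistent records are excluded. Zero
    discrepancies are reported as a lower bound at ``cap``.
    """
    if aligned_bp is None:
        aligned_bp = catalog.aligned_bp
    if aligned_bp <= 0:
        raise ValueError("aligned_bp must be positive")
    n = 0
    for r in catalog.records:
        if r.klass == SUBSTITUTION:
            n += 1
        elif r.klass in (INSERTION, DELETION):
            n += r.length if per_bp else 1
    if n == 0:
        return QvResult(qv=cap, capped=True, cap=cap, n_discrepancies=0, aligned_bp=aligned_bp)
    return QvResult(
        qv=-10.0 * math.log10(n / aligned_bp), capped=False, cap=cap, n_discrepancies=n, aligned_bp=aligned_bp
    )


def _block_edit_positions(seg: AlignmentSegment, bench: DiploidBenchmark, assembly_seqs: dict[str, str]) -> np.ndarray:
    """Sorted doubled-coordinate edit positions of a block on its target.

    Bases at t are encoded 2t (mismatch or deletion); an insertion junction
    between t-1 and t is encoded 2t-1. Lets window queries use searchsorted.
    """
    tb = sequtil.seq_bytes(bench.seq(seg.target_seq))
    qb = sequtil.seq_bytes(seg.oriented_query(assembly_seqs))
    pos: list[np.ndarray] = []
    t = seg.t_start
    q = 0
    for n, op in seg.cigar:
        if op in "M=X":
            if op == "X":
                mism = np.arange(t, t + n, dtype=np.int64)
            else:
                mism = t + np.nonzero(tb[t : t + n] != qb[q : q + n])[0]
            if len(mism):
                pos.append(2 * mism)
            t += n
            q += n
        elif op == "I":
            pos.append(np.array([2 * t - 1], dtype=np.int64))
            q += n
        elif op == "D":
            pos.append(2 * np.arange(t, t + n, dtype=np.int64))
            t += n
        elif op == "N":
            t += n
        elif op == "S":
            q += n
    if not pos:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(pos))


def mononuc_run_quality(
    blocks: list[AlignmentSegment],
    bench: DiploidBenchmark,
    runs: RunCatalog,
    assembly_seqs: dict[str, str],
    min_run_len: int = 2,
    cap: float = 60.0,
    region_mask: dict[str, np.ndarray] | None = None,
) -> dict[int, dict]:
    """Per-length accuracy of benchmark mononucleotide runs.

    A run is *aligned* when one block fully spans it plus one anchor base each
    side; *erroneous* when the block carries any edit (mismatch, insertion
    junction, deletion) within that window, i.e. the assembly does not
    reproduce the run at its exact length. Each run is judged once, by the
    longest spanning block. Returns {run_len: {aligned, erroneous, qv, capped}}.
    """
    judged: dict[str, np.ndarray] = {}
    tally: dict[int, list[int]] = {}
    for seg in sorted(blocks, key=lambda s: -s.target_span):
        starts, ends, seq_runs = runs.arrays(seg.target_seq, unit_len=1)
        if seg.target_seq not in judged:
            judged[seg.target_seq] = np.zeros(len(starts), dtype=bool)
        lo = np.searchsorted(starts, seg.t_start + 1, side="left")
        hi = np.searchsorted(starts, seg.t_end, side="left")
        if lo >= hi:
            continue
        idx = np.arange(lo, hi)
        sel = (ends[idx] + 1 <= seg.t_end) & (starts[idx] - 1 >= seg.t_start)
        sel &= (ends[idx] - starts[idx]) >= min_run_len
        sel &= ~judged[seg.target_seq][idx]
        idx = idx[sel]
        if not len(idx):
            continue
        if region_mask is not None:
            m = region_mask.get(seg.target_seq)
            if m is None:
                continue
            keep = np.array([m[starts[i] : ends[i]].all() for i in idx])
            idx = idx[keep]
            if not len(idx):
                continue
        edits = _block_edit_positions(seg, bench, assembly_seqs)
        n_in = np.searchsorted(edits, 2 * (ends[idx] + 1) - 1) - np.searchsorted(edits, 2 * (starts[idx] - 1))
        judged[seg.target_seq][idx] = True
        for i, bad in zip(idx, n_in > 0):
            length = int(ends[i] - starts[i])
            a = tally.setdefault(length, [0, 0])
            a[0] += 1
            a[1] += int(bad)
    out: dict[int, dict] = {}
    for length in sorted(tally):
        aligned, err = tally[length]
        if err == 0:
            out[length] = {"aligned": aligned, "erroneous": 0, "qv": cap, "capped": True}
        else:
            out[length] = {
                "aligned": aligned,
                "erroneous": err,
                "qv": -10.0 * math.log10(err / aligned),
                "capped": False,
            }
    return out


def uncovered_bases(catalog: DiscrepancyCatalog, bench: DiploidBenchmark) -> tuple[int, dict[str, np.ndarray]]:
    """Non-N benchmark bases not covered by the cataloged (primary) alignments."""
    total = 0
    intervals: dict[str, np.ndarray] = {}
    for name in bench.names():
        nonN = bench.non_n_mask(name)
        cov = catalog.covered.get(name)
        unc = nonN if cov is None else (~cov) & nonN
        n = int(np.count_nonzero(unc))
        total += n
        if n:
            intervals[name] = sequtil.mask_to_intervals(unc)
    return total, intervals


def region_masks(
    bench: DiploidBenchmark,
    include: list[dict[str, np.ndarray]] | None = None,
    exclude: list[dict[str, np.ndarray]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-sequence boolean masks for (union of include) minus (union of exclude)."""
    masks: dict[str, np.ndarray] = {}
    for name in bench.names():
        L = len(bench.seq(name))
        if include:
            m = np.zeros(L, dtype=bool)
            for bed in include:
                if name in bed:
                    m |= sequtil.interval_mask(L, bed[name])
        else:
            m = np.ones(L, dtype=bool)
        if exclude:
            for bed in exclude:
                if name in bed:
                    m &= ~sequtil.interval_mask(L, bed[name])
        masks[name] = m
    return masks


def stratify(
    catalog: DiscrepancyCatalog,
    bench: DiploidBenchmark,
    masks: dict[str, np.ndarray],
    per_bp: bool = False,
    cap: float = 90.0,
) -> dict | None:
    """Recompute discrepancy counts, aligned_bp and QV restricted to ``masks``.

    Returns None when the restricted region set contains no aligned bases
    (metrics undefined, not zero).
    """
    aligned_bp = 0
    for name, cov in catalog.covered.items():
        m = masks.get(name)
        if m is not None:
            aligned_bp += int(np.count_nonzero(cov & m & bench.non_n_mask(name)))
    kept = [r for r in catalog.records if masks.get(r.target_seq) is not None and masks[r.target_seq][r.t_pos]]
    if aligned_bp == 0:
        return None
    sub = DiscrepancyCatalog(records=kept, aligned_bp=aligned_bp, covered=catalog.covered)
    q = qv(sub, aligned_bp, per_bp=per_bp, cap=cap)
    mb = aligned_bp / 1e6
    return {
        "aligned_bp": aligned_bp,
        "n_substitutions": sub.n_substitutions,
        "n_insertions": sub.n_insertions,
        "n_deletions": sub.n_deletions,
        "n_phase_consistent": sub.n_phase_consistent,
        "sub_rate_per_mb": sub.n_substitutions / mb,
        "ti_rate_per_mb": sum(1 for r in kept if r.ti_tv == "Ti") / mb,
        "tv_rate_per_mb": sum(1 for r in kept if r.ti_tv == "Tv") / mb,
        "ins_rate_per_mb": sub.n_insertions / mb,
        "del_rate_per_mb": sub.n_deletions / mb,
        "qv": q.qv,
        "qv_capped": q.capped,
    }
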