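"""Diploid benchmark index: truth genome, het sites, haplotype markers and repeat runs.

Everything downstream (phase segmentation, assembly/read/variant evaluation)
consumes the catalogs built here. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from dibench import sequtil
from dibench.sequtil import interval_mask, kmer_codes, merge_intervals, read_bed, read_fasta

log = logging.getLogger(__name__)

HAP1 = "hap1"
HAP2 = "hap2"

#: default minimum number of unit copies for a run to be recorded, per unit size
DEFAULT_MIN_COPIES = {1: 2, 2: 3, 3: 3, 4: 3}

_HAP_TOKEN = re.compile(r"[._-](hap[12]|h[12]|mat(ernal)?|pat(ernal)?|[12])$", re.IGNORECASE)


@dataclass
class DiploidBenchmark:
    """The two truth haplotype sequence sets plus pairing and low-confidence regions."""

    hap1_seqs: dict[str, str]
    hap2_seqs: dict[str, str]
    pairing: dict[str, str]  # hap1 name -> homologous hap2 name
    lowconf: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = set(self.hap1_seqs) & set(self.hap2_seqs)
        if dup:
            raise ValueError(f"sequence names present in both haplotypes: {sorted(dup)}")
        for name, ivs in self.lowconf.items():
            seq = self.seq(name)
            if len(ivs) and (ivs[:, 0].min() < 0 or ivs[:, 1].max() > len(seq)):
                raise ValueError(f"low-confidence interval out of bounds on {name}")

    @property
    def total_diploid_bp(self) -> int:
        """Total non-N bases across both haplotypes."""
        return sum(len(s) - s.count("N") for s in self.hap1_seqs.values()) + sum(
            len(s) - s.count("N") for s in self.hap2_seqs.values()
        )

    def hap_of(self, name: str) -> str:
        if name in self.hap1_seqs:
            return HAP1
        if name in self.hap2_seqs:
            return HAP2
        raise KeyError(f"unknown benchmark sequence: {name}")

    def seq(self, name: str) -> str:
        if name in self.hap1_seqs:
            return self.hap1_seqs[name]
        return self.hap2_seqs[name]

    def names(self) -> list[str]:
        return list(self.hap1_seqs) + list(self.hap2_seqs)

    def non_n_mask(self, name: str) -> np.ndarray:
        return sequtil.seq_bytes(self.seq(name)) != ord("N")


@dataclass(frozen=True)
class HetSite:
    """One side of an inter-haplotype difference, in the coordinates of ``hap``.

    For SNVs ``end == pos + 1``; for insertions relative to the other haplotype
    ``end - pos`` is the inserted length (0 on the side lacking the bases).
    """

    hap: str
    seq: str
    pos: int
    end: int
    allele_self: str
    allele_other: str
    is_snv: bool
    in_lowconf: bool = False


@dataclass
class MarkerSet:
    """Canonical k-mers occurring in exactly one haplotype of the benchmark."""

    k: int
    hap1_codes: np.ndarray  # sorted uint64
    hap1_counts: np.ndarray
    hap2_codes: np.ndarray
    hap2_counts: np.ndarray

    def __post_init__(self) -> None:
        # disjointness is a structural invariant; assert on every build
        if len(np.intersect1d(self.hap1_codes, self.hap2_codes)):
            raise AssertionError("marker sets are not disjoint")

    @property
    def n_hap1(self) -> int:
        return len(self.hap1_codes)

    @property
    def n_hap2(self) -> int:
        return len(self.hap2_codes)


@dataclass(frozen=True)
class Run:
    seq: str
    start: int
    end: int
    unit: str

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def run_len_bp(self) -> int:
        return self.end - self.start


class RunCatalog:
    """Short tandem runs (unit size 1-4) indexed per sequence for interval query."""

    def __init__(self, runs: list[Run]):
        self.runs = sorted(runs, key=lambda r: (r.seq, r.start, r.unit_len))
        self._by_seq: dict[str, dict[str, np.ndarray]] = {}
        by_seq: dict[str, list[Run]] = {}
        for r in self.runs:
            by_seq.setdefault(r.seq, []).append(r)
        for name, rs in by_seq.items():
            self._by_seq[name] = {
                "start": np.array([r.start for r in rs], dtype=np.int64),
                "end": np.array([r.end for r in rs], dtype=np.int64),
                "unit_len": np.array([r.unit_len for r in rs], dtype=np.int64),
                "runs": np.array(rs, dtype=object),
            }

    def __len__(self) -> int:
        return len(self.runs)

    def of_unit_len(self, unit_len: int) -> list[Run]:
        return [r for r in self.runs if r.unit_len == unit_len]

    def arrays(self, seq: str, unit_len: int | None = None):
        """(starts, ends, runs) arrays for one sequence, optionally one unit size."""
        d = self._by_seq.get(seq)
        if d is None:
            e = np.empty(0, dtype=np.int64)
            return e, e, np.empty(0, dtype=object)
        if unit_len is None:
            return d["start"], d["end"], d["runs"]
        sel = d["unit_len"] == unit_len
        return d["start"][sel], d["end"][sel], d["runs"][sel]

    def contained_in(self, seq: str, start: int, end: int, unit_len: int | None = None) -> list[Run]:
        """Runs wholly inside [start, end) on ``seq``."""
        starts, ends, runs = self.arrays(seq, unit_len)
        lo = np.searchsorted(starts, start, side="left")
        hi = np.searchsorted(starts, end, side="left")
        return [r for r, e in zip(runs[lo:hi], ends[lo:hi]) if e <= end]


def infer_pairing(hap1_names: list[str], hap2_names: list[str]) -> dict[str, str]:
    """Pair homologs by name convention (shared stem after stripping a haplotype token)."""
    stems2 = {}
    for n in hap2_names:
        stems2.setdefault(_HAP_TOKEN.sub("", n), n)
    pairing = {}
    for n in hap1_names:
        stem = _HAP_TOKEN.sub("", n)
        if stem in stems2:
            pairing[n] = stems2[stem]
    if not pairing and len(hap1_names) == len(hap2_names):
        log.warning("no haplotype name convention detected; pairing sequences by order")
        pairing = dict(zip(hap1_names, hap2_names))
    return pairing


def load_benchmark(
    hap1_fasta,
    hap2_fasta,
    lowconf_bed=None,
    pairing: dict[str, str] | None = None,
) -> DiploidBenchmark:
    """Load the diploid truth genome from two FASTA files plus an optional BED.

    Pairing of homologous sequences is inferred from a shared name stem
    (``chr1_hap1``/``chr1_hap2`` etc.) when not supplied; hemizygous sequences
    simply stay unpaired.
    """
    hap1 = read_fasta(hap1_fasta)
    hap2 = read_fasta(hap2_fasta)
    if pairing is None:
        pairing = infer_pairing(list(hap1), list(hap2))
    else:
        for a, b in pairing.items():
            if a not in hap1 or b not in hap2:
                raise ValueError(f"pairing references unknown sequences: {a} -> {b}")
    lowconf: dict[str, np.ndarray] = {}
    if lowconf_bed is not None:
        raw = read_bed(lowconf_bed)
        known = set(hap1) | set(hap2)
        for name, ivs in raw.items():
            if name not in known:
                raise ValueError(f"low-confidence BED references unknown sequence {name!r}")
            lowconf[name] = merge_intervals(ivs)
    return DiploidBenchmark(hap1_seqs=hap1, hap2_seqs=hap2, pairing=pairing, lowconf=lowconf)


def build_het_catalog(bench: DiploidBenchmark, alignments) -> list[HetSite]:
    """Catalog inter-haplotype differences from hap1-vs-hap2 alignments.

    ``alignments`` is a path (PAF with cg tags / SAM / BAM) or a list of
    :class:`~dibench.alignio.AlignmentSegment` with query = hap1 sequence and
    target = hap2 sequence. Every difference inside the aligned blocks yields a
    mirrored pair of records, one per haplotype. Differences falling inside
    low-confidence regions are flagged, not dropped.
    """
    from dibench.alignio import AlignmentSegment, read_alignments

    if not isinstance(alignments, list):
        alignments = read_alignments(alignments)
    out: list[HetSite] = []
    for seg in alignments:
        if seg.query not in bench.hap1_seqs or seg.target_seq not in bench.hap2_seqs:
            log.warning("skipping alignment between unpaired sequences %s -> %s", seg.query, seg.target_seq)
            continue
        if bench.pairing.get(seg.query) != seg.target_seq:
            log.warning("skipping alignment not matching the pairing table: %s -> %s", seg.query, seg.target_seq)
            continue
        _collect_hets(bench, seg, out)
    out.sort(key=lambda h: (h.hap, h.seq, h.pos))
    return out


def _lowconf_flag(bench: DiploidBenchmark, name: str, pos: int) -> bool:
    ivs = bench.lowconf.get(name)
    if ivs is None or not len(ivs):
        return False
    i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
    return i >= 0 and pos < ivs[i, 1]

def _collect_hets(bench: DiploidBenchmark, seg, out: list[HetSite]) -> None:
    q = bench.hap1_seqs[seg.query]
    t = bench.hap2_seqs[seg.target_seq]
    if seg.strand != "+":
        raise ValueError("haplotype-to-haplotype truth alignments must be forward strand")
    qb = sequtil.seq_bytes(q)
    tb = sequtil.seq_bytes(t)
    qpos, tpos = seg.q_start, seg.t_start

    def add(hap, seq, pos, end, a_self, a_other, is_snv):
        out.append(
            HetSite(hap, seq, pos, end, a_self, a_other, is_snv, in_lowconf=_lowconf_flag(bench, seq, pos))
        )

    for length, op in seg.cigar:
        if op in "M=X":
            if op == "=":
                mism = np.empty(0, dtype=np.int64)
            elif op == "X":
                mism = np.arange(length, dtype=np.int64)
            else:
                mism = np.nonzero(qb[qpos : qpos + length] != tb[tpos : tpos + length])[0]
            for off in mism:
                a1, a2 = q[qpos + off], t[tpos + off]
                if a1 == "N" or a2 == "N":
                    continue
                add(HAP1, seg.query, qpos + off, qpos + off + 1, a1, a2, True)
                add(HAP2, seg.target_seq, tpos + off, tpos + off + 1, a2, a1, True)
            qpos += length
            tpos += length
        elif op == "I":  # bases present only in hap1
            ins = q[qpos : qpos + length]
            add(HAP1, seg.query, qpos, qpos + length, ins, "", False)
            add(HAP2, seg.target_seq, tpos, tpos, "", ins, False)
            qpos += length
        elif op == "D":  # bases present only in hap2
            dele = t[tpos : tpos + length]
            add(HAP1, seg.query, qpos, qpos, "", dele, False)
            add(HAP2, seg.target_seq, tpos, tpos + length, dele, "", False)
            tpos += length
        elif op in "SH":
            if op == "S":
                qpos += length
        elif op == "N":
            tpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")


def het_snv_lookup(hets: list[HetSite]) -> dict[tuple[str, int], tuple[str, str]]:
    """Fast (seq, pos) -> (allele_self, allele_other) lookup for SNV het sites."""
    return {(h.seq, h.pos): (h.allele_self, h.allele_other) for h in hets if h.is_snv}


def extract_markers(bench: DiploidBenchmark, k: int = 31) -> MarkerSet:
    """Haplotype-specific canonical k-mers: present in one haplotype, absent from the other."""
    if k % 2 == 0:
        raise ValueError("k must be odd so canonical k-mers are unambiguous")
    if k < 15:
        raise ValueError("k must be >= 15")

    def count_hap(seqs: dict[str, str]):
        chunks = [kmer_codes(s, k)[1] for s in seqs.values()]
        allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
        return np.unique(allc, return_counts=True)

    codes1, counts1 = count_hap(bench.hap1_seqs)
    codes2, counts2 = count_hap(bench.hap2_seqs)
    only1 = ~np.isin(codes1, codes2, assume_unique=True)
    only2 = ~np.isin(codes2, codes1, assume_unique=True)
    return MarkerSet(
        k=k,
        hap1_codes=codes1[only1],
        hap1_counts=counts1[only1],
        hap2_codes=codes2[only2],
        hap2_counts=counts2[only2],
    )


def _primitive(unit: str) -> bool:
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def annotate_runs(
    seqs: dict[str, str],
    unit_sizes=(1, 2, 3, 4),
    min_copies: dict[int, int] | None = None,
) -> RunCatalog:
    """Maximal perfect tandem runs of 1-4 bp units.

    A run of unit size u is kept only if its unit is primitive and the run is
    not wholly contained in a run of a smaller unit size (AAAA is a
    homopolymer, never a dinucleotide AAx2). Runs never span non-ACGT bases.
    """
    if min_copies is None:
        min_copies = DEFAULT_MIN_COPIES
    runs: list[Run] = []
    for name, seq in seqs.items():
        b = sequtil.encode(seq)
        smaller = np.empty((0, 2), dtype=np.int64)  # merged spans of smaller-unit runs
        for u in sorted(unit_sizes):
            if len(b) <= u:
                continue
            m = (b[:-u] == b[u:]) & (b[:-u] != sequtil.N_CODE) & (b[u:] != sequtil.N_CODE)
            iv = sequtil.mask_to_intervals(m)
            kept: list[tuple[int, int]] = []
            for a, bd in iv:
                end = int(bd) + u
                a = int(a)
                if (end - a) // u < min_copies.get(u, 2):
                    continue
                unit = seq[a : a + u]
                if not _primitive(unit):
                    continue
                if len(smaller):  # wholly contained in a smaller-unit run?
                    i = np.searchsorted(smaller[:, 0], a, side="right") - 1
                    if i >= 0 and end <= smaller[i, 1]:
                        continue
                runs.append(Run(name, a, end, unit))
                kept.append((a, end))
            if kept:
                smaller = merge_intervals(np.concatenate([smaller, np.array(kept, dtype=np.int64)]))
    return RunCatalog(runs)
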