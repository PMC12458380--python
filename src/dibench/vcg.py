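"""Variant constructed genomes: apply phased calls to a reference per haplotype,
mask low-confidence bases, and score the result against the diploid benchmark."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from dibench import sequtil
from dibench.sequtil import merge_intervals

log = logging.getLogger(__name__)

LOW_GQ = "low_GQ"
UNCALLED = "uncalled"
FILTERED = "filtered"


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int  # 0-based (converted from VCF's 1-based at parse time)
    ref: str
    alts: tuple[str, ...]
    gt: tuple[int | None, int | None]
    phased: bool
    gq: int | None
    is_ref_block: bool = False
    end: int | None = None  # gVCF block end (0-based half-open)

    @property
    def is_het(self) -> bool:
        return self.gt[0] != self.gt[1]


def read_vcf(path) -> list[VcfRecord]:
    """Parse a (g)VCF text file into records; gVCF reference blocks are kept."""
    recs: list[VcfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: VCF record lacks a sample column")
            chrom, pos, _id, ref, alt = f[0], int(f[1]) - 1, f[2], f[3], f[4]
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            fmt = f[8].split(":")
            sample = dict(zip(fmt, f[9].split(":")))
            gt_raw = sample.get("GT", "./.")
            phased = "|" in gt_raw
            alleles = gt_raw.replace("|", "/").split("/")
            gt = tuple(None if a in (".", "") else int(a) for a in alleles[:2])
            if len(gt) == 1:
                gt = (gt[0], gt[0])
            gq = int(float(sample["GQ"])) if sample.get("GQ", ".") not in (".", "") else None
            is_block = alt in (".", "<NON_REF>", "<*>")
            end = int(info["END"]) if "END" in info else None
            alts = () if is_block else tuple(alt.split(","))
            recs.append(
                VcfRecord(chrom, pos, ref, alts, gt, phased, gq, is_ref_block=is_block, end=end)
            )
    recs.sort(key=lambda r: (r.chrom, r.pos))
    return recs


@dataclass(frozen=True)
class Edit:
    """One applied replacement on the reference: ref[pos:pos+len(ref_allele)] -> alt."""

    pos: int
    ref_allele: str
    alt_allele: str


class CoordMap:
    """Piecewise-linear reference -> constructed coordinate map."""

    def __init__(self, anchors_ref: np.ndarray, anchors_cons: np.ndarray):
        self.anchors_ref = anchors_ref
        self.anchors_cons = anchors_cons

    def to_constructed(self, ref_pos: int) -> int:
        i = int(np.searchsorted(self.anchors_ref, ref_pos, side="right") - 1)
        return int(self.anchors_cons[i] + (ref_pos - self.anchors_ref[i]))


def apply_edits(ref: str, edits: list[Edit]) -> tuple[str, CoordMap, list[tuple[int, str]]]:
    """Apply sorted, non-overlapping edits to one sequence.

    Returns the constructed sequence, the reference->constructed coordinate
    map, and a reference-to-constructed CIGAR (query = constructed) with =/X
    ops for substitutions, I for constructed-only bases and D for
    reference-only bases.
    """
    parts: list[str] = []
    cigar: list[tuple[int, str]] = []
    a_ref = [0]
    a_cons = [0]
    rpos = 0
    cpos = 0

    def emit(n: int, op: str) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + n, op)
        else:
            cigar.append((n, op))

    for e in edits:
        if e.pos < rpos:
            raise ValueError(f"overlapping or unsorted edits at reference position {e.pos}")
        if ref[e.pos : e.pos + len(e.ref_allele)] != e.ref_allele:
            raise ValueError(
                f"reference mismatch at {e.pos}: expected {e.ref_allele!r}, "
                f"found {ref[e.pos : e.pos + len(e.ref_allele)]!r} (wrong reference build?)"
            )
        gap = e.pos - rpos
        parts.append(ref[rpos : e.pos])
        emit(gap, "=")
        cpos += gap
        rpos = e.pos

        r, a = e.ref_allele, e.alt_allele
        # common left anchor base (normalized indels) stays a match
        common = 0
        while common < min(len(r), len(a)) and r[common] == a[common]:
            common += 1
        parts.append(a)
        emit(common, "=")
        rmid, amid = r[common:], a[common:]
        if len(rmid) == len(amid):
            emit(len(amid), "X")
        elif not rmid:
            emit(len(amid), "I")
        elif not amid:
            emit(len(rmid), "D")
        else:
            emit(min(len(rmid), len(amid)), "X")
            if len(amid) > len(rmid):
                emit(len(amid) - len(rmid), "I")
            else:
                emit(len(rmid) - len(amid), "D")
        rpos += len(r)
        cpos += len(a)
        a_ref.append(rpos)
        a_cons.append(cpos)
    parts.append(ref[rpos:])
    emit(len(ref) - rpos, "=")
    cons = "".join(parts)
    return cons, CoordMap(np.array(a_ref, dtype=np.int64), np.array(a_cons, dtype=np.int64)), cigar


def select_edits(records: list[VcfRecord], chrom: str, hap_index: int) -> tuple[list[Edit], list[tuple[int, int, str]]]:
    """Pick the allele of ``hap_index`` from each phased genotype on one chromosome.

    Returns the edits to apply plus (start, end, reason) reference intervals
    that cannot be applied: unphased het genotypes and half-calls are masked as
    ``filtered`` rather than guessed. Homozygous records apply regardless of
    the phase separator.
    """
    edits: list[Edit] = []
    unusable: list[tuple[int, int, str]] = []
    for r in records:
        if r.chrom != chrom or r.is_ref_block:
            continue
        a = r.gt[hap_index] if len(r.gt) > 1 else r.gt[0]
        if a is None or (r.is_het and not r.phased):
            unusable.append((r.pos, r.pos + len(r.ref), FILTERED))
            continue
        if a == 0:
            continue
        if a > len(r.alts):
            raise ValueError(f"{r.chrom}:{r.pos + 1}: genotype allele {a} out of range")
        edits.append(Edit(r.pos, r.ref, r.alts[a - 1]))
    edits.sort(key=lambda e: e.pos)
    return edits, unusable


def apply_phased_variants(ref_seqs: dict[str, str], records: list[VcfRecord], hap_index: int):
    """Apply one haplotype of a phased callset to every reference sequence.

    Returns (constructed seqs, coord maps, applied edits, unusable intervals).
    """
    if hap_index not in (0, 1):
        raise ValueError("hap_index must be 0 or 1")
    cons: dict[str, str] = {}
    maps: dict[str, CoordMap] = {}
    applied: dict[str, list[Edit]] = {}
    unusable: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, ref in ref_seqs.items():
        edits, bad = select_edits(records, chrom, hap_index)
        seq, cmap, _ = apply_edits(ref, edits)
        cons[chrom] = seq
        maps[chrom] = cmap
        applied[chrom] = edits
        unusable[chrom] = bad
    return cons, maps, applied, unusable


@dataclass
class VCGResult:
    hap_index: int
    gq_min: int
    constructed: dict[str, str]  # masked bases already replaced by N
    coord_maps: dict[str, CoordMap]
    applied: dict[str, list[Edit]]
    masked: dict[str, list[tuple[int, int, str]]]  # reference coords, with reason

    def masked_bp(self) -> int:
        merged = 0
        for chrom, ivs in self.masked.items():
            if ivs:
                arr = merge_intervals(np.array([(s, e) for s, e, _ in ivs], dtype=np.int64))
                merged += int((arr[:, 1] - arr[:, 0]).sum())
        return merged


def mask_regions(
    ref_seqs: dict[str, str],
    records: list[VcfRecord],
    hap_index: int,
    gq_min: int,
    gvcf: list[VcfRecord] | None = None,
    pad: int = 0,
) -> VCGResult:
    """Build one constructed haplotype with sub-threshold bases masked to N.

    Masked (reference-coordinate) intervals, merged per reason:
      * variant loci with GQ < gq_min  -> ``low_GQ``
      * unphased het / half-called loci -> ``filtered``
      * gVCF reference blocks with GQ < gq_min, and positions in no block at
        all (when a gVCF is given)     -> ``uncalled``
    """
    cons, maps, applied, unusable = apply_phased_variants(ref_seqs, records, hap_index)
    masked: dict[str, list[tuple[int, int, str]]] = {c: list(unusable[c]) for c in ref_seqs}
    for r in records:
        if r.is_ref_block or r.chrom not in ref_seqs:
            continue
        if r.gq is not None and r.gq < gq_min:
            masked[r.chrom].append((r.pos - pad, r.pos + len(r.ref) + pad, LOW_GQ))
    if gvcf is not None:
        for chrom, ref in ref_seqs.items():
            ok = np.zeros(len(ref), dtype=bool)
            for r in gvcf:
                if r.chrom != chrom:
                    continue
                end = r.end if r.end is not None else r.pos + len(r.ref)
                if r.gq is None or r.gq >= gq_min:
                    ok[r.pos : end] = True
            for s, e in sequtil.mask_to_intervals(~ok):
                masked[chrom].append((int(s), int(e), UNCALLED))

    out_seqs: dict[str, str] = {}
    for chrom, seq in cons.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        cmap = maps[chrom]
        for s, e, _reason in masked[chrom]:
            s = max(0, s)
            # the coord map sends an edit's ref span to its alt span, so this
            # masks exactly the constructed bases of the locus
            cs, ce = cmap.to_constructed(s), cmap.to_constructed(e)
            if e > s:
                ce = max(ce, cs + 1)
            arr[cs:ce] = ord("N")
        out_seqs[chrom] = arr.tobytes().decode("ascii")
    return VCGResult(
        hap_index=hap_index,
        gq_min=gq_min,
        constructed=out_seqs,
        coord_maps=maps,
        applied=applied,
        masked={c: sorted(v) for c, v in masked.items()},
    )


def diff_alignment(query: str, target: str, qname: str, tname: str):
    """Full-length =/X alignment between two equal-length sequences."""
    from dibench.alignio import AlignmentSegment

    if len(query) != len(target):
        raise ValueError("diff_alignment requires equal-length sequences")
    qb = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    tb = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    same = qb == tb
    cigar: list[tuple[int, str]] = []
    if len(same):
        change = np.nonzero(np.diff(same))[0] + 1
        bounds = np.concatenate([[0], change, [len(same)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            cigar.append((int(b - a), "=" if same[a] else "X"))
    return AlignmentSegment(
        query=qname, q_start=0, q_end=len(query), q_len=len(query), strand="+",
        target_seq=tname, t_start=0, t_end=len(target), cigar=cigar, t_len=len(target),
    )


def build_and_score(
    ref_seqs: dict[str, str],
    records: list[VcfRecord],
    gvcf: list[VcfRecord] | None,
    thresholds: list[int],
    bench,
    hap_to_target: dict[int, dict[str, str]],
    gvcf_required: bool = False,
) -> dict[int, dict]:
    """Construct and score one genome per GQ threshold.

    ``hap_to_target`` maps hap_index -> {reference chrom -> benchmark sequence
    name} so each constructed haplotype is compared to its truth homolog.
    Constructed sequences must be colinear with their truth homolog
    (substitution-level differences); masked intervals are excluded from
    scoring. Returns {threshold: {masked_bp, aligned_bp, covered_fraction,
    qv, ...}} computed by the assembly evaluator.
    """
    from dibench.assembly import catalog_discrepancies, qv as compute_qv, region_masks, stratify

    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    out: dict[int, dict] = {}
    for gq_min in sorted(thresholds):
        segments = []
        cons_all: dict[str, str] = {}
        masked_by_target: dict[str, np.ndarray] = {}
        total_masked = 0
        results = {}
        for hap_index, chrom_map in hap_to_target.items():
            res = mask_regions(ref_seqs, records, hap_index, gq_min, gvcf=gvcf)
            results[hap_index] = res
            total_masked += res.masked_bp()
            for chrom, tname in chrom_map.items():
                qname = f"vcg_h{hap_index}_{chrom}"
                cons_all[qname] = res.constructed[chrom]
                seg = diff_alignment(res.constructed[chrom], bench.seq(tname), qname, tname)
                segments.append(seg)
                # map masked reference intervals to target coords via constructed coords
                ivs = []
                cmap = res.coord_maps[chrom]
                for s, e, _reason in res.masked[chrom]:
                    cs, ce = cmap.to_constructed(max(0, s)), cmap.to_constructed(e)
                    if ce > cs:
                        ivs.append((cs, ce))
                if ivs:
                    prev = masked_by_target.get(tname, np.empty((0, 2), dtype=np.int64))
                    masked_by_target[tname] = merge_intervals(
                        np.concatenate([prev, np.array(ivs, dtype=np.int64)])
                    )
        cat = catalog_discrepancies(segments, bench, hets={}, assembly_seqs=cons_all)
        masks = region_masks(bench, exclude=[masked_by_target] if masked_by_target else None)
        strat = stratify(cat, bench, masks)
        q = compute_qv(cat, cat.aligned_bp) if strat is None else None
        aligned = strat["aligned_bp"] if strat else cat.aligned_bp
        out[gq_min] = {
            "masked_bp": total_masked,
            "aligned_bp": aligned,
            "covered_fraction": aligned / bench.total_diploid_bp,
            "qv": strat["qv"] if strat else (q.qv if q else float("nan")),
            "qv_capped": strat["qv_capped"] if strat else (q.capped if q else True),
            "n_substitutions": strat["n_substitutions"] if strat else 0,
            "n_insertions": strat["n_insertions"] if strat else 0,
            "n_deletions": strat["n_deletions"] if strat else 0,
        }
    return out
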