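"""Alignment ingestion: PAF (with cg tags) and SAM/BAM into a common segment model."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from dibench.sequtil import revcomp

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume the query / the target
Q_OPS = set("MIS=X")
T_OPS = set("MDN=X")


def parse_cigar(text: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(text)]
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR: {text!r}")
    return ops


def cigar_spans(cigar: list[tuple[int, str]]) -> tuple[int, int]:
    """(query_consumed, target_consumed) for a CIGAR, soft clips excluded."""
    q = sum(n for n, op in cigar if op in "MI=X")
    t = sum(n for n, op in cigar if op in "MDN=X")
    return q, t


@dataclass
class AlignmentSegment:
    """One alignment of a query interval to a target interval, with base-level CIGAR.

    Coordinates are 0-based half-open on the forward strand of each sequence.
    For ``strand == '-'`` the CIGAR walks the target forward and the query
    reverse-complemented from ``q_end`` down to ``q_start``.
    """

    query: str
    q_start: int
    q_end: int
    q_len: int
    strand: str
    target_seq: str
    t_start: int
    t_end: int
    cigar: list[tuple[int, str]]
    is_primary: bool = True
    t_len: int = 0
    target_hap: str | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q, t = cigar_spans(self.cigar)
        if q != self.q_end - self.q_start:
            raise ValueError(
                f"{self.query}: CIGAR query span {q} != {self.q_end - self.q_start}"
            )
        if t != self.t_end - self.t_start:
            raise ValueError(
                f"{self.query}: CIGAR target span {t} != {self.t_end - self.t_start}"
            )

    @property
    def target_span(self) -> int:
        return self.t_end - self.t_start

    def oriented_query(self, assembly_seqs: dict[str, str]) -> str:
        """Query bases in target orientation, aligned to cigar order."""
        s = assembly_seqs[self.query][self.q_start : self.q_end]
        return revcomp(s) if self.strand == "-" else s

    def to_paf_line(self) -> str:
        cg = "".join(f"{n}{op}" for n, op in self.cigar)
        n_match, aln_len = 0, 0
        for n, op in self.cigar:
            aln_len += n
            if op in "M=":
                n_match += n
        tp = "P" if self.is_primary else "S"
        return "\t".join(
            [
                self.query,
                str(self.q_len),
                str(self.q_start),
                str(self.q_end),
                self.strand,
                self.target_seq,
                str(self.t_len or self.t_end),
                str(self.t_start),
                str(self.t_end),
                str(n_match),
                str(aln_len),
                "60",
                f"tp:A:{tp}",
                f"cg:Z:{cg}",
            ]
        )


def _read_paf(path) -> list[AlignmentSegment]:
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: not a PAF line")
            tags = {}
            for tag in f[12:]:
                name, typ, val = tag.split(":", 2)
                tags[name] = val
            if "cg" not in tags:
                raise ValueError(
                    f"{path}:{lineno}: PAF record lacks a cg CIGAR tag; "
                    "realign with 'minimap2 -c' (or --eqx) to include base-level CIGARs"
                )
            segs.append(
                AlignmentSegment(
                    query=f[0],
                    q_len=int(f[1]),
                    q_start=int(f[2]),
                    q_end=int(f[3]),
                    strand=f[4],
                    target_seq=f[5],
                    t_start=int(f[7]),
                    t_end=int(f[8]),
                    cigar=parse_cigar(tags["cg"]),
                    is_primary=tags.get("tp", "P") in ("P", "I"),
                    tags=tags,
                )
            )
    return segs


def _read_sam(path) -> list[AlignmentSegment]:
    import pysam

    segs = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            cigar = parse_cigar(rec.cigarstring)
            q_len = rec.infer_read_length() or 0
            lead = cigar[0][0] if cigar and cigar[0][1] in "SH" else 0
            core = [(n, op) for n, op in cigar if op not in "SH"]
            q_span = sum(n for n, op in core if op in "MI=X")
            # q_start/q_end are on the original read strand
            q_start = lead if not rec.is_reverse else q_len - lead - q_span
            segs.append(
                AlignmentSegment(
                    query=rec.query_name,
                    q_len=q_len,
                    q_start=q_start,
                    q_end=q_start + q_span,
                    strand="-" if rec.is_reverse else "+",
                    target_seq=rec.reference_name,
                    t_start=rec.reference_start,
                    t_end=rec.reference_end,
                    cigar=core,
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                )
            )
    return segs


def read_alignments(
    path,
    min_len: int = 0,
    primary_only: bool = False,
    bench=None,
) -> list[AlignmentSegment]:
    """Read PAF (requires cg tags) or SAM/BAM alignments.

    ``min_len`` drops segments whose target span is shorter; ``primary_only``
    drops secondary/supplementary records. When ``bench`` is given, each
    segment's ``target_hap`` is resolved and unknown targets are fatal.
    """
    p = str(path)
    if p.endswith((".bam", ".sam", ".cram")):
        segs = _read_sam(p)
    else:
        segs = _read_paf(p)
    if primary_only:
        segs = [s for s in segs if s.is_primary]
    if min_len:
        segs = [s for s in segs if s.target_span >= min_len]
    if bench is not None:
        for s in segs:
            s.target_hap = bench.hap_of(s.target_seq)  # raises KeyError if unknown
    return segs


def write_paf(path, segments: list[AlignmentSegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(seg.to_paf_line() + "\n")
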