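"""Low-level sequence utilities: 2-bit encoding, canonical k-mers, FASTA and BED I/O."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4  # anything that is not ACGT

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte value -> 0..3 code, everything else (incl. N) -> 4
_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def seq_bytes(seq: str) -> np.ndarray:
    """Raw ASCII byte view of a sequence (for fast elementwise comparison)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All canonical k-mer codes of ``seq``.

    Returns ``(positions, codes)`` where positions are 0-based window starts
    and codes are 2-bit packed canonical (lexicographic min of forward and
    reverse complement) k-mers as uint64. Windows containing non-ACGT bases
    are dropped. Requires k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit uint64 packing")
    b = encode(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)

    bad = (b == N_CODE).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0

    b2 = (b & 3).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b2[j : j + n]

    # rc code of the window at i equals the forward code of revcomp(seq) at n-1-i
    rb = (np.uint64(3) - b2)[::-1]
    rcf = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        rcf = (rcf << np.uint64(2)) | rb[j : j + n]
    rc = rcf[::-1]

    canon = np.minimum(fwd, rc)
    pos = np.nonzero(valid)[0]
    return pos, canon[valid]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name in {path}: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences parsed from {path}")
    return seqs


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a BED file into name -> (n, 2) array of 0-based half-open intervals."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: not a BED3+ line: {line!r}")
            name, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            ivs.setdefault(name, []).append((start, end))
    return {name: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for name, v in ivs.items()}


def write_bed(path, intervals: dict[str, np.ndarray], extra: dict[str, list] | None = None) -> None:
    with open(path, "w") as fh:
        for name, arr in intervals.items():
            cols = extra.get(name) if extra else None
            for i, (s, e) in enumerate(arr):
                tail = "\t" + "\t".join(str(x) for x in cols[i]) if cols else ""
                fh.write(f"{name}\t{s}\t{e}{tail}\n")


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted or unsorted intervals, (n,2) -> (m,2)."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr[np.argsort(arr[:, 0])]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def interval_mask(length: int, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of ``length`` with True inside the given intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(length, e)] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> np.ndarray:
    """Inverse of interval_mask: True stretches as (n,2) half-open intervals."""
    if len(mask) == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return np.stack([starts, ends], axis=1).astype(np.int64)
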