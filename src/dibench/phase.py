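"""Two-state HMM segmentation of assembly contigs into haplotype blocks.

Observations are haplotype-specific marker k-mers found in a contig; the
Viterbi path over a symmetric two-state chain assigns each observation to
hap1 or hap2, and consecutive same-state observations are merged into blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dibench.index import HAP1, HAP2, MarkerSet
from dibench.sequtil import kmer_codes


@dataclass(frozen=True)
class MarkerObservation:
    contig: str
    pos: int  # 0-based k-mer start
    source: str  # HAP1 or HAP2
    weight: float = 1.0


@dataclass
class PhaseBlock:
    contig: str
    start: int
    end: int
    state: str
    n_support: int
    n_conflict: int


@dataclass(frozen=True)
class HmmParams:
    """p_switch: per-observation transition probability; p_error: marker noise."""

    p_switch: float = 1e-5
    p_error: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.p_switch < 0.5):
            raise ValueError("p_switch must be in (0, 0.5)")
        if not (0 < self.p_error < 0.5):
            raise ValueError("p_error must be in (0, 0.5)")


def scan_markers(
    contig_seq: str,
    markers: MarkerSet,
    contig: str = "contig",
    weight_by_count: bool = False,
) -> list[MarkerObservation]:
    """Find every marker k-mer occurrence in a contig, in position order.

    With ``weight_by_count`` each observation is down-weighted by the marker's
    occurrence count in its haplotype (weight = 1/count).
    """
    pos, codes = kmer_codes(contig_seq, markers.k)
    out: list[MarkerObservation] = []
    for hap, mcodes, mcounts in (
        (HAP1, markers.hap1_codes, markers.hap1_counts),
        (HAP2, markers.hap2_codes, markers.hap2_counts),
    ):
        if not len(mcodes):
            continue
        idx = np.searchsorted(mcodes, codes)
        idx[idx == len(mcodes)] = 0
        hit = mcodes[idx] == codes
        for p, i in zip(pos[hit], idx[hit]):
            w = 1.0 / mcounts[i] if weight_by_count else 1.0
            out.append(MarkerObservation(contig, int(p), hap, w))
    out.sort(key=lambda o: o.pos)
    return out


def viterbi_phase(
    obs: list[MarkerObservation],
    params: HmmParams = HmmParams(),
    k: int = 0,
) -> list[PhaseBlock]:
    """Maximum-probability haplotype segmentation of one contig's observations.

    Uniform initial distribution; symmetric per-observation transitions;
    emission agrees with the hidden state with probability 1 - p_error. Ties
    are broken toward staying in the previous state. Block boundaries are
    placed at the midpoint between the flanking observations of adjacent
    blocks; ``k`` (marker length) extends the last block past its final
    observation start.
    """
    if not obs:
        return []
    contig = obs[0].contig
    n = len(obs)
    src = np.fromiter((0 if o.source == HAP1 else 1 for o in obs), dtype=np.int8, count=n)
    w = np.fromiter((o.weight for o in obs), dtype=np.float64, count=n)

    l_stay = math.log1p(-params.p_switch)
    l_switch = math.log(params.p_switch)
    l_match = math.log1p(-params.p_error)
    l_miss = math.log(params.p_error)

    # emission log-likelihood for state s at step i
    def emit(i: int, s: int) -> float:
        return w[i] * (l_match if src[i] == s else l_miss)

    score = np.array([emit(0, 0), emit(0, 1)])
    back = np.empty((n, 2), dtype=np.int8)
    for i in range(1, n):
        new = np.empty(2)
        for s in (0, 1):
            stay = score[s] + l_stay
            move = score[1 - s] + l_switch
            # ties broken toward no switch
            if move > stay:
                new[s] = move + emit(i, s)
                back[i, s] = 1 - s
            else:
                new[s] = stay + emit(i, s)
                back[i, s] = s
        score = new
    state = int(np.argmax(score)) if score[0] != score[1] else int(src[-1])
    path = np.empty(n, dtype=np.int8)
    path[-1] = state
    for i in range(n - 1, 0, -1):
        state = back[i, state]
        path[i - 1] = state

    return _blocks_from_path(contig, obs, path, k)


def _blocks_from_path(contig: str, obs, path: np.ndarray, k: int) -> list[PhaseBlock]:
    blocks: list[PhaseBlock] = []
    n = len(obs)
    seg_start = 0
    for i in range(1, n + 1):
        if i == n or path[i] != path[i - 1]:
            state = int(path[i - 1])
            hap = HAP1 if state == 0 else HAP2
            first, last = obs[seg_start], obs[i - 1]
            start = first.pos if not blocks else blocks[-1].end
            if i == n:
                end = last.pos + max(k, 1)
            else:
                end = (last.pos + obs[i].pos) // 2 + 1  # midpoint boundary
            support = sum(1 for j in range(seg_start, i) if (0 if obs[j].source == HAP1 else 1) == state)
            blocks.append(
                PhaseBlock(contig, start, end, hap, n_support=support, n_conflict=(i - seg_start) - support)
            )
            seg_start = i
    return blocks


def switch_stats(blocks_by_contig: dict[str, list[PhaseBlock]], aligned_bp: int) -> dict:
    """Phase-switch summary: total switches and switches per aligned megabase."""
    if aligned_bp <= 0:
        raise ValueError("aligned_bp must be positive")
    n_switches = sum(max(0, len(b) - 1) for b in blocks_by_contig.values())
    per_contig = {
        c: {
            "n_blocks": len(b),
            "n_switches": max(0, len(b) - 1),
            "largest_block": max((blk.end - blk.start for blk in b), default=0),
        }
        for c, b in blocks_by_contig.items()
    }
    return {
        "n_switches": n_switches,
        "switch_rate_per_mb": n_switches / (aligned_bp / 1e6),
        "aligned_bp": aligned_bp,
        "per_contig": per_contig,
    }


def phase_assembly(
    contigs: dict[str, str],
    markers: MarkerSet,
    params: HmmParams = HmmParams(),
    weight_by_count: bool = False,
) -> dict[str, list[PhaseBlock]]:
    """Scan and segment every contig; contigs with no markers map to empty lists."""
    out: dict[str, list[PhaseBlock]] = {}
    for name, seq in contigs.items():
        obs = scan_markers(seq, markers, contig=name, weight_by_count=weight_by_count)
        out[name] = viterbi_phase(obs, params, k=markers.k)
    return out
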