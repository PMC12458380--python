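"""Synthetic fixtures with known truth: diploid genomes, corrupted assemblies,
simulated reads and truth variant sets.

Every modification to every sequence is logged in a truth table, truth
alignments are emitted directly from the construction (no aligner in the
loop), and each generator draws from its own named RNG substream so outputs
are byte-stable under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from dibench import sequtil
from dibench.alignio import AlignmentSegment
from dibench.index import DiploidBenchmark
from dibench.vcg import CoordMap, Edit, VcfRecord, apply_edits

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, stream: str) -> np.random.Generator:
    # stable substream key (hash() is salted per process)
    key = zlib.crc32(stream.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def flip_cigar(cigar: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Swap query and target roles (I <-> D)."""
    sw = {"I": "D", "D": "I"}
    return [(n, sw.get(op, op)) for n, op in cigar]


@dataclass
class GenomeSpec:
    n_chroms: int = 2
    chrom_len: int = 500_000
    het_snv_rate: float = 1e-3
    het_indel_rate: float = 1e-4
    max_indel_len: int = 10
    sv_events: tuple = ()  # (type in {insertion, deletion, inversion, duplication}, length)
    run_density_per_mb: dict = field(default_factory=lambda: {1: 200, 2: 60, 3: 40, 4: 30})
    run_len_copies: dict = field(default_factory=lambda: {1: (6, 20), 2: (4, 8), 3: (3, 6), 4: (3, 5)})
    n_gaps: int = 0
    gap_len: int = 1000
    min_spacing: int = 70  # planted events keep >= ~2k bp apart
    snv_every: int | None = None  # regular SNV grid (marker-dense mode); overrides het_snv_rate
    gq_choices: tuple = (60,)
    gq_probs: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.het_snv_rate <= 0.05 and 0 <= self.het_indel_rate <= 0.05):
            raise ValueError("variant rates must be in [0, 0.05]")


@dataclass
class SimGenome:
    """A diploid benchmark plus complete truth bookkeeping."""

    bench: DiploidBenchmark
    spec: GenomeSpec
    truth_edits: dict[str, list[Edit]]  # hap1 seq name -> hap1->hap2 edits
    coord_maps: dict[str, CoordMap]  # hap1 -> hap2 coordinates
    truth_alignments: list[AlignmentSegment]  # query = hap1 seq, target = hap2 seq
    vcf_records: list[VcfRecord]
    non_n_bp: int

    def hap1_names(self) -> list[str]:
        return list(self.bench.hap1_seqs)

    def het_snv_positions(self, seq_name: str) -> list[int]:
        """Het SNV positions in the coordinates of either haplotype's sequence."""
        if seq_name in self.bench.hap1_seqs:
            return [e.pos for e in self.truth_edits[seq_name] if len(e.ref_allele) == len(e.alt_allele) == 1]
        inv = {v: k for k, v in self.bench.pairing.items()}
        h1 = inv[seq_name]
        cmap = self.coord_maps[h1]
        return [
            cmap.to_constructed(e.pos)
            for e in self.truth_edits[h1]
            if len(e.ref_allele) == len(e.alt_allele) == 1
        ]

    def het_allele_other(self, seq_name: str, pos: int) -> str:
        """At a het SNV on ``seq_name``, the allele carried by the homolog."""
        if seq_name in self.bench.hap1_seqs:
            for e in self.truth_edits[seq_name]:
                if e.pos == pos and len(e.ref_allele) == 1 == len(e.alt_allele):
                    return e.alt_allele
        else:
            inv = {v: k for k, v in self.bench.pairing.items()}
            h1 = inv[seq_name]
            cmap = self.coord_maps[h1]
            for e in self.truth_edits[h1]:
                if len(e.ref_allele) == 1 == len(e.alt_allele) and cmap.to_constructed(e.pos) == pos:
                    return e.ref_allele
        raise KeyError(f"no het SNV at {seq_name}:{pos}")

    def write_fastas(self, hap1_path, hap2_path) -> None:
        sequtil.write_fasta(hap1_path, self.bench.hap1_seqs)
        sequtil.write_fasta(hap2_path, self.bench.hap2_seqs)

    def write_truth_paf(self, path) -> None:
        from dibench.alignio import write_paf

        write_paf(path, self.truth_alignments)

    def write_vcf(self, path, drop: set | None = None) -> None:
        """Truth VCF against the hap1 reference; ``drop`` omits (chrom, pos) keys."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, seq in self.bench.hap1_seqs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for r in self.vcf_records:
                if drop and (r.chrom, r.pos) in drop:
                    continue
                gt = f"{r.gt[0]}|{r.gt[1]}"
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{','.join(r.alts)}\t.\tPASS\t.\tGT:GQ\t{gt}:{r.gq}\n"
                )

    def write_full_gvcf(self, path, gq: int = 99) -> None:
        """gVCF whose reference blocks confidently cover every hap1 position."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, seq in self.bench.hap1_seqs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
            for name, seq in self.bench.hap1_seqs.items():
                fh.write(f"{name}\t1\t.\t{seq[0]}\t<NON_REF>\t.\t.\tEND={len(seq)}\tGT:GQ\t0/0:{gq}\n")


def _plant_runs(rng: np.random.Generator, arr: np.ndarray, spec: GenomeSpec) -> int:
    """Overwrite stretches with tandem runs at the target density; returns bp planted."""
    L = len(arr)
    planted = 0
    for u, per_mb in spec.run_density_per_mb.items():
        n = int(round(per_mb * L / 1e6))
        lo, hi = spec.run_len_copies[u]
        total = n * hi * u
        if total > 0.3 * L:
            raise ValueError("requested run density is infeasible for this chromosome length")
        for _ in range(n):
            copies = int(rng.integers(lo, hi + 1))
            unit = _random_seq(rng, u)
            if u > 1 and len(set(unit)) == 1:
                unit = unit[:-1] + _other_base(rng, unit[-1])
            pos = int(rng.integers(0, L - copies * u))
            rep = np.frombuffer((unit * copies).encode(), dtype=np.uint8)
            arr[pos : pos + len(rep)] = rep
            planted += len(rep)
    return planted


def _pick_positions(rng: np.random.Generator, L: int, n: int, spacing: int, taken: list[int]) -> list[int]:
    """Up to n positions uniformly, each >= spacing from previous picks."""
    out: list[int] = []
    occupied = sorted(taken)
    tries = 0
    while len(out) < n and tries < 50 * n + 1000:
        tries += 1
        p = int(rng.integers(spacing, L - spacing))
        import bisect

        i = bisect.bisect_left(occupied, p)
        if (i < len(occupied) and occupied[i] - p < spacing) or (i > 0 and p - occupied[i - 1] < spacing):
            continue
        bisect.insort(occupied, p)
        out.append(p)
    out.sort()
    return out


def simulate_diploid_genome(spec: GenomeSpec) -> SimGenome:
    """Generate a diploid benchmark: hap2 is hap1 plus planted het variants and SVs.

    Emits the exact truth alignment and a truth VCF (hap1 as the reference,
    genotypes 0|1) alongside the genome.
    """
    rng_seq = _rng(spec.seed, "sequence")
    rng_var = _rng(spec.seed, "variants")
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    pairing: dict[str, str] = {}
    truth_edits: dict[str, list[Edit]] = {}
    coord_maps: dict[str, CoordMap] = {}
    alns: list[AlignmentSegment] = []
    vcf: list[VcfRecord] = []
    sv_per_chrom: dict[int, list] = {}
    for i, ev in enumerate(spec.sv_events):
        sv_per_chrom.setdefault(i % spec.n_chroms, []).append(ev)

    for c in range(spec.n_chroms):
        L = spec.chrom_len
        name1, name2 = f"chr{c + 1}_hap1", f"chr{c + 1}_hap2"
        arr = np.frombuffer(_random_seq(rng_seq, L).encode(), dtype=np.uint8).copy()
        _plant_runs(rng_seq, arr, spec)
        if spec.n_gaps:
            for _ in range(spec.n_gaps):
                g = int(rng_seq.integers(L // 10, L - L // 10 - spec.gap_len))
                arr[g : g + spec.gap_len] = ord("N")
        seq1 = arr.tobytes().decode("ascii")

        taken: list[int] = []
        edits: list[Edit] = []
        if spec.snv_every is not None:
            snv_pos = list(range(spec.snv_every, L - spec.snv_every, spec.snv_every))
            n_ind = 0
        else:
            n_snv = int(rng_var.binomial(L, spec.het_snv_rate))
            n_ind = int(rng_var.binomial(L, spec.het_indel_rate))
            snv_pos = _pick_positions(rng_var, L, n_snv, spec.min_spacing, taken)
        taken += snv_pos
        for p in snv_pos:
            if seq1[p] == "N":
                continue
            edits.append(Edit(p, seq1[p], _other_base(rng_var, seq1[p])))
        ind_pos = _pick_positions(rng_var, L, n_ind, spec.min_spacing, taken)
        taken += ind_pos
        for p in ind_pos:
            if "N" in seq1[p : p + spec.max_indel_len + 1]:
                continue
            ln = int(rng_var.integers(1, spec.max_indel_len + 1))
            if rng_var.random() < 0.5:
                edits.append(Edit(p, seq1[p], seq1[p] + _random_seq(rng_var, ln)))
            else:
                edits.append(Edit(p, seq1[p : p + ln + 1], seq1[p]))
        for kind, ln in sv_per_chrom.get(c, []):
            p = _pick_positions(rng_var, L - ln - 2, 1, spec.min_spacing + ln, taken)
            if not p:
                continue
            p = p[0]
            taken.append(p)
            if kind == "insertion":
                edits.append(Edit(p, seq1[p], seq1[p] + _random_seq(rng_var, ln)))
            elif kind == "deletion":
                edits.append(Edit(p, seq1[p : p + ln + 1], seq1[p]))
            elif kind == "inversion":
                seg = seq1[p : p + ln]
                if "N" not in seg:
                    edits.append(Edit(p, seg, sequtil.revcomp(seg)))
            elif kind == "duplication":
                seg = seq1[p : p + ln]
                if "N" not in seg:
                    edits.append(Edit(p, seg, seg + seg))
            else:
                raise ValueError(f"unknown SV type {kind!r}")
        edits.sort(key=lambda e: e.pos)

        seq2, cmap, cigar = apply_edits(seq1, edits)
        hap1[name1] = seq1
        hap2[name2] = seq2
        pairing[name1] = name2
        truth_edits[name1] = edits
        coord_maps[name1] = cmap
        alns.append(
            AlignmentSegment(
                query=name1, q_start=0, q_end=len(seq1), q_len=len(seq1), strand="+",
                target_seq=name2, t_start=0, t_end=len(seq2), cigar=flip_cigar(cigar),
                t_len=len(seq2),
            )
        )
        gqp = np.asarray(spec.gq_probs, dtype=float) if spec.gq_probs else None
        for e in edits:
            gq = int(rng_var.choice(np.asarray(spec.gq_choices), p=gqp))
            vcf.append(
                VcfRecord(name1, e.pos, e.ref_allele, (e.alt_allele,), (0, 1), True, gq)
            )

    bench = DiploidBenchmark(hap1_seqs=hap1, hap2_seqs=hap2, pairing=pairing)
    return SimGenome(
        bench=bench,
        spec=spec,
        truth_edits=truth_edits,
        coord_maps=coord_maps,
        truth_alignments=alns,
        vcf_records=sorted(vcf, key=lambda r: (r.chrom, r.pos)),
        non_n_bp=bench.total_diploid_bp,
    )


@dataclass
class ErrorSpec:
    """Planted corruption for a test assembly; every event is logged."""

    subs_per_contig: int = 0
    ins_per_contig: int = 0
    del_per_contig: int = 0
    phase_consistent_per_contig: int = 0
    indel_len: tuple = (1, 5)
    big_indels: tuple = ()  # (kind in {insertion, deletion}, length) applied to the first contig
    switches: dict = field(default_factory=dict)  # hap1 seq name -> [hap1 positions]
    dropouts: tuple = ()  # (benchmark seq name, start, end)
    seed: int = 0


@dataclass
class SimAssembly:
    contigs: dict[str, str]
    alignments: list[AlignmentSegment]  # truth alignments, query = contig
    truth_errors: list[dict]  # klass/seq/t_pos/length/sub_type records in benchmark coords
    switch_truth: dict[str, list[tuple[str, int]]]  # contig -> [(target seq, junction pos)]

    def write_fasta(self, path) -> None:
        sequtil.write_fasta(path, self.contigs)

    def write_paf(self, path) -> None:
        from dibench.alignio import write_paf

        write_paf(path, self.alignments)


def corrupt_assembly(sim: SimGenome, spec: ErrorSpec, k: int = 31) -> SimAssembly:
    """Derive a test assembly from the benchmark with planted, logged errors.

    Contigs listed in ``spec.switches`` are built by splicing the homologous
    haplotype at the given junctions and carry no other errors; all remaining
    contigs get planted substitutions / indels / phase-consistent alleles that
    avoid het sites and each other by at least k+1 bp.
    """
    rng = _rng(spec.seed, "assembly-errors")
    bench = sim.bench
    contigs: dict[str, str] = {}
    alns: list[AlignmentSegment] = []
    truth: list[dict] = []
    switch_truth: dict[str, list[tuple[str, int]]] = {}
    drop_by_seq: dict[str, list[tuple[int, int]]] = {}
    for seqname, a, b in spec.dropouts:
        drop_by_seq.setdefault(seqname, []).append((a, b))

    first = True
    for name in bench.names():
        seq = bench.seq(name)
        ctg = f"ctg_{name}"
        if name in spec.switches:
            contigs[ctg], segs, junctions = _spliced_contig(sim, name, spec.switches[name], ctg)
            alns.extend(segs)
            switch_truth[ctg] = junctions
            continue

        hets = sorted(sim.het_snv_positions(name))
        spacing = k + 1
        avoid = list(np.array(hets, dtype=int)) if hets else []
        edits: list[Edit] = []

        for p in _pick_positions(rng, len(seq), spec.subs_per_contig, spacing, avoid):
            if seq[p] == "N":
                continue
            alt = _other_base(rng, seq[p])
            edits.append(Edit(p, seq[p], alt))
            truth.append({"klass": "substitution", "seq": name, "t_pos": p, "sub_type": f"{seq[p]}>{alt}"})
        avoid = sorted(set(avoid) | {e.pos for e in edits})
        for p in _pick_positions(rng, len(seq), spec.ins_per_contig, spacing, avoid):
            if "N" in seq[p : p + 2]:
                continue
            ln = int(rng.integers(spec.indel_len[0], spec.indel_len[1] + 1))
            edits.append(Edit(p, seq[p], seq[p] + _random_seq(rng, ln)))
            truth.append({"klass": "insertion", "seq": name, "t_pos": p, "length": ln})
        avoid = sorted(set(avoid) | {e.pos for e in edits})
        for p in _pick_positions(rng, len(seq), spec.del_per_contig, spacing, avoid):
            ln = int(rng.integers(spec.indel_len[0], spec.indel_len[1] + 1))
            if "N" in seq[p : p + ln + 1]:
                continue
            edits.append(Edit(p, seq[p : p + ln + 1], seq[p]))
            truth.append({"klass": "deletion", "seq": name, "t_pos": p + 1, "length": ln})

        if spec.phase_consistent_per_contig:
            chosen = [h for h in hets if seq[h] != "N"]
            rng.shuffle(chosen)
            used = 0
            planted = {e.pos for e in edits}
            for h in chosen:
                if used >= spec.phase_consistent_per_contig:
                    break
                if any(abs(h - p) <= spacing for p in planted):
                    continue
                other = sim.het_allele_other(name, h)
                if other == seq[h] or len(other) != 1:
                    continue
                edits.append(Edit(h, seq[h], other))
                truth.append({"klass": "phase_consistent", "seq": name, "t_pos": h})
                planted.add(h)
                used += 1

        if first and spec.big_indels:
            avoid = sorted({e.pos for e in edits} | set(avoid))
            for kind, ln in spec.big_indels:
                p = _pick_positions(rng, len(seq) - ln - 2, 1, max(spacing, 200), avoid)
                if not p:
                    raise ValueError("could not place big indel")
                p = p[0]
                avoid = sorted(set(avoid) | {p})
                if kind == "insertion":
                    edits.append(Edit(p, seq[p], seq[p] + _random_seq(rng, ln)))
                    truth.append({"klass": "insertion", "seq": name, "t_pos": p, "length": ln})
                else:
                    if "N" in seq[p : p + ln + 1]:
                        raise ValueError("big deletion would span N")
                    edits.append(Edit(p, seq[p : p + ln + 1], seq[p]))
                    truth.append({"klass": "deletion", "seq": name, "t_pos": p + 1, "length": ln})
            first = False

        edits.sort(key=lambda e: e.pos)
        ctg_seq, _cmap, cigar = apply_edits(seq, edits)
        contigs[ctg] = ctg_seq
        drops = sorted(drop_by_seq.get(name, []))
        if not drops:
            alns.append(
                AlignmentSegment(
                    query=ctg, q_start=0, q_end=len(ctg_seq), q_len=len(ctg_seq), strand="+",
                    target_seq=name, t_start=0, t_end=len(seq), cigar=cigar, t_len=len(seq),
                )
            )
        else:
            contigs[ctg], segs = _dropout_contig(ctg, ctg_seq, cigar, name, len(seq), drops)
            alns.extend(segs)
            for a, b in drops:
                truth.append({"klass": "dropout", "seq": name, "t_pos": a, "length": b - a})
    return SimAssembly(contigs=contigs, alignments=alns, truth_errors=truth, switch_truth=switch_truth)


def _spliced_contig(sim: SimGenome, name1: str, junctions: list[int], ctg: str):
    """Contig alternating hap1/hap2 source at the given hap1 junction positions."""
    bench = sim.bench
    name2 = bench.pairing[name1]
    s1, s2 = bench.hap1_seqs[name1], bench.hap2_seqs[name2]
    cmap = sim.coord_maps[name1]
    cuts1 = [0] + sorted(junctions) + [len(s1)]
    parts: list[str] = []
    segs: list[AlignmentSegment] = []
    recorded: list[tuple[str, int]] = []
    qoff = 0
    for i in range(len(cuts1) - 1):
        a, b = cuts1[i], cuts1[i + 1]
        if i % 2 == 0:
            piece = s1[a:b]
            tname, ta, tb = name1, a, b
        else:
            ta, tb = cmap.to_constructed(a), cmap.to_constructed(b)
            piece = s2[ta:tb]
            tname = name2
        parts.append(piece)
        segs.append(
            AlignmentSegment(
                query=ctg, q_start=qoff, q_end=qoff + len(piece), q_len=0, strand="+",
                target_seq=tname, t_start=ta, t_end=tb, cigar=[(len(piece), "=")],
            )
        )
        if i:
            recorded.append((tname, qoff))
        qoff += len(piece)
    total = qoff
    for s in segs:
        s.q_len = total
    return "".join(parts), segs, recorded


def _dropout_contig(ctg: str, ctg_seq: str, cigar, tname: str, tlen: int, drops: list[tuple[int, int]]):
    """Remove target intervals from the contig, splitting its truth alignment."""
    keep: list[tuple[int, int]] = []
    prev = 0
    for a, b in drops:
        keep.append((prev, a))
        prev = b
    keep.append((prev, tlen))

    # walk the cigar once, slicing query/target jointly
    ops = list(cigar)
    out_parts: list[str] = []
    segs: list[AlignmentSegment] = []
    t = 0
    q = 0
    qout = 0
    op_i = 0
    for ka, kb in keep:
        if kb <= ka:
            continue
        # advance to ka
        while t < ka and op_i < len(ops):
            n, op = ops[op_i]
            tstep = n if op in "MDN=X" else 0
            qstep = n if op in "MI=X" else 0
            if t + tstep <= ka:
                t += tstep
                q += qstep
                op_i += 1
            else:
                take = ka - t
                ops[op_i] = (n - take, op)
                t += take
                q += take if qstep else 0
                break
        seg_cigar: list[tuple[int, str]] = []
        seg_t0, seg_q0 = t, q
        while t < kb and op_i < len(ops):
            n, op = ops[op_i]
            tstep = n if op in "MDN=X" else 0
            if tstep and t + tstep > kb:
                take = kb - t
                seg_cigar.append((take, op))
                ops[op_i] = (n - take, op)
                t += take
                q += take if op in "MI=X" else 0
                break
            seg_cigar.append((n, op))
            t += tstep
            q += n if op in "MI=X" else 0
            op_i += 1
        qa, qb_ = seg_q0, q
        piece = ctg_seq[qa:qb_]
        out_parts.append(piece)
        segs.append(
            AlignmentSegment(
                query=ctg, q_start=qout, q_end=qout + len(piece), q_len=0, strand="+",
                target_seq=tname, t_start=seg_t0, t_end=t, cigar=seg_cigar,
            )
        )
        qout += len(piece)
    new_seq = "".join(out_parts)
    for s in segs:
        s.q_len = len(new_seq)
    return new_seq, segs


@dataclass
class ReadSpec:
    read_len: int = 10_000
    depth: float = 10.0  # per haplotype
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    q_mode: str = "rate"  # "rate" (uniform rates, truthful constant Q) or "per_base"
    q_choices: tuple = (20, 25, 30, 35, 40)
    q_probs: tuple | None = None
    err_split: tuple = (0.6, 0.2, 0.2)  # sub/ins/del fractions in per_base mode
    miscal_offset: int = 0  # added to *reported* Q above miscal_above
    miscal_above: int | None = None
    cross_map_fraction: float = 0.0  # hap2 reads reported against hap1 coordinates
    gc_dropout_mid: float | None = None  # logistic dropout midpoint (GC fraction)
    gc_dropout_steep: float = 20.0
    seed: int = 0


@dataclass
class SimReads:
    n_reads: int
    total_bp: int
    injected_subs: int
    injected_ins: int
    injected_del: int
    aligned_bp: int


def simulate_reads(sim_or_bench, spec: ReadSpec, out_path) -> SimReads:
    """Simulate reads from both haplotypes and write a coordinate-sorted BAM/SAM.

    Reads carry truth =/X CIGARs from the construction; start positions are
    uniform (Poisson arrivals) unless a GC dropout curve is configured.
    """
    import pysam

    sim = sim_or_bench if isinstance(sim_or_bench, SimGenome) else None
    bench = sim.bench if sim else sim_or_bench
    rng = _rng(spec.seed, "reads")
    names = bench.names()
    header = pysam.AlignmentHeader.from_references(names, [len(bench.seq(n)) for n in names])
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    stats = SimReads(0, 0, 0, 0, 0, 0)

    inv_pairing = {v: k for k, v in bench.pairing.items()}
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        for name in names:
            seq = bench.seq(name)
            L = len(seq)
            rl = min(spec.read_len, L)
            n_reads = int(rng.poisson(spec.depth * L / rl))
            starts = np.sort(rng.integers(0, max(1, L - rl + 1), size=n_reads))
            records = []
            for ridx, start in enumerate(starts):
                template = seq[start : int(start) + rl]
                if "N" in template:
                    continue
                if spec.gc_dropout_mid is not None:
                    gc = (template.count("G") + template.count("C")) / len(template)
                    p_keep = 1.0 / (1.0 + np.exp(spec.gc_dropout_steep * (gc - spec.gc_dropout_mid)))
                    if rng.random() > p_keep:
                        continue
                read_seq, quals, cigar, ns, ni, nd = _mutate_read(template, spec, rng)
                stats.n_reads += 1
                stats.total_bp += len(read_seq)
                stats.injected_subs += ns
                stats.injected_ins += ni
                stats.injected_del += nd
                stats.aligned_bp += sum(n for n, op in cigar if op in "=X")
                ref_name, ref_start = name, int(start)
                if (
                    spec.cross_map_fraction
                    and name in inv_pairing
                    and cigar == [(len(read_seq), "=")]  # only error-free reads cross-map cleanly
                    and rng.random() < spec.cross_map_fraction
                ):
                    mapped = _cross_map(sim, name, int(start), rl)
                    if mapped is not None:
                        ref_name, ref_start = mapped
                        other = bench.seq(ref_name)[ref_start : ref_start + len(read_seq)]
                        cigar = _diff_cigar(read_seq, other)
                records.append((ref_name, ref_start, f"rd_{name}_{ridx}", read_seq, quals, cigar))
            for ref_name, ref_start, qname, read_seq, quals, cigar in records:
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.query_sequence = read_seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                a.reference_id = names.index(ref_name)
                a.reference_start = ref_start
                a.cigarstring = "".join(f"{n}{op}" for n, op in cigar)
                a.mapping_quality = 60
                a.flag = 0
                out.write(a)
    return stats


def _diff_cigar(a: str, b: str) -> list[tuple[int, str]]:
    """=/X run-length cigar between equal-length strings."""
    same = np.frombuffer(a.encode(), dtype=np.uint8) == np.frombuffer(b.encode(), dtype=np.uint8)
    out: list[tuple[int, str]] = []
    change = np.nonzero(np.diff(same))[0] + 1
    bounds = np.concatenate([[0], change, [len(same)]])
    for x, y in zip(bounds[:-1], bounds[1:]):
        out.append((int(y - x), "=" if same[x] else "X"))
    return out


def _cross_map(sim: SimGenome | None, name: str, start: int, rl: int):
    """Map a hap2 read window onto hap1 coordinates when the window has no het indel."""
    if sim is None:
        return None
    inv = {v: k for k, v in sim.bench.pairing.items()}
    h1 = inv[name]
    cmap = sim.coord_maps[h1]
    inv_map = CoordMap(cmap.anchors_cons, cmap.anchors_ref)
    a = inv_map.to_constructed(start)
    b = inv_map.to_constructed(start + rl)
    if b - a != rl:  # an indel het falls inside; keep the read on its own haplotype
        return None
    for e in sim.truth_edits[h1]:
        if len(e.ref_allele) != len(e.alt_allele) and a <= e.pos < b:
            return None
    return h1, a


def _mutate_read(template: str, spec: ReadSpec, rng: np.random.Generator):
    """Inject errors into one read; returns (seq, quals, cigar, n_sub, n_ins, n_del)."""
    L = len(template)
    if spec.q_mode == "per_base":
        qp = np.asarray(spec.q_probs, dtype=float) if spec.q_probs else None
        true_q = rng.choice(np.asarray(spec.q_choices), size=L, p=qp).astype(np.int64)
        perr = np.power(10.0, -true_q / 10.0)
        is_err = rng.random(L) < perr
        fs, fi, _fd = spec.err_split
        tdraw = rng.random(L)
        etype = np.where(tdraw < fs, 0, np.where(tdraw < fs + fi, 1, 2))
    else:
        total = spec.sub_rate + spec.ins_rate + spec.del_rate
        true_q = np.full(L, 60 if total == 0 else max(1, round(-10 * np.log10(total))), dtype=np.int64)
        is_err = rng.random(L) < total
        tdraw = rng.random(L) * (total if total else 1.0)
        etype = np.where(tdraw < spec.sub_rate, 0, np.where(tdraw < spec.sub_rate + spec.ins_rate, 1, 2))

    rep_q = true_q.copy()
    if spec.miscal_above is not None and spec.miscal_offset:
        rep_q = np.where(true_q > spec.miscal_above, true_q + spec.miscal_offset, true_q)
    rep_q = np.clip(rep_q, 0, 93)

    err_pos = np.nonzero(is_err)[0]
    out_seq: list[str] = []
    out_q: list[int] = []
    cigar: list[tuple[int, str]] = []
    ns = ni = nd = 0

    def emit(n: int, op: str) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + n, op)
        else:
            cigar.append((n, op))

    prev = 0
    for p in err_pos:
        p = int(p)
        if p < prev:  # consumed by a preceding deletion event
            continue
        if p > prev:
            emit(p - prev, "=")
            out_seq.append(template[prev:p])
            out_q.extend(rep_q[prev:p])
        t = int(etype[p])
        if t == 0:
            alt = _other_base(rng, template[p])
            out_seq.append(alt)
            out_q.append(int(rep_q[p]))
            emit(1, "X")
            ns += 1
            prev = p + 1
        elif t == 1:
            out_seq.append(template[p])
            out_q.append(int(rep_q[p]))
            emit(1, "=")
            ins = _random_seq(rng, 1)
            out_seq.append(ins)
            out_q.append(int(rep_q[p]))
            emit(1, "I")
            ni += 1
            prev = p + 1
        else:
            # deletions remove the base *after* p so the event rate is governed
            # by the same base the profiler attributes the event to (5' rule)
            if p >= L - 1:
                emit(1, "=")
                out_seq.append(template[p])
                out_q.append(int(rep_q[p]))
                prev = p + 1
            else:
                emit(1, "=")
                out_seq.append(template[p])
                out_q.append(int(rep_q[p]))
                emit(1, "D")
                nd += 1
                prev = p + 2
    if prev < L:
        emit(L - prev, "=")
        out_seq.append(template[prev:])
        out_q.extend(rep_q[prev:])
    return "".join(out_seq), list(map(int, out_q)), cigar, ns, ni, nd
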