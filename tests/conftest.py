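import numpy as np
import pytest

from dibench.alignio import AlignmentSegment
from dibench.index import annotate_runs, build_het_catalog, extract_markers, het_snv_lookup
from dibench.sim import ErrorSpec, GenomeSpec, corrupt_assembly, simulate_diploid_genome

K = 21  # small k keeps unit-test marker extraction fast


@pytest.fixture(scope="session")
def tiny_genome():
    """2 chroms x 120 kb diploid fixture with planted runs, SNVs and indels."""
    spec = GenomeSpec(n_chroms=2, chrom_len=120_000, het_snv_rate=1e-3, het_indel_rate=1e-4, seed=11)
    return simulate_diploid_genome(spec)


@pytest.fixture(scope="session")
def tiny_hets(tiny_genome):
    return build_het_catalog(tiny_genome.bench, tiny_genome.truth_alignments)


@pytest.fixture(scope="session")
def tiny_het_lut(tiny_hets):
    return het_snv_lookup(tiny_hets)


@pytest.fixture(scope="session")
def tiny_markers(tiny_genome):
    return extract_markers(tiny_genome.bench, k=K)


@pytest.fixture(scope="session")
def tiny_runs(tiny_genome):
    b = tiny_genome.bench
    return annotate_runs({n: b.seq(n) for n in b.names()})


@pytest.fixture(scope="session")
def tiny_assembly(tiny_genome):
    spec = ErrorSpec(
        subs_per_contig=12, ins_per_contig=6, del_per_contig=6, phase_consistent_per_contig=4, seed=13
    )
    return corrupt_assembly(tiny_genome, spec, k=K)


def identity_segments(bench, prefix="self_"):
    """Perfect self-alignment of the benchmark, one segment per sequence."""
    segs, seqs = [], {}
    for name in bench.names():
        s = bench.seq(name)
        q = prefix + name
        seqs[q] = s
        segs.append(
            AlignmentSegment(
                query=q, q_start=0, q_end=len(s), q_len=len(s), strand="+",
                target_seq=name, t_start=0, t_end=len(s), cigar=[(len(s), "=")], t_len=len(s),
            )
        )
    return segs, seqs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
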