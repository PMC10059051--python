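import numpy as np
import pytest

from isoannot.model import Exon, TranscriptModel
from isoannot.simulate import SimConfig, simulate_flnc, simulate_genome


def make_tx(name, exons, strand="+", chrom="chr1", **kw):
    return TranscriptModel(
        name, chrom, strand, [Exon(a, b) for a, b in exons], **kw
    )


def random_reads(rng, n, chrom_len=10_000, max_exons=4):
    """Random mapped transcripts dense enough for overlaps to be common."""
    reads = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, max_exons + 1))
        exons = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(30, 300))
        reads.append(make_tx(f"r{i}", exons, strand))
    return reads


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, jitter-free 100-gene simulation with reads and collapse."""
    from isoannot.collapse import collapse

    cfg = SimConfig(
        seed=11, n_genes=100, end_jitter_sd=0.0, noise_read_rate=0.0
    )
    ann, genome, truth = simulate_genome(cfg)
    reads = simulate_flnc(ann, truth, cfg)
    result = collapse(reads)
    return cfg, ann, genome, truth, reads, result


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-condition simulation (jitter and noise on)."""
    cfg = SimConfig(seed=23, n_genes=60)
    ann, genome, truth = simulate_genome(cfg)
    reads = simulate_flnc(ann, truth, cfg)
    return cfg, ann, genome, truth, reads


def collapsed_to_truth(result, reads, truth):
    """Map collapsed isoform id -> truth isoform id via read provenance."""
    mapping = {}
    for r in reads:
        iso = result.read_to_isoform.get(r.id)
        if iso is None:
            continue
        mapping.setdefault(iso, set()).add(truth.read_source[r.id])
    return {k: next(iter(v)) for k, v in mapping.items() if len(v) == 1}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
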