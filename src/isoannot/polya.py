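"""Alternative-polyadenylation site clustering and flanking-sequence profiling.

Read 3' ends of a gene (strand-aware terminal coordinates) are clustered by
single linkage: two ends join the same site when they are within
``merge_window`` bp of each other, directly or through intermediates.  The
representative cleavage position of a site is the support-weighted mode of its
member ends (ties broken toward the most distal position in transcription
direction).  Nucleotide composition around each site is profiled on the
transcribed strand over a +/- ``flank`` window, together with a fixed-consensus
scan for the A-run element over-represented downstream of cleavage sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import TranscriptModel, revcomp


@dataclass
class PolyASite:
    gene_id: str
    chrom: str
    strand: str
    position: int
    support: int
    member_end_positions: list[int]


@dataclass
class FlankProfile:
    """Per-offset nucleotide frequencies over [-flank, +flank] and A-run hits.

    Offsets are in transcription direction (negative = upstream of the
    cleavage site).  ``freq`` maps base -> array of length 2*flank + 1; at
    each offset the frequencies over {A, C, G, T, N} sum to 1 (masked
    positions at sequence edges are excluded from the denominators).
    ``element_hit_fraction`` is the fraction of sites whose window contains a
    run of >= ``min_run`` consecutive A.
    """

    flank: int
    freq: dict[str, np.ndarray]
    element_hit_fraction: float
    n_sites: int


def cluster_polya(
    ends: list[int],
    merge_window: int = 24,
    min_site_support: int = 2,
    gene_id: str = "?",
    chrom: str = "?",
    strand: str = "+",
) -> list[PolyASite]:
    """Single-linkage clustering of 3'-end positions into polyA sites."""
    if not ends:
        return []
    ends = sorted(ends)
    clusters: list[list[int]] = [[ends[0]]]
    for e in ends[1:]:
        if e - clusters[-1][-1] <= merge_window:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    sites = []
    for members in clusters:
        if len(members) < min_site_support:
            continue
        counts = Counter(members)
        top = max(counts.values())
        modes = [p for p, c in counts.items() if c == top]
        # most distal = downstream-most in transcription direction
        rep = max(modes) if strand == "+" else min(modes)
        sites.append(
            PolyASite(gene_id, chrom, strand, rep, len(members), members)
        )
    sites.sort(key=lambda s: s.position, reverse=(strand == "-"))
    return sites


def gene_polya_sites(
    gene_id: str,
    reads: list[TranscriptModel],
    merge_window: int = 24,
    min_site_support: int = 2,
) -> list[PolyASite]:
    """Cluster the 3' ends of a gene's assigned reads."""
    if not reads:
        return []
    ends = [r.three_prime_end() for r in reads]
    return cluster_polya(
        ends,
        merge_window,
        min_site_support,
        gene_id=gene_id,
        chrom=reads[0].chrom,
        strand=reads[0].strand,
    )


def apa_summary(sites_per_gene: dict[str, int]) -> dict:
    """Distribution of per-gene site counts.

    Only genes with >= 1 site enter the summary.  The mean is total sites /
    genes, reported to 2 decimals; bin shares (1-9 sites vs >= 10) are
    percentages to 2 decimals (round half up, matching the reporting style
    used throughout the package).
    """
    from .summary import percentage, round2

    counts = {g: n for g, n in sites_per_gene.items() if n >= 1}
    n_genes = len(counts)
    total_sites = sum(counts.values())
    histogram = Counter(counts.values())
    n_1_9 = sum(c for k, c in histogram.items() if 1 <= k <= 9)
    n_10_plus = sum(c for k, c in histogram.items() if k >= 10)
    return {
        "n_genes": n_genes,
        "total_sites": total_sites,
        "mean_sites_per_gene": round2(total_sites / n_genes) if n_genes else 0.0,
        "histogram": dict(sorted(histogram.items())),
        "bin_1_9": n_1_9,
        "bin_1_9_pct": percentage(n_1_9, n_genes),
        "bin_10_plus": n_10_plus,
        "bin_10_plus_pct": percentage(n_10_plus, n_genes),
    }


def _site_flank(site: PolyASite, genome: dict[str, str], flank: int) -> str:
    """Window around a site on the transcribed strand, '.'-masked at edges."""
    seq = genome[site.chrom]
    pos = site.position
    lo, hi = pos - flank, pos + flank + 1
    window = (
        "." * max(0, -lo)
        + seq[max(0, lo) : min(len(seq), hi)].upper()
        + "." * max(0, hi - len(seq))
    )
    if site.strand == "-":
        window = revcomp(window.replace(".", "N")).replace("N", ".")
    return window


def flank_profile(
    sites: list[PolyASite],
    genome: dict[str, str],
    flank: int = 50,
    min_run: int = 10,
) -> FlankProfile:
    """Composition and A-run element scan around polyA sites."""
    width = 2 * flank + 1
    counts = {b: np.zeros(width) for b in "ACGTN"}
    denom = np.zeros(width)
    hits = 0
    for site in sites:
        window = _site_flank(site, genome, flank)
        for i, base in enumerate(window):
            if base == ".":
                continue
            counts.get(base, counts["N"])[i] += 1
            denom[i] += 1
        if "A" * min_run in window:
            hits += 1
    freq = {}
    safe = np.where(denom > 0, denom, 1.0)
    for b in "ACGTN":
        freq[b] = counts[b] / safe
    return FlankProfile(
        flank=flank,
        freq=freq,
        element_hit_fraction=hits / len(sites) if sites else 0.0,
        n_sites=len(sites),
    )


def write_sites_bed(sites: list[PolyASite], path) -> None:
    """BED6 of sites, score = read support."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.position)):
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.gene_id}"
                f"\t{s.support}\t{s.strand}\n"
            )
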