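"""Synthetic full-length transcriptome data with known ground truth.

The generator builds a toy single-chromosome genome annotation in which every
downstream stage's assumptions are planted explicitly: multi-isoform genes
whose isoforms differ by exactly one typed splicing event each, several
polyadenylation sites per gene with an A-rich element planted downstream of
each cleavage position, noncoding transcripts in each of the four positional
classes, full-length reads with truncated end jitter and intergenic mono-exon
noise, and negative-binomial count matrices with planted fold changes.  Every
draw is a function of ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    Annotation,
    Exon,
    GeneLocus,
    TranscriptModel,
)

# gene geometry (bp).  Exon length is a multiple of 3 so that exon skipping
# preserves the reading frame of the planted coding sequence; boundary-shift
# events move splice sites by a multiple of 3 for the same reason.
EXON_LEN = 201
INTRON_LEN = 399
SHIFT = 30          # AA/AD boundary displacement
MEE_LEN = 120       # length of the mutually-exclusive partner exon
MEE_GAP = 99        # offset of the partner exon into the intron
APA_SPACING = 60    # distance between planted cleavage sites (> 2*merge window)
SPACER = 2000       # intergenic spacer between consecutive genes
LNC_LEN = 300       # planted noncoding transcript length

AS_TYPES = ("ES", "IR", "AA", "AD", "MEE")
LNC_CLASSES = ("intronic", "sense", "antisense", "intergenic")


@dataclass
class DeConfig:
    """Two-condition negative-binomial count simulation parameters."""

    n_replicates: int = 5
    dispersion: float = 0.1
    planted_log2fc: tuple[float, ...] = (1.5, 2.0, 3.0, -1.5, -2.0, -3.0)
    fraction_null: float = 0.8
    base_mean: float = 200.0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    seed: int = 0
    n_genes: int = 50
    isoform_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.15, 3: 0.10, 4: 0.08, 5: 0.07}
    )
    as_event_mix: dict[str, float] = field(
        default_factory=lambda: {
            "IR": 0.30, "ES": 0.25, "AA": 0.20, "AD": 0.20, "MEE": 0.05
        }
    )
    apa_sites_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.08, 8: 0.07}
    )
    polya_flank_A_enrichment: float = 0.9
    n_noncoding: dict[str, int] = field(
        default_factory=lambda: {
            "intronic": 10, "sense": 6, "antisense": 4, "intergenic": 6
        }
    )
    end_jitter_sd: float = 5.0
    noise_read_rate: float = 0.05
    samples: tuple[str, ...] = ("queen", "worker", "drone")
    reads_per_isoform_mean: float = 3.0
    sample_presence_prob: float = 0.6
    de_config: DeConfig = field(default_factory=DeConfig)
    chrom: str = "chr1"

    def __post_init__(self):
        for name, dist in (
            ("isoform_count_distribution", self.isoform_count_distribution),
            ("as_event_mix", self.as_event_mix),
            ("apa_sites_per_gene", self.apa_sites_per_gene),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, not 1")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative proportions")
        if not 0 <= self.noise_read_rate < 1:
            raise ValueError("noise_read_rate must be in [0, 1)")
        if any(n < 0 for n in self.n_noncoding.values()):
            raise ValueError("n_noncoding counts must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic files."""

    gene_to_isoforms: dict[str, list[str]] = field(default_factory=dict)
    as_events: list[dict] = field(default_factory=list)
    polya_sites: dict[str, list[int]] = field(default_factory=dict)
    lncrna_class: dict[str, str] = field(default_factory=dict)
    coding_transcripts: set[str] = field(default_factory=set)
    isoform_samples: dict[str, list[str]] = field(default_factory=dict)
    read_source: dict[str, str] = field(default_factory=dict)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    de_status: dict[str, bool] = field(default_factory=dict)

    def event_keys(self) -> set[tuple]:
        return {
            (e["gene"], e["type"], tuple(e["region"]), tuple(e["anchors"]))
            for e in self.as_events
        }

    def to_json(self, path) -> None:
        d = asdict(self)
        d["coding_transcripts"] = sorted(self.coding_transcripts)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _draw(rng, dist: dict):
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


# codon table: the 61 sense codons with a fixed non-uniform usage, so that
# planted coding sequence has hexamer statistics distinct from uniform noise
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _codon_weights(rng) -> np.ndarray:
    w = np.exp(rng.normal(0.0, 1.0, size=len(_SENSE)))
    return w / w.sum()


def _coding_seq(rng, length: int, weights: np.ndarray) -> str:
    """In-frame stopless coding-like sequence of the requested length."""
    n_codons = max(1, length // 3)
    idx = rng.choice(len(_SENSE), size=n_codons, p=weights)
    s = "ATG" + "".join(_SENSE[i] for i in idx)
    return s[:length].ljust(length, "A")


def _variant_isoform(base_exons, ev_type, slot, strand):
    """Apply one planted splicing event at an internal exon slot.

    Returns (variant exon list, truth event dict fields).  Event types are
    defined in transcription direction, so genomic boundary choices flip with
    strand.  The returned region/anchors are the keys the event classifier
    produces for the pair (base, variant).
    """
    ex = list(base_exons)
    s = slot
    if ev_type == "ES":
        region = (ex[s].start, ex[s].end)
        anchors = (ex[s - 1].end, ex[s + 1].start)
        del ex[s]
        return ex, region, anchors, None
    if ev_type == "IR":
        region = (ex[s].end, ex[s + 1].start)
        anchors = (ex[s].start, ex[s + 1].end)
        merged = Exon(ex[s].start, ex[s + 1].end)
        ex[s : s + 2] = [merged]
        # the retained intron becomes exonic: give it coding-like sequence
        return ex, region, anchors, region
    if ev_type == "MEE":
        a = ex[s]
        b = Exon(a.end + MEE_GAP, a.end + MEE_GAP + MEE_LEN)
        region = (a.start, b.end)
        anchors = (ex[s - 1].end, ex[s + 1].start)
        ex[s] = b
        return ex, region, anchors, (b.start, b.end)
    # boundary shifts: AA moves the acceptor, AD the donor, both inward
    # (shrinking the exon so the shifted boundary stays within the gene body)
    move_left = (ev_type == "AA") == (strand == "+")
    if move_left:
        old = ex[s].start
        new = old + SHIFT
        ex[s] = Exon(new, ex[s].end)
        region = (old, new)
        anchors = (ex[s - 1].end, ex[s].end)
    else:
        old = ex[s].end
        new = old - SHIFT
        ex[s] = Exon(ex[s].start, new)
        region = (new, old)
        anchors = (ex[s].start, ex[s + 1].start)
    return ex, region, anchors, None


def simulate_genome(cfg: SimConfig):
    """Generate (truth Annotation, genome dict {chrom: seq}, SimTruth)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    truth = SimTruth()
    codon_w = _codon_weights(rng)
    loci: list[GeneLocus] = []
    cursor = SPACER
    gene_specs = []  # (gene_id, strand, base_exons, k)
    for gi in range(cfg.n_genes):
        gid = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = _draw(rng, cfg.isoform_count_distribution)
        n_events = k - 1
        if n_events:
            m = 2 * n_events + 2
        else:
            m = int(rng.integers(1, 6))
        exons = []
        pos = cursor
        # single-exon mRNAs are realistically long (~600 nt), so their coding
        # signal is not swamped by untranslated 3' extension
        exon_len = 3 * EXON_LEN if m == 1 else EXON_LEN
        for _ in range(m):
            exons.append(Exon(pos, pos + exon_len))
            pos += exon_len + INTRON_LEN
        base_end = exons[-1].end
        gene_specs.append((gid, strand, exons, k))
        # room for 3' APA extension on the + strand side
        cursor = base_end + SPACER

    chrom_len = cursor + SPACER
    seq = rng.choice(list("ACGT"), size=chrom_len)

    for gid, strand, base_exons, k in gene_specs:
        isoforms = [
            TranscriptModel(
                id=f"{gid}.t1",
                chrom=cfg.chrom,
                strand=strand,
                exons=list(base_exons),
                gene_id=gid,
            )
        ]
        fills: list[tuple[int, int]] = []
        slots = list(range(1, 2 * (k - 1), 2))
        for j, slot in enumerate(slots, start=2):
            ev_type = _draw(rng, cfg.as_event_mix)
            ex, region, anchors, fill = _variant_isoform(
                base_exons, ev_type, slot, strand
            )
            if fill is not None:
                fills.append(fill)
            isoforms.append(
                TranscriptModel(
                    id=f"{gid}.t{j}",
                    chrom=cfg.chrom,
                    strand=strand,
                    exons=ex,
                    gene_id=gid,
                )
            )
            truth.as_events.append(
                {
                    "gene": gid,
                    "type": ev_type,
                    "region": list(region),
                    "anchors": list(anchors),
                    "witnesses": [f"{gid}.t1", f"{gid}.t{j}"],
                }
            )
        loci.append(GeneLocus(gid, cfg.chrom, strand, isoforms))
        truth.gene_to_isoforms[gid] = [t.id for t in isoforms]
        truth.coding_transcripts.update(t.id for t in isoforms)

        # planted polyadenylation sites: the annotated 3' end plus extensions
        # marching downstream into the spacer
        n_sites = _draw(rng, cfg.apa_sites_per_gene)
        if strand == "+":
            end3 = base_exons[-1].end
            sites = [end3 + APA_SPACING * j for j in range(n_sites)]
        else:
            end3 = base_exons[0].start
            sites = [end3 - APA_SPACING * j for j in range(n_sites)]
        truth.polya_sites[gid] = sites
        for site in sites:
            lo, hi = (site, site + 10) if strand == "+" else (site - 10, site)
            base = "A" if strand == "+" else "T"
            mask = rng.random(hi - lo) < cfg.polya_flank_A_enrichment
            window = rng.choice(list("ACGT"), size=hi - lo)
            window[mask] = base
            seq[lo:hi] = window

        # write coding-like sequence into the base isoform's exons
        # (transcribed-strand order)
        total = sum(len(e) for e in base_exons)
        cds = _coding_seq(rng, total, codon_w)
        if strand == "-":
            from .model import revcomp

            cds = revcomp(cds)
        off = 0
        for e in base_exons:
            seq[e.start : e.end] = list(cds[off : off + len(e)])
            off += len(e)
        # regions exonic only in variant isoforms (retained introns, MEE
        # partner exons) also carry coding-like sequence
        for lo, hi in fills:
            piece = _coding_seq(rng, hi - lo, codon_w)
            if strand == "-":
                from .model import revcomp

                piece = revcomp(piece)
            seq[lo:hi] = list(piece)

    # noncoding transcripts in the four positional classes
    multi_exon_hosts = sorted(
        (s for s in gene_specs if len(s[2]) >= 2), key=lambda s: s[0]
    )
    host_cursor = 0

    reuse_count: dict[tuple[str, str], int] = {}

    def next_host(cls):
        # prefer a host unused for this class; fall back to reuse with a
        # positional offset so repeated placements stay distinct
        nonlocal host_cursor
        if not multi_exon_hosts:
            raise ValueError(
                "gene-hosted noncoding transcripts need >= 1 multi-exon gene; "
                "increase n_genes"
            )
        for _ in range(len(multi_exon_hosts)):
            host = multi_exon_hosts[host_cursor % len(multi_exon_hosts)]
            host_cursor += 1
            if (host[0], cls) not in used_hosts:
                used_hosts.add((host[0], cls))
                return host, 0
        host = multi_exon_hosts[host_cursor % len(multi_exon_hosts)]
        host_cursor += 1
        n = reuse_count.get((host[0], cls), 0) + 1
        reuse_count[(host[0], cls)] = n
        return host, min(n * 24, 48)
    spacer_slots = [
        (spec[2][-1].end + SPACER // 4, spec[0]) for spec in gene_specs
    ]
    li = 0
    used_hosts: set[tuple[str, str]] = set()
    for cls in LNC_CLASSES:
        for _ in range(cfg.n_noncoding.get(cls, 0)):
            li += 1
            lid = f"L{li:03d}"
            if cls == "intergenic":
                base_pos = spacer_slots[li % len(spacer_slots)][0]
                start = base_pos + (li % 3) * (LNC_LEN + 10)
                strand = "+" if rng.random() < 0.5 else "-"
                exons = [Exon(start, start + LNC_LEN)]
            else:
                host, shift = next_host(cls)
                hid, hstrand, hexons, _k = host
                if cls == "intronic":
                    # strictly inside the first intron of the host
                    s0 = hexons[0].end + 50 + shift
                    exons = [Exon(s0, s0 + LNC_LEN)]
                    strand = "+" if rng.random() < 0.5 else "-"
                elif cls == "sense":
                    # 60 bp of exonic overlap: enough to class as sense, small
                    # enough that the coding hexamer signal does not dominate
                    s0 = hexons[0].end - 60 - shift
                    exons = [Exon(s0, s0 + LNC_LEN)]
                    strand = hstrand
                else:  # antisense
                    s0 = hexons[0].end - 60 - shift
                    exons = [Exon(s0, s0 + LNC_LEN)]
                    strand = "-" if hstrand == "+" else "+"
            t = TranscriptModel(
                id=f"{lid}.t1",
                chrom=cfg.chrom,
                strand=strand,
                exons=exons,
                gene_id=lid,
            )
            loci.append(GeneLocus(lid, cfg.chrom, strand, [t]))
            truth.gene_to_isoforms[lid] = [t.id]
            truth.lncrna_class[t.id] = cls
            truth.polya_sites[lid] = [t.three_prime_end()]

    ann = Annotation(loci)
    genome = {cfg.chrom: "".join(seq)}
    return ann, genome, truth


def simulate_flnc(
    ann: Annotation, truth: SimTruth, cfg: SimConfig
) -> list[TranscriptModel]:
    """Simulated mapped full-length reads: jittered isoform copies plus noise.

    End jitter is truncated so it never crosses a splice junction, and the 3'
    end of each read sits at one of the gene's planted cleavage sites (plus
    jitter).  Intergenic mono-exon noise reads are added so that they make up
    about ``noise_read_rate`` of the output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    reads: list[TranscriptModel] = []
    n = 0
    for gene in ann:
        sites = truth.polya_sites.get(gene.id, [])
        for iso in gene.members:
            present = [
                s for s in cfg.samples if rng.random() < cfg.sample_presence_prob
            ]
            if not present:
                present = [cfg.samples[int(rng.integers(len(cfg.samples)))]]
            truth.isoform_samples[iso.id] = list(present)
            for sample in present:
                for _ in range(1 + rng.poisson(cfg.reads_per_isoform_mean - 1)):
                    n += 1
                    rid = f"read{n:06d}"
                    reads.append(
                        _make_read(rng, iso, sites, sample, rid, cfg)
                    )
                    truth.read_source[rid] = iso.id
    n_signal = len(reads)
    rate = cfg.noise_read_rate
    if rate > 0:
        n_noise = rng.binomial(int(round(n_signal / (1.0 - rate))), rate)
    else:
        n_noise = 0
    spacer_noise_zones = [
        g.end + SPACER // 2 for g in ann if not g.id.startswith("L")
    ]
    for j in range(n_noise):
        n += 1
        rid = f"noise{n:06d}"
        base = spacer_noise_zones[int(rng.integers(len(spacer_noise_zones)))]
        start = base + int(rng.integers(0, 200))
        length = int(rng.integers(150, 350))
        reads.append(
            TranscriptModel(
                id=rid,
                chrom=cfg.chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=[Exon(start, start + length)],
                source_sample=cfg.samples[int(rng.integers(len(cfg.samples)))],
            )
        )
        truth.read_source[rid] = "noise"
    return reads


def _make_read(rng, iso, sites, sample, rid, cfg):
    exons = [Exon(e.start, e.end) for e in iso.exons]
    sd = cfg.end_jitter_sd
    j5 = int(round(rng.normal(0, sd))) if sd > 0 else 0
    j3 = int(round(rng.normal(0, sd))) if sd > 0 else 0
    site = sites[int(rng.integers(len(sites)))] if sites else None
    if iso.strand == "+":
        first, last = exons[0], exons[-1]
        end3 = (site if site is not None else last.end) + j3
        end3 = max(end3, last.start + 1)
        start5 = first.start + j5
        start5 = min(max(0, start5), first.end - 1)
        if len(exons) == 1:
            end3 = max(end3, start5 + 1)
            exons[0] = Exon(start5, end3)
        else:
            exons[0] = Exon(start5, first.end)
            exons[-1] = Exon(last.start, end3)
    else:
        first, last = exons[0], exons[-1]
        end3 = (site if site is not None else first.start) + j3
        end3 = min(end3, first.end - 1)
        start5 = last.end + j5
        start5 = max(start5, last.start + 1)
        if len(exons) == 1:
            end3 = min(end3, start5 - 1)
            exons[0] = Exon(end3, start5)
        else:
            exons[0] = Exon(end3, first.end)
            exons[-1] = Exon(last.start, start5)
    return TranscriptModel(
        id=rid,
        chrom=iso.chrom,
        strand=iso.strand,
        exons=exons,
        source_sample=sample,
    )


def simulate_counts(
    truth: SimTruth, de_cfg: DeConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Two-condition NB count matrix (transcripts x samples) with planted DE.

    A ``1 - fraction_null`` share of transcripts receives a log2 fold change
    drawn from ``planted_log2fc`` (applied to condition 2); the rest are null.
    Gene-level truth is the union of member-transcript statuses.
    """
    de_cfg = de_cfg or DeConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence(seed if seed is not None else 0).spawn(3)[2]
    )
    tids = [t for tids in truth.gene_to_isoforms.values() for t in tids]
    nrep = de_cfg.n_replicates
    cols = [f"C1_r{i+1}" for i in range(nrep)] + [
        f"C2_r{i+1}" for i in range(nrep)
    ]
    rows = []
    for tid in tids:
        mu1 = rng.lognormal(np.log(de_cfg.base_mean), 1.0)
        if rng.random() < de_cfg.fraction_null:
            lfc = 0.0
        else:
            lfc = float(
                de_cfg.planted_log2fc[
                    int(rng.integers(len(de_cfg.planted_log2fc)))
                ]
            )
        truth.de_log2fc[tid] = lfc
        truth.de_status[tid] = lfc != 0.0
        mu2 = mu1 * 2.0 ** lfc
        r = 1.0 / de_cfg.dispersion
        c1 = rng.negative_binomial(r, r / (r + mu1), size=nrep)
        c2 = rng.negative_binomial(r, r / (r + mu2), size=nrep)
        rows.append(np.concatenate([c1, c2]))
    return pd.DataFrame(rows, index=tids, columns=cols)


def simulate_switch_counts(
    n_switch: int = 50,
    n_stable: int = 50,
    mean: float = 2000.0,
    n_replicates: int = 5,
    dispersion: float = 0.005,
    seed: int = 0,
):
    """Isoform-switch scenario: per-gene expression is constant but the two
    isoforms swap their usage between conditions.

    Returns (counts DataFrame, transcript→gene map, set of switch gene ids).
    Transcript-level tests should flag the switch genes while gene-level
    aggregation cancels the signal.
    """
    rng = np.random.default_rng(seed)
    rows, index, tx2gene, switch = [], [], {}, set()
    nrep = n_replicates
    r = 1.0 / dispersion
    for gi in range(n_switch + n_stable):
        gid = f"SW{gi + 1:04d}"
        is_switch = gi < n_switch
        if is_switch:
            switch.add(gid)
            mus = [(0.8 * mean, 0.2 * mean), (0.2 * mean, 0.8 * mean)]
        else:
            mus = [(0.5 * mean, 0.5 * mean), (0.5 * mean, 0.5 * mean)]
        for ti, (m1, m2) in enumerate(mus, 1):
            tid = f"{gid}.t{ti}"
            tx2gene[tid] = gid
            c1 = rng.negative_binomial(r, r / (r + m1), size=nrep)
            c2 = rng.negative_binomial(r, r / (r + m2), size=nrep)
            rows.append(np.concatenate([c1, c2]))
            index.append(tid)
    cols = [f"C1_r{i+1}" for i in range(nrep)] + [
        f"C2_r{i+1}" for i in range(nrep)
    ]
    return pd.DataFrame(rows, index=index, columns=cols), tx2gene, switch


def withhold(
    ann: Annotation,
    truth: SimTruth,
    gene_fraction: float = 0.2,
    isoform_fraction: float = 0.2,
    seed: int = 0,
):
    """Build a reference annotation that omits a subset of the truth.

    Whole genes are dropped with probability ``gene_fraction``.  Within the
    retained multi-isoform genes, isoforms are dropped with probability
    ``isoform_fraction`` — but only isoforms that carry at least one splice
    junction absent from the retained set (so that, under the junction-level
    novelty rule, the withheld set is exactly the set recoverable as novel;
    an intron-retention variant, whose junctions are a subset of its base
    isoform's, can never be recovered and is never withheld).

    Returns (reference Annotation, withheld gene ids, withheld transcript ids).
    """
    rng = np.random.default_rng(seed)
    kept_genes: list[GeneLocus] = []
    dropped_genes: set[str] = set()
    dropped_tx: set[str] = set()
    for gene in ann:
        if rng.random() < gene_fraction:
            dropped_genes.add(gene.id)
            dropped_tx.update(t.id for t in gene.members)
            continue
        members = list(gene.members)
        if len(members) > 1:
            keep = list(members)
            for t in sorted(members, key=lambda t: t.id, reverse=True):
                if len(keep) == 1:
                    break
                if rng.random() >= isoform_fraction:
                    continue
                others = [u for u in keep if u.id != t.id]
                retained_junctions = {
                    iv for u in others for iv in u.intron_chain
                }
                if any(
                    iv not in retained_junctions for iv in t.intron_chain
                ):
                    keep = others
                    dropped_tx.add(t.id)
            members = keep
        kept_genes.append(
            GeneLocus(gene.id, gene.chrom, gene.strand, members)
        )
    return Annotation(kept_genes), dropped_genes, dropped_tx
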