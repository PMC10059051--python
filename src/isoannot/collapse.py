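"""Grouping of mapped full-length reads into gene loci and non-redundant isoforms.

Two mapped reads belong to the same gene when they lie on the same chromosome
and strand, their genomic spans overlap by more than a span threshold, and at
least one exon pair overlaps by more than an exon threshold (both thresholds
default to 20%, strict inequality).  Gene loci are the connected components of
this pairwise relation (built with union-find, so the result is independent of
read order).  Within a locus, multi-exon reads with the same intron chain are
merged into one isoform whose ends are the extreme observed read ends, and
mono-exon reads merge by containment within an end tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GeneLocus, TranscriptModel


@dataclass(frozen=True)
class SameGeneRule:
    """Thresholds of the same-gene relation.

    The overlap fraction is taken over the SHORTER of the two features, the
    symmetric choice and the strictest one for nested fragments; both
    thresholds use strict ``>``.
    """

    min_span_overlap_fraction: float = 0.20
    min_exon_overlap_fraction: float = 0.20
    require_same_strand: bool = True

    def __post_init__(self):
        for f in (self.min_span_overlap_fraction, self.min_exon_overlap_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"overlap fraction {f} outside [0, 1]")


def span_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """|a ∩ b| / min(|a|, |b|); 0 for disjoint intervals."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValueError(f"empty interval in {a} / {b}")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return inter / min(a1 - a0, b1 - b0)


def same_gene(
    t1: TranscriptModel, t2: TranscriptModel, rule: SameGeneRule | None = None
) -> bool:
    """The pairwise same-gene relation (symmetric)."""
    rule = rule or SameGeneRule()
    if t1.chrom != t2.chrom:
        return False
    if rule.require_same_strand and t1.strand != t2.strand:
        return False
    if span_overlap_fraction(t1.span, t2.span) <= rule.min_span_overlap_fraction:
        return False
    thr = rule.min_exon_overlap_fraction
    # sorted exon chains: sweep instead of full cross product
    i = j = 0
    e1, e2 = t1.exons, t2.exons
    while i < len(e1) and j < len(e2):
        a, b = e1[i], e2[j]
        inter = min(a.end, b.end) - max(a.start, b.start)
        if inter > 0 and inter / min(len(a), len(b)) > thr:
            return True
        if a.end <= b.end:
            i += 1
        else:
            j += 1
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_loci(
    reads: list[TranscriptModel], rule: SameGeneRule | None = None
) -> list[GeneLocus]:
    """Connected components of the same-gene graph, as :class:`GeneLocus` list.

    Locus ids are assigned deterministically in (chrom, start) order
    (``PB.1``, ``PB.2``, ...).
    """
    rule = rule or SameGeneRule()
    uf = _UnionFind(len(reads))
    # group by (chrom, strand); only span-overlapping pairs can be related
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(reads):
        key = (r.chrom, r.strand if rule.require_same_strand else ".")
        groups.setdefault(key, []).append(i)
    for idxs in groups.values():
        idxs.sort(key=lambda i: reads[i].start)
        active: list[int] = []
        for i in idxs:
            ri = reads[i]
            active = [j for j in active if reads[j].end > ri.start]
            for j in active:
                if same_gene(ri, reads[j], rule):
                    uf.union(i, j)
            active.append(i)
    comps: dict[int, list[int]] = {}
    for i in range(len(reads)):
        comps.setdefault(uf.find(i), []).append(i)
    members = [
        [reads[i] for i in idxs] for idxs in comps.values()
    ]
    members.sort(key=lambda ms: (ms[0].chrom, min(t.start for t in ms)))
    loci = []
    for k, ms in enumerate(members, 1):
        ms = sorted(ms, key=lambda t: (t.start, t.end, t.id))
        loci.append(GeneLocus(f"PB.{k}", ms[0].chrom, ms[0].strand, ms))
    return loci


def collapse_isoforms(
    locus: GeneLocus,
    mono_end_tolerance: int = 20,
    min_support: int = 1,
) -> list[TranscriptModel]:
    """Collapse a locus' reads into non-redundant isoforms with support.

    Multi-exon reads sharing an intron chain merge into one isoform spanning
    the extreme 5'/3' read ends.  Mono-exon reads merge into a representative
    when contained in it within ``mono_end_tolerance`` bp at each end; the
    representatives carry the union span of their merged reads.  Isoforms with
    fewer than ``min_support`` reads are dropped.
    """
    from .model import Exon

    multi: dict[tuple, list[TranscriptModel]] = {}
    mono: list[TranscriptModel] = []
    for t in locus.members:
        if t.is_mono_exon():
            mono.append(t)
        else:
            multi.setdefault(t.intron_chain, []).append(t)

    isoforms: list[TranscriptModel] = []
    n = 0
    for chain in sorted(multi):
        group = multi[chain]
        n += 1
        start = min(t.start for t in group)
        end = max(t.end for t in group)
        exons = [Exon(start, chain[0][0])]
        exons += [
            Exon(a[1], b[0]) for a, b in zip(chain, chain[1:])
        ]
        exons.append(Exon(chain[-1][1], end))
        isoforms.append(
            TranscriptModel(
                id=f"{locus.id}.{n}",
                chrom=locus.chrom,
                strand=locus.strand,
                exons=exons,
                support=sum(t.support for t in group),
                samples=set().union(*(t.samples for t in group)),
                gene_id=locus.id,
            )
        )

    # mono-exon: longest-first greedy containment merging, iterated to a
    # fixpoint so representatives are mutually non-contained (idempotence)
    reps = [[t] for t in mono]
    changed = True
    while changed:
        changed = False
        spans = [
            (min(u.start for u in g), max(u.end for u in g), g) for g in reps
        ]
        spans.sort(key=lambda x: (-(x[1] - x[0]), x[0], x[2][0].id))
        merged_reps: list[list[TranscriptModel]] = []
        for s, e, g in spans:
            placed = False
            for h in merged_reps:
                hs = min(u.start for u in h)
                he = max(u.end for u in h)
                if s >= hs - mono_end_tolerance and e <= he + mono_end_tolerance:
                    h.extend(g)
                    placed = True
                    changed = True
                    break
            if not placed:
                merged_reps.append(list(g))
        reps = merged_reps
    reps.sort(key=lambda g: (min(u.start for u in g), min(u.id for u in g)))
    for group in reps:
        n += 1
        start = min(u.start for u in group)
        end = max(u.end for u in group)
        isoforms.append(
            TranscriptModel(
                id=f"{locus.id}.{n}",
                chrom=locus.chrom,
                strand=locus.strand,
                exons=[Exon(start, end)],
                support=sum(u.support for u in group),
                samples=set().union(*(u.samples for u in group)),
                gene_id=locus.id,
            )
        )
    isoforms = [t for t in isoforms if t.support >= min_support]
    return sorted(isoforms, key=lambda t: (t.start, t.end, t.id))


@dataclass
class CollapseResult:
    """Loci, non-redundant isoforms and the read→isoform assignment."""

    loci: list[GeneLocus]
    isoforms: list[TranscriptModel]
    read_to_isoform: dict[str, str] = field(default_factory=dict)

    @property
    def isoform_loci(self) -> list[GeneLocus]:
        """Loci whose members are the collapsed isoforms (not the raw reads)."""
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.isoforms:
            by_gene.setdefault(t.gene_id, []).append(t)
        out = []
        for locus in self.loci:
            members = by_gene.get(locus.id, [])
            if members:
                out.append(
                    GeneLocus(locus.id, locus.chrom, locus.strand, members)
                )
        return out


def collapse(
    reads: list[TranscriptModel],
    rule: SameGeneRule | None = None,
    mono_end_tolerance: int = 20,
    min_support: int = 1,
) -> CollapseResult:
    """Full collapse: loci from reads, then non-redundant isoforms per locus."""
    loci = build_loci(reads, rule)
    isoforms: list[TranscriptModel] = []
    read_map: dict[str, str] = {}
    for locus in loci:
        isos = collapse_isoforms(locus, mono_end_tolerance, min_support)
        isoforms.extend(isos)
        for read in locus.members:
            target = _assign_read(read, isos, mono_end_tolerance)
            if target is not None:
                read_map[read.id] = target
    return CollapseResult(loci=loci, isoforms=isoforms, read_to_isoform=read_map)


def _assign_read(read, isoforms, tol) -> str | None:
    if read.is_mono_exon():
        for iso in isoforms:
            if iso.is_mono_exon() and (
                read.start >= iso.start - tol and read.end <= iso.end + tol
            ):
                return iso.id
    else:
        for iso in isoforms:
            if iso.intron_chain == read.intron_chain:
                return iso.id
    return None
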