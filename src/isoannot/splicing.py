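"""Alternative-splicing event extraction and typing between isoform pairs.

Events are extracted Astalavista-style: within the genomic region shared by
two isoforms of a locus, variants are the maximal regions between consecutive
*anchors* (splice sites present in both isoforms, plus the common-span
endpoints) where the two exon-intron structures disagree.  Each variant is
typed from the pair of local structures:

======  =========================================  =====================
type    structure A vs structure B (genomic)       meaning
======  =========================================  =====================
ES      intron  vs  intron-exon-intron             exon skipping
IR      exon    vs  exon-intron-exon               intron retention
AD/AA   exon-intron vs exon-intron (moved site)    alternative donor/
        or intron-exon vs intron-exon              acceptor (strand-aware:
                                                   donor = 5' splice site)
MEE     intron-exon-intron on both sides,          mutually exclusive
        disjoint exons                             exons
======  =========================================  =====================

Anything else is labelled ``complex`` and excluded from the five-type table.
Differences adjacent to an unshared common-span endpoint are terminal
(TSS/polyadenylation) variation, not splicing events, and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .model import GeneLocus, TranscriptModel

EVENT_TYPES = ("ES", "IR", "AA", "AD", "MEE")


@dataclass(frozen=True)
class AsEvent:
    gene_id: str
    type: str
    region: tuple[int, int]
    anchors: tuple[int, int]
    witnesses: tuple[str, str]

    @property
    def key(self) -> tuple:
        """Deduplication key: (gene, type, region, anchors)."""
        return (self.gene_id, self.type, self.region, self.anchors)


def _blocks(t: TranscriptModel, lo: int, hi: int) -> list[tuple[str, int, int]]:
    """Exon/intron blocks of a transcript clipped to [lo, hi)."""
    out = []
    pieces = [("E", e.start, e.end) for e in t.exons]
    pieces += [("I", s, e) for s, e in t.introns]
    for kind, s, e in sorted(pieces, key=lambda p: p[1]):
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((kind, s2, e2))
    return out


def _pattern(blocks) -> str:
    return "".join(b[0] for b in blocks)


def _classify_variant(b1, b2, strand: str) -> tuple[str, tuple[int, int]] | None:
    """Type one variant from the two local block structures.

    Returns (event type, variant region) or None when the pair is complex.
    """
    p1, p2 = _pattern(b1), _pattern(b2)
    if {p1, p2} == {"I", "IEI"}:
        exon = (b1 if p1 == "IEI" else b2)[1]
        return "ES", (exon[1], exon[2])
    if {p1, p2} == {"E", "EIE"}:
        intron = (b1 if p1 == "EIE" else b2)[1]
        return "IR", (intron[1], intron[2])
    if p1 == p2 == "EI":
        x1, x2 = b1[0][2], b2[0][2]
        if x1 == x2:
            return None
        return ("AD" if strand == "+" else "AA"), (min(x1, x2), max(x1, x2))
    if p1 == p2 == "IE":
        x1, x2 = b1[0][2], b2[0][2]
        if x1 == x2:
            return None
        return ("AA" if strand == "+" else "AD"), (min(x1, x2), max(x1, x2))
    if p1 == p2 == "IEI":
        e1 = (b1[1][1], b1[1][2])
        e2 = (b2[1][1], b2[1][2])
        if e1 == e2:
            return None
        if e1[1] <= e2[0] or e2[1] <= e1[0]:
            lo = min(e1[0], e2[0])
            hi = max(e1[1], e2[1])
            return "MEE", (lo, hi)
        return "complex", None
    return "complex", None


def pairwise_events(
    t1: TranscriptModel, t2: TranscriptModel, gene_id: str | None = None
) -> list[AsEvent]:
    """All typed splicing differences between two isoforms (symmetric)."""
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError(
            f"{t1.id} and {t2.id} are not on the same chromosome/strand"
        )
    gene_id = gene_id or t1.gene_id or "?"
    lo = max(t1.start, t2.start)
    hi = min(t1.end, t2.end)
    if lo >= hi:
        return []
    shared = sorted(
        x for x in (t1.splice_sites & t2.splice_sites) if lo < x < hi
    )
    anchors = [lo] + shared + [hi]
    witnesses = tuple(sorted((t1.id, t2.id)))
    events: list[AsEvent] = []
    for L, R in zip(anchors, anchors[1:]):
        b1 = _blocks(t1, L, R)
        b2 = _blocks(t2, L, R)
        if _pattern(b1) == _pattern(b2) and b1 == b2:
            continue
        # terminal variation: a disagreement flush against an unshared
        # common-span endpoint is TSS/3'-end variation, not splicing
        if L == lo and L not in shared and t1.start != t2.start:
            if b1 and b2 and b1[0][0] != b2[0][0]:
                continue
        if R == hi and R not in shared and t1.end != t2.end:
            if b1 and b2 and b1[-1][0] != b2[-1][0]:
                continue
        typed = _classify_variant(b1, b2, t1.strand)
        if typed is None:
            continue
        ev_type, region = typed
        if ev_type == "complex":
            region = (L, R)
        events.append(
            AsEvent(gene_id, ev_type, region, (L, R), witnesses)
        )
    return events


def gene_events(locus: GeneLocus) -> list[AsEvent]:
    """Union of pairwise events over all isoform pairs, deduplicated by key."""
    seen: dict[tuple, AsEvent] = {}
    members = sorted(locus.members, key=lambda t: t.id)
    for t1, t2 in combinations(members, 2):
        for ev in pairwise_events(t1, t2, locus.id):
            seen.setdefault(ev.key, ev)
    return sorted(seen.values(), key=lambda e: (e.region, e.type))


def event_counts(events, include_complex: bool = False) -> dict[str, int]:
    """Per-type event counts over the five canonical types."""
    counts = {t: 0 for t in EVENT_TYPES}
    if include_complex:
        counts["complex"] = 0
    for e in events:
        if e.type in counts:
            counts[e.type] += 1
    return counts


def genes_with_events(all_events) -> dict[str, int]:
    """Number of distinct genes containing >= 1 event of each type."""
    by_type: dict[str, set] = {t: set() for t in EVENT_TYPES}
    for e in all_events:
        if e.type in by_type:
            by_type[e.type].add(e.gene_id)
    return {t: len(g) for t, g in by_type.items()}


def count_by_sample(
    loci: list[GeneLocus], samples: list[str]
) -> dict[str, list[AsEvent]]:
    """Events per sample (on sample-restricted isoform sets) and combined.

    The combined analysis runs on the full pooled isoform set, so the
    combined count is at least each per-sample count but need not equal the
    per-sample sum: an event whose two witnesses were seen in different
    samples appears only in the combined analysis.
    """
    out: dict[str, list[AsEvent]] = {}
    for sample in samples:
        evs: list[AsEvent] = []
        for locus in loci:
            members = [t for t in locus.members if sample in t.samples]
            if len(members) < 2:
                continue
            sub = GeneLocus(locus.id, locus.chrom, locus.strand, members)
            evs.extend(gene_events(sub))
        out[sample] = evs
    combined: list[AsEvent] = []
    for locus in loci:
        combined.extend(gene_events(locus))
    out["combined"] = combined
    return out
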