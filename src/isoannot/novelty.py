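"""Known/novel classification of collapsed loci and isoforms against a reference.

A collapsed locus is a novel gene when it has no (or at most threshold)
span overlap with any annotated gene, or when its best-overlapping annotated
gene lies on the opposite strand.  An isoform of a known gene is a novel
transcript when it carries a splice junction absent from every reference
isoform of that gene, or when exactly one of the pair (isoform, reference
gene's isoforms) is single-exon.

``site_level`` controls what counts as a new splicing site: ``"junction"``
(default) treats each intron as a (donor, acceptor) pair, so an exon-skipping
isoform that joins two known boundaries into an unannotated intron is novel;
``"boundary"`` compares individual donor/acceptor coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .collapse import SameGeneRule, span_overlap_fraction
from .model import Annotation, GeneLocus, TranscriptModel


@dataclass(frozen=True)
class NoveltyCall:
    feature_id: str
    level: str  # "gene" | "transcript"
    call: str  # "known" | "novel"
    reason: str  # no_overlap | low_overlap | opposite_strand |
    #              new_splice_site | single_exon_mismatch | matched
    matched_reference_id: str | None = None


def classify_gene(
    locus: GeneLocus, ref: Annotation, rule: SameGeneRule | None = None
) -> NoveltyCall:
    """Novel-gene criteria: low/no overlap, or overlap only in antisense."""
    rule = rule or SameGeneRule()
    thr = rule.min_span_overlap_fraction
    span = locus.span
    candidates = ref.query(locus.chrom, *span)
    best = None  # ((overlap, same_strand, reciprocal overlap, -start), gene)
    for g in candidates:
        ov = span_overlap_fraction(span, g.span)
        if ov <= 0:
            continue
        # among equally-overlapping candidates (the shorter-feature fraction
        # saturates at 1.0 for nested genes) prefer the more reciprocal match
        inter = min(span[1], g.end) - max(span[0], g.start)
        ov_ref = inter / max(span[1] - span[0], g.end - g.start)
        key = (ov, g.strand == locus.strand, ov_ref, -g.start)
        if best is None or key > best[0]:
            best = (key, g)
    if best is None:
        return NoveltyCall(locus.id, "gene", "novel", "no_overlap")
    (ov, same_strand, _, _), g = best
    if ov <= thr:
        return NoveltyCall(locus.id, "gene", "novel", "low_overlap")
    if not same_strand:
        return NoveltyCall(locus.id, "gene", "novel", "opposite_strand")
    return NoveltyCall(locus.id, "gene", "known", "matched", g.id)


def _reference_junctions(ref_gene: GeneLocus) -> set[tuple[int, int]]:
    return {iv for t in ref_gene.members for iv in t.intron_chain}


def _reference_boundaries(ref_gene: GeneLocus) -> set[int]:
    return {x for t in ref_gene.members for x in t.splice_sites}


def classify_transcript(
    iso: TranscriptModel,
    ref_gene: GeneLocus,
    rule: SameGeneRule | None = None,
    site_level: str = "junction",
) -> NoveltyCall:
    """Novel-transcript criteria within a matched known gene."""
    rule = rule or SameGeneRule()
    if site_level not in ("junction", "boundary"):
        raise ValueError(f"site_level {site_level!r}")
    # exact intron-chain identity -> known
    if not iso.is_mono_exon():
        for t in ref_gene.members:
            if not t.is_mono_exon() and t.intron_chain == iso.intron_chain:
                return NoveltyCall(iso.id, "transcript", "known", "matched", t.id)
    if iso.is_mono_exon():
        mono_refs = [t for t in ref_gene.members if t.is_mono_exon()]
        for t in mono_refs:
            if span_overlap_fraction(iso.span, t.span) > rule.min_span_overlap_fraction:
                return NoveltyCall(iso.id, "transcript", "known", "matched", t.id)
        return NoveltyCall(iso.id, "transcript", "novel", "single_exon_mismatch")
    if all(t.is_mono_exon() for t in ref_gene.members):
        return NoveltyCall(iso.id, "transcript", "novel", "single_exon_mismatch")
    if site_level == "junction":
        known = _reference_junctions(ref_gene)
        novel_site = any(iv not in known for iv in iso.intron_chain)
    else:
        known_b = _reference_boundaries(ref_gene)
        novel_site = any(x not in known_b for x in iso.splice_sites)
    if novel_site:
        return NoveltyCall(iso.id, "transcript", "novel", "new_splice_site")
    # all junctions annotated but no single reference isoform matches the
    # full chain: attribute to the reference isoform sharing most junctions
    best = max(
        (t for t in ref_gene.members if not t.is_mono_exon()),
        key=lambda t: (
            len(set(t.intron_chain) & set(iso.intron_chain)),
            -t.start,
        ),
    )
    return NoveltyCall(iso.id, "transcript", "known", "matched", best.id)


def classify_all(
    loci: list[GeneLocus],
    isoforms: list[TranscriptModel],
    ref: Annotation,
    rule: SameGeneRule | None = None,
    site_level: str = "junction",
) -> list[NoveltyCall]:
    """Gene- and transcript-level calls for a collapsed dataset.

    Isoforms of a novel gene are novel transcripts by inheritance (same
    reason as their gene), so a transcript of a novel gene is never known.
    """
    rule = rule or SameGeneRule()
    calls: list[NoveltyCall] = []
    gene_call: dict[str, NoveltyCall] = {}
    for locus in loci:
        c = classify_gene(locus, ref, rule)
        gene_call[locus.id] = c
        calls.append(c)
    for iso in isoforms:
        gc = gene_call.get(iso.gene_id)
        if gc is None:
            raise ValueError(f"isoform {iso.id} not assigned to any locus")
        if gc.call == "novel":
            calls.append(
                NoveltyCall(iso.id, "transcript", "novel", gc.reason)
            )
        else:
            calls.append(
                classify_transcript(
                    iso, ref[gc.matched_reference_id], rule, site_level
                )
            )
    return calls


def novelty_table(calls: list[NoveltyCall]):
    """Calls as a pandas DataFrame (feature_id, level, call, reason, match)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "level": c.level,
                "call": c.call,
                "reason": c.reason,
                "matched_reference_id": c.matched_reference_id or "",
            }
            for c in calls
        ]
    )
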