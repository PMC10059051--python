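"""Noncoding-transcript calling and positional classification.

Coding potential is scored with a built-in heuristic: the longest open reading
frame over the three forward frames (transcripts are already stranded) plus a
hexamer log-likelihood-ratio score against a 6-mer model trained on the run's
reference coding sequences (pseudocount 1, uniform background).  This
heuristic deliberately mirrors the logic of the standard coding-potential
tools but is not equivalent to them; external per-transcript calls can be
substituted via ``external_calls``.

A transcript is called noncoding when its longest ORF is below
``orf_min_codons`` AND its hexamer score is below ``score_threshold`` AND it
is at least ``min_lnc_length`` nt long (the community-standard 200 nt / 100
codon thresholds by default).

Noncoding transcripts are then placed into one of four positional classes
against the reference annotation, in precedence order: intronic (entirely
within a single intron of a reference transcript, either strand), sense
(exonic overlap with a same-strand reference gene), antisense (exonic overlap
opposite strand), intergenic (no overlap with any reference gene span).
Intronic outranks sense/antisense so that intron-contained transcripts form a
class disjoint from the exon-overlapping ones.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .model import Annotation, TranscriptModel

START = "ATG"
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodingCall:
    transcript_id: str
    orf_codons: int
    hexamer_score: float
    call: str  # "coding" | "noncoding"


@dataclass(frozen=True)
class PositionClass:
    transcript_id: str
    position_class: str  # intronic | sense | antisense | intergenic
    anchor_gene_id: str | None


def longest_orf(seq: str) -> int:
    """Longest ORF in codons over the 3 forward frames.

    An ORF starts at ATG and runs to the first in-frame stop, or to the end
    of the sequence (open 3' end) — the stop codon is not counted.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == START:
                j = i
                while j < len(codons) and codons[j] not in STOPS:
                    j += 1
                best = max(best, j - i)
                i = j
            i += 1
    return best


class HexamerModel:
    """6-mer log-likelihood ratio of a coding model vs uniform background."""

    K = 6

    def __init__(self, training_seqs: list[str], pseudocount: float = 1.0):
        if not training_seqs:
            raise ValueError("hexamer model requires a nonempty training set")
        counts: Counter[str] = Counter()
        for s in training_seqs:
            s = s.upper()
            for i in range(len(s) - self.K + 1):
                kmer = s[i : i + self.K]
                if set(kmer) <= set("ACGT"):
                    counts[kmer] += 1
        total = sum(counts.values()) + pseudocount * 4**self.K
        self._logp = {
            kmer: math.log((counts.get(kmer, 0) + pseudocount) / total)
            for kmer in counts
        }
        self._log_default = math.log(pseudocount / total)
        self._log_bg = math.log(1.0 / 4**self.K)

    def score(self, seq: str) -> float:
        """Mean per-hexamer log-likelihood ratio (0 for too-short input)."""
        seq = seq.upper()
        n = 0
        total = 0.0
        for i in range(len(seq) - self.K + 1):
            kmer = seq[i : i + self.K]
            if set(kmer) <= set("ACGT"):
                total += self._logp.get(kmer, self._log_default) - self._log_bg
                n += 1
        return total / n if n else 0.0


def coding_potential(
    transcript_id: str,
    seq: str,
    model: HexamerModel,
    orf_min_codons: int = 100,
    score_threshold: float = 0.0,
    min_lnc_length: int = 200,
) -> CodingCall:
    """Score one transcript sequence; deterministic."""
    if not seq:
        raise ValueError(f"{transcript_id}: empty sequence")
    orf = longest_orf(seq)
    score = model.score(seq)
    noncoding = (
        orf < orf_min_codons
        and score < score_threshold
        and len(seq) >= min_lnc_length
    )
    return CodingCall(
        transcript_id, orf, score, "noncoding" if noncoding else "coding"
    )


def call_noncoding(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    training_cds: list[str],
    orf_min_codons: int = 100,
    score_threshold: float = 0.0,
    min_lnc_length: int = 200,
    external_calls: dict[str, str] | None = None,
) -> list[CodingCall]:
    """Coding calls for a transcript set, optionally from an external tool.

    ``external_calls`` maps transcript id -> "coding"/"noncoding" and takes
    precedence, so ensembles like CPC2/CNCI/CPAT/PLEK can be plugged in.
    """
    from .model import spliced_sequence

    model = HexamerModel(training_cds)
    calls = []
    for t in transcripts:
        if external_calls and t.id in external_calls:
            calls.append(CodingCall(t.id, -1, float("nan"), external_calls[t.id]))
            continue
        calls.append(
            coding_potential(
                t.id,
                spliced_sequence(t, genome),
                model,
                orf_min_codons,
                score_threshold,
                min_lnc_length,
            )
        )
    return calls


def classify_position(
    t: TranscriptModel, ref: Annotation
) -> PositionClass:
    """Four-way positional class against the reference annotation.

    Reference gene order never changes a call: candidates are ranked by
    (precedence, exonic overlap, gene id).
    """
    hits = ref.query(t.chrom, t.start, t.end)
    if not hits:
        return PositionClass(t.id, "intergenic", None)
    # (1) intronic: span entirely inside a single intron of some reference
    # transcript, either strand
    intronic_anchor = None
    for g in hits:
        for rt in g.members:
            for istart, iend in rt.introns:
                if istart <= t.start and t.end <= iend:
                    if intronic_anchor is None or g.id < intronic_anchor:
                        intronic_anchor = g.id
    if intronic_anchor is not None:
        return PositionClass(t.id, "intronic", intronic_anchor)
    # (2)/(3) exonic overlap, same strand outranking opposite strand
    best = None  # (same_strand, overlap, -ord(id)) -> gene
    for g in hits:
        ov = _exonic_overlap(t, g)
        if ov <= 0:
            continue
        key = (g.strand == t.strand, ov)
        if best is None or key > best[0] or (key == best[0] and g.id < best[1].id):
            best = (key, g)
    if best is not None:
        (same, _), g = best
        return PositionClass(t.id, "sense" if same else "antisense", g.id)
    # span overlaps a gene but touches no exon and is not inside one intron
    # (straddles a junction region): attribute to the gene body as intronic
    g = min(hits, key=lambda g: g.id)
    return PositionClass(t.id, "intronic", g.id)


def _exonic_overlap(t: TranscriptModel, g) -> int:
    total = 0
    union = g.exon_union()
    for e in t.exons:
        for s, x in union:
            if s >= e.end:
                break
            ov = min(e.end, x) - max(e.start, s)
            if ov > 0:
                total += ov
    return total


def lncrna_summary(
    classes: list[PositionClass],
    lnc_transcripts: list[TranscriptModel] | None = None,
    mrna_transcripts: list[TranscriptModel] | None = None,
    known_lncrnas: list[TranscriptModel] | None = None,
) -> dict:
    """Per-class counts/percentages, novel fraction and length summaries.

    A lncRNA is novel when no known lncRNA on the same strand shares its
    exact exon chain.
    """
    import numpy as np

    from .summary import percentage

    total = len(classes)
    per_class = Counter(c.position_class for c in classes)
    out = {
        "total": total,
        "classes": {
            cls: {
                "count": per_class.get(cls, 0),
                "pct": percentage(per_class.get(cls, 0), total) if total else 0.0,
            }
            for cls in ("intronic", "sense", "antisense", "intergenic")
        },
    }
    if lnc_transcripts is not None and known_lncrnas is not None:
        known_keys = {
            (k.chrom, k.strand, tuple((e.start, e.end) for e in k.exons))
            for k in known_lncrnas
        }
        novel = sum(
            1
            for t in lnc_transcripts
            if (t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons))
            not in known_keys
        )
        out["novel"] = novel
        out["novel_pct"] = percentage(novel, total) if total else 0.0
    for label, txs in (
        ("lncrna_length", lnc_transcripts),
        ("mrna_length", mrna_transcripts),
    ):
        if txs:
            lens = np.array([t.spliced_length for t in txs])
            out[label] = {
                "n": len(lens),
                "mean": float(np.mean(lens)),
                "median": float(np.median(lens)),
            }
    return out
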