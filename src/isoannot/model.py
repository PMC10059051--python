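"""Core genomic transcript data model and standard-format I/O.

The universal currency of the pipeline is the :class:`TranscriptModel`: a
strand-aware ordered exon chain on a chromosome.  All internal coordinates are
0-based half-open; the 1-based closed convention of GFF3/GTF exists only at the
file boundary.  Readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

logger = logging.getLogger("isoannot")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ParseError(ValueError):
    """Raised when an input annotation file violates its format contract."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty exon [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript as an ordered, non-overlapping, non-adjacent exon chain.

    Attributes
    ----------
    id : str
        Transcript identifier.
    chrom, strand : str
        Chromosome name and strand ("+" or "-").  Strandless single-exon
        features from permissive GFF are stored as "+" with
        ``strand_uncertain=True``; such features never satisfy a same-strand
        test against a "-" feature (they are simply "+" internally).
    exons : list[Exon]
        Sorted by start; gaps between consecutive exons are introns (>= 1 bp).
    source_sample : str | None
        Label of the dataset/sample the read came from.
    support : int
        Number of raw reads merged into this model (1 for a raw read).
    samples : set[str]
        Source samples of the merged reads.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Exon]
    source_sample: str | None = None
    strand_uncertain: bool = False
    support: int = 1
    samples: set[str] = field(default_factory=set)
    gene_id: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript with no exons")
        self.exons = merge_adjacent(sorted(self.exons), self.id)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.id}: overlapping exons {a} and {b}")
        if not self.samples and self.source_sample is not None:
            self.samples = {self.source_sample}

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [first exon start, last exon end)."""
        return (self.start, self.end)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) coordinates of the gaps between exons."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Alias of :attr:`introns`; the identity key for isoform collapse."""
        return self.introns

    @property
    def splice_sites(self) -> frozenset[int]:
        """All intron boundary coordinates (donors and acceptors pooled)."""
        return frozenset(x for iv in self.introns for x in iv)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    def three_prime_end(self) -> int:
        """Strand-aware 3' terminal genomic coordinate (cleavage position)."""
        return self.end if self.strand == "+" else self.start

    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end

    def same_structure(self, other: "TranscriptModel") -> bool:
        """Chrom, strand, and exact exon chain equality."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.exons == other.exons
        )

    def copy(self, **changes) -> "TranscriptModel":
        kw = dict(
            id=self.id,
            chrom=self.chrom,
            strand=self.strand,
            exons=list(self.exons),
            source_sample=self.source_sample,
            strand_uncertain=self.strand_uncertain,
            support=self.support,
            samples=set(self.samples),
            gene_id=self.gene_id,
        )
        kw.update(changes)
        return TranscriptModel(**kw)


def merge_adjacent(exons: list[Exon], tid: str = "?") -> list[Exon]:
    """Merge book-ended exons (gap < 1).  Zero-length introns are format noise."""
    out: list[Exon] = []
    for e in exons:
        if out and e.start <= out[-1].end:
            if e.start < out[-1].end:
                return exons  # overlapping: let the caller's validation fail
            logger.warning("%s: merged adjacent exons at %d", tid, e.start)
            out[-1] = Exon(out[-1].start, max(out[-1].end, e.end))
        else:
            out.append(e)
    return out


@dataclass
class GeneLocus:
    """A connected set of transcripts under the same-gene relation."""

    id: str
    chrom: str
    strand: str
    members: list[TranscriptModel]

    def __post_init__(self):
        for t in self.members:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"locus {self.id}: member {t.id} on {t.chrom}{t.strand}, "
                    f"locus on {self.chrom}{self.strand}"
                )

    @property
    def start(self) -> int:
        return min(t.start for t in self.members)

    @property
    def end(self) -> int:
        return max(t.end for t in self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def exon_union(self) -> list[tuple[int, int]]:
        """Union of member exons as a sorted list of disjoint intervals."""
        ivs = sorted((e.start, e.end) for t in self.members for e in t.exons)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]


class Annotation:
    """A set of gene loci with an interval index by chromosome.

    The index returns exactly the loci whose spans intersect a query interval
    (verified against brute-force scan in the test suite).
    """

    def __init__(self, genes: list[GeneLocus]):
        ids = [g.id for g in genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.id))
        self._by_id = {g.id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def transcripts(self):
        for g in self.genes:
            yield from g.members

    def query(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneLocus]:
        """Loci whose span intersects [start, end), optionally strand-filtered."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.id))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.genes, other.genes):
            if (a.id, a.chrom, a.strand) != (b.id, b.chrom, b.strand):
                return False
            am = sorted(a.members, key=lambda t: t.id)
            bm = sorted(b.members, key=lambda t: t.id)
            if len(am) != len(bm):
                return False
            for t, u in zip(am, bm):
                if t.id != u.id or not t.same_structure(u):
                    return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _validate_gff3_parents(text: str) -> None:
    """Fail fast, with a line number, on exons whose Parent is undeclared."""
    declared: set[str] = set()
    pending: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            continue
        ftype, attrs = cols[2], cols[8]
        fields = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        if "ID" in fields:
            declared.add(fields["ID"])
        if ftype == "exon":
            parent = fields.get("Parent")
            if parent is None:
                raise ParseError(f"line {lineno}: exon without Parent attribute")
            for p in parent.split(","):
                if p not in declared:
                    pending.append((lineno, p))
    for lineno, p in pending:
        if p not in declared:
            raise ParseError(
                f"line {lineno}: exon Parent {p!r} never declared"
            )


def _looks_like_gtf(text: str) -> bool:
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 9:
            return "gene_id" in cols[8] and "=" not in cols[8].split(";")[0]
    return False


def read_annotation(path) -> Annotation:
    """Read a GFF3 or GTF annotation into an :class:`Annotation`.

    The two dialects produce identical internal models.  Coordinates are
    converted from 1-based closed to 0-based half-open.  An exon referencing an
    undeclared parent transcript is a :class:`ParseError` naming the line; an
    unknown strand "." on a multi-exon transcript is an error, while
    strandless single-exon features are accepted as "+" and flagged.
    """
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()
    is_gtf = _looks_like_gtf(text)
    if not is_gtf:
        _validate_gff3_parents(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        verbose=False,
    )
    transcript_types = {
        "mRNA", "transcript", "lnc_RNA", "ncRNA", "lincRNA", "miRNA",
        "snoRNA", "snRNA", "rRNA", "tRNA", "pseudogenic_transcript",
    }
    genes: list[GeneLocus] = []
    for gfeat in db.features_of_type("gene", order_by=("seqid", "start")):
        members = []
        for tfeat in db.children(gfeat, level=1, order_by="start"):
            if tfeat.featuretype not in transcript_types:
                continue
            exons = [
                Exon(e.start - 1, e.end)
                for e in db.children(tfeat, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise ParseError(f"transcript {tfeat.id} has no exons")
            strand = tfeat.strand
            uncertain = False
            if strand not in ("+", "-"):
                if len(exons) > 1:
                    raise ParseError(
                        f"transcript {tfeat.id}: strand '.' on a multi-exon "
                        "transcript"
                    )
                logger.warning(
                    "transcript %s: strandless single-exon feature kept as '+'",
                    tfeat.id,
                )
                strand, uncertain = "+", True
            members.append(
                TranscriptModel(
                    id=tfeat.id,
                    chrom=tfeat.seqid,
                    strand=strand,
                    exons=exons,
                    strand_uncertain=uncertain,
                    gene_id=gfeat.id,
                )
            )
        if not members:
            continue
        strand = members[0].strand
        genes.append(GeneLocus(gfeat.id, gfeat.seqid, strand, members))
    return Annotation(genes)


def write_annotation(ann: Annotation, path) -> None:
    """Write an :class:`Annotation` as GFF3, deterministically ordered."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tisoannot\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
            for t in sorted(g.members, key=lambda t: (t.start, t.id)):
                attrs = f"ID={t.id};Parent={g.id}"
                if t.support > 1 or t.samples:
                    attrs += f";support={t.support}"
                    if t.samples:
                        attrs += ";samples=" + ",".join(sorted(t.samples))
                fh.write(
                    f"{t.chrom}\tisoannot\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.chrom}\tisoannot\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{t.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )


def read_bed12(path, source_sample: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from a 12-column BED file.

    BED is already 0-based half-open; blocks become exons (blockStarts are
    relative to chromStart).  A blockCount that disagrees with the
    blockSizes/blockStarts lists is a :class:`ParseError`.
    """
    out: list[TranscriptModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"line {lineno}: expected 12 BED columns, got {len(cols)}"
                )
            chrom, start = cols[0], int(cols[1])
            name, strand = cols[3], cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(
                    f"line {lineno}: blockCount={n_blocks} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = [
                Exon(start + off, start + off + size)
                for off, size in zip(starts, sizes)
            ]
            uncertain = False
            if strand not in ("+", "-"):
                if n_blocks > 1:
                    raise ParseError(
                        f"line {lineno}: strand {strand!r} on multi-block record"
                    )
                strand, uncertain = "+", True
            out.append(
                TranscriptModel(
                    id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    source_sample=source_sample,
                    strand_uncertain=uncertain,
                )
            )
    return out


def write_bed12(transcripts, path) -> None:
    """Write transcript models as BED12 (score 0, thick range = span)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            sizes = ",".join(str(len(e)) for e in t.exons) + ","
            starts = ",".join(str(e.start - t.start) for e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file into a dict of upper-case sequences."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")
        }


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def spliced_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Exonic sequence of a transcript on the transcribed strand (5'→3')."""
    chrom_seq = genome[t.chrom]
    s = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return revcomp(s) if t.strand == "-" else s
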