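"""Strand-aware gene models and genomic/transcript compartment assignment.

Genes are loaded from GFF3 into :class:`GeneModel` objects holding the genomic
span, TSS/TES, and the 5'UTR / CDS / 3'UTR exonic pieces. All internal
coordinates are 0-based half-open; GFF3 at the boundary is 1-based closed.

Two compartment systems are exposed:

* genomic — the promoter (a fixed window upstream of the TSS in transcription
  orientation, 2000 bp by default) and the gene body (TSS through TES,
  introns included), used to place differentially methylated CpG sites;
* transcript — the 5'UTR / CDS / 3'UTR partition of the spliced transcript,
  used to place miRNA binding sites reported in transcript coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal, Optional

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneCatalog",
    "AnnotationError",
    "Gff3ParseError",
    "load_annotation",
    "write_gff3",
    "promoter_interval",
    "gene_body_interval",
    "assign_site_location",
    "assign_binding_region",
]

SiteLocation = Literal["promoter", "gene_body", "none"]
BindingRegion = Literal["utr5", "cds", "utr3"]


class AnnotationError(ValueError):
    """Invalid gene structure or out-of-range query."""


class Gff3ParseError(AnnotationError):
    """Malformed GFF3 input; carries the offending line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not (0 <= self.start <= self.end):
            raise AnnotationError(
                f"require 0 <= start <= end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class GeneModel:
    """One gene with a single representative transcript.

    ``utr5``/``cds``/``utr3`` are genomic exonic pieces in genomic order.
    ``tss``/``tes`` are 0-based positions of the first/last transcribed base.
    """

    gene_id: str
    span: GenomicInterval
    symbol: Optional[str] = None
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        pieces = sorted(
            self.utr5 + self.cds + self.utr3, key=lambda iv: (iv.start, iv.end)
        )
        for a, b in zip(pieces, pieces[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.gene_id}: overlapping transcript pieces "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for iv in pieces:
            if iv.start < self.span.start or iv.end > self.span.end:
                raise AnnotationError(
                    f"{self.gene_id}: piece [{iv.start},{iv.end}) outside gene span"
                )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tes(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start

    @property
    def transcript_length(self) -> int:
        return sum(len(iv) for iv in self.utr5 + self.cds + self.utr3)

    def compartment_lengths(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths of the spliced transcript."""
        return (
            sum(len(iv) for iv in self.utr5),
            sum(len(iv) for iv in self.cds),
            sum(len(iv) for iv in self.utr3),
        )


@dataclass
class GeneCatalog:
    """All gene models of an annotation, keyed by gene_id."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for gid, gene in self.genes.items():
            if gid != gene.gene_id:
                raise AnnotationError(f"catalog key {gid!r} != gene_id {gene.gene_id!r}")
            limit = self.chrom_lengths.get(gene.span.chrom)
            if limit is not None and gene.span.end > limit:
                raise AnnotationError(
                    f"{gid}: span end {gene.span.end} exceeds {gene.span.chrom} "
                    f"length {limit}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_symbol(self, symbol: str) -> list[GeneModel]:
        s = symbol.upper()
        return [g for g in self if g.symbol and g.symbol.upper() == s]


# ---------------------------------------------------------------------------
# GFF3 I/O

_FEATURE_KINDS = {"gene", "mRNA", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}


def _prevalidate_gff3(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise Gff3ParseError(
                f"expected 9 tab-separated columns, found {len(cols)}", lineno
            )
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise Gff3ParseError(f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", lineno)
        if start < 1 or end < start:
            raise Gff3ParseError(f"invalid 1-based span {start}..{end}", lineno)
        if cols[6] not in ("+", "-", "."):
            raise Gff3ParseError(f"invalid strand {cols[6]!r}", lineno)


def load_annotation(
    gff3: "str | io.TextIOBase", chrom_lengths: Optional[dict[str, int]] = None
) -> GeneCatalog:
    """Parse GFF3 (text, path-like stream) into a :class:`GeneCatalog`.

    One representative transcript is kept per gene: the mRNA with the largest
    spliced (exonic) length, ties broken by mRNA ID. GFF3 1-based closed
    coordinates become internal 0-based half-open ones.
    """
    if hasattr(gff3, "read"):
        text = gff3.read()
    else:
        text = gff3
    _prevalidate_gff3(text)
    if not any(line and not line.startswith("#") for line in text.splitlines()):
        return GeneCatalog(chrom_lengths=dict(chrom_lengths or {}))

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    genes: dict[str, GeneModel] = {}
    for grec in db.features_of_type("gene"):
        gid = grec.id
        span = GenomicInterval(grec.seqid, grec.start - 1, grec.end, grec.strand)
        symbol = grec.attributes.get("Name", [None])[0]

        mrnas = list(db.children(grec, featuretype="mRNA"))
        best, best_len = None, -1
        for m in mrnas:
            exlen = sum(e.end - e.start + 1 for e in db.children(m, featuretype="exon"))
            if exlen > best_len or (exlen == best_len and best is not None and m.id < best.id):
                best, best_len = m, exlen
        kinds = {"five_prime_UTR": [], "CDS": [], "three_prime_UTR": []}
        if best is not None:
            for kind in kinds:
                for f in db.children(best, featuretype=kind):
                    if f.start - 1 < span.start or f.end > span.end:
                        raise AnnotationError(
                            f"{gid}: {kind} {f.start}..{f.end} outside gene span "
                            f"{grec.start}..{grec.end}"
                        )
                    kinds[kind].append(
                        GenomicInterval(f.seqid, f.start - 1, f.end, grec.strand)
                    )
        if gid in genes:
            raise AnnotationError(f"duplicate gene id {gid}")
        genes[gid] = GeneModel(
            gene_id=gid,
            span=span,
            symbol=symbol,
            utr5=sorted(kinds["five_prime_UTR"], key=lambda iv: iv.start),
            cds=sorted(kinds["CDS"], key=lambda iv: iv.start),
            utr3=sorted(kinds["three_prime_UTR"], key=lambda iv: iv.start),
        )
    return GeneCatalog(genes=genes, chrom_lengths=dict(chrom_lengths or {}))


def write_gff3(catalog: GeneCatalog) -> str:
    """Serialize a catalog back to GFF3 (1-based closed), round-tripping
    the coordinates produced by :func:`load_annotation`."""
    out = ["##gff-version 3"]

    def row(iv: GenomicInterval, kind: str, attrs: str) -> str:
        return "\t".join(
            [iv.chrom, "mirmeth", kind, str(iv.start + 1), str(iv.end), ".",
             iv.strand, ".", attrs]
        )

    for gene in sorted(catalog, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
        gattrs = f"ID={gene.gene_id}"
        if gene.symbol:
            gattrs += f";Name={gene.symbol}"
        out.append(row(gene.span, "gene", gattrs))
        mid = f"{gene.gene_id}.t1"
        out.append(row(gene.span, "mRNA", f"ID={mid};Parent={gene.gene_id}"))
        pieces = sorted(
            [(iv, "five_prime_UTR") for iv in gene.utr5]
            + [(iv, "CDS") for iv in gene.cds]
            + [(iv, "three_prime_UTR") for iv in gene.utr3],
            key=lambda p: p[0].start,
        )
        # exons = maximal runs of adjacent transcript pieces
        exons: list[list[int]] = []
        for iv, _ in pieces:
            if exons and exons[-1][1] == iv.start:
                exons[-1][1] = iv.end
            else:
                exons.append([iv.start, iv.end])
        for i, (s, e) in enumerate(exons, 1):
            ex = GenomicInterval(gene.span.chrom, s, e, gene.strand)
            out.append(row(ex, "exon", f"ID={mid}.exon{i};Parent={mid}"))
        for i, (iv, kind) in enumerate(pieces, 1):
            out.append(row(iv, kind, f"ID={mid}.{kind}{i};Parent={mid}"))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Compartment assignment

def promoter_interval(
    gene: GeneModel,
    upstream_bp: int = 2000,
    chrom_length: Optional[int] = None,
    strand_aware: bool = True,
) -> GenomicInterval:
    """The promoter window upstream of the TSS, clipped to the chromosome.

    On the + strand this is ``[tss - upstream_bp, tss)``; on the - strand the
    window sits genomically right of the gene span. With
    ``strand_aware=False`` the window is always genomically left of the span.
    """
    if upstream_bp <= 0:
        raise AnnotationError("upstream_bp must be positive")
    if gene.strand == "+" or not strand_aware:
        start, end = gene.span.start - upstream_bp, gene.span.start
    else:
        start, end = gene.span.end, gene.span.end + upstream_bp
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
        start = min(start, end)
    return GenomicInterval(gene.span.chrom, start, max(start, end), gene.strand)


def gene_body_interval(gene: GeneModel) -> GenomicInterval:
    """TSS through TES on the genome, introns included: the gene span."""
    return gene.span


def assign_site_location(
    position: int,
    gene: GeneModel,
    upstream_bp: int = 2000,
    chrom_length: Optional[int] = None,
    strand_aware: bool = True,
) -> SiteLocation:
    """Place a 1-based genomic position in the gene's promoter or body.

    The gene body takes precedence should the two windows ever touch (by
    construction they are disjoint).
    """
    if position < 1:
        raise AnnotationError(f"position must be >= 1, got {position}")
    pos0 = position - 1
    if gene_body_interval(gene).contains(pos0):
        return "gene_body"
    if promoter_interval(gene, upstream_bp, chrom_length, strand_aware).contains(pos0):
        return "promoter"
    return "none"


_REGION_PRIORITY = {"utr3": 0, "cds": 1, "utr5": 2}


def assign_binding_region(
    binding: tuple[int, int], gene: GeneModel
) -> BindingRegion:
    """Label a transcript-coordinate binding interval as utr5/cds/utr3.

    The label is the compartment with maximal overlap; exact ties resolve
    utr3 > cds > utr5 (canonical miRNA target-site priority).
    """
    start, end = binding
    tlen = gene.transcript_length
    if not (0 <= start < end <= tlen):
        raise AnnotationError(
            f"binding [{start},{end}) outside transcript [0,{tlen}) of {gene.gene_id}"
        )
    l5, lc, l3 = gene.compartment_lengths()
    bounds = {
        "utr5": (0, l5),
        "cds": (l5, l5 + lc),
        "utr3": (l5 + lc, l5 + lc + l3),
    }
    overlaps = {
        region: max(0, min(e, end) - max(s, start)) for region, (s, e) in bounds.items()
    }
    return max(overlaps, key=lambda r: (overlaps[r], -_REGION_PRIORITY[r]))


def read_chrom_lengths(source: "str | io.TextIOBase") -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict."""
    text = source.read() if hasattr(source, "read") else source
    lengths: dict[str, int] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, length = line.split("\t")[:2]
        lengths[chrom] = int(length)
    return lengths
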