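"""Genome/annotation I/O and strand-aware promoter extraction.

Promoter windows span -100..+50 around the annotated gene start by
default.  Position +1 is the first base of the gene and there is no
position 0, so the window covers ``upstream + downstream`` nucleotides
(150 by default) and is always reported in gene-sense orientation: the
window of a minus-strand gene is the reverse complement of the genomic
slice ending ``upstream`` bases past its annotated end.

External coordinates (gene tables, FASTA headers, TSV indexes) are
1-based inclusive, following GFF3; all internal arithmetic is 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeRecord",
    "GeneAnnotation",
    "PromoterRegion",
    "ParseError",
    "ValidationError",
    "reverse_complement",
    "read_fasta",
    "read_gene_table",
    "extract_promoters",
    "write_promoter_fasta",
    "write_promoter_tsv",
]

_VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes other than N; mapped to N in lenient mode.
_AMBIGUITY = frozenset("RYSWKMBDHVU")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file (message carries the offending line number)."""


class ValidationError(ValueError):
    """Input violates a contract (coordinates, strand, uniqueness...)."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the {A,C,G,T,N} alphabet.

    Case-insensitive on input; N maps to N.  Applying the function twice
    returns the input (involution).
    """
    s = seq.upper()
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValidationError(f"illegal nucleotide(s) {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with a circularity flag."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with 1-based inclusive chromosomal coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    locus_tag: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, got {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window in gene-sense orientation with provenance coordinates.

    ``chrom_start``/``chrom_end`` are 1-based inclusive positions of the
    genomic window on the forward strand (after clipping on a linear
    genome; on a circular genome a wrapped window has start > end).
    """

    gene_id: str
    sequence: str
    chrom_start: int
    chrom_end: int
    strand: str
    truncated: bool = False


def _normalize_sequence(seq: str, line_no: int, strict: bool) -> str:
    s = seq.upper()
    bad = set(s) - _VALID_BASES
    if not bad:
        return s
    ambig = bad & _AMBIGUITY
    if bad - _AMBIGUITY:
        raise ParseError(
            f"line {line_no}: illegal character(s) {sorted(bad - _AMBIGUITY)}"
        )
    if strict:
        raise ParseError(
            f"line {line_no}: ambiguity code(s) {sorted(ambig)} not allowed in strict mode"
        )
    return "".join("N" if c in _AMBIGUITY else c for c in s)


def read_fasta(path: str | Path, *, strict: bool = True, circular: bool = False) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased.  In strict mode (default) IUPAC ambiguity
    codes other than N raise a :class:`ParseError`; otherwise they are
    mapped to N.  An empty file, a header with no sequence, or sequence
    data before the first header is a parse error naming the line.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"line {header_line}: record {header!r} has no sequence")
        records.append(GenomeRecord(header, "".join(chunks), circular=circular))

    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise ParseError(f"line {line_no}: empty FASTA header")
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {line_no}: sequence data before any header")
                chunks.append(_normalize_sequence(line, line_no, strict))
    flush()
    if not records:
        raise ParseError("line 1: file contains no FASTA records")
    return records


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            key, _, val = item.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    genome_length: int | None = None,
    circular: bool = False,
) -> list[GeneAnnotation]:
    """Read gene annotations from a 4-column TSV or a GFF3 file.

    TSV columns: gene_id, start, end, strand (1-based inclusive).  GFF3
    rows of type ``gene`` or ``CDS`` are used; the gene id is taken from
    the ``ID`` (or ``locus_tag``) attribute.  Duplicated gene ids and,
    when ``genome_length`` is given on a linear genome, coordinates
    beyond the genome are validation errors.
    """
    if dialect not in ("tsv", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "tsv":
                if len(fields) < 4:
                    raise ParseError(f"line {line_no}: expected 4 tab-separated columns")
                gene_id, start_s, end_s, strand = (f.strip() for f in fields[:4])
                locus_tag = None
            else:
                if len(fields) < 9:
                    raise ParseError(f"line {line_no}: expected 9 GFF3 columns")
                if fields[2] not in ("gene", "CDS"):
                    continue
                attrs = _parse_gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("locus_tag") or ""
                if not gene_id:
                    raise ParseError(f"line {line_no}: GFF3 row lacks ID/locus_tag attribute")
                locus_tag = attrs.get("locus_tag")
                start_s, end_s, strand = fields[3], fields[4], fields[6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {line_no}: non-integer coordinate") from exc
            ann = GeneAnnotation(gene_id, start, end, strand, locus_tag=locus_tag)
            if ann.gene_id in seen:
                raise ValidationError(f"line {line_no}: duplicate gene_id {ann.gene_id!r}")
            seen.add(ann.gene_id)
            if genome_length is not None and not circular and ann.end > genome_length:
                raise ValidationError(
                    f"line {line_no}: gene {ann.gene_id!r} ends at {ann.end}, "
                    f"beyond linear genome length {genome_length}"
                )
            genes.append(ann)
    return genes


def _slice_window(genome: GenomeRecord, lo: int, hi: int) -> tuple[str, int, int, bool]:
    """Extract the 0-based half-open window [lo, hi) from the forward strand.

    Wraps on a circular genome, clips on a linear one.  Returns
    (sequence, 1-based start, 1-based end, truncated flag); on a wrapped
    circular window start > end.
    """
    n = len(genome)
    if genome.circular:
        seq = "".join(genome.sequence[i % n] for i in range(lo, hi))
        return seq, lo % n + 1, (hi - 1) % n + 1, False
    clipped_lo, clipped_hi = max(lo, 0), min(hi, n)
    if clipped_lo >= clipped_hi:
        return "", 0, 0, True
    seq = genome.sequence[clipped_lo:clipped_hi]
    truncated = clipped_lo != lo or clipped_hi != hi
    return seq, clipped_lo + 1, clipped_hi, truncated


def extract_promoters(
    genome: GenomeRecord,
    genes: Iterable[GeneAnnotation],
    upstream: int = 100,
    downstream: int = 50,
) -> list[PromoterRegion]:
    """Extract -upstream..+downstream promoter windows for each gene.

    For a plus-strand gene starting at s the genomic window is
    [s-upstream, s+downstream-1] (1-based inclusive); for a minus-strand
    gene ending at e it is [e-downstream+1, e+upstream], reverse
    complemented.  Windows wrap on a circular genome and are clipped
    (``truncated=True``) on a linear one.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    n = len(genome)
    out: list[PromoterRegion] = []
    for gene in genes:
        if gene.end > n:
            raise ValidationError(
                f"gene {gene.gene_id!r} lies beyond genome {genome.id!r} (length {n})"
            )
        if gene.strand == "+":
            lo = gene.start - 1 - upstream
            hi = gene.start - 1 + downstream
        else:
            lo = gene.end - downstream
            hi = gene.end + upstream
        seq, c_start, c_end, truncated = _slice_window(genome, lo, hi)
        if gene.strand == "-":
            seq = reverse_complement(seq) if seq else seq
        out.append(
            PromoterRegion(
                gene_id=gene.gene_id,
                sequence=seq,
                chrom_start=c_start,
                chrom_end=c_end,
                strand=gene.strand,
                truncated=truncated,
            )
        )
    return out


def write_promoter_fasta(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    """Write promoters as FASTA; headers carry coordinates, strand and flag."""
    with Path(path).open("w") as fh:
        for p in promoters:
            fh.write(
                f">{p.gene_id} {p.chrom_start}..{p.chrom_end} strand={p.strand} "
                f"truncated={'yes' if p.truncated else 'no'}\n{p.sequence}\n"
            )


def write_promoter_tsv(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchrom_start\tchrom_end\tstrand\ttruncated\tlength\n")
        for p in promoters:
            fh.write(
                f"{p.gene_id}\t{p.chrom_start}\t{p.chrom_end}\t{p.strand}\t"
                f"{int(p.truncated)}\t{len(p.sequence)}\n"
            )
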