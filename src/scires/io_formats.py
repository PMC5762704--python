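"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions are fixed per format: samtools mpileup, GTF and VCF
are all 1-based with closed intervals; any BED emitted downstream is 0-based
half-open.  Base quality strings are parsed (and can gate bases via
``min_base_quality``) but by default every base counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
STRANDS = ("+", "-")

#: biotypes retained when reading annotation
KEPT_BIOTYPES = frozenset({"protein_coding", "lncRNA"})


class ParseError(ValueError):
    """Malformed input; message names the offending line number."""


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PileupColumn:
    """Stranded base counts for one sample at one genomic position.

    ``counts`` maps ``(base, strand)`` with base in A/C/G/T and strand
    ``+``/``-`` to a non-negative read count; ``depth`` is the total number
    of counted reads and always equals the sum of ``counts``.  A reference
    base of ``N`` marks the site as excluded from all downstream calling.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[tuple[str, str], int]
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        total = sum(self.counts.values())
        if total != self.depth:
            raise ValueError(
                f"depth {self.depth} != sum of counts {total} at "
                f"{self.chrom}:{self.pos}"
            )
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative base count")

    def base_count(self, base: str) -> int:
        """Total count for ``base`` over both strands."""
        return self.counts.get((base, "+"), 0) + self.counts.get((base, "-"), 0)


def _decode_base_string(bases: str, quals: str, ref_base: str,
                        min_base_quality: int, line_no: int
                        ) -> dict[tuple[str, str], int]:
    """Decode one mpileup base string into stranded counts.

    ``.``/``,`` are reference matches on +/- strand; upper/lowercase letters
    are alternative bases on +/- strand; ``^X`` (read start plus mapping
    quality) and ``$`` (read end) carry no base; ``+n...``/``-n...`` indel
    runs are skipped; ``*`` is a deletion placeholder that consumes a quality
    character but counts toward no base.
    """
    counts: dict[tuple[str, str], int] = {}
    ref = ref_base.upper()
    i = 0
    qi = 0  # index into quality string
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(
                    f"line {line_no}: malformed indel (no length after "
                    f"'{c}')"
                )
            length = int(bases[i + 1:j])
            if j + length > n:
                raise ParseError(
                    f"line {line_no}: indel run of length {length} exceeds "
                    "base string"
                )
            i = j + length
            continue
        # everything below consumes one quality character
        if qi >= len(quals):
            raise ParseError(
                f"line {line_no}: base/quality length mismatch"
            )
        qual = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if qual < min_base_quality:
            continue
        if c == ".":
            base, strand = ref, "+"
        elif c == ",":
            base, strand = ref, "-"
        elif c == "*":
            continue  # deletion placeholder: no base counted
        else:
            base, strand = c.upper(), ("+" if c.isupper() else "-")
        if base in BASES:
            key = (base, strand)
            counts[key] = counts.get(key, 0) + 1
        # N (unknown read base, or ref match against ref N) counts nothing
    if qi != len(quals):
        raise ParseError(f"line {line_no}: base/quality length mismatch")
    return counts


def read_pileup(stream: Iterable[str], sample_index: int = 0,
                min_base_quality: int = 0) -> Iterator[PileupColumn]:
    """Parse samtools mpileup text, yielding one column per line.

    ``sample_index`` selects the sample in a multi-sample pileup (each
    sample contributes a depth/bases/quals column triple).  Depth is
    recomputed from the decoded base counts, so quality- or indel-masked
    bases never inflate it.
    """
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(
                f"line {line_no}: expected >= 6 tab-separated columns, "
                f"got {len(fields)}"
            )
        base_col = 3 + 3 * sample_index
        if len(fields) < base_col + 3:
            raise ParseError(
                f"line {line_no}: no sample column {sample_index}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ParseError(f"line {line_no}: bad position {pos_s!r}") from exc
        bases, quals = fields[base_col + 1], fields[base_col + 2]
        counts = _decode_base_string(bases, quals, ref, min_base_quality,
                                     line_no)
        yield PileupColumn(chrom=chrom, pos=pos, ref_base=ref.upper(),
                           counts=counts, depth=sum(counts.values()))


def write_pileup(columns: Iterable[PileupColumn], stream: IO[str]) -> None:
    """Emit columns as single-sample mpileup text (quality fixed at 'I').

    Inverse of :func:`read_pileup` for indel-free columns.
    """
    for col in columns:
        parts: list[str] = []
        for (base, strand), count in sorted(col.counts.items()):
            if base == col.ref_base:
                sym = "." if strand == "+" else ","
            else:
                sym = base if strand == "+" else base.lower()
            parts.append(sym * count)
        base_str = "".join(parts)
        stream.write(
            f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{col.depth}\t"
            f"{base_str}\t{'I' * col.depth}\n"
        )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS span.

    Coordinates are 1-based closed (GTF convention); exons are
    non-overlapping and sorted by start.  ``strand`` is ``+`` (Watson) or
    ``-`` (Crick).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[tuple[int, int]] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.span[0] <= cs <= ce <= self.span[1]):
                raise ValueError(
                    f"CDS of {self.transcript_id} outside exon union"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exon-union) length in bp."""
        return sum(e - s + 1 for s, e in self.exons)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(stream: Iterable[str]) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into transcript models.

    Only ``protein_coding`` and ``lncRNA`` biotypes are retained; records of
    other biotypes are skipped (the skip count is logged).  Exons are grouped
    per transcript and sorted; CDS features collapse to a genomic span.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, tuple[int, int]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> gene,chrom,strand,biotype
    n_skipped = 0
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ParseError(f"line {line_no}: expected 9 GTF columns")
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = \
            fields[:9]
        if feature not in ("exon", "CDS"):
            continue
        attrs = _parse_attrs(attrs_s)
        biotype = attrs.get("gene_biotype", "")
        if biotype not in KEPT_BIOTYPES:
            n_skipped += 1
            continue
        tid = attrs.get("transcript_id")
        if not tid:
            raise ParseError(f"line {line_no}: {feature} without transcript_id")
        gene = attrs.get("gene_id")
        if not gene:
            raise ParseError(f"line {line_no}: {feature} without gene_id")
        start, end = int(start_s), int(end_s)
        meta.setdefault(tid, (gene, chrom, strand, biotype))
        if feature == "exon":
            exons.setdefault(tid, []).append((start, end))
        else:
            lo, hi = cds.get(tid, (start, end))
            cds[tid] = (min(lo, start), max(hi, end))
    if n_skipped:
        logger.info("read_gtf: skipped %d records of non-retained biotypes",
                    n_skipped)
    models = []
    for tid in sorted(meta):
        gene, chrom, strand, biotype = meta[tid]
        if tid not in exons:
            continue  # CDS-only stub; no exon structure to model
        models.append(TranscriptModel(
            gene_id=gene, transcript_id=tid, chrom=chrom, strand=strand,
            exons=sorted(exons[tid]), cds=cds.get(tid), biotype=biotype,
        ))
    return models


def write_gtf(models: Sequence[TranscriptModel], stream: IO[str]) -> None:
    """Emit transcript models as Ensembl-dialect GTF exon/CDS lines."""
    for m in models:
        attrs = (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                 f'gene_biotype "{m.biotype}";')
        for start, end in m.exons:
            stream.write(f"{m.chrom}\tsim\texon\t{start}\t{end}\t.\t"
                         f"{m.strand}\t.\t{attrs}\n")
        if m.cds is not None:
            cs, ce = m.cds
            for start, end in m.exons:
                lo, hi = max(start, cs), min(end, ce)
                if lo <= hi:
                    stream.write(f"{m.chrom}\tsim\tCDS\t{lo}\t{hi}\t.\t"
                                 f"{m.strand}\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternative allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=PV,Number=1,Type=Float,Description="Variant call p-value">
##INFO=<ID=ST,Number=1,Type=String,Description="Consensus call status">
##FILTER=<ID=strand_bias,Description="Variant support confined to one strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fmt_float(x: Optional[float]) -> str:
    return "." if x is None else repr(float(x))


def write_variants(calls: Sequence, stream: IO[str]) -> None:
    """Write consensus calls as a minimal VCF 4.2.

    Input must be sorted by ``(chrom, pos)``.  The INFO field carries AF,
    DP, PV plus the call status (ST) so that a write/read cycle through
    :func:`read_variants` is lossless.
    """
    last = None
    stream.write(_VCF_HEADER)
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and key < last:
            raise ValueError(
                f"calls not sorted by (chrom, pos) at {call.chrom}:{call.pos}"
            )
        last = key
        alt = call.alt_base if call.alt_base else "."
        filt = "PASS" if call.strand_filter_pass else "strand_bias"
        info = (f"AF={_fmt_float(call.af)};DP={call.depth};"
                f"PV={_fmt_float(call.p_value)};ST={call.status}")
        stream.write(f"{call.chrom}\t{call.pos}\t.\t{call.ref_base}\t{alt}\t"
                     f".\t{filt}\t{info}\n")


def read_variants(stream: Iterable[str]) -> list:
    """Read the VCF subset written by :func:`write_variants`."""
    from .genotyping import GenotypeCall  # local import avoids a cycle

    calls = []
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise ParseError(f"line {line_no}: expected 8 VCF columns")
        chrom, pos_s, _id, ref, alt, _qual, filt, info_s = fields[:8]
        info = dict(kv.split("=", 1) for kv in info_s.split(";") if "=" in kv)
        af = None if info.get("AF", ".") == "." else float(info["AF"])
        pv = None if info.get("PV", ".") == "." else float(info["PV"])
        calls.append(GenotypeCall(
            chrom=chrom, pos=int(pos_s), ref_base=ref,
            alt_base=None if alt == "." else alt,
            status=info.get("ST", "no_call"),
            af=af, depth=int(info.get("DP", 0)), p_value=pv,
            strand_filter_pass=(filt == "PASS"),
        ))
    return calls
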