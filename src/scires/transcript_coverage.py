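"""Expression quantification and transcript-coverage statistics.

FPKM is computed on a union-exon gene model:

    FPKM_g = count_g * 1e9 / (length_g * total_mapped)

Metagene profiles aggregate per-transcript coverage and read-start
frequency into 100 percentile bins (5'->3' after strand orientation),
optionally stratified by transcript length — the standard way to visualise
the 3' bias of oligo-dT-primed single-cell cDNA amplification.  Reads are
assigned to genomic regions (exonic > intronic > intergenic) by their
5'-most aligned base, and between-sample reproducibility is the Pearson
correlation of log10(FPKM + 1) over the union gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import TranscriptModel

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ExpressionRecord:
    """Per-gene assigned read count and FPKM for one RNA sample."""

    gene_id: str
    assigned_read_count: int
    gene_length: int  # bp, union-exon model
    fpkm: float


@dataclass(slots=True)
class TranscriptReads:
    """Reads of one transcript in transcript coordinates (5'->3').

    ``offsets`` are 0-based 5'-most positions in [0, L); ``cover``
    intervals are 0-based half-open spans of aligned bases.
    """

    offsets: Sequence[int]
    cover: Sequence[tuple[int, int]]


@dataclass(slots=True)
class CoverageProfile:
    """Mean per-bin metagene profile for a group of transcripts.

    ``covered_fraction[b]`` is the mean fraction of bin b's bases covered
    by >=1 read; ``read_fraction[b]`` the mean fraction of a transcript's
    reads whose 5'-most base falls in bin b (transcripts without reads are
    excluded from the read-fraction mean).
    """

    label: str
    n_bins: int
    covered_fraction: np.ndarray
    read_fraction: np.ndarray
    n_transcripts: int
    n_transcripts_with_reads: int


def gene_lengths(transcripts: Sequence[TranscriptModel]) -> dict[str, int]:
    """Union-exon length per gene (exons merged across transcripts)."""
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        per_gene.setdefault(t.gene_id, []).extend(t.exons)
    out = {}
    for gene, ivs in per_gene.items():
        ivs.sort()
        total, cur_s, cur_e = 0, *ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        out[gene] = total + cur_e - cur_s + 1
    return out


def compute_fpkm(read_counts: Mapping[str, int],
                 transcripts: Sequence[TranscriptModel],
                 total_mapped: int) -> list[ExpressionRecord]:
    """Union-exon FPKM for every annotated gene.

    Genes absent from ``read_counts`` appear with zero reads; a count for
    a gene missing from the annotation is an error.
    """
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    lengths = gene_lengths(transcripts)
    unknown = set(read_counts) - set(lengths)
    if unknown:
        raise ValueError(f"genes not in annotation: {sorted(unknown)[:5]}")
    records = []
    for gene in sorted(lengths):
        count = int(read_counts.get(gene, 0))
        length = lengths[gene]
        fpkm = count * 1e9 / (length * total_mapped)
        records.append(ExpressionRecord(gene_id=gene,
                                        assigned_read_count=count,
                                        gene_length=length, fpkm=fpkm))
    return records


def count_expressed(records: Sequence[ExpressionRecord], threshold: float,
                    inclusive: bool = False) -> int:
    """Number of genes past an FPKM threshold.

    ``inclusive=False`` counts FPKM strictly greater than the threshold
    (the "greater than 0.1" convention); ``inclusive=True`` counts FPKM at
    or above it (the "at least 1" convention).
    """
    if inclusive:
        return sum(1 for r in records if r.fpkm >= threshold)
    return sum(1 for r in records if r.fpkm > threshold)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def _bin_edges(length: int, n_bins: int) -> np.ndarray:
    """Position of the first base of each bin (bin b spans
    floor(b*L/n) .. floor((b+1)*L/n) - 1)."""
    return (np.arange(n_bins + 1) * length) // n_bins


def _group_label(length: int, breakpoints: Sequence[int]) -> str:
    prev = None
    for bp in breakpoints:
        if length < bp:
            return f"<{bp}" if prev is None else f"{prev}-{bp - 1}"
        prev = bp
    return f">={prev}"


def metagene_profiles(read_positions: Mapping[str, TranscriptReads],
                      transcripts: Sequence[TranscriptModel],
                      n_bins: int = 100,
                      length_groups: Optional[Sequence[int]] = None
                      ) -> dict[str, CoverageProfile]:
    """Mean metagene coverage and read-start profiles, per length group.

    Offsets must already be in strand-oriented transcript coordinates.
    Transcripts shorter than ``n_bins`` are excluded (a bin would span
    less than one base); an offset outside [0, L) is an error naming the
    transcript.  Group profiles are unweighted means over transcripts.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    acc: dict[str, dict] = {}
    n_short = 0
    for tid, reads in read_positions.items():
        if tid not in by_tid:
            raise ValueError(f"transcript {tid} not in annotation")
        length = by_tid[tid].length
        if length < n_bins:
            n_short += 1
            continue
        offsets = np.asarray(reads.offsets, dtype=np.int64)
        if offsets.size and (offsets.min() < 0 or offsets.max() >= length):
            raise ValueError(
                f"read offset outside [0, {length}) for transcript {tid}")
        edges = _bin_edges(length, n_bins)
        covered = np.zeros(length, dtype=bool)
        for s, e in reads.cover:
            covered[max(0, s):min(length, e)] = True
        cum = np.concatenate([[0], np.cumsum(covered)])
        cov_frac = (cum[edges[1:]] - cum[edges[:-1]]) / np.diff(edges)
        label = ("all" if length_groups is None
                 else _group_label(length, list(length_groups)))
        slot = acc.setdefault(label, {
            "cov": np.zeros(n_bins), "reads": np.zeros(n_bins),
            "n": 0, "n_reads": 0})
        slot["cov"] += cov_frac
        slot["n"] += 1
        if offsets.size:
            hist = np.histogram(offsets, bins=edges)[0]
            slot["reads"] += hist / offsets.size
            slot["n_reads"] += 1
    if n_short:
        logger.info("metagene_profiles: excluded %d transcripts shorter "
                    "than %d nt", n_short, n_bins)
    return {
        label: CoverageProfile(
            label=label, n_bins=n_bins,
            covered_fraction=slot["cov"] / slot["n"],
            read_fraction=(slot["reads"] / slot["n_reads"]
                           if slot["n_reads"] else np.zeros(n_bins)),
            n_transcripts=slot["n"],
            n_transcripts_with_reads=slot["n_reads"])
        for label, slot in sorted(acc.items())
    }


# ---------------------------------------------------------------------------
# genomic region assignment
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals.sort()
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _member(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray
            ) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] <= ends[idx[ok]]
    return out


def region_fractions(reads: Sequence[tuple],
                     transcripts: Sequence[TranscriptModel]
                     ) -> dict[str, float]:
    """Fractions of reads landing in exonic / intronic / intergenic space.

    Each read is a ``(chrom, start, end[, strand])`` 1-based closed
    genomic interval and is labelled once, by its 5'-most aligned base
    (start on '+', end on '-'), with precedence exonic > intronic >
    intergenic; the three fractions sum to 1.
    """
    exon_ivs: dict[str, list[tuple[int, int]]] = {}
    span_ivs: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        exon_ivs.setdefault(t.chrom, []).extend(t.exons)
        span_ivs.setdefault(t.chrom, []).append(t.span)
    exon_idx = {c: _merge(v) for c, v in exon_ivs.items()}
    span_idx = {c: _merge(v) for c, v in span_ivs.items()}

    by_chrom: dict[str, list[int]] = {}
    for read in reads:
        chrom, start, end = read[0], read[1], read[2]
        strand = read[3] if len(read) > 3 else "+"
        by_chrom.setdefault(chrom, []).append(start if strand == "+" else end)
    n_total = sum(len(v) for v in by_chrom.values())
    if n_total == 0:
        return {"exonic": 0.0, "intronic": 0.0, "intergenic": 0.0}
    n_exonic = n_genic = 0
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        in_exon = _member(*exon_idx.get(chrom, (np.empty(0, np.int64),) * 2),
                          pos)
        in_span = _member(*span_idx.get(chrom, (np.empty(0, np.int64),) * 2),
                          pos)
        n_exonic += int(in_exon.sum())
        n_genic += int((in_span & ~in_exon).sum())
    return {
        "exonic": n_exonic / n_total,
        "intronic": n_genic / n_total,
        "intergenic": (n_total - n_exonic - n_genic) / n_total,
    }


def sample_correlation(records_a: Sequence[ExpressionRecord],
                       records_b: Sequence[ExpressionRecord],
                       log_transform: bool = True) -> Optional[float]:
    """Pearson correlation of expression between two samples.

    Computed over the union gene set (a gene absent from one sample
    contributes FPKM 0), on log10(FPKM + 1) by default.  Returns None when
    either vector has zero variance.
    """
    a = {r.gene_id: r.fpkm for r in records_a}
    b = {r.gene_id: r.fpkm for r in records_b}
    genes = sorted(set(a) | set(b))
    if not genes:
        return None
    va = np.array([a.get(g, 0.0) for g in genes])
    vb = np.array([b.get(g, 0.0) for g in genes])
    if log_transform:
        va, vb = np.log10(va + 1), np.log10(vb + 1)
    if va.std() == 0 or vb.std() == 0:
        return None
    return float(np.corrcoef(va, vb)[0, 1])
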