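"""RNA-editing-site (RES) detection from matched single-cell DNA and RNA.

A candidate RES is a genomic position where, within one cell, both the
exome and the transcriptome are covered by at least eight reads, both
consensus calls are homozygous, and the called bases differ.  Candidates
then pass a fixed filter chain: strand-filter failures are discarded at
discovery, sites whose cells disagree on the mismatch type are dropped,
and sites heterozygous in the diploid liver reference are dropped (a
transcript made before meiosis I may carry the homologue lost to the polar
body).  Because mRNA-seq is not strand-specific, mismatch types are
reported relative to the Watson strand and resolved to a biological editing
type only when a unique annotated gene strand covers the site.

Every stage keeps an audit: records in = records out + records removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genotyping import GenotypeCall
from .io_formats import TranscriptModel

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

REGION_START = "start_codon"
REGION_STOP = "stop_codon"
REGION_CDS = "CDS"
REGION_UTR5 = "UTR5"
REGION_UTR3 = "UTR3"
REGION_NONCODING_EXON = "noncoding_exon"
REGION_INTRON = "intron"
REGION_INTERGENIC = "intergenic"


@dataclass(slots=True)
class CellEvidence:
    """One cell's support for a candidate site."""

    dna_base: str
    rna_base: str
    dna_depth: int
    rna_depth: int


@dataclass(slots=True)
class ResRecord:
    """A DNA-RNA mismatch candidate carried through the filter chain.

    ``mismatch_type`` is Watson-strand relative (e.g. ``"A>G"``);
    ``resolved_editing_type`` (e.g. ``"A-to-G"``) is present only when
    exactly one annotated gene strand covers the site.  ``filter_trail``
    records each stage as ``(stage, "pass"|"fail"|flag)``.
    """

    chrom: str
    pos: int
    dna_base: str
    rna_base: str
    cells: dict[str, CellEvidence]
    resolved_editing_type: Optional[str] = None
    gene_id: Optional[str] = None
    region: str = REGION_INTERGENIC
    strand_ambiguous: bool = False
    liver_uncovered: bool = False
    filter_trail: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mismatch_type(self) -> str:
        return f"{self.dna_base}>{self.rna_base}"

    @property
    def occurrence(self) -> int:
        return len(self.cells)


@dataclass(slots=True)
class StageAudit:
    """Record conservation at one filter stage."""

    stage: str
    n_in: int
    n_out: int
    n_removed: int


@dataclass(slots=True)
class CoverageOverlap:
    """Pairwise genomic-coverage overlap between samples.

    ``rates.loc[r, c]`` is |covered(r) ∩ covered(c)| / |covered(c)| — the
    matrix is column-normalised and not symmetric unless set sizes match.
    """

    sizes: dict[str, int]
    counts: pd.DataFrame
    rates: pd.DataFrame


def _covered_hom(call: Optional[GenotypeCall], min_depth: int
                 ) -> Optional[str]:
    """The single called base, if the call is a depth-qualified hom call
    that (for variants) passed the strand filter; else None."""
    if call is None or call.depth < min_depth:
        return None
    if call.status == "hom_ref":
        return call.ref_base
    if call.status == "hom_var" and call.strand_filter_pass:
        return call.alt_base
    return None


def find_candidates(dna_calls: Mapping[str, Sequence[GenotypeCall]],
                    rna_calls: Mapping[str, Sequence[GenotypeCall]],
                    min_depth: int = 8) -> list[ResRecord]:
    """DNA-RNA mismatch discovery, one candidate per (cell, site).

    Requires both modalities covered by at least ``min_depth`` reads with
    homozygous consensus calls for distinct bases; heterozygous sites
    (either molecule) and strand-filter failures are excluded.
    """
    if set(dna_calls) != set(rna_calls):
        missing = set(dna_calls) ^ set(rna_calls)
        raise ValueError(
            f"cells present in only one modality: {sorted(missing)}")
    candidates: list[ResRecord] = []
    for cell in sorted(dna_calls):
        rna_idx = {(c.chrom, c.pos): c for c in rna_calls[cell]}
        for dna in dna_calls[cell]:
            rna = rna_idx.get((dna.chrom, dna.pos))
            if rna is None:
                continue
            dna_base = _covered_hom(dna, min_depth)
            rna_base = _covered_hom(rna, min_depth)
            if dna_base is None or rna_base is None or dna_base == rna_base:
                continue
            candidates.append(ResRecord(
                chrom=dna.chrom, pos=dna.pos,
                dna_base=dna_base, rna_base=rna_base,
                cells={cell: CellEvidence(dna_base, rna_base,
                                          dna.depth, rna.depth)},
                filter_trail=[("depth_mismatch", "pass")],
            ))
    return candidates


def merge_by_site(candidates: Sequence[ResRecord]) -> list[ResRecord]:
    """Merge per-cell candidates into one record per genomic site.

    Cell evidence is pooled; the site-level (dna, rna) bases are taken from
    the cells and may disagree — :func:`filter_multitype` resolves that.
    """
    by_site: dict[tuple[str, int], ResRecord] = {}
    for cand in candidates:
        key = (cand.chrom, cand.pos)
        if key not in by_site:
            by_site[key] = ResRecord(
                chrom=cand.chrom, pos=cand.pos, dna_base=cand.dna_base,
                rna_base=cand.rna_base, cells=dict(cand.cells),
                filter_trail=list(cand.filter_trail))
        else:
            by_site[key].cells.update(cand.cells)
    return [by_site[k] for k in sorted(by_site)]


def filter_multitype(candidates: Sequence[ResRecord]
                     ) -> tuple[list[ResRecord], list[ResRecord]]:
    """Drop sites whose cells report more than one mismatch type.

    Input may be per-(cell, site) or already site-merged; output is
    site-merged.  A site is removed entirely when its cells disagree on the
    (DNA base, RNA base) pair; agreeing multi-cell sites keep all evidence.
    Returns ``(kept, removed)``.
    """
    merged = merge_by_site(candidates)
    kept, removed = [], []
    for rec in merged:
        types = {(ev.dna_base, ev.rna_base) for ev in rec.cells.values()}
        if len(types) > 1:
            rec.filter_trail.append(("multitype", "fail"))
            removed.append(rec)
        else:
            rec.filter_trail.append(("multitype", "pass"))
            kept.append(rec)
    return kept, removed


def filter_liver_het(candidates: Sequence[ResRecord],
                     liver_calls: Sequence[GenotypeCall]
                     ) -> tuple[list[ResRecord], list[ResRecord]]:
    """Drop candidates heterozygous in the diploid liver reference.

    Sites the liver exome does not cover are retained with a
    ``liver_uncovered`` flag (only sites *found* heterozygous are
    discarded).  Returns ``(kept, removed)``.
    """
    liver_idx = {(c.chrom, c.pos): c for c in liver_calls}
    kept, removed = [], []
    for rec in candidates:
        liver = liver_idx.get((rec.chrom, rec.pos))
        if liver is not None and liver.is_covered:
            if liver.status == "het":
                rec.filter_trail.append(("liver_het", "fail"))
                removed.append(rec)
                continue
            rec.filter_trail.append(("liver_het", "pass"))
        else:
            rec.liver_uncovered = True
            rec.filter_trail.append(("liver_het", "liver_uncovered"))
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# annotation-based resolution
# ---------------------------------------------------------------------------

def _codon_spans(t: TranscriptModel) -> tuple[Optional[tuple[int, int]],
                                              Optional[tuple[int, int]]]:
    """Genomic (start_codon, stop_codon) spans: the terminal codons of the
    CDS span, oriented by strand."""
    if t.cds is None:
        return None, None
    cs, ce = t.cds
    if t.strand == "+":
        return (cs, min(cs + 2, ce)), (max(ce - 2, cs), ce)
    return (max(ce - 2, cs), ce), (cs, min(cs + 2, ce))


def _region_in_transcript(t: TranscriptModel, pos: int) -> str:
    lo, hi = t.span
    if not (lo <= pos <= hi):
        return REGION_INTERGENIC
    exonic = any(s <= pos <= e for s, e in t.exons)
    if not exonic:
        return REGION_INTRON
    if t.cds is None:
        return REGION_NONCODING_EXON
    start_span, stop_span = _codon_spans(t)
    if start_span[0] <= pos <= start_span[1]:
        return REGION_START
    if stop_span[0] <= pos <= stop_span[1]:
        return REGION_STOP
    cs, ce = t.cds
    if cs <= pos <= ce:
        return REGION_CDS
    before_cds = pos < cs
    if (t.strand == "+") == before_cds:
        return REGION_UTR5
    return REGION_UTR3


class AnnotationIndex:
    """Transcript lookup by genomic position (per-chromosome lists)."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        return [t for t in self._by_chrom.get(chrom, ())
                if t.span[0] <= pos <= t.span[1]]


def resolve_editing_type(record: ResRecord,
                         annotation) -> ResRecord:
    """Assign genic region and strand-resolve the editing type in place.

    Region precedence: start/stop codon > CDS > UTR > intron > intergenic.
    Among same-strand genes the longest overlapping transcript wins (ties
    by gene_id).  If the unique covering gene strand is Crick, both bases
    of the Watson-relative mismatch are complemented (A>G on a Crick-strand
    gene is a T-to-C edit); genes on both strands leave the type unresolved
    with a ``strand_ambiguous`` flag.
    """
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex(annotation)
    hits = annotation.overlapping(record.chrom, record.pos)
    if not hits:
        record.region = REGION_INTERGENIC
        record.gene_id = None
        record.resolved_editing_type = None
        record.filter_trail.append(("annotate", "intergenic"))
        return record
    # longest overlapping transcript wins; ties by lexicographic gene_id
    winner = sorted(hits, key=lambda t: (-t.length, t.gene_id))[0]
    record.region = _region_in_transcript(winner, record.pos)
    record.gene_id = winner.gene_id
    strands = {t.strand for t in hits}
    if len(strands) > 1:
        record.strand_ambiguous = True
        record.resolved_editing_type = None
        record.filter_trail.append(("annotate", "strand_ambiguous"))
    else:
        strand = strands.pop()
        if strand == "+":
            d, r = record.dna_base, record.rna_base
        else:
            d, r = COMPLEMENT[record.dna_base], COMPLEMENT[record.rna_base]
        record.resolved_editing_type = f"{d}-to-{r}"
        record.filter_trail.append(("annotate", "pass"))
    return record


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def occurrence_summary(records: Sequence[ResRecord]
                       ) -> tuple[dict[int, int], pd.DataFrame]:
    """Histogram of per-site cell occurrence plus a per-gene RES table.

    The histogram maps (number of cells a RES was detected in) -> count of
    distinct sites; the gene table is sorted by descending RES count, ties
    by gene_id.
    """
    hist: dict[int, int] = {}
    gene_counts: dict[str, int] = {}
    for rec in records:
        hist[rec.occurrence] = hist.get(rec.occurrence, 0) + 1
        if rec.gene_id is not None:
            gene_counts[rec.gene_id] = gene_counts.get(rec.gene_id, 0) + 1
    table = pd.DataFrame(
        sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "n_res"],
    )
    return hist, table


def coverage_overlap(site_sets: Mapping[str, set]) -> CoverageOverlap:
    """Pairwise coverage-overlap rates between per-sample covered-site sets.

    rate(row r, column c) = |r ∩ c| / |c|; a sample with an empty covered
    set yields an undefined (NaN) column.
    """
    samples = sorted(site_sets)
    counts = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    rates = pd.DataFrame(float("nan"), index=samples, columns=samples)
    for r in samples:
        for c in samples:
            inter = len(site_sets[r] & site_sets[c])
            counts.loc[r, c] = inter
            if site_sets[c]:
                rates.loc[r, c] = inter / len(site_sets[c])
    return CoverageOverlap(
        sizes={s: len(site_sets[s]) for s in samples},
        counts=counts, rates=rates,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PipelineResult:
    """Final RES set plus the per-stage conservation audit."""

    records: list[ResRecord]
    removed: dict[str, list[ResRecord]]
    audit: list[StageAudit]

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame([(a.stage, a.n_in, a.n_out, a.n_removed)
                             for a in self.audit],
                            columns=["stage", "n_in", "n_out", "n_removed"])


def run_pipeline(dna_calls: Mapping[str, Sequence[GenotypeCall]],
                 rna_calls: Mapping[str, Sequence[GenotypeCall]],
                 liver_calls: Sequence[GenotypeCall],
                 annotation: Sequence[TranscriptModel] | AnnotationIndex,
                 min_depth: int = 8) -> PipelineResult:
    """Run the full detection chain and audit every stage.

    Stages: per-cell mismatch discovery, site merge, multi-type filter,
    liver-het filter, annotation/strand resolution.  Conservation
    (n_in == n_out + n_removed) holds at each site-level stage.
    """
    candidates = find_candidates(dna_calls, rna_calls, min_depth)
    merged = merge_by_site(candidates)
    audit = [StageAudit("discovery", len(candidates), len(candidates), 0),
             StageAudit("site_merge", len(merged), len(merged), 0)]
    kept, rm_multi = filter_multitype(merged)
    audit.append(StageAudit("multitype", len(merged), len(kept),
                            len(rm_multi)))
    n_in = len(kept)
    kept, rm_liver = filter_liver_het(kept, liver_calls)
    audit.append(StageAudit("liver_het", n_in, len(kept), len(rm_liver)))
    index = annotation if isinstance(annotation, AnnotationIndex) \
        else AnnotationIndex(annotation)
    for rec in kept:
        resolve_editing_type(rec, index)
    audit.append(StageAudit("annotate", len(kept), len(kept), 0))
    return PipelineResult(records=kept,
                          removed={"multitype": rm_multi,
                                   "liver_het": rm_liver},
                          audit=audit)
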