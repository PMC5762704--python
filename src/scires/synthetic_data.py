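"""Seeded simulator for the full study design the pipeline assumes.

One diploid individual (the liver reference genotype, heterozygous at
every simulated SNP) undergoes independent meioses, one per oocyte: a
classic two-strand crossover exchanges the distal segments of one
chromatid of each homolog, the MII oocyte receives one homolog's chromatid
pair and the first polar body the other, so the oocyte is heterozygous
exactly at SNPs distal to an odd number of crossovers — and its PB1 at the
same sites.  DNA pileups are drawn under two whole-genome-amplification
regimes (MDA-like: broad coverage in long runs; DOP-PCR-like: sparser,
fragmented runs with low inter-sample overlap); RNA pileups come from
log-normally expressed transcripts with 3'-biased read placement
(truncated-exponential over the transcript coordinate) and planted
editing events (default A-to-G on the sense strand, emitted
strand-correctly in genomic coordinates).  Sequencing is non-strand-
specific and errors substitute uniformly among the other three bases.

Every planted feature is recorded in ground-truth ledgers; the whole
bundle is a pure function of :class:`SimConfig`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import BASES, PileupColumn, TranscriptModel, write_gtf, \
    write_pileup
from .transcript_coverage import TranscriptReads

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

MDA_LIKE = "MDA_like"
DOPPCR_LIKE = "DOPPCR_like"


@dataclass
class SimConfig:
    """All knobs of the simulator; the seed fixes every draw.

    Coverage regimes: ``amplification_modes`` assigns one regime per
    oocyte (its PB1 inherits the same regime); the liver bulk sample is
    always MDA-like at ``liver_covered_fraction``.  ``editing_site_rate``
    is events per expressed exonic kb; ``editing_level`` is the fraction
    of transcripts edited at a planted site (1.0 by default so the
    >= 75%-consensus rule makes recovery well defined; set
    ``editing_level_sd`` > 0 for the mixed-level mode).
    """

    seed: int = 42
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    snp_density: float = 1e-3
    n_genes: int = 60
    exons_per_gene: int = 3
    exon_length: int = 400
    intron_length: int = 600
    utr_length: int = 120
    coding_fraction: float = 0.85
    crossovers_per_chromosome: int = 1
    n_oocytes: int = 6
    dna_depth_mean: float = 25.0
    rna_depth_mean: float = 30.0
    read_length: int = 100
    seq_error_rate: float = 0.001
    editing_site_rate: float = 4.0
    editing_level: float = 1.0
    editing_level_sd: float = 0.0
    amplification_modes: tuple[str, ...] = (
        MDA_LIKE, MDA_LIKE, DOPPCR_LIKE, DOPPCR_LIKE, DOPPCR_LIKE,
        DOPPCR_LIKE)
    covered_fraction: dict = field(default_factory=lambda: {
        MDA_LIKE: 0.7, DOPPCR_LIKE: 0.3})
    mean_covered_run: dict = field(default_factory=lambda: {
        MDA_LIKE: 10_000, DOPPCR_LIKE: 1_500})
    liver_covered_fraction: float = 0.9
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    expressed_fraction: float = 0.9
    three_prime_tau: float = 600.0
    intronic_read_fraction: float = 0.055
    intergenic_read_fraction: float = 0.18

    def __post_init__(self) -> None:
        if len(self.amplification_modes) != self.n_oocytes:
            raise ValueError("need one amplification mode per oocyte")
        for mode in self.amplification_modes:
            if mode not in (MDA_LIKE, DOPPCR_LIKE):
                raise ValueError(f"unknown amplification mode {mode!r}")
        if not (0 < self.liver_covered_fraction <= 1):
            raise ValueError("liver_covered_fraction must be in (0, 1]")
        for v in self.covered_fraction.values():
            if not (0 < v <= 1):
                raise ValueError("covered_fraction values must be in (0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def oocyte_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_oocytes)]

    @property
    def pb1_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_oocytes)]


# ---------------------------------------------------------------------------
# compact pileup container
# ---------------------------------------------------------------------------

class SamplePileup:
    """Per-sample pileups stored as compact per-chromosome arrays.

    Column counts live in an (n_sites, 8) array ordered
    (A+, A-, C+, C-, G+, G-, T+, T-); :meth:`iter_columns` yields standard
    :class:`PileupColumn` objects in (chrom, pos) order.
    """

    def __init__(self) -> None:
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.covered_bp: int = 0  # total covered genome length (intervals)

    def add_chrom(self, chrom: str, pos: np.ndarray, ref_idx: np.ndarray,
                  counts: np.ndarray) -> None:
        self.data[chrom] = (pos, ref_idx, counts)

    def iter_columns(self) -> Iterator[PileupColumn]:
        for chrom in sorted(self.data):
            pos, ref_idx, counts = self.data[chrom]
            for i in range(len(pos)):
                row = counts[i]
                cdict = {}
                for j in range(8):
                    if row[j]:
                        cdict[(BASES[j // 2], "+" if j % 2 == 0 else "-")] = \
                            int(row[j])
                yield PileupColumn(chrom=chrom, pos=int(pos[i]),
                                   ref_base=BASES[int(ref_idx[i])],
                                   counts=cdict,
                                   depth=int(row.sum()))

    def depth_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Read depth at the given positions (0 where uncovered)."""
        if chrom not in self.data:
            return np.zeros(len(positions), dtype=np.int64)
        pos, _ref, counts = self.data[chrom]
        depth = counts.sum(axis=1)
        idx = np.searchsorted(pos, positions)
        out = np.zeros(len(positions), dtype=np.int64)
        ok = (idx < len(pos))
        ok[ok] &= pos[idx[ok]] == np.asarray(positions)[ok]
        out[ok] = depth[idx[ok]]
        return out

    def covered_sites(self, min_depth: int = 8) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for chrom, (pos, _ref, counts) in self.data.items():
            depth = counts.sum(axis=1)
            out.update((chrom, int(p)) for p in pos[depth >= min_depth])
        return out


# ---------------------------------------------------------------------------
# individual, meiosis
# ---------------------------------------------------------------------------

@dataclass
class Diploid:
    """Reference sequence plus the diploid (liver) SNP set.

    Liver is heterozygous at every SNP; ``hom1_base``/``hom2_base`` give
    the (random) phase of the two homologs.
    """

    config: SimConfig
    ref: dict[str, np.ndarray]  # base indices 0..3
    snps: pd.DataFrame  # chrom, pos, ref_base, alt_base, hom1_base, hom2_base

    def snp_positions(self, chrom: str) -> np.ndarray:
        sub = self.snps[self.snps["chrom"] == chrom]
        return sub["pos"].to_numpy(dtype=np.int64)


def simulate_individual(config: SimConfig,
                        rng: Optional[np.random.Generator] = None) -> Diploid:
    """Draw the reference genome and the diploid SNP set.

    SNP positions are Bernoulli(``snp_density``) per base; alleles are
    ref plus a distinct alt; the phase assigns each allele to a homolog at
    random.  Liver truth is heterozygous at every SNP and homozygous
    reference elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.snp_density * config.chrom_length * config.n_chromosomes < 1:
        warnings.warn("expected SNP count below 1; zero SNPs is possible")
    ref = {}
    rows = []
    for chrom in config.chrom_names:
        seq = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        ref[chrom] = seq
        hits = np.nonzero(rng.random(config.chrom_length)
                          < config.snp_density)[0]
        for p0 in hits:
            r = int(seq[p0])
            alt = int(rng.integers(0, 3))
            if alt >= r:
                alt += 1
            phase = int(rng.integers(0, 2))
            h1, h2 = (r, alt) if phase == 0 else (alt, r)
            rows.append((chrom, int(p0) + 1, BASES[r], BASES[alt],
                         BASES[h1], BASES[h2]))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref_base",
                                       "alt_base", "hom1_base", "hom2_base"])
    return Diploid(config=config, ref=ref, snps=snps)


@dataclass
class MeiosisProduct:
    """Chromatid pairs and derived truth genotypes for one meiosis.

    ``oocyte_chromatids[chrom]`` is a pair of base-character arrays over
    that chromosome's SNP sites; ``truth`` has one row per SNP with the
    oocyte and PB1 status (het/hom) and allele pair.
    """

    crossovers: dict[str, list[int]]
    oocyte_chromatids: dict[str, tuple[np.ndarray, np.ndarray]]
    pb1_chromatids: dict[str, tuple[np.ndarray, np.ndarray]]
    truth: pd.DataFrame  # chrom,pos,oocyte_status,oocyte_bases,pb1_status,pb1_bases


def simulate_meiosis(diploid: Diploid, config: SimConfig,
                     rng: np.random.Generator) -> MeiosisProduct:
    """One meiosis: two-strand crossovers, random segregation.

    Each crossover exchanges the segments distal to a uniform position
    between one chromatid of each homolog; the oocyte keeps one homolog's
    chromatid pair (chosen at random), the PB1 the other.  A SNP is
    heterozygous in the oocyte — and in its PB1 — iff an odd number of
    crossovers lie proximal to it.
    """
    crossovers: dict[str, list[int]] = {}
    oo_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pb_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for chrom in config.chrom_names:
        sub = diploid.snps[diploid.snps["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        h1 = sub["hom1_base"].to_numpy().copy()
        h2 = sub["hom2_base"].to_numpy().copy()
        xs = sorted(int(x) for x in
                    rng.integers(1, config.chrom_length + 1,
                                 size=config.crossovers_per_chromosome))
        crossovers[chrom] = xs
        h1a, h1b = h1.copy(), h1.copy()
        h2a, h2b = h2.copy(), h2.copy()
        for x in xs:
            distal = pos > x
            h1b[distal], h2b[distal] = h2b[distal].copy(), h1b[distal].copy()
        if rng.integers(0, 2) == 0:
            oo, pb = (h1a, h1b), (h2a, h2b)
        else:
            oo, pb = (h2a, h2b), (h1a, h1b)
        oo_chrom[chrom] = oo
        pb_chrom[chrom] = pb
        for i, p in enumerate(pos):
            o1, o2 = oo[0][i], oo[1][i]
            p1, p2 = pb[0][i], pb[1][i]
            rows.append((chrom, int(p),
                         "het" if o1 != o2 else "hom", o1 + "/" + o2,
                         "het" if p1 != p2 else "hom", p1 + "/" + p2))
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "oocyte_status",
                                        "oocyte_bases", "pb1_status",
                                        "pb1_bases"])
    return MeiosisProduct(crossovers=crossovers, oocyte_chromatids=oo_chrom,
                          pb1_chromatids=pb_chrom, truth=truth)


# ---------------------------------------------------------------------------
# gene models, expression, editing
# ---------------------------------------------------------------------------

def simulate_genes(config: SimConfig, rng: np.random.Generator
                   ) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Place non-overlapping gene models and draw expression levels.

    Genes are laid out left to right, round-robin over chromosomes, with
    random intergenic gaps; most are protein-coding (CDS inset by
    ``utr_length`` from each end of the exon union), the rest lncRNA.
    Expression is log-normal for an ``expressed_fraction`` of genes, zero
    for the rest; ``rel_level`` is level / median(expressed levels).
    """
    transcripts: list[TranscriptModel] = []
    cursors = {c: 2_000 for c in config.chrom_names}
    span = (config.exons_per_gene * config.exon_length
            + (config.exons_per_gene - 1) * config.intron_length)
    rows = []
    for i in range(config.n_genes):
        chrom = config.chrom_names[i % config.n_chromosomes]
        start = cursors[chrom] + int(rng.integers(500, 3_000))
        if start + span > config.chrom_length - 2_000:
            continue  # chromosome full
        cursors[chrom] = start + span
        exons = []
        s = start
        for _ in range(config.exons_per_gene):
            exons.append((s, s + config.exon_length - 1))
            s += config.exon_length + config.intron_length
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        coding = rng.random() < config.coding_fraction
        cds = None
        if coding:
            cds = (exons[0][0] + config.utr_length,
                   exons[-1][1] - config.utr_length)
        gene_id, tid = f"gene{i:04d}", f"tx{i:04d}"
        transcripts.append(TranscriptModel(
            gene_id=gene_id, transcript_id=tid, chrom=chrom, strand=strand,
            exons=exons, cds=cds,
            biotype="protein_coding" if coding else "lncRNA"))
        expressed = rng.random() < config.expressed_fraction
        level = float(rng.lognormal(config.expression_mu,
                                    config.expression_sigma)) \
            if expressed else 0.0
        rows.append((gene_id, tid, level))
    expr = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "level"])
    pos_levels = expr.loc[expr["level"] > 0, "level"]
    med = float(pos_levels.median()) if len(pos_levels) else 1.0
    expr["rel_level"] = expr["level"] / med
    return transcripts, expr


def _transcript_gpos(t: TranscriptModel) -> np.ndarray:
    """Genomic position of each transcript base, 5'->3'."""
    gpos = np.concatenate([np.arange(s, e + 1) for s, e in t.exons])
    return gpos[::-1] if t.strand == "-" else gpos


def plant_editing(transcripts: Sequence[TranscriptModel],
                  expression: pd.DataFrame, diploid: Diploid,
                  config: SimConfig, rng: np.random.Generator
                  ) -> pd.DataFrame:
    """Plant A-to-G sense-strand editing events on expressed transcripts.

    Events land on exonic positions whose sense-strand base is A (so the
    genomic pileup shows A>G for Watson-strand genes and T>C for
    Crick-strand genes), never on a SNP.  Counts per transcript are
    Poisson(``editing_site_rate`` x exonic kb); levels come from the
    configured level distribution clipped to (0, 1].
    """
    expr_by_tid = dict(zip(expression["transcript_id"],
                           expression["rel_level"]))
    snp_keys = set(zip(diploid.snps["chrom"], diploid.snps["pos"]))
    rows = []
    for t in transcripts:
        if expr_by_tid.get(t.transcript_id, 0.0) <= 0:
            continue
        gpos = _transcript_gpos(t)
        ref = diploid.ref[t.chrom][gpos - 1]
        sense_a = ref == (_BASE_IDX["A"] if t.strand == "+"
                          else _BASE_IDX["T"])
        ok = np.array([(t.chrom, int(p)) not in snp_keys for p in gpos])
        pool = gpos[sense_a & ok]
        if pool.size == 0:
            continue
        n = min(int(rng.poisson(config.editing_site_rate * t.length / 1000)),
                pool.size)
        if n == 0:
            continue
        chosen = rng.choice(pool, size=n, replace=False)
        for p in np.sort(chosen):
            if config.editing_level_sd > 0:
                level = float(np.clip(rng.normal(config.editing_level,
                                                 config.editing_level_sd),
                                      0.05, 1.0))
            else:
                level = config.editing_level
            if t.strand == "+":
                dna_b, rna_b = "A", "G"
            else:
                dna_b, rna_b = "T", "C"
            rows.append((t.chrom, int(p), t.gene_id, t.transcript_id,
                         t.strand, dna_b, rna_b, level))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id",
                                       "transcript_id", "strand",
                                       "watson_dna_base", "watson_rna_base",
                                       "level"])


# ---------------------------------------------------------------------------
# pileup synthesis
# ---------------------------------------------------------------------------

def _site_universe(diploid: Diploid,
                   transcripts: Sequence[TranscriptModel]
                   ) -> dict[str, np.ndarray]:
    """Sorted union of SNP and exonic positions per chromosome — the
    positions at which pileups are materialised."""
    universe = {}
    for chrom in diploid.config.chrom_names:
        parts = [diploid.snp_positions(chrom)]
        for t in transcripts:
            if t.chrom == chrom:
                parts.extend(np.arange(s, e + 1) for s, e in t.exons)
        universe[chrom] = np.unique(
            np.concatenate(parts).astype(np.int64)) if parts else \
            np.empty(0, dtype=np.int64)
    return universe


def _coverage_intervals(length: int, fraction: float, mean_run: float,
                        rng: np.random.Generator) -> list[tuple[int, int]]:
    """Alternating exponential covered/gap runs achieving the target
    covered fraction in expectation."""
    if fraction >= 1.0:
        return [(1, length)]
    mean_gap = mean_run * (1 - fraction) / fraction
    intervals = []
    pos = 1
    covered = rng.random() < fraction
    while pos <= length:
        mean = mean_run if covered else mean_gap
        run = max(1, int(rng.exponential(mean)))
        if covered:
            intervals.append((pos, min(length, pos + run - 1)))
        pos += run
        covered = not covered
    return intervals


def _mask_from_intervals(positions: np.ndarray,
                         intervals: list[tuple[int, int]]) -> np.ndarray:
    if not intervals:
        return np.zeros(len(positions), dtype=bool)
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(len(positions), dtype=bool)
    mask[ok] = positions[ok] <= ends[idx[ok]]
    return mask


def _error_smear(weights: np.ndarray, error_rate: float) -> np.ndarray:
    """Apply uniform substitution error to per-site base weights (n, 4)."""
    return weights * (1 - error_rate) + (1 - weights) * (error_rate / 3)


def _draw_counts(weights: np.ndarray, depth: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Multinomial stranded counts (n, 8) from base weights and depths."""
    p8 = np.repeat(weights, 2, axis=1) * 0.5
    p8 /= p8.sum(axis=1, keepdims=True)
    return rng.multinomial(depth, p8).astype(np.uint16)


def _genotype_weights(alleles: np.ndarray) -> np.ndarray:
    """(n, 2) allele indices -> (n, 4) base weights (het sites 50/50)."""
    n = len(alleles)
    w = np.zeros((n, 4))
    rows = np.arange(n)
    np.add.at(w, (rows, alleles[:, 0]), 0.5)
    np.add.at(w, (rows, alleles[:, 1]), 0.5)
    return w


def _sample_genotype(diploid: Diploid, universe: dict[str, np.ndarray],
                     chromatids: Optional[dict[str, tuple[np.ndarray,
                                                          np.ndarray]]]
                     ) -> dict[str, np.ndarray]:
    """Per-chromosome (n_sites, 2) allele indices over the site universe.

    ``chromatids=None`` gives the diploid (liver) genotype: het at SNPs.
    """
    out = {}
    for chrom, pos in universe.items():
        ref = diploid.ref[chrom][pos - 1]
        geno = np.stack([ref, ref], axis=1).astype(np.int64)
        snp_pos = diploid.snp_positions(chrom)
        if len(snp_pos):
            idx = np.searchsorted(pos, snp_pos)
            sub = diploid.snps[diploid.snps["chrom"] == chrom]
            if chromatids is None:
                a1 = sub["hom1_base"].map(_BASE_IDX).to_numpy()
                a2 = sub["hom2_base"].map(_BASE_IDX).to_numpy()
            else:
                c1, c2 = chromatids[chrom]
                a1 = np.array([_BASE_IDX[b] for b in c1])
                a2 = np.array([_BASE_IDX[b] for b in c2])
            geno[idx, 0] = a1
            geno[idx, 1] = a2
        out[chrom] = geno
    return out


def simulate_dna_pileups(genotype: dict[str, np.ndarray],
                         universe: dict[str, np.ndarray],
                         diploid: Diploid, fraction: float, mean_run: float,
                         config: SimConfig, rng: np.random.Generator
                         ) -> SamplePileup:
    """Amplification-biased DNA pileups for one sample.

    Coverage comes in alternating exponential runs (regime-specific run
    length and fraction), depth is negative-binomial around
    ``dna_depth_mean``, reads draw alleles 50/50 at het sites with
    ``seq_error_rate`` substitutions and Bernoulli(0.5) strands.
    """
    sample = SamplePileup()
    for chrom in config.chrom_names:
        pos = universe[chrom]
        intervals = _coverage_intervals(config.chrom_length, fraction,
                                        mean_run, rng)
        sample.covered_bp += sum(e - s + 1 for s, e in intervals)
        mask = _mask_from_intervals(pos, intervals)
        cpos = pos[mask]
        if cpos.size == 0:
            sample.add_chrom(chrom, cpos, np.empty(0, np.uint8),
                             np.empty((0, 8), np.uint16))
            continue
        depth = rng.negative_binomial(
            8, 8 / (8 + config.dna_depth_mean - 1), size=cpos.size) + 1
        weights = _error_smear(_genotype_weights(genotype[chrom][mask]),
                               config.seq_error_rate)
        counts = _draw_counts(weights, depth, rng)
        sample.add_chrom(chrom, cpos, diploid.ref[chrom][cpos - 1], counts)
    return sample


@dataclass
class RnaSample:
    """RNA pileups plus the read-level ledgers for one cell."""

    pileup: SamplePileup
    read_positions: dict[str, TranscriptReads]  # transcript coords
    read_intervals: list[tuple[str, int, int, str]]  # genomic, 1-based closed
    gene_counts: dict[str, int]  # exonic reads per gene
    total_reads: int


def simulate_rna(genotype: dict[str, np.ndarray],
                 universe: dict[str, np.ndarray],
                 diploid: Diploid, transcripts: Sequence[TranscriptModel],
                 expression: pd.DataFrame, editing: pd.DataFrame,
                 config: SimConfig, rng: np.random.Generator) -> RnaSample:
    """3'-biased, edited RNA for one enucleated-oocyte cytoplasm.

    Reads per transcript are Poisson around a coverage target proportional
    to the relative expression level; 5' offsets follow a truncated
    exponential rising toward the 3' end (scale ``three_prime_tau`` bp, so
    the percentile-space skew grows with transcript length).  Pileups at
    planted editing sites replace the transcribed base at the configured
    level; background intronic and intergenic reads are added to the
    read-interval ledger only.
    """
    expr_by_tid = dict(zip(expression["transcript_id"],
                           expression["rel_level"]))
    edit_idx: dict[str, dict[int, tuple[int, float]]] = {}
    for row in editing.itertuples():
        edit_idx.setdefault(row.chrom, {})[row.pos] = \
            (_BASE_IDX[row.watson_rna_base], row.level)

    depth_arrays = {c: np.zeros(len(universe[c]), dtype=np.int64)
                    for c in universe}
    read_positions: dict[str, TranscriptReads] = {}
    read_intervals: list[tuple[str, int, int, str]] = []
    gene_counts: dict[str, int] = {}
    rl = config.read_length
    for t in transcripts:
        rel = expr_by_tid.get(t.transcript_id, 0.0)
        if rel <= 0:
            continue
        length = t.length
        n_reads = int(rng.poisson(rel * config.rna_depth_mean
                                  * length / rl))
        if n_reads == 0:
            read_positions[t.transcript_id] = TranscriptReads([], [])
            continue
        span_max = max(1, length - rl)
        u = rng.random(n_reads)
        tau = config.three_prime_tau
        # inverse CDF of f(x) ~ exp(x / tau) on [0, span_max]
        offsets = (span_max
                   + tau * np.log(u + (1 - u) * np.exp(-span_max / tau)))
        offsets = np.clip(offsets.astype(np.int64), 0, span_max)
        cover = [(int(o), int(min(o + rl, length))) for o in offsets]
        read_positions[t.transcript_id] = TranscriptReads(
            offsets=[int(o) for o in offsets], cover=cover)
        gene_counts[t.gene_id] = gene_counts.get(t.gene_id, 0) + n_reads
        # per-base transcript depth -> genomic depth over the universe
        delta = np.zeros(length + 1, dtype=np.int64)
        for o, e in cover:
            delta[o] += 1
            delta[e] -= 1
        tdepth = np.cumsum(delta[:-1])
        gpos = _transcript_gpos(t)
        uidx = np.searchsorted(universe[t.chrom], gpos)
        np.add.at(depth_arrays[t.chrom], uidx, tdepth)
        for o in offsets:
            g5 = int(gpos[o])
            g3 = int(gpos[min(o + rl - 1, length - 1)])
            read_intervals.append((t.chrom, min(g5, g3), max(g5, g3),
                                   t.strand))

    n_exonic = len(read_intervals)
    read_intervals.extend(_background_reads(diploid, transcripts, n_exonic,
                                            config, rng))
    total_reads = len(read_intervals)

    pileup = SamplePileup()
    for chrom in config.chrom_names:
        pos = universe[chrom]
        depth = depth_arrays[chrom]
        mask = depth > 0
        cpos = pos[mask]
        if cpos.size == 0:
            pileup.add_chrom(chrom, cpos, np.empty(0, np.uint8),
                             np.empty((0, 8), np.uint16))
            continue
        weights = _genotype_weights(genotype[chrom][mask])
        edits = edit_idx.get(chrom, {})
        if edits:
            for i, p in enumerate(cpos):
                hit = edits.get(int(p))
                if hit is not None:
                    base, level = hit
                    onehot = np.zeros(4)
                    onehot[base] = 1.0
                    weights[i] = (1 - level) * weights[i] + level * onehot
        weights = _error_smear(weights, config.seq_error_rate)
        counts = _draw_counts(weights, depth[mask], rng)
        pileup.add_chrom(chrom, cpos, diploid.ref[chrom][cpos - 1], counts)
    return RnaSample(pileup=pileup, read_positions=read_positions,
                     read_intervals=read_intervals, gene_counts=gene_counts,
                     total_reads=total_reads)


def _background_reads(diploid: Diploid,
                      transcripts: Sequence[TranscriptModel], n_exonic: int,
                      config: SimConfig, rng: np.random.Generator
                      ) -> list[tuple[str, int, int, str]]:
    """Intronic and intergenic reads (ledger only, no pileup depth)."""
    f_in, f_ig = config.intronic_read_fraction, config.intergenic_read_fraction
    f_ex = 1 - f_in - f_ig
    if f_ex <= 0 or n_exonic == 0:
        return []
    out: list[tuple[str, int, int, str]] = []
    exonic: dict[str, set[int]] = {}
    genic: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        s = exonic.setdefault(t.chrom, set())
        for a, b in t.exons:
            s.update(range(a, b + 1))
        genic.setdefault(t.chrom, []).append(t.span)
    intronic_pool = []
    for chrom, spans in genic.items():
        ex = exonic[chrom]
        for a, b in spans:
            intronic_pool.extend((chrom, p) for p in range(a, b + 1)
                                 if p not in ex)
    n_in = int(round(n_exonic * f_in / f_ex))
    n_ig = int(round(n_exonic * f_ig / f_ex))
    if intronic_pool:
        picks = rng.integers(0, len(intronic_pool), size=n_in)
        for i in picks:
            chrom, p = intronic_pool[i]
            out.append((chrom, p, min(p + config.read_length - 1,
                                      config.chrom_length), "+"))
    for _ in range(n_ig):
        while True:
            chrom = config.chrom_names[int(rng.integers(
                0, config.n_chromosomes))]
            p = int(rng.integers(1, config.chrom_length + 1))
            spans = genic.get(chrom, [])
            if not any(a <= p <= b for a, b in spans):
                break
        out.append((chrom, p, min(p + config.read_length - 1,
                                  config.chrom_length), "+"))
    return out


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """Everything one simulated study produces, with ground truth."""

    config: SimConfig
    diploid: Diploid
    transcripts: list[TranscriptModel]
    expression: pd.DataFrame
    editing: pd.DataFrame
    meioses: dict[str, MeiosisProduct]  # oocyte name -> product
    dna_pileups: dict[str, SamplePileup]  # S*, P*, liver
    rna: dict[str, RnaSample]  # oocyte name -> RNA sample
    universe: dict[str, np.ndarray]

    @property
    def snp_sites(self) -> set[tuple[str, int]]:
        return set(zip(self.diploid.snps["chrom"], self.diploid.snps["pos"]))

    @property
    def editing_sites(self) -> set[tuple[str, int]]:
        return set(zip(self.editing["chrom"], self.editing["pos"]))


def generate_bundle(config: SimConfig) -> Bundle:
    """Simulate the full default study: oocytes + PB1s + liver + RNA.

    Deterministic given ``config.seed``: every component draws from its
    own child stream of one seed sequence, in fixed order.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(4 + 3 * config.n_oocytes + 1)
    rng_genome = np.random.default_rng(streams[0])
    rng_genes = np.random.default_rng(streams[1])
    rng_editing = np.random.default_rng(streams[2])
    rng_liver = np.random.default_rng(streams[3])

    diploid = simulate_individual(config, rng_genome)
    transcripts, expression = simulate_genes(config, rng_genes)
    editing = plant_editing(transcripts, expression, diploid, config,
                            rng_editing)
    universe = _site_universe(diploid, transcripts)

    liver_geno = _sample_genotype(diploid, universe, None)
    dna_pileups = {"liver": simulate_dna_pileups(
        liver_geno, universe, diploid, config.liver_covered_fraction,
        config.mean_covered_run[MDA_LIKE], config, rng_liver)}

    meioses: dict[str, MeiosisProduct] = {}
    rna: dict[str, RnaSample] = {}
    for i, name in enumerate(config.oocyte_names):
        rng_mei = np.random.default_rng(streams[4 + 3 * i])
        rng_dna = np.random.default_rng(streams[5 + 3 * i])
        rng_rna = np.random.default_rng(streams[6 + 3 * i])
        product = simulate_meiosis(diploid, config, rng_mei)
        meioses[name] = product
        mode = config.amplification_modes[i]
        oo_geno = _sample_genotype(diploid, universe,
                                   product.oocyte_chromatids)
        pb_geno = _sample_genotype(diploid, universe,
                                   product.pb1_chromatids)
        dna_pileups[name] = simulate_dna_pileups(
            oo_geno, universe, diploid, config.covered_fraction[mode],
            config.mean_covered_run[mode], config, rng_dna)
        dna_pileups[config.pb1_names[i]] = simulate_dna_pileups(
            pb_geno, universe, diploid, config.covered_fraction[mode],
            config.mean_covered_run[mode], config, rng_dna)
        rna[name] = simulate_rna(oo_geno, universe, diploid, transcripts,
                                 expression, editing, config, rng_rna)
    return Bundle(config=config, diploid=diploid, transcripts=transcripts,
                  expression=expression, editing=editing, meioses=meioses,
                  dna_pileups=dna_pileups, rna=rna, universe=universe)


def emit_dataset(config: SimConfig, outdir: str | Path,
                 force: bool = False) -> Bundle:
    """Write a complete on-disk bundle; returns the in-memory bundle.

    Layout: ``<sample>.dna.pileup`` (S1..Sn, P1..Pn, liver),
    ``<cell>.rna.pileup``, ``readpos_<cell>.tsv``, ``reads_<cell>.tsv``,
    ``annotation.gtf``, ``truth_*.tsv`` ledgers and ``config.yaml``.
    Regenerating with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)

    for name in sorted(bundle.dna_pileups):
        with open(outdir / f"{name}.dna.pileup", "w") as fh:
            write_pileup(bundle.dna_pileups[name].iter_columns(), fh)
    for name in sorted(bundle.rna):
        sample = bundle.rna[name]
        with open(outdir / f"{name}.rna.pileup", "w") as fh:
            write_pileup(sample.pileup.iter_columns(), fh)
        with open(outdir / f"readpos_{name}.tsv", "w") as fh:
            fh.write("transcript_id\toffset\tcover_start\tcover_end\n")
            for tid in sorted(sample.read_positions):
                reads = sample.read_positions[tid]
                for o, (cs, ce) in zip(reads.offsets, reads.cover):
                    fh.write(f"{tid}\t{o}\t{cs}\t{ce}\n")
        with open(outdir / f"reads_{name}.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\n")
            for chrom, s, e, strand in sample.read_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{strand}\n")
    with open(outdir / "annotation.gtf", "w") as fh:
        write_gtf(bundle.transcripts, fh)
    bundle.diploid.snps.to_csv(outdir / "truth_snps.tsv", sep="\t",
                               index=False)
    xo_rows = [(name, chrom, x)
               for name in sorted(bundle.meioses)
               for chrom, xs in sorted(bundle.meioses[name].crossovers.items())
               for x in xs]
    pd.DataFrame(xo_rows, columns=["sample", "chrom", "pos"]).to_csv(
        outdir / "truth_crossovers.tsv", sep="\t", index=False)
    bundle.editing.to_csv(outdir / "truth_editing.tsv", sep="\t", index=False)
    expr = bundle.expression.copy()
    for name in sorted(bundle.rna):
        expr[f"reads_{name}"] = expr["gene_id"].map(
            bundle.rna[name].gene_counts).fillna(0).astype(int)
    expr.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
    geno_rows = []
    for name in sorted(bundle.meioses):
        truth = bundle.meioses[name].truth
        for row in truth.itertuples():
            geno_rows.append((name, row.chrom, row.pos, row.oocyte_status,
                              row.oocyte_bases, row.pb1_status,
                              row.pb1_bases))
    pd.DataFrame(geno_rows, columns=["sample", "chrom", "pos",
                                     "oocyte_status", "oocyte_bases",
                                     "pb1_status", "pb1_bases"]).to_csv(
        outdir / "truth_genotypes.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(config)
    cfg["amplification_modes"] = list(cfg["amplification_modes"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return bundle
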