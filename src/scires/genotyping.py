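"""Per-site consensus genotype calling on DNA or RNA pileups.

The caller reproduces the behaviour of a VarScan-style consensus pass run
with its defaults: a site needs at least eight reads before anything is
called, a variant needs a one-sided binomial-tail p-value below 0.01
against a fixed per-base error rate, a variant with allele frequency below
75% is heterozygous and one at or above 75% is homozygous, and variants
whose supporting reads sit (almost) entirely on one sequencing strand are
flagged by the strand filter.  The same operation and parameters are applied
to DNA exome pileups and to mRNA-seq pileups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

from scipy.stats import binom

from .io_formats import BASES, PileupColumn

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HOM_VAR = "hom_var"
HET = "het"
NO_CALL = "no_call"


@dataclass(frozen=True, slots=True)
class CallingParams:
    """Consensus-calling thresholds.

    min_coverage : int
        Minimum read depth to call anything at a site (default 8).
    p_threshold : float
        Maximum binomial-tail p-value for the variant call (default 0.01).
    het_af_upper : float
        Variants with allele frequency below this are heterozygous,
        at/above it homozygous (default 0.75).
    min_var_freq : float
        Minimum allele frequency to consider a variant at all (default
        0.20, the VarScan mpileup2cns default).
    error_rate : float
        Per-base sequencing error rate of the binomial null (default 0.01).
    strand_bias_max : float
        Maximum fraction of variant-supporting reads allowed on the
        majority strand (default 0.90).
    """

    min_coverage: int = 8
    p_threshold: float = 0.01
    het_af_upper: float = 0.75
    min_var_freq: float = 0.20
    error_rate: float = 0.01
    strand_bias_max: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.min_var_freq <= self.het_af_upper <= 1):
            raise ValueError("need 0 < min_var_freq <= het_af_upper <= 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("need 0 < p_threshold < 1")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(slots=True)
class GenotypeCall:
    """Consensus call at one site.

    ``alt_base`` is absent for hom-ref and no-call sites; ``af`` is the
    frequency of the evaluated alternative allele; ``strand_filter_pass``
    is meaningful only for variant calls (het / hom_var).
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str]
    status: str
    af: Optional[float]
    depth: int
    p_value: Optional[float]
    strand_filter_pass: bool = True

    @property
    def is_variant(self) -> bool:
        return self.status in (HET, HOM_VAR)

    @property
    def is_covered(self) -> bool:
        return self.status != NO_CALL

    def called_bases(self) -> frozenset[str]:
        """The allele set implied by the call (empty for no-call)."""
        if self.status == HOM_REF:
            return frozenset((self.ref_base,))
        if self.status == HOM_VAR:
            return frozenset((self.alt_base,))
        if self.status == HET:
            return frozenset((self.ref_base, self.alt_base))
        return frozenset()


@lru_cache(maxsize=100_000)
def _binom_tail(alt_count: int, depth: int, error_rate: float) -> float:
    return float(binom.sf(alt_count - 1, depth, error_rate))


def variant_p_value(alt_count: int, depth: int,
                    error_rate: float = 0.01) -> float:
    """P(X >= alt_count) for X ~ Binomial(depth, error_rate).

    The one-sided tail probability that sequencing error alone produces at
    least the observed variant support; monotonically non-increasing in
    ``alt_count`` at fixed depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= alt_count <= depth):
        raise ValueError("need 0 <= alt_count <= depth")
    if alt_count == 0:
        return 1.0
    return _binom_tail(alt_count, depth, error_rate)


def strand_filter(column: PileupColumn, alt_base: str,
                  strand_bias_max: float = 0.90) -> bool:
    """True if variant support is acceptably balanced across strands.

    Passes iff alt-supporting reads occur on both strands and the majority
    strand carries at most ``strand_bias_max`` of them; a single supporting
    read necessarily fails.
    """
    fwd = column.counts.get((alt_base, "+"), 0)
    rev = column.counts.get((alt_base, "-"), 0)
    total = fwd + rev
    if total == 0:
        raise ValueError(f"alt base {alt_base} absent at "
                         f"{column.chrom}:{column.pos}")
    if fwd == 0 or rev == 0:
        return False
    return max(fwd, rev) / total <= strand_bias_max


def call_genotype(column: PileupColumn,
                  params: CallingParams = CallingParams()) -> GenotypeCall:
    """Consensus-call a single pileup column.

    No-call below ``min_coverage`` or on an N reference.  Otherwise the
    single most frequent non-reference base (ties broken alphabetically) is
    evaluated: the site is hom-ref when its frequency is below
    ``min_var_freq`` or its binomial p-value exceeds ``p_threshold``, het
    when the frequency is below ``het_af_upper``, hom-var otherwise.
    """
    if column.ref_base not in BASES or column.depth < params.min_coverage:
        return GenotypeCall(chrom=column.chrom, pos=column.pos,
                            ref_base=column.ref_base, alt_base=None,
                            status=NO_CALL, af=None, depth=column.depth,
                            p_value=None)
    alt_base, alt_count = None, 0
    for base in BASES:  # alphabetical order implements the tie-break
        if base == column.ref_base:
            continue
        c = column.base_count(base)
        if c > alt_count:
            alt_base, alt_count = base, c
    af = alt_count / column.depth
    p = variant_p_value(alt_count, column.depth, params.error_rate)
    if alt_count == 0 or af < params.min_var_freq or p > params.p_threshold:
        return GenotypeCall(chrom=column.chrom, pos=column.pos,
                            ref_base=column.ref_base, alt_base=None,
                            status=HOM_REF, af=af, depth=column.depth,
                            p_value=p)
    status = HET if af < params.het_af_upper else HOM_VAR
    return GenotypeCall(chrom=column.chrom, pos=column.pos,
                        ref_base=column.ref_base, alt_base=alt_base,
                        status=status, af=af, depth=column.depth, p_value=p,
                        strand_filter_pass=strand_filter(
                            column, alt_base, params.strand_bias_max))


def call_sample(columns: Iterable[PileupColumn],
                params: CallingParams = CallingParams()) -> list[GenotypeCall]:
    """Call every column of one sample, preserving input order.

    Columns must arrive sorted by ``(chrom, pos)``; summary counters are
    logged after the pass.
    """
    calls: list[GenotypeCall] = []
    last: Optional[tuple[str, int]] = None
    n_var = n_het = n_hom = 0
    for col in columns:
        key = (col.chrom, col.pos)
        if last is not None and key < last:
            raise ValueError(
                f"pileup not sorted by (chrom, pos) at {col.chrom}:{col.pos}"
            )
        last = key
        call = call_genotype(col, params)
        calls.append(call)
        if call.is_variant:
            n_var += 1
            if call.status == HET:
                n_het += 1
            else:
                n_hom += 1
    logger.info("call_sample: %d sites, %d variants (%d het, %d hom-var)",
                len(calls), n_var, n_het, n_hom)
    return calls
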