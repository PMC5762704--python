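"""Heterozygosity patterns of haploid MII oocytes against a diploid reference.

An MII oocyte is haploid but carries two sister chromatids per chromosome,
so a meiosis-I crossover between a site and the centromere leaves the site
heterozygous in the oocyte.  Sites heterozygous in the diploid reference
tissue (liver) are therefore classified as *recombined* when at least one
oocyte shows both alleles, and *non-recombined* when every covered oocyte
is homozygous; the first polar body (PB1) of each oocyte carries the
complementary chromatid pair and is used as an internal consistency check.
Counts are summarised in fixed genomic windows (default 1 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .genotyping import HET, GenotypeCall

RECOMBINED_HET = "recombined_het"
NON_RECOMBINED_HET = "non_recombined_het"
DISCORDANT = "discordant"
UNINFORMATIVE = "uninformative"


@dataclass(slots=True)
class SiteClass:
    """Pooled classification of one liver-covered variant site.

    Per-sample oocyte/PB1 statuses are ``het``/``hom`` for covered samples;
    uncovered samples are simply absent from the maps.  ``concordant_hom``
    marks sites where liver is homozygous-variant and every covered oocyte
    agrees — the denominator of the per-window het/hom ratio.
    """

    chrom: str
    pos: int
    liver_status: str  # "het" | "hom"
    oocyte_status: dict[str, str]
    pb1_status: dict[str, str]
    pooled_class: str
    recombined_in: frozenset[str] = frozenset()  # per-cell recombination flag
    concordant_hom: bool = False


@dataclass(slots=True)
class WindowSummary:
    """Counts of site classes within one genomic window."""

    chrom: str
    window_start: int  # 1-based
    n_recombined_het: int
    n_non_recombined_het: int
    n_hom: int

    @property
    def het_hom_ratio(self) -> float:
        return (self.n_recombined_het + self.n_non_recombined_het) / \
            max(self.n_hom, 1)


def _status(call: Optional[GenotypeCall]) -> Optional[str]:
    """Reduce a call to het/hom, or None when uncovered / no-call."""
    if call is None or not call.is_covered:
        return None
    return "het" if call.status == HET else "hom"


def _index(calls: Sequence[GenotypeCall]) -> dict[tuple[str, int], GenotypeCall]:
    return {(c.chrom, c.pos): c for c in calls}


def _check_reference(sample_calls: Mapping[str, Sequence[GenotypeCall]],
                     liver_calls: Sequence[GenotypeCall]) -> None:
    liver_chroms = {c.chrom for c in liver_calls}
    for name, calls in sample_calls.items():
        chroms = {c.chrom for c in calls}
        if chroms and liver_chroms and not (chroms & liver_chroms):
            raise ValueError(
                f"sample {name} shares no reference sequence names with "
                "the liver call set"
            )


def classify_sites(oocyte_calls: Mapping[str, Sequence[GenotypeCall]],
                   pb1_calls: Mapping[str, Sequence[GenotypeCall]],
                   liver_calls: Sequence[GenotypeCall]) -> list[SiteClass]:
    """Classify every liver-covered variant site across the oocyte panel.

    The site universe is all liver-covered sites at which either liver or
    at least one covered oocyte reports a variant.  Sites covered in no
    oocyte, and concordant homozygous sites, are ``uninformative``; a
    heterozygous oocyte at a liver-homozygous site — or any oocyte allele
    absent from the liver genotype — is ``discordant``.
    """
    _check_reference(oocyte_calls, liver_calls)
    _check_reference(pb1_calls, liver_calls)
    oo_idx = {s: _index(c) for s, c in oocyte_calls.items()}
    pb_idx = {s: _index(c) for s, c in pb1_calls.items()}

    out: list[SiteClass] = []
    for liver in sorted(liver_calls, key=lambda c: (c.chrom, c.pos)):
        if not liver.is_covered:
            continue
        key = (liver.chrom, liver.pos)
        oo_here = {s: idx[key] for s, idx in oo_idx.items()
                   if key in idx and idx[key].is_covered}
        if not liver.is_variant and not any(c.is_variant
                                            for c in oo_here.values()):
            continue  # invariant site everywhere: not part of the universe
        oo_status = {s: _status(c) for s, c in oo_here.items()}
        pb_status = {s: _status(pb_idx[s][key]) for s in pb_idx
                     if key in pb_idx[s] and pb_idx[s][key].is_covered}
        liver_alleles = liver.called_bases()
        liver_status = "het" if liver.status == HET else "hom"
        recombined_in: set[str] = set()
        concordant_hom = False
        if not oo_here:
            pooled = UNINFORMATIVE
        else:
            alleles_ok = all(c.called_bases() <= liver_alleles
                             for c in oo_here.values())
            any_het = any(st == "het" for st in oo_status.values())
            if liver_status == "het":
                if not alleles_ok:
                    pooled = DISCORDANT
                elif any_het:
                    pooled = RECOMBINED_HET
                    recombined_in = {s for s, st in oo_status.items()
                                     if st == "het"}
                else:
                    pooled = NON_RECOMBINED_HET
            else:
                if any_het or not alleles_ok:
                    pooled = DISCORDANT
                else:
                    pooled = UNINFORMATIVE
                    concordant_hom = liver.is_variant
        out.append(SiteClass(
            chrom=liver.chrom, pos=liver.pos, liver_status=liver_status,
            oocyte_status=oo_status, pb1_status=pb_status,
            pooled_class=pooled, recombined_in=frozenset(recombined_in),
            concordant_hom=concordant_hom,
        ))
    return out


def window_summary(site_classes: Sequence[SiteClass],
                   window_size: int = 1_000_000) -> list[WindowSummary]:
    """Bin classified sites into fixed windows.

    Site at 1-based position p falls into window floor((p-1)/window_size);
    windows containing no classified site are omitted.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for sc in site_classes:
        widx = (sc.pos - 1) // window_size
        rec = counts.setdefault((sc.chrom, widx), [0, 0, 0])
        if sc.pooled_class == RECOMBINED_HET:
            rec[0] += 1
        elif sc.pooled_class == NON_RECOMBINED_HET:
            rec[1] += 1
        elif sc.concordant_hom:
            rec[2] += 1
    return [WindowSummary(chrom=chrom, window_start=widx * window_size + 1,
                          n_recombined_het=rec[0],
                          n_non_recombined_het=rec[1], n_hom=rec[2])
            for (chrom, widx), rec in sorted(counts.items())]


def concordance_stats(oocyte_calls, liver_calls: Sequence[GenotypeCall]
                      ) -> dict:
    """Cross-tissue concordance of het/hom status at commonly covered sites.

    ``oocyte_calls`` is a call sequence or a sample->calls mapping (pooled
    over per-sample observations).  Returns the fraction of oocyte-hom
    observations that liver calls het, and the fraction of oocyte-het
    observations that liver calls hom, with explicit numerators and
    denominators; an empty denominator yields a fraction of None.
    """
    if not isinstance(oocyte_calls, Mapping):
        oocyte_calls = {"pooled": oocyte_calls}
    liver_idx = _index(liver_calls)
    n_hom = n_hom_liver_het = n_het = n_het_liver_hom = 0
    for calls in oocyte_calls.values():
        for call in calls:
            if not call.is_covered:
                continue
            liver = liver_idx.get((call.chrom, call.pos))
            if liver is None or not liver.is_covered:
                continue
            if call.status == HET:
                n_het += 1
                if liver.status != HET:
                    n_het_liver_hom += 1
            else:
                n_hom += 1
                if liver.status == HET:
                    n_hom_liver_het += 1
    return {
        "frac_hom_oocyte_het_liver":
            n_hom_liver_het / n_hom if n_hom else None,
        "frac_het_oocyte_hom_liver":
            n_het_liver_hom / n_het if n_het else None,
        "n_hom_oocyte": n_hom,
        "n_hom_oocyte_het_liver": n_hom_liver_het,
        "n_het_oocyte": n_het,
        "n_het_oocyte_hom_liver": n_het_liver_hom,
    }


def pb1_consistency(oocyte_calls: Mapping[str, Sequence[GenotypeCall]],
                    pb1_calls: Mapping[str, Sequence[GenotypeCall]],
                    liver_calls: Sequence[GenotypeCall]
                    ) -> dict[str, Optional[float]]:
    """Het/hom agreement between each oocyte and its matched PB1.

    Samples are paired by identical key in the two mappings.  For each pair
    the fraction of commonly covered liver-het sites with matching het/hom
    status is returned; None when no such site exists.
    """
    if set(oocyte_calls) != set(pb1_calls):
        missing = set(oocyte_calls) ^ set(pb1_calls)
        raise ValueError(f"unpaired samples: {sorted(missing)}")
    liver_het = {(c.chrom, c.pos) for c in liver_calls if c.status == HET}
    out: dict[str, Optional[float]] = {}
    for sample in sorted(oocyte_calls):
        oo_idx = _index(oocyte_calls[sample])
        pb_idx = _index(pb1_calls[sample])
        n = n_agree = 0
        for key in liver_het:
            oo, pb = oo_idx.get(key), pb_idx.get(key)
            if oo is None or pb is None or \
                    not oo.is_covered or not pb.is_covered:
                continue
            n += 1
            if _status(oo) == _status(pb):
                n_agree += 1
        out[sample] = n_agree / n if n else None
    return out
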