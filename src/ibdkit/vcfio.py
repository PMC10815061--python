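"""Multi-sample VCF access and per-sample hard filters.

Reads biallelic autosomal SNVs from a VCF (via cyvcf2) into site-level
records carrying each sample's genotype, allelic depths (AD), total depth
(DP) and genotype quality (GQ), then applies the hard filters used for
allele-balance IBD mapping: DP strictly greater than 14, GQ strictly
greater than 30, no Mendelian error within any genotyped trio, and —
optionally — at least one alternate-supporting read for every non-reference
call (the per-site reading of "allelic ratio difference of > 0").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .pedigree import Pedigree, mendelian_consistent

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "SiteRecord",
    "FilterThresholds",
    "VcfSiteReader",
    "read_sites",
    "write_sites",
    "call_passes",
    "site_passes_for",
]

AUTOSOMES = {str(i) for i in range(1, 23)}
_BASES = {"A", "C", "G", "T"}


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``allele_indices`` is an unphased diploid pair referencing REF (0) or an
    ALT (>= 1), or ``None`` when the call is missing.  ``ad`` holds per-allele
    read counts (REF first).  ``sum(ad) <= dp`` is expected but violations are
    flagged rather than rejected (some callers count differently).
    """

    allele_indices: Optional[tuple[int, int]]
    ad: Optional[tuple[int, ...]] = None
    dp: Optional[int] = None
    gq: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def has_alt(self) -> bool:
        return self.allele_indices is not None and any(
            a > 0 for a in self.allele_indices)

    @property
    def alt_depth(self) -> Optional[int]:
        """Reads supporting any non-reference allele."""
        if self.ad is None:
            return None
        return int(sum(self.ad[1:]))

    @property
    def ad_dp_inconsistent(self) -> bool:
        return (self.ad is not None and self.dp is not None
                and sum(self.ad) > self.dp)


@dataclass(frozen=True)
class SiteRecord:
    """A normalized biallelic SNV with per-sample calls."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    calls: dict[str, GenotypeCall]

    def genotype(self, sample: str) -> Optional[tuple[int, int]]:
        return self.calls[sample].allele_indices


@dataclass(frozen=True)
class FilterThresholds:
    """Per-sample hard-filter thresholds (strict inequalities, as printed)."""

    min_dp_exclusive: int = 14
    min_gq_exclusive: int = 30
    require_alt_support: bool = True

    def __post_init__(self) -> None:
        if self.min_dp_exclusive < 0 or self.min_gq_exclusive < 0:
            raise ValueError("thresholds must be non-negative")


def call_passes(call: GenotypeCall, t: FilterThresholds = FilterThresholds()) -> bool:
    """DP > threshold, GQ > threshold, and alt support for non-ref calls.

    Missing DP or GQ fails the filter.
    """
    if call.dp is None or call.gq is None:
        return False
    if not (call.dp > t.min_dp_exclusive and call.gq > t.min_gq_exclusive):
        return False
    if t.require_alt_support and call.has_alt:
        alt = call.alt_depth
        if alt is None or alt <= 0:
            return False
    return True


def site_passes_for(
    record: SiteRecord,
    sample_ids: Sequence[str],
    ped: Pedigree,
    t: FilterThresholds = FilterThresholds(),
) -> bool:
    """Every listed sample passes the call filter and every genotyped
    child–parent trio among the listed samples is Mendelian-consistent."""
    listed = set(sample_ids)
    for s in sample_ids:
        if not call_passes(record.calls[s], t):
            return False
    for s in sample_ids:
        if s not in ped:
            continue
        father, mother = ped.parents_of(s)
        f_gt = record.genotype(father) if father in listed else None
        m_gt = record.genotype(mother) if mother in listed else None
        if f_gt is None and m_gt is None:
            continue
        if not mendelian_consistent(record.genotype(s), f_gt, m_gt):
            return False
    return True


class VcfSiteReader:
    """Iterate biallelic autosomal SNVs of a multi-sample VCF.

    Skipped records are tallied in :attr:`counters` (``multiallelic``,
    ``indel``, ``non_autosomal``, ``malformed``) for the filter summary.
    ``multiallelic="split"`` decomposes multi-ALT records into per-alternate
    biallelic sites instead of skipping them.
    """

    def __init__(
        self,
        path: str | Path,
        sample_ids: Optional[Sequence[str]] = None,
        autosomes_only: bool = True,
        multiallelic: str = "skip",
    ) -> None:
        import cyvcf2  # deferred: htslib import is comparatively heavy

        if multiallelic not in ("skip", "split"):
            raise ValueError("multiallelic must be 'skip' or 'split'")
        self.path = str(path)
        self.autosomes_only = autosomes_only
        self.multiallelic = multiallelic
        self._vcf = cyvcf2.VCF(self.path)
        header = list(self._vcf.samples)
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in header]
            if missing:
                raise KeyError(
                    f"samples absent from VCF header: {', '.join(missing)}")
            self._vcf.set_samples(list(sample_ids))
        self.samples: list[str] = list(self._vcf.samples)
        self.counters: dict[str, int] = {
            "read": 0, "yielded": 0, "multiallelic": 0,
            "indel": 0, "non_autosomal": 0, "malformed": 0,
        }

    def __iter__(self) -> Iterator[SiteRecord]:
        for v in self._vcf:
            self.counters["read"] += 1
            chrom = _norm_chrom(v.CHROM)
            if self.autosomes_only and chrom not in AUTOSOMES:
                self.counters["non_autosomal"] += 1
                continue
            alts = list(v.ALT)
            if not alts or v.REF is None:
                self.counters["malformed"] += 1
                continue
            if len(v.REF) != 1 or v.REF.upper() not in _BASES:
                self.counters["indel"] += 1
                continue
            if len(alts) > 1:
                self.counters["multiallelic"] += 1
                if self.multiallelic == "skip":
                    continue
                yield from self._split(v, chrom, alts)
                continue
            alt = alts[0]
            if len(alt) != 1 or alt.upper() not in _BASES:
                self.counters["indel"] += 1
                continue
            record = self._to_record(v, chrom, alt)
            if record is None:
                self.counters["malformed"] += 1
                continue
            self.counters["yielded"] += 1
            yield record

    # -- record construction --------------------------------------------

    def _per_sample(self, v):
        gts = v.genotypes
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        return gts, ad, dp, gq

    def _to_record(self, v, chrom: str, alt: str) -> Optional[SiteRecord]:
        gts, ad, dp, gq = self._per_sample(v)
        if gts is None or len(gts) != len(self.samples):
            return None
        calls: dict[str, GenotypeCall] = {}
        for i, sample in enumerate(self.samples):
            calls[sample] = _make_call(gts[i],
                                       None if ad is None else ad[i],
                                       None if dp is None else dp[i],
                                       None if gq is None else gq[i])
        return SiteRecord(chrom=chrom, pos=int(v.POS), ref=v.REF.upper(),
                          alt=alt.upper(), calls=calls)

    def _split(self, v, chrom: str, alts: list[str]) -> Iterator[SiteRecord]:
        """Decompose a multi-ALT record into biallelic per-alternate sites."""
        gts, ad, dp, gq = self._per_sample(v)
        if gts is None:
            self.counters["malformed"] += 1
            return
        for k, alt in enumerate(alts, start=1):
            if len(alt) != 1 or alt.upper() not in _BASES or len(v.REF) != 1:
                continue
            calls: dict[str, GenotypeCall] = {}
            for i, sample in enumerate(self.samples):
                row = list(gts[i][:2])
                if any(a is not None and a > 0 and a != k for a in row):
                    recoded = None  # carries a different alternate allele
                else:
                    recoded = tuple(
                        (1 if a == k else (0 if a == 0 else -1)) for a in row)
                ad_i = None
                if ad is not None:
                    full = [int(x) for x in ad[i]]
                    if len(full) > k:
                        ad_i = [full[0], full[k]]
                calls[sample] = _make_call(
                    list(recoded) + [False] if recoded is not None else [-1, -1, False],
                    ad_i,
                    None if dp is None else dp[i],
                    None if gq is None else gq[i])
            self.counters["yielded"] += 1
            yield SiteRecord(chrom=chrom, pos=int(v.POS), ref=v.REF.upper(),
                             alt=alt.upper(), calls=calls)


def _make_call(gt_row, ad_row, dp_val, gq_val) -> GenotypeCall:
    alleles = [int(a) for a in gt_row[:2]]
    indices: Optional[tuple[int, int]]
    if len(alleles) < 2 or any(a < 0 for a in alleles):
        indices = None
    else:
        indices = (alleles[0], alleles[1])

    ad: Optional[tuple[int, ...]] = None
    if ad_row is not None:
        vals = [int(x) for x in _as_iter(ad_row)]
        if vals and all(x >= 0 for x in vals):
            ad = tuple(vals)

    dp = _scalar(dp_val)
    gq = _scalar(gq_val)
    return GenotypeCall(allele_indices=indices, ad=ad, dp=dp, gq=gq)


def _as_iter(x):
    try:
        return list(x)
    except TypeError:
        return [x]


def _scalar(x) -> Optional[int]:
    if x is None:
        return None
    vals = _as_iter(x)
    if not vals:
        return None
    v = vals[0]
    try:
        v = int(v)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def read_sites(
    vcf_source: str | Path,
    sample_ids: Optional[Sequence[str]] = None,
    **kwargs,
) -> VcfSiteReader:
    """Convenience constructor for :class:`VcfSiteReader` (itself iterable)."""
    return VcfSiteReader(vcf_source, sample_ids=sample_ids, **kwargs)


def write_sites(
    records: Iterable[SiteRecord],
    sample_ids: Sequence[str],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write site records as a minimal plain-text VCF 4.2 (GT:AD:DP:GQ)."""
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for rec in records:
        fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS",
                  ".", "GT:AD:DP:GQ"]
        for s in sample_ids:
            call = rec.calls[s]
            gt = ("./." if call.allele_indices is None
                  else "/".join(str(a) for a in call.allele_indices))
            ad = "." if call.ad is None else ",".join(str(x) for x in call.ad)
            dp = "." if call.dp is None else str(call.dp)
            gq = "." if call.gq is None else str(call.gq)
            fields.append(f"{gt}:{ad}:{dp}:{gq}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
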