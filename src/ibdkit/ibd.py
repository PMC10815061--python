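"""Allele-balance IBD mapping across affected relatives.

The mapping statistic is the pairwise allelic-ratio difference: at each
filtered biallelic SNV *A* and for each pair of affected samples (1, 2),

    ratio_diff_A = | AD_A1 / DP_A1  -  AD_A2 / DP_A2 |

where AD is the alternate-allele read count and DP the total read depth.
Two samples sharing a haplotype identical by descent (IBD1 or IBD2) can
never be opposite homozygotes, so sites where the two genotypes share no
allele — which at the read level show a ratio difference near 1 — are the
per-site evidence *against* sharing.  Sites with identical genotypes are
non-informative and are ignored.  Runs of informative sites free of
read-corroborated discordance are emitted as IBD segments per pair, and the
intersection of every affected pair's segments yields the regions shared by
all affected members, which is where a dominantly acting variant must lie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import intervals as iv
from .pedigree import Pedigree, affected_pairs, parse_pedigree
from .vcfio import (FilterThresholds, GenotypeCall, SiteRecord, VcfSiteReader,
                    site_passes_for)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "IBDSegment",
    "SharedRegion",
    "RegionSummary",
    "allelic_ratio",
    "ratio_diff",
    "pair_site_informative",
    "shared_allele_count",
    "pairwise_segments",
    "shared_regions",
    "summarize_regions",
    "IBDMapping",
    "IBDResults",
]

Pair = tuple[str, str]
Genotype = tuple[int, int]


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs for run-based IBD segmentation.

    max_ratio_diff
        Read-level corroboration threshold: a genotype-discordant site
        (no shared allele) only counts against sharing when its allelic
        ratio difference also exceeds this value.  True opposite homozygotes
        sit near 0.96 at 30x; genotype miscalls of real reads sit near 0.5
        or below, so 0.7 separates the two.
    max_discordant_run
        Number of consecutive corroborated-discordant sites tolerated inside
        a segment before it is closed.  Because discordance already requires
        both genotype- and read-level contradiction, a single such site is
        strong IBD0 evidence and the default is 0.
    min_sites / min_span_bp
        Minimum supporting-site count (genotyped, sharing-compatible sites,
        whether informative or identical) and physical span for a segment
        to be reported.  Support cannot be restricted to informative sites:
        a pair sharing both haplotypes (IBD2) has *identical* genotypes at
        every site of the region and would otherwise be invisible.
    """

    max_ratio_diff: float = 0.7
    max_discordant_run: int = 0
    min_sites: int = 25
    min_span_bp: int = 500_000

    def __post_init__(self) -> None:
        if not (0.0 < self.max_ratio_diff < 1.0):
            raise ValueError("max_ratio_diff must lie in (0, 1)")
        if min(self.max_discordant_run, self.min_sites, self.min_span_bp) < 0:
            raise ValueError("segmentation parameters must be non-negative")


@dataclass(frozen=True)
class IBDSegment:
    """Maximal run of allele sharing for one affected pair.

    Coordinates are 0-based half-open; ``min_shared_alleles`` distinguishes
    IBD1 (1) from IBD2 (2) support among the segment's informative sites.
    """

    chrom: str
    start: int
    end: int
    pair: Pair
    min_shared_alleles: int
    n_informative_sites: int
    n_supporting_sites: int
    mean_ratio_diff: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SharedRegion:
    """Interval shared (IBD1 or IBD2) by every affected pair."""

    chrom: str
    start: int
    end: int
    supporting_pairs: tuple[Pair, ...]
    n_genes: Optional[int] = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSummary:
    n_regions: int
    total_bp: int
    n_genes: int


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def allelic_ratio(call: GenotypeCall) -> float:
    """Alternate-allele read fraction AD_alt / DP for a biallelic call."""
    if call.dp is None or call.dp <= 0:
        raise ValueError("allelic ratio undefined at zero read depth")
    if call.ad is None or len(call.ad) != 2:
        raise ValueError("allelic ratio requires biallelic AD counts")
    if call.allele_indices is not None and any(a > 1 for a in call.allele_indices):
        raise ValueError("allelic ratio undefined for multi-allelic calls")
    return call.ad[1] / call.dp


def ratio_diff(c1: GenotypeCall, c2: GenotypeCall) -> float:
    """Absolute difference of the two samples' alternate-allele fractions."""
    return abs(allelic_ratio(c1) - allelic_ratio(c2))


def pair_site_informative(gt1: Optional[Genotype], gt2: Optional[Genotype]) -> bool:
    """A site is informative for a pair iff both genotypes are present and
    differ as unordered pairs; identical genotypes carry no IBD signal."""
    if gt1 is None or gt2 is None:
        return False
    return sorted(gt1) != sorted(gt2)


def shared_allele_count(gt1: Genotype, gt2: Genotype) -> int:
    """Size of the maximum matching between the two allele multisets (0-2)."""
    if gt1 is None or gt2 is None:
        raise ValueError("shared_allele_count requires non-missing genotypes")
    a, b = list(gt1), list(gt2)
    shared = 0
    for allele in a:
        if allele in b:
            b.remove(allele)
            shared += 1
    return shared


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class _OpenSegment:
    __slots__ = ("first", "last", "n_info", "n_support", "sum_rd", "n_rd",
                 "min_shared", "pending")

    def __init__(self, pos: int) -> None:
        self.first = pos
        self.last = pos
        self.n_info = 0
        self.n_support = 1
        self.sum_rd = 0.0
        self.n_rd = 0
        self.min_shared = 2  # IBD2 unless an informative site says less
        self.pending = 0

    def absorb(self, pos: int) -> None:
        self.n_support += self.pending + 1
        self.pending = 0
        self.last = pos

    def note_informative(self, rd: Optional[float], shared: int) -> None:
        self.n_info += 1
        if rd is not None:
            self.sum_rd += rd
            self.n_rd += 1
        if shared > 0:
            self.min_shared = min(self.min_shared, shared)


def pairwise_segments(
    sites: Iterable[SiteRecord],
    pair: Pair,
    params: SegmentationParams = SegmentationParams(),
) -> list[IBDSegment]:
    """Segment a filtered, position-sorted site stream into IBD segments.

    Classification per informative site (both genotypes present, unordered
    genotypes differ):

    * discordant — ``shared_allele_count == 0`` *and* the allelic ratio
      difference exceeds ``params.max_ratio_diff`` (read-corroborated
      opposite homozygotes);
    * compatible — every other site with both genotypes present: concordant
      informative sites (the genotypes differ but share an allele, or the
      read-level signal contradicts an apparent genotype discordance) and
      identical-genotype sites, which carry no IBD1/IBD0 information but are
      fully consistent with sharing (and are *all* a pair in IBD2 shows).

    Missing-genotype sites are neutral: they neither extend nor break runs.
    Segments are trimmed to the outermost compatible sites, closed after
    more than ``max_discordant_run`` consecutive discordant sites, and
    reported when supported by at least ``min_sites`` compatible sites over
    at least ``min_span_bp``.
    """
    s1, s2 = pair
    segments: list[IBDSegment] = []
    current: Optional[_OpenSegment] = None
    cur_chrom: Optional[str] = None
    last_pos = -1
    seen_chroms: set[str] = set()

    def close() -> None:
        nonlocal current
        if current is None:
            return
        start0, end0 = current.first - 1, current.last
        if (current.n_support >= params.min_sites
                and (end0 - start0) >= params.min_span_bp):
            segments.append(IBDSegment(
                chrom=cur_chrom, start=start0, end=end0, pair=(s1, s2),
                min_shared_alleles=current.min_shared,
                n_informative_sites=current.n_info,
                n_supporting_sites=current.n_support,
                mean_ratio_diff=(current.sum_rd / current.n_rd
                                 if current.n_rd else 0.0),
            ))
        current = None

    for site in sites:
        if site.chrom != cur_chrom:
            if site.chrom in seen_chroms:
                raise ValueError(
                    f"site stream not sorted: chromosome {site.chrom} revisited")
            close()
            cur_chrom = site.chrom
            seen_chroms.add(site.chrom)
            last_pos = -1
        if site.pos < last_pos:
            raise ValueError(
                f"site stream not sorted at {site.chrom}:{site.pos}")
        last_pos = site.pos

        c1, c2 = site.calls[s1], site.calls[s2]
        gt1, gt2 = c1.allele_indices, c2.allele_indices
        if gt1 is None or gt2 is None:
            continue
        informative = pair_site_informative(gt1, gt2)
        if informative:
            shared = shared_allele_count(gt1, gt2)
            try:
                rd: Optional[float] = ratio_diff(c1, c2)
            except ValueError:
                rd = None
            discordant = (shared == 0
                          and (rd is None or rd > params.max_ratio_diff))
        else:
            discordant = False

        if discordant:
            if current is not None:
                current.pending += 1
                if current.pending > params.max_discordant_run:
                    close()
        else:
            if current is None:
                current = _OpenSegment(site.pos)
            else:
                current.absorb(site.pos)
            if informative:
                current.note_informative(rd, shared)
    close()
    return segments


def shared_regions(
    segments_by_pair: Mapping[Pair, Sequence[IBDSegment]],
    ped: Pedigree,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[SharedRegion]:
    """Intersect every affected pair's segment union into shared regions."""
    pairs = affected_pairs(ped, sample_ids)
    if not pairs:
        return []
    normalized = {tuple(sorted(p)): list(v) for p, v in segments_by_pair.items()}
    maps: list[iv.IntervalMap] = []
    for pair in pairs:
        key = tuple(sorted(pair))
        if key not in normalized:
            raise KeyError(f"no segment list supplied for affected pair {pair}")
        m: iv.IntervalMap = {}
        for seg in normalized[key]:
            m.setdefault(seg.chrom, []).append((seg.start, seg.end))
        maps.append(m)
    inter = iv.intersect_many(maps)
    regions = [
        SharedRegion(chrom=c, start=s, end=e, supporting_pairs=tuple(pairs))
        for c in sorted(inter, key=_chrom_key) for s, e in inter[c]
    ]
    return regions


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def summarize_regions(
    regions: Sequence[SharedRegion],
    gene_intervals: Optional[Sequence[tuple]] = None,
) -> RegionSummary:
    """Region count, cumulative span and number of distinct overlapping genes.

    ``gene_intervals`` rows are ``(chrom, start, end, name)`` (0-based
    half-open, e.g. straight from BED).
    """
    total_bp = sum(r.span for r in regions)
    n_genes = 0
    if gene_intervals is not None and regions:
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for r in regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        hit: set[str] = set()
        for chrom, start, end, name in gene_intervals:
            chrom = str(chrom)
            if chrom in trees and end > start and trees[chrom].overlap(start, end):
                hit.add(str(name))
        n_genes = len(hit)
    return RegionSummary(n_regions=len(regions), total_bp=total_bp,
                         n_genes=n_genes)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class IBDMapping:
    """Allele-balance IBD mapping model for one sequenced pedigree.

    Parameters
    ----------
    sites
        Iterable of :class:`~ibdkit.vcfio.SiteRecord` (materialized on
        construction) — typically a :class:`~ibdkit.vcfio.VcfSiteReader`.
    pedigree
        Family structure with affection status.
    sample_ids
        Samples with genotype data; defaults to the pedigree members present
        in the first record's calls.
    thresholds
        Per-sample hard filters applied before segmentation.
    """

    def __init__(
        self,
        sites: Iterable[SiteRecord],
        pedigree: Pedigree,
        sample_ids: Optional[Sequence[str]] = None,
        thresholds: FilterThresholds = FilterThresholds(),
    ) -> None:
        self.sites: list[SiteRecord] = list(sites)
        self.pedigree = pedigree
        if sample_ids is None:
            if not self.sites:
                raise ValueError("cannot infer sample ids from an empty stream")
            sample_ids = [m for m in pedigree.ids
                          if m in self.sites[0].calls]
        self.sample_ids = list(sample_ids)
        self.thresholds = thresholds
        self.reader_counters: Optional[dict[str, int]] = None
        if isinstance(sites, VcfSiteReader):
            self.reader_counters = dict(sites.counters)

    @classmethod
    def from_files(
        cls,
        vcf_path: str | Path,
        ped_path: str | Path,
        sample_ids: Optional[Sequence[str]] = None,
        thresholds: FilterThresholds = FilterThresholds(),
        **reader_kwargs,
    ) -> "IBDMapping":
        ped = parse_pedigree(Path(ped_path).read_text())
        requested = sample_ids
        if requested is None:
            import cyvcf2

            header = list(cyvcf2.VCF(str(vcf_path)).samples)
            requested = [m for m in ped.ids if m in header]
        reader = VcfSiteReader(vcf_path, sample_ids=requested, **reader_kwargs)
        return cls(reader, ped, sample_ids=requested, thresholds=thresholds)

    def fit(
        self,
        params: SegmentationParams = SegmentationParams(),
        exclude_unaffected: bool = False,
    ) -> "IBDResults":
        """Filter sites, segment every affected pair, intersect into regions.

        ``exclude_unaffected`` additionally subtracts intervals that every
        affected member also shares with each unaffected sequenced member
        (the "absent in the healthy relatives" reading).
        """
        passing = [r for r in self.sites
                   if site_passes_for(r, self.sample_ids, self.pedigree,
                                      self.thresholds)]
        pairs = affected_pairs(self.pedigree, self.sample_ids)
        segments = {p: pairwise_segments(passing, p, params) for p in pairs}
        regions = shared_regions(segments, self.pedigree, self.sample_ids)

        excluded_bp = 0
        if exclude_unaffected:
            regions, excluded_bp = self._subtract_unaffected(
                passing, regions, params)

        counts = {
            "sites_input": len(self.sites),
            "sites_passing_filters": len(passing),
            "affected_pairs": len(pairs),
            "segments_total": sum(len(v) for v in segments.values()),
            "shared_regions": len(regions),
            "shared_bp": sum(r.span for r in regions),
            "excluded_unaffected_bp": excluded_bp,
        }
        if self.reader_counters:
            counts = {**{f"vcf_{k}": v for k, v in self.reader_counters.items()},
                      **counts}
        return IBDResults(model=self, params=params,
                          segments_by_pair=segments, regions=regions,
                          filter_counts=counts)

    def _subtract_unaffected(
        self,
        passing: Sequence[SiteRecord],
        regions: list[SharedRegion],
        params: SegmentationParams,
    ) -> tuple[list[SharedRegion], int]:
        affected = [s for s in self.sample_ids
                    if s in self.pedigree and self.pedigree.get(s).affected]
        unaffected = [s for s in self.sample_ids
                      if s in self.pedigree and not self.pedigree.get(s).affected]
        region_map: iv.IntervalMap = {}
        for r in regions:
            region_map.setdefault(r.chrom, []).append((r.start, r.end))
        before = iv.total_length(region_map)
        for u in unaffected:
            per_affected: list[iv.IntervalMap] = []
            for a in affected:
                segs = pairwise_segments(passing, tuple(sorted((u, a))), params)
                m: iv.IntervalMap = {}
                for seg in segs:
                    m.setdefault(seg.chrom, []).append((seg.start, seg.end))
                per_affected.append(m)
            shared_with_u = iv.intersect_many(per_affected) if per_affected else {}
            region_map = iv.subtract(region_map, shared_with_u)
        after = iv.total_length(region_map)
        pairs = tuple(affected_pairs(self.pedigree, self.sample_ids))
        out = [SharedRegion(chrom=c, start=s, end=e, supporting_pairs=pairs)
               for c in sorted(region_map, key=_chrom_key)
               for s, e in region_map[c]]
        return out, before - after


@dataclass
class IBDResults:
    """Fitted IBD map: per-pair segments, all-pair shared regions, funnel."""

    model: IBDMapping
    params: SegmentationParams
    segments_by_pair: dict[Pair, list[IBDSegment]]
    regions: list[SharedRegion]
    filter_counts: dict[str, int]

    def region_summary(
        self, gene_intervals: Optional[Sequence[tuple]] = None
    ) -> RegionSummary:
        return summarize_regions(self.regions, gene_intervals)

    def regions_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end,
              "span_bp": r.span, "n_pairs": len(r.supporting_pairs)}
             for r in self.regions])

    def regions_to_bed(self, path: str | Path) -> None:
        lines = [f"{r.chrom}\t{r.start}\t{r.end}\tshared_region_{i}"
                 for i, r in enumerate(self.regions, 1)]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def segments_to_bed(self, path: str | Path, pair: Pair) -> None:
        key = tuple(sorted(pair))
        segs = self.segments_by_pair[key]
        lines = [
            f"{s.chrom}\t{s.start}\t{s.end}\tIBD{s.min_shared_alleles}"
            f"\t{s.n_informative_sites}" for s in segs]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def region_interval_map(self) -> iv.IntervalMap:
        m: iv.IntervalMap = {}
        for r in self.regions:
            m.setdefault(r.chrom, []).append((r.start, r.end))
        return m

    def summary(self) -> str:
        c = self.filter_counts
        lines = [
            "Allele-balance IBD mapping",
            "=" * 52,
            f"samples: {', '.join(self.model.sample_ids)}",
            f"sites input / passing filters: "
            f"{c['sites_input']} / {c['sites_passing_filters']}",
            f"thresholds: DP > {self.model.thresholds.min_dp_exclusive}, "
            f"GQ > {self.model.thresholds.min_gq_exclusive}, "
            f"alt support required: {self.model.thresholds.require_alt_support}",
            f"segmentation: max_ratio_diff={self.params.max_ratio_diff}, "
            f"max_discordant_run={self.params.max_discordant_run}, "
            f"min_sites={self.params.min_sites}, "
            f"min_span_bp={self.params.min_span_bp}",
            "-" * 52,
            f"{'pair':<22s}{'segments':>9s}{'span (Mb)':>12s}",
        ]
        for pair, segs in sorted(self.segments_by_pair.items()):
            span = sum(s.span for s in segs) / 1e6
            lines.append(f"{pair[0] + ' x ' + pair[1]:<22s}"
                         f"{len(segs):>9d}{span:>12.2f}")
        lines += [
            "-" * 52,
            f"shared regions: {len(self.regions)}  "
            f"({sum(r.span for r in self.regions) / 1e6:.2f} Mb)",
        ]
        return "\n".join(lines)
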