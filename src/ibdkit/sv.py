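"""Multi-caller structural-variant consensus and inheritance filtering.

Calls from several SV callers are clustered with the standard two-part
matching rule — at least 50% reciprocal overlap *and* both breakends within
1000 bp — using single-linkage (transitive) clustering within chromosome
and SV type, the behaviour of the common SV mergers.  Consensus coordinates
are per-coordinate medians of the cluster members.  Downstream filters keep
clusters whose genotypes fit a dominant inheritance model (carried by every
affected, absent in every unaffected) and which overlap at least one
phenotype-related gene and, optionally, an IBD shared region.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import overlaps
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "SVCall",
    "MergeParams",
    "MergedSV",
    "reciprocal_overlap",
    "breakend_distances",
    "mergeable",
    "caller_hard_filter",
    "merge_callsets",
    "dominant_model_filter",
    "annotate_and_filter_sv",
    "read_sv_vcf",
    "write_merged_tsv",
]

INTERVAL_TYPES = {"DEL", "DUP", "INV"}
POINT_TYPES = {"INS", "BND"}  # reciprocal overlap is meaningless for these
GT_STATES = {"ref", "het", "hom", "missing"}


@dataclass(frozen=True)
class SVCall:
    """One caller's structural-variant call (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    svtype: str
    caller: str
    sample_genotypes: Mapping[str, str] = field(default_factory=dict)
    quality: Optional[float] = None
    filter_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"SV interval must satisfy start < end ({self.chrom}:"
                f"{self.start}-{self.end}); represent insertions as "
                "start, start+1")
        bad = set(self.sample_genotypes.values()) - GT_STATES
        if bad:
            raise ValueError(f"unknown genotype states: {bad}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MergeParams:
    min_reciprocal_overlap: float = 0.5
    max_breakend_distance_bp: int = 1000
    require_same_type: bool = True
    require_both_breakends: bool = True  # else either breakend within distance

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_reciprocal_overlap <= 1.0):
            raise ValueError("min_reciprocal_overlap must lie in [0, 1]")
        if self.max_breakend_distance_bp < 0:
            raise ValueError("max_breakend_distance_bp must be >= 0")


@dataclass
class MergedSV:
    """A consensus cluster of calls supporting the same structural variant."""

    chrom: str
    start: int
    end: int
    svtype: str
    members: list[SVCall]
    annotations: dict = field(default_factory=dict)

    @property
    def n_callers(self) -> int:
        return len({m.caller for m in self.members})

    @property
    def sample_genotypes(self) -> dict[str, str]:
        """Per-sample consensus: any non-ref member call marks a carrier."""
        samples: set[str] = set()
        for m in self.members:
            samples.update(m.sample_genotypes)
        out: dict[str, str] = {}
        for s in samples:
            states = [m.sample_genotypes[s] for m in self.members
                      if s in m.sample_genotypes
                      and m.sample_genotypes[s] != "missing"]
            if any(st in ("het", "hom") for st in states):
                out[s] = "hom" if all(st == "hom" for st in states) else "het"
            elif states:
                out[s] = "ref"
            else:
                out[s] = "missing"
        return out


def reciprocal_overlap(a: tuple[int, int] | SVCall, b: tuple[int, int] | SVCall,
                       chrom_a: Optional[str] = None,
                       chrom_b: Optional[str] = None) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or trans-chromosomal."""
    if isinstance(a, SVCall):
        chrom_a, ivl_a = a.chrom, (a.start, a.end)
    else:
        ivl_a = a
    if isinstance(b, SVCall):
        chrom_b, ivl_b = b.chrom, (b.start, b.end)
    else:
        ivl_b = b
    if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
        return 0.0
    (s1, e1), (s2, e2) = ivl_a, ivl_b
    if e1 <= s1 or e2 <= s2:
        raise ValueError("reciprocal overlap requires positive-length intervals")
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def breakend_distances(a: SVCall | tuple[int, int],
                       b: SVCall | tuple[int, int]) -> tuple[int, int]:
    """(|start difference|, |end difference|) of two same-chromosome intervals."""
    if isinstance(a, SVCall) and isinstance(b, SVCall) and a.chrom != b.chrom:
        raise ValueError("breakend distance undefined across chromosomes")
    s1, e1 = (a.start, a.end) if isinstance(a, SVCall) else a
    s2, e2 = (b.start, b.end) if isinstance(b, SVCall) else b
    return abs(s1 - s2), abs(e1 - e2)


def mergeable(a: SVCall, b: SVCall, p: MergeParams = MergeParams()) -> bool:
    """Do two calls describe the same variant under the matching rule?"""
    if a.chrom != b.chrom:
        return False
    if p.require_same_type and a.svtype != b.svtype:
        return False
    d_start, d_end = breakend_distances(a, b)
    if p.require_both_breakends:
        dist_ok = (d_start <= p.max_breakend_distance_bp
                   and d_end <= p.max_breakend_distance_bp)
    else:
        dist_ok = (d_start <= p.max_breakend_distance_bp
                   or d_end <= p.max_breakend_distance_bp)
    if not dist_ok:
        return False
    if a.svtype in POINT_TYPES or b.svtype in POINT_TYPES:
        return True  # breakend distance only: length is meaningless
    return reciprocal_overlap(a, b) >= p.min_reciprocal_overlap


def caller_hard_filter(
    calls: Iterable[SVCall],
    caller_config: Mapping[str, Mapping] = None,
) -> list[SVCall]:
    """Apply per-caller hard filters (configuration, not code).

    ``caller_config`` maps caller name to predicate parameters:
    ``require_filter`` (flag that must be present; calls with no flags are
    treated as PASS) and/or ``min_quality``.  Callers without configuration
    pass through with a warning.
    """
    caller_config = caller_config or {}
    warned: set[str] = set()
    out: list[SVCall] = []
    for call in calls:
        cfg = caller_config.get(call.caller)
        if cfg is None:
            if call.caller not in warned:
                logger.warning("no hard-filter configuration for caller %r; "
                               "passing its calls through", call.caller)
                warned.add(call.caller)
            out.append(call)
            continue
        required = cfg.get("require_filter")
        if required is not None:
            flags = call.filter_flags or ("PASS",)
            if required not in flags:
                continue
        min_q = cfg.get("min_quality")
        if min_q is not None and (call.quality is None or call.quality < min_q):
            continue
        out.append(call)
    return out


def merge_callsets(
    callsets: Sequence[Sequence[SVCall]],
    p: MergeParams = MergeParams(),
) -> list[MergedSV]:
    """Single-linkage clustering of all callers' calls under ``mergeable``.

    Every input call lands in exactly one cluster.  Consensus coordinates
    are the per-coordinate medians of cluster members; output is sorted by
    (chromosome, consensus start) and deterministic given input order.
    """
    calls: list[SVCall] = [c for cs in callsets for c in cs]
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # group candidates by chromosome (and type when required) to bound pairs
    groups: dict[tuple, list[int]] = {}
    for idx, c in enumerate(calls):
        key = (c.chrom, c.svtype) if p.require_same_type else (c.chrom,)
        groups.setdefault(key, []).append(idx)
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: (calls[i].start, calls[i].end))
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if (p.require_both_breakends
                        and calls[j].start - calls[i].start
                        > p.max_breakend_distance_bp):
                    break  # sorted by start: no later call can match i
                if mergeable(calls[i], calls[j], p):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged: list[MergedSV] = []
    for idxs in clusters.values():
        members = sorted((calls[i] for i in idxs),
                         key=lambda c: (c.caller, c.start, c.end))
        start = int(statistics.median(m.start for m in members))
        end = int(statistics.median(m.end for m in members))
        if end <= start:
            end = start + 1
        merged.append(MergedSV(chrom=members[0].chrom, start=start, end=end,
                               svtype=members[0].svtype, members=members))
    merged.sort(key=lambda m: (_chrom_key(m.chrom), m.start, m.end, m.svtype))
    return merged


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def dominant_model_filter(
    merged: Iterable[MergedSV],
    ped: Pedigree,
    sample_ids: Optional[Sequence[str]] = None,
) -> list[MergedSV]:
    """Keep SVs carried by every affected and absent in every unaffected
    sequenced member; missing genotypes are non-informative."""
    out: list[MergedSV] = []
    for sv in merged:
        gts = sv.sample_genotypes
        ok = True
        for member in ped.members:
            if sample_ids is not None and member.id not in sample_ids:
                continue
            state = gts.get(member.id, "missing")
            if state == "missing":
                continue
            if member.affected and state == "ref":
                ok = False
                break
            if not member.affected and state in ("het", "hom"):
                ok = False
                break
        if ok:
            out.append(sv)
    return out


def annotate_and_filter_sv(
    merged: Iterable[MergedSV],
    gene_intervals: Optional[Sequence[tuple]] = None,
    regulatory_intervals: Optional[Sequence[tuple]] = None,
    freq_table: Optional[Sequence[tuple]] = None,
    phenotype_genes: Optional[Iterable[str]] = None,
    ibd_regions: Optional[Sequence] = None,
) -> list[MergedSV]:
    """Annotate clusters and apply the phenotype-gene / IBD-region filters.

    Interval tables are rows of ``(chrom, start, end, name)``; the frequency
    table rows are ``(chrom, start, end, frequency)`` and the maximum
    frequency of any overlapping entry is recorded.  Absent annotation
    sources are skipped with a warning.  The output keeps clusters that
    overlap at least one phenotype-related gene and, when ``ibd_regions``
    is given, fall inside an IBD shared region.
    """
    merged = list(merged)
    for name, source in (("genes", gene_intervals),
                         ("regulatory elements", regulatory_intervals),
                         ("population frequencies", freq_table)):
        if source is None:
            logger.warning("no %s supplied; annotation skipped", name)

    pheno: Optional[set[str]] = None
    if phenotype_genes is not None:
        pheno = {str(g) for g in phenotype_genes}
        if not pheno:
            logger.warning("empty phenotype-gene list: every SV will be rejected")

    region_ivs: Optional[list[tuple[str, int, int]]] = None
    if ibd_regions is not None:
        region_ivs = [(r.chrom, r.start, r.end) if hasattr(r, "chrom")
                      else (str(r[0]), int(r[1]), int(r[2]))
                      for r in ibd_regions]

    def _hits(sv: MergedSV, table: Sequence[tuple]) -> list[str]:
        ivl = (sv.start, sv.end)
        return [str(name) for chrom, s, e, name in table
                if str(chrom) == sv.chrom and overlaps(ivl, (int(s), int(e)))]

    out: list[MergedSV] = []
    for sv in merged:
        if gene_intervals is not None:
            sv.annotations["genes"] = _hits(sv, gene_intervals)
        if regulatory_intervals is not None:
            sv.annotations["regulatory"] = _hits(sv, regulatory_intervals)
        if freq_table is not None:
            freqs = [float(f) for chrom, s, e, f in freq_table
                     if str(chrom) == sv.chrom
                     and overlaps((sv.start, sv.end), (int(s), int(e)))]
            sv.annotations["max_population_frequency"] = (
                max(freqs) if freqs else 0.0)
        if region_ivs is not None:
            sv.annotations["in_ibd_region"] = any(
                chrom == sv.chrom and overlaps((sv.start, sv.end), (s, e))
                for chrom, s, e in region_ivs)

        keep = True
        if pheno is not None:
            hit_genes = set(sv.annotations.get("genes", []))
            sv.annotations["phenotype_genes"] = sorted(hit_genes & pheno)
            keep = bool(hit_genes & pheno)
        if keep and region_ivs is not None:
            keep = sv.annotations["in_ibd_region"]
        if keep:
            out.append(sv)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | Path, caller: str) -> list[SVCall]:
    """Read an SV VCF (symbolic ALT, SVTYPE/END INFO dialect) for one caller."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    out: list[SVCall] = []
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            alt = v.ALT[0] if v.ALT else ""
            svtype = alt.strip("<>") if alt.startswith("<") else "BND"
        svtype = str(svtype)
        start = int(v.POS) - 1
        end = v.INFO.get("END")
        end = int(end) if end is not None else int(v.end)
        if svtype in POINT_TYPES or end <= start:
            end = start + 1
        gts: dict[str, str] = {}
        for i, s in enumerate(samples):
            alleles = v.genotypes[i][:2] if v.genotypes else [-1, -1]
            if any(a < 0 for a in alleles):
                gts[s] = "missing"
            elif all(a == 0 for a in alleles):
                gts[s] = "ref"
            elif all(a > 0 for a in alleles):
                gts[s] = "hom"
            else:
                gts[s] = "het"
        flags: tuple[str, ...] = ("PASS",) if v.FILTER is None else tuple(
            v.FILTER.split(";"))
        out.append(SVCall(chrom=v.CHROM, start=start, end=end, svtype=svtype,
                          caller=caller, sample_genotypes=gts,
                          quality=None if v.QUAL is None else float(v.QUAL),
                          filter_flags=flags))
    return out


def write_merged_tsv(merged: Sequence[MergedSV], path: str | Path) -> None:
    header = ["chrom", "start", "end", "svtype", "n_callers", "callers",
              "carriers", "genes", "in_ibd_region"]
    lines = ["\t".join(header)]
    for sv in merged:
        carriers = sorted(s for s, g in sv.sample_genotypes.items()
                          if g in ("het", "hom"))
        lines.append("\t".join([
            sv.chrom, str(sv.start), str(sv.end), sv.svtype,
            str(sv.n_callers),
            ",".join(sorted({m.caller for m in sv.members})),
            ",".join(carriers) or ".",
            ",".join(sv.annotations.get("genes", [])) or ".",
            str(sv.annotations.get("in_ibd_region", ".")),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
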