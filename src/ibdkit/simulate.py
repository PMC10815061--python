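"""Synthetic pedigree genomes, SV call sets and assay tables with known truth.

The generator gene-drops founder haplotypes through a pedigree: founder
haplotypes carry per-site Bernoulli alternate alleles, each meiosis places
crossovers as a Poisson process along the chromosome, and a designated risk
haplotype is forced into every affected member (autosomal dominant
transmission with an unaffected carrier founder, as in families with
incomplete penetrance).  Read-level data follow a simple 30x short-read
model: per-sample depth is Poisson, alternate allelic depth is binomial
with allele fractions 0.02 / 0.5 / 0.98 for the three genotypes (allowing
sequencing error on homozygotes), and GQ is a phred-scaled likelihood
margin capped at 99.  Injected genotype errors are confident miscalls: the
reported genotype flips but the reads still reflect the true genotype,
which is what a joint caller's rare mistakes look like downstream.

The realized crossovers give exact truth: per-pair IBD segments (shared
founder-haplotype ancestry) and their all-affected-pair intersection, so
recovery can be scored without any external data.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .pedigree import Member, Pedigree, affected_pairs
from .sv import SVCall
from .vcfio import GenotypeCall, SiteRecord, write_sites

__all__ = [
    "SimConfig",
    "TruthSet",
    "FamilySimulation",
    "gwc_like_pedigree",
    "simulate_family",
    "simulate_sv_callsets",
    "simulate_assay",
    "simulate_bundle",
    "write_ped",
]

_BASES = np.array(list("ACGT"))
_ALT_FRACTIONS = np.array([0.02, 0.5, 0.98])  # ref-hom, het, alt-hom


def _distinct_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted 0-based positions in [0, length), drawn uniformly.

    Over-draws and deduplicates; cheaper than a full permutation of a
    megabase-scale range at the sparse densities used here.
    """
    if n > length:
        raise ValueError("more positions requested than available")
    pool = np.unique(rng.integers(0, length, size=int(n * 1.05) + 16))
    while len(pool) < n:
        pool = np.unique(np.concatenate(
            [pool, rng.integers(0, length, size=n)]))
    keep = rng.choice(len(pool), size=n, replace=False)
    return np.sort(pool[keep])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; the seed fixes every draw."""

    seed: int = 0
    chrom: str = "1"
    chrom_length_bp: int = 20_000_000
    snv_density_per_bp: float = 1.0 / 1500.0
    mean_depth: float = 30.0
    recombination_rate_per_bp_per_meiosis: float = 1e-8
    genotype_error_rate: float = 0.0
    founder_alt_freq: float = 0.3
    # structural variants
    truth_sv_count: int = 10
    sv_min_len_bp: int = 10_000
    sv_max_len_bp: int = 50_000
    sv_jitter_sd_bp: float = 100.0
    sv_fp_rate: float = 0.2
    # reporter assay
    assay_replicates: int = 3
    assay_experiments: int = 3
    assay_tf_wt: float = 5.0
    assay_tf_variant: float = 3.0
    assay_log_sd: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.genotype_error_rate <= 1.0):
            raise ValueError("genotype_error_rate must lie in [0, 1]")
        if not (0.0 < self.founder_alt_freq < 1.0):
            raise ValueError("founder_alt_freq must lie in (0, 1)")
        if self.chrom_length_bp <= 0 or self.mean_depth <= 0:
            raise ValueError("lengths and depths must be positive")


@dataclass
class TruthSet:
    """Ground truth written alongside generated data, sufficient for scoring."""

    ibd_segments: dict[tuple[str, str], iv.IntervalMap] = field(default_factory=dict)
    shared_regions: iv.IntervalMap = field(default_factory=dict)
    risk_locus: Optional[tuple[str, int]] = None
    sv_table: list[dict] = field(default_factory=list)
    assay_effect: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for pair, imap in sorted(self.ibd_segments.items()):
            for chrom, ivs in sorted(imap.items()):
                for s, e in ivs:
                    rows.append((pair[0], pair[1], chrom, s, e))
        pd.DataFrame(rows, columns=["sample1", "sample2", "chrom",
                                    "start", "end"]).to_csv(
            outdir / "truth_pair_segments.tsv", sep="\t", index=False)
        bed = [f"{c}\t{s}\t{e}" for c, ivs in sorted(self.shared_regions.items())
               for s, e in ivs]
        (outdir / "truth_shared_regions.bed").write_text(
            "\n".join(bed) + ("\n" if bed else ""))
        meta = {"risk_locus": self.risk_locus, "assay_effect": self.assay_effect}
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2))
        if self.sv_table:
            pd.DataFrame(self.sv_table).to_csv(
                outdir / "truth_svs.tsv", sep="\t", index=False)


def gwc_like_pedigree() -> tuple[Pedigree, list[str]]:
    """Three-generation pedigree with 4 affected + 1 unaffected sequenced.

    Two affected brothers (II.8, II.9) descend from an unaffected carrier
    founder couple (I.1 x I.2, not sequenced); II.9's children III.3 and
    III.7 with the unaffected founder II.10 are also affected.  Returns the
    pedigree and the five sequenced sample ids.
    """
    members = [
        Member("I.1", None, None, "male", False),
        Member("I.2", None, None, "female", False),
        Member("II.8", "I.1", "I.2", "male", True),
        Member("II.9", "I.1", "I.2", "male", True),
        Member("II.10", None, None, "female", False),
        Member("III.3", "II.9", "II.10", "female", True),
        Member("III.7", "II.9", "II.10", "male", True),
    ]
    sequenced = ["II.8", "II.9", "II.10", "III.3", "III.7"]
    return Pedigree(members), sequenced


def write_ped(ped: Pedigree, path: str | Path, family: str = "FAM1") -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    lines = []
    for m in ped.members:
        lines.append("\t".join([
            family, m.id, m.father_id or "0", m.mother_id or "0",
            sex_code[m.sex], "2" if m.affected else "1"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------
# A haplotype is a piecewise-constant ancestry map: sorted (start, end,
# founder-haplotype-index) triples covering [0, L).

Ancestry = list[tuple[int, int, int]]


def _hap_at(hap: Ancestry, pos: int) -> int:
    for s, e, hid in hap:
        if s <= pos < e:
            return hid
    raise ValueError(f"position {pos} outside ancestry map")


def _restrict(hap: Ancestry, lo: int, hi: int) -> Ancestry:
    out: Ancestry = []
    for s, e, hid in hap:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2, hid))
    return out


def _meiosis(
    hap_a: Ancestry,
    hap_b: Ancestry,
    length: int,
    rate: float,
    rng: np.random.Generator,
    require_hid: Optional[int] = None,
    at_pos: Optional[int] = None,
) -> Ancestry:
    """Recombine two parental haplotypes into one gamete.

    ``require_hid`` forces the gamete to carry the given founder haplotype
    at ``at_pos`` (by flipping the starting strand if needed) — this is how
    the risk haplotype is pushed into every affected descendant.
    """
    n_x = rng.poisson(rate * length)
    xs = sorted(int(p) for p in rng.integers(1, length, size=n_x))
    start = int(rng.integers(0, 2))
    if require_hid is not None:
        carriers = []
        for idx, hap in enumerate((hap_a, hap_b)):
            if _hap_at(hap, at_pos) == require_hid:
                carriers.append(idx)
        if not carriers:
            raise ValueError("parent does not carry the required haplotype")
        active = (start + bisect_right(xs, at_pos)) % 2
        if active not in carriers:
            start = (start + 1) % 2
    bounds = [0] + xs + [length]
    gamete: Ancestry = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if lo >= hi:
            continue
        source = (hap_a, hap_b)[(start + i) % 2]
        for seg in _restrict(source, lo, hi):
            if gamete and gamete[-1][1] == seg[0] and gamete[-1][2] == seg[2]:
                gamete[-1] = (gamete[-1][0], seg[1], seg[2])
            else:
                gamete.append(seg)
    return gamete


def _drop_haplotypes(
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
    risk_locus: int,
) -> tuple[dict[str, tuple[Ancestry, Ancestry]], int, int]:
    """Assign ancestry maps to every member; returns (maps, n_founder_haps,
    risk haplotype index)."""
    length = config.chrom_length_bp
    rate = config.recombination_rate_per_bp_per_meiosis
    maps: dict[str, tuple[Ancestry, Ancestry]] = {}
    hap_counter = 0
    risk_hid: Optional[int] = None

    # founders first, in pedigree order; the risk haplotype belongs to the
    # first founder who is an ancestor of every affected member.
    risk_founder = _common_founder_ancestor(ped)
    pending = list(ped.members)
    while pending:
        progressed = False
        for m in list(pending):
            father, mother = ped.parents_of(m.id)
            if father is None and mother is None:
                maps[m.id] = ([(0, length, hap_counter)],
                              [(0, length, hap_counter + 1)])
                if m.id == risk_founder:
                    risk_hid = hap_counter
                hap_counter += 2
                pending.remove(m)
                progressed = True
            elif (father is None or father in maps) and \
                 (mother is None or mother in maps):
                gametes = []
                for parent in (father, mother):
                    if parent is None:
                        # un-genotyped parent: fresh founder haplotype
                        gametes.append([(0, length, hap_counter)])
                        hap_counter += 1
                        continue
                    require = None
                    if (m.affected and risk_hid is not None
                            and _carries(maps[parent], risk_hid, risk_locus)):
                        require = risk_hid
                    pa, pb = maps[parent]
                    gametes.append(_meiosis(pa, pb, length, rate, rng,
                                            require_hid=require,
                                            at_pos=risk_locus))
                maps[m.id] = (gametes[0], gametes[1])
                pending.remove(m)
                progressed = True
        if not progressed:
            raise ValueError("pedigree member without a resolvable genotype path")
    if risk_hid is None:
        risk_hid = 0
    return maps, hap_counter, risk_hid


def _carries(haps: tuple[Ancestry, Ancestry], hid: int, pos: int) -> bool:
    return _hap_at(haps[0], pos) == hid or _hap_at(haps[1], pos) == hid


def _common_founder_ancestor(ped: Pedigree) -> str:
    """First founder who is an ancestor of (or identical to) every affected."""

    def ancestors(mid: str) -> set[str]:
        out = {mid}
        stack = [mid]
        while stack:
            cur = stack.pop()
            for p in ped.parents_of(cur):
                if p is not None and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    affected = ped.affected_ids()
    if not affected:
        return ped.founders()[0] if ped.founders() else ped.members[0].id
    common = set.intersection(*(ancestors(a) for a in affected))
    for f in ped.founders():
        if f in common:
            return f
    # no single founder covers all affected; fall back to the first founder
    return ped.founders()[0]


def _pair_sharing(
    haps1: tuple[Ancestry, Ancestry],
    haps2: tuple[Ancestry, Ancestry],
    length: int,
) -> list[tuple[int, int]]:
    """Intervals where two individuals share >= 1 founder haplotype."""
    bounds = {0, length}
    for hap in (*haps1, *haps2):
        for s, e, _ in hap:
            bounds.add(s)
            bounds.add(e)
    cuts = sorted(b for b in bounds if 0 <= b <= length)
    shared: list[tuple[int, int]] = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if lo >= hi:
            continue
        set1 = {_hap_at(haps1[0], lo), _hap_at(haps1[1], lo)}
        set2 = {_hap_at(haps2[0], lo), _hap_at(haps2[1], lo)}
        if set1 & set2:
            shared.append((lo, hi))
    return iv.merge_intervals(shared)


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilySimulation:
    """Generated site records plus the truth they were drawn from."""

    config: SimConfig
    pedigree: Pedigree
    sample_ids: list[str]
    records: list[SiteRecord]
    truth: TruthSet
    positions: np.ndarray

    def write_vcf(self, path: str | Path) -> None:
        write_sites(self.records, self.sample_ids, path,
                    contig_lengths={self.config.chrom:
                                    self.config.chrom_length_bp})

    def write(self, outdir: str | Path, family: str = "FAM1") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf = outdir / "family.vcf"
        ped = outdir / "family.ped"
        self.write_vcf(vcf)
        write_ped(self.pedigree, ped, family=family)
        self.truth.write(outdir)
        return {"vcf": vcf, "ped": ped}


def simulate_family(
    config: SimConfig,
    ped: Optional[Pedigree] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> FamilySimulation:
    """Gene-drop a pedigree and emit multi-sample SNV records with truth.

    Identical configs (and therefore seeds) produce byte-identical output.
    """
    if ped is None:
        ped, default_samples = gwc_like_pedigree()
        if sample_ids is None:
            sample_ids = default_samples
    if sample_ids is None:
        sample_ids = ped.ids
    sample_ids = list(sample_ids)

    rng = np.random.default_rng(config.seed)
    length = config.chrom_length_bp
    n_sites = int(round(length * config.snv_density_per_bp))
    positions = _distinct_positions(rng, n_sites, length) + 1

    risk_locus = length // 2
    maps, n_haps, risk_hid = _drop_haplotypes(ped, config, rng, risk_locus)

    founder_alleles = (rng.random((n_haps, n_sites))
                       < config.founder_alt_freq).astype(np.int8)
    # the risk haplotype carries the alternate allele at the risk locus
    risk_site = int(np.searchsorted(positions - 1, risk_locus))
    if risk_site >= n_sites:
        risk_site = n_sites - 1
    founder_alleles[risk_hid, risk_site] = 1

    pos0 = positions - 1  # 0-based coordinates of sites

    def hap_alleles(hap: Ancestry) -> np.ndarray:
        out = np.empty(n_sites, dtype=np.int8)
        for s, e, hid in hap:
            i0, i1 = np.searchsorted(pos0, [s, e])
            out[i0:i1] = founder_alleles[hid, i0:i1]
        return out

    n_samples = len(sample_ids)
    true_gt = np.empty((n_sites, n_samples), dtype=np.int8)
    for j, sample in enumerate(sample_ids):
        h1, h2 = maps[sample]
        true_gt[:, j] = hap_alleles(h1) + hap_alleles(h2)

    # read model driven by the TRUE genotype (errors are caller mistakes)
    dp = rng.poisson(config.mean_depth, size=true_gt.shape)
    p_alt = _ALT_FRACTIONS[true_gt]
    ad_alt = rng.binomial(dp, p_alt)
    ad_ref = dp - ad_alt

    # errors come from their own stream so the clean and noisy versions of
    # one seed differ only in the flipped calls, not in the reads
    called_gt = true_gt.copy()
    err_mask = np.zeros_like(true_gt, dtype=bool)
    err_rng = np.random.default_rng([int(config.seed), 5])
    if config.genotype_error_rate > 0:
        err_mask = err_rng.random(true_gt.shape) < config.genotype_error_rate
        shift = err_rng.integers(1, 3, size=int(err_mask.sum()))
        called_gt[err_mask] = (called_gt[err_mask] + shift) % 3

    gq = _genotype_quality(ad_alt, dp, called_gt)
    if err_mask.any():
        # confident miscalls: GQ drawn high enough to survive the GQ filter
        gq[err_mask] = err_rng.integers(35, 71, size=int(err_mask.sum()))

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    gt_tuples = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    records: list[SiteRecord] = []
    for i in range(n_sites):
        calls = {}
        for j, sample in enumerate(sample_ids):
            calls[sample] = GenotypeCall(
                allele_indices=gt_tuples[int(called_gt[i, j])],
                ad=(int(ad_ref[i, j]), int(ad_alt[i, j])),
                dp=int(dp[i, j]),
                gq=int(gq[i, j]),
            )
        records.append(SiteRecord(chrom=config.chrom, pos=int(positions[i]),
                                  ref=str(refs[i]), alt=str(alts[i]),
                                  calls=calls))

    truth = _build_truth(ped, sample_ids, maps, length, config, risk_locus)
    return FamilySimulation(config=config, pedigree=ped,
                            sample_ids=sample_ids, records=records,
                            truth=truth, positions=positions)


def _genotype_quality(ad_alt: np.ndarray, dp: np.ndarray,
                      called: np.ndarray) -> np.ndarray:
    """Phred-scaled margin between the called genotype's binomial
    log-likelihood and the best alternative, capped at 99."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack([
            ad_alt * np.log(p) + (dp - ad_alt) * np.log1p(-p)
            for p in _ALT_FRACTIONS
        ], axis=-1)
    ll = np.nan_to_num(ll, nan=-np.inf)
    called_ll = np.take_along_axis(ll, called[..., None].astype(int),
                                   axis=-1)[..., 0]
    masked = ll.copy()
    np.put_along_axis(masked, called[..., None].astype(int), -np.inf, axis=-1)
    best_other = masked.max(axis=-1)
    margin = (called_ll - best_other) * (10.0 / np.log(10.0))
    return np.clip(np.round(margin), 0, 99).astype(np.int16)


def _build_truth(
    ped: Pedigree,
    sample_ids: Sequence[str],
    maps: dict[str, tuple[Ancestry, Ancestry]],
    length: int,
    config: SimConfig,
    risk_locus: int,
) -> TruthSet:
    truth = TruthSet(risk_locus=(config.chrom, risk_locus))
    pair_maps: list[iv.IntervalMap] = []
    for pair in affected_pairs(ped, sample_ids):
        shared = _pair_sharing(maps[pair[0]], maps[pair[1]], length)
        truth.ibd_segments[pair] = {config.chrom: shared}
        pair_maps.append({config.chrom: shared})
    if pair_maps:
        truth.shared_regions = iv.intersect_many(pair_maps)
    return truth


# ---------------------------------------------------------------------------
# SV call sets
# ---------------------------------------------------------------------------

CALLER_NAMES = ("callerA", "callerB", "callerC")


def simulate_sv_callsets(
    config: SimConfig,
    sample_ids: Optional[Sequence[str]] = None,
    affected_ids: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[SVCall]], list[dict]]:
    """Three pseudo-callers over a planted SV truth set.

    Truth SVs are placed without mutual proximity (separated by well over
    the merge distance) so cluster counting against truth is unambiguous.
    Each caller reports every truth SV with Normal(0, jitter) breakpoint
    noise plus Poisson(fp_rate x truth count) private false positives.  The
    first truth SV follows the dominant carrier model (all affected carry
    it); the rest get random carrier subsets.  The third caller emits no
    genotypes, like a read-depth CNV caller.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 11])
    if sample_ids is None:
        _, sample_ids = gwc_like_pedigree()
    sample_ids = list(sample_ids)
    if affected_ids is None:
        ped, _ = gwc_like_pedigree()
        affected_ids = [s for s in sample_ids
                        if s in ped and ped.get(s).affected]
    affected = set(affected_ids)

    length = config.chrom_length_bp
    # spacing well beyond the merge distance keeps truth clusters distinct
    min_gap = 20_000
    truth: list[dict] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(truth) < config.truth_sv_count and attempts < 10_000:
        attempts += 1
        sv_len = int(rng.integers(config.sv_min_len_bp, config.sv_max_len_bp + 1))
        if not truth:
            # the dominant-model SV sits over the risk locus so the planted
            # candidate is recoverable through the SV branch as well
            start = max(0, length // 2 - sv_len // 2)
        else:
            start = int(rng.integers(0, max(1, length - sv_len)))
        ivl = (start - min_gap, start + sv_len + min_gap)
        if any(iv.overlaps(ivl, o) for o in occupied):
            continue
        occupied.append(ivl)
        svtype = str(rng.choice(["DEL", "DUP"]))
        if len(truth) == 0:
            carriers = sorted(affected)
        else:
            k = int(rng.integers(1, len(sample_ids) + 1))
            carriers = sorted(rng.choice(sample_ids, size=k, replace=False))
        truth.append({"chrom": config.chrom, "start": start,
                      "end": start + sv_len, "svtype": svtype,
                      "carriers": ",".join(carriers)})

    callsets: dict[str, list[SVCall]] = {}
    for c_idx, caller in enumerate(CALLER_NAMES):
        calls: list[SVCall] = []
        for sv in truth:
            js, je = (int(round(v)) for v in
                      rng.normal(0.0, config.sv_jitter_sd_bp, size=2))
            start = max(0, sv["start"] + js)
            end = min(length, sv["end"] + je)
            if end <= start:
                end = start + 1
            carriers = set(sv["carriers"].split(","))
            if c_idx == 2:
                gts = {s: "missing" for s in sample_ids}
            else:
                gts = {s: ("het" if s in carriers else "ref")
                       for s in sample_ids}
            calls.append(SVCall(
                chrom=sv["chrom"], start=start, end=end, svtype=sv["svtype"],
                caller=caller, sample_genotypes=gts,
                quality=float(rng.integers(20, 61)), filter_flags=("PASS",)))
        n_fp = int(rng.poisson(config.sv_fp_rate * max(1, len(truth))))
        for _ in range(n_fp):
            sv_len = int(rng.integers(config.sv_min_len_bp,
                                      config.sv_max_len_bp + 1))
            start = int(rng.integers(0, max(1, length - sv_len)))
            calls.append(SVCall(
                chrom=config.chrom, start=start, end=start + sv_len,
                svtype=str(rng.choice(["DEL", "DUP"])), caller=caller,
                sample_genotypes={s: "missing" for s in sample_ids},
                quality=float(rng.integers(5, 30)), filter_flags=("PASS",)))
        callsets[caller] = calls
    return callsets, truth


def write_sv_vcf(calls: Sequence[SVCall], sample_ids: Sequence[str],
                 path: str | Path, contig: str = "1",
                 contig_length: int = 20_000_000) -> None:
    """Write one caller's calls as a symbolic-ALT SV VCF."""
    gt_code = {"ref": "0/0", "het": "0/1", "hom": "1/1", "missing": "./."}
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start)), 1):
        info = f"SVTYPE={c.svtype};END={c.end}"
        qual = "." if c.quality is None else f"{c.quality:g}"
        filt = ";".join(c.filter_flags) if c.filter_flags else "."
        gt_fields = [gt_code[c.sample_genotypes.get(s, "missing")]
                     for s in sample_ids]
        lines.append("\t".join([
            c.chrom, str(c.start + 1), f"sv{i}", "N", f"<{c.svtype}>",
            qual, filt, info, "GT"] + gt_fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reporter assay
# ---------------------------------------------------------------------------

def simulate_assay(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Log-normal firefly/renilla well readings for wt and variant constructs.

    Normalized FOP activity is centred at 1 for both constructs; normalized
    TOP activity is centred at the construct's configured T/F level, so the
    per-replicate TOP/FOP ratios separate according to the planted effect.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 23])
    levels = {"wt": config.assay_tf_wt, "variant": config.assay_tf_variant}
    rows = []
    for exp_idx in range(1, config.assay_experiments + 1):
        for construct, tf_level in levels.items():
            for reporter in ("TOP", "FOP"):
                centre = tf_level if reporter == "TOP" else 1.0
                for rep in range(1, config.assay_replicates + 1):
                    renilla = float(np.exp(rng.normal(np.log(1000.0),
                                                      config.assay_log_sd)))
                    firefly = float(centre * renilla
                                    * np.exp(rng.normal(0.0, config.assay_log_sd)))
                    rows.append({"construct": construct, "reporter": reporter,
                                 "firefly_rlu": firefly,
                                 "renilla_rlu": renilla,
                                 "replicate": rep,
                                 "experiment": f"exp{exp_idx}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig, outdir: str | Path,
                    n_genes: int = 50) -> dict[str, Path]:
    """Generate every pipeline input into one directory.

    Besides the family VCF/PED and truth files this writes a synthetic gene
    BED (one gene planted over the risk locus, named GENE_RISK, scored
    0.95), an Exomiser-style score table, three SV caller VCFs and the
    assay CSV.  Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam = simulate_family(config)
    paths = fam.write(outdir)

    rng = np.random.default_rng([int(config.seed), 7])
    length = config.chrom_length_bp
    risk_chrom, risk_pos = fam.truth.risk_locus
    genes = []
    starts = _distinct_positions(rng, n_genes, length - 100_000)
    for i, s in enumerate(starts, 1):
        genes.append((risk_chrom, int(s),
                      int(s + rng.integers(20_000, 100_000)), f"GENE{i:03d}"))
    genes.append((risk_chrom, max(0, risk_pos - 25_000),
                  min(length, risk_pos + 25_000), "GENE_RISK"))
    genes.sort(key=lambda g: g[1])
    gene_bed = outdir / "genes.bed"
    gene_bed.write_text("".join(
        f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in genes))

    scores = []
    for c, s, e, name in genes:
        score = 0.95 if name == "GENE_RISK" else float(
            np.round(rng.beta(1.0, 4.0), 4))
        scores.append({"gene": name, "score": score, "chrom": c,
                       "start": s, "end": e})
    scores_path = outdir / "gene_scores.tsv"
    pd.DataFrame(scores).to_csv(scores_path, sep="\t", index=False)

    callsets, sv_truth = simulate_sv_callsets(config, fam.sample_ids)
    sv_paths = {}
    for caller, calls in callsets.items():
        p = outdir / f"sv_{caller}.vcf"
        write_sv_vcf(calls, fam.sample_ids, p, contig=config.chrom,
                     contig_length=length)
        sv_paths[caller] = p
    fam.truth.sv_table = sv_truth
    fam.truth.assay_effect = {
        "tf_wt": config.assay_tf_wt, "tf_variant": config.assay_tf_variant,
        "log_sd": config.assay_log_sd}
    fam.truth.write(outdir)

    assay_path = outdir / "assay.csv"
    simulate_assay(config).to_csv(assay_path, index=False)

    manifest = {**paths, "genes": gene_bed, "scores": scores_path,
                "assay": assay_path, **{f"sv_{k}": v for k, v in sv_paths.items()}}
    return manifest
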