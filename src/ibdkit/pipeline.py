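"""End-to-end orchestration: filter -> IBD -> prioritize -> SV merge -> assay.

Every stage is a pure function of its inputs and the run configuration;
the run report records every threshold used and the count at each filter
step (sites read, passing hard filters, segments, shared regions, genes in
regions, genes above the cutoff, merged SVs surviving each rejection rule),
so the funnel on any dataset is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .ibd import IBDMapping, SegmentationParams
from .pedigree import parse_pedigree
from .prioritize import load_gene_scores, prioritize_candidates
from .reporter import ReporterAssay
from .sv import (MergeParams, annotate_and_filter_sv, caller_hard_filter,
                 dominant_model_filter, merge_callsets, read_sv_vcf,
                 write_merged_tsv)
from .vcfio import FilterThresholds

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending path."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    vcf: str
    ped: str
    outdir: str = "ibdkit_run"
    samples: Optional[list[str]] = None
    scores: Optional[str] = None
    gene_bed: Optional[str] = None
    regulatory_bed: Optional[str] = None
    sv_callsets: dict[str, str] = field(default_factory=dict)
    phenotype_genes: Optional[list[str]] = None
    assay: Optional[str] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    merge: MergeParams = field(default_factory=MergeParams)
    cutoff: float = 0.5
    min_callers: int = 1
    alternative: str = "two-sided"
    exclude_unaffected: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("thresholds", FilterThresholds),
                           ("segmentation", SegmentationParams),
                           ("merge", MergeParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def parameters(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out


def _require(path: Optional[str], stage: str) -> Path:
    if path is None:
        raise PipelineError(f"stage {stage!r}: required input not configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage {stage!r}: missing input {p}")
    return p


def _read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        name = cols[3] if len(cols) > 3 else f"feature{i}"
        rows.append((cols[0], int(cols[1]), int(cols[2]), name))
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write per-stage outputs.

    Returns the run report (also written as ``report.json`` and
    ``report.tsv`` in the output directory).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": config.parameters(), "counts": {}}
    counts = report["counts"]

    # -- stage: IBD mapping ------------------------------------------------
    vcf = _require(config.vcf, "ibd")
    ped_path = _require(config.ped, "ibd")
    try:
        model = IBDMapping.from_files(vcf, ped_path,
                                      sample_ids=config.samples,
                                      thresholds=config.thresholds)
        ibd = model.fit(config.segmentation,
                        exclude_unaffected=config.exclude_unaffected)
    except PipelineError:
        raise
    except Exception as exc:  # surface the stage in the error
        raise PipelineError(f"stage 'ibd' failed on {vcf}: {exc}") from exc
    counts.update(ibd.filter_counts)
    ibd.regions_to_bed(outdir / "shared_regions.bed")
    for pair in ibd.segments_by_pair:
        ibd.segments_to_bed(
            outdir / f"segments_{pair[0]}_{pair[1]}.bed", pair)
    (outdir / "ibd_summary.txt").write_text(ibd.summary() + "\n")

    gene_rows = None
    if config.gene_bed is not None:
        gene_rows = _read_bed(_require(config.gene_bed, "ibd"))
        summary = ibd.region_summary(gene_rows)
        counts["genes_overlapping_regions"] = summary.n_genes

    # -- stage: prioritization --------------------------------------------
    if config.scores is not None:
        scores_path = _require(config.scores, "prioritize")
        try:
            scores = load_gene_scores(scores_path)
            gene_map = ({name: (c, s, e) for c, s, e, name in gene_rows}
                        if gene_rows else None)
            in_regions, candidates = prioritize_candidates(
                scores, ibd.regions, gene_map, cutoff=config.cutoff)
        except Exception as exc:
            raise PipelineError(
                f"stage 'prioritize' failed on {scores_path}: {exc}") from exc
        counts["genes_scored"] = len(scores)
        counts["genes_in_ibd_regions"] = len(in_regions)
        counts["candidate_genes"] = len(candidates)
        pd.DataFrame(
            [{"gene": g.gene, "score": g.score} for g in candidates]
        ).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        report["top_candidates"] = [
            {"gene": g.gene, "score": g.score} for g in candidates[:10]]

    # -- stage: SV consensus ----------------------------------------------
    if config.sv_callsets:
        callsets = []
        for caller, path in sorted(config.sv_callsets.items()):
            p = _require(path, "svmerge")
            try:
                callsets.append(read_sv_vcf(p, caller))
            except Exception as exc:
                raise PipelineError(
                    f"stage 'svmerge' failed on {p}: {exc}") from exc
        counts["sv_calls_input"] = sum(len(c) for c in callsets)
        filtered = [caller_hard_filter(c, {}) for c in callsets]
        merged = merge_callsets(filtered, config.merge)
        counts["sv_clusters"] = len(merged)
        merged = [m for m in merged if m.n_callers >= config.min_callers]
        counts["sv_clusters_min_callers"] = len(merged)
        ped = parse_pedigree(ped_path.read_text())
        merged = dominant_model_filter(merged, ped, config.samples)
        counts["sv_dominant_consistent"] = len(merged)
        pheno = config.phenotype_genes
        merged = annotate_and_filter_sv(
            merged,
            gene_intervals=gene_rows,
            regulatory_intervals=(_read_bed(config.regulatory_bed)
                                  if config.regulatory_bed else None),
            phenotype_genes=pheno,
            ibd_regions=ibd.regions if ibd.regions else None,
        )
        counts["sv_candidates"] = len(merged)
        write_merged_tsv(merged, outdir / "merged_svs.tsv")

    # -- stage: reporter assay --------------------------------------------
    if config.assay is not None:
        assay_path = _require(config.assay, "assay")
        try:
            results = ReporterAssay.from_csv(assay_path).fit(
                alternative=config.alternative)
        except Exception as exc:
            raise PipelineError(
                f"stage 'assay' failed on {assay_path}: {exc}") from exc
        results.to_frame().to_csv(outdir / "assay_stats.tsv", sep="\t",
                                  index=False)
        t = results.test
        report["assay"] = {
            "U": t.u_statistic, "Z": round(t.z_value, 6),
            "p_value": t.p_value, "effect_size_r": round(t.effect_size_r, 6),
            "method": t.method, "alternative": t.alternative,
            "tf_ratios": {k: round(v, 6) for k, v in results.ratios.items()},
        }

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    pd.DataFrame(sorted(counts.items()), columns=["step", "count"]).to_csv(
        outdir / "report.tsv", sep="\t", index=False)
    return report
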