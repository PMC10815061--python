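"""Candidate-gene prioritization against IBD shared regions.

Externally produced gene scores (Exomiser-style TSV: one row per gene with
a phenotype-aware score in [0, 1]) are intersected with the shared regions
from IBD mapping and thresholded: records with a score *less than* the
cutoff (default 0.5) are discarded, as in the source workflow.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .ibd import SharedRegion
from .intervals import overlaps

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScore",
    "load_gene_scores",
    "filter_by_score",
    "genes_in_regions",
    "prioritize_candidates",
]

_GENE_COLUMNS = ("gene", "gene_symbol", "#gene_symbol", "symbol")
_SCORE_COLUMNS = ("score", "exomiser_score", "exomiser_gene_combined_score",
                  "combined_score", "gene_combined_score")
_VARIANT_COLUMNS = ("variants", "variant_ids", "contributing_variants")


@dataclass(frozen=True)
class GeneScore:
    """A gene symbol with its prioritization score and optional interval."""

    gene: str
    score: float
    variant_ids: tuple[str, ...] = ()
    interval: Optional[tuple[str, int, int]] = None  # chrom, start, end (0-based)

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score for {self.gene!r} outside [0, 1]: {self.score}")


def _pick_column(columns: Sequence[str], candidates: Sequence[str],
                 explicit: Optional[str], what: str) -> str:
    if explicit is not None:
        if explicit not in columns:
            raise KeyError(f"{what} column {explicit!r} not in header {list(columns)}")
        return explicit
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise KeyError(f"no {what} column found in header {list(columns)}; "
                   f"tried {list(candidates)}")


def load_gene_scores(
    tsv_source: Union[str, Path, io.IOBase],
    gene_col: Optional[str] = None,
    score_col: Optional[str] = None,
    sep: str = "\t",
) -> list[GeneScore]:
    """Read a gene-score table; rows with unparseable scores are skipped.

    Column names are auto-detected case-insensitively among the usual
    Exomiser-style candidates unless given explicitly.  Optional
    ``chrom``/``start``/``end`` columns populate gene intervals; an optional
    variants column (comma-separated) populates ``variant_ids``.
    """
    df = pd.read_csv(tsv_source, sep=sep, dtype=str)
    gene_c = _pick_column(df.columns, _GENE_COLUMNS, gene_col, "gene")
    score_c = _pick_column(df.columns, _SCORE_COLUMNS, score_col, "score")
    lowered = {c.lower(): c for c in df.columns}
    variant_c = next((lowered[c] for c in _VARIANT_COLUMNS if c in lowered), None)
    has_iv = all(c in lowered for c in ("chrom", "start", "end"))

    out: list[GeneScore] = []
    n_skipped = 0
    for _, row in df.iterrows():
        score = pd.to_numeric(row[score_c], errors="coerce")
        if pd.isna(score):
            n_skipped += 1
            continue
        variants: tuple[str, ...] = ()
        if variant_c is not None and isinstance(row[variant_c], str):
            variants = tuple(v for v in row[variant_c].split(",") if v)
        interval = None
        if has_iv and not pd.isna(row[lowered["start"]]):
            interval = (str(row[lowered["chrom"]]),
                        int(row[lowered["start"]]), int(row[lowered["end"]]))
        out.append(GeneScore(gene=str(row[gene_c]), score=float(score),
                             variant_ids=variants, interval=interval))
    if n_skipped:
        logger.info("skipped %d rows with unparseable scores", n_skipped)
    return out


def filter_by_score(
    scores: Sequence[GeneScore], cutoff: float = 0.5
) -> list[GeneScore]:
    """Retain genes with score >= cutoff, sorted descending for reporting.

    "Less than the cutoff" is discarded — a score exactly at the cutoff
    survives.  Ties keep input order (stable sort).
    """
    kept = [g for g in scores if g.score >= cutoff]
    return sorted(kept, key=lambda g: -g.score)


def genes_in_regions(
    scores: Sequence[GeneScore],
    regions: Sequence[SharedRegion],
    gene_intervals: Optional[Mapping[str, tuple[str, int, int]]] = None,
) -> list[GeneScore]:
    """Genes whose interval overlaps >= 1 bp of any shared region.

    Intervals come from each :class:`GeneScore` or, failing that, from the
    ``gene_intervals`` mapping (symbol -> (chrom, start, end), 0-based
    half-open).  Genes without a locatable interval are logged and dropped.
    """
    if not regions:
        return []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    out: list[GeneScore] = []
    n_unmapped = 0
    for g in scores:
        interval = g.interval
        if interval is None and gene_intervals is not None:
            interval = gene_intervals.get(g.gene)
        if interval is None:
            n_unmapped += 1
            continue
        chrom, start, end = str(interval[0]), int(interval[1]), int(interval[2])
        if any(overlaps((start, end), riv) for riv in by_chrom.get(chrom, ())):
            out.append(g)
    if n_unmapped:
        logger.info("no interval available for %d scored genes", n_unmapped)
    return out


def prioritize_candidates(
    scores: Sequence[GeneScore],
    regions: Sequence[SharedRegion],
    gene_intervals: Optional[Mapping[str, tuple[str, int, int]]] = None,
    cutoff: float = 0.5,
) -> tuple[list[GeneScore], list[GeneScore]]:
    """The two-step funnel: restrict to IBD regions, then apply the cutoff.

    Returns ``(in_regions, candidates)`` so callers can report the size of
    both filtering stages.
    """
    in_regions = genes_in_regions(scores, regions, gene_intervals)
    return in_regions, filter_by_score(in_regions, cutoff)
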