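"""Candidate reference-gene screening from a stage-wise RPKM matrix.

The screen reduces a whole-transcriptome RPKM matrix to a short list of
candidate reference genes with a five-stage filter cascade:

1. expressed      — min RPKM over stages >= threshold (default 0.17)
2. stability      — RPKM_max/min < 2 and CV < 0.3 (strict inequalities)
3. abundance      — min RPKM > 40 (strict)
4. top-N          — the N survivors with the smallest max/min ratio
5. annotation     — keep single-transcript genes, or two-transcript genes
                    whose isoforms overlap

The "expressed" filter is inclusive at the boundary and applies to the
per-gene minimum, which guarantees that RPKM_max/min is defined for every
survivor. CV is sample SD divided by mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .datamodel import (ExpressionMatrix, GeneAnnotation, PipelineConfig,
                        ValidationError)

logger = logging.getLogger("refrank")


@dataclass(frozen=True)
class GeneScreenStats:
    """Per-gene summary statistics over stages.

    ``max_min_ratio`` is NaN when the minimum RPKM is zero (the ratio is
    undefined, a marker rather than an error).
    """

    gene_id: str
    min_rpkm: float
    max_rpkm: float
    max_min_ratio: float
    mean: float
    sd: float
    cv: float

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.max_min_ratio)


@dataclass
class FilterStage:
    name: str
    parameters: dict
    survivors: list[str]

    @property
    def count(self) -> int:
        return len(self.survivors)


@dataclass
class ScreeningReport:
    """The full cascade: per-stage survivor sets plus the final candidates.

    Survivor sets are strictly nested along the cascade.
    """

    stages: list[FilterStage] = field(default_factory=list)

    @property
    def final_candidates(self) -> list[str]:
        return list(self.stages[-1].survivors) if self.stages else []

    @property
    def counts(self) -> list[tuple[str, int]]:
        return [(s.name, s.count) for s in self.stages]

    def add(self, name: str, parameters: dict, survivors: list[str]) -> None:
        if self.stages and not set(survivors) <= set(self.stages[-1].survivors):
            raise ValidationError(
                f"stage {name!r} survivors are not a subset of the previous stage")
        self.stages.append(FilterStage(name, parameters, list(survivors)))
        logger.info("screen stage %-12s: %d survivors", name, len(survivors))


def compute_screen_stats(m: ExpressionMatrix) -> list[GeneScreenStats]:
    """Per-gene min/max RPKM, max/min ratio, mean, sample SD and CV."""
    v = m.values
    mins = v.min(axis=1)
    maxs = v.max(axis=1)
    means = v.mean(axis=1)
    sds = v.std(axis=1, ddof=1)
    out = []
    for gid, lo, hi, mu, sd in zip(m.gene_ids, mins, maxs, means, sds):
        ratio = hi / lo if lo > 0 else math.nan
        cv = sd / mu if mu > 0 else (0.0 if sd == 0 else math.nan)
        out.append(GeneScreenStats(gid, float(lo), float(hi), float(ratio),
                                   float(mu), float(sd), float(cv)))
    return out


def filter_expressed(stats: list[GeneScreenStats],
                     threshold: float) -> list[str]:
    """Genes expressed at every stage: min RPKM >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValidationError("expressed threshold must be > 0")
    return [s.gene_id for s in stats if s.min_rpkm >= threshold]


def filter_stability(stats: list[GeneScreenStats], ratio_limit: float = 2.0,
                     cv_limit: float = 0.3) -> list[str]:
    """Stably expressed genes: defined max/min ratio < limit AND CV < limit.

    Both inequalities are strict; a gene with an undefined ratio (zero
    minimum) never passes.
    """
    if ratio_limit <= 0 or cv_limit <= 0:
        raise ValidationError("stability limits must be > 0")
    return [s.gene_id for s in stats
            if s.ratio_defined and s.max_min_ratio < ratio_limit
            and s.cv < cv_limit]


def filter_abundance(stats: list[GeneScreenStats],
                     min_rpkm_limit: float = 40.0) -> list[str]:
    """Moderately-to-highly expressed genes: min RPKM > limit (strict)."""
    if min_rpkm_limit <= 0:
        raise ValidationError("abundance limit must be > 0")
    return [s.gene_id for s in stats if s.min_rpkm > min_rpkm_limit]


def select_top_candidates(stats: list[GeneScreenStats], survivors: list[str],
                          top_n: int = 5) -> list[str]:
    """The ``top_n`` survivors with the smallest max/min ratio.

    Ties on the ratio break by CV (ascending), then gene id. If fewer than
    ``top_n`` survivors exist, all are returned with a warning.
    """
    if not survivors:
        raise ValidationError("cannot rank an empty survivor set")
    by_id = {s.gene_id: s for s in stats}
    ordered = sorted(survivors,
                     key=lambda g: (by_id[g].max_min_ratio, by_id[g].cv, g))
    if top_n > len(ordered):
        logger.warning("top_n=%d exceeds %d survivors; returning all",
                       top_n, len(ordered))
    return ordered[:top_n]


def filter_annotation(candidates: list[str],
                      annotation: dict[str, GeneAnnotation],
                      allow_multi_isoform: bool = False,
                      keep_missing: bool = False) -> list[str]:
    """Keep genes amenable to unambiguous primer design.

    A gene is retained iff it has exactly one transcript, or exactly two
    transcripts that overlap. Genes with more isoforms are dropped unless
    ``allow_multi_isoform``. Candidates without an annotation row are dropped
    with a warning unless ``keep_missing``.
    """
    kept = []
    for gid in candidates:
        ann = annotation.get(gid)
        if ann is None:
            logger.warning("candidate %s has no annotation row; %s",
                           gid, "kept" if keep_missing else "dropped")
            if keep_missing:
                kept.append(gid)
            continue
        if ann.transcript_count == 1:
            kept.append(gid)
        elif ann.transcript_count == 2 and ann.two_transcripts_overlap:
            kept.append(gid)
        elif allow_multi_isoform:
            kept.append(gid)
    return kept


def run_screen(m: ExpressionMatrix,
               annotation: dict[str, GeneAnnotation] | None = None,
               cfg: PipelineConfig | None = None,
               allow_multi_isoform: bool = False) -> ScreeningReport:
    """Run the full five-stage cascade and record survivors at every stage.

    The annotation stage is applied only when an annotation table is given.
    An empty survivor set at any stage short-circuits the remaining filters
    but still yields a complete report (later stages record zero survivors),
    except top-N which requires a non-empty input and is recorded as empty.
    """
    cfg = cfg or PipelineConfig()
    stats = compute_screen_stats(m)
    report = ScreeningReport()

    expressed = filter_expressed(stats, cfg.expressed_threshold)
    report.add("expressed", {"threshold": cfg.expressed_threshold}, expressed)

    stats_by_id = {s.gene_id: s for s in stats}
    stable = [g for g in filter_stability(stats, cfg.max_min_ratio_limit,
                                          cfg.cv_limit) if g in set(expressed)]
    report.add("stability", {"ratio_limit": cfg.max_min_ratio_limit,
                             "cv_limit": cfg.cv_limit}, stable)

    abundant = [g for g in filter_abundance(stats, cfg.min_rpkm)
                if g in set(stable)]
    report.add("abundance", {"min_rpkm": cfg.min_rpkm}, abundant)

    top = (select_top_candidates(list(stats_by_id.values()), abundant,
                                 cfg.top_n) if abundant else [])
    report.add("top_n", {"top_n": cfg.top_n}, top)

    if annotation is not None:
        final = filter_annotation(top, annotation,
                                  allow_multi_isoform=allow_multi_isoform)
        report.add("annotation", {"allow_multi_isoform": allow_multi_isoform},
                   final)
    return report


def report_to_frame(report: ScreeningReport):
    """Flatten a ScreeningReport to a tidy DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for stage in report.stages:
        rows.append({"stage": stage.name,
                     "parameters": ";".join(f"{k}={v}" for k, v in
                                            stage.parameters.items()),
                     "survivor_count": stage.count,
                     "survivors": ",".join(stage.survivors)})
    return pd.DataFrame(rows)


__all__ = [
    "GeneScreenStats", "FilterStage", "ScreeningReport",
    "compute_screen_stats", "filter_expressed", "filter_stability",
    "filter_abundance", "select_top_candidates", "filter_annotation",
    "run_screen", "report_to_frame",
]
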