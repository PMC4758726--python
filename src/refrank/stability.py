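"""Reference-gene stability ranking from CT data.

Implements four independent stability statistics, each computed on a
replicate-collapsed CT matrix (genes × samples), plus a cross-method
aggregate rank:

* **delta-CT** — for every ordered gene pair (i, j) the per-sample difference
  ΔCT_ij(s) = CT_i(s) − CT_j(s) is formed; gene i's statistic is the mean
  over partners j of the sample SD of ΔCT_ij. Units: cycles; lower = more
  stable.
* **geNorm** — expression quantities q_i(s) = base^(min_s CT_i − CT_i(s));
  M_i is the mean over partners of the SD of the pairwise log-ratio series.
  The highest-M gene is excluded stepwise until two remain (the most stable
  pair, which shares rank 1). The pairwise-variation series V_n/n+1 compares
  normalization factors (geometric means of quantities) built from the n vs
  n + 1 most stable genes. With base 2 and no exclusion, M equals the
  delta-CT statistic gene-by-gene — an exact algebraic identity used as a
  cross-method check.
* **BestKeeper** — descriptive statistics of the raw CT values (arithmetic
  and geometric mean, min, max, sample SD, CV = 100·SD/mean) plus the
  Pearson correlation of each gene with the BestKeeper index, the per-sample
  geometric mean CT over all candidates. Genes rank by ascending SD (CV
  breaks ties).
* **NormFinder** (single-group) — fits the additive model
  y_ij = α_i + β_j + ε_ij on log-scale expression y = −CT by double
  centering; per-gene residual variances v_i are converted to unbiased
  per-gene variance estimates σ̂²_i = (g/(g−2))·v_i − Σv/((g−1)(g−2)), and
  the stability value is σ̂_i = sqrt(max(0, σ̂²_i)).

Ranks are 1 = most stable; ties share a rank and the next gene skips
(1, 1, 3, …). All SDs are sample SDs (n − 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .datamodel import (CtDataset, PipelineConfig, ValidationError,
                        collapse_replicates)

logger = logging.getLogger("refrank")

METHODS = ("deltaCT", "geNorm", "BestKeeper", "NormFinder")


@dataclass(frozen=True)
class StabilityScore:
    """One gene's statistic and rank under one method (1 = most stable)."""

    gene_id: str
    method: str
    value: float
    rank: int


def _tied_ranks(values: Sequence[float]) -> list[int]:
    """Competition ranks (1, 1, 3, ...) for ascending values."""
    return [int(r) for r in sstats.rankdata(values, method="min")]


def _tied_ranks_lex(keys: Sequence[tuple]) -> list[int]:
    """Competition ranks for tuple sort keys (lexicographic ascending)."""
    return [1 + sum(other < key for other in keys) for key in keys]


def _require_collapsed(ds: CtDataset, caller: str) -> np.ndarray:
    if not ds.is_collapsed:
        raise ValidationError(
            f"{caller} expects a replicate-collapsed dataset; "
            "apply collapse_replicates first")
    return ds.ct_matrix()


# ---------------------------------------------------------------------------
# delta-CT
# ---------------------------------------------------------------------------


def delta_ct_stability(ds: CtDataset) -> list[StabilityScore]:
    """Mean pairwise ΔCT standard deviation per gene, ranked ascending."""
    ct = _require_collapsed(ds, "delta_ct_stability")
    g, n = ct.shape
    if g < 2:
        raise ValidationError("delta-CT needs at least 2 genes")
    if n < 2:
        raise ValidationError("delta-CT needs at least 2 samples (SD undefined)")
    diffs = ct[:, None, :] - ct[None, :, :]          # (g, g, n)
    pair_sd = diffs.std(axis=2, ddof=1)              # (g, g)
    stat = pair_sd.sum(axis=1) / (g - 1)             # diagonal is 0
    ranks = _tied_ranks(stat)
    return [StabilityScore(gid, "deltaCT", float(v), r)
            for gid, v, r in zip(ds.gene_ids, stat, ranks)]


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


@dataclass
class GeNormResult:
    """Stepwise geNorm output.

    ``m_full`` holds each gene's M over the full candidate set; ``m_final``
    holds the M value at the step where the gene was excluded (for the final
    pair, their shared two-gene M) — the value conventionally reported.
    ``stability_order`` lists genes from most to least stable (the final
    pair first, then the reverse exclusion order). ``pairwise_variation``
    maps "V2/3", "V3/4", … to the SD of the log-ratio of normalization
    factors built from the n vs n + 1 most stable genes.
    """

    gene_ids: list[str]
    m_full: dict[str, float]
    m_final: dict[str, float]
    exclusion_order: list[str]
    most_stable_pair: tuple[str, str]
    stability_order: list[str]
    pairwise_variation: dict[str, float]
    scores: list[StabilityScore] = field(default_factory=list)


def genorm_m_values(ds: CtDataset, efficiency_base: float = 2.0,
                    genes: Sequence[str] | None = None) -> dict[str, float]:
    """Full-set (no exclusion) geNorm M value for each gene."""
    ct = _require_collapsed(ds, "genorm_m_values")
    ids = list(ds.gene_ids) if genes is None else list(genes)
    idx = [ds.gene_ids.index(g) for g in ids]
    # log2-quantities relative to the per-gene minimum CT; the calibrator
    # cancels in every pairwise ratio, so any per-gene affine choice works
    a = (ct[idx].min(axis=1, keepdims=True) - ct[idx]) * math.log2(efficiency_base)
    diffs = a[:, None, :] - a[None, :, :]
    pair_sd = diffs.std(axis=2, ddof=1)
    m = pair_sd.sum(axis=1) / (len(ids) - 1)
    return dict(zip(ids, m.astype(float)))


def genorm(ds: CtDataset, efficiency_base: float = 2.0) -> GeNormResult:
    """Stepwise geNorm: M values, exclusion order, most-stable pair, V_n/n+1."""
    ct = _require_collapsed(ds, "genorm")
    g, n = ct.shape
    if g < 3:
        raise ValidationError("geNorm stepwise exclusion needs at least 3 genes")
    if n < 2:
        raise ValidationError("geNorm needs at least 2 samples")

    m_full = genorm_m_values(ds, efficiency_base)
    m_final: dict[str, float] = {}
    remaining = list(ds.gene_ids)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = genorm_m_values(ds, efficiency_base, genes=remaining)
        worst_val = max(m.values())
        # tie on the highest M: exclude the lexicographically last gene id
        worst = max(gid for gid, v in m.items() if v == worst_val)
        m_final[worst] = m[worst]
        exclusion.append(worst)
        remaining.remove(worst)

    m_pair = genorm_m_values(ds, efficiency_base, genes=remaining)
    pair = tuple(sorted(remaining))
    for gid in pair:
        m_final[gid] = m_pair[gid]

    stability_order = list(pair) + list(reversed(exclusion))

    # normalization factors over increasing reference-set sizes
    log_q = (ct.min(axis=1, keepdims=True) - ct) * math.log2(efficiency_base)
    order_idx = [ds.gene_ids.index(gid) for gid in stability_order]
    v_series: dict[str, float] = {}
    for k in range(2, g):
        nf_k = log_q[order_idx[:k]].mean(axis=0)      # log of geometric mean
        nf_k1 = log_q[order_idx[:k + 1]].mean(axis=0)
        v_series[f"V{k}/{k + 1}"] = float(np.std(nf_k - nf_k1, ddof=1))

    rank_of = {gid: i + 1 for i, gid in enumerate(stability_order)}
    rank_of[pair[0]] = rank_of[pair[1]] = 1
    if len(stability_order) > 2:
        # the pair shares rank 1; third place is rank 3
        for i, gid in enumerate(stability_order[2:], start=3):
            rank_of[gid] = i
    scores = [StabilityScore(gid, "geNorm", m_final[gid], rank_of[gid])
              for gid in ds.gene_ids]
    return GeNormResult(list(ds.gene_ids), m_full, m_final, exclusion, pair,
                        stability_order, v_series, scores)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------


@dataclass
class BestKeeperResult:
    """Descriptive CT statistics, the per-sample index and correlations.

    ``per_gene`` columns: mean_ct, geo_mean_ct, min_ct, max_ct, sd_ct,
    cv_pct, pearson_r (NaN marks an undefined correlation for a
    zero-variance gene). ``index`` is the per-sample geometric mean CT over
    all candidates.
    """

    per_gene: pd.DataFrame
    index: pd.Series
    scores: list[StabilityScore] = field(default_factory=list)


def bestkeeper(ds: CtDataset) -> BestKeeperResult:
    """BestKeeper descriptive analysis; ranking by ascending CT SD."""
    ct = _require_collapsed(ds, "bestkeeper")
    g, n = ct.shape
    if (ct <= 0).any():
        raise ValidationError("BestKeeper needs strictly positive CT values")
    if n < 3:
        raise ValidationError("BestKeeper needs >= 3 samples for Pearson r")

    index = sstats.gmean(ct, axis=0)
    mean = ct.mean(axis=1)
    sd = ct.std(axis=1, ddof=1)
    rows = []
    for i, gid in enumerate(ds.gene_ids):
        if sd[i] > 0 and np.std(index) > 0:
            r = float(sstats.pearsonr(ct[i], index).statistic)
        else:
            r = math.nan
        rows.append({"gene_id": gid, "mean_ct": float(mean[i]),
                     "geo_mean_ct": float(sstats.gmean(ct[i])),
                     "min_ct": float(ct[i].min()), "max_ct": float(ct[i].max()),
                     "sd_ct": float(sd[i]),
                     "cv_pct": float(100.0 * sd[i] / mean[i]),
                     "pearson_r": r})
    per_gene = pd.DataFrame(rows).set_index("gene_id")

    # rank primarily by SD (cycles), CV as tie-breaker
    order_key = list(zip(per_gene["sd_ct"], per_gene["cv_pct"]))
    ranks = _tied_ranks_lex(order_key)
    scores = [StabilityScore(gid, "BestKeeper", float(per_gene.loc[gid, "sd_ct"]),
                             r)
              for gid, r in zip(ds.gene_ids, ranks)]
    return BestKeeperResult(per_gene, pd.Series(index, index=ds.sample_labels),
                            scores)


# ---------------------------------------------------------------------------
# NormFinder (single group)
# ---------------------------------------------------------------------------


@dataclass
class NormFinderResult:
    """Variance decomposition of the gene + sample additive model.

    ``residual_variance`` is v_i = Σ_j r_ij² / (n − 1) from the
    double-centered residuals; ``sigma_sq`` the unbiased per-gene variance
    estimate (may be negative before clamping); ``stability`` is
    sqrt(max(0, σ̂²)), in log2 units.
    """

    gene_ids: list[str]
    residual_variance: np.ndarray
    sigma_sq: np.ndarray
    stability: np.ndarray
    n_genes: int
    n_samples: int
    scores: list[StabilityScore] = field(default_factory=list)


def normfinder_single_group(ds: CtDataset) -> NormFinderResult:
    """NormFinder stability values for one experimental group."""
    ct = _require_collapsed(ds, "normfinder_single_group")
    g, n = ct.shape
    if g < 3:
        raise ValidationError("NormFinder estimator is undefined for g < 3")
    if n < 2:
        raise ValidationError("NormFinder needs at least 2 samples")

    y = -ct   # log2 expression up to an additive constant (cancels below)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) \
        + y.mean()
    v = (resid ** 2).sum(axis=1) / (n - 1)
    sigma_sq = (g / (g - 2)) * v - v.sum() / ((g - 1) * (g - 2))
    stability = np.sqrt(np.clip(sigma_sq, 0.0, None))
    ranks = _tied_ranks(stability)
    scores = [StabilityScore(gid, "NormFinder", float(s), r)
              for gid, s, r in zip(ds.gene_ids, stability, ranks)]
    return NormFinderResult(list(ds.gene_ids), v, sigma_sq, stability, g, n,
                            scores)


# ---------------------------------------------------------------------------
# Cross-method aggregation
# ---------------------------------------------------------------------------


@dataclass
class StabilityRanking:
    """All per-method scores for one group plus the aggregate rank.

    The aggregate statistic is the geometric mean of the per-method ranks;
    aggregate ranks re-rank those means (ties shared).
    """

    group: str
    method_scores: dict[str, list[StabilityScore]]
    aggregate: list[StabilityScore]
    genorm: GeNormResult | None = None
    bestkeeper: BestKeeperResult | None = None
    normfinder: NormFinderResult | None = None

    def to_frame(self) -> pd.DataFrame:
        """Wide table: per-method statistic and rank columns per gene."""
        genes = [s.gene_id for s in self.aggregate]
        df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        for method, scores in self.method_scores.items():
            by_id = {s.gene_id: s for s in scores}
            df[f"{method}_value"] = [by_id[g].value if g in by_id else np.nan
                                     for g in genes]
            df[f"{method}_rank"] = [by_id[g].rank if g in by_id else np.nan
                                    for g in genes]
        df["aggregate_value"] = [s.value for s in self.aggregate]
        df["aggregate_rank"] = [s.rank for s in self.aggregate]
        df["group"] = self.group
        return df.sort_values("aggregate_rank")


def rank_all(ds: CtDataset, cfg: PipelineConfig | None = None,
             methods: Sequence[str] = METHODS) -> StabilityRanking:
    """Run the requested stability methods and aggregate their ranks.

    Replicates are collapsed automatically. A method whose preconditions the
    dataset cannot meet is omitted with a warning and the aggregate is taken
    over the remaining methods.
    """
    cfg = cfg or PipelineConfig()
    ds = collapse_replicates(ds)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown stability methods: {sorted(unknown)}")

    method_scores: dict[str, list[StabilityScore]] = {}
    gn = bk = nf = None
    runners = {
        "deltaCT": lambda: delta_ct_stability(ds),
        "geNorm": lambda: genorm(ds, cfg.efficiency_base),
        "BestKeeper": lambda: bestkeeper(ds),
        "NormFinder": lambda: normfinder_single_group(ds),
    }
    for method in methods:
        try:
            result = runners[method]()
        except ValidationError as exc:
            logger.warning("method %s skipped for group %s: %s",
                           method, ds.group, exc)
            continue
        if method == "geNorm":
            gn = result
            method_scores[method] = result.scores
        elif method == "BestKeeper":
            bk = result
            method_scores[method] = result.scores
        elif method == "NormFinder":
            nf = result
            method_scores[method] = result.scores
        else:
            method_scores[method] = result
    if not method_scores:
        raise ValidationError("no stability method could run on this dataset")

    rank_matrix = np.array(
        [[{s.gene_id: s.rank for s in scores}[g]
          for scores in method_scores.values()]
         for g in ds.gene_ids], dtype=float)
    geo_rank = np.exp(np.log(rank_matrix).mean(axis=1))
    agg_ranks = _tied_ranks(geo_rank)
    aggregate = [StabilityScore(g, "aggregate", float(v), r)
                 for g, v, r in zip(ds.gene_ids, geo_rank, agg_ranks)]
    return StabilityRanking(ds.group, method_scores, aggregate,
                            genorm=gn, bestkeeper=bk, normfinder=nf)


def rank_groups(datasets: Mapping[str, CtDataset],
                cfg: PipelineConfig | None = None,
                methods: Sequence[str] = METHODS) -> dict[str, StabilityRanking]:
    """Rank each priming group (e.g. OP and RP) separately."""
    return {group: rank_all(ds, cfg, methods) for group, ds in datasets.items()}


# ---------------------------------------------------------------------------
# CT summaries
# ---------------------------------------------------------------------------


@dataclass
class CtSummary:
    """Per-(gene, group) mean/SD of CT plus between-group mean differences."""

    per_gene: pd.DataFrame
    group_difference: pd.Series | None = None


def ct_summary(datasets: Sequence[CtDataset]) -> CtSummary:
    """Mean and sample SD of CT per gene and group.

    Statistics pool all samples and replicates within a group. When exactly
    two groups are supplied, the per-gene difference of group means (first
    minus second) is reported alongside.
    """
    rows = []
    for ds in datasets:
        flat = ds.values.reshape(ds.n_genes, -1)
        for gid, row in zip(ds.gene_ids, flat):
            rows.append({"gene_id": gid, "group": ds.group,
                         "mean_ct": float(row.mean()),
                         "sd_ct": float(row.std(ddof=1)) if row.size > 1 else 0.0})
    per_gene = pd.DataFrame(rows)
    diff = None
    if len(datasets) == 2:
        a, b = datasets
        ma = per_gene[per_gene["group"] == a.group].set_index("gene_id")["mean_ct"]
        mb = per_gene[per_gene["group"] == b.group].set_index("gene_id")["mean_ct"]
        shared = [g for g in a.gene_ids if g in mb.index]
        diff = (ma.loc[shared] - mb.loc[shared]).rename(
            f"{a.group}-{b.group}_mean_ct_diff")
    return CtSummary(per_gene, diff)


__all__ = [
    "METHODS", "StabilityScore", "GeNormResult", "BestKeeperResult",
    "NormFinderResult", "StabilityRanking", "CtSummary",
    "delta_ct_stability", "genorm", "genorm_m_values", "bestkeeper",
    "normfinder_single_group", "rank_all", "rank_groups", "ct_summary",
]
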