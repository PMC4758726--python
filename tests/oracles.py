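"""Independent brute-force implementations used as oracles in tests.

Everything here is written from the defining formulas with plain Python
loops and the statistics module, deliberately sharing no code with the
package implementations.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def sample_sd(xs) -> float:
    return statistics.stdev(xs)


def brute_delta_ct(ct: np.ndarray) -> list[float]:
    """Mean over partners of the sample SD of pairwise CT differences."""
    g, n = ct.shape
    out = []
    for i in range(g):
        sds = []
        for j in range(g):
            if j == i:
                continue
            deltas = [ct[i, s] - ct[j, s] for s in range(n)]
            sds.append(sample_sd(deltas))
        out.append(sum(sds) / len(sds))
    return out


def brute_genorm_m(ct: np.ndarray, base: float = 2.0) -> list[float]:
    """Full-set geNorm M via explicit quantities and log2 pairwise ratios."""
    g, n = ct.shape
    q = [[base ** (min(ct[i]) - ct[i, s]) for s in range(n)] for i in range(g)]
    out = []
    for i in range(g):
        sds = []
        for j in range(g):
            if j == i:
                continue
            ratios = [math.log2(q[i][s] / q[j][s]) for s in range(n)]
            sds.append(sample_sd(ratios))
        out.append(sum(sds) / len(sds))
    return out


def brute_bestkeeper(ct: np.ndarray) -> dict:
    """Descriptive stats, geometric-mean index and Pearson r per gene."""
    g, n = ct.shape
    index = [math.prod(ct[i, s] for i in range(g)) ** (1.0 / g)
             for s in range(n)]
    per_gene = []
    for i in range(g):
        row = list(ct[i])
        mean = sum(row) / n
        sd = sample_sd(row)
        gm = math.prod(row) ** (1.0 / n)
        if sd > 0 and sample_sd(index) > 0:
            mi = sum(index) / n
            cov = sum((x - mean) * (y - mi) for x, y in zip(row, index)) / (n - 1)
            r = cov / (sd * sample_sd(index))
        else:
            r = math.nan
        per_gene.append({"mean": mean, "geo_mean": gm, "min": min(row),
                         "max": max(row), "sd": sd,
                         "cv": 100.0 * sd / mean, "r": r})
    return {"index": index, "per_gene": per_gene}


def brute_normfinder_v(ct: np.ndarray) -> list[float]:
    """Per-gene residual variances of the additive model, by explicit loops."""
    g, n = ct.shape
    y = [[-ct[i, s] for s in range(n)] for i in range(g)]
    row_mean = [sum(y[i]) / n for i in range(g)]
    col_mean = [sum(y[i][s] for i in range(g)) / g for s in range(n)]
    grand = sum(row_mean) / g
    v = []
    for i in range(g):
        ss = sum((y[i][s] - row_mean[i] - col_mean[s] + grand) ** 2
                 for s in range(n))
        v.append(ss / (n - 1))
    return v


def normfinder_sigma_sq_by_system(ct: np.ndarray) -> np.ndarray:
    """Solve the g×g expectation system E[v_i] = σ²_i(g−2)/g + Σσ²/g²."""
    v = np.array(brute_normfinder_v(ct))
    g = ct.shape[0]
    a = np.full((g, g), 1.0 / g ** 2)
    a[np.diag_indices(g)] += (g - 2) / g
    return np.linalg.solve(a, v)


def brute_screen(values: np.ndarray, gene_ids: list[str], *,
                 expressed_threshold: float, ratio_limit: float,
                 cv_limit: float, min_rpkm: float, top_n: int,
                 annotation: dict | None = None) -> dict:
    """Apply the screening predicates directly, stage by stage."""
    stats = {}
    for gid, row in zip(gene_ids, values):
        row = list(row)
        mu = sum(row) / len(row)
        sd = sample_sd(row)
        stats[gid] = {
            "min": min(row), "max": max(row),
            "ratio": max(row) / min(row) if min(row) > 0 else math.nan,
            "cv": sd / mu if mu > 0 else 0.0,
        }
    expressed = [g for g in gene_ids if stats[g]["min"] >= expressed_threshold]
    stable = [g for g in expressed
              if not math.isnan(stats[g]["ratio"])
              and stats[g]["ratio"] < ratio_limit
              and stats[g]["cv"] < cv_limit]
    abundant = [g for g in stable if stats[g]["min"] > min_rpkm]
    top = sorted(abundant, key=lambda g: (stats[g]["ratio"], stats[g]["cv"],
                                          g))[:top_n]
    stages = {"expressed": expressed, "stability": stable,
              "abundance": abundant, "top_n": top}
    if annotation is not None:
        final = []
        for g in top:
            ann = annotation.get(g)
            if ann is None:
                continue
            if ann.transcript_count == 1 or (
                    ann.transcript_count == 2 and ann.two_transcripts_overlap):
                final.append(g)
        stages["annotation"] = final
    return stages
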