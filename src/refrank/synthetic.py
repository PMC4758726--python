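"""Synthetic RPKM matrices and CT datasets with known ground truth.

The generator emulates the structure of a stage-wise developmental
expression study: a genes × 9-stages RPKM matrix containing a small set of
designed-stable genes (near-constant expression, CV < 0.3 and max/min ratio
< 2 by construction) embedded among designed-variable genes carrying stage
trends (monotone ramps and maternal-decay shapes) with max/min ratio >= 2,
plus optional designed-target genes. From the matrix it derives qPCR CT
datasets for two priming groups (OP/RP) sharing the expression signal:

    CT_g(s, rep) = intercept − log2(RPKM_g(s)) + δ_group,g + τ_g(s) + η

with a per-gene priming-chemistry offset δ, extra per-stage instability
τ ~ Normal(0, σ_g) for designed-variable genes only, and technical replicate
noise η ~ Normal(0, σ_tech). All noise is Normal on the CT (log2) scale,
matching the multiplicative error structure qPCR assumes. With every noise
term at zero the CT values are the exact closed form, so quantities are
recoverable bit-exactly.

Identical configuration + seed yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (CtDataset, ExpressionMatrix, GeneAnnotation,
                        ValidationError)

#: Stage names used when a 9-stage matrix is generated (cleavage through
#: early larva); other stage counts fall back to generic labels.
DEFAULT_STAGE_LABELS = ("64-cell", "sphere", "50pct-epiboly", "15-somite",
                        "36hpf", "48hpf", "60hpf", "72hpf", "1-week")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    The desk-scale default genome is 2,000 genes (12 designed-stable among
    1,988 designed-variable) over 9 stages with technical triplicates —
    small enough that the full screen runs in seconds; scale up via the
    counts. Expression ranges are log2 RPKM; ``sigma_stable`` is the log2
    expression noise of stable genes (0.05 keeps CV ≈ 0.035, far inside the
    screen limits), ``trend_amplitude_range`` the log2 span of variable-gene
    stage trends (>= 1.5, i.e. max/min ratio >= 2^1.5 ≈ 2.8), and
    ``sigma_ct_variable_range`` the extra CT instability given to variable
    genes in the qPCR layer.
    """

    n_stable: int = 12
    n_variable: int = 1988
    n_target: int = 0
    n_stages: int = 9
    stable_log2_mean_range: tuple[float, float] = (5.6, 9.0)
    variable_log2_mean_range: tuple[float, float] = (-2.0, 10.0)
    target_log2_mean_range: tuple[float, float] = (3.0, 8.0)
    sigma_stable: float = 0.05
    sigma_variable_expr: float = 0.15
    trend_amplitude_range: tuple[float, float] = (1.5, 4.0)
    sigma_ct_variable_range: tuple[float, float] = (0.5, 1.5)
    ct_intercept: float = 34.0
    n_replicates: int = 3
    sigma_tech: float = 0.1
    group_offset_sd: float = 0.5
    groups: tuple[str, ...] = ("OP", "RP")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stable, self.n_variable, self.n_target) < 0:
            raise ValidationError("gene class counts must be >= 0")
        if self.n_stages < 2:
            raise ValidationError("need at least 2 stages")
        if self.n_replicates < 1:
            raise ValidationError("need at least 1 replicate")

    def stage_labels(self) -> list[str]:
        if self.n_stages == len(DEFAULT_STAGE_LABELS):
            return list(DEFAULT_STAGE_LABELS)
        return [f"stage{i + 1}" for i in range(self.n_stages)]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data.

    ``labels`` partitions genes into stable / variable / target;
    ``sigma_ct`` is each gene's extra CT instability σ (log2 cycles; 0 for
    stable and target genes); ``stage_profiles`` the true log2 stage-effect
    profile; ``group_offsets`` the per-group per-gene priming offsets δ.
    """

    labels: dict[str, str]
    sigma_ct: dict[str, float]
    stage_profiles: dict[str, np.ndarray]
    group_offsets: dict[str, dict[str, float]]
    seed: int

    def genes_with_label(self, label: str) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]


def _trend(rng: np.random.Generator, n_stages: int,
           amplitude: float) -> np.ndarray:
    """A mean-centered log2 stage trend: ramp or maternal-decay shape."""
    t = np.linspace(0.0, 1.0, n_stages)
    kind = rng.integers(0, 3)
    if kind == 0:            # monotone ramp
        profile = amplitude * t
    elif kind == 1:          # maternal decay: high early, exponential loss
        profile = amplitude * np.exp(-4.0 * t)
    else:                    # late induction
        profile = amplitude * (1.0 - np.exp(-4.0 * t))
    if rng.random() < 0.5:
        profile = profile[::-1].copy()
    return profile - profile.mean()


def generate_rpkm(cfg: GeneratorConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a genes × stages RPKM matrix plus its ground truth."""
    rng = np.random.default_rng([cfg.seed, 1])
    stages = cfg.stage_labels()
    gene_ids: list[str] = []
    labels: dict[str, str] = {}
    sigma_ct: dict[str, float] = {}
    profiles: dict[str, np.ndarray] = {}
    rows: list[np.ndarray] = []

    for i in range(cfg.n_stable):
        gid = f"stab{i + 1:04d}"
        mu = rng.uniform(*cfg.stable_log2_mean_range)
        eps = rng.normal(0.0, cfg.sigma_stable, cfg.n_stages)
        gene_ids.append(gid)
        labels[gid] = "stable"
        sigma_ct[gid] = 0.0
        profiles[gid] = np.zeros(cfg.n_stages)
        rows.append(2.0 ** (mu + eps))

    for i in range(cfg.n_variable):
        gid = f"var{i + 1:05d}"
        mu = rng.uniform(*cfg.variable_log2_mean_range)
        amp = rng.uniform(*cfg.trend_amplitude_range)
        profile = _trend(rng, cfg.n_stages, amp)
        eps = rng.normal(0.0, cfg.sigma_variable_expr, cfg.n_stages)
        gene_ids.append(gid)
        labels[gid] = "variable"
        sigma_ct[gid] = float(rng.uniform(*cfg.sigma_ct_variable_range))
        profiles[gid] = profile
        rows.append(2.0 ** (mu + profile + eps))

    for i in range(cfg.n_target):
        gid = f"tgt{i + 1:02d}"
        mu = rng.uniform(*cfg.target_log2_mean_range)
        amp = rng.uniform(*cfg.trend_amplitude_range)
        profile = _trend(rng, cfg.n_stages, amp)
        gene_ids.append(gid)
        labels[gid] = "target"
        sigma_ct[gid] = 0.0
        profiles[gid] = profile
        rows.append(2.0 ** (mu + profile))

    offsets = {group: {g: float(rng.normal(0.0, cfg.group_offset_sd))
                       for g in gene_ids} for group in cfg.groups}
    data = pd.DataFrame(np.vstack(rows) if rows else
                        np.empty((0, cfg.n_stages)),
                        index=gene_ids, columns=stages)
    return (ExpressionMatrix(data),
            SyntheticTruth(labels, sigma_ct, profiles, offsets, cfg.seed))


def generate_ct(m: ExpressionMatrix, truth: SyntheticTruth,
                cfg: GeneratorConfig,
                genes: Sequence[str] | None = None) -> dict[str, CtDataset]:
    """Derive one CT dataset per priming group from an RPKM matrix.

    ``genes`` restricts the qPCR panel (default: every gene in the matrix).
    Raises on non-positive RPKM, naming the gene and stage.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    panel = list(m.gene_ids) if genes is None else list(genes)
    sub = m.subset(panel)
    rpkm = sub.values
    if (rpkm <= 0).any():
        gi, si = np.argwhere(rpkm <= 0)[0]
        raise ValidationError(
            f"non-positive RPKM for gene {panel[gi]!r} at stage "
            f"{sub.stage_labels[si]!r}")

    base_ct = cfg.ct_intercept - np.log2(rpkm)        # (g, s)
    g, s = base_ct.shape
    out: dict[str, CtDataset] = {}
    for group in cfg.groups:
        delta = np.array([truth.group_offsets[group].get(gid, 0.0)
                          for gid in panel])[:, None]
        sigmas = np.array([truth.sigma_ct.get(gid, 0.0) for gid in panel])
        tau = rng.normal(0.0, 1.0, (g, s)) * sigmas[:, None]
        eta = (rng.normal(0.0, cfg.sigma_tech, (g, s, cfg.n_replicates))
               if cfg.sigma_tech > 0 else np.zeros((g, s, cfg.n_replicates)))
        values = (base_ct + delta + tau)[:, :, None] + eta
        out[group] = CtDataset(panel, list(sub.stage_labels), values,
                               group=group)
    return out


def generate_annotation(truth: SyntheticTruth,
                        cfg: GeneratorConfig) -> dict[str, GeneAnnotation]:
    """Transcript-structure annotation consistent with the ground truth.

    Designed-stable and target genes get a single transcript (always
    primer-friendly); variable genes draw 1–7 transcripts with a random
    overlap flag for two-transcript cases.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    out: dict[str, GeneAnnotation] = {}
    for gid, label in truth.labels.items():
        if label in ("stable", "target"):
            out[gid] = GeneAnnotation(gid, 1)
        else:
            count = int(rng.integers(1, 8))
            overlap = bool(rng.random() < 0.5) if count == 2 else False
            out[gid] = GeneAnnotation(gid, count, overlap)
    return out


def generate_dilution(true_efficiency: float, intercept: float = 20.0,
                      dilutions: Sequence[float] = (1, 2, 4, 8, 16),
                      noise_sd: float = 0.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A standard-curve dilution series with known per-cycle efficiency E.

    CT at dilution d is intercept + log_{1+E}(d) (+ noise); for E = 1 the
    noiseless series rises exactly one cycle per twofold dilution.
    """
    if not 0.0 < true_efficiency <= 1.2:
        raise ValidationError("true_efficiency must be in (0, 1.2]")
    d = np.asarray(dilutions, dtype=float)
    if (d <= 0).any():
        raise ValidationError("dilution factors must be > 0")
    cts = intercept + np.log(d) / np.log(1.0 + true_efficiency)
    if noise_sd > 0:
        cts = cts + np.random.default_rng([seed, 4]).normal(0.0, noise_sd,
                                                            d.size)
    return d, cts


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist ground-truth labels, σ and group offsets as TSV."""
    rows = []
    for gid, label in truth.labels.items():
        row = {"gene_id": gid, "label": label,
               "sigma_ct": truth.sigma_ct[gid]}
        for group, offs in truth.group_offsets.items():
            row[f"offset_{group}"] = offs[gid]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "DEFAULT_STAGE_LABELS", "GeneratorConfig", "SyntheticTruth",
    "generate_rpkm", "generate_ct", "generate_annotation",
    "generate_dilution", "write_truth",
]
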