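"""Comparative-CT normalization, RNA-seq concordance and primer-efficiency QC.

Relative expression of a target gene is computed by the comparative-CT
(ΔΔCT) method under the equal-efficiency assumption: per sample,
rel = 2^(−(CT_target − CT_ref)), where CT_ref is the arithmetic mean of the
chosen reference genes' CTs — equivalently, the log2 of the geometric mean
of their quantities, the conventional way to combine multiple references.
An optional calibrator sample rescales the profile so the calibrator equals 1.

Concordance with an RNA-seq profile is scored as the Pearson correlation
between log2 relative expression and log2 RPKM over matched stages, which is
invariant to multiplicative rescaling of either profile.

Primer efficiency is estimated from a dilution series by least squares on
CT = a + b·log2(dilution); the per-reaction efficiency is E = 2^(1/b) − 1,
and the series passes QC when the fit's R² exceeds 0.99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .datamodel import (CtDataset, ExpressionMatrix, ValidationError,
                        collapse_replicates)


@dataclass
class NormalizedProfile:
    """Per-sample relative expression of one target on the 2^(−ΔCT) scale."""

    target: str
    references: tuple[str, ...]
    sample_labels: list[str]
    values: np.ndarray
    calibrator: str | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sample_labels, self.values.astype(float)))


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson r between a normalized qPCR profile and an RPKM profile.

    ``r`` is NaN with an explanatory ``note`` when either side has zero
    variance on the chosen scale.
    """

    target: str
    references: tuple[str, ...]
    r: float
    n_stages: int
    transform: str
    note: str = ""


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit for one primer pair.

    ``slope`` is in CT per log2 dilution step; ``efficiency`` is the
    fractional per-cycle gain (1.0 = perfect doubling) and is NaN when the
    slope is non-positive (CT must rise with dilution).
    """

    gene_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    passed: bool
    dilutions: tuple[float, ...]
    cts: tuple[float, ...]


def comparative_ct(targets: CtDataset, refs: CtDataset,
                   ref_set: Sequence[str], calibrator: str | None = None,
                   efficiency_base: float = 2.0) -> list[NormalizedProfile]:
    """Normalize every target gene against the mean CT of ``ref_set``.

    Targets and references must share identical sample labels; a mismatch is
    an error listing the symmetric difference. Replicates are collapsed to
    means first.
    """
    if not ref_set:
        raise ValidationError("ref_set must contain at least one gene")
    targets = collapse_replicates(targets)
    refs = collapse_replicates(refs)
    if list(targets.sample_labels) != list(refs.sample_labels):
        odd = sorted(set(targets.sample_labels) ^ set(refs.sample_labels))
        raise ValidationError(f"sample label mismatch: {odd}")
    missing = [g for g in ref_set if g not in refs.gene_ids]
    if missing:
        raise ValidationError(f"reference genes absent from dataset: {missing}")

    ref_ct = refs.ct_matrix()[[refs.gene_ids.index(g) for g in ref_set]]
    mean_ref = ref_ct.mean(axis=0)
    out = []
    for gi, gid in enumerate(targets.gene_ids):
        delta = targets.ct_matrix()[gi] - mean_ref
        rel = efficiency_base ** (-delta)
        if calibrator is not None:
            if calibrator not in targets.sample_labels:
                raise ValidationError(f"calibrator sample {calibrator!r} unknown")
            rel = rel / rel[targets.sample_labels.index(calibrator)]
        out.append(NormalizedProfile(gid, tuple(ref_set),
                                     list(targets.sample_labels), rel,
                                     calibrator))
    return out


def concordance(profile: NormalizedProfile, m: ExpressionMatrix,
                transform: str = "log2") -> ConcordanceResult:
    """Pearson r between a normalized profile and the target's RPKM profile.

    Stages are matched by label (profile order); at least 3 matched stages
    are required. ``transform`` is "log2" (default; scale-invariant) or
    "linear".
    """
    if transform not in ("log2", "linear"):
        raise ValidationError(f"unknown transform {transform!r}")
    if profile.target not in m.data.index:
        raise ValidationError(f"target {profile.target!r} not in RPKM matrix")
    matched = [s for s in profile.sample_labels if s in m.data.columns]
    if len(matched) < 3:
        raise ValidationError(
            f"need >= 3 matched stages, found {len(matched)}")
    q = np.array([profile.as_dict()[s] for s in matched], dtype=float)
    rpkm = m.data.loc[profile.target, matched].to_numpy(dtype=float)
    if transform == "log2":
        if (q <= 0).any() or (rpkm <= 0).any():
            raise ValidationError("log2 concordance needs positive values")
        q, rpkm = np.log2(q), np.log2(rpkm)
    if np.std(q) == 0 or np.std(rpkm) == 0:
        return ConcordanceResult(profile.target, profile.references,
                                 math.nan, len(matched), transform,
                                 note="zero variance on one side")
    r = float(sstats.pearsonr(q, rpkm).statistic)
    return ConcordanceResult(profile.target, profile.references, r,
                             len(matched), transform)


def fit_efficiency(dilutions: Sequence[float], cts: Sequence[float],
                   gene_id: str = "", r2_threshold: float = 0.99) -> EfficiencyFit:
    """Fit CT = a + b·log2(dilution) and derive the primer efficiency.

    A perfect twofold series (CT rising one cycle per dilution step) gives
    b = 1 and E = 100%. The QC pass flag requires R² > ``r2_threshold`` and
    a positive slope.
    """
    dilutions = np.asarray(dilutions, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if dilutions.size < 3:
        raise ValidationError("need >= 3 dilution points")
    if (dilutions <= 0).any():
        raise ValidationError("dilution factors must be > 0")
    fit = sstats.linregress(np.log2(dilutions), cts)
    b, a = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    eff = (2.0 ** (1.0 / b) - 1.0) if b > 0 else math.nan
    passed = bool(b > 0 and r2 > r2_threshold)
    return EfficiencyFit(gene_id, b, a, eff, r2, passed,
                         tuple(dilutions), tuple(cts))


__all__ = [
    "NormalizedProfile", "ConcordanceResult", "EfficiencyFit",
    "comparative_ct", "concordance", "fit_efficiency",
]
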