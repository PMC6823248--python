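"""Two-group differential expression with empirical-Bayes variance moderation.

The procedure mirrors the classical moderated-t workflow for a two-group
contrast: per-gene log2 fold change and pooled residual variance, a scaled
inverse-chi-square prior on the gene variances fitted by moment matching on
``log s^2`` (digamma/trigamma), shrunken variances
``s~^2 = (d0 s0^2 + d s^2)/(d0 + d)``, a t statistic on ``d0 + d`` degrees
of freedom, and Benjamini–Hochberg FDR.  The shrinkage is global (a single
(d0, s0^2) pair), not intensity-dependent; see docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, ndtr, polygamma
from statsmodels.stats.multitest import multipletests

from .core import (
    SCALE_LOG2,
    SCALE_RAW,
    ExpressionMatrix,
    StudyDesign,
    ValidationError,
)

logger = logging.getLogger("immunosig")

MIN_GENES_FOR_PRIOR = 50


def normalize_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million log2 transform: ``log2(x / libsize * 1e6 + 0.5)``.

    Already-log2 input passes through unchanged with a logged notice.
    An all-zero sample has no library size and is an error.
    """
    if matrix.scale == SCALE_LOG2:
        logger.info("input already log2; normalize_log2 is a pass-through")
        return matrix
    lib = matrix.data.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample column(s): {zero}")
    cpm = matrix.data / lib * 1e6
    return ExpressionMatrix(np.log2(cpm + 0.5), SCALE_LOG2)


def fit_two_group(
    matrix: ExpressionMatrix, design: StudyDesign
) -> tuple[pd.DataFrame, int, int, int]:
    """Per-gene logFC and pooled variance for a two-group contrast.

    Returns ``(frame, d, n_ref, n_trt)`` where frame has columns
    ``logFC`` (= mean(treatment) - mean(reference)) and ``s2`` (pooled
    within-group variance on ``d = n1 + n2 - 2`` degrees of freedom).
    """
    if matrix.scale != SCALE_LOG2:
        raise ValidationError("fit_two_group expects log2 input; run normalize_log2")
    design.check_covers(matrix)
    ref = [s for s in matrix.sample_ids if design.assignments[s] == design.reference]
    trt = [s for s in matrix.sample_ids if design.assignments[s] == design.treatment]
    n1, n2 = len(ref), len(trt)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got {design.reference}:{n1}, "
            f"{design.treatment}:{n2})"
        )
    x1 = matrix.data[ref].to_numpy()
    x2 = matrix.data[trt].to_numpy()
    logfc = x2.mean(axis=1) - x1.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = (ss1 + ss2) / d
    frame = pd.DataFrame({"logFC": logfc, "s2": s2}, index=matrix.data.index)
    return frame, d, n1, n2


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on gene variances: d0 may be inf."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("prior degrees of freedom must be >= 0")
        if not (self.s02 > 0):
            raise ValidationError("prior variance must be > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (x > 0); monotone bisection/brentq."""
    if x <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    f = lambda y: polygamma(1, y) - x
    if f(lo) < 0:  # x larger than trigamma can reach near 0
        return lo
    if f(hi) > 0:  # x tiny; trigamma(y) ~ 1/y
        return 1.0 / x
    from scipy.optimize import brentq

    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_prior(s2: np.ndarray, d: int) -> VariancePrior:
    """Moment-matching fit of (d0, s0^2) from the gene variances.

    With ``e_g = log(s2_g) - psi(d/2) + log(d/2)``, the model implies
    ``var(e) = psi'(d/2) + psi'(d0/2)`` and
    ``mean(e) = log(s0^2) - psi(d0/2) + log(d0/2)``; d0 is recovered by
    inverting the trigamma function (d0 = inf when the excess spread is
    non-positive).
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    positive = s2 > 0
    n_zero = int((~positive).sum())
    if n_zero:
        if n_zero > 0.1 * s2.size:
            logger.warning(
                "%d/%d genes have zero variance; prior fitted on positive-"
                "variance genes only", n_zero, s2.size,
            )
    s2p = s2[positive]
    if s2p.size < MIN_GENES_FOR_PRIOR:
        raise ValidationError(
            f"need >= {MIN_GENES_FOR_PRIOR} genes with positive variance to fit "
            f"the prior (got {s2p.size}); simulate or supply more genes"
        )
    e = np.log(s2p) - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    rhs = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if rhs <= 0:
        # no excess spread beyond chi-square sampling noise: the variances
        # share one value, estimated unbiasedly by their mean
        return VariancePrior(math.inf, float(s2p.mean()))
    d0 = 2.0 * _trigamma_inverse(rhs)
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0, s02)


def moderate(
    logfc: np.ndarray,
    s2: np.ndarray,
    d: int,
    prior: VariancePrior,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t and two-sided p.

    ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)``;
    ``t = logFC / (s~ sqrt(1/n1 + 1/n2))`` on ``d0 + d`` df (normal when
    d0 = inf; ordinary pooled t when d0 = 0).  Returns (t, p, s2_tilde).
    A zero shrunken variance with nonzero logFC yields t = +/-inf, p = 0.
    """
    logfc = np.asarray(logfc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        s2t = np.full_like(s2, prior.s02)
        df = math.inf
    else:
        s2t = (prior.d0 * prior.s02 + d * s2) / (prior.d0 + d)
        df = prior.d0 + d
    se = np.sqrt(s2t * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    if math.isinf(df):
        p = 2.0 * ndtr(-np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (logfc == 0), 1.0, p)
    return t, p, s2t


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    fdr_threshold: float = 0.05,
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Full DE result: gene, logFC, s2, s2_tilde, t, p, q, direction.

    ``direction`` is sign(logFC) for genes with q < fdr_threshold, else 0.
    """
    if not (0 < fdr_threshold < 1):
        raise ValidationError("fdr_threshold must be in (0, 1)")
    frame, d, n1, n2 = fit_two_group(matrix, design)
    if prior is None:
        prior = estimate_prior(frame["s2"].to_numpy(), d)
    t, p, s2t = moderate(
        frame["logFC"].to_numpy(), frame["s2"].to_numpy(), d, prior, n1, n2
    )
    q = bh_fdr(p)
    direction = np.where(q < fdr_threshold, np.sign(frame["logFC"].to_numpy()), 0.0)
    out = pd.DataFrame(
        {
            "gene": frame.index,
            "logFC": frame["logFC"].to_numpy(),
            "s2": frame["s2"].to_numpy(),
            "s2_tilde": s2t,
            "t": t,
            "p": p,
            "q": q,
            "direction": direction.astype(int),
        }
    ).reset_index(drop=True)
    out.attrs["prior"] = prior
    out.attrs["df_residual"] = d
    return out


def call_de(table: pd.DataFrame, fdr_threshold: float) -> tuple[list[str], list[str]]:
    """Split significant genes (q < threshold) by logFC sign, sorted by p."""
    if not (0 < fdr_threshold < 1):
        raise ValidationError("fdr_threshold must be in (0, 1)")
    sig = table[table["q"] < fdr_threshold].sort_values("p", kind="stable")
    increased = sig.loc[sig["logFC"] > 0, "gene"].tolist()
    decreased = sig.loc[sig["logFC"] < 0, "gene"].tolist()
    return increased, decreased
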