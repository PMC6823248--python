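"""Single-sample gene-module enrichment scores (GSVA-style KS random walk).

For each gene a kernel-smoothed cumulative density of its expression is
estimated across samples; within each sample genes are ranked by that
statistic and a weighted Kolmogorov–Smirnov-like random walk over the
ranking yields, per gene set, the largest positive (ES+) and negative (ES-)
deviations from zero.  A negative score means the set is expressed lower
in that sample than in samples with positive scores.

Conventions (all configurable):

* Gaussian kernel with per-gene bandwidth ``h_i = s_i / 4`` (sample sd).
* Rank weight ``rho = |p/2 - r|`` raised to ``tau`` (default 1).
* Reported ES: ``signed_sum`` = ES+ + ES- (default) or ``max_abs`` =
  the extremum of larger magnitude, sign preserved.
* Ties in the gene-level statistic are broken by input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import (
    ExpressionMatrix,
    GeneSetModule,
    ValidationError,
    intersect_module,
)

logger = logging.getLogger("immunosig")

ES_SIGNED_SUM = "signed_sum"
ES_MAX_ABS = "max_abs"
_CONVENTIONS = (ES_SIGNED_SUM, ES_MAX_ABS)


def kernel_cdf_stats(values: np.ndarray) -> np.ndarray:
    """Gene-level statistic z_ij: kernel-estimated CDF of gene i at sample j.

    ``z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i)`` with Gaussian CDF Phi and
    bandwidth ``h_i = s_i/4`` (sd across samples, ddof=1).  A constant gene
    has no distribution to place a sample in; it gets z = 0.5 everywhere.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("kernel CDF needs a 2-D matrix with >= 2 samples")
    s = x.std(axis=1, ddof=1)
    h = s / 4.0
    z = np.full_like(x, 0.5)
    active = h > 0
    if active.any():
        xa = x[active]
        diffs = (xa[:, :, None] - xa[:, None, :]) / h[active, None, None]
        z[active] = ndtr(diffs).mean(axis=2)
    return z


def rank_stats(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ranks (1 = largest z; ties stable by row order) and weights.

    Returns ``(ranks, rho)`` where ``rho = |p/2 - rank|`` is the centered
    rank weight entering the walk.
    """
    z = np.asarray(z, dtype=float)
    p = z.shape[0]
    # stable argsort of -z gives descending order with ties by row order
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    positions = np.arange(1, p + 1)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(positions, order.shape), axis=0)
    rho = np.abs(p / 2.0 - ranks)
    return ranks, rho


def walk_es(
    ranks: np.ndarray, member_mask: np.ndarray, tau: float = 1.0
) -> tuple[float, float, float]:
    """Weighted KS-like random walk over one sample's ranking.

    ``ranks`` holds each gene's rank (1..p) in this sample; ``member_mask``
    flags the module's genes.  Walking genes in rank order, the statistic is

        nu(l) = sum_{rank<=l, in set} rho^tau / sum_{in set} rho^tau
              - #{rank<=l, not in set} / (p - m)

    Returns ``(es_pos, es_neg, es_signed_sum)`` with
    ``es_pos = max(nu, 0)`` and ``es_neg = min(nu, 0)``.
    """
    ranks = np.asarray(ranks)
    member = np.asarray(member_mask, dtype=bool)
    p = ranks.shape[0]
    m = int(member.sum())
    if m == 0:
        raise ValidationError("module has no genes in the matrix")
    if m == p:
        raise ValidationError("module covers every gene; walk undefined")
    order = np.argsort(ranks, kind="stable")
    in_set = member[order]
    rho = np.abs(p / 2.0 - np.arange(1, p + 1))
    w = rho ** tau
    denom = float(w[in_set].sum())
    if denom == 0.0:
        # all member weights vanish (member sits exactly at rank p/2);
        # fall back to unweighted steps so the walk stays defined
        w = np.ones(p)
        denom = float(m)
    inc = np.where(in_set, w / denom, 0.0)
    dec = np.where(in_set, 0.0, 1.0 / (p - m))
    nu = np.cumsum(inc - dec)
    es_pos = max(float(nu.max()), 0.0)
    es_neg = min(float(nu.min()), 0.0)
    return es_pos, es_neg, es_pos + es_neg


@dataclass
class ModuleScores:
    """Per (module, sample) enrichment scores."""

    es: pd.DataFrame       # module x sample, reported convention
    es_pos: pd.DataFrame   # largest positive deviation
    es_neg: pd.DataFrame   # largest negative deviation
    tau: float
    convention: str


def score_matrix(
    matrix: ExpressionMatrix,
    modules: Sequence[GeneSetModule],
    tau: float = 1.0,
    convention: str = ES_SIGNED_SUM,
) -> ModuleScores:
    """Score every module in every sample; modules absent from the matrix
    are skipped with a warning."""
    if convention not in _CONVENTIONS:
        raise ValidationError(f"es convention must be one of {_CONVENTIONS}")
    z = kernel_cdf_stats(matrix.values)
    ranks, _ = rank_stats(z)
    positions = matrix.gene_positions()
    p = matrix.n_genes

    kept: list[str] = []
    pos_rows, neg_rows = [], []
    for module in modules:
        idx = intersect_module(module, positions)
        if not idx:
            logger.warning("module %r shares no genes with the matrix; skipped",
                           module.name)
            continue
        if len(idx) == p:
            raise ValidationError(
                f"module {module.name!r} covers every gene; walk undefined"
            )
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        pos_j, neg_j = [], []
        for j in range(matrix.n_samples):
            ep, en, _ = walk_es(ranks[:, j], mask, tau)
            pos_j.append(ep)
            neg_j.append(en)
        kept.append(module.name)
        pos_rows.append(pos_j)
        neg_rows.append(neg_j)

    cols = matrix.sample_ids
    es_pos = pd.DataFrame(pos_rows, index=kept, columns=cols, dtype=float)
    es_neg = pd.DataFrame(neg_rows, index=kept, columns=cols, dtype=float)
    if convention == ES_SIGNED_SUM:
        es = es_pos + es_neg
    else:
        # extremum of larger magnitude; exact-magnitude ties go positive
        take_pos = es_pos.to_numpy() >= -es_neg.to_numpy() - 1e-12
        es = es_pos.where(take_pos, es_neg)
    es.index.name = es_pos.index.name = es_neg.index.name = "module"
    return ModuleScores(es, es_pos, es_neg, tau, convention)
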