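"""scikit-learn style estimators wrapping the scoring and DE stages.

`GSVAScorer` is a transformer (samples x genes -> samples x modules) and
`ModeratedTTest` a fit-only estimator exposing the per-gene DE statistics
as fitted attributes; both follow the get_params/set_params contract so
they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import diffexpr, gsva
from .core import (
    SCALE_LOG2,
    SCALE_RAW,
    ExpressionMatrix,
    GeneSetModule,
    StudyDesign,
    ValidationError,
)


def _as_modules(gene_sets) -> list[GeneSetModule]:
    if isinstance(gene_sets, Mapping):
        return [GeneSetModule(str(k), tuple(v)) for k, v in gene_sets.items()]
    return list(gene_sets)


def _to_expression(X, gene_names, scale) -> ExpressionMatrix:
    """samples x genes input -> internal genes x samples container."""
    if isinstance(X, pd.DataFrame):
        frame = X.T.copy()
    else:
        X = np.asarray(X)
        if gene_names is None:
            raise ValidationError(
                "array input requires gene_names (or pass a DataFrame with "
                "gene columns)"
            )
        if len(gene_names) != X.shape[1]:
            raise ValidationError("gene_names length must match n_features")
        frame = pd.DataFrame(
            X.T, index=list(gene_names),
            columns=[f"s{i + 1}" for i in range(X.shape[0])],
        )
    return ExpressionMatrix(frame, scale)


class GSVAScorer(TransformerMixin, BaseEstimator):
    """Transform expression profiles into per-sample gene-module scores.

    Parameters
    ----------
    gene_sets : mapping name -> genes, or sequence of GeneSetModule
    tau : rank-weight exponent of the random walk (0 = unweighted KS).
    es_convention : 'signed_sum' (ES+ + ES-) or 'max_abs'.
    input_scale : 'log2' (default) or 'raw_counts'; raw counts are CPM
        log2-normalized before scoring.
    gene_names : feature names for plain-array input.

    The kernel CDF is estimated on the cohort passed to ``transform``, so
    scores are relative within that cohort (as in the underlying method).
    """

    def __init__(self, gene_sets=(), tau: float = 1.0,
                 es_convention: str = gsva.ES_SIGNED_SUM,
                 input_scale: str = SCALE_LOG2, gene_names=None):
        self.gene_sets = gene_sets
        self.tau = tau
        self.es_convention = es_convention
        self.input_scale = input_scale
        self.gene_names = gene_names

    def fit(self, X, y=None):
        modules = _as_modules(self.gene_sets)
        if not modules:
            raise ValidationError("GSVAScorer requires at least one gene set")
        self.modules_ = modules
        self.n_features_in_ = (
            X.shape[1] if hasattr(X, "shape") else len(X[0])
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "modules_")
        em = _to_expression(X, self.gene_names, self.input_scale)
        if em.scale == SCALE_RAW:
            em = diffexpr.normalize_log2(em)
        scores = gsva.score_matrix(
            em, self.modules_, tau=self.tau, convention=self.es_convention
        )
        out = scores.es.T  # samples x modules
        if isinstance(X, pd.DataFrame):
            out.index = X.index
        self.last_scores_ = scores
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "modules_")
        return np.asarray([m.name for m in self.modules_], dtype=object)


class ModeratedTTest(BaseEstimator):
    """Two-group moderated-t differential expression as an estimator.

    ``fit(X, y)`` takes samples x genes expression and a two-level group
    label vector; fitted attributes carry the per-gene statistics
    (``logfc_``, ``s2_``, ``s2_tilde_``, ``t_``, ``p_``, ``q_``,
    ``direction_``) and the fitted variance prior (``prior_d0_``,
    ``prior_s02_``).  ``results_`` is the assembled DE table.
    """

    def __init__(self, fdr_threshold: float = 0.05, reference: str = "",
                 input_scale: str = SCALE_LOG2, gene_names=None):
        self.fdr_threshold = fdr_threshold
        self.reference = reference
        self.input_scale = input_scale
        self.gene_names = gene_names

    def fit(self, X, y):
        em = _to_expression(X, self.gene_names, self.input_scale)
        if em.scale == SCALE_RAW:
            em = diffexpr.normalize_log2(em)
        y = np.asarray(y)
        if y.shape[0] != em.n_samples:
            raise ValidationError("y length must match the number of samples")
        design = StudyDesign.from_mapping(
            dict(zip(em.sample_ids, map(str, y))), reference=self.reference
        )
        table = diffexpr.de_table(em, design, self.fdr_threshold)
        self.results_ = table
        self.gene_names_ = table["gene"].to_numpy()
        self.logfc_ = table["logFC"].to_numpy()
        self.s2_ = table["s2"].to_numpy()
        self.s2_tilde_ = table["s2_tilde"].to_numpy()
        self.t_ = table["t"].to_numpy()
        self.p_ = table["p"].to_numpy()
        self.q_ = table["q"].to_numpy()
        self.direction_ = table["direction"].to_numpy()
        prior = table.attrs["prior"]
        self.prior_d0_ = prior.d0
        self.prior_s02_ = prior.s02
        self.df_residual_ = table.attrs["df_residual"]
        self.n_features_in_ = len(self.gene_names_)
        return self

    def significant_genes(self) -> tuple[list[str], list[str]]:
        """(increased, decreased) gene lists at the configured threshold."""
        check_is_fitted(self, "results_")
        return diffexpr.call_de(self.results_, self.fdr_threshold)
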