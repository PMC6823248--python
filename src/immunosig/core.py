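"""Domain containers shared across the pipeline.

The pipeline moves three kinds of objects between stages: a gene x sample
expression matrix (raw counts or log2 values), a two-group study design, and
gene annotations (gene-set modules, one-category-per-gene registries).  All
gene matching throughout the package goes through :func:`harmonize_symbol`
(trim + upper-case) so that mouse Title-case symbols (``Bcl6``) and human
upper-case symbols (``BCL6``) co-match; original casing is preserved for
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("immunosig")

SCALE_RAW = "raw_counts"
SCALE_LOG2 = "log2"
_SCALES = (SCALE_RAW, SCALE_LOG2)


def harmonize_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol used for all matching: trim + uppercase."""
    return str(symbol).strip().upper()


def harmonize_symbols(symbols: Iterable[str]) -> list[str]:
    return [harmonize_symbol(s) for s in symbols]


class ImmunosigError(Exception):
    """Base class for package errors."""


class FormatError(ImmunosigError):
    """Malformed input file."""


class ValidationError(ImmunosigError):
    """Invalid in-memory object or configuration."""


@dataclass(frozen=True)
class GeneSetModule:
    """A named gene set (one GMT record) used for single-sample scoring."""

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene-set module requires a non-empty name")
        if len(self.genes) == 0:
            raise ValidationError(f"module {self.name!r} has no genes")
        harmonized = harmonize_symbols(self.genes)
        if len(set(harmonized)) != len(harmonized):
            raise ValidationError(f"module {self.name!r} contains duplicate genes")

    @property
    def harmonized_genes(self) -> tuple[str, ...]:
        return tuple(harmonize_symbols(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of raw counts or log2 expression values.

    ``data`` is indexed by gene symbol (rows) and sample id (columns).
    Raw counts must be non-negative and integral; both id axes must be
    unique after whitespace trimming.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        df = self.data
        df.index = pd.Index([str(g).strip() for g in df.index], name="gene")
        df.columns = pd.Index([str(s).strip() for s in df.columns], name="sample")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if self.scale == SCALE_RAW:
            if (values < 0).any():
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("raw counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def harmonized_genes(self) -> list[str]:
        return harmonize_symbols(self.data.index)

    def gene_positions(self) -> dict[str, int]:
        """Map harmonized symbol -> row position (first occurrence on collision)."""
        positions: dict[str, int] = {}
        collisions = []
        for i, g in enumerate(self.harmonized_genes()):
            if g in positions:
                collisions.append(g)
            else:
                positions[g] = i
        if collisions:
            logger.warning(
                "%d gene symbols collide after case-folding; first occurrence used: %s",
                len(collisions), collisions[:5],
            )
        return positions


@dataclass
class StudyDesign:
    """Two-group sample assignment; ``reference`` is the baseline of the contrast.

    Fold changes downstream are ``mean(treatment) - mean(reference)``.
    """

    assignments: pd.Series  # sample id -> group label
    reference: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        s = self.assignments
        s.index = pd.Index([str(x).strip() for x in s.index], name="sample")
        if s.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        groups = list(dict.fromkeys(s.astype(str)))
        if len(groups) != 2:
            raise ValidationError(f"design must have exactly two groups, got {groups}")
        if not self.reference:
            self.reference = sorted(groups)[0]
            logger.info("design reference group not given; using %r", self.reference)
        if self.reference not in groups:
            raise ValidationError(f"reference group {self.reference!r} not in design")
        if not self.treatment:
            self.treatment = next(g for g in groups if g != self.reference)
        if self.treatment not in groups or self.treatment == self.reference:
            raise ValidationError("treatment group invalid")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str], reference: str = "",
                     treatment: str = "") -> "StudyDesign":
        return cls(pd.Series(dict(mapping), dtype=str), reference, treatment)

    @property
    def sample_ids(self) -> list[str]:
        return self.assignments.index.tolist()

    def samples_in(self, group: str) -> list[str]:
        return self.assignments.index[self.assignments == group].tolist()

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing[:5]}")


@dataclass
class CategoryRegistry:
    """One-category-per-gene mapping with a closed category vocabulary.

    Used both for hematopoietic cell-type registries (I-Scope style) and
    for functional-category registries (BIG-C / GO-BP style); a gene may
    appear only once, and every mapped category must be in the vocabulary.
    """

    table: pd.DataFrame  # columns: gene, category (original casing)
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.table.columns[:2]) != ["gene", "category"]:
            self.table = self.table.rename(
                columns=dict(zip(self.table.columns[:2], ["gene", "category"]))
            )
        genes = harmonize_symbols(self.table["gene"])
        if len(set(genes)) != len(genes):
            dupes = pd.Index(genes)[pd.Index(genes).duplicated()].unique().tolist()
            raise ValidationError(
                f"registry maps a gene to more than one category: {dupes[:5]}"
            )
        cats = [str(c).strip() for c in self.table["category"]]
        if not self.vocabulary:
            self.vocabulary = tuple(dict.fromkeys(cats))
        unknown = sorted(set(cats) - set(self.vocabulary))
        if unknown:
            raise ValidationError(f"categories outside vocabulary: {unknown[:5]}")
        self._mapping = dict(zip(genes, cats))

    @property
    def mapping(self) -> dict[str, str]:
        """Harmonized gene symbol -> category."""
        return self._mapping

    def category_of(self, gene: str) -> str | None:
        return self._mapping.get(harmonize_symbol(gene))

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in self._mapping.items() if c == category]

    def __len__(self) -> int:
        return len(self._mapping)


def intersect_module(module: GeneSetModule, positions: Mapping[str, int]) -> list[int]:
    """Row positions of a module's genes in a matrix (harmonized match)."""
    return [positions[g] for g in module.harmonized_genes if g in positions]
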