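"""Readers and writers for the pipeline's plain-text formats.

Formats: expression TSV/CSV (first column gene symbols, header row sample
ids), design TSV (sample, group), GMT gene sets, registry CSV
(gene, category), pathway CSV (pathway, gene, expected_direction).
All output tables are tab-separated with floats at 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    SCALE_LOG2,
    SCALE_RAW,
    CategoryRegistry,
    ExpressionMatrix,
    FormatError,
    GeneSetModule,
    StudyDesign,
    harmonize_symbol,
)
from .pathways import PathwayDefinition

logger = logging.getLogger("immunosig")

FLOAT_FORMAT = "%.6g"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a gene x sample matrix; see module docstring for layout.

    Duplicate gene rows are summed for raw counts and rejected for log2
    input (summing log2 values is meaningless).  A non-numeric cell raises
    a :class:`FormatError` naming the offending gene and sample.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = [s.strip() for s in header[1:]]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"duplicate sample id in header: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric value for gene {gene!r} in sample {col!r}"
            )
        numeric[col] = converted

    if numeric.index.has_duplicates:
        if scale == SCALE_RAW:
            dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
            logger.info("summing duplicate gene rows: %s", dupes[:5])
            numeric = numeric.groupby(level=0, sort=False).sum()
        else:
            dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
            raise FormatError(
                f"duplicate gene rows not allowed for log2 input: {dupes[:5]}"
            )
    return ExpressionMatrix(numeric, scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data
    if matrix.scale == SCALE_RAW:
        df = df.astype(np.int64)
        df.to_csv(path, sep=_sep_for(path))
    else:
        df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT)


def read_design(path: str | Path, reference: str = "") -> StudyDesign:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError("design file needs columns: sample, group")
    df = df.rename(columns=dict(zip(df.columns[:2], ["sample", "group"])))
    return StudyDesign(
        pd.Series(df["group"].to_numpy(), index=df["sample"]), reference=reference
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": design.sample_ids, "group": design.assignments.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSetModule]:
    """Parse a GMT file: name TAB description TAB gene1 TAB gene2 ...

    Duplicate genes within a record are dropped with a warning; a line with
    fewer than three fields is a format error reported with its line number.
    """
    modules: list[GeneSetModule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, source = fields[0].strip(), fields[1].strip()
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                key = harmonize_symbol(g)
                if key in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %r in module %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(key)
                genes.append(g)
            modules.append(GeneSetModule(name, tuple(genes), source))
    return modules


def write_gmt(modules: list[GeneSetModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.name, m.source or "."] + list(m.genes)) + "\n")


def read_registry(path: str | Path, vocabulary: tuple[str, ...] = ()) -> CategoryRegistry:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError("registry file needs columns: gene, category")
    df = df.rename(columns=dict(zip(df.columns[:2], ["gene", "category"])))
    return CategoryRegistry(df[["gene", "category"]], vocabulary)


def write_registry(registry: CategoryRegistry, path: str | Path) -> None:
    registry.table.to_csv(path, sep=_sep_for(path), index=False)


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Pathway registry CSV: pathway, gene, expected_direction in {+1, -1}."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 3:
        raise FormatError(
            "pathway file needs columns: pathway, gene, expected_direction"
        )
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["pathway", "gene", "expected_direction"]))
    )
    out: list[PathwayDefinition] = []
    for name, grp in df.groupby("pathway", sort=False):
        directions: dict[str, int] = {}
        for _, row in grp.iterrows():
            try:
                d = int(float(row["expected_direction"]))
            except ValueError as exc:
                raise FormatError(
                    f"pathway {name!r}: bad direction {row['expected_direction']!r}"
                ) from exc
            if d not in (1, -1):
                raise FormatError(
                    f"pathway {name!r}: expected_direction must be +1 or -1, got {d}"
                )
            key = harmonize_symbol(row["gene"])
            if key in directions:
                raise FormatError(f"pathway {name!r}: duplicate gene {row['gene']!r}")
            directions[key] = d
        out.append(PathwayDefinition(str(name), directions))
    return out


def write_pathways(pathways: list[PathwayDefinition], path: str | Path) -> None:
    rows = [
        {"pathway": p.name, "gene": g, "expected_direction": d}
        for p in pathways
        for g, d in p.directions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Standard output table: tab-separated, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
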