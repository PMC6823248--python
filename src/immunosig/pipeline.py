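"""Stage orchestration: chain the pipeline end to end and write one table
per stage plus a JSON run manifest.

Stages communicate through files in ``config.outdir`` so every stage can
also run standalone from the CLI.  A failing stage aborts the run with the
stage name and removes any partially written outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, enrich, gsva, io, pathways as pw
from .config import PipelineConfig, derive_seed
from .core import ImmunosigError, ValidationError
from .simulate import (
    human_disease_config,
    make_fixture_pathways,
    make_fixture_registry,
    simulate_bulk,
)

logger = logging.getLogger("immunosig")


class PipelineError(ImmunosigError):
    """A stage failed; message carries the stage name and cause."""


def _out(cfg: PipelineConfig, name: str) -> Path:
    return Path(cfg.outdir) / name


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    """Generate the demo experiment and register its files as the run inputs."""
    from dataclasses import replace

    sim = replace(cfg.sim, seed=derive_seed(cfg.seed, 0))
    matrix, truth, design = simulate_bulk(sim)
    registry, gmt = make_fixture_registry(sim)
    pathway_defs = make_fixture_pathways(sim)

    written = []
    for name, writer in (
        ("counts.tsv", lambda p: io.write_expression(matrix, p)),
        ("design.tsv", lambda p: io.write_design(design, p)),
        ("modules.gmt", lambda p: io.write_gmt(gmt, p)),
        ("registry_celltype.csv", lambda p: io.write_registry(registry, p)),
        ("pathways.csv", lambda p: io.write_pathways(pathway_defs, p)),
        ("truth_genes.tsv", lambda p: io.write_table(truth.genes, p)),
        ("truth_samples.tsv", lambda p: io.write_table(truth.samples, p)),
        ("truth_modules.tsv", lambda p: io.write_table(truth.modules, p)),
    ):
        path = _out(cfg, name)
        writer(path)
        written.append(path)
    cfg.counts = str(_out(cfg, "counts.tsv"))
    cfg.design = str(_out(cfg, "design.tsv"))
    cfg.gmt = str(_out(cfg, "modules.gmt"))
    cfg.registry_celltype = str(_out(cfg, "registry_celltype.csv"))
    cfg.pathways = str(_out(cfg, "pathways.csv"))
    cfg.counts_scale = "raw_counts"
    cfg.reference_group = "control"
    return written


def _default_path(cfg: PipelineConfig, attr: str, filename: str) -> None:
    """Unset input paths fall back to the simulate stage's outputs in outdir,
    so CLI stages chain through files without re-editing the config."""
    if not getattr(cfg, attr):
        candidate = _out(cfg, filename)
        if candidate.exists():
            setattr(cfg, attr, str(candidate))


def _resolve_defaults(cfg: PipelineConfig) -> None:
    _default_path(cfg, "counts", "counts.tsv")
    _default_path(cfg, "design", "design.tsv")
    _default_path(cfg, "gmt", "modules.gmt")
    _default_path(cfg, "registry_celltype", "registry_celltype.csv")
    _default_path(cfg, "pathways", "pathways.csv")
    if cfg.simulate and not cfg.reference_group:
        cfg.reference_group = "control"


def _load_inputs(cfg: PipelineConfig):
    _resolve_defaults(cfg)
    if not cfg.counts or not cfg.design:
        raise ValidationError("counts and design paths are required")
    matrix = io.read_expression(cfg.counts, cfg.counts_scale)
    design = io.read_design(cfg.design, reference=cfg.reference_group)
    return matrix, design


def stage_de(cfg: PipelineConfig) -> list[Path]:
    matrix, design = _load_inputs(cfg)
    log2 = diffexpr.normalize_log2(matrix)
    table = diffexpr.de_table(log2, design, cfg.de_fdr)
    path = _out(cfg, "de.tsv")
    io.write_table(table, path)
    return [path]


def _read_de(cfg: PipelineConfig) -> pd.DataFrame:
    path = _out(cfg, "de.tsv")
    if not path.exists():
        raise ValidationError("de.tsv not found; run the de stage first")
    return pd.read_csv(path, sep="\t")


def stage_score(cfg: PipelineConfig) -> list[Path]:
    _resolve_defaults(cfg)
    if not cfg.gmt:
        raise ValidationError("gmt path required for scoring")
    matrix, _ = _load_inputs(cfg)
    log2 = diffexpr.normalize_log2(matrix)
    modules = io.read_gmt(cfg.gmt)
    scores = gsva.score_matrix(log2, modules, cfg.tau, cfg.es_convention)
    path = _out(cfg, "scores.tsv")
    io.write_table(scores.es.reset_index(), path)
    return [path]


def stage_cellmap(cfg: PipelineConfig) -> list[Path]:
    _resolve_defaults(cfg)
    if not cfg.registry_celltype:
        raise ValidationError("registry_celltype path required for cellmap")
    table = _read_de(cfg)
    inc, dec = diffexpr.call_de(table, cfg.de_fdr)
    registry = io.read_registry(cfg.registry_celltype)
    counts = enrich.count_by_category(inc, dec, registry)
    path = _out(cfg, "cellmap.tsv")
    io.write_table(counts.reset_index(), path)
    return [path]


def stage_enrich(cfg: PipelineConfig) -> list[Path]:
    _resolve_defaults(cfg)
    table = _read_de(cfg)
    inc, dec = diffexpr.call_de(table, cfg.de_fdr)
    universe = table["gene"].tolist()
    registries = {}
    if cfg.registry_celltype:
        registries["celltype"] = io.read_registry(cfg.registry_celltype)
    if cfg.registry_functional:
        registries["functional"] = io.read_registry(cfg.registry_functional)
    if not registries:
        raise ValidationError("at least one registry is required for enrichment")
    report = enrich.run_enrichment(
        inc, dec, universe, registries, chi_p=cfg.chi_p, exact_p=cfg.go_p
    )
    path = _out(cfg, "enrichment.tsv")
    io.write_table(report, path)
    return [path]


def _profile_from_de(cfg: PipelineConfig, table: pd.DataFrame,
                     fdr: float) -> pd.DataFrame:
    defs = io.read_pathways(cfg.pathways)
    inc, dec = diffexpr.call_de(table, fdr)
    directions = {g: 1 for g in inc} | {g: -1 for g in dec}
    profile = pw.activation_z(directions, defs, table["gene"].tolist())
    sig = pw.significant_pathways(profile, cfg.z_cut, cfg.overlap_p)
    profile["significant"] = profile["pathway"].isin(sig["pathway"])
    return profile


def stage_pathwayz(cfg: PipelineConfig) -> list[Path]:
    _resolve_defaults(cfg)
    if not cfg.pathways:
        raise ValidationError("pathways path required for pathwayz")
    table = _read_de(cfg)
    profile = _profile_from_de(cfg, table, cfg.de_fdr)
    path = _out(cfg, "pathway_z.tsv")
    io.write_table(profile, path)
    return [path]


def stage_compare(cfg: PipelineConfig) -> list[Path]:
    """Concordance of the (mouse-style) profile with human-style tissue profiles.

    Human profiles come either from precomputed Z tables (``cfg.human_z``)
    or, in simulation mode, from freshly simulated disease-vs-control
    tissue datasets run through the same DE + activation-Z path.
    """
    path_profile = _out(cfg, "pathway_z.tsv")
    if not path_profile.exists():
        raise ValidationError("pathway_z.tsv not found; run pathwayz first")
    mouse_profile = pd.read_csv(path_profile, sep="\t")
    _resolve_defaults(cfg)

    human_profiles: dict[str, pd.DataFrame] = {}
    if cfg.human_z:
        for tissue, p in cfg.human_z.items():
            human_profiles[tissue] = pd.read_csv(p, sep="\t")
    elif cfg.simulate:
        for t in range(cfg.n_human_tissues):
            hcfg = human_disease_config(cfg.sim, seed=derive_seed(cfg.seed, 100 + t))
            hmatrix, _, hdesign = simulate_bulk(hcfg)
            # human symbols are upper-case; matching is case-folded anyway
            hmatrix.data.index = hmatrix.data.index.str.upper()
            log2 = diffexpr.normalize_log2(hmatrix)
            htable = diffexpr.de_table(log2, hdesign, cfg.human_de_fdr)
            human_profiles[f"tissue{t + 1}"] = _profile_from_de(
                cfg, htable, cfg.human_de_fdr
            )
    else:
        raise ValidationError(
            "compare needs human_z profiles (or simulate=True for the demo)"
        )

    per_pathway, summary = pw.concordance(
        mouse_profile, human_profiles, cfg.z_cut, cfg.overlap_p, cfg.min_tissues
    )
    out_tsv = _out(cfg, "concordance.tsv")
    io.write_table(per_pathway, out_tsv)
    out_json = _out(cfg, "concordance.json")
    clean = {
        k: (None if isinstance(v, float) and np.isnan(v) else v)
        for k, v in summary.items()
    }
    out_json.write_text(json.dumps(clean, indent=2, sort_keys=True))
    return [out_tsv, out_json]


STAGES = (
    ("simulate", stage_simulate),
    ("de", stage_de),
    ("score", stage_score),
    ("cellmap", stage_cellmap),
    ("enrich", stage_enrich),
    ("pathwayz", stage_pathwayz),
    ("compare", stage_compare),
)


def write_manifest(cfg: PipelineConfig, outputs: list[Path]) -> Path:
    import pandas, scipy

    manifest = {
        "config": cfg.to_dict(),
        "outputs": sorted(str(p) for p in outputs),
        "versions": {
            "immunosig": __version__,
            "numpy": np.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = _out(cfg, "manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_pipeline(cfg: PipelineConfig) -> list[Path]:
    """Run every applicable stage; returns the written output paths."""
    cfg.validate()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, stage in STAGES:
        if name == "simulate" and not cfg.simulate:
            continue
        if name == "compare" and not (cfg.simulate or cfg.human_z):
            logger.info("no human profiles configured; compare stage skipped")
            continue
        try:
            written.extend(stage(cfg))
        except Exception as exc:
            for p in written:
                Path(p).unlink(missing_ok=True)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    written.append(write_manifest(cfg, written))
    return written


def replay(manifest_path: str | Path) -> list[Path]:
    """Re-execute a run from its manifest alone."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(cfg)
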