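"""Synthetic two-group bulk splenocyte RNA-seq with known ground truth.

The generator emulates a control-vs-treated splenocyte experiment in which
treatment ablates specific immune populations.  Each cell module c carries
a baseline latent proportion ``pi_c`` that treatment multiplies by
``kappa_c`` (the remainder of the composition is unmodelled "other"
tissue).  Marker genes of module c are elevated ``lambda``-fold in their
own cell type, so their bulk mean scales with the latent proportion:

    mu_ij = L_j * b_i * (1 + (lambda - 1) * pi_{c(i),j})      marker gene
    mu_ij = L_j * b_i                                         otherwise

with an extra factor ``2**delta_i`` for direct-effect genes in treated
samples.  Counts are negative binomial with variance ``mu + phi mu^2``
(Poisson at phi = 0).  Every latent quantity is recorded so downstream
stages can be scored against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    SCALE_RAW,
    CategoryRegistry,
    ExpressionMatrix,
    GeneSetModule,
    StudyDesign,
    ValidationError,
)

logger = logging.getLogger("immunosig")


@dataclass(frozen=True)
class CellModule:
    """One simulated immune population: markers, abundance, treatment effect."""

    name: str
    n_markers: int
    proportion: float  # baseline (control) latent proportion pi_c
    kappa: float       # treatment multiplier on pi_c

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValidationError(f"module {self.name}: n_markers must be >= 1")
        if not (0 < self.proportion < 1):
            raise ValidationError(f"module {self.name}: proportion must be in (0,1)")
        if not (self.kappa > 0):
            raise ValidationError(f"module {self.name}: kappa must be > 0")


def default_modules() -> tuple[CellModule, ...]:
    """The demo splenocyte composition: PC/GC/Tfh ablated hard (kappa 0.2),
    B and myeloid compartments reduced more mildly (kappa 0.6)."""
    return (
        CellModule("PC", 20, 0.05, 0.2),
        CellModule("GC", 20, 0.05, 0.2),
        CellModule("Tfh", 20, 0.05, 0.2),
        CellModule("B", 20, 0.40, 0.6),
        CellModule("Myeloid", 20, 0.10, 0.6),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment (defaults = demo conditions)."""

    n_genes: int = 2000
    n_control: int = 4
    n_treated: int = 4
    modules: tuple[CellModule, ...] = field(default_factory=default_modules)
    marker_fold: float = 10.0       # lambda: marker mean fold-up in its own cell type
    baseline_sigma: float = 1.0     # sd of log baseline abundance b_i
    dispersion: float = 0.01        # phi: NB variance = mu + phi mu^2
                                    # (BCV 0.1, genetically identical mice)
    n_direct: int = 100             # direct-effect genes (half up, half down)
    direct_lfc: float = 1.0         # |delta|, log2 units
    library_size: float = 1.0e6
    library_sigma: float = 0.2      # sd of log library size
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_control < 1 or self.n_treated < 1:
            raise ValidationError("n_genes and group sizes must be positive")
        if not (self.marker_fold > 1):
            raise ValidationError("marker_fold (lambda) must be > 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion (phi) must be >= 0")
        if self.n_direct < 0 or self.direct_lfc < 0:
            raise ValidationError("direct-effect settings must be non-negative")
        if self.library_size <= 0 or self.library_sigma < 0:
            raise ValidationError("library size settings invalid")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValidationError("module names must be unique")
        total = sum(m.proportion for m in self.modules)
        if total > 1:
            raise ValidationError(
                f"baseline proportions sum to {total:.3f} > 1"
            )
        treated = sum(m.proportion * m.kappa for m in self.modules)
        if treated > 1:
            raise ValidationError(
                f"treated proportions sum to {treated:.3f} > 1 after perturbation"
            )
        n_markers = sum(m.n_markers for m in self.modules)
        if n_markers + self.n_direct > self.n_genes:
            raise ValidationError("markers + direct-effect genes exceed n_genes")


@dataclass
class GroundTruth:
    """Latent state of one simulated experiment.

    ``genes``: per-gene module membership, direct effect delta, baseline b_i.
    ``samples``: group, library size and latent module proportions per sample.
    ``modules``: kappa, baseline proportion and the expected treated/control
    marker-mean ratio per module.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    modules: pd.DataFrame
    config: SimulationConfig

    def expected_mean(self) -> pd.DataFrame:
        """The exact NB mean matrix mu (genes x samples) implied by the latents."""
        b = self.genes["baseline"].to_numpy()
        L = self.samples["library_size"].to_numpy()
        mu = np.outer(b, L)
        lam = self.config.marker_fold
        for mod in self.config.modules:
            rows = (self.genes["module"] == mod.name).to_numpy()
            pi = self.samples[f"pi_{mod.name}"].to_numpy()
            mu[rows] *= 1.0 + (lam - 1.0) * pi[None, :]
        treated = (self.samples["group"] == "treated").to_numpy()
        delta = self.genes["delta"].to_numpy()
        mu[:, treated] *= (2.0 ** delta)[:, None]
        return pd.DataFrame(
            mu, index=self.genes["gene"], columns=self.samples["sample"]
        )


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Gene id list, per-gene module labels, per-gene delta."""
    names: list[str] = []
    module_of: list[str] = []
    for mod in config.modules:
        for k in range(mod.n_markers):
            names.append(f"{mod.name}m{k + 1:03d}")
            module_of.append(mod.name)
    delta = np.zeros(config.n_genes)
    n_up = config.n_direct // 2
    for k in range(config.n_direct):
        names.append(f"Deg{k + 1:04d}")
        module_of.append("")
        delta[len(names) - 1] = config.direct_lfc if k < n_up else -config.direct_lfc
    for k in range(config.n_genes - len(names)):
        names.append(f"Bkg{k + 1:05d}")
        module_of.append("")
    return names, module_of, delta


def simulate_bulk(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth, StudyDesign]:
    """Draw one synthetic experiment; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, module_of, delta = _gene_names(config)

    # baseline relative abundances, normalized to sum to 1
    b = rng.lognormal(0.0, config.baseline_sigma, config.n_genes)
    b /= b.sum()

    n_c, n_t = config.n_control, config.n_treated
    sample_ids = [f"C{j + 1}" for j in range(n_c)] + [f"T{j + 1}" for j in range(n_t)]
    groups = ["control"] * n_c + ["treated"] * n_t
    # mean-centered log-normal library sizes around the nominal depth
    sig = config.library_sigma
    L = config.library_size * rng.lognormal(-0.5 * sig**2, sig, n_c + n_t)

    mu = np.outer(b, L)
    lam = config.marker_fold
    pi_cols = {}
    for mod in config.modules:
        pi = np.array(
            [mod.proportion] * n_c + [mod.proportion * mod.kappa] * n_t
        )
        pi_cols[f"pi_{mod.name}"] = pi
        rows = np.array([m == mod.name for m in module_of])
        mu[rows] *= 1.0 + (lam - 1.0) * pi[None, :]
    treated_mask = np.array([g == "treated" for g in groups])
    mu[:, treated_mask] *= (2.0 ** delta)[:, None]

    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=names, columns=sample_ids), SCALE_RAW
    )
    design = StudyDesign.from_mapping(
        dict(zip(sample_ids, groups)), reference="control", treatment="treated"
    )
    genes = pd.DataFrame(
        {"gene": names, "module": module_of, "delta": delta, "baseline": b}
    )
    samples = pd.DataFrame(
        {"sample": sample_ids, "group": groups, "library_size": L, **pi_cols}
    )
    modules = pd.DataFrame(
        {
            "module": [m.name for m in config.modules],
            "proportion": [m.proportion for m in config.modules],
            "kappa": [m.kappa for m in config.modules],
            "expected_ratio": [
                (1.0 + (lam - 1.0) * m.kappa * m.proportion)
                / (1.0 + (lam - 1.0) * m.proportion)
                for m in config.modules
            ],
        }
    )
    truth = GroundTruth(genes, samples, modules, config)
    return matrix, truth, design


def make_fixture_pathways(config: SimulationConfig):
    """Synthetic pathway registry with per-gene expected activation directions.

    Immune pathways are built from the ablated modules' markers (all +1:
    the member transcripts rise when the pathway is active), a xenobiotic-
    metabolism pathway from the up-regulated direct-effect genes, and a
    null housekeeping pathway from background genes.  In a treated-vs-
    control contrast the immune pathways should come out suppressed
    (Z <= -2) and the null pathway near zero.
    """
    from .pathways import PathwayDefinition

    config.validate()
    names, module_of, delta = _gene_names(config)
    by_module: dict[str, list[str]] = {}
    for g, m in zip(names, module_of):
        if m:
            by_module.setdefault(m, []).append(g)

    def updirs(genes):
        return {g.upper(): 1 for g in genes}

    defs: list[PathwayDefinition] = []
    have = by_module.keys()
    if {"B", "PC"} <= have:
        defs.append(PathwayDefinition(
            "BCR signaling (synthetic)", updirs(by_module["B"] + by_module["PC"])))
    if {"GC", "Tfh"} <= have:
        defs.append(PathwayDefinition(
            "Germinal center reaction (synthetic)",
            updirs(by_module["GC"] + by_module["Tfh"])))
    if "PC" in have:
        defs.append(PathwayDefinition(
            "Plasma cell differentiation (synthetic)", updirs(by_module["PC"])))
    if "Myeloid" in have:
        defs.append(PathwayDefinition(
            "Myeloid inflammation (synthetic)", updirs(by_module["Myeloid"])))
    up_direct = [g for g, d in zip(names, delta) if d > 0]
    if up_direct:
        defs.append(PathwayDefinition(
            "Xenobiotic metabolism (synthetic)", updirs(up_direct)))
    background = [g for g, m, d in zip(names, module_of, delta) if not m and d == 0]
    if len(background) >= 30:
        defs.append(PathwayDefinition(
            "Housekeeping (synthetic)", updirs(background[:30])))
    return defs


def human_disease_config(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Demo analog of a human disease-vs-control tissue dataset.

    The same gene panel, but disease *elevates* the immune populations the
    mouse treatment ablates (multiplier 2 for strongly ablated modules,
    1.3 for mildly ablated ones), so pathways suppressed by treatment come
    out activated here — the cross-dataset concordance pattern.
    """
    modules = tuple(
        replace(m, kappa=2.0 if m.kappa < 0.5 else 1.3) for m in config.modules
    )
    cfg = replace(config, modules=modules, seed=seed)
    cfg.validate()
    return cfg


def make_fixture_registry(
    config: SimulationConfig,
) -> tuple[CategoryRegistry, list[GeneSetModule]]:
    """Marker-gene registry and matching GMT for the configured modules.

    Marker genes map to their module's category; non-markers stay unmapped.
    The GMT records and the registry agree gene-for-gene.
    """
    config.validate()
    names, module_of, _ = _gene_names(config)
    rows = [
        {"gene": g, "category": m} for g, m in zip(names, module_of) if m
    ]
    registry = CategoryRegistry(
        pd.DataFrame(rows), vocabulary=tuple(m.name for m in config.modules)
    )
    gmt = [
        GeneSetModule(
            mod.name,
            tuple(g for g, m in zip(names, module_of) if m == mod.name),
            source="synthetic splenocyte markers",
        )
        for mod in config.modules
    ]
    return registry, gmt
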