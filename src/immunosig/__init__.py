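"""immunosig: immune transcriptomic signature analysis.

A reusable pipeline for two-group bulk RNA-seq of immune tissue:
negative-binomial splenocyte simulation with ground truth, empirical-Bayes
moderated-t differential expression, GSVA-style single-sample gene-module
scores, hematopoietic/functional category enrichment, and directional
pathway activation Z-scores with cross-dataset concordance.
"""

__version__ = "0.1.0"

from .core import (  # noqa: F401
    CategoryRegistry,
    ExpressionMatrix,
    FormatError,
    GeneSetModule,
    ImmunosigError,
    StudyDesign,
    ValidationError,
    harmonize_symbol,
)
from .config import PipelineConfig  # noqa: F401
from .diffexpr import (  # noqa: F401
    VariancePrior,
    bh_fdr,
    call_de,
    de_table,
    estimate_prior,
    fit_two_group,
    moderate,
    normalize_log2,
)
from .enrich import (  # noqa: F401
    chisq_enrich,
    count_by_category,
    exact_overlap_enrich,
    run_enrichment,
)
from .estimators import GSVAScorer, ModeratedTTest  # noqa: F401
from .gsva import kernel_cdf_stats, rank_stats, score_matrix, walk_es  # noqa: F401
from .pathways import (  # noqa: F401
    PathwayDefinition,
    activation_z,
    concordance,
    significant_pathways,
)
from .pipeline import run_pipeline, replay  # noqa: F401
from .simulate import (  # noqa: F401
    CellModule,
    SimulationConfig,
    make_fixture_pathways,
    make_fixture_registry,
    simulate_bulk,
)


def packaged_modules_path() -> str:
    """Path to the packaged GMT with the printed GC and Tfh modules (and a
    synthetic plasma-cell placeholder the user should replace)."""
    from importlib.resources import files

    return str(files("immunosig.data") / "immune_modules.gmt")
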