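"""hscage: aging-heterogeneity analytics for hematopoietic stem cells.

Per-cell aging scoring of single-cell RNA-seq, a staged surface-marker
prioritization cascade, marker-correlated feature-gene derivation, linear
DNA-methylation age prediction, and competitive-transplantation / lifespan
cohort statistics — with a seeded synthetic-data generator that plants
recoverable ground truth for every stage.
"""

from importlib import resources

from .datatypes import (
    CellMatrix,
    ClockModel,
    CohortTables,
    FormatError,
    GeneAnnotation,
    MethylationMatrix,
    NormalizedMatrix,
    PeakTable,
    ValidationError,
)
from .pipeline import RunConfig, RunReport, run_all
from .synthgen import (
    SimConfig,
    TruthBundle,
    generate_bulk_quartiles,
    generate_cohort,
    generate_methylation,
    generate_sc,
)

__version__ = "0.1.0"


def load_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """Default S-phase and G2/M gene lists (mouse-cased stand-in fixtures)."""

    def read(name):
        text = resources.files("hscage.data").joinpath(name).read_text()
        return [g.strip() for g in text.splitlines() if g.strip() and not g.startswith("#")]

    return read("s_genes.txt"), read("g2m_genes.txt")


__all__ = [
    "CellMatrix",
    "ClockModel",
    "CohortTables",
    "FormatError",
    "GeneAnnotation",
    "MethylationMatrix",
    "NormalizedMatrix",
    "PeakTable",
    "RunConfig",
    "RunReport",
    "SimConfig",
    "TruthBundle",
    "ValidationError",
    "generate_bulk_quartiles",
    "generate_cohort",
    "generate_methylation",
    "generate_sc",
    "load_cell_cycle_genes",
    "run_all",
]
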