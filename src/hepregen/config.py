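"""Simulation configuration shared by every synthetic-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field

#: The eight transplantation samples in chronological order: the adult baseline,
#: the first-round timecourse (1/3/6/12 weeks) and the second-round serial
#: transplantation timecourse (3/6/12 weeks).
DEFAULT_TIMEPOINTS = (
    "R0_0W",
    "R1_1W",
    "R1_3W",
    "R1_6W",
    "R1_12W",
    "R2_3W",
    "R2_6W",
    "R2_12W",
)

#: Hepatocyte state groups of the transplantation model: resident adult
#: hepatocytes, the two Afp-low reprogrammed states (quiescent and cycling),
#: the Afp-high detoxifying state, and injured host hepatocytes.
DEFAULT_GROUP_SIZES = {
    "Adult": 400,
    "Afp_low": 400,
    "Afp_low_cycling": 250,
    "Afp_high": 300,
    "Host": 300,
}


@dataclass
class SimConfig:
    """Parameters controlling all synthetic inputs.

    Attributes
    ----------
    seed
        Master seed. A fixed seed makes every generator byte-reproducible.
    n_cells_per_layer
        Cells simulated per lobule layer in the zonated reference.
    n_layers
        Number of lobule layers; the zonation classifier contract requires 8.
    noise_sd
        Per-cell Gaussian noise standard deviation applied on the log scale
        before counts are drawn.
    n_background_genes
        Genes with no planted structure, shared by all generators.
    group_sizes
        Cells per hepatocyte state group.
    timepoints
        Ordered sample names of the transplantation timecourse.
    effect_size
        Magnitude of every planted signal (log-scale gradient ranges, group
        offsets, regulon enrichments). Zero yields a global null.
    n_ars_genes
        Size of the planted reprogramming signature (default mirrors a
        realistic signature size of 78 genes).
    n_cycling_genes
        Genes elevated only in the cycling state.
    module_size
        Size of the planted co-expression module anchored on Afp.
    n_cells_per_sample
        Cells per timecourse sample when expression is generated.
    n_pathways
        Pathway activity profiles in the timecourse (1 planted + decoys).
    pathway_size
        Genes per pathway gene set in timecourse expression.
    """

    seed: int = 0
    n_cells_per_layer: int = 150
    n_layers: int = 8
    noise_sd: float = 0.3
    n_background_genes: int = 300
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    timepoints: tuple = DEFAULT_TIMEPOINTS
    effect_size: float = 3.0
    n_ars_genes: int = 78
    n_cycling_genes: int = 20
    module_size: int = 200
    n_cells_per_sample: int = 500
    n_pathways: int = 21
    pathway_size: int = 30

    def validate(self) -> None:
        if self.n_cells_per_layer < 1:
            raise ValueError("n_cells_per_layer must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_background_genes < 1:
            raise ValueError("n_background_genes must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if len(self.timepoints) != len(set(self.timepoints)):
            raise ValueError("timepoint names must be unique")
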