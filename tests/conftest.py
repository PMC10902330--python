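import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from wormclock import (
    GeneModel,
    circadian_design,
    make_gene_specs,
    simulate_expression,
    simulate_genome,
    MotifDef,
)

RORE = MotifDef("RORE", "WAWNTRGGTCA")


@pytest.fixture(scope="session")
def circ_matrix_truth():
    """Medium circadian-design matrix with a planted rhythmic fraction."""
    design = circadian_design(seed=11, noise_sd=0.25)
    return simulate_expression(design, n_genes=300, frac_rhythmic=0.3)


@pytest.fixture(scope="session")
def toy_genome():
    """Small toy genome: 30 'magenta' genes always carrying a RORE, 30 without."""
    clusters = ["magenta"] * 30 + ["none"] * 30
    specs = make_gene_specs(clusters, n_exons=2, exon_length=150, intron_length=250)
    genome, models, truth = simulate_genome(
        specs,
        motifs=[RORE],
        placement_probs={"magenta": 1.0, "none": 0.0},
        seed=5,
    )
    return genome, models, truth, specs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
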