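import numpy as np
import pytest

from mpratag.library import VariantPair, build_constructs
from mpratag.simulate import SimulationParams, simulate_counts, simulate_library

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pairs():
    """Three deterministic variant pairs: two SNVs and one indel."""
    f = [
        ("AGTCAGTCAGTCAGTCAGTCAGTCA", "TGCATGCATGCATGCATGCATGCAT"),
        ("CCCCAAAATTTTGGGGCCCCAAAAT", "GGGGTTTTAAAACCCCGGGGTTTTA"),
        ("ACACACACACACACACACACACACA", "GTGTGTGTGTGTGTGTGTGTGTGTG"),
    ]
    return [
        VariantPair(
            variant_id="chr10:118707481G>C",
            chrom="chr10",
            pos=118707481,
            ancestral_allele="G",
            derived_allele="C",
            flank5=f[0][0],
            flank3=f[0][1],
            tf_name="AP-1",
        ),
        VariantPair(
            variant_id="chr2:9983591AG>A",
            chrom="chr2",
            pos=9983591,
            ancestral_allele="AG",
            derived_allele="A",
            flank5=f[1][0],
            flank3=f[1][1],
            tf_name="KLF",
        ),
        VariantPair(
            variant_id="chr6:20212662G>T",
            chrom="chr6",
            pos=20212662,
            ancestral_allele="G",
            derived_allele="T",
            flank5=f[2][0],
            flank3=f[2][1],
            tf_name="REP",
        ),
    ]


@pytest.fixture
def small_constructs(small_pairs):
    return build_constructs(small_pairs)


@pytest.fixture
def sim_small():
    """A small but complete simulated dataset (library + counts + truth)."""
    params = SimulationParams(
        n_variants=4,
        n_cell_lines=2,
        n_replicates=6,
        depth_rtplus=30_000,
        depth_dna=30_000,
        activity_ratios=[1.0, 2.0, 1.0, 0.5],
        seed=7,
    )
    library = simulate_library(params)
    samples, truth = simulate_counts(library, params)
    return params, library, samples, truth
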