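import numpy as np
import pytest

from maspect.genome import ReferenceGenome, encode_sequence
from maspect.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_lines,
)


def genome_from_seqs(seqs: dict, exclude=None) -> ReferenceGenome:
    """Build an in-memory reference from {name: sequence string}.

    ``exclude`` maps chromosome name to a list of (start, end) 1-based
    inclusive intervals to mask out.
    """
    names = list(seqs)
    codes = {n: encode_sequence(s) for n, s in seqs.items()}
    mask = {n: np.ones(len(s), dtype=bool) for n, s in seqs.items()}
    for chrom, ivals in (exclude or {}).items():
        for start, end in ivals:
            mask[chrom][start - 1 : end] = False
    return ReferenceGenome(names=names, seqs=codes, mask=mask)


@pytest.fixture(scope="session")
def clean_config():
    """Small genome carrying study-scale counts, no markers/dropout/spikes:
    classification should reproduce simulator truth exactly (barring rare
    position collisions, which the truth records)."""
    return SimulationConfig(
        genome_length_bp=300_000,
        rate_denominator_bp=12.47e6,
        n_markers={},
        dropout={},
        n_low_quality_per_line=0,
    )


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return generate_genome(clean_config, seed=11)


@pytest.fixture(scope="session")
def clean_experiment(clean_config, clean_bundle):
    return simulate_lines(clean_bundle, clean_config, seed=12)


@pytest.fixture(scope="session")
def qc_config():
    """Configuration with ancestral markers, dropout, and low-quality
    spike-ins, for the error-rate and filtering paths."""
    return SimulationConfig(
        genome_length_bp=200_000,
        rate_denominator_bp=12.47e6,
        n_lines=40,
        n_markers={"SNM": 40, "insertion": 60, "deletion": 21},
        n_low_quality_per_line=3,
    )


@pytest.fixture(scope="session")
def qc_bundle(qc_config):
    return generate_genome(qc_config, seed=21)


@pytest.fixture(scope="session")
def qc_experiment(qc_config, qc_bundle):
    return simulate_lines(qc_bundle, qc_config, seed=22)
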