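"""Shared fixtures: synthetic genomes and an intron factory.

All genomes are generated in-process from fixed seeds; no test reads external
data.  The recovery genome is sized so the planted intron statistics can be
checked at better than a thousand introns.
"""

from __future__ import annotations

import pytest

from intron_constraint import genome_io, synthetic_data


@pytest.fixture(scope="session")
def stranded_genome():
    """Small genome with 50% minus-strand genes and boosted UTR-intron rate,
    for strand handling, UTR compartments and round-trip checks."""
    config = synthetic_data.SimulationConfig(
        seed=11, n_genes=150, minus_strand_fraction=0.5, utr5_intron_rate=0.08
    )
    return synthetic_data.generate(config)


@pytest.fixture(scope="session")
def stranded_introns(stranded_genome):
    return genome_io.extract_introns(stranded_genome.annotation)


@pytest.fixture(scope="session")
def default_genome():
    """Moderate genome at default (study) conditions."""
    return synthetic_data.generate(synthetic_data.SimulationConfig(seed=7, n_genes=400))


@pytest.fixture(scope="session")
def default_introns(default_genome):
    return genome_io.extract_introns(default_genome.annotation, include_pseudo=False)


@pytest.fixture(scope="session")
def recovery_genome():
    """Genome at default conditions sized for >= 1000 planted CDS introns."""
    return synthetic_data.generate(
        synthetic_data.SimulationConfig(seed=101, n_genes=6700)
    )


@pytest.fixture()
def mk():
    """Factory for standalone introns used in unit tests."""

    def make_intron(
        sequence: str,
        phase: int | None = 0,
        compartment: str = "CDS",
        gene_id: str = "g",
        ordinal: int = 1,
        start: int = 1,
        strand: str = "+",
    ) -> genome_io.Intron:
        return genome_io.Intron(
            gene_id=gene_id,
            ordinal=ordinal,
            start=start,
            end=start + len(sequence) - 1,
            sequence=sequence,
            phase=phase,
            compartment=compartment,
            chromosome="chr1",
            strand=strand,
        )

    return make_intron
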