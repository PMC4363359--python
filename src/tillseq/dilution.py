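"""Closed-form pool-dilution arithmetic.

These are the sanity checks run before committing a pooling design: how
many template copies each individual contributes to a PCR given the DNA
mass and genome size, the allele frequency at which a single carrier is
expected to appear in a pool, and the molarity-to-molecule conversion
used when diluting libraries for template preparation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Zygosity",
    "PoolDilution",
    "copies_per_allele",
    "expected_variant_frequency",
    "molecules_per_microliter",
]

AVOGADRO = 6.02214076e23  # molecules per mole

# Flax (Linum usitatissimum) diploid genome mass in picograms.
FLAX_GENOME_2C_PG = 0.764


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"

    @property
    def allele_dose(self) -> int:
        """Mutant allele copies carried by a diploid individual (1 or 2)."""
        return 1 if self is Zygosity.HET else 2


@dataclass(frozen=True)
class PoolDilution:
    """One individual's DNA entering a pool.

    dna_mass_per_individual in ng, genome_2c (diploid genome mass) in pg.
    """

    dna_mass_per_individual: float
    genome_2c: float = FLAX_GENOME_2C_PG
    pool_size: int = 96

    def __post_init__(self) -> None:
        if self.dna_mass_per_individual <= 0:
            raise ValueError("dna_mass_per_individual must be > 0")
        if self.genome_2c <= 0:
            raise ValueError("genome_2c must be > 0")
        if not isinstance(self.pool_size, int) or self.pool_size < 1:
            raise ValueError("pool_size must be a positive integer")


def copies_per_allele(d: PoolDilution) -> float:
    """Template copies per allele contributed by one individual to the pool.

    The DNA mass (converted to pg) divided by the diploid genome mass 2C
    counts genome copies; dividing by the pool size gives each
    individual's share.  Reported to one decimal place: 10 ng of flax DNA
    (2C = 0.764 pg) yields 204.5 copies at a 1-in-64 dilution and 136.3
    at 1-in-96 — comfortably above the ~40-copy floor below which
    stochastic template loss becomes a concern.
    """
    mass_pg = d.dna_mass_per_individual * 1000.0
    return round(mass_pg / d.genome_2c / d.pool_size, 1)


def expected_variant_frequency(pool_size: int, zygosity: Zygosity) -> float:
    """Expected allele frequency of a single carrier in an equimolar pool.

    A homozygote contributes 2 of the pool's ``2 * pool_size`` allele
    copies (1/pool_size, ~1% at 96); a heterozygote half that (~0.5%).
    """
    if not isinstance(pool_size, int) or pool_size < 1:
        raise ValueError("pool_size must be a positive integer")
    zygosity = Zygosity(zygosity)
    return zygosity.allele_dose / (2.0 * pool_size)


def molecules_per_microliter(concentration_pm: float) -> float:
    """Convert a picomolar DNA concentration to molecules per microliter.

    ``c[pM] * 1e-12 mol/L * N_A / 1e6 uL/L``.  At the 26 pM template
    concentration commonly targeted for Ion Torrent template prep this
    gives 1.566e7 molecules/uL (protocol sheets often quote the slightly
    lower round figure 15.5e6; the Avogadro-derived value is returned).
    """
    if concentration_pm < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_pm * 1e-12 * AVOGADRO / 1e6
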